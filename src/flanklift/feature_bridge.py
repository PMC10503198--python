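"""Turn SNPs into parent/child flank features and map projections back to SNPs.

A SNP at 1-based position ``pos`` with flank length ``L`` becomes a parent
window ``[max(1, pos-L), min(chrom_len, pos+L)]`` (2L+1 bases when
untruncated, SNP base included) and a 1-bp child at ``pos``.  Feature IDs
are ``snp<index>_flank<L>`` with ``index`` the 0-based input order, so
reruns on the same input are reproducible and the ID alone recovers the
originating SNP.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from .assembly_io import Assembly, SnpRecord

__all__ = [
    "FlankFeature",
    "LiftOutcome",
    "build_flank_features",
    "default_flank_set",
    "validate_flank_set",
    "feature_to_snp",
    "make_feature_id",
    "parse_feature_id",
    "DEFAULT_MIN_ALIGN_LEN",
]

#: Minimum alignable parent length (bases) below which a window is pre-flagged.
DEFAULT_MIN_ALIGN_LEN = 100

_ID_RE = re.compile(r"^snp(\d+)_flank(\d+)$")


def make_feature_id(snp_index: int, flank_len: int) -> str:
    return f"snp{snp_index}_flank{flank_len}"


def parse_feature_id(feature_id: str) -> Tuple[int, int]:
    """Return (snp_index, flank_len) encoded in a feature ID."""
    m = _ID_RE.match(feature_id)
    if not m:
        raise ValueError(f"unparseable feature ID {feature_id!r}")
    return int(m.group(1)), int(m.group(2))


@dataclass
class FlankFeature:
    """A parent window plus its 1-bp child, 1-based inclusive coordinates."""

    feature_id: str
    snp: Optional[SnpRecord]
    chrom: str
    flank_len: int
    parent_start: int
    parent_end: int
    child_pos: int
    truncated_left: bool = False
    truncated_right: bool = False
    too_short: bool = False
    error: Optional[str] = None  # e.g. "chrom_missing"

    @property
    def parent_length(self) -> int:
        return self.parent_end - self.parent_start + 1

    def parent_sequence(self, assembly: Assembly) -> str:
        return assembly.fetch(self.chrom, self.parent_start - 1, self.parent_end)


@dataclass
class LiftOutcome:
    """A per-(SNP, flank-length) projection result, resolved back to the SNP."""

    snp: SnpRecord
    snp_index: int
    flank_len: int
    status: str  # "lifted" or one of the unlifted statuses
    target_chrom: Optional[str] = None
    target_pos: Optional[int] = None  # 1-based
    target_strand: Optional[str] = None
    identity: Optional[float] = None
    coverage: Optional[float] = None
    truncated_left: bool = False
    truncated_right: bool = False

    @property
    def lifted(self) -> bool:
        return self.status == "lifted"

    @property
    def location(self) -> Optional[Tuple[str, int, str]]:
        if not self.lifted:
            return None
        return (self.target_chrom, self.target_pos, self.target_strand)


def default_flank_set() -> List[int]:
    """The four flank lengths assessed by default: 500, 1000, 1250 and 1980 bp."""
    return [500, 1000, 1250, 1980]


def validate_flank_set(
    flank_set: Sequence[int], min_align_len: int = DEFAULT_MIN_ALIGN_LEN
) -> List[int]:
    """Sort, deduplicate and sanity-check a flank set.

    Flank lengths whose untruncated window (2L+1) falls below the minimum
    alignable length trigger a warning: every untruncated parent at that
    length would violate the alignability floor.
    """
    if not flank_set:
        raise ValueError("flank set must be non-empty")
    cleaned = sorted(set(int(L) for L in flank_set))
    if any(L < 1 for L in cleaned):
        raise ValueError("flank lengths must be >= 1")
    for L in cleaned:
        if 2 * L + 1 < min_align_len:
            warnings.warn(
                f"flank length {L}: window 2*{L}+1={2 * L + 1} bp is below the "
                f"{min_align_len} bp alignability floor; all untruncated parents "
                "will be flagged too_short",
                stacklevel=2,
            )
    return cleaned


def build_flank_features(
    snps: Iterable[SnpRecord],
    flank_len: int,
    assembly: Assembly,
    min_align_len: int = DEFAULT_MIN_ALIGN_LEN,
    start_index: int = 0,
) -> Iterator[FlankFeature]:
    """Yield exactly one :class:`FlankFeature` per SNP at the given flank length.

    A SNP whose chromosome is absent from ``assembly`` yields a feature with
    ``error="chrom_missing"`` rather than raising.  Windows clamped at
    sequence ends carry truncation flags; windows shorter than
    ``min_align_len`` are flagged ``too_short`` but still emitted.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    lengths = assembly.lengths
    for i, snp in enumerate(snps, start=start_index):
        fid = make_feature_id(i, flank_len)
        if snp.chrom not in lengths:
            yield FlankFeature(
                feature_id=fid,
                snp=snp,
                chrom=snp.chrom,
                flank_len=flank_len,
                parent_start=snp.pos,
                parent_end=snp.pos,
                child_pos=snp.pos,
                error="chrom_missing",
            )
            continue
        chrom_len = lengths[snp.chrom]
        start = max(1, snp.pos - flank_len)
        end = min(chrom_len, snp.pos + flank_len)
        feat = FlankFeature(
            feature_id=fid,
            snp=snp,
            chrom=snp.chrom,
            flank_len=flank_len,
            parent_start=start,
            parent_end=end,
            child_pos=snp.pos,
            truncated_left=start > snp.pos - flank_len,
            truncated_right=end < snp.pos + flank_len,
        )
        if feat.parent_length < min_align_len:
            feat.too_short = True
        yield feat


def feature_to_snp(projected, features_by_id: Dict[str, FlankFeature]) -> LiftOutcome:
    """Resolve a projected feature back to its SNP via the feature ID.

    ``projected`` is a :class:`~flanklift.projection_engine.ProjectedFeature`.
    An unknown feature ID indicates pipeline corruption and raises ``KeyError``.
    """
    if projected.feature_id not in features_by_id:
        raise KeyError(f"unknown feature ID {projected.feature_id!r}")
    feat = features_by_id[projected.feature_id]
    if feat.snp is None:
        raise KeyError(f"feature {projected.feature_id!r} has no stored SNP record")
    snp_index, flank_len = parse_feature_id(projected.feature_id)
    return LiftOutcome(
        snp=feat.snp,
        snp_index=snp_index,
        flank_len=flank_len,
        status=projected.status,
        target_chrom=projected.target_chrom,
        target_pos=projected.target_pos,
        target_strand=projected.target_strand,
        identity=projected.identity,
        coverage=projected.coverage,
        truncated_left=feat.truncated_left,
        truncated_right=feat.truncated_right,
    )
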