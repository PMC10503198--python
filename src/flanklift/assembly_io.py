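"""Reading and writing FASTA / VCF / GFF3 under one explicit coordinate convention.

External coordinates (VCF, GFF3, user-facing positions) are 1-based
inclusive; everything internal is 0-based half-open.  :func:`to_internal`
and :func:`to_external` are the only two conversion points.

The VCF layer is deliberately minimal: it owns CHROM/POS/ID/REF/ALT/INFO
and carries QUAL, FILTER, FORMAT and genotype columns through verbatim as
opaque text (no FORMAT parsing, per the tool's contract).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

__all__ = [
    "Assembly",
    "SnpRecord",
    "FastaFormatError",
    "VcfFormatError",
    "GffFormatError",
    "read_fasta",
    "write_fasta",
    "VcfReader",
    "read_vcf",
    "write_vcf",
    "read_gff3",
    "write_gff3",
    "to_internal",
    "to_external",
    "revcomp",
]

_VALID_RESIDUES = frozenset("ACGTNRYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


class FastaFormatError(ValueError):
    pass


class VcfFormatError(ValueError):
    pass


class GffFormatError(ValueError):
    pass


def to_internal(start1: int, end1: int) -> Tuple[int, int]:
    """1-based inclusive [start1, end1] -> 0-based half-open [start0, end0)."""
    return start1 - 1, end1


def to_external(start0: int, end0: int) -> Tuple[int, int]:
    """0-based half-open [start0, end0) -> 1-based inclusive [start1, end1]."""
    return start0 + 1, end0


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Assembly:
    """A set of named random-access nucleotide sequences.

    Sequence order is preserved from the source file; sequences are stored
    upper-cased.  Per-instance caches (e.g. k-mer indexes built by the
    projection engine) live in ``_caches`` and are never serialized.
    """

    sequences: Dict[str, str] = field(default_factory=dict)
    _caches: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("empty sequence name")
            self.sequences[name] = seq.upper()

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def names(self) -> List[str]:
        return list(self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, name: str, start0: int, end0: int) -> str:
        """Return the sub-sequence [start0, end0) of ``name`` (0-based half-open)."""
        return self.sequences[name][start0:end0]


@dataclass
class SnpRecord:
    """One single-nucleotide variant (possibly multiallelic), 1-based."""

    chrom: str
    pos: int
    ref: str
    alts: List[str]
    id: Optional[str] = None
    info: Dict[str, object] = field(default_factory=dict)
    qual: str = "."
    filter: str = "."
    extra: List[str] = field(default_factory=list)  # FORMAT + genotype columns, verbatim

    def validate_against(self, assembly: Assembly) -> None:
        if self.chrom in assembly:
            if not (1 <= self.pos <= len(assembly.sequences[self.chrom])):
                raise ValueError(
                    f"position {self.pos} out of range for {self.chrom}"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _open_text(path) -> io.TextIOBase:
    """Open plain or (b)gzip-compressed text transparently."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(path) -> Assembly:
    """Parse a (possibly bgzipped) multi-record FASTA into an :class:`Assembly`.

    Soft-masked lowercase is upper-cased.  Malformed headers, non-IUPAC
    residues and duplicate names raise :class:`FastaFormatError` naming the
    offending line.
    """
    sequences: Dict[str, List[str]] = {}
    current: Optional[str] = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FastaFormatError(f"line {lineno}: malformed header {line!r}")
                if name in sequences:
                    raise FastaFormatError(
                        f"line {lineno}: duplicate sequence name {name!r}"
                    )
                sequences[name] = []
                current = name
            else:
                if current is None:
                    raise FastaFormatError(
                        f"line {lineno}: sequence data before first header"
                    )
                chunk = line.upper()
                bad = set(chunk) - _VALID_RESIDUES
                if bad:
                    raise FastaFormatError(
                        f"line {lineno}: non-IUPAC residue(s) {sorted(bad)!r}"
                    )
                sequences[current].append(chunk)
    if not sequences:
        raise FastaFormatError("no sequences")
    return Assembly({name: "".join(parts) for name, parts in sequences.items()})


def write_fasta(assembly: Assembly, path, width: int = 80) -> None:
    with open(path, "wt") as fh:
        for name, seq in assembly.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNV_BASES = frozenset("ACGT")


def _parse_info(text: str) -> Dict[str, object]:
    info: Dict[str, object] = {}
    if text in (".", ""):
        return info
    for item in text.split(";"):
        if "=" in item:
            key, _, value = item.partition("=")
            info[key] = value
        elif item:
            info[item] = True
    return info


def _format_info(info: Dict[str, object]) -> str:
    if not info:
        return "."
    parts = []
    for key, value in info.items():
        if value is True:
            parts.append(key)
        else:
            parts.append(f"{key}={value}")
    return ";".join(parts)


class VcfReader:
    """Iterate SNV records from a VCF 4.x file, counting skipped non-SNVs.

    Records whose REF or any ALT is not a single A/C/G/T base are skipped
    and tallied in :attr:`skipped` by reason (``indel``, ``symbolic``,
    ``ambiguous_ref``, ``multi_base``).
    """

    def __init__(self, path):
        self.path = path
        self.skipped: Dict[str, int] = {}
        self.n_kept = 0
        self.header_lines: List[str] = []
        self.column_header: Optional[str] = None

    def _skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())

    def __iter__(self) -> Iterator[SnpRecord]:
        with _open_text(self.path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("##"):
                    self.header_lines.append(line)
                    continue
                if line.startswith("#CHROM"):
                    self.column_header = line
                    continue
                if self.column_header is None:
                    raise VcfFormatError(
                        f"line {lineno}: data before #CHROM header line"
                    )
                fields = line.split("\t")
                if len(fields) < 5:
                    raise VcfFormatError(f"line {lineno}: fewer than 8 columns")
                chrom, pos_s, vid, ref, alt_s = fields[:5]
                ref = ref.upper()
                alts = [a.upper() for a in alt_s.split(",")]
                if any(a.startswith("<") or "[" in a or "]" in a for a in alts):
                    self._skip("symbolic")
                    continue
                if len(ref) != 1 or any(len(a) != 1 for a in alts):
                    self._skip("indel")
                    continue
                if ref not in _SNV_BASES:
                    self._skip("ambiguous_ref")
                    continue
                if any(a not in _SNV_BASES for a in alts):
                    self._skip("ambiguous_alt")
                    continue
                self.n_kept += 1
                yield SnpRecord(
                    chrom=chrom,
                    pos=int(pos_s),
                    id=None if vid == "." else vid,
                    ref=ref,
                    alts=alts,
                    qual=fields[5] if len(fields) > 5 else ".",
                    filter=fields[6] if len(fields) > 6 else ".",
                    info=_parse_info(fields[7]) if len(fields) > 7 else {},
                    extra=fields[8:],
                )


def read_vcf(path) -> VcfReader:
    """Open a VCF for SNV streaming; iterate the returned reader."""
    return VcfReader(path)


def write_vcf(
    records: Iterable[SnpRecord],
    path,
    contig_lengths: Dict[str, int],
    info_headers: Optional[List[Tuple[str, str, str, str]]] = None,
    extra_columns: Optional[List[str]] = None,
) -> int:
    """Write records as VCF 4.2, enforcing sort order by contig order then position.

    ``info_headers`` entries are (ID, Number, Type, Description) tuples for
    INFO keys the pipeline adds.  Returns the number of records written.
    Raises ``ValueError`` on unsorted input or a record whose chrom is not
    in ``contig_lengths``.
    """
    order = {name: i for i, name in enumerate(contig_lengths)}
    last: Optional[Tuple[int, int]] = None
    n = 0
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=flanklift\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for hid, num, typ, desc in info_headers or []:
            fh.write(
                f'##INFO=<ID={hid},Number={num},Type={typ},Description="{desc}">\n'
            )
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if extra_columns:
            cols += extra_columns
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            if rec.chrom not in order:
                raise ValueError(f"record chrom {rec.chrom!r} not in target contigs")
            key = (order[rec.chrom], rec.pos)
            if last is not None and key < last:
                raise ValueError(
                    f"unsorted input at {rec.chrom}:{rec.pos}; sort before writing"
                )
            last = key
            fields = [
                rec.chrom,
                str(rec.pos),
                rec.id or ".",
                rec.ref,
                ",".join(rec.alts),
                rec.qual,
                rec.filter,
                _format_info(rec.info),
            ]
            fields.extend(rec.extra)
            fh.write("\t".join(fields) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# GFF3 (the parent/child flank dialect)
# ---------------------------------------------------------------------------

def write_gff3(features: Iterable, path) -> int:
    """Write flank features as paired GFF3 rows: a 'region' parent plus a 'SNP' child.

    Coordinates are 1-based inclusive; every row is written on strand '+'
    (the input strand convention).  Returns the number of features written.
    """
    seen: set = set()
    n = 0
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            if feat.feature_id in seen:
                raise GffFormatError(f"duplicate feature ID {feat.feature_id!r}")
            seen.add(feat.feature_id)
            parent_id = feat.feature_id
            child_id = feat.feature_id + "_snp"
            fh.write(
                "\t".join(
                    [
                        feat.chrom,
                        "flanklift",
                        "region",
                        str(feat.parent_start),
                        str(feat.parent_end),
                        ".",
                        "+",
                        ".",
                        f"ID={parent_id}",
                    ]
                )
                + "\n"
            )
            fh.write(
                "\t".join(
                    [
                        feat.chrom,
                        "flanklift",
                        "SNP",
                        str(feat.child_pos),
                        str(feat.child_pos),
                        ".",
                        "+",
                        ".",
                        f"ID={child_id};Parent={parent_id}",
                    ]
                )
                + "\n"
            )
            n += 1
    return n


def _parse_attributes(text: str, lineno: int) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for item in text.rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise GffFormatError(f"line {lineno}: malformed attribute {item!r}")
        key, _, value = item.partition("=")
        attrs[key] = value
    return attrs


def read_gff3(path) -> List:
    """Read the flank dialect back into :class:`~flanklift.feature_bridge.FlankFeature`s.

    A child row whose Parent does not match any parent row raises
    :class:`GffFormatError` naming the ID.
    """
    from .feature_bridge import FlankFeature, parse_feature_id

    parents: Dict[str, Tuple[str, int, int]] = {}
    children: List[Tuple[str, str, int, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffFormatError(f"line {lineno}: expected 9 columns")
            chrom, _, ftype, start_s, end_s, _, _, _, attr_s = fields
            attrs = _parse_attributes(attr_s, lineno)
            if ftype == "region":
                if "ID" not in attrs:
                    raise GffFormatError(f"line {lineno}: region row without ID")
                parents[attrs["ID"]] = (chrom, int(start_s), int(end_s))
            elif ftype == "SNP":
                if "Parent" not in attrs:
                    raise GffFormatError(f"line {lineno}: SNP row without Parent")
                children.append((attrs["Parent"], chrom, int(start_s), lineno))
    features: List[FlankFeature] = []
    for parent_id, chrom, pos, lineno in children:
        if parent_id not in parents:
            raise GffFormatError(
                f"line {lineno}: orphan child references unknown parent {parent_id!r}"
            )
        pchrom, pstart, pend = parents[parent_id]
        _, flank_len = parse_feature_id(parent_id)
        features.append(
            FlankFeature(
                feature_id=parent_id,
                snp=None,
                chrom=pchrom,
                flank_len=flank_len,
                parent_start=pstart,
                parent_end=pend,
                child_pos=pos,
                truncated_left=False,
                truncated_right=False,
            )
        )
    return features
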