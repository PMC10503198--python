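"""Multi-flank-length lifting with consensus filtering, strand policy and reporting.

A SNP is *consistent* when every configured flank length lifted it to the
identical (chromosome, position, strand) triple; *incomplete* when at
least one flank length failed to lift; *inconsistent* when all lifted but
the triples disagree.  Only consistent SNPs can be retained, and under the
default ``drop_minus`` strand policy only plus-strand ones are — the
definition of the final dataset.  ``rescue_minus`` instead keeps
minus-strand SNPs with complemented alleles and a strand tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .assembly_io import Assembly, SnpRecord
from .feature_bridge import (
    LiftOutcome,
    build_flank_features,
    validate_flank_set,
)
from .projection_engine import AlignParams, project_feature

__all__ = [
    "ConsensusOutcome",
    "SummaryReport",
    "lift_consensus",
    "apply_strand_policy",
    "classify_transition",
    "summarize",
    "density_profile",
    "INFO_HEADERS",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: INFO keys the pipeline adds to the output VCF.
INFO_HEADERS = [
    ("LV1_CHROM", "1", "String", "Chromosome in the source assembly"),
    ("LV1_POS", "1", "Integer", "1-based position in the source assembly"),
    ("LV_STRAND", "1", "String", "Strand of the lifted placement"),
    ("LV_IDENTITY_MIN", "1", "Float", "Minimum alignment identity across flank lengths"),
    ("LV_TRUNC", "1", "String", "Flank truncation flags (L/R) at any flank length"),
]


@dataclass
class ConsensusOutcome:
    """Cross-flank-length consensus status for one SNP."""

    snp: SnpRecord
    snp_index: int
    per_flank: Dict[int, LiftOutcome]
    status: str  # consistent | inconsistent | incomplete
    final_chrom: Optional[str] = None
    final_pos: Optional[int] = None
    final_strand: Optional[str] = None
    transition: Optional[str] = None
    retained: bool = False
    final_ref: Optional[str] = None
    final_alts: Optional[List[str]] = None

    @property
    def strand_class(self) -> Optional[str]:
        if self.final_strand == "+":
            return "plus"
        if self.final_strand == "-":
            return "minus"
        return None

    @property
    def min_identity(self) -> Optional[float]:
        idents = [o.identity for o in self.per_flank.values() if o.identity is not None]
        return min(idents) if idents else None

    def truncation_flags(self) -> str:
        left = any(o.truncated_left for o in self.per_flank.values())
        right = any(o.truncated_right for o in self.per_flank.values())
        return ("L" if left else "") + ("R" if right else "") or "."

    def to_record(self) -> SnpRecord:
        """Final-coordinate SNP record with provenance INFO keys."""
        if not self.retained:
            raise ValueError("only retained outcomes convert to output records")
        info = dict(self.snp.info)
        info["LV1_CHROM"] = self.snp.chrom
        info["LV1_POS"] = self.snp.pos
        info["LV_STRAND"] = self.final_strand
        mi = self.min_identity
        if mi is not None:
            info["LV_IDENTITY_MIN"] = f"{mi:.4f}"
        info["LV_TRUNC"] = self.truncation_flags()
        return SnpRecord(
            chrom=self.final_chrom,
            pos=self.final_pos,
            id=self.snp.id,
            ref=self.final_ref or self.snp.ref,
            alts=list(self.final_alts or self.snp.alts),
            info=info,
            qual=self.snp.qual,
            filter=self.snp.filter,
            extra=list(self.snp.extra),
        )


def lift_consensus(
    snps: Sequence[SnpRecord],
    source: Assembly,
    target: Assembly,
    flank_set: Sequence[int],
    params: Optional[AlignParams] = None,
    un_prefix_source: str = "chrUn",
    un_prefix_target: str = "chrUn",
) -> List[ConsensusOutcome]:
    """Project every SNP at every flank length and take the cross-flank consensus."""
    params = params or AlignParams()
    flank_set = validate_flank_set(flank_set, params.min_len)
    snps = list(snps)
    per_flank_outcomes: Dict[int, List[LiftOutcome]] = {}
    for L in flank_set:
        outcomes_L: List[LiftOutcome] = []
        for i, feat in enumerate(build_flank_features(snps, L, source, params.min_len)):
            projected = project_feature(feat, source, target, params)
            outcomes_L.append(
                LiftOutcome(
                    snp=feat.snp,
                    snp_index=i,
                    flank_len=L,
                    status=projected.status,
                    target_chrom=projected.target_chrom,
                    target_pos=projected.target_pos,
                    target_strand=projected.target_strand,
                    identity=projected.identity,
                    coverage=projected.coverage,
                    truncated_left=feat.truncated_left,
                    truncated_right=feat.truncated_right,
                )
            )
        per_flank_outcomes[L] = outcomes_L

    results: List[ConsensusOutcome] = []
    for i, snp in enumerate(snps):
        per_flank = {L: per_flank_outcomes[L][i] for L in flank_set}
        locations = {L: o.location for L, o in per_flank.items()}
        if any(loc is None for loc in locations.values()):
            status = "incomplete"
        elif len(set(locations.values())) == 1:
            status = "consistent"
        else:
            status = "inconsistent"
        outcome = ConsensusOutcome(
            snp=snp, snp_index=i, per_flank=per_flank, status=status
        )
        if status == "consistent":
            chrom, pos, strand = next(iter(locations.values()))
            outcome.final_chrom = chrom
            outcome.final_pos = pos
            outcome.final_strand = strand
            outcome.retained = True
            outcome.transition = classify_transition(
                outcome, un_prefix_source, un_prefix_target
            )
        results.append(outcome)
    return results


def apply_strand_policy(
    outcome: ConsensusOutcome, policy: str = "drop_minus"
) -> ConsensusOutcome:
    """Resolve minus-strand consistent lifts per policy (in place, returned).

    ``drop_minus`` marks them not retained; ``rescue_minus`` keeps them with
    ref and all alts complemented (strand stays recorded for the INFO tag).
    """
    if policy not in ("drop_minus", "rescue_minus"):
        raise ValueError(f"unknown strand policy {policy!r}")
    if outcome.status != "consistent":
        return outcome
    if outcome.final_strand == "+":
        return outcome
    if policy == "drop_minus":
        outcome.retained = False
    else:
        outcome.final_ref = _COMPLEMENT[outcome.snp.ref]
        outcome.final_alts = [_COMPLEMENT[a] for a in outcome.snp.alts]
        outcome.retained = True
    return outcome


def classify_transition(
    outcome: ConsensusOutcome,
    un_prefix_source: str = "chrUn",
    un_prefix_target: str = "chrUn",
) -> str:
    """Label the source→target chromosome relationship of a consistent lift."""
    if outcome.status != "consistent":
        raise ValueError("transition classification requires a consistent outcome")
    src = outcome.snp.chrom
    tgt = outcome.final_chrom
    src_un = src.startswith(un_prefix_source)
    tgt_un = tgt.startswith(un_prefix_target)
    if src_un and tgt_un:
        return "un_to_un"
    if src_un:
        return "un_to_anchored"
    if tgt_un:
        return "anchored_to_un"
    return "same_chrom" if src == tgt else "diff_chrom"


@dataclass
class SummaryReport:
    total: int
    per_flank_lifted: Dict[int, int]
    consensus: int
    inconsistent: int
    incomplete: int
    plus: int
    minus: int
    retained: int
    transitions: Dict[str, int]
    transition_matrix: Dict[Tuple[str, str], int]

    @property
    def plus_pct(self) -> float:
        return 100.0 * self.plus / self.consensus if self.consensus else 0.0

    @property
    def minus_pct(self) -> float:
        return 100.0 * self.minus / self.consensus if self.consensus else 0.0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "per_flank_lifted": {str(k): v for k, v in self.per_flank_lifted.items()},
            "consensus": self.consensus,
            "inconsistent": self.inconsistent,
            "incomplete": self.incomplete,
            "plus": self.plus,
            "minus": self.minus,
            "plus_pct": round(self.plus_pct, 2),
            "minus_pct": round(self.minus_pct, 2),
            "retained": self.retained,
            "transitions": dict(self.transitions),
        }

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def matrix_rows(self) -> List[Tuple[str, str, int]]:
        return sorted(
            (src, tgt, n) for (src, tgt), n in self.transition_matrix.items()
        )


def summarize(outcomes: Iterable[ConsensusOutcome]) -> SummaryReport:
    """Per-flank lifted counts, consensus/strand partition and transition matrix."""
    outcomes = list(outcomes)
    per_flank: Dict[int, int] = {}
    consensus = inconsistent = incomplete = plus = minus = retained = 0
    transitions: Dict[str, int] = {}
    matrix: Dict[Tuple[str, str], int] = {}
    for outcome in outcomes:
        for L, lo in outcome.per_flank.items():
            per_flank.setdefault(L, 0)
            if lo.lifted:
                per_flank[L] += 1
        if outcome.status == "consistent":
            consensus += 1
            if outcome.strand_class == "plus":
                plus += 1
            else:
                minus += 1
            if outcome.transition:
                transitions[outcome.transition] = (
                    transitions.get(outcome.transition, 0) + 1
                )
            key = (outcome.snp.chrom, outcome.final_chrom)
            matrix[key] = matrix.get(key, 0) + 1
        elif outcome.status == "inconsistent":
            inconsistent += 1
        else:
            incomplete += 1
        if outcome.retained:
            retained += 1
    return SummaryReport(
        total=len(outcomes),
        per_flank_lifted=per_flank,
        consensus=consensus,
        inconsistent=inconsistent,
        incomplete=incomplete,
        plus=plus,
        minus=minus,
        retained=retained,
        transitions=transitions,
        transition_matrix=matrix,
    )


def density_profile(
    positions: Iterable[Tuple[str, int]],
    assembly: Assembly,
    bin_size: int = 10_000_000,
) -> Dict[str, np.ndarray]:
    """Count SNPs per fixed-width bin per chromosome.

    ``positions`` are (chrom, 1-based pos) pairs; position p falls in bin
    ``(p - 1) // bin_size`` so a SNP at exactly ``bin_size`` lands in the
    first bin.  The last bin may be short.  Bin totals conserve the input
    count for positions on known chromosomes.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    profile: Dict[str, np.ndarray] = {}
    for name, length in assembly.lengths.items():
        n_bins = max(1, -(-length // bin_size))
        profile[name] = np.zeros(n_bins, dtype=np.int64)
    for chrom, pos in positions:
        if chrom not in profile:
            raise KeyError(f"position on unknown chromosome {chrom!r}")
        profile[chrom][(pos - 1) // bin_size] += 1
    return profile


def density_rows(
    profile: Dict[str, np.ndarray], assembly: Assembly, bin_size: int
) -> List[Tuple[str, int, int, int]]:
    """Flatten a density profile into (chrom, bin_start1, bin_end1, count) rows."""
    rows = []
    for chrom, counts in profile.items():
        length = assembly.lengths[chrom]
        for i, count in enumerate(counts):
            start1 = i * bin_size + 1
            end1 = min((i + 1) * bin_size, length)
            rows.append((chrom, start1, end1, int(count)))
    return rows
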