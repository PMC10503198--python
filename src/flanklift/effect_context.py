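"""Transcript-relative region classification, coding effects and impact buckets.

Region labels follow a most-specific-wins precedence:

    splice_site_donor > splice_site_acceptor > splice_site_region >
    utr5/utr3 > exon > intron > upstream/downstream > intergenic

where donor/acceptor are the first/last two intronic bases of an intron in
transcript orientation, splice_site_region covers intronic bases 3–8 from
a junction and exonic bases 1–3 adjacent to an internal junction, and
up/downstream extend a configurable window (default 5,000 bp) from the
transcript span.  UTRs are exonic bases outside the CDS; "exon" therefore
means CDS or noncoding-exon bases.  One SNP yields one annotation per
transcript within reach, so effect counts exceed SNP counts.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .assembly_io import Assembly, GffFormatError, SnpRecord, _open_text, revcomp

__all__ = [
    "TranscriptModel",
    "EffectAnnotation",
    "classify_region",
    "classify_coding_effect",
    "impact_bucket",
    "annotate",
    "read_gene_models",
    "DEFAULT_UPDOWN_WINDOW",
]

DEFAULT_UPDOWN_WINDOW = 5000

REGIONS = (
    "downstream", "exon", "intergenic", "intron", "splice_site_acceptor",
    "splice_site_donor", "splice_site_region", "upstream", "utr3", "utr5",
)

_HIGH = {"start_lost", "stop_gained", "stop_lost"}
_SEVERITY = {
    "stop_gained": 4, "stop_lost": 4, "start_lost": 4,
    "missense": 3, "synonymous": 2, "none": 0,
}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class TranscriptModel:
    """One transcript: ordered exons and CDS intervals, 1-based inclusive."""

    id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]] = field(default_factory=list)
    confidence: Optional[str] = None  # carried attribute only, no differential use

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 <= e0:
                raise ValueError(f"{self.id}: overlapping exons")
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(f"{self.id}: CDS interval outside exon space")

    @property
    def biotype(self) -> str:
        return "coding" if self.cds else "noncoding"

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def frame_ok(self) -> bool:
        return self.cds_length % 3 == 0

    def introns(self) -> List[Tuple[int, int]]:
        return [
            (e0 + 1, s1 - 1)
            for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]

    def contains_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def spliced_cds(self, assembly: Assembly) -> str:
        parts = [assembly.fetch(self.chrom, s - 1, e) for s, e in self.cds]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_offset(self, pos: int) -> int:
        """Transcript-orientation 0-based offset of a genomic CDS position."""
        g = 0
        for s, e in self.cds:
            if s <= pos <= e:
                g += pos - s
                break
            g += e - s + 1
        else:
            raise ValueError(f"position {pos} not in CDS of {self.id}")
        return self.cds_length - 1 - g if self.strand == "-" else g


@dataclass
class EffectAnnotation:
    snp: SnpRecord
    transcript_id: Optional[str]
    region: str
    coding_effect: str = "none"
    impact: str = "modifier"


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

def classify_region(
    snp: SnpRecord,
    transcript: TranscriptModel,
    updown_window: int = DEFAULT_UPDOWN_WINDOW,
) -> str:
    """Label the SNP's position relative to one transcript (most specific wins)."""
    if snp.chrom != transcript.chrom:
        return "intergenic"
    pos = snp.pos
    span_start, span_end = transcript.span
    strand = transcript.strand

    if pos < span_start or pos > span_end:
        if span_start - updown_window <= pos < span_start:
            return "upstream" if strand == "+" else "downstream"
        if span_end < pos <= span_end + updown_window:
            return "downstream" if strand == "+" else "upstream"
        return "intergenic"

    for istart, iend in transcript.introns():
        if istart <= pos <= iend:
            d = pos - istart  # offset from the intron's low-coordinate end
            a = iend - pos  # offset from the intron's high-coordinate end
            donor_off, acceptor_off = (d, a) if strand == "+" else (a, d)
            if donor_off <= 1:
                return "splice_site_donor"
            if acceptor_off <= 1:
                return "splice_site_acceptor"
            if min(d, a) <= 7:  # intronic bases 3-8 from either junction
                return "splice_site_region"
            return "intron"

    # exonic: near-junction bases first (internal junctions only)
    n_exons = len(transcript.exons)
    for i, (es, ee) in enumerate(transcript.exons):
        if es <= pos <= ee:
            left_junction = i > 0
            right_junction = i < n_exons - 1
            if (left_junction and pos <= es + 2) or (right_junction and pos >= ee - 2):
                return "splice_site_region"
            break
    if transcript.biotype == "coding" and not transcript.contains_cds(pos):
        cds_min = transcript.cds[0][0]
        cds_max = transcript.cds[-1][1]
        if pos < cds_min:
            return "utr5" if strand == "+" else "utr3"
        if pos > cds_max:
            return "utr3" if strand == "+" else "utr5"
    return "exon"


# ---------------------------------------------------------------------------
# Coding effects
# ---------------------------------------------------------------------------

def classify_coding_effect(
    snp: SnpRecord, transcript: TranscriptModel, assembly: Assembly
) -> str:
    """Codon-level consequence of a CDS SNV; most severe label across alts.

    Locates the codon and within-codon offset (reverse-complementing for
    '−' transcripts), substitutes each alternate base and compares the
    translations under the standard genetic code.
    """
    if not transcript.contains_cds(snp.pos):
        raise ValueError(f"SNP {snp.chrom}:{snp.pos} not in CDS of {transcript.id}")
    cds_seq = transcript.spliced_cds(assembly)
    off = transcript.cds_offset(snp.pos)
    codon_idx, within = divmod(off, 3)
    ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    if len(ref_codon) < 3:
        return "none"  # trailing partial codon on a frame-violating model
    ref_aa = _CODON_TABLE.get(ref_codon)
    best = "none"
    for alt in snp.alts:
        alt_base = _COMPLEMENT[alt] if transcript.strand == "-" else alt
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        if alt_codon == ref_codon:
            continue
        alt_aa = _CODON_TABLE.get(alt_codon)
        if ref_aa is None or alt_aa is None:
            continue
        if codon_idx == 0 and ref_codon == "ATG" and alt_codon != "ATG":
            label = "start_lost"
        elif ref_aa != "*" and alt_aa == "*":
            label = "stop_gained"
        elif ref_aa == "*" and alt_aa != "*":
            label = "stop_lost"
        elif ref_aa == alt_aa:
            label = "synonymous"
        else:
            label = "missense"
        if _SEVERITY[label] > _SEVERITY[best]:
            best = label
    return best


def impact_bucket(region: str, coding_effect: str = "none") -> str:
    """Severity bucket: high / moderate / low / modifier."""
    if coding_effect in _HIGH:
        return "high"
    if region in ("splice_site_donor", "splice_site_acceptor"):
        return "high"
    if coding_effect == "missense":
        return "moderate"
    if coding_effect == "synonymous" or region == "splice_site_region":
        return "low"
    return "modifier"


# ---------------------------------------------------------------------------
# Annotation driver
# ---------------------------------------------------------------------------

class _TranscriptIndex:
    """Window-padded interval lookup: sorted starts with a running max end."""

    def __init__(self, transcripts: Sequence[TranscriptModel], window: int):
        self.window = window
        self.by_chrom: Dict[str, Tuple[List[int], List[int], List[TranscriptModel]]] = {}
        grouped: Dict[str, List[TranscriptModel]] = {}
        for tx in transcripts:
            grouped.setdefault(tx.chrom, []).append(tx)
        for chrom, txs in grouped.items():
            txs.sort(key=lambda t: t.span[0])
            starts = [t.span[0] - window for t in txs]
            max_ends: List[int] = []
            running = -(10 ** 12)
            for t in txs:
                running = max(running, t.span[1] + window)
                max_ends.append(running)
            self.by_chrom[chrom] = (starts, max_ends, txs)

    def query(self, chrom: str, pos: int) -> List[TranscriptModel]:
        if chrom not in self.by_chrom:
            return []
        starts, max_ends, txs = self.by_chrom[chrom]
        hi = bisect.bisect_right(starts, pos)
        hits: List[TranscriptModel] = []
        for i in range(hi - 1, -1, -1):
            if max_ends[i] < pos:
                break  # running max: nothing earlier can reach pos either
            tx = txs[i]
            if tx.span[0] - self.window <= pos <= tx.span[1] + self.window:
                hits.append(tx)
        hits.reverse()
        return hits


def annotate(
    snps: Iterable[SnpRecord],
    transcripts: Sequence[TranscriptModel],
    assembly: Optional[Assembly] = None,
    updown_window: int = DEFAULT_UPDOWN_WINDOW,
) -> Tuple[List[EffectAnnotation], Dict[str, Dict[str, float]]]:
    """Annotate each SNP against every transcript within span±window.

    Returns (effects, category table); the table maps region -> {count,
    percentage} with percentages over effects, not SNPs.  SNPs hitting no
    transcript yield a single intergenic effect.  Coding effects are only
    computed when ``assembly`` is given.
    """
    index = _TranscriptIndex(transcripts, updown_window)
    effects: List[EffectAnnotation] = []
    for snp in snps:
        hits = index.query(snp.chrom, snp.pos)
        if not hits:
            effects.append(
                EffectAnnotation(
                    snp=snp, transcript_id=None, region="intergenic",
                    impact=impact_bucket("intergenic"),
                )
            )
            continue
        for tx in hits:
            region = classify_region(snp, tx, updown_window)
            coding_effect = "none"
            if (
                assembly is not None
                and tx.biotype == "coding"
                and region in ("exon", "splice_site_region")
                and tx.contains_cds(snp.pos)
            ):
                coding_effect = classify_coding_effect(snp, tx, assembly)
            effects.append(
                EffectAnnotation(
                    snp=snp,
                    transcript_id=tx.id,
                    region=region,
                    coding_effect=coding_effect,
                    impact=impact_bucket(region, coding_effect),
                )
            )
    total = len(effects)
    table: Dict[str, Dict[str, float]] = {}
    for region in REGIONS:
        count = sum(1 for e in effects if e.region == region)
        table[region] = {
            "count": count,
            "percentage": round(100.0 * count / total, 2) if total else 0.0,
        }
    return effects, table


# ---------------------------------------------------------------------------
# Gene-model GFF3 input
# ---------------------------------------------------------------------------

_TX_TYPES = {"mRNA", "transcript"}


def read_gene_models(path) -> List[TranscriptModel]:
    """Parse a gene→mRNA→exon/CDS GFF3 hierarchy into transcript models.

    Exon/CDS rows whose Parent references no transcript raise
    :class:`GffFormatError` naming the line.
    """
    tx_meta: Dict[str, Tuple[str, str, Optional[str]]] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    order: List[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffFormatError(f"line {lineno}: expected 9 columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
            attrs = {}
            for item in attr_s.rstrip(";").split(";"):
                if item and "=" in item:
                    key, _, value = item.partition("=")
                    attrs[key] = value
            if ftype in _TX_TYPES:
                if "ID" not in attrs:
                    raise GffFormatError(f"line {lineno}: transcript without ID")
                tid = attrs["ID"]
                tx_meta[tid] = (chrom, strand, attrs.get("confidence"))
                exons.setdefault(tid, [])
                cds.setdefault(tid, [])
                order.append(tid)
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise GffFormatError(f"line {lineno}: {ftype} without Parent")
                for pid in parent.split(","):
                    if pid not in tx_meta:
                        raise GffFormatError(
                            f"line {lineno}: {ftype} Parent {pid!r} references "
                            "no known transcript"
                        )
                    target = exons if ftype == "exon" else cds
                    target[pid].append((int(start_s), int(end_s)))
    models = []
    for tid in order:
        chrom, strand, conf = tx_meta[tid]
        ex = exons[tid] or cds[tid]  # exon rows optional if CDS given
        models.append(
            TranscriptModel(
                id=tid, chrom=chrom, strand=strand,
                exons=ex, cds=cds[tid], confidence=conf,
            )
        )
    return models
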