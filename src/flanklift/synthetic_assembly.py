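"""Synthetic assembly-update simulator with an exact coordinate truth map.

Generates a source assembly (anchored chromosomes plus unanchored
scaffolds), derives a target assembly through an ordered edit script of
structural operations (inversion, relocation, scaffold anchoring/dropping),
small indels and point divergence, and emits a :class:`TruthMap` — the
piecewise source→target coordinate function used as the oracle for every
recovery test.  SNP planting produces records whose true target
coordinates are known by construction.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .assembly_io import Assembly, SnpRecord, revcomp

__all__ = [
    "Invert",
    "Relocate",
    "Anchor",
    "Drop",
    "Diverge",
    "Indel",
    "AssemblyEditScript",
    "TruthMap",
    "EvalReport",
    "generate_source",
    "apply_edit_script",
    "plant_snps",
    "evaluate",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Edit-script vocabulary (external coordinates are 1-based inclusive)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Invert:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Relocate:
    src_chrom: str
    start: int
    end: int
    dst_chrom: str
    dst_pos: int  # inserted before this 1-based position on dst_chrom
    orientation: str = "+"


@dataclass(frozen=True)
class Anchor:
    un_scaffold: str
    dst_chrom: str
    dst_pos: int
    orientation: str = "+"


@dataclass(frozen=True)
class Drop:
    scaffold: str


@dataclass(frozen=True)
class Diverge:
    rate: float  # substitutions per target base


@dataclass(frozen=True)
class Indel:
    rate: float  # events per target base
    max_len: int = 10


_OP_TAGS = {
    "invert": Invert,
    "relocate": Relocate,
    "anchor": Anchor,
    "drop": Drop,
    "diverge": Diverge,
    "indel": Indel,
}


@dataclass
class AssemblyEditScript:
    """Ordered assembly-update operations applied to a source assembly."""

    seed: int = 0
    ops: List[object] = field(default_factory=list)

    def validate(self, source: Assembly) -> None:
        """Check bounds and that no two structural ops overlap on the source."""
        used: Dict[str, List[Tuple[int, int]]] = {}
        lengths = source.lengths

        def claim(chrom: str, start: int, end: int, what: str) -> None:
            if chrom not in lengths:
                raise ValueError(f"{what}: unknown sequence {chrom!r}")
            if not (1 <= start <= end <= lengths[chrom]):
                raise ValueError(f"{what}: interval [{start},{end}] out of bounds")
            for s, e in used.get(chrom, []):
                if start <= e and s <= end:
                    raise ValueError(
                        f"{what}: interval [{start},{end}] on {chrom} overlaps "
                        f"another structural operation"
                    )
            used.setdefault(chrom, []).append((start, end))

        for op in self.ops:
            if isinstance(op, Invert):
                claim(op.chrom, op.start, op.end, "invert")
            elif isinstance(op, Relocate):
                claim(op.src_chrom, op.start, op.end, "relocate")
            elif isinstance(op, Anchor):
                claim(op.un_scaffold, 1, lengths.get(op.un_scaffold, 1), "anchor")
            elif isinstance(op, Drop):
                claim(op.scaffold, 1, lengths.get(op.scaffold, 1), "drop")
            elif isinstance(op, (Diverge, Indel)):
                if not (0.0 <= op.rate < 1.0):
                    raise ValueError("rate must be in [0, 1)")
            else:
                raise ValueError(f"unknown operation {op!r}")

    # -- config round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        serial = []
        for op in self.ops:
            tag = next(t for t, cls in _OP_TAGS.items() if isinstance(op, cls))
            serial.append({"op": tag, **op.__dict__})
        return {"seed": self.seed, "ops": serial}

    @classmethod
    def from_dict(cls, data: dict) -> "AssemblyEditScript":
        ops = []
        for item in data.get("ops", []):
            item = dict(item)
            tag = item.pop("op")
            if tag not in _OP_TAGS:
                raise ValueError(f"unknown operation tag {tag!r}")
            ops.append(_OP_TAGS[tag](**item))
        return cls(seed=int(data.get("seed", 0)), ops=ops)

    def to_yaml(self, path) -> None:
        with open(path, "wt") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AssemblyEditScript":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Truth map
# ---------------------------------------------------------------------------

@dataclass
class TruthMap:
    """Piecewise source→target coordinate function.

    Pieces are (src_chrom, src_start0, src_end0, tgt_chrom, tgt_start0,
    strand) with 0-based half-open source intervals; a '−' piece maps
    source base p to ``tgt_start0 + (src_end0 - 1 - p)``.
    """

    pieces: List[Tuple[str, int, int, str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_chrom: Dict[str, List[Tuple[int, int, str, int, str]]] = {}
        for sc, s0, e0, tc, t0, strand in self.pieces:
            self._by_chrom.setdefault(sc, []).append((s0, e0, tc, t0, strand))
        for chrom, items in self._by_chrom.items():
            items.sort()
            for (s0, e0, *_), (s1, *_rest) in zip(items, items[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping truth pieces on {chrom}")

    def lookup(self, chrom: str, pos: int) -> Optional[Tuple[str, int, str]]:
        """1-based source position -> (target chrom, 1-based pos, strand) or None."""
        p0 = pos - 1
        items = self._by_chrom.get(chrom)
        if not items:
            return None
        idx = bisect.bisect_right(items, (p0, float("inf"))) - 1
        if idx < 0:
            return None
        s0, e0, tc, t0, strand = items[idx]
        if not (s0 <= p0 < e0):
            return None
        if strand == "+":
            return (tc, t0 + (p0 - s0) + 1, "+")
        return (tc, t0 + (e0 - 1 - p0) + 1, "-")

    def breakpoint_distance(self, chrom: str, pos: int) -> Optional[int]:
        """Distance (bases) from the position to the nearest edge of its piece."""
        p0 = pos - 1
        items = self._by_chrom.get(chrom)
        if not items:
            return None
        idx = bisect.bisect_right(items, (p0, float("inf"))) - 1
        if idx < 0:
            return None
        s0, e0, *_ = items[idx]
        if not (s0 <= p0 < e0):
            return None
        return min(p0 - s0, e0 - 1 - p0)

    def to_tsv(self, path) -> None:
        with open(path, "wt") as fh:
            fh.write("#src_chrom\tsrc_start\tsrc_end\ttgt_chrom\ttgt_start\ttgt_end\tstrand\n")
            for sc, s0, e0, tc, t0, strand in self.pieces:
                fh.write(
                    f"{sc}\t{s0}\t{e0}\t{tc}\t{t0}\t{t0 + (e0 - s0)}\t{strand}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "TruthMap":
        pieces = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                sc, s0, e0, tc, t0, _t1, strand = line.rstrip("\n").split("\t")
                pieces.append((sc, int(s0), int(e0), tc, int(t0), strand))
        return cls(pieces)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draw = rng.choice(_BASES, size=length, p=probs)
    return draw.tobytes().decode("ascii")


def generate_source(
    n_chroms: int,
    chrom_lengths: Sequence[int],
    n_unanchored: int = 0,
    un_lengths: Sequence[int] = (),
    gc: float = 0.5,
    seed: int = 0,
    un_prefix: str = "chrUn",
) -> Assembly:
    """I.i.d. random assembly: chr1..chrN plus unanchored chrUn_1.. scaffolds."""
    if len(chrom_lengths) != n_chroms or len(un_lengths) != n_unanchored:
        raise ValueError("length lists must match the sequence counts")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    if any(l < 1 for l in list(chrom_lengths) + list(un_lengths)):
        raise ValueError("sequence lengths must be >= 1")
    rng = np.random.default_rng(seed)
    sequences: Dict[str, str] = {}
    for i, length in enumerate(chrom_lengths, start=1):
        sequences[f"chr{i}"] = _random_seq(rng, length, gc)
    for i, length in enumerate(un_lengths, start=1):
        sequences[f"{un_prefix}_{i}"] = _random_seq(rng, length, gc)
    return Assembly(sequences)


def inject_tandem_repeat(
    assembly: Assembly, chrom: str, start: int, length: int, copies: int = 2
) -> Assembly:
    """Duplicate assembly with [start, start+length) repeated ``copies`` times.

    A deliberate multi-mapping trap for ambiguity tests; coordinates after
    the insertion shift, so use only on assemblies without a truth map.
    """
    seq = assembly.sequences[chrom]
    unit = seq[start : start + length]
    new = seq[: start + length] + unit * (copies - 1) + seq[start + length :]
    sequences = dict(assembly.sequences)
    sequences[chrom] = new
    return Assembly(sequences)


# ---------------------------------------------------------------------------
# Edit-script application
# ---------------------------------------------------------------------------

@dataclass
class _Segment:
    src_chrom: Optional[str]  # None for novel (inserted) sequence
    s0: int
    e0: int
    strand: str = "+"
    novel: str = ""

    @property
    def length(self) -> int:
        return len(self.novel) if self.src_chrom is None else self.e0 - self.s0


def _find_segment(
    layouts: Dict[str, List[_Segment]], chrom: str, s0: int, e0: int
) -> Tuple[str, int]:
    """Locate the layout segment fully containing source interval [s0, e0)."""
    for tname, segs in layouts.items():
        for i, seg in enumerate(segs):
            if (
                seg.src_chrom == chrom
                and seg.strand == "+"
                and seg.s0 <= s0
                and e0 <= seg.e0
            ):
                return tname, i
    raise ValueError(
        f"source interval {chrom}:[{s0},{e0}) not contiguous in the current layout"
    )


def _split_out(segs: List[_Segment], i: int, s0: int, e0: int) -> Tuple[List[_Segment], _Segment]:
    seg = segs[i]
    pieces: List[_Segment] = []
    if seg.s0 < s0:
        pieces.append(_Segment(seg.src_chrom, seg.s0, s0))
    mid = _Segment(seg.src_chrom, s0, e0)
    if e0 < seg.e0:
        tail = _Segment(seg.src_chrom, e0, seg.e0)
    else:
        tail = None
    out = segs[:i] + pieces + ([tail] if tail else []) + segs[i + 1 :]
    return out, mid


def apply_edit_script(
    source: Assembly, script: AssemblyEditScript
) -> Tuple[Assembly, TruthMap]:
    """Apply the script in order; return the target assembly and its truth map."""
    script.validate(source)
    rng = np.random.default_rng(script.seed)
    layouts: Dict[str, List[_Segment]] = {
        name: [_Segment(name, 0, len(seq))] for name, seq in source.sequences.items()
    }
    diverge_rates: List[float] = []

    for op in script.ops:
        if isinstance(op, Drop):
            if op.scaffold not in layouts:
                raise ValueError(f"drop: {op.scaffold!r} not present")
            del layouts[op.scaffold]
        elif isinstance(op, Invert):
            s0, e0 = op.start - 1, op.end
            tname, i = _find_segment(layouts, op.chrom, s0, e0)
            segs, mid = _split_out(layouts[tname], i, s0, e0)
            mid.strand = "-"
            # _split_out removed mid from the list; re-insert in place
            segs.insert(_insertion_index(segs, op.chrom, e0), mid)
            layouts[tname] = segs
        elif isinstance(op, Relocate):
            s0, e0 = op.start - 1, op.end
            tname, i = _find_segment(layouts, op.src_chrom, s0, e0)
            segs, mid = _split_out(layouts[tname], i, s0, e0)
            layouts[tname] = segs
            mid.strand = op.orientation
            _insert_at_point(layouts, op.dst_chrom, op.dst_pos - 1, mid)
        elif isinstance(op, Anchor):
            if op.un_scaffold not in layouts:
                raise ValueError(f"anchor: {op.un_scaffold!r} not present")
            segs = layouts.pop(op.un_scaffold)
            if len(segs) != 1:
                raise ValueError("anchor: scaffold already structurally edited")
            seg = segs[0]
            seg.strand = op.orientation
            _insert_at_point(layouts, op.dst_chrom, op.dst_pos - 1, seg)
        elif isinstance(op, Indel):
            layouts = _apply_indels(layouts, op, rng)
        elif isinstance(op, Diverge):
            diverge_rates.append(op.rate)
        else:  # pragma: no cover - validate() already rejects
            raise ValueError(f"unknown operation {op!r}")

    # materialize
    sequences: Dict[str, str] = {}
    pieces: List[Tuple[str, int, int, str, int, str]] = []
    for tname, segs in layouts.items():
        parts: List[str] = []
        cursor = 0
        for seg in segs:
            if seg.src_chrom is None:
                parts.append(seg.novel)
            else:
                chunk = source.sequences[seg.src_chrom][seg.s0 : seg.e0]
                if seg.strand == "-":
                    chunk = revcomp(chunk)
                parts.append(chunk)
                pieces.append(
                    (seg.src_chrom, seg.s0, seg.e0, tname, cursor, seg.strand)
                )
            cursor += seg.length
        sequences[tname] = "".join(parts)
    target = Assembly(sequences)

    for rate in diverge_rates:
        if rate <= 0:
            continue
        for name, seq in target.sequences.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            n_sub = rng.binomial(len(arr), rate)
            if n_sub == 0:
                continue
            sites = rng.choice(len(arr), size=n_sub, replace=False)
            shift = rng.integers(1, 4, size=n_sub)
            code = {65: 0, 67: 1, 71: 2, 84: 3}
            inv = np.frombuffer(b"ACGT", dtype=np.uint8)
            old = np.array([code.get(b, 0) for b in arr[sites]], dtype=np.int64)
            arr[sites] = inv[(old + shift) % 4]
            target.sequences[name] = arr.tobytes().decode("ascii")

    return target, TruthMap(pieces)


def _insertion_index(segs: List[_Segment], chrom: str, e0: int) -> int:
    """Index where the piece whose source interval ends at e0 should sit."""
    for j, seg in enumerate(segs):
        if seg.src_chrom == chrom and seg.strand == "+" and seg.s0 >= e0:
            return j
    return len(segs)


def _insert_at_point(
    layouts: Dict[str, List[_Segment]], dst_chrom: str, p0: int, piece: _Segment
) -> None:
    """Insert ``piece`` into dst_chrom's layout before source position p0."""
    segs = layouts.get(dst_chrom)
    if segs is None:
        raise ValueError(f"destination {dst_chrom!r} not present")
    for i, seg in enumerate(segs):
        if seg.src_chrom == dst_chrom and seg.strand == "+" and seg.s0 <= p0 <= seg.e0:
            if p0 == seg.s0:
                segs.insert(i, piece)
            elif p0 == seg.e0:
                segs.insert(i + 1, piece)
            else:
                head = _Segment(seg.src_chrom, seg.s0, p0)
                tail = _Segment(seg.src_chrom, p0, seg.e0)
                segs[i : i + 1] = [head, piece, tail]
            return
    raise ValueError(
        f"insertion point {dst_chrom}:{p0 + 1} falls inside another operation"
    )


def _apply_indels(
    layouts: Dict[str, List[_Segment]], op: Indel, rng: np.random.Generator
) -> Dict[str, List[_Segment]]:
    out: Dict[str, List[_Segment]] = {}
    for tname, segs in layouts.items():
        new_segs: List[_Segment] = []
        for seg in segs:
            if seg.src_chrom is None or seg.length < 2 * op.max_len + 2:
                new_segs.append(seg)
                continue
            n_events = rng.binomial(seg.length, op.rate)
            if n_events == 0:
                new_segs.append(seg)
                continue
            offs = np.sort(
                rng.choice(
                    np.arange(op.max_len, seg.length - op.max_len),
                    size=min(n_events, max(1, seg.length // (2 * op.max_len + 2))),
                    replace=False,
                )
            )
            cur = seg.s0
            for off in offs:
                cut = seg.s0 + int(off)
                size = int(rng.integers(1, op.max_len + 1))
                if rng.random() < 0.5:  # deletion of source bases from the target
                    if cut + size > seg.e0 - 1 or cut <= cur:
                        continue
                    new_segs.append(_Segment(seg.src_chrom, cur, cut, seg.strand))
                    cur = cut + size
                else:  # insertion of novel bases into the target
                    if cut <= cur:
                        continue
                    new_segs.append(_Segment(seg.src_chrom, cur, cut, seg.strand))
                    novel = rng.choice(_BASES, size=size).tobytes().decode("ascii")
                    new_segs.append(_Segment(None, 0, 0, "+", novel))
                    cur = cut
            new_segs.append(_Segment(seg.src_chrom, cur, seg.e0, seg.strand))
        # minus-strand segments keep their orientation: indels were placed in
        # source coordinates, which is fine for map bookkeeping either way
        out[tname] = new_segs
    return out


# ---------------------------------------------------------------------------
# SNP planting and evaluation
# ---------------------------------------------------------------------------

def plant_snps(
    source: Assembly,
    n: int,
    seed: int = 0,
    exclude_N: bool = True,
    windows: Optional[List[Tuple[str, int, int]]] = None,
) -> List[SnpRecord]:
    """Sample n distinct positions; ref is the source base, alt a random other base.

    ``windows`` (chrom, start1, end1 inclusive) optionally restricts the
    sampled space, emulating exome-style clustering.  Deterministic from
    ``seed``; records come out sorted by (source sequence order, position).
    """
    rng = np.random.default_rng(seed)
    if windows is None:
        space = [(name, 1, len(seq)) for name, seq in source.sequences.items()]
    else:
        space = list(windows)
    sizes = np.array([end - start + 1 for _, start, end in space], dtype=np.int64)
    total = int(sizes.sum())
    if n > total:
        raise ValueError(f"cannot plant {n} SNPs in {total} available positions")
    flat = rng.choice(total, size=n, replace=False)
    flat.sort()
    bounds = np.cumsum(sizes)
    records: List[SnpRecord] = []
    order = {name: i for i, name in enumerate(source.names)}
    picks: List[Tuple[str, int]] = []
    for f in flat:
        wi = int(np.searchsorted(bounds, f, side="right"))
        chrom, start, _ = space[wi]
        offset = int(f - (bounds[wi] - sizes[wi]))
        picks.append((chrom, start + offset))
    picks.sort(key=lambda item: (order[item[0]], item[1]))
    kept = 0
    for chrom, pos in picks:
        ref = source.sequences[chrom][pos - 1]
        if ref not in "ACGT":
            if exclude_N:
                continue
            ref = "N"
        choices = [b for b in "ACGT" if b != ref]
        alt = choices[int(rng.integers(0, len(choices)))]
        records.append(
            SnpRecord(chrom=chrom, pos=pos, id=f"sim{kept}", ref=ref, alts=[alt])
        )
        kept += 1
    return records


@dataclass
class EvalReport:
    """Outcome-vs-truth tally for a lift run over planted SNPs."""

    n_total: int = 0
    n_mapped: int = 0
    n_eligible: int = 0  # mapped, not breakpoint-adjacent
    recovered: int = 0  # consistent and exactly matching truth (eligible only)
    mislifted: int = 0  # consistent but wrong vs truth (counted everywhere)
    missed: int = 0  # mapped + eligible but not consistent
    correct_rejections: int = 0  # truth-unmapped and not consistent
    false_lifts: int = 0  # truth-unmapped but consistent
    by_transition: Dict[str, int] = field(default_factory=dict)

    @property
    def recovery_rate(self) -> float:
        return self.recovered / self.n_eligible if self.n_eligible else 0.0

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_total", "n_mapped", "n_eligible", "recovered", "mislifted",
            "missed", "correct_rejections", "false_lifts",
        )}
        d["recovery_rate"] = self.recovery_rate
        d["by_transition"] = dict(self.by_transition)
        return d


def evaluate(outcomes: Iterable, truth: TruthMap, exclusion_zone: int = 1980) -> EvalReport:
    """Score consensus outcomes against the truth map.

    SNPs within ``exclusion_zone`` bases of a structural breakpoint (or
    piece end) are excluded from the recovery denominator — their windows
    legitimately span discordant material — but any consistent lift is
    still checked for exactness, so mis-lifts are never excused.
    """
    report = EvalReport()
    for outcome in outcomes:
        report.n_total += 1
        snp = outcome.snp
        expected = truth.lookup(snp.chrom, snp.pos)
        consistent = outcome.status == "consistent"
        if expected is None:
            if consistent:
                report.false_lifts += 1
            else:
                report.correct_rejections += 1
            continue
        report.n_mapped += 1
        dist = truth.breakpoint_distance(snp.chrom, snp.pos)
        eligible = dist is not None and dist >= exclusion_zone
        if eligible:
            report.n_eligible += 1
        if consistent:
            actual = (outcome.final_chrom, outcome.final_pos, outcome.final_strand)
            if actual == expected:
                if eligible:
                    report.recovered += 1
                key = outcome.transition or "unclassified"
                report.by_transition[key] = report.by_transition.get(key, 0) + 1
            else:
                report.mislifted += 1
        elif eligible:
            report.missed += 1
    return report
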