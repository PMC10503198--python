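"""Align a parent flank window to a whole target assembly and project its child base.

The engine is a self-contained seed–chain–extend aligner:

1. exact-match k-mer seeding (default k=15) against a sorted k-mer index of
   the target built once per assembly;
2. per-(chromosome, strand) colinear chaining of maximal exact seed runs,
   with a cap on the gap between chained seeds;
3. gapped extension of the inter-seed segments and window ends with an
   affine-gap Needleman–Wunsch, producing an explicit coordinate map of
   (op, length) runs — ``=``/``X`` consume both sequences, ``I`` consumes
   target only, ``D`` consumes parent only.

Every target sequence and both strands are searched (no chromosome-to-
chromosome restriction), so a parent may land on a different chromosome
than its source.  Minus-strand placements store the coordinate map in
reverse-complement-query orientation against the forward target;
:func:`project_child` folds the strand back in.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .assembly_io import Assembly, revcomp
from .feature_bridge import FlankFeature, DEFAULT_MIN_ALIGN_LEN

__all__ = [
    "AlignParams",
    "Placement",
    "ProjectedFeature",
    "Signal",
    "TargetIndex",
    "align_parent",
    "choose_best",
    "project_child",
    "project_feature",
]


@dataclass
class AlignParams:
    """Tunables for seeding, chaining, extension and placement filtering."""

    k: int = 15
    seed_stride: int = 8  # query k-mers sampled every this many bases
    min_len: int = DEFAULT_MIN_ALIGN_LEN
    min_identity: float = 0.5
    min_coverage: float = 0.5
    min_margin: int = 1  # best score must exceed runner-up by >= this
    band: int = 32
    max_gap_factor: float = 2.0  # max seed gap = factor * parent length
    max_occ: int = 100  # drop seeds occurring more often than this
    diag_gap: int = 64  # diagonal jump separating alternative chains at one locus
    min_anchor: int = 20  # min anchored bases for a chain to be extended
    max_chains: int = 8  # extend at most this many top chains
    end_pad: int = 16  # extra target bases allowed at window ends
    max_end_extend: int = 300  # clip (rather than align) window ends longer than this
    max_interior_cells: int = 250_000  # gap segments beyond this become plain D+I runs

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 1.0 and 0.0 <= self.min_coverage <= 1.0):
            raise ValueError("identity/coverage thresholds must be in [0, 1]")
        if self.k < 4 or self.k > 31:
            raise ValueError("k must be in [4, 31]")
        if not (1 <= self.seed_stride <= self.k):
            # stride > k would leave unverified bases between merged seeds
            raise ValueError("seed_stride must be in [1, k]")


class Signal(enum.Enum):
    NO_ALIGNMENT = "no_alignment"
    AMBIGUOUS = "ambiguous"


@dataclass
class Placement:
    """One alignment of a parent window onto the target (forward coordinates).

    ``coord_map`` is in oriented-query order: the query is the parent for
    '+' placements and its reverse complement for '−' placements; target
    coordinates always increase left to right.
    """

    target_chrom: str
    target_start: int  # 0-based half-open, forward strand
    target_end: int
    strand: str  # '+' or '-'
    score: int
    identity: float
    coverage: float
    coord_map: List[Tuple[str, int]]
    query_length: int
    qry_aln_start: int  # 0-based offsets into the oriented query
    qry_aln_end: int

    def __post_init__(self) -> None:
        q_cons = sum(n for op, n in self.coord_map if op in "=XD")
        t_cons = sum(n for op, n in self.coord_map if op in "=XI")
        if q_cons != self.qry_aln_end - self.qry_aln_start:
            raise ValueError("coord_map parent-consumption inconsistent with span")
        if t_cons != self.target_end - self.target_start:
            raise ValueError("coord_map target-consumption inconsistent with span")

    def overlaps(self, other: "Placement") -> bool:
        return (
            self.target_chrom == other.target_chrom
            and self.target_start < other.target_end
            and other.target_start < self.target_end
        )


@dataclass
class ProjectedFeature:
    """Projection result for one flank feature."""

    feature_id: str
    status: str  # lifted | unlifted_* | too_short | chrom_missing
    target_chrom: Optional[str] = None
    target_pos: Optional[int] = None  # 1-based
    target_strand: Optional[str] = None
    identity: Optional[float] = None
    coverage: Optional[float] = None
    score: Optional[int] = None
    score_margin: Optional[float] = None

    def __post_init__(self) -> None:
        has_coords = self.target_chrom is not None and self.target_pos is not None
        if (self.status == "lifted") != has_coords:
            raise ValueError("lifted status must coincide with target coordinates")


# ---------------------------------------------------------------------------
# Sequence encoding and the target k-mer index
# ---------------------------------------------------------------------------

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
    _ENCODE_LUT[_b + 32] = _i  # lowercase


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer codes plus a validity mask (no non-ACGT inside)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    acc = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        acc = acc * np.uint64(4) + codes[j : j + n].astype(np.uint64)
    bad = (codes >= 4).astype(np.int64)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    return acc, valid


def _query_seeds(
    query_codes: np.ndarray, k: int, stride: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Valid query k-mers sampled every ``stride`` bases (last k-mer included)."""
    qk, qvalid = _kmer_codes(query_codes, k)
    if len(qk) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    if stride > 1:
        take = np.zeros(len(qk), dtype=bool)
        take[::stride] = True
        take[-1] = True  # anchor the tail
        qvalid = qvalid & take
    qpos = np.nonzero(qvalid)[0].astype(np.int64)
    return qpos, qk[qvalid]


class TargetIndex:
    """Sorted k-mer index over all target sequences (forward strand).

    Sequences are concatenated with k invalid separators so no k-mer spans
    a boundary; global positions map back to (chromosome, local offset).
    """

    def __init__(self, assembly: Assembly, k: int):
        self.k = k
        self.chrom_names: List[str] = assembly.names
        starts: List[int] = []
        parts: List[np.ndarray] = []
        sep = np.full(k, 255, dtype=np.uint8)
        cur = 0
        for name in self.chrom_names:
            starts.append(cur)
            enc = _encode(assembly.sequences[name])
            parts.append(enc)
            parts.append(sep)
            cur += len(enc) + k
        self.chrom_starts = np.asarray(starts, dtype=np.int64)
        self.chrom_lengths = np.asarray(
            [len(assembly.sequences[n]) for n in self.chrom_names], dtype=np.int64
        )
        codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        kmers, valid = _kmer_codes(codes, k)
        pos = np.nonzero(valid)[0].astype(np.int64)
        km = kmers[valid]
        order = np.argsort(km, kind="stable")
        self.sorted_kmers = km[order]
        self.positions = pos[order]

    @classmethod
    def for_assembly(cls, assembly: Assembly, k: int) -> "TargetIndex":
        """Build or fetch the cached index for ``assembly`` at word size ``k``."""
        key = ("kmer_index", k)
        if key not in assembly._caches:
            assembly._caches[key] = cls(assembly, k)
        return assembly._caches[key]

    def hits_multi(
        self,
        queries: Sequence[Tuple[np.ndarray, np.ndarray]],
        max_occ: int,
    ) -> List[Tuple[np.ndarray, np.ndarray]]:
        """Batched seed lookup: one searchsorted pass over several queries.

        ``queries`` holds (query positions, k-mer codes) pairs; returns the
        matching (query positions, global target positions) per query.
        """
        empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        sizes = [len(qk) for _, qk in queries]
        if sum(sizes) == 0 or len(self.sorted_kmers) == 0:
            return [empty] * len(queries)
        allk = np.concatenate([qk for _, qk in queries])
        left_all = np.searchsorted(self.sorted_kmers, allk, side="left")
        right_all = np.searchsorted(self.sorted_kmers, allk, side="right")
        counts_all = right_all - left_all
        counts_all[counts_all > max_occ] = 0  # repeat masking
        results: List[Tuple[np.ndarray, np.ndarray]] = []
        off = 0
        for (qpos, _), size in zip(queries, sizes):
            left = left_all[off : off + size]
            counts = counts_all[off : off + size]
            off += size
            total = int(counts.sum())
            if total == 0:
                results.append(empty)
                continue
            qidx = np.repeat(qpos, counts)
            starts = np.repeat(left, counts)
            offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
            gpos = self.positions[starts + offs]
            results.append((qidx.astype(np.int64), gpos.astype(np.int64)))
        return results

    def hits(
        self, query_codes: np.ndarray, max_occ: int, stride: int = 1
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Return (query positions, global target positions) of exact k-mer matches."""
        return self.hits_multi(
            [_query_seeds(query_codes, self.k, stride)], max_occ
        )[0]

    def locate(self, gpos: int) -> Tuple[int, int]:
        """Global position -> (chromosome index, local 0-based offset)."""
        ci = int(np.searchsorted(self.chrom_starts, gpos, side="right")) - 1
        return ci, int(gpos - self.chrom_starts[ci])


# ---------------------------------------------------------------------------
# Affine-gap Needleman–Wunsch on short segments
# ---------------------------------------------------------------------------

_NEG = -(10 ** 9)

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -2, -1


class SegmentTooLarge(RuntimeError):
    pass


def _affine_align(
    a: str,
    b: str,
    free_b_start: bool = False,
    free_b_end: bool = False,
    max_cells: int = 4_000_000,
) -> List[Tuple[str, int]]:
    """Global affine-gap alignment of a vs b; returns the (op, length) edit script.

    ``free_b_start``/``free_b_end`` leave leading/trailing unaligned target
    bases unpenalized (emitted as 'I' runs the caller trims).  Scoring:
    match +1, mismatch −1, gap of length L costs −(2 + L).
    """
    n, m = len(a), len(b)
    if n == 0:
        return [("I", m)] if m else []
    if m == 0:
        return [("D", n)]
    if (n + 1) * (m + 1) > max_cells:
        raise SegmentTooLarge(f"alignment segment {n}x{m} exceeds cell budget")
    ea = _encode(a)
    eb = _encode(b)
    go_ge = GAP_OPEN + GAP_EXTEND

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in b: consumes a ('D')
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in a: consumes b ('I')
    tb_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    LM, LX, LY = 0, 1, 2

    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * i
        tb_x[i, 0] = LX
    if free_b_start:
        Y[0, 1:] = 0
    else:
        Y[0, 1:] = GAP_OPEN + GAP_EXTEND * np.arange(1, m + 1, dtype=np.int32)
    tb_y[0, 1:] = LY

    for i in range(1, n + 1):
        ai = ea[i - 1]
        sub = np.where(eb == ai, MATCH, MISMATCH).astype(np.int32)
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        # M and X depend only on the previous row -> vectorize over j
        diag_best = np.maximum(np.maximum(Mp[:-1], Xp[:-1]), Yp[:-1])
        diag_src = np.where(
            Mp[:-1] >= np.maximum(Xp[:-1], Yp[:-1]),
            LM,
            np.where(Xp[:-1] >= Yp[:-1], LX, LY),
        )
        Mi[1:] = diag_best + sub
        tb_m[i, 1:] = diag_src
        x_open = np.maximum(Mp[1:], Yp[1:]) + go_ge
        x_ext = Xp[1:] + GAP_EXTEND
        Xi[1:] = np.maximum(x_open, x_ext)
        tb_x[i, 1:] = np.where(
            x_ext >= x_open, LX, np.where(Mp[1:] >= Yp[1:], LM, LY)
        )
        # Y has an intra-row dependency; short rows keep this loop cheap
        for j in range(1, m + 1):
            y_open = max(Mi[j - 1], Xi[j - 1]) + go_ge
            y_ext = Yi[j - 1] + GAP_EXTEND
            if y_ext >= y_open:
                Yi[j] = y_ext
                tb_y[i, j] = LY
            else:
                Yi[j] = y_open
                tb_y[i, j] = LM if Mi[j - 1] >= Xi[j - 1] else LX

    if free_b_end:
        finals = np.stack([M[n], X[n], Y[n]])
        flat = int(np.argmax(finals))
        layer, j = divmod(flat, m + 1)
        trailing = m - j
    else:
        scores = (M[n, m], X[n, m], Y[n, m])
        layer = int(np.argmax(scores))
        j = m
        trailing = 0

    ops_rev: List[str] = []
    i = n
    while i > 0 or j > 0:
        if layer == LM:
            src = tb_m[i, j]
            ops_rev.append("=" if ea[i - 1] == eb[j - 1] else "X")
            i -= 1
            j -= 1
            layer = src
        elif layer == LX:
            src = tb_x[i, j]
            ops_rev.append("D")
            i -= 1
            layer = src
        else:
            src = tb_y[i, j]
            ops_rev.append("I")
            j -= 1
            layer = src
    ops: List[Tuple[str, int]] = []
    for op in reversed(ops_rev):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    if trailing:
        ops.append(("I", trailing))
    return ops


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

@dataclass
class _Run:
    q: int  # oriented-query start
    g: int  # global target start
    length: int

    @property
    def qend(self) -> int:
        return self.q + self.length

    @property
    def gend(self) -> int:
        return self.g + self.length


def _exact_runs(
    qpos: np.ndarray, gpos: np.ndarray, k: int, stride: int = 1
) -> List[_Run]:
    """Merge diagonal-consecutive k-mer hits into maximal exact-match runs.

    Two same-diagonal hits ``stride`` apart overlap by ``k - stride`` bases
    (stride ≤ k), so their union is itself an exact match.
    """
    if len(qpos) == 0:
        return []
    diag = gpos - qpos
    order = np.lexsort((qpos, diag))
    q = qpos[order]
    g = gpos[order]
    d = diag[order]
    new = np.empty(len(q), dtype=bool)
    new[0] = True
    new[1:] = (np.diff(d) != 0) | (np.diff(q) != stride)
    starts = np.nonzero(new)[0]
    ends = np.append(starts[1:], len(q))
    runs = []
    for s, e in zip(starts, ends):
        span_kmers = int(q[e - 1] - q[s])  # stride-spaced, same diagonal
        runs.append(_Run(int(q[s]), int(g[s]), span_kmers + k))
    return runs


def _cluster_and_chain(
    runs: List[_Run], index: TargetIndex, max_gap: int, min_anchor: int, diag_gap: int
) -> List[Tuple[int, List[_Run]]]:
    """Group runs into candidate loci and pick a colinear chain per locus.

    Runs first cluster by target proximity (same chromosome, gaps at most
    ``max_gap``), then split on diagonal jumps larger than ``diag_gap``:
    indel drift moves the diagonal gradually, whereas an alternative copy
    at the same locus (e.g. a tandem repeat) jumps it by the unit length,
    and such copies must compete as separate placements rather than be
    swallowed by a greedy chain.  Returns (anchored bases, chain) per
    candidate, best-anchored first.
    """
    if not runs:
        return []
    runs_by_g = sorted(runs, key=lambda r: r.g)
    chrom_ids = np.searchsorted(
        index.chrom_starts,
        np.fromiter((r.g for r in runs_by_g), dtype=np.int64, count=len(runs_by_g)),
        side="right",
    ) - 1
    clusters: List[List[_Run]] = [[runs_by_g[0]]]
    cluster_chrom = [chrom_ids[0]]
    for run, ci in zip(runs_by_g[1:], chrom_ids[1:]):
        prev = clusters[-1][-1]
        if ci == cluster_chrom[-1] and run.g - prev.gend <= max_gap:
            clusters[-1].append(run)
        else:
            clusters.append([run])
            cluster_chrom.append(ci)
    chained: List[Tuple[int, List[_Run]]] = []
    for cluster in clusters:
        for group in _split_by_diagonal(cluster, diag_gap):
            chain: List[_Run] = []
            for run in sorted(group, key=lambda r: (r.q, r.g)):
                if not chain:
                    chain.append(run)
                    continue
                prev = chain[-1]
                trim = max(prev.qend - run.q, prev.gend - run.g, 0)
                if run.length - trim <= 0:
                    continue
                if run.g + trim - prev.gend > max_gap:
                    continue
                chain.append(_Run(run.q + trim, run.g + trim, run.length - trim))
            anchored = sum(r.length for r in chain)
            if anchored >= min_anchor:
                chained.append((anchored, chain))
    chained.sort(key=lambda item: -item[0])
    return chained


def _split_by_diagonal(cluster: List[_Run], diag_gap: int) -> List[List[_Run]]:
    by_diag = sorted(cluster, key=lambda r: r.g - r.q)
    groups: List[List[_Run]] = [[by_diag[0]]]
    for run in by_diag[1:]:
        prev = groups[-1][-1]
        if (run.g - run.q) - (prev.g - prev.q) > diag_gap:
            groups.append([run])
        else:
            groups[-1].append(run)
    return groups


# ---------------------------------------------------------------------------
# Extension: chain -> Placement
# ---------------------------------------------------------------------------

def _ops_stats(ops: Sequence[Tuple[str, int]]) -> Tuple[int, int, float, int, int]:
    """(score, columns, identity, q_consumed, t_consumed) of an edit script."""
    score = 0
    matches = mismatches = columns = q_cons = t_cons = 0
    for op, n in ops:
        columns += n
        if op == "=":
            matches += n
            q_cons += n
            t_cons += n
            score += MATCH * n
        elif op == "X":
            mismatches += n
            q_cons += n
            t_cons += n
            score += MISMATCH * n
        elif op == "D":
            q_cons += n
            score += GAP_OPEN + GAP_EXTEND * n
        elif op == "I":
            t_cons += n
            score += GAP_OPEN + GAP_EXTEND * n
        else:  # pragma: no cover - internal invariant
            raise ValueError(f"unknown op {op!r}")
    identity = matches / columns if columns else 0.0
    return score, columns, identity, q_cons, t_cons


def _append_ops(ops: List[Tuple[str, int]], new: Sequence[Tuple[str, int]]) -> None:
    for op, n in new:
        if n <= 0:
            continue
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))


def _extend_chain(
    chain: List[_Run],
    qseq: str,
    tseq: str,
    chrom_name: str,
    chrom_start: int,
    strand: str,
    params: AlignParams,
) -> Optional[Placement]:
    """Fill inter-anchor gaps and window ends, yielding a full Placement."""
    ops: List[Tuple[str, int]] = []
    first = chain[0]
    t_first = first.g - chrom_start
    qry_aln_start = 0
    t_start = t_first
    # left end: align a short unanchored prefix, clip a long one
    if first.q > 0:
        qa = qseq[: first.q]
        if len(qa) > params.max_end_extend:
            qry_aln_start = first.q
        else:
            w0 = max(0, t_first - len(qa) - params.end_pad)
            ta = tseq[w0:t_first]
            try:
                pre = _affine_align(qa, ta, free_b_start=True)
            except SegmentTooLarge:
                return None
            # trim unanchored edge artifacts: leading unaligned target, clipped query
            t_start = w0
            while pre and pre[0][0] in "ID":
                op, n = pre.pop(0)
                if op == "I":
                    t_start += n
                else:
                    qry_aln_start += n
            _append_ops(ops, pre)
    _append_ops(ops, [("=", first.length)])
    prev = first
    for run in chain[1:]:
        qgap = qseq[prev.qend : run.q]
        tgap = tseq[prev.gend - chrom_start : run.g - chrom_start]
        if qgap and tgap:
            if len(qgap) == 1 and len(tgap) == 1:
                _append_ops(ops, [("X", 1)])
            elif len(qgap) * len(tgap) > params.max_interior_cells:
                # unalignably large gap (e.g. an intervening relocation):
                # bridge with explicit gap runs; identity filtering decides
                _append_ops(ops, [("D", len(qgap)), ("I", len(tgap))])
            else:
                try:
                    _append_ops(ops, _affine_align(qgap, tgap))
                except SegmentTooLarge:
                    return None
        elif qgap:
            _append_ops(ops, [("D", len(qgap))])
        elif tgap:
            _append_ops(ops, [("I", len(tgap))])
        _append_ops(ops, [("=", run.length)])
        prev = run
    qry_aln_end = prev.qend
    # right end: align a short unanchored suffix, clip a long one
    if prev.qend < len(qseq):
        qb = qseq[prev.qend :]
        if len(qb) > params.max_end_extend:
            qry_aln_end = prev.qend
        else:
            t_last = prev.gend - chrom_start
            tb = tseq[t_last : min(len(tseq), t_last + len(qb) + params.end_pad)]
            try:
                post = _affine_align(qb, tb, free_b_end=True)
            except SegmentTooLarge:
                return None
            clipped_q = 0
            while post and post[-1][0] in "ID":
                op, n = post.pop()
                if op == "D":
                    clipped_q += n
            _append_ops(ops, post)
            qry_aln_end = len(qseq) - clipped_q
    score, _, identity, q_cons, t_cons = _ops_stats(ops)
    return Placement(
        target_chrom=chrom_name,
        target_start=t_start,
        target_end=t_start + t_cons,
        strand=strand,
        score=score,
        identity=identity,
        coverage=q_cons / len(qseq),
        coord_map=ops,
        query_length=len(qseq),
        qry_aln_start=qry_aln_start,
        qry_aln_end=qry_aln_end,
    )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _candidate_placements(
    parent_seq: str, target: Assembly, params: AlignParams
) -> List[Placement]:
    """All chain-extended placements on both strands, unfiltered."""
    index = TargetIndex.for_assembly(target, params.k)
    max_gap = int(params.max_gap_factor * len(parent_seq))
    placements: List[Placement] = []
    oriented = {"+": parent_seq, "-": revcomp(parent_seq)}
    seed_queries = [
        _query_seeds(_encode(oriented[strand]), params.k, params.seed_stride)
        for strand in "+-"
    ]
    strand_hits = dict(zip("+-", index.hits_multi(seed_queries, params.max_occ)))
    for strand in "+-":
        qseq = oriented[strand]
        qpos, gpos = strand_hits[strand]
        runs = _exact_runs(qpos, gpos, params.k, params.seed_stride)
        chains = _cluster_and_chain(
            runs, index, max_gap, params.min_anchor, params.diag_gap
        )
        for _, chain in chains[: params.max_chains]:
            ci, _ = index.locate(chain[0].g)
            chrom_name = index.chrom_names[ci]
            placement = _extend_chain(
                chain,
                qseq,
                target.sequences[chrom_name],
                chrom_name,
                int(index.chrom_starts[ci]),
                strand,
                params,
            )
            if placement is not None:
                placements.append(placement)
    return placements


def align_parent(
    parent_seq: str, target: Assembly, params: Optional[AlignParams] = None
) -> List[Placement]:
    """Align a parent window to the whole target; return passing placements.

    Placements are filtered by ``min_identity`` and ``min_coverage``.
    Parents shorter than ``min_len`` violate the precondition and raise.
    """
    params = params or AlignParams()
    if len(parent_seq) < params.min_len:
        raise ValueError(
            f"parent length {len(parent_seq)} below minimum alignable "
            f"length {params.min_len}"
        )
    if len(target) == 0:
        raise ValueError("empty target assembly")
    return [
        p
        for p in _candidate_placements(parent_seq, target, params)
        if p.identity >= params.min_identity and p.coverage >= params.min_coverage
    ]


def choose_best(
    placements: List[Placement], params: Optional[AlignParams] = None
) -> Union[Placement, Signal]:
    """Pick the single best placement, or signal ambiguity / no alignment.

    Placements are sorted by (score desc, chrom, start) so the result does
    not depend on input order; overlapping same-strand placements collapse
    to their best representative before the margin test.
    """
    params = params or AlignParams()
    if not placements:
        return Signal.NO_ALIGNMENT
    ranked = sorted(
        placements, key=lambda p: (-p.score, p.target_chrom, p.target_start, p.strand)
    )
    distinct: List[Placement] = []
    for p in ranked:
        if not any(p.overlaps(kept) and p.strand == kept.strand for kept in distinct):
            distinct.append(p)
    if len(distinct) == 1:
        return distinct[0]
    if distinct[0].score - distinct[1].score < params.min_margin:
        return Signal.AMBIGUOUS
    return distinct[0]


def project_child(
    placement: Placement, parent_start: int, child_pos: int
) -> Optional[Tuple[str, int, str]]:
    """Walk the coordinate map to the child base; None if it was deleted/clipped.

    ``parent_start`` and ``child_pos`` are 1-based source coordinates; the
    returned target position is 1-based.  For '−' placements the child
    offset is counted from the oriented (reverse-complement) query start,
    i.e. from the placement's right edge in parent terms.
    """
    offset = child_pos - parent_start  # 0-based offset in the parent
    if not (0 <= offset < placement.query_length):
        raise ValueError("child position outside parent window")
    if placement.strand == "+":
        qo = offset
    else:
        qo = placement.query_length - 1 - offset
    if not (placement.qry_aln_start <= qo < placement.qry_aln_end):
        return None  # clipped end
    q = placement.qry_aln_start
    t = placement.target_start
    for op, n in placement.coord_map:
        if op in "=X":
            if qo < q + n:
                return (placement.target_chrom, t + (qo - q) + 1, placement.strand)
            q += n
            t += n
        elif op == "D":
            if qo < q + n:
                return None  # child base deleted from the target
            q += n
        else:  # "I"
            t += n
    return None  # pragma: no cover - walk always terminates inside the span


def project_feature(
    feature: FlankFeature,
    source: Assembly,
    target: Assembly,
    params: Optional[AlignParams] = None,
) -> ProjectedFeature:
    """Extract, align and project one flank feature end to end."""
    params = params or AlignParams()
    if feature.error is not None:
        return ProjectedFeature(feature_id=feature.feature_id, status=feature.error)
    if feature.too_short or feature.parent_length < params.min_len:
        return ProjectedFeature(feature_id=feature.feature_id, status="too_short")
    parent_seq = feature.parent_sequence(source)
    raw = _candidate_placements(parent_seq, target, params)
    if not raw:
        return ProjectedFeature(
            feature_id=feature.feature_id, status="unlifted_no_alignment"
        )
    passing = [
        p
        for p in raw
        if p.identity >= params.min_identity and p.coverage >= params.min_coverage
    ]
    if not passing:
        return ProjectedFeature(
            feature_id=feature.feature_id, status="unlifted_below_threshold"
        )
    best = choose_best(passing, params)
    if best is Signal.AMBIGUOUS:
        return ProjectedFeature(
            feature_id=feature.feature_id, status="unlifted_ambiguous"
        )
    assert isinstance(best, Placement)
    margin = float("inf")
    others = [p.score for p in passing if p is not best]
    if others:
        margin = best.score - max(others)
    result = project_child(best, feature.parent_start, feature.child_pos)
    if result is None:
        return ProjectedFeature(
            feature_id=feature.feature_id, status="unlifted_child_deleted"
        )
    chrom, pos, strand = result
    return ProjectedFeature(
        feature_id=feature.feature_id,
        status="lifted",
        target_chrom=chrom,
        target_pos=pos,
        target_strand=strand,
        identity=best.identity,
        coverage=best.coverage,
        score=best.score,
        score_margin=margin,
    )
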