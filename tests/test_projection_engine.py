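import numpy as np
import pytest
from Bio import Align

from flanklift.assembly_io import Assembly, SnpRecord, revcomp
from flanklift.feature_bridge import build_flank_features
from flanklift.projection_engine import (
    AlignParams,
    Placement,
    Signal,
    align_parent,
    choose_best,
    project_child,
    project_feature,
)
from flanklift.synthetic_assembly import (
    AssemblyEditScript,
    Drop,
    Invert,
    apply_edit_script,
    generate_source,
    inject_tandem_repeat,
    plant_snps,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _match_placement(chrom, start, n, strand="+", score=None):
    return Placement(
        target_chrom=chrom, target_start=start, target_end=start + n,
        strand=strand, score=score if score is not None else n,
        identity=1.0, coverage=1.0, coord_map=[("=", n)],
        query_length=n, qry_aln_start=0, qry_aln_end=n,
    )


# ---------------------------------------------------------------------------
# The brute-force oracle: optimal glocal alignment with the engine's scoring
# ---------------------------------------------------------------------------

def _oracle_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3  # gap of length L costs -(2 + L)
    aligner.extend_gap_score = -1
    # target overhang at either end is free (glocal: global in the query)
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


def _oracle_child_pos(parent, target_seq, child_off, alignment):
    """Target position (1-based) aligned to parent[child_off] in one alignment."""
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        if q0 <= child_off < q1:
            return t0 + (child_off - q0) + 1
    return None


class TestAlignParent:
    def test_exact_substring(self):
        rng = np.random.default_rng(0)
        tseq = _random_seq(rng, 30_000)
        target = Assembly({"c3": tseq})
        parent = tseq[10_000:11_001]
        placements = align_parent(parent, target)
        assert len(placements) == 1
        p = placements[0]
        assert (p.target_chrom, p.target_start, p.target_end, p.strand) == (
            "c3", 10_000, 11_001, "+"
        )
        assert p.identity == 1.0 and p.coverage == 1.0

    def test_reverse_complement_hits_minus(self):
        rng = np.random.default_rng(1)
        tseq = _random_seq(rng, 20_000)
        target = Assembly({"t": tseq})
        parent = revcomp(tseq[5_000:5_601])
        (p,) = align_parent(parent, target)
        assert p.strand == "-"
        assert (p.target_start, p.target_end) == (5_000, 5_601)
        assert p.identity == 1.0

    def test_scattered_substitutions_identity(self):
        rng = np.random.default_rng(2)
        tseq = _random_seq(rng, 10_000)
        target = Assembly({"t": tseq})
        parent = list(tseq[4_000:4_150])
        for off in (20, 75, 130):
            parent[off] = {"A": "C", "C": "G", "G": "T", "T": "A"}[parent[off]]
        parent = "".join(parent)
        (p,) = align_parent(parent, target)
        assert p.identity == pytest.approx(147 / 150)
        # cross-check against the brute-force global aligner's optimum
        aligner = _oracle_aligner()
        best = aligner.align(tseq[3_900:4_250], parent)[0]
        assert p.score == best.score

    def test_short_parent_precondition(self):
        target = Assembly({"t": "ACGT" * 100})
        with pytest.raises(ValueError, match="minimum alignable"):
            align_parent("ACGT" * 20, target)  # 80 bp < 100

    def test_absent_homology_no_placements(self):
        rng = np.random.default_rng(3)
        target = Assembly({"t": _random_seq(rng, 5_000)})
        foreign = _random_seq(np.random.default_rng(999), 500)
        assert align_parent(foreign, target) == []


class TestChooseBest:
    def test_max_wins(self):
        a = _match_placement("c1", 100, 980, score=980)
        b = _match_placement("c1", 50_000, 400, score=400)
        assert choose_best([b, a]) is a

    def test_tie_on_different_loci_is_ambiguous(self):
        a = _match_placement("c1", 100, 980, score=980)
        b = _match_placement("c5", 100, 980, score=980)
        assert choose_best([a, b]) is Signal.AMBIGUOUS

    def test_empty_is_no_alignment(self):
        assert choose_best([]) is Signal.NO_ALIGNMENT

    def test_order_independence(self):
        a = _match_placement("c1", 100, 500, score=500)
        b = _match_placement("c2", 100, 500, score=499)
        assert choose_best([a, b]) is choose_best([b, a]) is a

    def test_overlapping_duplicates_collapse(self):
        a = _match_placement("c1", 100, 500, score=500)
        b = _match_placement("c1", 120, 500, score=500)  # same locus, overlap
        assert choose_best([a, b]) in (a, b)


class TestProjectChild:
    def test_identity_map(self):
        p = _match_placement("t", 4499, 1001)
        assert project_child(p, parent_start=4500, child_pos=5000) == ("t", 5000, "+")

    def test_walk_through_insertion(self):
        coord_map = [("=", 100), ("I", 10), ("=", 401)]
        p = Placement(
            target_chrom="t", target_start=1000, target_end=1511, strand="+",
            score=499, identity=501 / 511, coverage=1.0, coord_map=coord_map,
            query_length=501, qry_aln_start=0, qry_aln_end=501,
        )
        # child at parent offset 300: 1000 + 300 + 10 + 1 (1-based)
        assert project_child(p, parent_start=1, child_pos=301) == ("t", 1311, "+")

    def test_child_inside_deletion(self):
        coord_map = [("=", 100), ("D", 5), ("=", 396)]
        p = Placement(
            target_chrom="t", target_start=0, target_end=496, strand="+",
            score=489, identity=496 / 501, coverage=1.0, coord_map=coord_map,
            query_length=501, qry_aln_start=0, qry_aln_end=501,
        )
        assert project_child(p, parent_start=1, child_pos=103) is None

    def test_clipped_child_is_deleted_signal(self):
        p = Placement(
            target_chrom="t", target_start=0, target_end=90, strand="+",
            score=90, identity=1.0, coverage=0.9, coord_map=[("=", 90)],
            query_length=100, qry_aln_start=10, qry_aln_end=100,
        )
        assert project_child(p, parent_start=1, child_pos=5) is None

    def test_out_of_window_raises(self):
        p = _match_placement("t", 0, 100)
        with pytest.raises(ValueError):
            project_child(p, parent_start=1, child_pos=500)


class TestCoordMapConservation:
    def test_inconsistent_parent_span_rejected(self):
        with pytest.raises(ValueError, match="parent-consumption"):
            Placement(
                target_chrom="t", target_start=0, target_end=10, strand="+",
                score=10, identity=1.0, coverage=1.0, coord_map=[("=", 10)],
                query_length=10, qry_aln_start=0, qry_aln_end=9,
            )

    def test_inconsistent_target_span_rejected(self):
        with pytest.raises(ValueError, match="target-consumption"):
            Placement(
                target_chrom="t", target_start=0, target_end=11, strand="+",
                score=10, identity=1.0, coverage=1.0, coord_map=[("=", 10)],
                query_length=10, qry_aln_start=0, qry_aln_end=10,
            )


class TestProjectFeature:
    def test_self_lift(self, small_source, small_snps):
        feats = build_flank_features(small_snps[:10], 500, small_source)
        for feat in feats:
            pf = project_feature(feat, small_source, small_source)
            assert pf.status == "lifted"
            assert (pf.target_chrom, pf.target_pos, pf.target_strand) == (
                feat.chrom, feat.child_pos, "+"
            )
            assert pf.identity == 1.0

    def test_inversion_maps_to_closed_form(self):
        source = generate_source(1, [60_000], 0, [], 0.5, seed=11)
        a, b = 20_001, 30_000
        target, truth = apply_edit_script(
            source, AssemblyEditScript(seed=0, ops=[Invert("chr1", a, b)])
        )
        snps = [s for s in plant_snps(source, 200, seed=4)
                if a + 2000 <= s.pos <= b - 2000][:5]
        assert snps
        for snp in snps:
            (feat,) = list(build_flank_features([snp], 1000, source))
            pf = project_feature(feat, source, target)
            assert pf.status == "lifted"
            assert (pf.target_chrom, pf.target_pos, pf.target_strand) == (
                "chr1", a + b - snp.pos, "-"
            )
            assert truth.lookup(snp.chrom, snp.pos) == (
                pf.target_chrom, pf.target_pos, pf.target_strand
            )

    def test_dropped_scaffold_unlifted(self):
        source = generate_source(1, [40_000], 1, [8_000], 0.5, seed=12)
        target, _ = apply_edit_script(
            source, AssemblyEditScript(seed=0, ops=[Drop("chrUn_1")])
        )
        snp = plant_snps(source, 400, seed=5)
        un = [s for s in snp if s.chrom == "chrUn_1"][0]
        (feat,) = list(build_flank_features([un], 500, source))
        pf = project_feature(feat, source, target)
        assert pf.status == "unlifted_no_alignment"

    def test_too_short_feature(self):
        source = Assembly({"c1": "ACGT" * 20})
        snp = SnpRecord("c1", 40, "A", ["G"])
        (feat,) = list(build_flank_features([snp], 10, source))
        pf = project_feature(feat, source, source)
        assert pf.status == "too_short"

    def test_tandem_repeat_ambiguous(self):
        source = generate_source(1, [30_000], 0, [], 0.5, seed=13)
        target = inject_tandem_repeat(source, "chr1", 5_000, 2_000, copies=2)
        snp = SnpRecord("chr1", 6_000, source.sequences["chr1"][5_999], ["A"])
        if snp.alts[0] == snp.ref:
            snp.alts = ["C"]
        (feat,) = list(build_flank_features([snp], 500, source))
        pf = project_feature(feat, source, target)
        assert pf.status == "unlifted_ambiguous"


class TestReverseComplementSymmetry:
    def test_whole_target_revcomp(self):
        source = generate_source(1, [25_000], 0, [], 0.5, seed=21)
        length = source.lengths["chr1"]
        target = Assembly({"chr1": revcomp(source.sequences["chr1"])})
        for snp in plant_snps(source, 10, seed=6):
            (feat,) = list(build_flank_features([snp], 500, source))
            pf = project_feature(feat, source, target)
            assert pf.status == "lifted"
            assert (pf.target_pos, pf.target_strand) == (length - snp.pos + 1, "-")


class TestOracleEquivalence:
    """Dual-route check: engine coord-map walk vs optimal global alignment."""

    def _one_case(self, rng):
        plen = int(rng.integers(200, 601))
        parent = _random_seq(rng, plen)
        child_off = plen // 2
        mutated = list(parent)
        for i in range(plen):  # ~1% substitutions
            if rng.random() < 0.01:
                mutated[i] = "ACGT"[(("ACGT".index(mutated[i])) + 1 + int(rng.integers(3))) % 4]
        # up to 2 small indels away from the child base
        for _ in range(int(rng.integers(0, 3))):
            at = int(rng.integers(20, plen - 20))
            if abs(at - child_off) < 30:
                continue
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                mutated[at : at + size] = []
            else:
                mutated[at:at] = list(_random_seq(rng, size))
        flank_l = _random_seq(rng, int(rng.integers(200, 700)))
        flank_r = _random_seq(rng, int(rng.integers(200, 700)))
        return parent, child_off, flank_l + "".join(mutated) + flank_r

    def run_cases(self, n_cases, seed):
        rng = np.random.default_rng(seed)
        aligner = _oracle_aligner()
        checked = agreed = 0
        for _ in range(n_cases):
            parent, child_off, tseq = self._one_case(rng)
            target = Assembly({"t": tseq})
            placements = align_parent(parent, target)
            best = choose_best(placements)
            if not isinstance(best, Placement):
                continue
            engine = project_child(best, 1, child_off + 1)
            alignments = aligner.align(tseq, parent)
            oracle = _oracle_child_pos(parent, tseq, child_off, alignments[0])
            engine_pos = engine[1] if engine else None
            checked += 1
            if engine_pos == oracle:
                agreed += 1
                continue
            # the optimum may be degenerate: accept if any co-optimal
            # alignment places the child where the engine did
            co_optimal = {oracle}
            for i, aln in enumerate(alignments):
                if i >= 20:
                    break
                co_optimal.add(_oracle_child_pos(parent, tseq, child_off, aln))
            if engine_pos in co_optimal:
                agreed += 1
        return checked, agreed

    def test_engine_matches_brute_force(self):
        checked, agreed = self.run_cases(40, seed=31)
        assert checked >= 35
        assert agreed == checked
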