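import numpy as np
import pytest
from Bio.Seq import Seq

from flanklift.assembly_io import Assembly, GffFormatError, SnpRecord, revcomp
from flanklift.effect_context import (
    REGIONS,
    TranscriptModel,
    annotate,
    classify_coding_effect,
    classify_region,
    impact_bucket,
    read_gene_models,
)


def _snp(chrom, pos, ref="A", alt="C"):
    return SnpRecord(chrom, pos, ref, [alt])


@pytest.fixture
def two_exon_plus():
    # exons [101,200] and [301,400]; CDS [121,200] + [301,380]
    return TranscriptModel(
        id="tx+", chrom="c", strand="+",
        exons=[(101, 200), (301, 400)], cds=[(121, 200), (301, 380)],
    )


class TestRegionRules:
    def expected_label(self, pos):
        """Independent positional rule table for the two-exon '+' fixture."""
        if pos in (201, 202):
            return "splice_site_donor"
        if pos in (299, 300):
            return "splice_site_acceptor"
        if 203 <= pos <= 208 or 293 <= pos <= 298:
            return "splice_site_region"
        if 198 <= pos <= 200 or 301 <= pos <= 303:
            return "splice_site_region"  # exonic bases 1-3 at internal junctions
        if 209 <= pos <= 292:
            return "intron"
        if 101 <= pos <= 120:
            return "utr5"
        if 381 <= pos <= 400:
            return "utr3"
        if 101 <= pos <= 200 or 301 <= pos <= 400:
            return "exon"
        if pos < 101:
            return "upstream" if pos >= 101 - 5000 else "intergenic"
        return "downstream" if pos <= 400 + 5000 else "intergenic"

    def test_exhaustive_sweep_total_function(self, two_exon_plus):
        for pos in range(1, 6000):
            label = classify_region(_snp("c", pos), two_exon_plus)
            assert label in REGIONS
            assert label == self.expected_label(pos), f"pos {pos}"

    def test_spec_examples(self, two_exon_plus):
        tx = TranscriptModel(id="t", chrom="c", strand="+", exons=[(101, 200), (301, 400)])
        assert classify_region(_snp("c", 201), tx) == "splice_site_donor"
        assert classify_region(_snp("c", 202), tx) == "splice_site_donor"
        assert classify_region(_snp("c", 203), tx) == "splice_site_region"
        assert classify_region(_snp("c", 299), tx) == "splice_site_acceptor"
        assert classify_region(_snp("c", 300), tx) == "splice_site_acceptor"
        assert classify_region(_snp("c", 50), tx) == "upstream"
        minus = TranscriptModel(id="tm", chrom="c", strand="-", exons=[(101, 200), (301, 400)])
        assert classify_region(_snp("c", 50), minus) == "downstream"

    def test_window_boundary(self, two_exon_plus):
        assert classify_region(_snp("c", 101 - 5000), two_exon_plus) == "upstream"
        assert classify_region(_snp("c", 400 + 5001), two_exon_plus) == "intergenic"
        assert classify_region(_snp("other", 150), two_exon_plus) == "intergenic"

    def test_strand_mirror_property(self):
        """A '-' transcript equals its '+' mirror on the reverse-complemented chromosome."""
        L = 1000
        exons = [(101, 200), (301, 400)]
        cds = [(121, 200), (301, 380)]

        def mirror(iv):
            return (L - iv[1] + 1, L - iv[0] + 1)

        minus = TranscriptModel(id="m", chrom="c", strand="-", exons=exons, cds=cds)
        plus = TranscriptModel(
            id="p", chrom="c", strand="+",
            exons=sorted(mirror(e) for e in exons),
            cds=sorted(mirror(c) for c in cds),
        )
        for pos in range(1, L + 1):
            lab_minus = classify_region(_snp("c", pos), minus)
            lab_plus = classify_region(_snp("c", L - pos + 1), plus)
            assert lab_minus == lab_plus, f"pos {pos}: {lab_minus} != {lab_plus}"


class TestCodingEffect:
    def _single_exon(self, cds_seq, strand="+"):
        if strand == "-":
            genomic = revcomp(cds_seq)
        else:
            genomic = cds_seq
        chrom_seq = "ACGT" * 25 + genomic + "TGCA" * 25
        start = 101
        end = start + len(genomic) - 1
        asm = Assembly({"c": chrom_seq})
        tx = TranscriptModel(
            id="t", chrom="c", strand=strand, exons=[(start, end)], cds=[(start, end)]
        )
        return asm, tx, start

    def test_start_lost(self):
        asm, tx, start = self._single_exon("ATGGCTTAA")
        snp = SnpRecord("c", start, "A", ["G"])  # ATG -> GTG
        assert classify_coding_effect(snp, tx, asm) == "start_lost"

    def test_stop_gained(self):
        asm, tx, start = self._single_exon("ATGTACTAA")
        snp = SnpRecord("c", start + 5, "C", ["A"])  # TAC -> TAA
        assert classify_coding_effect(snp, tx, asm) == "stop_gained"

    def test_stop_lost(self):
        asm, tx, start = self._single_exon("ATGGCTTAA")
        snp = SnpRecord("c", start + 8, "A", ["C"])  # TAA -> TAC
        assert classify_coding_effect(snp, tx, asm) == "stop_lost"

    def test_synonymous(self):
        asm, tx, start = self._single_exon("ATGCTATAA")
        snp = SnpRecord("c", start + 5, "A", ["G"])  # CTA -> CTG, both Leu
        assert classify_coding_effect(snp, tx, asm) == "synonymous"

    def test_missense(self):
        asm, tx, start = self._single_exon("ATGGCTTAA")
        snp = SnpRecord("c", start + 4, "C", ["A"])  # GCT -> GAT, Ala -> Asp
        assert classify_coding_effect(snp, tx, asm) == "missense"

    def test_minus_strand(self):
        asm, tx, start = self._single_exon("ATGGCTTAA", strand="-")
        # genomic = revcomp(CDS); codon 1 base 1 is the genomic LAST base
        end = start + 8
        genomic_ref = asm.sequences["c"][end - 1]
        assert genomic_ref == "T"  # complement of CDS 'A'
        snp = SnpRecord("c", end, "T", ["C"])  # CDS A->G: ATG -> GTG
        assert classify_coding_effect(snp, tx, asm) == "start_lost"

    def test_non_cds_is_contract_violation(self, two_exon_plus):
        asm = Assembly({"c": "A" * 500})
        with pytest.raises(ValueError):
            classify_coding_effect(_snp("c", 110), two_exon_plus, asm)

    def test_oracle_translate_and_diff(self):
        """Engine codon-local labels vs a whole-CDS translate-and-diff oracle."""
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(250):
            n_codons = int(rng.integers(4, 40))
            body = "".join(
                rng.choice(["GCT", "TGC", "GAT", "GAA", "TTT", "GGA", "CAT",
                            "AAA", "CTG", "AAT", "CCC", "AGA", "TCA", "GTT",
                            "TGG", "TAC"], size=n_codons)
            )
            cds = "ATG" + body + "TAA"
            strand = "+" if rng.random() < 0.5 else "-"
            asm, tx, start = self._single_exon(cds, strand=strand)
            off = int(rng.integers(0, len(cds)))
            ref_base = cds[off]
            alt_base = "ACGT"[("ACGT".index(ref_base) + 1 + int(rng.integers(3))) % 4]
            if strand == "+":
                pos = start + off
                g_ref, g_alt = ref_base, alt_base
            else:
                pos = start + len(cds) - 1 - off
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                g_ref, g_alt = comp[ref_base], comp[alt_base]
            snp = SnpRecord("c", pos, g_ref, [g_alt])
            got = classify_coding_effect(snp, tx, asm)
            mutated = cds[:off] + alt_base + cds[off + 1 :]
            ref_prot = str(Seq(cds).translate())
            alt_prot = str(Seq(mutated).translate())
            if off < 3:
                want = "start_lost" if alt_prot[0] != "M" else "synonymous"
            else:
                ci = off // 3
                if ref_prot[ci] == alt_prot[ci]:
                    want = "synonymous"
                elif ref_prot[ci] != "*" and alt_prot[ci] == "*":
                    want = "stop_gained"
                elif ref_prot[ci] == "*" and alt_prot[ci] != "*":
                    want = "stop_lost"
                else:
                    want = "missense"
            assert got == want, f"off={off} strand={strand}: {got} != {want}"
            checked += 1
        assert checked == 250


class TestImpact:
    @pytest.mark.parametrize(
        "region,effect,want",
        [
            ("exon", "missense", "moderate"),
            ("splice_site_donor", "none", "high"),
            ("splice_site_acceptor", "none", "high"),
            ("exon", "stop_gained", "high"),
            ("exon", "stop_lost", "high"),
            ("exon", "start_lost", "high"),
            ("exon", "synonymous", "low"),
            ("splice_site_region", "none", "low"),
            ("intergenic", "none", "modifier"),
            ("intron", "none", "modifier"),
            ("utr5", "none", "modifier"),
            ("upstream", "none", "modifier"),
            ("exon", "none", "modifier"),
        ],
    )
    def test_buckets(self, region, effect, want):
        assert impact_bucket(region, effect) == want


class TestAnnotate:
    def test_multiple_isoforms_multiple_effects(self):
        tx1 = TranscriptModel(id="iso1", chrom="c", strand="+", exons=[(101, 400)])
        tx2 = TranscriptModel(
            id="iso2", chrom="c", strand="+", exons=[(101, 200), (301, 400)]
        )
        effects, _ = annotate([_snp("c", 250)], [tx1, tx2])
        assert len(effects) == 2
        regions = {e.transcript_id: e.region for e in effects}
        assert regions == {"iso1": "exon", "iso2": "intron"}

    def test_intergenic_when_nothing_in_reach(self, two_exon_plus):
        effects, _ = annotate([_snp("c", 50_000)], [two_exon_plus])
        (eff,) = effects
        assert eff.region == "intergenic" and eff.transcript_id is None

    def test_window_rule(self, two_exon_plus):
        effects, _ = annotate([_snp("c", 400 + 6000)], [two_exon_plus], updown_window=5000)
        assert effects[0].region == "intergenic"

    def test_percentages_normalize(self, two_exon_plus):
        snps = [_snp("c", p) for p in range(90, 500, 40)]
        effects, table = annotate(snps, [two_exon_plus])
        assert len(effects) >= len(snps)
        assert sum(v["count"] for v in table.values()) == len(effects)
        assert sum(v["percentage"] for v in table.values()) == pytest.approx(100.0, abs=0.1)


class TestGeneModels:
    GFF = (
        "##gff-version 3\n"
        "c\tsrc\tgene\t101\t400\t.\t+\t.\tID=g1\n"
        "c\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=g1\n"
        "c\tsrc\texon\t101\t200\t.\t+\t.\tParent=t1\n"
        "c\tsrc\texon\t301\t400\t.\t+\t.\tParent=t1\n"
        "c\tsrc\tCDS\t121\t200\t.\t+\t0\tParent=t1\n"
        "c\tsrc\tCDS\t301\t379\t.\t+\t2\tParent=t1\n"
    )

    def test_parse_hierarchy(self, tmp_path):
        path = tmp_path / "m.gff3"
        path.write_text(self.GFF)
        (tx,) = read_gene_models(path)
        assert tx.id == "t1" and tx.biotype == "coding"
        assert tx.exons == [(101, 200), (301, 400)]
        assert tx.cds == [(121, 200), (301, 379)]
        assert tx.frame_ok  # 80 + 79 = 159 bases, 53 codons

    def test_orphan_child_names_line(self, tmp_path):
        path = tmp_path / "m.gff3"
        path.write_text("##gff-version 3\nc\tsrc\texon\t1\t10\t.\t+\t.\tParent=nope\n")
        with pytest.raises(GffFormatError, match="line 2"):
            read_gene_models(path)
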