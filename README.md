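# flanklift

Chain-file-free lift-over of SNPs between two versions of a genome
assembly.

Classic lift-over tools need a precomputed chain file, which is expensive
to build for large, repeat-rich genomes. `flanklift` instead treats each
SNP as a 1-bp *child* feature inside a *parent* flank window (SNP ± L
bases, 2L+1 bp total). The parent is aligned against the whole target
assembly — every sequence, both strands, no chromosome-to-chromosome
restriction — and the child's single-base target coordinate is read off
the alignment's coordinate map. Lifting is repeated at several flank
lengths (default 500, 1,000, 1,250 and 1,980 bp) and only SNPs projected
to the identical (chromosome, position, strand) at **every** length are
kept: the consensus set. Minus-strand lifts are dropped by default
(`drop_minus`) or kept with complemented alleles (`rescue_minus`).

The aligner is a self-contained seed–chain–extend implementation:
exact-match k-mer seeding (k = 15, strided sampling), colinear chaining of
exact seed runs per (chromosome, strand) locus, and affine-gap
Needleman–Wunsch extension of the inter-seed segments, producing an
explicit edit script that is walked to project the child base. Parents
shorter than 100 bp are flagged unalignable; placements below 50%
identity or coverage are discarded; exact score ties across loci are
reported as ambiguous and left unlifted.

The package also ships:

- a **synthetic assembly-update simulator** (`flanklift simulate`)
  generating a source assembly (chromosomes + unanchored `chrUn_*`
  scaffolds), a derived target produced by inversions, relocations,
  scaffold anchoring/dropping, indels and point divergence, a planted SNP
  VCF, and an exact source→target *truth map* used as the oracle in every
  recovery test;
- **transition classification** (same chromosome, different chromosome,
  unanchored→anchored, …), summary tables and per-chromosome binned SNP
  **density profiles**;
- a minimal **effect classifier** (`flanklift annotate`): transcript-
  relative regions (splice donor/acceptor/region, UTRs, exon, intron,
  up/downstream, intergenic), codon-level coding effects (synonymous,
  missense, start lost, stop gained/lost) and high/moderate/low/modifier
  impact buckets.

## CLI

```sh
flanklift --show-config                 # all defaults as JSON

# simulate an assembly update + planted SNPs
flanklift simulate --config sim.yaml --out-dir sim/

# lift a VCF from source to target coordinates
flanklift lift sim/snps.vcf sim/source.fa sim/target.fa --out-dir lift/ \
    --flanks 500,1000,1250,1980 --strand-policy drop_minus

# score the run against the simulator's truth map
flanklift evaluate lift/outcomes.tsv sim/truth.tsv

# effect classification and density profiles
flanklift annotate lift/lifted.vcf genes.gff3 --fasta sim/target.fa --out-dir ann/
flanklift density lift/lifted.vcf sim/target.fa --bin-size 10000000 --out density.tsv
```

`lift` writes `lifted.vcf` (with `LV1_CHROM`/`LV1_POS` original
coordinates, `LV_STRAND`, `LV_IDENTITY_MIN` and `LV_TRUNC` INFO keys),
`summary.json`, `transitions.tsv`, a per-SNP `outcomes.tsv` and a
`manifest.json` recording config and input checksums.

A simulation config looks like:

```yaml
seed: 11
genome:
  n_chroms: 2
  chrom_lengths: [60000, 40000]
  n_unanchored: 1
  un_lengths: [10000]
  gc: 0.5
n_snps: 40
ops:
  - {op: invert, chrom: chr1, start: 20001, end: 30000}
  - {op: relocate, src_chrom: chr2, start: 5001, end: 9000, dst_chrom: chr1, dst_pos: 40001, orientation: "+"}
  - {op: anchor, un_scaffold: chrUn_1, dst_chrom: chr2, dst_pos: 20001, orientation: "+"}
  - {op: diverge, rate: 0.005}
```

## Coordinate conventions

VCF/GFF3 coordinates are 1-based inclusive at every file boundary;
all internal interval arithmetic is 0-based half-open. Coordinate maps
are (op, length) runs where `=`/`X` consume both sequences, `I` consumes
target only and `D` consumes parent only.
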