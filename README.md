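# ampliseq

A toolkit for processing microfluidic, dual-barcoded amplicon sequencing
runs of the kind used to build large multilocus phylogenetic datasets:
dozens of target regions amplified across dozens of samples in a single
microfluidic array, tagged with combinatorial (P5 × P7) index barcodes and
sequenced as paired-end short reads. It is aimed at phylogeneticists and
population geneticists who need per-sample, per-locus sequences — and,
for nuclear loci, the separate alleles of heterozygotes — out of raw
paired FASTQ files.

## What it does

**Demultiplexing.** Each read pair carries two 8 bp index sequences naming
the sample and begins, on each mate, with a target-specific primer naming
the locus. Indexes are matched within edit distance ≤ 1 per side; primers
are matched by Levenshtein distance ≤ 4 with a *firm end* — the primer's
3'-terminal 4 bases must match the read exactly and contiguously, anchoring
the primer/insert boundary so the primer can be stripped cleanly.
Ambiguous matches are rejected rather than guessed: in phylogenetics a
misassigned read is worse than a lost one.

**Reduction.** Each (sample, target) read pool is trimmed at the 3' ends
(where short-read error concentrates), mates are merged when they overlap
by ≥ 10 bp (otherwise concatenated), reads are reduced to the modal
amplicon length, and the pool is summarised as either

* a strict per-column consensus,
* a consensus with IUPAC ambiguity codes for every base variant supported
  by ≥ *s* reads and ≥ *f* of the column (defaults *s* = 5, *f* = 0.05), or
* a set of **alleles**: groups of identical sequences kept when they hold
  ≥ *s* reads *and* ≥ *f* of the pool. If no candidate passes both
  thresholds the sample × target cell is discarded.

**Ploidy summaries.** Per-locus allele counts aggregate into minimum-ploidy
calls: a sample showing at most 2 distinct alleles at every locus is
consistent with diploidy; 3–4 distinct sequences at any locus imply a
tetraploid minimum; more than 4 is flagged for inspection. Per-sample and
per-species tables report the percentage of loci (or individuals) with ≥ 3
alleles so weak calls are visible.

**Target selection.** A sliding-window scan over a plastome-scale multiple
sequence alignment ranks 400–1000 bp windows by summed pairwise divergence,
requiring strictly conserved, fully occupied, ambiguity-free 25-column
flanks (candidate primer sites). A companion island search pairs conserved
multi-taxon coverage blocks separated by 400–800 bp (padding 100 bp per
predicted intron) for low-coverage nuclear loci. Alignment cleaning
(occupancy threshold) and supermatrix concatenation with a partition table
round out the utilities.

**Simulation.** A built-in generator emits whole runs — four-primer
amplicon anatomy, per-sample allele mixtures for haploid/diploid/tetraploid
samples, negative-binomial pool depths, 3'-ramped substitution error,
index-sequence errors — with complete ground truth, so the entire pipeline
is testable end to end without external data.

## Worked example

```
$ ampliseq full-run --seed 11 --out-dir demo
simulated 4893 read pairs for 8 samples x 6 targets -> demo/sim
assigned 4857/4893 reads (99.3%) into 48 pools
reduced 48 pools (occurrence mode) -> demo/reduce
called minimum ploidy for 8 samples, 4 species -> demo/ploidy
```

This simulates a small run (8 samples × 6 targets, mean depth 100, 0.2%
sequencing error, occasional index errors), demultiplexes it, recovers
alleles, and calls ploidy. 99.3% of reads are assigned — the remainder
carry index errors that push them past the barcode threshold or make them
ambiguous. The allele table then drives the ploidy summary:

```
$ head -5 demo/ploidy/ploidy_per_sample.tsv
sample	max_alleles	min_ploidy	pct_loci_ge3
S001	2	diploid	0.00
S002	2	diploid	0.00
S003	4	tetraploid	66.67
S004	1	diploid	0.00
```

S003 was simulated as a tetraploid with heterozygous homeolog pairs: up to
four distinct sequences survive the ≥ 5-read / ≥ 5% filters at a locus, so
its minimum ploidy is called tetraploid, with 66.67% of its loci showing
≥ 3 alleles. Samples with at most two alleles everywhere are consistent
with diploidy.

Each stage is also its own subcommand (`simulate`, `demux`, `reduce`,
`ploidy`, `targets scan|islands|clean|concat`) over plain
FASTQ/FASTA/TSV files, and the same functionality is importable from
`ampliseq` as a library.

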