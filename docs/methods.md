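# Methods

This note documents the models and procedures the toolkit implements, the
parameters that matter, what the simulator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Read anatomy and demultiplexing

The library model is a four-primer amplicon: a target-specific primer pair
(with universal CS1/CS2 tails) amplifies the locus, and a second primer
pair adds platform adapters plus a sample-specific (P5, P7) index
combination. Read 1 therefore begins with the forward target primer, read 2
with the reverse, and the two 8 bp indexes travel either as separate index
reads or in the read header. Combinatorial indexing yields n×m sample
identities from n+m oligos; the arithmetic in `ampliseq.multiplex` (pools
per array, barcode pairs, arrays and plates needed) is exact and is exposed
so run reports can be audited against the design.

**Barcode matching** compares each observed index against the same-end
barcode list. For equal-length sequences the distance is Hamming; at the
default threshold of 1 edit this is equivalent to unrestricted edit
distance (a single edit between equal-length strings must be a
substitution), and the fallback to Levenshtein handles length-discordant
input. The two ends are thresholded separately (≤ 1 each) rather than as a
sum — dual-index practice, and the stricter of the two readings. A match is
accepted only when exactly one barcode attains the minimum distance;
equidistant candidates leave the read unassigned.

**Primer matching** allows Levenshtein edits (substitutions and indels)
across the primer except in its 3'-terminal `firm_end_len` bases (default
4), which must match the read exactly and contiguously. Implementation: for
every read position where the firm block occurs within `max_primer_dist`
(default 4) of its expected offset, the 5' remainder of the primer is
globally aligned (edlib) against the read prefix; the minimum-distance
anchor wins, ties preferring the least-shifted anchor so the number of
stripped bases is deterministic. Because indels are allowed 5' of the firm
block, the consumed prefix may differ from the primer length. The test
suite checks this matcher against an exhaustive dynamic-programming oracle
that enumerates every firm-end-respecting alignment.

Reads shorter than a primer, reads failing either barcode, and ambiguous
primer hits are counted as unassigned with a recorded reason; assigned plus
unassigned always equals the input count. An optional mate-swap rescue pass
exists but is off by default because it changes counts.

## Reduction: consensus and allele recovery

Per pool the pipeline is trim → join → modal-length reduction → summary.

* **Trimming** removes a fixed number of bases from each mate's 3' end
  (defaults 0/0; the reference workflow for 300 bp MiSeq reads used 75/150,
  read 2 being worse). Trimming exists because substitution error rises
  toward the 3' end; cutting it improves exact-identity allele grouping.
* **Joining** scans all overlaps ≥ `min_overlap` (default 10) between read
  1 and the reverse complement of read 2, picks the overlap with the lowest
  mismatch fraction (ties → longest), and merges if that fraction is
  ≤ 0.25 — FLASH-like defaults, exposed as flags since the upstream joiner's
  parameters are a free choice here. Disagreements resolve to the
  higher-quality base (tie → read 1); merged quality is the max.
  Non-overlapping mates are concatenated directly (read 1 + revcomp read 2)
  with the junction index recorded, and downstream treats the result as one
  sequence.
* **Modal-length reduction** keeps only reads at the most frequent length
  (tie → longer, for determinism and more sequence at equal support).
  It is applied in all three modes, including allele recovery, and the
  support fractions below use the post-reduction total.
* **Consensus** is per-column plurality (tie → alphabetical A<C<G<T).
  Ambiguity mode emits the IUPAC code over the set of bases individually
  supported by ≥ `min_reads` (s, default 5) reads and ≥ `min_freq` (f,
  default 0.05) of the column, falling back to plurality when no base
  qualifies.
* **Allele recovery** groups reads by exact sequence identity — no
  clustering, on the assumption that true alleles dominate the post-PCR
  pool while error-bearing reads are low-frequency — and keeps groups
  passing both thresholds (≥ s reads and ≥ f of the pool). If none passes,
  the (sample, target) is discarded. Indel-aware clustering and statistical
  phasing are deliberately out of scope.

Chloroplast targets default to strict consensus (haploid genome); nuclear
targets to ambiguity/occurrence. Each pool is also categorised
joined/concatenated/failed for a coverage heat-map table.

## Minimum ploidy

The largest number of distinct alleles observed at any locus bounds ploidy
from below: ≤ 2 → diploid minimum, 3–4 → tetraploid minimum (two homeolog
pairs), > 4 → "higher", reported rather than raised as an error since
artifacts can inflate counts. Species-level calls take the max over
member samples. Discarded loci (count 0) say nothing about allele number
and are excluded from the per-sample percentage denominator. The
`pct_ge3` columns (loci per sample, individuals per species with ≥ 3
alleles) exist to expose weakly supported tetraploid calls.

## Target-region selection

**Variable-region scan.** Column divergence is the mean pairwise difference:
the fraction of differing pairs among unambiguous (A/C/G/T) bases, pairs
involving gaps or N ignored; columns with fewer than two comparable bases
are missing. (The metric is a deliberate, documented choice — swappable for
e.g. parsimony-informative-site counts.) Windows of every admissible length
(400–1000 columns) are slid over the alignment; a placement qualifies when
both 25-column flanks are conserved (divergence ≤ `max_flank_div`, default
0), fully occupied, and free of ambiguity codes — the flanks being the
future primer sites. Candidates are ranked by **summed** window divergence
with ties broken toward the shorter, then leftmost window: total variation
makes a complete divergent block beat both its dense sub-windows and
padded super-windows, so blocks are reported at their exact spans. Scores
are quantized to 1e-4 before ranking so windows covering the same variable
columns tie exactly despite prefix-sum rounding; real score differences in
DNA alignments are orders of magnitude larger. Selection is greedy
non-overlapping; within each run of equivalent placements of one length
only the best is kept (any other would lose the greedy anyway), which keeps
the candidate set small on ~125 kb alignments. Coordinates are 0-based
half-open internally, 1-based inclusive in emitted tables. Primer
thermodynamics are not computed; the table is a hand-off to a primer-design
step.

**Conserved islands.** For sparse nuclear alignments, an island is a
maximal column run where ≥ `min_taxa` (default 2) rows have non-gap bases.
Ordered island pairs qualify when their separation, padded by 100 bp per
predicted intron between them (positions supplied as an annotation track,
since intron counts cannot be derived from the alignment itself), falls in
400–800 bp.

**Cleaning and concatenation.** Cleaning drops columns whose non-gap,
non-N occupancy is below a threshold (default 50%); it is idempotent and
preserves row order. Concatenation fills missing taxon × locus blocks with
gaps and emits a contiguous 1-based partition table; slicing the
supermatrix by a partition recovers the input locus.

## The simulator

The generator emulates: the four-primer read anatomy (primer + insert on
each mate, reading inward); per-sample allele mixtures — haploid/homozygous
(1 sequence), diploid heterozygote (2 at 50/50), tetraploid as two
homeolog pairs each independently heterozygous (2–4 sequences at copy-
number weights); negative-binomial pool depth (dispersion 10 by default,
mimicking uneven amplicon recovery; dispersion ≤ 0 fixes depth exactly);
substitution error with a linear 5'→3' ramp (mean rate `error_rate`,
default 0.2%, rising 3× across the read — the dominant short-read error
mode); and index-sequence substitutions at their own rate. Defaults are 8
samples × 6 targets, 300 bp reads, 300–560 bp inserts, 2% allele
divergence, heterozygosity 0.5, ploidy cycling (2, 2, 4, 1) so a default
run contains every scenario class.

It does **not** model indels (allele identity downstream is exact-match;
an indel channel would only exercise the modal-length filter), PCR
chimeras, polymerase error accumulation, quality-score miscalibration, or
cross-talk between index pairs. Passing tests therefore demonstrate
correct algorithmic behaviour under substitution-dominated noise, not
robustness to chimeric or indel-rich libraries.

Truth tables record every pool's allele sequences, mixture weights, the
per-read source allele, and — via a closed-form geometry helper — the exact
sequence the trim/join/strip pipeline should reconstruct per allele,
enabling byte-exact end-to-end checks. Everything derives from one seed;
identical seeds give byte-identical FASTQ.

The plastome-alignment generator places divergent blocks (400–1000 bp,
0.8–7.5% target divergence) on an invariant 6-taxon background. Divergence
is realised by making a fraction of block columns variable with a 3/3
taxon split (0.6 pairwise difference per such column); block end columns
are always variable so the nominal span equals the realised divergent
span, and blocks are separated by at least 1000 invariant columns —
comfortably above the largest scan window, as plastome hotspots sit
between conserved genes.

## Problem sizes used in the checks

The shipped verification runs use desk-scale sizes chosen to exercise
every code path: 8 samples × 6 targets at fixed depth 50 for the
noise-free closure; 200 pools per allele-count class (1–4) at depth 100,
0.2% mean error, 450 bp inserts, reduced with the reference 75/150 trims;
10,000 random primer/read pairs and 2,000 index lookups for the oracle
comparisons; one ~125 kb, 48-block alignment plus an invariant control for
the scan. Full-size runs (48 × 48 arrays, millions of reads) are the same
code on bigger inputs.

## Known limitations

* Allele identity is exact sequence equality; a single uncorrected error
  splits an allele, which the joint ≥ 5-read / ≥ 5% filter absorbs only at
  adequate depth. Very deep pools make the 5% relative threshold the
  binding constraint; very shallow pools (< ~7× per allele) lose real
  alleles to the absolute threshold.
* The firm-end rule rejects any read whose primer 3' terminus is
  miscalled, trading sensitivity for a clean primer/insert boundary.
* The scan's flank requirement (strictly conserved, fully occupied) means
  divergent blocks longer than `max_len` have no admissible placement and
  are skipped entirely rather than truncated.
* Ploidy calls are lower bounds from allele counts alone; they are not a
  statistical estimator of ploidy and do not use allele balance.
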