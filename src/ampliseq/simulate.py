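"""Synthetic microfluidic-amplicon sequencing runs with full ground truth.

Each simulated read pair follows the four-primer amplicon anatomy: the
sequenced insert is bracketed by target-specific primers, the sample is
encoded in a (P5, P7) index pair, and the mates read inward from the two
amplicon ends. Per sample the simulator draws an allele mixture determined
by ploidy — one sequence for a homozygote, two for a diploid heterozygote,
up to four (two homeolog pairs) for a tetraploid — and emits reads with
substitution errors ramping toward the 3' end, the dominant short-read
error mode. Index reads receive their own (synthesis/sequencing) error
rate. Everything is driven by one seed; identical seeds give byte-identical
output.

The generated truth tables record, per (sample, target), the allele insert
sequences, their mixture proportions, the exact sequence the reduction
stage should reconstruct for each allele, and per-sample ploidy, so the
demultiplex → reduce → ploidy chain can be checked end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_sheets import (
    BarcodeEntry,
    BarcodeTable,
    PrimerPair,
    PrimerTable,
    ReadPair,
    SampleRecord,
    SampleTable,
    write_fastq,
    write_table,
)
from .reduce import revcomp
from .targets import Msa

__all__ = [
    "SimConfig",
    "PoolTruth",
    "RunTruth",
    "SimResult",
    "make_tables",
    "expected_reduced_sequence",
    "simulate_pool",
    "simulate_run",
    "simulate_plastome_msa",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated run.

    ploidy
        A single value in {1, 2, 4} for all samples, or one value per
        sample. Default cycles (2, 2, 4, 1) so a run contains homozygotes,
        heterozygotes and polyploids.
    heterozygosity
        Probability that a locus is heterozygous, per homeolog pair.
    allele_divergence
        Substitutions per site separating alleles of one locus (and the two
        homeolog pairs of a tetraploid).
    depth_mean, depth_dispersion
        Negative-binomial read depth per (sample, target) pool, emulating
        uneven amplicon recovery; a dispersion <= 0 fixes every pool at
        exactly ``depth_mean`` reads.
    error_rate
        Mean substitution rate per sequenced base; the positional profile
        rises linearly toward the 3' end by ``ramp_factor`` while keeping
        this mean.
    barcode_error_rate
        Per-base substitution rate on the index sequences.
    """

    n_samples: int = 8
    n_targets: int = 6
    target_len_range: tuple[int, int] = (300, 560)
    ploidy: int | Sequence[int] = (2, 2, 4, 1)
    heterozygosity: float = 0.5
    allele_divergence: float = 0.02
    depth_mean: float = 100.0
    depth_dispersion: float = 10.0
    read_len: int = 300
    error_rate: float = 0.002
    ramp_factor: float = 3.0
    barcode_error_rate: float = 0.001
    barcode_len: int = 8
    primer_len: int = 20
    seed: int = 0

    def ploidy_of(self, sample_index: int) -> int:
        if isinstance(self.ploidy, int):
            p = self.ploidy
        else:
            p = self.ploidy[sample_index % len(self.ploidy)]
        if p not in (1, 2, 4):
            raise ValueError(f"ploidy must be 1, 2 or 4, got {p}")
        return p


@dataclass
class PoolTruth:
    """Ground truth for one (sample, target) pool."""

    sample_id: str
    target_id: str
    alleles: list[str]  # insert sequences
    reduced: list[str]  # sequence the reduction stage should recover per allele
    proportions: list[float]
    depth: int
    read_alleles: list[int] = field(default_factory=list)  # per-read allele index

    @property
    def n_distinct(self) -> int:
        return len(set(self.alleles))


@dataclass
class RunTruth:
    ploidy: dict[str, int]
    pools: dict[tuple[str, str], PoolTruth]


@dataclass
class SimResult:
    reads: list[ReadPair]
    truth: RunTruth
    barcodes: BarcodeTable
    primers: PrimerTable
    samples: SampleTable


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)].astype("U1"))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def _distinct_barcodes(rng: np.random.Generator, n: int, length: int, min_diff: int = 3) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        cand = _random_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, prev)) >= min_diff for prev in out):
            out.append(cand)
    return out


def make_tables(
    config: SimConfig, rng: np.random.Generator
) -> tuple[BarcodeTable, PrimerTable, SampleTable]:
    """Generate barcode, primer and sample sheets sized for the run."""
    n_p5 = int(np.ceil(np.sqrt(config.n_samples)))
    n_p7 = int(np.ceil(config.n_samples / n_p5))
    if n_p5 * n_p7 < config.n_samples:
        raise ValueError("insufficient barcode pairs for the requested samples")
    p5 = _distinct_barcodes(rng, n_p5, config.barcode_len)
    p7 = _distinct_barcodes(rng, n_p7, config.barcode_len)
    entries = [BarcodeEntry(f"P5_{i + 1:02d}", "P5", s) for i, s in enumerate(p5)]
    entries += [BarcodeEntry(f"P7_{i + 1:02d}", "P7", s) for i, s in enumerate(p7)]
    barcodes = BarcodeTable(entries)
    primers = PrimerTable(
        [
            PrimerPair(
                f"T{i + 1:03d}",
                "nuclear" if i % 2 else "chloroplast",
                _random_seq(rng, config.primer_len),
                _random_seq(rng, config.primer_len),
            )
            for i in range(config.n_targets)
        ]
    )
    samples = []
    for i in range(config.n_samples):
        samples.append(
            SampleRecord(
                f"S{i + 1:03d}",
                f"P5_{i // n_p7 + 1:02d}",
                f"P7_{i % n_p7 + 1:02d}",
                "sim",
            )
        )
    return barcodes, primers, SampleTable(samples)


def expected_reduced_sequence(
    insert: str,
    fwd_len: int,
    rev_len: int,
    read_len: int,
    trim1: int = 0,
    trim2: int = 0,
    min_overlap: int = 10,
) -> str:
    """Sequence the trim→join→strip geometry reconstructs for one allele.

    With the full amplicon being primer + insert + primer', each stripped,
    trimmed mate is a window into the insert; when the windows overlap by at
    least ``min_overlap`` the merged product is the insert span they jointly
    cover, otherwise the two windows are concatenated in read order.
    """
    A = fwd_len + len(insert) + rev_len
    len1 = min(read_len, A) - trim1  # mate lengths after 3' trimming
    len2 = min(read_len, A) - trim2
    # primer-stripped windows in amplicon coordinates, clamped to the insert
    s1, e1 = fwd_len, max(fwd_len, min(len1, A - rev_len))
    s2, e2 = min(max(A - len2, fwd_len), A - rev_len), A - rev_len
    overlap = e1 - s2
    if s1 <= s2 and overlap >= min_overlap:
        return insert[s1 - fwd_len : e2 - fwd_len]
    return insert[s1 - fwd_len : e1 - fwd_len] + insert[s2 - fwd_len : e2 - fwd_len]


def _pool_alleles(rng: np.random.Generator, config: SimConfig, base_insert: str, ploidy: int) -> tuple[list[str], list[float]]:
    """Draw the allele mixture for one (sample, target)."""
    div = config.allele_divergence
    if ploidy == 1:
        return [base_insert], [1.0]
    if ploidy == 2:
        if rng.random() < config.heterozygosity:
            alt = _mutate_distinct(rng, base_insert, div)
            return [base_insert, alt], [0.5, 0.5]
        return [base_insert], [1.0]
    # tetraploid: two homeolog pairs, each independently het
    homeolog = _mutate_distinct(rng, base_insert, div)
    alleles: list[str] = []
    weights: list[float] = []
    for anchor in (base_insert, homeolog):
        if rng.random() < config.heterozygosity:
            alt = _mutate_distinct(rng, anchor, div)
            alleles += [anchor, alt]
            weights += [0.25, 0.25]
        else:
            alleles.append(anchor)
            weights.append(0.5)
    return alleles, weights


def _mutate_distinct(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Mutated copy guaranteed to differ from the template."""
    out = _mutate(rng, seq, rate)
    while out == seq:
        i = int(rng.integers(0, len(seq)))
        choices = [b for b in "ACGT" if b != seq[i]]
        out = seq[:i] + choices[int(rng.integers(0, 3))] + seq[i + 1 :]
    return out


def _error_profile(length: int, mean_rate: float, ramp: float) -> np.ndarray:
    """Per-position substitution rates rising linearly 5'→3' with the given mean."""
    if length == 0:
        return np.zeros(0)
    x = np.linspace(0.0, 1.0, length)
    profile = 1.0 + (ramp - 1.0) * x
    profile /= profile.mean()
    return mean_rate * profile


def _qual_from_rates(rates: np.ndarray) -> str:
    q = np.clip(-10.0 * np.log10(np.maximum(rates, 1e-4)), 2, 40).astype(int)
    return "".join(chr(33 + int(v)) for v in q)


def _apply_errors(rng: np.random.Generator, seq: str, rates: np.ndarray) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rates[: len(arr)])
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_pool(
    alleles: Sequence[str],
    weights: Sequence[float],
    depth: int,
    config: SimConfig,
    rng: np.random.Generator,
    fwd_primer: str = "",
    rev_primer: str = "",
    sample_id: str = "S001",
    target_id: str = "T001",
) -> tuple[list[ReadPair], PoolTruth]:
    """Emit reads for one (sample, target) pool from a known allele mixture.

    ``alleles`` are insert sequences; reads carry the primers (empty by
    default, giving primer-free reads straight into the reduction stage).
    Index fields are left empty — use :func:`simulate_run` for full runs.
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    reduced = [
        expected_reduced_sequence(a, len(fwd_primer), len(rev_primer), config.read_len)
        for a in alleles
    ]
    truth = PoolTruth(sample_id, target_id, list(alleles), reduced, list(w), depth)
    reads: list[ReadPair] = []
    for ri in range(depth):
        ai = int(rng.choice(len(alleles), p=w))
        truth.read_alleles.append(ai)
        amplicon = fwd_primer + alleles[ai] + revcomp(rev_primer)
        r1 = amplicon[: config.read_len]
        r2 = revcomp(amplicon)[: config.read_len]
        rates1 = _error_profile(len(r1), config.error_rate, config.ramp_factor)
        rates2 = _error_profile(len(r2), config.error_rate, config.ramp_factor)
        reads.append(
            ReadPair(
                id=f"sim:{sample_id}:{target_id}:{ri}",
                r1_seq=_apply_errors(rng, r1, rates1),
                r2_seq=_apply_errors(rng, r2, rates2),
                r1_qual=_qual_from_rates(rates1),
                r2_qual=_qual_from_rates(rates2),
            )
        )
    return reads, truth


def simulate_run(
    config: SimConfig,
    tables: tuple[BarcodeTable, PrimerTable, SampleTable] | None = None,
    out_dir: str | Path | None = None,
) -> SimResult:
    """Simulate a full sequencing run.

    Returns the read pairs (index sequences populated), the ground truth and
    the three sheets. When ``out_dir`` is given, also writes ``r1.fastq`` /
    ``r2.fastq`` (index pair embedded in the header as ``BC1+BC2``), the
    three sheets, and truth TSVs.
    """
    rng = np.random.default_rng(config.seed)
    if tables is None:
        tables = make_tables(config, rng)
    barcodes, primers, samples = tables
    if len(samples) < config.n_samples or barcodes.n_possible_pairs < config.n_samples:
        raise ValueError(
            f"tables provide {len(samples)} samples over {barcodes.n_possible_pairs} "
            f"barcode pairs; {config.n_samples} samples requested"
        )
    bc_seq = {("P5", e.name): e.sequence for e in barcodes.by_end["P5"]}
    bc_seq |= {("P7", e.name): e.sequence for e in barcodes.by_end["P7"]}

    target_inserts = {
        p.target_id: _random_seq(rng, int(rng.integers(*config.target_len_range)))
        for p in primers
    }
    ploidy = {s.sample_id: config.ploidy_of(i) for i, s in enumerate(samples)}

    reads: list[ReadPair] = []
    pools: dict[tuple[str, str], PoolTruth] = {}
    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.depth_mean)

    for si, sample in enumerate(samples):
        for primer in primers:
            insert = target_inserts[primer.target_id]
            alleles, weights = _pool_alleles(rng, config, insert, ploidy[sample.sample_id])
            if config.depth_dispersion > 0:
                depth = int(rng.negative_binomial(nb_n, nb_p))
            else:
                depth = int(round(config.depth_mean))
            pool_reads, truth = simulate_pool(
                alleles,
                weights,
                depth,
                config,
                rng,
                fwd_primer=primer.fwd_seq,
                rev_primer=primer.rev_seq,
                sample_id=sample.sample_id,
                target_id=primer.target_id,
            )
            pools[(sample.sample_id, primer.target_id)] = truth
            for read in pool_reads:
                read.r1_bc = _mutate(
                    rng, bc_seq[("P5", sample.p5_barcode)], config.barcode_error_rate
                )
                read.r2_bc = _mutate(
                    rng, bc_seq[("P7", sample.p7_barcode)], config.barcode_error_rate
                )
            reads.extend(pool_reads)

    result = SimResult(reads, RunTruth(ploidy, pools), barcodes, primers, samples)
    if out_dir is not None:
        _write_run(result, Path(out_dir))
    return result


def _write_run(result: SimResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fastq(
        (
            (f"{r.id} 1:N:0:{r.r1_bc}+{r.r2_bc}", r.r1_seq, r.r1_qual)
            for r in result.reads
        ),
        out_dir / "r1.fastq",
    )
    write_fastq(
        (
            (f"{r.id} 2:N:0:{r.r1_bc}+{r.r2_bc}", r.r2_seq, r.r2_qual)
            for r in result.reads
        ),
        out_dir / "r2.fastq",
    )
    write_table(
        [(e.name, e.end, e.sequence) for e in result.barcodes.entries],
        out_dir / "barcodes.tsv",
        header=("name", "end", "sequence"),
    )
    write_table(
        [(p.target_id, p.genome, p.fwd_seq, p.rev_seq) for p in result.primers],
        out_dir / "primers.tsv",
        header=("target", "genome", "fwd", "rev"),
    )
    write_table(
        [(s.sample_id, s.p5_barcode, s.p7_barcode, s.project) for s in result.samples],
        out_dir / "samples.tsv",
        header=("sample", "p5", "p7", "project"),
    )
    write_table(
        [(s, p) for s, p in sorted(result.truth.ploidy.items())],
        out_dir / "truth_ploidy.tsv",
        header=("sample", "ploidy"),
    )
    rows = []
    for (s, t), pt in sorted(result.truth.pools.items()):
        for i, (a, r, w) in enumerate(zip(pt.alleles, pt.reduced, pt.proportions)):
            rows.append((s, t, i, w, pt.depth, a, r))
    write_table(
        rows,
        out_dir / "truth_alleles.tsv",
        header=("sample", "target", "allele", "proportion", "depth", "insert", "reduced"),
    )


def simulate_plastome_msa(
    n_taxa: int = 6,
    length: int = 125_000,
    n_blocks: int = 48,
    block_len_range: tuple[int, int] = (400, 1000),
    block_div_range: tuple[float, float] = (0.008, 0.075),
    min_gap: int = 1000,
    seed: int = 0,
) -> tuple[Msa, list[tuple[int, int, float]]]:
    """Invariant plastome-like alignment with seeded divergent blocks.

    Divergence inside a block is generated by making a fraction of its
    columns variable: at a variable column half the taxa carry an
    alternative base, so with 6 taxa each such column contributes 0.6 to the
    mean pairwise difference. A block's first and last columns are always
    variable, so the nominal span coincides with the realised divergent
    span. Blocks are separated by at least ``min_gap`` invariant columns
    (default 1000, comfortably above the largest scan window, as plastome
    hotspots sit between conserved genes). Returns the alignment plus the
    truth table of ``(start, end, realised_divergence)`` per block (0-based
    half-open).
    """
    rng = np.random.default_rng(seed)
    ancestral = np.frombuffer(_random_seq(rng, length).encode(), dtype="S1")
    arr = np.tile(ancestral, (n_taxa, 1)).copy()

    lengths = rng.integers(block_len_range[0], block_len_range[1] + 1, n_blocks)
    slack = length - int(lengths.sum()) - (n_blocks + 1) * min_gap
    if slack < 0:
        raise ValueError("blocks do not fit in the alignment")
    cuts = np.sort(rng.integers(0, slack + 1, n_blocks))
    blocks: list[tuple[int, int, float]] = []
    pos = min_gap
    prev_cut = 0
    half = n_taxa // 2
    per_col_div = (half * (n_taxa - half)) / (n_taxa * (n_taxa - 1) / 2)
    for i in range(n_blocks):
        pos += int(cuts[i] - prev_cut)
        prev_cut = int(cuts[i])
        start, end = pos, pos + int(lengths[i])
        target_div = float(rng.uniform(*block_div_range))
        n_var = min(max(2, round(target_div / per_col_div * (end - start))), end - start)
        interior = 1 + rng.choice(end - start - 2, size=max(0, n_var - 2), replace=False)
        var_cols = start + np.concatenate([[0, end - start - 1], interior])
        for col in var_cols:
            ref = arr[0, col]
            alt = _BASES[_BASES != ref][rng.integers(0, 3)]
            carriers = rng.choice(n_taxa, size=half, replace=False)
            arr[carriers, col] = alt
        realised = per_col_div * len(var_cols) / (end - start)
        blocks.append((start, end, realised))
        pos = end + min_gap
    rows = [arr[i].tobytes().decode() for i in range(n_taxa)]
    msa = Msa([f"taxon_{i + 1}" for i in range(n_taxa)], rows)
    return msa, blocks
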