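"""Reduction of per-(sample, target) read pools to consensus sequences or
recovered alleles.

Pipeline per pool: optional 3'-end trimming of each mate (sequencing error
concentrates there, worst on read 2), FLASH-style overlap joining of mates
(non-overlapping mates are concatenated), reduction to the modal amplicon
length, then either a per-column consensus (strict or with IUPAC ambiguity
codes) or exact-identity allele counting under joint absolute (>= s reads)
and relative (>= f of the pool) support thresholds. The thresholds encode
the working assumption that true alleles dominate the post-PCR pool while
error-bearing reads occur at low frequency.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .demux import AmpliconPool
from .io_sheets import ReadPair

__all__ = [
    "ReduceConfig",
    "JoinedRead",
    "Allele",
    "AlleleSet",
    "IUPAC_CODES",
    "revcomp",
    "trim_pair",
    "join_pair",
    "reduce_to_modal_length",
    "consensus",
    "call_alleles",
    "reduce_pool",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

# base set -> one-letter ambiguity code
IUPAC_CODES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReduceConfig:
    """Knobs of the reduction stage.

    trim1, trim2
        Bases removed from the 3' ends of read 1 / read 2 before joining
        (the reference run used 75 and 150 on 300 bp reads).
    min_overlap
        Minimum overlap (bases) for mates to be merged rather than
        concatenated. Default 10.
    max_mismatch_frac
        Maximum mismatch fraction tolerated in the chosen overlap. Default
        0.25 (FLASH-like).
    min_reads, min_freq
        Joint support thresholds: a base variant (ambiguity mode) or a
        candidate allele (occurrence mode) must be seen in at least
        ``min_reads`` reads AND at least ``min_freq`` of the pool.
        Defaults 5 and 0.05.
    mode
        ``consensus`` (plurality base per column), ``ambiguity`` (IUPAC code
        over the supported bases per column) or ``occurrence`` (allele
        recovery by exact sequence identity).
    """

    trim1: int = 0
    trim2: int = 0
    min_overlap: int = 10
    max_mismatch_frac: float = 0.25
    min_reads: int = 5
    min_freq: float = 0.05
    mode: str = "consensus"

    def __post_init__(self) -> None:
        if self.trim1 < 0 or self.trim2 < 0:
            raise ValueError("trims must be >= 0")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0 < self.min_freq <= 1:
            raise ValueError("min_freq must be in (0, 1]")
        if self.mode not in ("consensus", "ambiguity", "occurrence"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class JoinedRead:
    """A single continuous sequence per read pair.

    ``joined`` is True when the mates overlapped and were merged; otherwise
    the sequence is read 1 followed by the reverse complement of read 2 with
    the junction index recorded so downstream users can split it.
    """

    sequence: str
    qual: str
    joined: bool
    junction: int = -1  # concatenation point when not joined


@dataclass
class Allele:
    sequence: str
    read_count: int
    frequency: float


@dataclass
class AlleleSet:
    """Surviving candidate alleles for one (sample, target)."""

    sample_id: str
    target_id: str
    alleles: list[Allele] = field(default_factory=list)
    total_reads: int = 0
    status: str = "ok"  # ok | discarded


def trim_pair(pair: ReadPair, trim1: int, trim2: int) -> ReadPair:
    """Remove ``trim1``/``trim2`` bases (and qualities) from the 3' end of
    each mate. Trimming a read to nothing is allowed but warned about."""
    if trim1 >= len(pair.r1_seq) or trim2 >= len(pair.r2_seq):
        warnings.warn(f"read {pair.id!r}: trim leaves an empty mate", stacklevel=2)
    end1 = max(0, len(pair.r1_seq) - trim1)
    end2 = max(0, len(pair.r2_seq) - trim2)
    return ReadPair(
        id=pair.id,
        r1_seq=pair.r1_seq[:end1],
        r2_seq=pair.r2_seq[:end2],
        r1_qual=pair.r1_qual[:end1],
        r2_qual=pair.r2_qual[:end2],
        r1_bc=pair.r1_bc,
        r2_bc=pair.r2_bc,
    )


def join_pair(pair: ReadPair, min_overlap: int = 10, max_mismatch_frac: float = 0.25) -> JoinedRead:
    """Merge mates by their best 3' overlap, or concatenate them.

    All overlaps of length >= ``min_overlap`` between read 1 and the reverse
    complement of read 2 are scored by mismatch fraction; the lowest-fraction
    overlap wins (ties go to the longest). If even the best overlap exceeds
    ``max_mismatch_frac`` the mates are concatenated unmerged. Disagreements
    inside a merged overlap resolve to the higher-quality base (tie: the
    read-1 base); the merged quality is the max of the two.
    """
    import numpy as np

    r1, q1 = pair.r1_seq, pair.r1_qual
    r2 = revcomp(pair.r2_seq)
    q2 = pair.r2_qual[::-1]
    best_len, best_frac = 0, 2.0
    max_ov = min(len(r1), len(r2))
    a1 = np.frombuffer(r1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(r2.encode(), dtype=np.uint8)
    for ov in range(max_ov, min_overlap - 1, -1):
        mism = int(np.count_nonzero(a1[len(r1) - ov :] != a2[:ov]))
        frac = mism / ov
        if frac < best_frac:  # strict: ties keep the longer (earlier) overlap
            best_len, best_frac = ov, frac
        if frac == 0.0:
            break  # nothing can beat a perfect overlap; longest wins ties
    if best_len >= min_overlap and best_frac <= max_mismatch_frac:
        ov = best_len
        head, head_q = r1[: len(r1) - ov], q1[: len(q1) - ov]
        tail, tail_q = r2[ov:], q2[ov:]
        mid = []
        mid_q = []
        for x, y, qx, qy in zip(r1[len(r1) - ov :], r2[:ov], q1[len(q1) - ov :], q2[:ov]):
            if x == y:
                mid.append(x)
            else:
                mid.append(x if qx >= qy else y)
            mid_q.append(max(qx, qy))
        return JoinedRead(head + "".join(mid) + tail, head_q + "".join(mid_q) + tail_q, True)
    return JoinedRead(r1 + r2, q1 + q2, False, junction=len(r1))


def reduce_to_modal_length(reads: Sequence[JoinedRead]) -> tuple[list[JoinedRead], int]:
    """Keep only reads of the most frequent sequence length.

    A tie between lengths goes to the longer variant (more sequence for the
    same support). Returns the kept reads and the modal length.
    """
    if not reads:
        raise ValueError("cannot reduce an empty pool")
    counts = Counter(len(r.sequence) for r in reads)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return [r for r in reads if len(r.sequence) == best], best


def consensus(reads: Sequence[JoinedRead], mode: str = "consensus", s: int = 5, f: float = 0.05) -> str:
    """Per-column consensus over equal-length reads.

    ``consensus`` mode takes the plurality base per column (tie broken
    alphabetically). ``ambiguity`` mode emits the IUPAC code for the set of
    bases supported by at least ``s`` reads and ``f`` of the column; when no
    base clears both thresholds the column falls back to plurality.
    """
    if not reads:
        raise ValueError("empty pool has no consensus")
    length = len(reads[0].sequence)
    if any(len(r.sequence) != length for r in reads):
        raise ValueError("consensus requires equal-length reads (apply modal reduction first)")
    total = len(reads)
    out = []
    for col in range(length):
        counts = Counter(r.sequence[col] for r in reads)
        plurality = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        if mode == "ambiguity":
            supported = {
                b for b, c in counts.items() if c >= s and c / total >= f and b in "ACGT"
            }
            if supported:
                out.append(IUPAC_CODES[frozenset(supported)])
            else:
                out.append(plurality)
        else:
            out.append(plurality)
    return "".join(out)


def call_alleles(
    reads: Sequence[JoinedRead], sample_id: str, target_id: str, s: int = 5, f: float = 0.05
) -> AlleleSet:
    """Group reads by exact sequence identity and keep the supported groups.

    A candidate allele survives with at least ``s`` reads and at least ``f``
    of the pool total. Surviving alleles are sorted by descending count,
    then sequence. If nothing survives the (sample, target) is discarded.
    """
    total = len(reads)
    counts = Counter(r.sequence for r in reads)
    kept = [
        Allele(seq, c, c / total)
        for seq, c in counts.items()
        if c >= s and c / total >= f
    ]
    kept.sort(key=lambda a: (-a.read_count, a.sequence))
    return AlleleSet(
        sample_id=sample_id,
        target_id=target_id,
        alleles=kept,
        total_reads=total,
        status="ok" if kept else "discarded",
    )


def reduce_pool(pool: AmpliconPool, config: ReduceConfig) -> tuple[object, str]:
    """Run the full reduction pipeline on one pool.

    Returns ``(result, category)`` where result is a consensus ``(name,
    sequence)`` record (consensus/ambiguity modes) or an :class:`AlleleSet`
    (occurrence mode), and category records how the pool's mates combined:
    ``joined`` (majority of kept reads merged), ``concatenated`` (majority
    ran mate-to-mate without overlap) or ``failed`` (empty pool, or nothing
    survived).
    """
    if not pool.reads:
        return None, "failed"
    trimmed = [trim_pair(p, config.trim1, config.trim2) for p in pool.reads]
    joined = [
        join_pair(p, config.min_overlap, config.max_mismatch_frac)
        for p in trimmed
        if p.r1_seq and p.r2_seq
    ]
    if not joined:
        return None, "failed"
    kept, _ = reduce_to_modal_length(joined)
    n_joined = sum(1 for r in kept if r.joined)
    category = "joined" if n_joined * 2 >= len(kept) else "concatenated"
    if config.mode == "occurrence":
        aset = call_alleles(kept, pool.sample_id, pool.target_id, config.min_reads, config.min_freq)
        if aset.status == "discarded":
            category = "failed"
        return aset, category
    seq = consensus(kept, config.mode, config.min_reads, config.min_freq)
    return (f"{pool.sample_id}|{pool.target_id}", seq), category
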