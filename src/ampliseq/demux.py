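"""Dual-barcode / primer demultiplexing of amplicon read pairs.

Every read pair carries two index sequences (P5 side and P7 side) naming the
sample, and begins — on each mate — with the target-specific primer naming
the amplified region. Assignment is therefore a two-stage lookup:

1. each observed index is matched against the same-end barcode list within a
   small edit distance (default 1);
2. the 5' end of each mate is matched against the candidate primers with
   Levenshtein edits allowed everywhere except the primer's 3'-terminal
   *firm end* (default 4 bases), which must match the read exactly and
   contiguously — anchoring the primer/insert boundary so the primer can be
   stripped cleanly.

Ambiguity at either stage (two candidates tied at the minimum distance)
leaves the read unassigned: a lost read is recoverable, a misassigned one is
not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import edlib

from .io_sheets import (
    BarcodeEntry,
    BarcodeTable,
    PrimerPair,
    PrimerTable,
    ReadPair,
    SampleTable,
)

__all__ = [
    "DemuxConfig",
    "Assignment",
    "AmpliconPool",
    "DemuxReport",
    "UNASSIGNED",
    "match_barcode",
    "match_primer",
    "demultiplex",
]

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class DemuxConfig:
    """Thresholds for barcode and primer matching.

    max_bc_dist
        Maximum edits tolerated per index (P5 and P7 thresholded
        separately). Default 1.
    max_primer_dist
        Maximum Levenshtein distance for the fuzzy part of a primer match.
        Default 4.
    firm_end_len
        Number of 3'-terminal primer bases that must match the read exactly
        (no substitutions or indels). Default 4.
    swap_rescue
        If True, reads failing primer matching in the native orientation are
        retried with mates swapped. Default off: the library's read anatomy
        is fixed, and rescue changes counts.
    """

    max_bc_dist: int = 1
    max_primer_dist: int = 4
    firm_end_len: int = 4
    swap_rescue: bool = False

    def __post_init__(self) -> None:
        if self.max_bc_dist < 0 or self.max_primer_dist < 0 or self.firm_end_len < 0:
            raise ValueError("demux thresholds must be non-negative")


@dataclass
class Assignment:
    """Per-read outcome of demultiplexing."""

    read_id: str
    sample_id: str = UNASSIGNED
    target_id: str = UNASSIGNED
    bc_dist_p5: int = -1
    bc_dist_p7: int = -1
    primer_dist_f: int = -1
    primer_dist_r: int = -1
    fail_reason: str = "none"  # none | barcode | primer | both


@dataclass
class AmpliconPool:
    """All primer-stripped reads assigned to one (sample, target)."""

    sample_id: str
    target_id: str
    reads: list[ReadPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class DemuxReport:
    n_total: int = 0
    n_assigned: int = 0
    n_fail_barcode: int = 0
    n_fail_primer: int = 0
    n_fail_both: int = 0
    pool_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_unassigned(self) -> int:
        return self.n_fail_barcode + self.n_fail_primer + self.n_fail_both

    @property
    def fraction_matched(self) -> float:
        return self.n_assigned / self.n_total if self.n_total else 0.0

    @property
    def n_pools(self) -> int:
        return len(self.pool_counts)

    def rows(self) -> list[tuple[str, str, int]]:
        return [(s, t, c) for (s, t), c in sorted(self.pool_counts.items())]


def _edit_distance(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def match_barcode(
    observed: str, table: list[BarcodeEntry], max_dist: int = 1
) -> tuple[str | None, int]:
    """Match an observed index against a same-end barcode list.

    Uses Hamming distance when lengths agree (the usual fixed-length index
    case) and falls back to Levenshtein otherwise. Returns ``(name, dist)``
    for the unique best barcode within ``max_dist``; ``(None, -1)`` when no
    barcode is close enough or two are tied at the minimum distance.
    """
    if not observed:
        return None, -1
    observed = observed.upper()
    best_name: str | None = None
    best_dist = max_dist + 1
    tied = False
    for entry in table:
        seq = entry.sequence
        if len(seq) == len(observed):
            d = sum(1 for x, y in zip(observed, seq) if x != y)
        else:
            d = _edit_distance(observed, seq)
        if d < best_dist:
            best_name, best_dist, tied = entry.name, d, False
        elif d == best_dist:
            tied = True
    if best_name is None or tied or best_dist > max_dist:
        return None, -1
    return best_name, best_dist


def _match_one_primer(
    read: str, primer: str, max_dist: int, firm_len: int
) -> tuple[int, int] | None:
    """Best firm-end-anchored match of one primer against a read prefix.

    The primer's last ``firm_len`` bases must appear contiguously and exactly
    at some read position ``j``; the remaining 5' part is aligned globally
    against ``read[:j]`` with Levenshtein edits. Returns ``(dist, consumed)``
    for the best anchor, or ``None``. Ties between anchor positions at equal
    distance prefer the least-shifted anchor (consumed closest to the primer
    length), which keeps stripping deterministic.
    """
    k = min(firm_len, len(primer))
    fuzzy, firm = primer[:-k] if k else primer, primer[-k:] if k else ""
    best: tuple[int, int] | None = None
    lo = max(0, len(fuzzy) - max_dist)
    hi = min(len(read) - k, len(fuzzy) + max_dist)
    # try anchors nearest the unshifted position first so distance ties
    # resolve toward minimal shift
    for j in sorted(range(lo, hi + 1), key=lambda x: (abs(x - len(fuzzy)), x)):
        if k and read[j : j + k] != firm:
            continue
        d = _edit_distance(fuzzy, read[:j])
        if d <= max_dist and (best is None or d < best[0]):
            best = (d, j + k)
    return best


def match_primer(
    read_5prime: str, primers: list[tuple[str, str]], config: DemuxConfig
) -> tuple[str | None, int, int]:
    """Match a read's 5' end against candidate primers with firm 3' ends.

    ``primers`` is a list of ``(target_id, primer_sequence)``. Returns
    ``(target_id, dist, consumed)`` for the unique minimum-distance
    candidate, or ``(None, -1, 0)`` if nothing matches within
    ``config.max_primer_dist`` or two targets tie at the minimum.
    """
    read = read_5prime.upper()
    best: tuple[int, int, str] | None = None  # (dist, consumed, target)
    tied = False
    for target_id, primer in primers:
        if len(read) < len(primer):
            continue
        hit = _match_one_primer(read, primer.upper(), config.max_primer_dist, config.firm_end_len)
        if hit is None:
            continue
        d, consumed = hit
        if best is None or d < best[0]:
            best, tied = (d, consumed, target_id), False
        elif d == best[0] and target_id != best[2]:
            tied = True
    if best is None or tied:
        return None, -1, 0
    return best[2], best[0], best[1]


def demultiplex(
    read_stream: Iterable[ReadPair],
    barcodes: BarcodeTable,
    primers: PrimerTable,
    samples: SampleTable,
    config: DemuxConfig | None = None,
    assignments_out: list[Assignment] | None = None,
) -> tuple[dict[tuple[str, str], AmpliconPool], DemuxReport]:
    """Assign every read pair to a (sample, target) pool.

    Forward primers are matched on read 1 and reverse primers on read 2;
    both must name the same target. Primer bases are stripped from pooled
    reads. Returns the pools plus a run report; every input read is either
    in exactly one pool or counted unassigned with a fail reason.
    """
    config = config or DemuxConfig()
    p5_list = barcodes.by_end["P5"]
    p7_list = barcodes.by_end["P7"]
    pair_to_sample = {(s.p5_barcode, s.p7_barcode): s.sample_id for s in samples}
    fwd_primers = [(p.target_id, p.fwd_seq) for p in primers]
    rev_primers = [(p.target_id, p.rev_seq) for p in primers]

    pools: dict[tuple[str, str], AmpliconPool] = {}
    report = DemuxReport()

    for pair in read_stream:
        report.n_total += 1
        asg = Assignment(read_id=pair.id)

        p5_name, d5 = match_barcode(pair.r1_bc, p5_list, config.max_bc_dist)
        p7_name, d7 = match_barcode(pair.r2_bc, p7_list, config.max_bc_dist)
        asg.bc_dist_p5, asg.bc_dist_p7 = d5, d7
        sample_id = None
        if p5_name is not None and p7_name is not None:
            sample_id = pair_to_sample.get((p5_name, p7_name))

        target_id, consumed1, consumed2 = None, 0, 0
        orientations = [(pair.r1_seq, pair.r2_seq)]
        if config.swap_rescue:
            orientations.append((pair.r2_seq, pair.r1_seq))
        for r1_seq, r2_seq in orientations:
            t_f, d_f, c_f = match_primer(r1_seq, fwd_primers, config)
            t_r, d_r, c_r = match_primer(r2_seq, rev_primers, config)
            if t_f is not None and t_f == t_r:
                target_id, consumed1, consumed2 = t_f, c_f, c_r
                asg.primer_dist_f, asg.primer_dist_r = d_f, d_r
                if (r1_seq, r2_seq) != (pair.r1_seq, pair.r2_seq):
                    pair = ReadPair(
                        id=pair.id,
                        r1_seq=pair.r2_seq,
                        r2_seq=pair.r1_seq,
                        r1_qual=pair.r2_qual,
                        r2_qual=pair.r1_qual,
                        r1_bc=pair.r1_bc,
                        r2_bc=pair.r2_bc,
                    )
                break

        if sample_id is not None and target_id is not None:
            asg.sample_id, asg.target_id = sample_id, target_id
            stripped = ReadPair(
                id=pair.id,
                r1_seq=pair.r1_seq[consumed1:],
                r2_seq=pair.r2_seq[consumed2:],
                r1_qual=pair.r1_qual[consumed1:],
                r2_qual=pair.r2_qual[consumed2:],
                r1_bc=pair.r1_bc,
                r2_bc=pair.r2_bc,
            )
            key = (sample_id, target_id)
            pools.setdefault(key, AmpliconPool(sample_id, target_id)).reads.append(stripped)
            report.pool_counts[key] = report.pool_counts.get(key, 0) + 1
            report.n_assigned += 1
        else:
            if sample_id is None and target_id is None:
                asg.fail_reason = "both"
                report.n_fail_both += 1
            elif sample_id is None:
                asg.fail_reason = "barcode"
                report.n_fail_barcode += 1
            else:
                asg.fail_reason = "primer"
                report.n_fail_primer += 1
        if assignments_out is not None:
            assignments_out.append(asg)

    return pools, report
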