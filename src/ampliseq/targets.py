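"""Selection of amplification targets from multiple sequence alignments.

Two complementary strategies:

* a plastome-style sliding-window scan for highly variable 400–1000 bp
  regions bracketed by strictly conserved primer-length flanks, ranked by
  mean pairwise divergence;
* a conserved-island search for low-coverage nuclear loci, pairing runs of
  multi-taxon coverage whose separation (padded by an assumed ~100 bp per
  predicted intron) falls in an amplifiable 400–800 bp window.

Also provides the alignment utilities around them: column-occupancy
cleaning (drop columns below 50% non-gap coverage by default) and
supermatrix concatenation with a partition table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Msa",
    "ScanConfig",
    "VariableRegion",
    "Island",
    "IslandPair",
    "column_divergence",
    "column_divergence_profile",
    "scan_variable_regions",
    "find_conserved_islands",
    "clean_alignment",
    "concat_alignments",
]

_BASES = "ACGT"
_GAPLIKE = set("-N.")


@dataclass
class Msa:
    """A multiple sequence alignment: taxon names plus equal-length rows."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows are not equal length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def array(self) -> np.ndarray:
        """Rows as a (n_taxa, length) array of single characters."""
        return np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            self.n_taxa, self.length
        )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Msa":
        names, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            rows.append(str(rec.seq))
        return cls(names, rows)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        from .io_sheets import write_fasta

        write_fasta(zip(self.names, self.rows), path, width=width)

    def slice(self, start: int, end: int) -> "Msa":
        return Msa(list(self.names), [r[start:end] for r in self.rows])


@dataclass(frozen=True)
class ScanConfig:
    """Window-scan parameters.

    Regions of ``min_len``–``max_len`` columns are admissible; each must be
    bracketed by two ``flank_len``-column flanks (the primer sites) whose
    divergence does not exceed ``max_flank_div`` (default 0: strictly
    conserved), which are present in every taxon and free of ambiguity
    codes. ``min_region_div`` sets an absolute divergence floor; at the
    default 0 the scan is rank-only but still requires some variation in the
    window.
    """

    min_len: int = 400
    max_len: int = 1000
    flank_len: int = 25
    max_flank_div: float = 0.0
    min_region_div: float = 0.0
    require_full_occupancy: bool = True
    forbid_ambiguity: bool = True

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.flank_len < 18:
            raise ValueError("flank_len below the primer length floor (18)")


@dataclass(frozen=True)
class VariableRegion:
    """One ranked variable region (0-based half-open column coordinates).

    ``divergence`` is the mean pairwise difference per site inside the
    region; ``score`` is its column-summed divergence, the quantity regions
    are ranked by (total variation favours complete divergent blocks over
    dense sub-windows of them).
    """

    start: int
    end: int
    divergence: float
    score: float
    left_flank_div: float
    right_flank_div: float
    rank: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Island:
    start: int
    end: int  # half-open


@dataclass(frozen=True)
class IslandPair:
    left: Island
    right: Island
    separation: int  # columns between the islands
    n_introns: int
    effective_separation: int  # separation + intron_pad per predicted intron


def _column_stats(msa: Msa) -> dict[str, np.ndarray]:
    """Per-column divergence and flank-eligibility flags, vectorised.

    divergence: fraction of differing pairs among columns' unambiguous
    bases (NaN where fewer than 2 are comparable). full: every row has a
    non-gap, non-N character. clean: no character outside {A,C,G,T,-,N}
    (i.e. no IUPAC ambiguity codes).
    """
    arr = msa.array()
    counts = np.stack([(arr == b.encode()).sum(axis=0) for b in _BASES])  # (4, L)
    n_comp = counts.sum(axis=0)
    pairs = n_comp * (n_comp - 1) / 2
    same = (counts * (counts - 1) / 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        div = np.where(pairs > 0, (pairs - same) / np.maximum(pairs, 1), np.nan)
    div[n_comp < 2] = np.nan
    gaplike = np.isin(arr, [b"-", b"N", b"."])
    known = gaplike | np.isin(arr, [b.encode() for b in _BASES])
    return {
        "div": div,
        "full": ~gaplike.any(axis=0),
        "clean": known.all(axis=0),
        "occupancy": (~gaplike).sum(axis=0) / msa.n_taxa,
    }


def column_divergence(msa: Msa, col: int) -> float:
    """Mean pairwise difference at one column, ignoring gap/N bases.

    Returns NaN when fewer than two comparable bases remain.
    """
    return float(_column_stats(msa)["div"][col])


def column_divergence_profile(msa: Msa) -> np.ndarray:
    """Per-column mean pairwise difference for the whole alignment."""
    return _column_stats(msa)["div"]


def scan_variable_regions(msa: Msa, config: ScanConfig | None = None) -> list[VariableRegion]:
    """Find and rank non-overlapping variable regions with conserved flanks.

    Every admissible window length is slid over the alignment; a placement
    passes when both flanks qualify as primer sites and the window contains
    variation (mean divergence above ``min_region_div``, and nonzero).
    Within each contiguous run of passing placements of one length only the
    highest-scoring is kept (any other would lose to it in the greedy
    selection anyway), then the survivors are ranked by descending summed
    divergence — ties broken toward the shorter, then leftmost window, so a
    divergent block is reported at its exact span rather than padded with
    invariant columns — and greedily accepted if they do not overlap an
    already accepted region.
    """
    config = config or ScanConfig()
    L = msa.length
    fl = config.flank_len
    if L < config.min_len + 2 * fl:
        import warnings

        warnings.warn("alignment shorter than the smallest window plus flanks", stacklevel=2)
        return []
    stats = _column_stats(msa)
    div = np.nan_to_num(stats["div"], nan=0.0)
    flank_ok = ~np.isnan(stats["div"]) if config.max_flank_div == 0 else np.ones(L, bool)
    flank_ok &= np.nan_to_num(stats["div"], nan=1.0) <= config.max_flank_div
    if config.require_full_occupancy:
        flank_ok &= stats["full"]
    if config.forbid_ambiguity:
        flank_ok &= stats["clean"]

    div_ps = np.concatenate([[0.0], np.cumsum(div)])
    ok_ps = np.concatenate([[0], np.cumsum(flank_ok.astype(np.int64))])

    candidates: list[tuple[float, int, int]] = []  # (score, start, end)
    for length in range(config.min_len, min(config.max_len, L - 2 * fl) + 1):
        starts = np.arange(fl, L - length - fl + 1)
        if len(starts) == 0:
            continue
        left_ok = ok_ps[starts] - ok_ps[starts - fl] == fl
        right_ok = ok_ps[starts + length + fl] - ok_ps[starts + length] == fl
        # quantize scores so windows covering the same variable columns tie
        # exactly despite prefix-sum rounding noise
        wsum = np.round(div_ps[starts + length] - div_ps[starts], 4)
        mask = left_ok & right_ok & (wsum > 0) & (wsum / length >= config.min_region_div)
        if not mask.any():
            continue
        # one candidate per contiguous run of passing placements; argmax
        # takes the leftmost of tied placements
        idx = np.flatnonzero(mask)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for seg in np.split(idx, breaks + 1):
            best = seg[np.argmax(wsum[seg])]
            s = int(starts[best])
            candidates.append((float(wsum[best]), s, s + length))

    candidates.sort(key=lambda c: (-c[0], c[2] - c[1], c[1]))
    accepted: list[tuple[float, int, int]] = []
    occupied = np.zeros(L, bool)
    for d, s, e in candidates:
        if occupied[s:e].any():
            continue
        occupied[s:e] = True
        accepted.append((d, s, e))

    def flank_div(a: int, b: int) -> float:
        vals = stats["div"][a:b]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if len(vals) else 0.0

    return [
        VariableRegion(
            start=s,
            end=e,
            divergence=d / (e - s),
            score=d,
            left_flank_div=flank_div(s - fl, s),
            right_flank_div=flank_div(e, e + fl),
            rank=i + 1,
        )
        for i, (d, s, e) in enumerate(accepted)
    ]


def find_conserved_islands(
    msa: Msa,
    min_taxa: int = 2,
    min_sep: int = 400,
    max_sep: int = 800,
    intron_pad: int = 100,
    intron_positions: Sequence[int] = (),
    min_island_len: int = 1,
) -> list[IslandPair]:
    """Pair conserved coverage islands at amplifiable separations.

    An island is a maximal run of columns where at least ``min_taxa`` rows
    have a non-gap base. For every ordered island pair, the separation
    (columns between them) is padded by ``intron_pad`` per predicted intron
    position falling between them; pairs whose effective separation lies in
    ``[min_sep, max_sep]`` are candidates for primer design.
    """
    arr = msa.array()
    covered = (~np.isin(arr, [b"-", b"N", b"."])).sum(axis=0) >= min_taxa
    islands: list[Island] = []
    idx = np.flatnonzero(covered)
    if len(idx):
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for seg in np.split(idx, breaks + 1):
            if len(seg) >= min_island_len:
                islands.append(Island(int(seg[0]), int(seg[-1]) + 1))
    introns = np.asarray(sorted(intron_positions), dtype=int)
    pairs: list[IslandPair] = []
    for i, left in enumerate(islands):
        for right in islands[i + 1 :]:
            sep = right.start - left.end
            n_introns = int(((introns >= left.end) & (introns < right.start)).sum())
            eff = sep + intron_pad * n_introns
            if min_sep <= eff <= max_sep:
                pairs.append(IslandPair(left, right, sep, n_introns, eff))
    return pairs


def clean_alignment(msa: Msa, occupancy: float = 0.5) -> Msa:
    """Drop columns whose non-gap, non-N occupancy is below the threshold.

    Mirrors a 50%-threshold alignment cleanup; row order is preserved and
    the operation is idempotent.
    """
    occ = _column_stats(msa)["occupancy"]
    keep = np.flatnonzero(occ >= occupancy)
    rows = ["".join(r[i] for i in keep) for r in msa.rows]
    return Msa(list(msa.names), rows)


def concat_alignments(
    alignments: Sequence[tuple[str, Msa]] | Sequence[Msa],
) -> tuple[Msa, list[tuple[str, int, int]]]:
    """Concatenate per-locus alignments into a supermatrix.

    Taxa missing from a locus are filled with gap blocks of that locus's
    width. Returns the supermatrix and a partition table of ``(locus,
    start, end)`` with 1-based inclusive coordinates covering the matrix
    contiguously.
    """
    named: list[tuple[str, Msa]] = []
    for i, item in enumerate(alignments):
        if isinstance(item, Msa):
            named.append((f"locus_{i + 1}", item))
        else:
            named.append(item)
    if not named:
        raise ValueError("nothing to concatenate")
    taxa: list[str] = []
    for _, aln in named:
        for name in aln.names:
            if name not in taxa:
                taxa.append(name)
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for locus, aln in named:
        width = aln.length
        rowmap = dict(zip(aln.names, aln.rows))
        for t in taxa:
            chunks[t].append(rowmap.get(t, "-" * width))
        parts.append((locus, pos + 1, pos + width))
        pos += width
    supermatrix = Msa(taxa, ["".join(chunks[t]) for t in taxa])
    return supermatrix, parts
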