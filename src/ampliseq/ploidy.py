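"""Minimum-ploidy summaries from per-locus allele counts.

A sample showing at most two distinct alleles at every locus is consistent
with diploidy; three or four distinct sequences at any locus imply at least
two genome copies' worth of homeologs, i.e. a tetraploid minimum. More than
four observed alleles is flagged ``higher`` (and is usually worth manual
inspection — sequencing artifacts can inflate the count). The percentage of
loci (per sample) or of individuals (per species) showing >= 3 alleles is
reported alongside each call so weakly supported tetraploid calls are
visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .reduce import AlleleSet

__all__ = ["PloidyCall", "build_matrix", "call_min_ploidy", "min_ploidy_label"]


@dataclass(frozen=True)
class PloidyCall:
    unit: str  # sample id or species name
    level: str  # "sample" | "species"
    max_alleles: int
    min_ploidy: str  # diploid | tetraploid | higher | unknown
    pct_ge3: float  # % of loci (sample) or individuals (species) with >=3 alleles


def min_ploidy_label(max_alleles: int) -> str:
    """Smallest ploidy consistent with the largest per-locus allele count."""
    if max_alleles <= 0:
        return "unknown"
    if max_alleles <= 2:
        return "diploid"
    if max_alleles <= 4:
        return "tetraploid"
    return "higher"


def build_matrix(allele_sets: Iterable[AlleleSet]) -> pd.DataFrame:
    """Samples × targets matrix of allele counts (0 = discarded/missing)."""
    cells: dict[tuple[str, str], int] = {}
    for aset in allele_sets:
        key = (aset.sample_id, aset.target_id)
        if key in cells:
            raise ValueError(f"duplicate allele set for {key}")
        cells[key] = 0 if aset.status == "discarded" else len(aset.alleles)
    if not cells:
        return pd.DataFrame(dtype=int)
    samples = sorted({s for s, _ in cells})
    targets = sorted({t for _, t in cells})
    mat = pd.DataFrame(0, index=samples, columns=targets, dtype=int)
    for (s, t), n in cells.items():
        mat.loc[s, t] = n
    return mat


def call_min_ploidy(
    matrix: pd.DataFrame, species_map: Mapping[str, str]
) -> list[PloidyCall]:
    """Per-sample and per-species minimum-ploidy calls from an allele matrix.

    Missing loci (count 0) are excluded from the per-sample percentage
    denominator: an absent amplicon says nothing about allele number. Every
    sample must appear in ``species_map``.
    """
    unmapped = [s for s in matrix.index if s not in species_map]
    if unmapped:
        raise ValueError(f"samples without a species mapping: {unmapped}")
    calls: list[PloidyCall] = []
    sample_max: dict[str, int] = {}
    for sample in matrix.index:
        row = matrix.loc[sample]
        observed = row[row > 0]
        mx = int(observed.max()) if len(observed) else 0
        pct = 100.0 * (observed >= 3).sum() / len(observed) if len(observed) else 0.0
        sample_max[sample] = mx
        calls.append(PloidyCall(sample, "sample", mx, min_ploidy_label(mx), pct))
    by_species: dict[str, list[str]] = {}
    for sample in matrix.index:
        by_species.setdefault(species_map[sample], []).append(sample)
    for species in sorted(by_species):
        members = by_species[species]
        mx = max(sample_max[s] for s in members)
        pct = 100.0 * sum(sample_max[s] >= 3 for s in members) / len(members)
        calls.append(PloidyCall(species, "species", mx, min_ploidy_label(mx), pct))
    return calls
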