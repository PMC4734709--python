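"""Closed-form multiplexing arithmetic for dual-barcoded microfluidic runs.

The economics of the approach rest on simple combinatorics: a microfluidic
array amplifies every sample against every target in isolated chambers, and
combinatorial (P5 × P7) dual indexing yields n×m sample identities from
n+m barcode oligos. These helpers make that arithmetic explicit so run
reports and experimental designs can be checked against it.
"""

from __future__ import annotations

import math

__all__ = [
    "pools_per_array",
    "barcode_pairs",
    "max_multiplexed_samples",
    "total_amplicons",
    "arrays_needed",
    "tas_plates_needed",
]


def pools_per_array(n_samples: int, n_targets: int) -> int:
    """Distinct (sample, target) amplicon pools one array produces."""
    return n_samples * n_targets


def barcode_pairs(n_p5: int, n_p7: int) -> int:
    """Distinct dual-barcode combinations available from the two index sets."""
    return n_p5 * n_p7


def max_multiplexed_samples(n_fwd_barcoded: int, n_rev_barcoded: int) -> int:
    """Samples addressable by combinatorial use of the barcoded primers."""
    return n_fwd_barcoded * n_rev_barcoded


def total_amplicons(n_samples: int, n_targets: int) -> int:
    """Unique barcoded amplicon species across the whole experiment."""
    return n_samples * n_targets


def arrays_needed(n_amplicons: int, samples_per_array: int = 48, targets_per_array: int = 48) -> int:
    """Arrays required to run ``n_amplicons`` sample×target reactions."""
    return math.ceil(n_amplicons / (samples_per_array * targets_per_array))


def tas_plates_needed(
    n_samples: int, n_targets: int, wells_per_plate: int = 96, reactions_per_amplicon: int = 2
) -> int:
    """PCR plates a two-reaction targeted-amplicon-sequencing workflow needs
    to barcode the same sample×target matrix one well at a time."""
    return math.ceil(n_samples * n_targets / wells_per_plate) * reactions_per_amplicon
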