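"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately avoid the library code they verify: plain-Python dynamic
programming for edit distances and exhaustive enumeration for the anchored
(firm-end) primer matching rule.
"""

from __future__ import annotations


def levenshtein(a: str, b: str) -> int:
    """Classic O(len(a)·len(b)) DP edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein_to_prefixes(a: str, b: str) -> list[int]:
    """d(a, b[:j]) for every j in 0..len(b), from one DP sweep."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev


def firm_end_match(read: str, primer: str, max_dist: int, firm_len: int) -> tuple[int, int] | None:
    """Exhaustive firm-end anchored match.

    Enumerates every read position where the primer's 3'-terminal
    ``firm_len`` bases occur exactly and contiguously, scoring the 5' part
    against the read prefix by Levenshtein distance. Returns
    ``(dist, consumed)`` minimising distance (ties: anchor least shifted
    from the primer length, then leftmost) or None if nothing is within
    ``max_dist``.
    """
    if len(read) < len(primer):
        return None
    k = min(firm_len, len(primer))
    fuzzy, firm = (primer[:-k], primer[-k:]) if k else (primer, "")
    prefix_d = levenshtein_to_prefixes(fuzzy, read)
    best: tuple[int, int] | None = None
    anchors = sorted(range(0, len(read) - k + 1), key=lambda j: (abs(j - len(fuzzy)), j))
    for j in anchors:
        if k and read[j : j + k] != firm:
            continue
        d = prefix_d[j]
        if d <= max_dist and (best is None or d < best[0]):
            best = (d, j + k)
    return best


def nearest_barcode(observed: str, barcodes: list[tuple[str, str]], max_dist: int) -> tuple[str | None, int]:
    """Brute-force unique-nearest-barcode search (Levenshtein throughout)."""
    scored = sorted((levenshtein(observed, seq), name) for name, seq in barcodes)
    if not scored or scored[0][0] > max_dist:
        return None, -1
    if len(scored) > 1 and scored[1][0] == scored[0][0]:
        return None, -1
    return scored[0][1], scored[0][0]


def pairwise_column_divergence(column: list[str]) -> float | None:
    """Fraction of differing pairs among comparable (ACGT) bases."""
    bases = [b for b in column if b in "ACGT"]
    if len(bases) < 2:
        return None
    pairs = diff = 0
    for i in range(len(bases)):
        for j in range(i + 1, len(bases)):
            pairs += 1
            diff += bases[i] != bases[j]
    return diff / pairs
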