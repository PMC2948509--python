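"""Independent reference implementations used only to check the package.

These are deliberately naive: exhaustive enumeration and plain-Python
dynamic programming, sharing no code with the package's alignment or
scoring paths.
"""

from __future__ import annotations

import math
from functools import lru_cache

PURINES = {"A", "G"}


def enumerate_global_score(a: str, b: str, match: float, mismatch: float,
                           gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap score by exhaustive recursion (tiny inputs).

    State: positions consumed in a and b plus which sequence (if any) the
    previous column gapped, so affine costs are exact.  A gap of length g
    costs gap_open + (g-1)*gap_extend.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            options.append(sub + best(i + 1, j + 1, "m"))
        if i < len(a):   # gap in b
            cost = gap_extend if prev == "b" else gap_open
            options.append(cost + best(i + 1, j, "b"))
        if j < len(b):   # gap in a
            cost = gap_extend if prev == "a" else gap_open
            options.append(cost + best(i, j + 1, "a"))
        return max(options)

    return best(0, 0, "m")


def smith_waterman_score(a: str, b: str, match: float, mismatch: float,
                         gap_open: float, gap_extend: float) -> float:
    """Plain-Python local affine-gap alignment score (Gotoh three-state)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]   # best ending in a match column
    E = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in b (consume a)
    F = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0,
                          sub + max(H[i - 1][j - 1], E[i - 1][j - 1],
                                    F[i - 1][j - 1]))
            best = max(best, H[i][j], E[i][j], F[i][j])
    return best


def k2p_aligned(a: str, b: str) -> float:
    """K2P distance of two pre-aligned gap-free sequences, by the formula."""
    ts = tv = n = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def nearest_neighbor_species(query_id: str, query_seq: str, subjects: dict,
                             species_of: dict, match: float, mismatch: float,
                             gap_open: float, gap_extend: float) -> set[str]:
    """Species set of the top-scoring subjects, by exhaustive local alignment.

    ``subjects`` maps id -> sequence; the query's own id is excluded.
    """
    scores = {}
    for sid, seq in subjects.items():
        if sid == query_id:
            continue
        scores[sid] = smith_waterman_score(query_seq, seq, match, mismatch,
                                           gap_open, gap_extend)
    top = max(scores.values())
    return {species_of[sid] for sid, sc in scores.items() if sc == top}
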