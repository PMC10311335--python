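"""Distinct subsequence / substring sets and their Jaccard indices.

The motivating observation for subsequence seeding: two strings one edit
apart can share zero length-k substrings yet most of their length-k
subsequences.  This module provides exact counts of distinct length-k
subsequences, distinct common subsequences of two strings, and the
resulting Jaccard indices for both subsequences and substrings.

Counting walks the (product) subsequence automaton: state (i) — or (i, j)
for two strings — is the leftmost position a prefix can be embedded at, and
every distinct string corresponds to exactly one automaton path, so path
counting needs no inclusion–exclusion.  Counts are Python integers, hence
arbitrary precision (they grow combinatorially).
"""

from __future__ import annotations

from functools import lru_cache

from .alphabet import SIGMA, check_dna


def _next_occurrence(x: str) -> list[list[int]]:
    """nxt[p][c]: smallest q >= p with code(x[q]) == c, else len(x).

    The deterministic subsequence automaton of x: consuming symbol c from
    state p moves to nxt[p][c] + 1.
    """
    n = len(x)
    codes = check_dna(x, "string")
    nxt = [[n] * SIGMA for _ in range(n + 1)]
    for p in range(n - 1, -1, -1):
        row = nxt[p]
        row[:] = nxt[p + 1]
        row[codes[p]] = p
    return nxt


def count_distinct_subsequences(x: str, k: int) -> int:
    """|S_k(x)|: the number of distinct length-k subsequence strings."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return 1
    if k > len(x):
        return 0
    n = len(x)
    nxt = _next_occurrence(x)
    # f[p] = number of distinct length-r strings embeddable starting at p
    f = [1] * (n + 1)
    for _ in range(k):
        g = [0] * (n + 1)
        for p in range(n - 1, -1, -1):
            total = 0
            for c in range(SIGMA):
                q = nxt[p][c]
                if q < n:
                    total += f[q + 1]
            g[p] = total
        f = g
    return f[0]


def count_common_distinct_subsequences(x: str, y: str, k: int) -> int:
    """|S_k(x) ∩ S_k(y)|: distinct strings embeddable in both x and y."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return 1
    if k > len(x) or k > len(y):
        return 0
    nx, ny = len(x), len(y)
    nxt_x = _next_occurrence(x)
    nxt_y = _next_occurrence(y)

    @lru_cache(maxsize=None)
    def paths(p: int, q: int, r: int) -> int:
        if r == 0:
            return 1
        total = 0
        for c in range(SIGMA):
            px = nxt_x[p][c]
            py = nxt_y[q][c]
            if px < nx and py < ny:
                total += paths(px + 1, py + 1, r - 1)
        return total

    result = paths(0, 0, k)
    paths.cache_clear()
    return result


def jaccard_subsequences(x: str, y: str, k: int) -> float:
    """|S_k(x) ∩ S_k(y)| / |S_k(x) ∪ S_k(y)|."""
    cx = count_distinct_subsequences(x, k)
    cy = count_distinct_subsequences(y, k)
    common = count_common_distinct_subsequences(x, y, k)
    union = cx + cy - common
    if union == 0:
        raise ValueError(f"neither string has a length-{k} subsequence")
    return common / union


def substring_set(x: str, k: int) -> set[str]:
    """The set of distinct length-k substrings (k-mers) of x."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return {x[i : i + k] for i in range(len(x) - k + 1)}


def jaccard_substrings(x: str, y: str, k: int) -> float:
    """Jaccard index over distinct length-k substrings."""
    sx, sy = substring_set(x, k), substring_set(y, k)
    union = sx | sy
    if not union:
        raise ValueError(f"neither string has a length-{k} substring")
    return len(sx & sy) / len(union)


def subsequence_set(x: str, k: int, cap: int = 5_000_000) -> set[str]:
    """Explicit S_k(x) by enumerating position subsets (small inputs only).

    This is the brute-force oracle for the counting routines.
    """
    from itertools import combinations
    from math import comb

    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(x):
        return set()
    if comb(len(x), k) > cap:
        raise ValueError("instance too large for explicit enumeration")
    return {"".join(x[p] for p in pos) for pos in combinations(range(len(x)), k)}
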