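"""Minimized length-k subsequence of a string under an ABC order.

``min_subsequence`` runs the O(nkd) dynamic program (numba kernels in
:mod:`subseqhash._kernels`); ``brute_force_min_subsequence`` enumerates all
C(n, k) position subsets and is the independent oracle the DP is validated
against.  Both apply identical tie rules, so they agree on positions, not
just on the score:

* the optimal residue is the smallest defined psi; among Tmin/Tmax the
  branch of larger |omega| wins, with an exact tie going to the Tmax
  (positive omega) branch;
* among position sets achieving the optimal (psi, omega) the
  lexicographically smallest tuple is reported (the DP traceback prefers
  skipping a character whenever skipping preserves the optimum).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from ._kernels import UNDEF_CUTOFF, _fill, _init_tables, single_window
from .alphabet import check_dna
from .order import ABCTables, OrderScore, score

#: refuse brute force beyond this many subsets
DEFAULT_BRUTE_CAP = 2_000_000

#: tagged sentinel marking undefined DP cells in :func:`dp_tables`
UNDEF = np.int64(np.iinfo(np.int64).min)


def _prepared(tables):
    """Kernel-layout views of the tables: A/B transposed to (k, 4, d)."""
    return (
        np.ascontiguousarray(tables.A.transpose(0, 2, 1)),
        np.ascontiguousarray(tables.B1.transpose(0, 2, 1)),
        np.ascontiguousarray(tables.B2.transpose(0, 2, 1)),
        np.ascontiguousarray(tables.C),
    )


@dataclass(frozen=True)
class SeedHit:
    """One extracted seed.

    ``positions`` are 0-based offsets WITHIN the window; absolute
    coordinates in the parent sequence are ``window_start + positions``.
    """

    sequence_id: str
    window_start: int
    repeat_index: int
    positions: tuple[int, ...]
    subseq: str
    score: OrderScore

    def __post_init__(self):
        if len(self.positions) != len(self.subseq):
            raise ValueError("positions and subsequence lengths differ")

    @property
    def abs_positions(self) -> tuple[int, ...]:
        return tuple(self.window_start + p for p in self.positions)


def min_subsequence(x: str, tables: ABCTables, sequence_id: str = "") -> SeedHit:
    """Smallest length-k subsequence of x under the order, via the DP."""
    codes = check_dna(x, "string")
    n, k = len(codes), tables.k
    if n < k:
        raise ValueError(f"string length {n} < k = {k}")
    At, B1t, B2t, C = _prepared(tables)
    psi, omega, pos = single_window(codes, n, k, tables.d, At, B1t, B2t, C)
    positions = tuple(int(p) for p in pos)
    subseq = "".join(x[p] for p in positions)
    return SeedHit(
        sequence_id=sequence_id,
        window_start=0,
        repeat_index=0,
        positions=positions,
        subseq=subseq,
        score=OrderScore(psi=int(psi), omega=int(omega), lex_key=subseq),
    )


def brute_force_min_subsequence(
    x: str, tables: ABCTables, sequence_id: str = "", cap: int = DEFAULT_BRUTE_CAP
) -> SeedHit:
    """Exact argmin over all position subsets; oracle for the DP.

    The comparison key mirrors the DP's rules exactly: ascending psi, then
    descending |omega|, then (for identical (psi, |omega|)) preferring
    positive omega, then the lexicographically smallest position tuple.
    """
    check_dna(x, "string")
    n, k = len(x), tables.k
    if n < k:
        raise ValueError(f"string length {n} < k = {k}")
    if comb(n, k) > cap:
        raise ValueError(f"C({n},{k}) subsets exceed brute-force cap {cap}")
    best_key = None
    best = None
    for positions in combinations(range(n), k):
        z = "".join(x[p] for p in positions)
        s = score(z, tables)
        # sign=0 for omega >= 0 sorts the Tmax branch first on |omega| ties
        key = (s.psi, -abs(s.omega), 0 if s.omega >= 0 else 1, positions)
        if best_key is None or key < best_key:
            best_key = key
            best = (positions, z, s)
    positions, z, s = best
    return SeedHit(
        sequence_id=sequence_id,
        window_start=0,
        repeat_index=0,
        positions=positions,
        subseq=z,
        score=s,
    )


def dp_tables(x: str, tables: ABCTables) -> tuple[np.ndarray, np.ndarray]:
    """The filled (Tmin, Tmax) arrays, shape (n+1, k+1, d), for inspection.

    Cells holding the UNDEF sentinel mark (l, i, j) combinations realized
    by no subsequence.  Exposed for tests of the DP invariants.
    """
    codes = check_dna(x, "string")
    n, k, d = len(codes), tables.k, tables.d
    At, B1t, B2t, C = _prepared(tables)
    Tmin = np.empty((n + 1, k + 1, d), dtype=np.int64)
    Tmax = np.empty((n + 1, k + 1, d), dtype=np.int64)
    _init_tables(Tmin, Tmax, n, k, d)
    _fill(codes, 0, n, k, d, At, B1t, B2t, C, Tmin, Tmax)
    undefined = (np.abs(Tmin) >= UNDEF_CUTOFF) | (np.abs(Tmax) >= UNDEF_CUTOFF)
    Tmin[undefined] = UNDEF
    Tmax[undefined] = UNDEF
    return Tmin, Tmax
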