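"""Numba kernels for the minimized-subsequence dynamic program.

The DP fills two tables Tmin/Tmax indexed [prefix length l][picked chars
i][residue class j]: the minimum / maximum omega over all length-i
subsequences of x1..xl whose psi equals j.  Both extremes are tracked
because a -1 first component in table B swaps them, and the final answer
needs the maximal |omega|.

Undefined cells (no subsequence realizes the (i, j) combination) carry
explicit integer sentinels, never a float NaN: +2^62 in Tmin and -2^62 in
Tmax.  Real omega values are bounded by k * 2^31 << 2^60, so plain min/max
arithmetic keeps undefined cells out of the way without any branching, the
negation performed when a B sign pair swaps the tables maps one sentinel
onto the other, and a |value| >= 2^60 test recovers definedness exactly
(sentinel drift along a DP path is at most k * 2^31).

The window-scan kernel reuses one table allocation: cells outside the
feasible region i <= min(l, k) are set to their sentinel once and are never
written by the fill loop, while every feasible cell is rewritten before it
is read, so no per-window re-initialization is needed.

Kernels take the A/B tables transposed to shape (k, 4, d) so the inner loop
over the residue class j runs over contiguous memory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: sentinels standing for "no such subsequence" (quasi +/- infinity)
POS_UNDEF = np.int64(2**62)
NEG_UNDEF = np.int64(-(2**62))
#: |value| >= UNDEF_CUTOFF <=> the cell is undefined
UNDEF_CUTOFF = np.int64(2**60)


@njit(cache=True)
def _init_tables(Tmin, Tmax, n, k, d):
    for l in range(n + 1):
        for i in range(k + 1):
            for j in range(d):
                Tmin[l, i, j] = POS_UNDEF
                Tmax[l, i, j] = NEG_UNDEF
        Tmin[l, 0, 0] = 0
        Tmax[l, 0, 0] = 0


@njit(cache=True)
def _fill(codes, start, n, k, d, At, B1t, B2t, C, Tmin, Tmax):
    """Fill the feasible region for the window codes[start:start+n]."""
    for l in range(1, n + 1):
        c = codes[start + l - 1]
        imax = k if k < l else l
        for i in range(1, imax + 1):
            ci = C[i - 1, c]
            Ac = At[i - 1, c]
            B1c = B1t[i - 1, c]
            B2c = B2t[i - 1, c]
            Pmin = Tmin[l - 1, i - 1]
            Pmax = Tmax[l - 1, i - 1]
            Smin = Tmin[l - 1, i]
            Smax = Tmax[l - 1, i]
            Omin = Tmin[l, i]
            Omax = Tmax[l, i]
            jp = d - ci if ci > 0 else 0
            for j in range(d):
                if jp == d:
                    jp = 0
                base = Ac[j] * B2c[j]
                if B1c[j] == 1:
                    tmin = base + Pmin[jp]
                    tmax = base + Pmax[jp]
                else:
                    tmin = base - Pmax[jp]
                    tmax = base - Pmin[jp]
                smin = Smin[j]
                smax = Smax[j]
                Omin[j] = smin if smin <= tmin else tmin
                Omax[j] = smax if smax >= tmax else tmax
                jp += 1


@njit(cache=True)
def _select(Tmin, Tmax, n, k, d):
    """Pick (psi_opt, omega_opt, follow_max) from the filled tables.

    psi_opt is the smallest residue with a defined cell; omega_opt is the
    extreme of larger absolute value there.  On an exact |Tmin| == |Tmax|
    tie the Tmax (positive-omega) branch is preferred.
    Returns psi_opt = -1 when no length-k subsequence exists.
    """
    for j in range(d):
        vmin = Tmin[n, k, j]
        vmax = Tmax[n, k, j]
        amin = -vmin if vmin < 0 else vmin
        amax = -vmax if vmax < 0 else vmax
        if amin >= UNDEF_CUTOFF and amax >= UNDEF_CUTOFF:
            continue
        if amin >= UNDEF_CUTOFF:
            return j, vmax, True
        if amax >= UNDEF_CUTOFF:
            return j, vmin, False
        if amax >= amin:
            return j, vmax, True
        return j, vmin, False
    return -1, np.int64(0), True


@njit(cache=True)
def _traceback(codes, start, n, k, d, At, B1t, B2t, C, Tmin, Tmax, j_opt, follow_max, pos):
    """Recover the positions (0-based, window-relative) of the optimum.

    Ties prefer skipping the current character over taking it; for position
    sets extracting the same string this reports the leftmost embedding,
    i.e. the lexicographically smallest position tuple.
    """
    l = n
    i = k
    j = j_opt
    v = Tmax[n, k, j] if follow_max else Tmin[n, k, j]
    while i > 0:
        skip = Tmax[l - 1, i, j] if follow_max else Tmin[l - 1, i, j]
        if skip == v:
            l -= 1
            continue
        c = codes[start + l - 1]
        ci = C[i - 1, c]
        jp = j - ci
        if jp < 0:
            jp += d
        b1 = B1t[i - 1, c, j]
        base = At[i - 1, c, j] * B2t[i - 1, c, j]
        pos[i - 1] = l - 1
        v = (v - base) * b1
        if b1 == -1:
            follow_max = not follow_max
        l -= 1
        i -= 1
        j = jp


@njit(cache=True)
def scan_windows(codes, n, k, d, At, B1t, B2t, C):
    """Run the DP over every length-n window of an encoded sequence.

    Returns (psi, omega, positions): psi[w] == -1 marks a window skipped
    because it contains a non-ACGT code; positions are window-relative.
    """
    L = codes.shape[0]
    W = L - n + 1
    psi_out = np.empty(W, dtype=np.int64)
    omega_out = np.empty(W, dtype=np.int64)
    pos_out = np.empty((W, k), dtype=np.int32)
    Tmin = np.empty((n + 1, k + 1, d), dtype=np.int64)
    Tmax = np.empty((n + 1, k + 1, d), dtype=np.int64)
    _init_tables(Tmin, Tmax, n, k, d)
    # rolling count of invalid codes for O(1) window validity checks
    bad = np.zeros(L + 1, dtype=np.int64)
    for p in range(L):
        bad[p + 1] = bad[p] + (1 if codes[p] < 0 else 0)
    for w in range(W):
        if bad[w + n] - bad[w] > 0:
            psi_out[w] = -1
            omega_out[w] = 0
            for r in range(k):
                pos_out[w, r] = -1
            continue
        _fill(codes, w, n, k, d, At, B1t, B2t, C, Tmin, Tmax)
        j_opt, v, follow_max = _select(Tmin, Tmax, n, k, d)
        psi_out[w] = j_opt
        omega_out[w] = v
        _traceback(
            codes, w, n, k, d, At, B1t, B2t, C, Tmin, Tmax, j_opt, follow_max,
            pos_out[w],
        )
    return psi_out, omega_out, pos_out


@njit(cache=True)
def single_window(codes, n, k, d, At, B1t, B2t, C):
    """DP + traceback for one whole string (codes of length n)."""
    Tmin = np.empty((n + 1, k + 1, d), dtype=np.int64)
    Tmax = np.empty((n + 1, k + 1, d), dtype=np.int64)
    _init_tables(Tmin, Tmax, n, k, d)
    _fill(codes, 0, n, k, d, At, B1t, B2t, C, Tmin, Tmax)
    j_opt, v, follow_max = _select(Tmin, Tmax, n, k, d)
    pos = np.empty(k, dtype=np.int32)
    if j_opt >= 0:
        _traceback(codes, 0, n, k, d, At, B1t, B2t, C, Tmin, Tmax, j_opt, follow_max, pos)
    return j_opt, v, pos
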