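"""Whole-sequence seeding and seed matching.

Three seeders share one interface:

* ``subseqhash`` — every length-n sliding window contributes its minimal
  length-k subsequence under an ABC order; t independent repeats, each
  with its own random tables, are unioned to boost sensitivity;
* ``minimizer`` — the smallest k-mer of each length-n window under a keyed
  pseudo-random order (ties to the leftmost occurrence);
* ``all_kmers`` — every k-mer is a seed (the limit of repeating
  minimizers; the window length is ignored).

Two extractions count as the same seed iff (repeat index, subsequence,
absolute position tuple) coincide, so identical picks from overlapping
windows collapse to one seed and density stays meaningful.  Seeds match
across sequences only within the same repeat index: each repeat is its own
hash function, and string equality across different orders is not a
collision of the same function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .alphabet import encode
from .dp import SeedHit, _prepared
from ._kernels import scan_windows
from .order import ABCTables, OrderScore, tables_for_repeats

METHODS = ("subseqhash", "minimizer", "all_kmers")


@dataclass(frozen=True)
class SeedingConfig:
    """Parameters of one seeding run.

    ``d`` and ``t`` only apply to subseqhash; for the minimizer the
    "window" is the n-window whose smallest k-mer is selected.
    """

    method: str
    n: int
    k: int
    d: int = 11
    t: int = 1
    base_seed: int = 0
    stride: int = 1

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown seeding method {self.method!r}")
        if self.k < 1 or (self.method != "all_kmers" and self.k > self.n):
            raise ValueError("need 1 <= k <= n")
        if self.method == "subseqhash" and self.d < 1:
            raise ValueError("modulus d must be positive")
        if self.t < 1:
            raise ValueError("repeats t must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class SeedMatch:
    """A pair of identical seeds across two sequences.

    ``aligned_pairs`` are the k induced (position in x, position in y)
    character alignments, in absolute coordinates.
    """

    hit_x: SeedHit
    hit_y: SeedHit
    aligned_pairs: tuple[tuple[int, int], ...]
    label: str = "unlabeled"

    def __post_init__(self):
        if self.hit_x.subseq != self.hit_y.subseq:
            raise ValueError("matched hits carry different seed strings")


# ---------------------------------------------------------------------------
# k-mer hashing for the minimizer's fully random order


def _splitmix64(v: np.ndarray) -> np.ndarray:
    """Deterministic 64-bit mixer (splitmix64 finalizer), vectorized."""
    v = (v + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    v ^= v >> np.uint64(30)
    v = (v * np.uint64(0xBF58476D1CE4E5B9)).astype(np.uint64)
    v ^= v >> np.uint64(27)
    v = (v * np.uint64(0x94D049BB133111EB)).astype(np.uint64)
    v ^= v >> np.uint64(31)
    return v


def kmer_codes(codes: np.ndarray, k: int) -> tuple[list[np.ndarray], np.ndarray]:
    """(packed columns, valid): 2-bit packed k-mers and a validity mask.

    k-mers longer than 31 characters are split into ceil(k/31) uint64
    words; equality of all words is equality of the k-mer.
    """
    L = len(codes)
    if L < k:
        return [np.empty(0, dtype=np.uint64)], np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    cols = []
    for lo in range(0, k, 31):
        chunk = win[:, lo : lo + 31].astype(np.uint64)
        width = chunk.shape[1]
        powers = np.uint64(4) ** np.arange(width - 1, -1, -1, dtype=np.uint64)
        cols.append((chunk * powers).sum(axis=1, dtype=np.uint64))
    bad = (codes < 0).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    return cols, valid


def kmer_hashes(codes: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Keyed pseudo-random hash per k-mer offset, realizing a random order."""
    cols, valid = kmer_codes(codes, k)
    key = np.uint64(np.random.SeedSequence([seed, k]).generate_state(1, np.uint64)[0])
    h = _splitmix64(cols[0] ^ key)
    for col in cols[1:]:
        h = _splitmix64(h ^ col)
    return h, valid


# ---------------------------------------------------------------------------
# array-level seeding (no SeedHit objects; used by the experiment drivers)


def subseqhash_window_scan(codes: np.ndarray, n: int, k: int, tables: ABCTables):
    """Raw (psi, omega, positions) per window start; psi=-1 marks skipped."""
    At, B1t, B2t, C = _prepared(tables)
    return scan_windows(codes, n, k, tables.d, At, B1t, B2t, C)


def minimizer_positions(codes: np.ndarray, n: int, k: int, seed: int) -> np.ndarray:
    """Distinct selected k-mer start offsets over all length-n windows."""
    L = len(codes)
    if L < n:
        return np.empty(0, dtype=np.int64)
    h, valid = kmer_hashes(codes, k, seed)
    wk = n - k + 1  # k-mers per window
    hwin = np.lib.stride_tricks.sliding_window_view(h, wk)
    vwin = np.lib.stride_tricks.sliding_window_view(valid, wk)
    sel = hwin.argmin(axis=1) + np.arange(L - n + 1)
    ok = vwin.all(axis=1)  # windows containing non-ACGT are skipped
    return np.unique(sel[ok])


def all_kmer_positions(codes: np.ndarray, k: int) -> np.ndarray:
    """Every valid k-mer start offset."""
    _, valid = kmer_codes(codes, k)
    return np.flatnonzero(valid)


# ---------------------------------------------------------------------------
# object-level seeding (the reference interface)


def seed_sequence(
    x: str,
    cfg: SeedingConfig,
    tables_list: list[ABCTables] | None = None,
    sequence_id: str = "",
) -> list[SeedHit]:
    """Extract all (deduplicated) seeds of a sequence under one config.

    For subseqhash a list of t table sets may be supplied (otherwise they
    are derived from ``cfg.base_seed``).  A sequence shorter than the
    window yields an empty list.
    """
    codes = encode(x)
    L = len(codes)
    hits: list[SeedHit] = []
    if cfg.method == "all_kmers":
        for p in all_kmer_positions(codes, cfg.k)[:: cfg.stride]:
            p = int(p)
            hits.append(
                SeedHit(
                    sequence_id=sequence_id,
                    window_start=p,
                    repeat_index=0,
                    positions=tuple(range(cfg.k)),
                    subseq=x[p : p + cfg.k].upper(),
                    score=OrderScore(0, 0, x[p : p + cfg.k].upper()),
                )
            )
        return hits
    if L < cfg.n:
        return []
    if cfg.method == "minimizer":
        for p in minimizer_positions(codes, cfg.n, cfg.k, cfg.base_seed):
            p = int(p)
            hits.append(
                SeedHit(
                    sequence_id=sequence_id,
                    window_start=p,
                    repeat_index=0,
                    positions=tuple(range(cfg.k)),
                    subseq=x[p : p + cfg.k].upper(),
                    score=OrderScore(0, 0, x[p : p + cfg.k].upper()),
                )
            )
        return hits
    # subseqhash
    if tables_list is None:
        tables_list = tables_for_repeats(cfg.k, cfg.d, cfg.base_seed, cfg.t)
    if len(tables_list) != cfg.t:
        raise ValueError(f"need {cfg.t} table sets, got {len(tables_list)}")
    xu = x.upper()
    for r, tables in enumerate(tables_list):
        psi, omega, pos = subseqhash_window_scan(codes, cfg.n, cfg.k, tables)
        seen: set[tuple] = set()
        for w in range(0, len(psi), cfg.stride):
            if psi[w] < 0:
                continue
            abs_pos = tuple(int(p) + w for p in pos[w])
            subseq = "".join(xu[p] for p in abs_pos)
            key = (subseq, abs_pos)
            if key in seen:
                continue
            seen.add(key)
            hits.append(
                SeedHit(
                    sequence_id=sequence_id,
                    window_start=w,
                    repeat_index=r,
                    positions=tuple(int(p) for p in pos[w]),
                    subseq=subseq,
                    score=OrderScore(int(psi[w]), int(omega[w]), subseq),
                )
            )
    return hits


def density(hits: Iterable[SeedHit], L: int) -> float:
    """Number of distinct seeds (after dedup) divided by sequence length."""
    if L <= 0:
        raise ValueError("sequence length must be positive")
    distinct = {(h.repeat_index, h.subseq, h.abs_positions) for h in hits}
    return len(distinct) / L


def match_seeds(
    hits_x: Iterable[SeedHit], hits_y: Iterable[SeedHit]
) -> list[SeedMatch]:
    """All pairs of identical seeds (same repeat index, same string)."""
    buckets: dict[tuple[int, str], list[SeedHit]] = {}
    for h in hits_x:
        buckets.setdefault((h.repeat_index, h.subseq), []).append(h)
    matches: list[SeedMatch] = []
    for h in hits_y:
        for hx in buckets.get((h.repeat_index, h.subseq), ()):
            matches.append(
                SeedMatch(
                    hit_x=hx,
                    hit_y=h,
                    aligned_pairs=tuple(zip(hx.abs_positions, h.abs_positions)),
                )
            )
    return matches
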