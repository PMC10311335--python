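"""Experiment drivers: collision curves, coverage grids, overlap detection.

These reproduce the package's benchmark protocols end to end on synthetic
data.  The pairwise-alignment coverage grid works on position arrays and
packed seed codes rather than per-seed objects — the arithmetic (dedup
rule, matching rule, 50% truth rule, coverage definition) is identical to
the object-level API in :mod:`subseqhash.seeding` / :mod:`subseqhash.evaluate`,
which the test suite verifies on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import encode
from .dp import min_subsequence
from .order import ABCTables, generate_tables, tables_for_repeats
from .seeding import (
    all_kmer_positions,
    kmer_hashes,
    minimizer_positions,
    subseqhash_window_scan,
)
from .simulate import collision_pairs, mutate_pair, random_sequence
from .evaluate import (
    collision_probability,
    lexicographic_min_subsequence,
    random_order_collider,
)


# ---------------------------------------------------------------------------
# hash-collision curves (single seed per whole string, binned by distance)


def minimizer_single_seed(x: str, k: int, seed: int) -> str | None:
    """Smallest k-mer of the whole string under a keyed random order."""
    codes = encode(x)
    if len(codes) < k:
        return None
    h, valid = kmer_hashes(codes, k, seed)
    h = h.copy()
    h[~valid] = np.iinfo(np.uint64).max
    if not valid.any():
        return None
    p = int(np.argmin(h))
    return x[p : p + k]


def make_collider(order: str, k: int, d: int = 11, seed: int = 0):
    """collide(x, y) callables for the four order families.

    ``order`` is one of "abc", "minimizer", "lexicographic", "random".
    """
    if order == "abc":
        tables = generate_tables(k, d, seed)

        def collide(x: str, y: str) -> bool:
            if len(x) < k or len(y) < k:
                return False
            return (
                min_subsequence(x, tables).subseq == min_subsequence(y, tables).subseq
            )

    elif order == "minimizer":

        def collide(x: str, y: str) -> bool:
            sx = minimizer_single_seed(x, k, seed)
            sy = minimizer_single_seed(y, k, seed)
            return sx is not None and sx == sy

    elif order == "lexicographic":

        def collide(x: str, y: str) -> bool:
            if len(x) < k or len(y) < k:
                return False
            return lexicographic_min_subsequence(
                x, k
            ) == lexicographic_min_subsequence(y, k)

    elif order == "random":
        collide = random_order_collider(k, seed)
    else:
        raise ValueError(f"unknown order {order!r}")
    return collide


def collision_curve(
    order: str,
    n: int,
    k: int,
    d: int = 11,
    chains: int = 500,
    seed: int = 0,
    max_distance: int = 10,
) -> dict[int, float | None]:
    """Empirical collision frequency per edit-distance bin 1..max_distance.

    Pairs come from mutation chains on random roots of length n (each
    chain yields n pairs); one seed is extracted from each full string.
    """
    bins = collision_pairs(n, chains, seed, max_distance=max_distance)
    return collision_probability(bins, make_collider(order, k, d, seed=seed + 1))


# ---------------------------------------------------------------------------
# pairwise-alignment coverage benchmark


def _pack_rows(mat: np.ndarray) -> list[np.ndarray]:
    """Pack a (m, k) symbol matrix into ceil(k/31) uint64 columns."""
    m, k = mat.shape
    cols = []
    for lo in range(0, k, 31):
        chunk = mat[:, lo : lo + 31].astype(np.uint64)
        width = chunk.shape[1]
        powers = np.uint64(4) ** np.arange(width - 1, -1, -1, dtype=np.uint64)
        cols.append((chunk * powers).sum(axis=1, dtype=np.uint64))
    return cols


def _dedup(pos: np.ndarray) -> np.ndarray:
    """Drop duplicate rows (identical absolute position tuples)."""
    if len(pos) == 0:
        return pos
    return np.unique(pos, axis=0)


def _subseqhash_seed_positions(
    codes: np.ndarray, n: int, k: int, tables: ABCTables
) -> np.ndarray:
    """(m, k) absolute seed positions for one repeat, deduplicated."""
    psi, _, pos = subseqhash_window_scan(codes, n, k, tables)
    valid = psi >= 0
    if not valid.any():
        return np.empty((0, k), dtype=np.int64)
    starts = np.flatnonzero(valid)
    abs_pos = pos[valid].astype(np.int64) + starts[:, None]
    return _dedup(abs_pos)


def _match_and_score(
    pos_x: np.ndarray,
    pos_y: np.ndarray,
    codes_x: np.ndarray,
    codes_y: np.ndarray,
    gt_map: np.ndarray,
    cov_true: tuple[np.ndarray, np.ndarray],
    cov_false: tuple[np.ndarray, np.ndarray],
) -> tuple[int, int]:
    """Match seed position matrices, label matches, accumulate coverage.

    Returns (number of matches, number of true matches).  A match pairs
    identical seed strings; it is true when at least half of its k aligned
    character pairs agree with the ground-truth map.
    """
    if len(pos_x) == 0 or len(pos_y) == 0:
        return 0, 0
    k = pos_x.shape[1]
    dfx = pd.DataFrame({f"c{i}": c for i, c in enumerate(_pack_rows(codes_x[pos_x]))})
    dfx["ix"] = np.arange(len(pos_x))
    dfy = pd.DataFrame({f"c{i}": c for i, c in enumerate(_pack_rows(codes_y[pos_y]))})
    dfy["iy"] = np.arange(len(pos_y))
    keys = [c for c in dfx.columns if c != "ix"]
    merged = dfx.merge(dfy, on=keys, how="inner")
    if len(merged) == 0:
        return 0, 0
    X = pos_x[merged["ix"].to_numpy()]
    Y = pos_y[merged["iy"].to_numpy()]
    good = (gt_map[X] == Y).sum(axis=1)
    true = 2 * good >= k
    tx, ty = cov_true
    fx, fy = cov_false
    tx[X[true].ravel()] = True
    ty[Y[true].ravel()] = True
    fx[X[~true].ravel()] = True
    fy[Y[~true].ravel()] = True
    return len(merged), int(true.sum())


@dataclass(frozen=True)
class GridSetting:
    method: str  # subseqhash | minimizer | all_kmers
    n: int
    k: int
    t: int = 1


def default_grid(
    subseq_windows: dict[int, range] | None = None,
    minimizer_windows: dict[int, range] | None = None,
    all_kmer_ks: range = range(9, 26),
    t: int = 10,
) -> list[GridSetting]:
    """The benchmark parameter grid.

    Defaults: minimizers with windows 20/25/30/35 and k = 8..n-1;
    all-kmers with k = 9..25; subsequence seeds with window 30 and
    k = 18..29, repeated t times.
    """
    if subseq_windows is None:
        subseq_windows = {30: range(18, 30)}
    if minimizer_windows is None:
        minimizer_windows = {n: range(8, n) for n in (20, 25, 30, 35)}
    grid = [
        GridSetting("subseqhash", n, k, t)
        for n, ks in subseq_windows.items()
        for k in ks
    ]
    grid += [
        GridSetting("minimizer", n, k)
        for n, ks in minimizer_windows.items()
        for k in ks
    ]
    grid += [GridSetting("all_kmers", 0, k) for k in all_kmer_ks]
    return grid


def alignment_coverage_experiment(
    L: int,
    n_pairs: int,
    error_rate: float,
    seed: int,
    grid: list[GridSetting] | None = None,
    d: int = 11,
) -> pd.DataFrame:
    """True/false coverage of every grid setting on simulated pairs.

    For each pair, the first sequence is random of length L and the second
    is pushed through the per-position error channel; seeds are extracted
    from both, matched, labeled against the construction's ground-truth
    alignment, and coverage is the percentage of characters (both
    sequences) under at least one true (false) match.  Rows report the
    mean over pairs per setting.
    """
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        x = random_sequence(L, rng)
        y, gt = mutate_pair(x, error_rate, rng)
        pairs.append((encode(x), encode(y), gt.as_map(len(x))))

    # tables shared across pairs: one set of t per (k) for subseqhash
    table_cache: dict[tuple[int, int], list[ABCTables]] = {}
    minimizer_seed = int(rng.integers(0, 2**31))

    records = []
    for setting in grid:
        acc = []
        for cx, cy, gt_map in pairs:
            lx, ly = len(cx), len(cy)
            cov_true = (np.zeros(lx, bool), np.zeros(ly, bool))
            cov_false = (np.zeros(lx, bool), np.zeros(ly, bool))
            n_matches = n_true = 0
            if setting.method == "subseqhash":
                key = (setting.k, setting.t)
                if key not in table_cache:
                    table_cache[key] = tables_for_repeats(
                        setting.k, d, int(rng.integers(0, 2**31)), setting.t
                    )
                for tables in table_cache[key]:
                    px = _subseqhash_seed_positions(cx, setting.n, setting.k, tables)
                    py = _subseqhash_seed_positions(cy, setting.n, setting.k, tables)
                    nm, nt = _match_and_score(
                        px, py, cx, cy, gt_map, cov_true, cov_false
                    )
                    n_matches += nm
                    n_true += nt
            else:
                if setting.method == "minimizer":
                    sx = minimizer_positions(cx, setting.n, setting.k, minimizer_seed)
                    sy = minimizer_positions(cy, setting.n, setting.k, minimizer_seed)
                else:
                    sx = all_kmer_positions(cx, setting.k)
                    sy = all_kmer_positions(cy, setting.k)
                offs = np.arange(setting.k, dtype=np.int64)
                px = sx[:, None] + offs
                py = sy[:, None] + offs
                n_matches, n_true = _match_and_score(
                    px, py, cx, cy, gt_map, cov_true, cov_false
                )
            total = lx + ly
            acc.append(
                (
                    n_matches,
                    n_true,
                    100.0 * (cov_true[0].sum() + cov_true[1].sum()) / total,
                    100.0 * (cov_false[0].sum() + cov_false[1].sum()) / total,
                )
            )
        arr = np.asarray(acc, dtype=float)
        mean = arr.mean(axis=0)
        records.append(
            {
                "method": setting.method,
                "n": setting.n,
                "k": setting.k,
                "t": setting.t,
                "n_matches": mean[0],
                "true_ratio": (arr[:, 1].sum() / arr[:, 0].sum())
                if arr[:, 0].sum()
                else np.nan,
                "true_coverage": mean[2],
                "false_coverage": mean[3],
            }
        )
    return pd.DataFrame.from_records(records)


def best_true_coverage(
    df: pd.DataFrame, methods: tuple[str, ...], max_false: float = 5.0
) -> float:
    """Best mean true coverage among settings with false coverage below cap."""
    sel = df[df["method"].isin(methods) & (df["false_coverage"] < max_false)]
    if len(sel) == 0:
        return float("nan")
    return float(sel["true_coverage"].max())


# ---------------------------------------------------------------------------
# overlap detection on synthetic reads


def overlap_experiment(
    reads,
    truth_pairs: set[tuple[int, int]],
    n: int,
    k: int,
    d: int,
    t: int,
    seed: int,
    method: str = "subseqhash",
):
    """Sensitivity/precision of candidate overlap pairs, per repeat count.

    Returns a list of (t_used, OverlapResult) for t_used = 1..t: the
    candidate set is the union over the first t_used repeats, so adding
    repeats can only add candidates.
    """
    from .evaluate import overlap_detect
    from .seeding import SeedingConfig, seed_sequence

    cfg = SeedingConfig(method=method, n=n, k=k, d=d, t=t, base_seed=seed)
    tables = (
        tables_for_repeats(k, d, seed, t) if method == "subseqhash" else None
    )
    seed_lists = [
        seed_sequence(read, cfg, tables_list=tables, sequence_id=f"read{i}")
        for i, read in enumerate(reads)
    ]
    results = []
    for t_used in range(1, t + 1):
        filtered = [
            [h for h in hits if h.repeat_index < t_used] for hits in seed_lists
        ]
        results.append((t_used, overlap_detect(filtered, truth_pairs)))
    return results
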