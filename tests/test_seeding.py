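"""Sliding-window seeding, dedup, matching, and density."""

import numpy as np
import pytest

from subseqhash.alphabet import encode
from subseqhash.dp import min_subsequence
from subseqhash.order import generate_tables, tables_for_repeats
from subseqhash.seeding import (
    SeedingConfig,
    density,
    match_seeds,
    minimizer_positions,
    seed_sequence,
)
from subseqhash.simulate import random_sequence

from conftest import random_dna


def test_all_kmers_enumerates_every_position(rng):
    x = random_dna(rng, 100)
    cfg = SeedingConfig(method="all_kmers", n=10, k=10)
    hits = seed_sequence(x, cfg)
    assert len(hits) == 91
    assert density(hits, 100) == pytest.approx(0.91)
    assert all(h.subseq == x[h.window_start : h.window_start + 10] for h in hits)


def test_density_of_empty_hits():
    assert density([], 50) == 0.0
    with pytest.raises(ValueError):
        density([], 0)


def test_single_window_equals_min_subsequence(rng):
    x = random_dna(rng, 25)
    tables = tables_for_repeats(10, 11, base_seed=4, t=3)
    cfg = SeedingConfig(method="subseqhash", n=25, k=10, d=11, t=3, base_seed=4)
    hits = seed_sequence(x, cfg, tables)
    assert len(hits) == 3
    for r, h in enumerate(sorted(hits, key=lambda h: h.repeat_index)):
        ref = min_subsequence(x, tables[r])
        assert h.repeat_index == r
        assert h.subseq == ref.subseq
        assert h.positions == ref.positions


def test_sequence_shorter_than_window_yields_nothing(rng):
    cfg = SeedingConfig(method="subseqhash", n=30, k=10, base_seed=0)
    assert seed_sequence(random_dna(rng, 20), cfg) == []


def test_repeats_use_independent_orders(rng):
    x = random_dna(rng, 40)
    cfg = SeedingConfig(method="subseqhash", n=40, k=12, d=11, t=2, base_seed=1)
    hits = seed_sequence(x, cfg)
    by_rep = {h.repeat_index: h for h in hits}
    assert set(by_rep) == {0, 1}
    # independent tables: agreeing on the same window is possible but not
    # forced; scores must come from different orders
    t0, t1 = tables_for_repeats(12, 11, 1, 2)
    assert not np.array_equal(t0.A, t1.A)


def test_dedup_collapses_identical_extractions(rng):
    x = random_dna(rng, 300)
    cfg = SeedingConfig(method="subseqhash", n=30, k=24, d=11, t=1, base_seed=5)
    hits = seed_sequence(x, cfg)
    keys = [(h.repeat_index, h.subseq, h.abs_positions) for h in hits]
    assert len(keys) == len(set(keys))
    assert density(hits, 300) <= 1.0


def test_windows_containing_non_acgt_are_skipped():
    x = "ACGT" * 10 + "N" + "ACGT" * 10
    cfg = SeedingConfig(method="subseqhash", n=20, k=8, d=11, t=1, base_seed=2)
    hits = seed_sequence(x, cfg)
    assert hits  # valid windows still seed
    for h in hits:
        assert not (h.window_start <= 40 < h.window_start + 20)
    mcfg = SeedingConfig(method="minimizer", n=20, k=8, base_seed=2)
    for h in seed_sequence(x, mcfg):
        assert "N" not in h.subseq


def test_minimizer_is_smallest_kmer_leftmost(rng):
    x = random_dna(rng, 60)
    n, k, seed = 20, 6, 13
    pos = minimizer_positions(encode(x), n, k, seed)
    from subseqhash.seeding import kmer_hashes

    h, _ = kmer_hashes(encode(x), k, seed)
    for w in range(len(x) - n + 1):
        window_hashes = h[w : w + n - k + 1]
        assert int(np.argmin(window_hashes)) + w in pos


def test_match_seeds_identity_and_disjoint(rng):
    x = random_dna(rng, 50)
    cfg = SeedingConfig(method="minimizer", n=20, k=8, base_seed=3)
    hits = seed_sequence(x, cfg, sequence_id="x")
    matches = match_seeds(hits, hits)
    identical = [
        m
        for m in matches
        if m.hit_x.abs_positions == m.hit_y.abs_positions
    ]
    assert len(identical) == len(hits)
    for m in identical:
        assert all(i == j for i, j in m.aligned_pairs)
    a = seed_sequence("A" * 30, SeedingConfig(method="all_kmers", n=5, k=5))
    t = seed_sequence("T" * 30, SeedingConfig(method="all_kmers", n=5, k=5))
    assert match_seeds(a, t) == []


def test_match_exists_iff_same_minimal_subsequence(rng):
    tables = [generate_tables(8, 11, seed=21)]
    cfg = SeedingConfig(method="subseqhash", n=20, k=8, d=11, t=1, base_seed=21)
    for _ in range(20):
        x, y = random_dna(rng, 20), random_dna(rng, 20)
        hx = seed_sequence(x, cfg, tables, "x")
        hy = seed_sequence(y, cfg, tables, "y")
        expect = min_subsequence(x, tables[0]).subseq == min_subsequence(
            y, tables[0]
        ).subseq
        assert bool(match_seeds(hx, hy)) == expect


def test_minimizer_collision_sanity(rng):
    w = random_dna(rng, 30)
    cfg = SeedingConfig(method="minimizer", n=30, k=10, base_seed=6)
    assert match_seeds(seed_sequence(w, cfg), seed_sequence(w, cfg))
    # no shared k-mer => no possible match
    assert not match_seeds(
        seed_sequence("AC" * 15, cfg), seed_sequence("GT" * 15, cfg)
    )


def test_minimizer_density_falls_faster_with_small_k(rng):
    """Shrinking k widens the minimizer's selection window and thins seeds;
    subsequence seeds keep near-every-window density."""
    L, n = 4000, 20
    x = random_sequence(L, rng)
    dens = {}
    for method, k in [("minimizer", 16), ("minimizer", 10), ("subseqhash", 16),
                      ("subseqhash", 10)]:
        cfg = SeedingConfig(method=method, n=n, k=k, d=11, t=1, base_seed=8)
        dens[(method, k)] = density(seed_sequence(x, cfg), L)
    drop_minimizer = dens[("minimizer", 16)] / dens[("minimizer", 10)]
    drop_subseq = dens[("subseqhash", 16)] / dens[("subseqhash", 10)]
    assert dens[("minimizer", 10)] < dens[("minimizer", 16)]
    assert drop_minimizer > drop_subseq


def test_config_validation():
    with pytest.raises(ValueError):
        SeedingConfig(method="bogus", n=10, k=5)
    with pytest.raises(ValueError):
        SeedingConfig(method="subseqhash", n=10, k=11)
    with pytest.raises(ValueError):
        SeedingConfig(method="subseqhash", n=10, k=5, t=0)
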