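"""Metrics: edit distance, AMNED, collision frequency, truth, coverage."""

from functools import lru_cache

import pytest

from subseqhash.dp import SeedHit
from subseqhash.evaluate import (
    amned,
    classify_match,
    collision_probability,
    coverage,
    edit_distance,
    label_matches,
    lexicographic_min_subsequence,
    overlap_detect,
)
from subseqhash.order import OrderScore, generate_tables, rank_top
from subseqhash.seeding import SeedMatch, SeedingConfig, seed_sequence
from subseqhash.simulate import GroundTruthAlignment, simulate_reads
from subseqhash.subseq_sets import subsequence_set

from conftest import random_dna


def _levenshtein_oracle(a, b):
    """Textbook recursive definition, memoized; independent of edlib."""

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


def test_edit_distance_basics_and_oracle(rng):
    assert edit_distance("ACGCCTA", "ACGGCTA") == 1
    assert edit_distance("ACGT", "ACGT") == 0
    assert edit_distance("", "ACG") == 3
    for _ in range(50):
        a = random_dna(rng, int(rng.integers(0, 13)))
        b = random_dna(rng, int(rng.integers(0, 13)))
        assert edit_distance(a, b) == _levenshtein_oracle(a, b)


def _mk_hit(seq_id, positions, subseq, repeat=0):
    return SeedHit(
        sequence_id=seq_id,
        window_start=min(positions) if positions else 0,
        repeat_index=repeat,
        positions=tuple(p - min(positions) for p in positions),
        subseq=subseq,
        score=OrderScore(0, 0, subseq),
    )


def _mk_match(pairs_xy, subseq):
    xs = [i for i, _ in pairs_xy]
    ys = [j for _, j in pairs_xy]
    return SeedMatch(
        hit_x=_mk_hit("x", xs, subseq),
        hit_y=_mk_hit("y", ys, subseq),
        aligned_pairs=tuple(pairs_xy),
    )


def test_true_match_needs_half_the_aligned_pairs():
    gt = GroundTruthAlignment(pairs=tuple((i, i) for i in range(5)))
    nine = [(i, i) for i in range(5)] + [(10 + r, 20 + r) for r in range(4)]
    m = _mk_match(nine, "ACCCACGTC")
    assert classify_match(m, gt)  # 5 of 9 = 55.6% -> true
    none = _mk_match([(30 + r, 40 + r) for r in range(9)], "ACCCACGTC")
    assert not classify_match(none, gt)
    # even k: exactly half qualifies ("at least 50%")
    gt2 = GroundTruthAlignment(pairs=((0, 0), (1, 1)))
    half = _mk_match([(0, 0), (1, 1), (5, 9), (6, 10)], "ACGT")
    assert classify_match(half, gt2)


def test_classify_is_symmetric():
    gt = GroundTruthAlignment(pairs=((0, 4), (1, 5), (2, 6)))
    gt_swapped = GroundTruthAlignment(pairs=tuple((j, i) for i, j in gt.pairs))
    m = _mk_match([(0, 4), (1, 5), (9, 9), (12, 13)], "ACGT")
    m_swapped = _mk_match([(j, i) for i, j in m.aligned_pairs], "ACGT")
    assert classify_match(m, gt) == classify_match(m_swapped, gt_swapped)


def test_coverage_percentages():
    gt = GroundTruthAlignment(pairs=tuple((i, i) for i in range(100)))
    assert coverage([], (100, 100)).true_coverage == 0.0
    m = _mk_match([(i, i) for i in range(10)], "A" * 10)
    labeled = label_matches([m], gt)
    cov = coverage(labeled, (100, 100))
    assert cov.true_coverage == pytest.approx(10.0)  # 20 of 200 characters
    assert cov.false_coverage == 0.0
    read_cov = coverage(labeled, (100, 50), scope="read_only")
    assert read_cov.true_coverage == pytest.approx(20.0)
    with pytest.raises(ValueError):
        coverage([m], (100, 100))  # unlabeled


def test_coverage_invariant_under_reordering():
    gt = GroundTruthAlignment(pairs=tuple((i, i) for i in range(50)))
    ms = label_matches(
        [
            _mk_match([(i, i) for i in range(5)], "AAAAA"),
            _mk_match([(i + 9, i + 30) for i in range(5)], "CCCCC"),
        ],
        gt,
    )
    a = coverage(ms, (50, 50))
    b = coverage(list(reversed(ms)), (50, 50))
    assert a == b


def test_amned_lexicographic_small_scale():
    from subseqhash.order import lexicographic_top

    top = lexicographic_top(6, 300)
    for w in (1, 2, 5):
        assert amned(top, w).value == 1.0


def test_amned_separated_strings_bound():
    strings = [c * 6 for c in "ACGT"]  # pairwise distance 6
    assert amned(strings, 2).value == 6.0


def test_amned_equals_naive_recomputation(rng):
    tables = generate_tables(4, 11, seed=3)
    top = rank_top(tables, 100)
    w = 3
    naive = []
    for i in range(100):
        lo, hi = max(0, i - w), min(100, i + w + 1)
        naive.append(
            min(edit_distance(top[i], top[j]) for j in range(lo, hi) if j != i)
        )
    assert amned(top, w).value == pytest.approx(sum(naive) / 100)
    assert amned(top, w).value >= 1.0


def test_amned_rejects_trivial_input():
    with pytest.raises(ValueError):
        amned(["ACGT"], 1)
    with pytest.raises(ValueError):
        amned(["ACGT", "AAAA"], 0)


def test_collision_probability_bins():
    pairs = {0: [("ACGT", "ACGT")] * 5, 1: [("ACGT", "ACGA")] * 4, 2: []}
    freqs = collision_probability(pairs, lambda x, y: x == y)
    assert freqs[0] == 1.0
    assert freqs[1] == 0.0
    assert freqs[2] is None  # empty bin reported missing, not zero


def test_lexicographic_min_subsequence_is_true_minimum(rng):
    for _ in range(40):
        n = int(rng.integers(3, 11))
        k = int(rng.integers(1, n + 1))
        x = random_dna(rng, n)
        assert lexicographic_min_subsequence(x, k) == min(subsequence_set(x, k))


def test_overlap_detection_zero_error(rng):
    sim = simulate_reads(400, 8, 120, 0.0, rng)
    cfg = SeedingConfig(method="subseqhash", n=30, k=20, d=11, t=1, base_seed=2)
    seeds = [
        seed_sequence(r, cfg, sequence_id=i)
        for i, r in zip(sim.read_ids, sim.reads)
    ]
    truth = sim.true_overlap_pairs(min_overlap=30)
    res = overlap_detect(seeds, truth)
    # identical-interval or heavily overlapping error-free reads share all
    # their window seeds; every truth pair with >= one full shared window
    wide = {
        (a, b)
        for a, b in truth
        if min(sim.intervals[a][1], sim.intervals[b][1])
        - max(sim.intervals[a][0], sim.intervals[b][0])
        >= 30
    }
    assert wide <= res.candidates
    if res.candidates:
        assert res.precision is not None


def test_overlap_union_monotone_in_repeats(rng):
    from subseqhash.experiments import overlap_experiment

    sim = simulate_reads(1500, 14, 250, 0.1, rng)
    truth = sim.true_overlap_pairs()
    results = overlap_experiment(
        sim.reads, truth, n=25, k=18, d=11, t=4, seed=11
    )
    sens = [r.sensitivity for _, r in results]
    cands = [len(r.candidates) for _, r in results]
    assert cands == sorted(cands)
    assert sens == sorted(sens)


def test_overlap_empty_truth_reports_missing():
    res = overlap_detect([[], []], set())
    assert res.sensitivity is None and res.precision is None
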