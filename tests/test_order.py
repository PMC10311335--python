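"""ABC order construction, scoring, and comparator semantics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from subseqhash.order import (
    SIGN_PAIRS,
    generate_tables,
    lexicographic_top,
    load_tables,
    rank_top,
    save_tables,
    score,
    compare,
    tables_for_repeats,
)

from conftest import random_dna

DNA = st.text(alphabet="ACGT", min_size=1, max_size=8)


@pytest.mark.parametrize("k,d", [(1, 1), (4, 4), (15, 11), (6, 2), (5, 31)])
def test_table_invariants(k, d):
    t = generate_tables(k, d, seed=7)
    assert t.A.shape == (k, d, 4)
    assert t.A.min() >= 2**30 and t.A.max() < 2**31
    # B is a bijection onto the 4 sign pairs at every (i, j)
    for i in range(k):
        for j in range(d):
            pairs = {(int(a), int(b)) for a, b in zip(t.B1[i, j], t.B2[i, j])}
            assert pairs == set(SIGN_PAIRS)
    assert t.C.min() >= 0 and t.C.max() < d
    if d >= 4:
        for i in range(k):
            assert len(set(t.C[i].tolist())) == 4


def test_tables_deterministic():
    a = generate_tables(15, 11, seed=7)
    b = generate_tables(15, 11, seed=7)
    for x, y in ((a.A, b.A), (a.B1, b.B1), (a.B2, b.B2), (a.C, b.C)):
        assert np.array_equal(x, y)
    c = generate_tables(15, 11, seed=8)
    assert not np.array_equal(a.A, c.A)


@pytest.mark.parametrize("k,d", [(0, 5), (-1, 5), (5, 0), (5, -2)])
def test_invalid_parameters_rejected(k, d):
    with pytest.raises(ValueError):
        generate_tables(k, d, seed=1)


def test_repeat_tables_differ():
    ts = tables_for_repeats(4, 11, base_seed=3, t=3)
    assert len(ts) == 3
    assert not np.array_equal(ts[0].A, ts[1].A)
    again = tables_for_repeats(4, 11, base_seed=3, t=3)
    assert np.array_equal(ts[2].A, again[2].A)


def test_score_single_character():
    t = generate_tables(1, 7, seed=5)
    s = score("A", t)
    psi = int(t.C[0, 0]) % 7
    assert s.psi == psi
    assert s.omega == int(t.A[0, psi, 0]) * int(t.B2[0, psi, 0])


def test_score_d1_psi_zero():
    t = generate_tables(5, 1, seed=2)
    assert score("ACGTA", t).psi == 0


def test_score_matches_hand_unrolled_recurrence():
    """Three recurrence steps, unrolled independently of the implementation."""
    t = generate_tables(3, 4, seed=11)
    for z in ("ACG", "TTT", "GAC"):
        codes = ["ACGT".index(ch) for ch in z]
        psi = omega = 0
        for i, c in enumerate(codes):
            psi = (psi + int(t.C[i, c])) % 4
            omega = omega * int(t.B1[i, psi, c]) + int(t.A[i, psi, c]) * int(
                t.B2[i, psi, c]
            )
        s = score(z, t)
        assert (s.psi, s.omega) == (psi, omega)


def test_score_input_validation(tables_k4):
    with pytest.raises(ValueError):
        score("ACG", tables_k4)  # wrong length
    with pytest.raises(ValueError):
        score("ACGN", tables_k4)  # non-DNA


def test_comparator_psi_primary_omega_secondary(tables_k4):
    strings = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
    scores = {z: score(z, tables_k4) for z in strings}
    for z1, z2 in itertools.islice(itertools.combinations(strings, 2), 500):
        s1, s2 = scores[z1], scores[z2]
        c = compare(z1, z2, tables_k4)
        if s1.psi != s2.psi:
            assert c == (-1 if s1.psi < s2.psi else 1)
        elif abs(s1.omega) != abs(s2.omega):
            # larger |omega| ranks SMALLER
            assert c == (-1 if abs(s1.omega) > abs(s2.omega) else 1)
        else:
            assert c == (-1 if z1 < z2 else 1)
    assert compare("ACGT", "ACGT", tables_k4) == 0


def test_rank_top_is_brute_force_sort(tables_k4):
    strings = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
    expected = sorted(strings, key=lambda z: score(z, tables_k4).sort_key())
    assert rank_top(tables_k4, 10) == expected[:10]
    full = rank_top(tables_k4, 256)
    assert full == expected
    assert len(set(full)) == 256


def test_rank_top_k1_is_alphabet_permutation():
    t = generate_tables(1, 11, seed=9)
    top = rank_top(t, 10)
    assert sorted(top) == list("ACGT")


def test_rank_top_refuses_large_k():
    t = generate_tables(20, 11, seed=1)
    with pytest.raises(ValueError):
        rank_top(t, 10)


def test_psi_changes_under_any_single_substitution(rng):
    """With d >= 4 the C column is injective per position, so one
    substitution always changes psi."""
    for d in (4, 11):
        t = generate_tables(6, d, seed=int(rng.integers(2**31)))
        for _ in range(20):
            z = random_dna(rng, 6)
            base = score(z, t).psi
            for pos in range(6):
                for sub in "ACGT":
                    if sub == z[pos]:
                        continue
                    z2 = z[:pos] + sub + z[pos + 1 :]
                    assert score(z2, t).psi != base


@settings(max_examples=60, derandomize=True)
@given(st.integers(1, 6), st.integers(1, 12), st.integers(0, 2**20))
def test_omega_bounded_and_deterministic(k, d, seed):
    t = generate_tables(k, d, seed)
    z = "ACGT" * 2
    z = (z * 2)[:k]
    s1, s2 = score(z, t), score(z, t)
    assert (s1.psi, s1.omega) == (s2.psi, s2.omega)
    assert 0 <= s1.psi < d
    assert abs(s1.omega) <= k * (2**31 - 1)


def test_lexicographic_top_counts_in_base_four():
    top = lexicographic_top(3, 6)
    assert top == ["AAA", "AAC", "AAG", "AAT", "ACA", "ACC"]
    assert lexicographic_top(2, 100) == sorted(
        "".join(p) for p in itertools.product("ACGT", repeat=2)
    )


def test_table_file_roundtrip(tmp_path, tables_k4):
    full = tmp_path / "full.json"
    slim = tmp_path / "slim.json"
    save_tables(tables_k4, full)
    save_tables(tables_k4, slim, include_tables=False)
    for path in (full, slim):
        loaded = load_tables(path)
        assert loaded.k == tables_k4.k and loaded.d == tables_k4.d
        assert np.array_equal(loaded.A, tables_k4.A)
        assert np.array_equal(loaded.C, tables_k4.C)
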