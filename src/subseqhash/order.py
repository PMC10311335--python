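"""ABC orders over length-k DNA strings.

An ABC order is a pseudo-random total order over all 4^k strings of length
k, designed so that the minimal length-k subsequence of a longer string can
be found in polynomial time (see :mod:`subseqhash.dp`).  It is defined by
three random tables:

* ``A[i][j][sigma]`` — integer magnitudes, drawn uniformly from
  [2^30, 2^31);
* ``B[i][j][sigma]`` — sign pairs from {(+1,+1), (+1,-1), (-1,+1),
  (-1,-1)}, a random bijection onto the four pairs for every fixed (i, j);
* ``C[i][sigma]`` — residues in {0..d-1}; drawn without replacement across
  the four symbols when d >= 4, with replacement otherwise.

A string z = z1..zk is scored by the pair (psi, omega) accumulated as

    psi_i   = (psi_{i-1} + C[i][z_i]) mod d
    omega_i = omega_{i-1} * B[i][psi_i][z_i]_1 + A[i][psi_i][z_i] * B[i][psi_i][z_i]_2

starting from psi_0 = omega_0 = 0.  Strings are ordered by ascending psi,
then by DESCENDING |omega|, with the (rare) residual tie broken by
lexicographic order.  Because A holds integers and omega is accumulated in
exact integer arithmetic, scores are bit-reproducible and ties are
well-defined.

The modulus d controls how sensitive psi is to edits: with d >= 4 the C
column at each position is a partial injection, so any single substitution
is guaranteed to change psi.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import ALPHABET, SIGMA, check_dna, decode

#: The four sign pairs table B maps symbols onto (order fixed for reproducibility).
SIGN_PAIRS = ((1, 1), (1, -1), (-1, 1), (-1, -1))

A_LOW = 2**30
A_HIGH = 2**31  # exclusive

TABLE_FORMAT_VERSION = 1

#: refuse rank_top beyond this many strings unless the caller raises the cap
DEFAULT_ENUM_CAP = 4**10


@dataclass(frozen=True)
class OrderScore:
    """Score (psi, omega) of a length-k string under an ABC order.

    The string itself is kept as ``lex_key`` so that the comparator can
    break exact (psi, |omega|) ties lexicographically.
    """

    psi: int
    omega: int
    lex_key: str

    def sort_key(self) -> tuple:
        """Key realizing the total order: psi asc, |omega| desc, lex asc."""
        return (self.psi, -abs(self.omega), self.lex_key)

    def __lt__(self, other: "OrderScore") -> bool:
        return self.sort_key() < other.sort_key()


@dataclass(frozen=True)
class ABCTables:
    """One ABC order: parameters (k, d, seed) plus the three tables.

    ``A`` has shape (k, d, 4) with values in [2^30, 2^31); ``B1``/``B2``
    (same shape, values +-1) are the first/second components of the sign
    pairs; ``C`` has shape (k, 4) with residues in {0..d-1}.  Position i of
    the recurrences (1-based in the formulas) is row i-1 of the arrays.
    """

    k: int
    d: int
    seed: int
    A: np.ndarray = field(repr=False)
    B1: np.ndarray = field(repr=False)
    B2: np.ndarray = field(repr=False)
    C: np.ndarray = field(repr=False)

    def validate(self) -> None:
        if self.A.shape != (self.k, self.d, SIGMA):
            raise ValueError("table A has wrong shape")
        if self.B1.shape != self.A.shape or self.B2.shape != self.A.shape:
            raise ValueError("table B has wrong shape")
        if self.C.shape != (self.k, SIGMA):
            raise ValueError("table C has wrong shape")
        if self.A.min() < A_LOW or self.A.max() >= A_HIGH:
            raise ValueError("table A entries outside [2^30, 2^31)")
        pairs = self.B1 * 2 + self.B2  # injective encoding of the sign pair
        for i in range(self.k):
            for j in range(self.d):
                if len(set(pairs[i, j].tolist())) != SIGMA:
                    raise ValueError("table B row is not a sign-pair bijection")
        if self.C.min() < 0 or self.C.max() >= self.d:
            raise ValueError("table C entries outside {0..d-1}")
        if self.d >= SIGMA:
            for i in range(self.k):
                if len(set(self.C[i].tolist())) != SIGMA:
                    raise ValueError("table C row drawn with replacement despite d>=4")


def generate_tables(k: int, d: int, seed: int) -> ABCTables:
    """Draw the A/B/C tables for one ABC order, deterministically in seed.

    Draw order is fixed (the A block, then B, then C) so that (k, d, seed)
    fully determines the order.
    """
    if k < 1:
        raise ValueError(f"seed length k must be positive, got {k}")
    if d < 1:
        raise ValueError(f"modulus d must be positive, got {d}")
    rng = np.random.default_rng(seed)
    A = rng.integers(A_LOW, A_HIGH, size=(k, d, SIGMA), dtype=np.int64)
    # one independent permutation of the 4 sign pairs per (i, j)
    perm = rng.permuted(
        np.broadcast_to(np.arange(SIGMA), (k, d, SIGMA)).copy(), axis=-1
    )
    pair_arr = np.array(SIGN_PAIRS, dtype=np.int64)
    B1 = pair_arr[perm, 0]
    B2 = pair_arr[perm, 1]
    if d >= SIGMA:
        C = rng.permuted(np.broadcast_to(np.arange(d), (k, d)).copy(), axis=-1)[
            :, :SIGMA
        ].astype(np.int64)
    else:
        C = rng.integers(0, d, size=(k, SIGMA), dtype=np.int64)
    tables = ABCTables(k=k, d=d, seed=seed, A=A, B1=B1, B2=B2, C=C)
    tables.validate()
    return tables


def tables_for_repeats(k: int, d: int, base_seed: int, t: int) -> list[ABCTables]:
    """Independent table sets for t repeated runs, derived from one base seed.

    Repeat 0 uses ``base_seed`` itself (so a single-repeat run equals
    ``generate_tables(k, d, base_seed)``); later repeats use seeds derived
    deterministically from (base_seed, r).
    """
    if t < 1:
        raise ValueError("number of repeats must be >= 1")
    seeds = [base_seed] + [
        int(np.random.SeedSequence([base_seed, r]).generate_state(1)[0] & 0x7FFFFFFF)
        for r in range(1, t)
    ]
    return [generate_tables(k, d, s) for s in seeds]


def score(z: str, tables: ABCTables) -> OrderScore:
    """Evaluate (psi, omega) of a length-k string under the given order."""
    codes = check_dna(z, "string")
    if len(codes) != tables.k:
        raise ValueError(f"string length {len(z)} != k = {tables.k}")
    psi = 0
    omega = 0
    d = tables.d
    for i, c in enumerate(codes):
        psi = (psi + int(tables.C[i, c])) % d
        omega = omega * int(tables.B1[i, psi, c]) + int(tables.A[i, psi, c]) * int(
            tables.B2[i, psi, c]
        )
    return OrderScore(psi=psi, omega=omega, lex_key=z)


def compare(z1: str, z2: str, tables: ABCTables) -> int:
    """Strict comparison under the ABC order: -1 if z1 < z2, 1 if >, 0 if equal.

    Equality holds only for identical strings.
    """
    if z1 == z2:
        return 0
    k1, k2 = score(z1, tables).sort_key(), score(z2, tables).sort_key()
    return -1 if k1 < k2 else 1


def _all_strings(k: int):
    """All 4^k strings in lexicographic order (generator)."""
    from itertools import product

    for tup in product(ALPHABET, repeat=k):
        yield "".join(tup)


def rank_top(tables: ABCTables, m: int, cap: int = DEFAULT_ENUM_CAP) -> list[str]:
    """The m smallest strings of Sigma^k under the order, by exhaustive sort.

    Only feasible for small k; refuses if 4^k exceeds ``cap``.
    """
    total = SIGMA**tables.k
    if total > cap:
        raise ValueError(f"4^{tables.k} = {total} strings exceed enumeration cap {cap}")
    scored = sorted(score(z, tables).sort_key() for z in _all_strings(tables.k))
    return [key[2] for key in scored[: max(0, m)]]


def lexicographic_top(k: int, m: int) -> list[str]:
    """The m lexicographically smallest length-k DNA strings.

    String number i (0-based) is i written in base 4 over A<C<G<T, padded
    with leading A's; no enumeration of the full 4^k space is needed.
    """
    if m > SIGMA**k:
        m = SIGMA**k
    out = []
    for i in range(m):
        digits = []
        v = i
        for _ in range(k):
            digits.append(v & 3)
            v >>= 2
        out.append(decode(reversed(digits)))
    return out


def save_tables(tables: ABCTables, path, include_tables: bool = True) -> None:
    """Write a self-describing JSON table file."""
    obj = {
        "format": "abc-order-tables",
        "version": TABLE_FORMAT_VERSION,
        "k": tables.k,
        "d": tables.d,
        "seed": tables.seed,
    }
    if include_tables:
        obj["A"] = tables.A.tolist()
        obj["B1"] = tables.B1.tolist()
        obj["B2"] = tables.B2.tolist()
        obj["C"] = tables.C.tolist()
    Path(path).write_text(json.dumps(obj))


def load_tables(path) -> ABCTables:
    """Read a table file; regenerate from (k, d, seed) if no dump is present.

    Invariants are verified on read either way.
    """
    obj = json.loads(Path(path).read_text())
    if obj.get("format") != "abc-order-tables":
        raise ValueError(f"{path} is not an ABC table file")
    k, d, seed = int(obj["k"]), int(obj["d"]), int(obj["seed"])
    if "A" in obj:
        tables = ABCTables(
            k=k,
            d=d,
            seed=seed,
            A=np.asarray(obj["A"], dtype=np.int64),
            B1=np.asarray(obj["B1"], dtype=np.int64),
            B2=np.asarray(obj["B2"], dtype=np.int64),
            C=np.asarray(obj["C"], dtype=np.int64),
        )
        tables.validate()
        return tables
    return generate_tables(k, d, seed)
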