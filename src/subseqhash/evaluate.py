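"""Evaluation metrics for orders, seeds, and seed-matches.

* :func:`edit_distance` — unit-cost Levenshtein distance (edlib-backed).
* :func:`amned` — averaged minimum neighboring edit distance of an order:
  how dissimilar each top-ranked string is from its 2w ranked neighbors;
  1.0 for the lexicographic order, larger for more "random" orders.
* :func:`collision_probability` — empirical hash-collision frequency per
  edit-distance bin for any single-seed extraction rule.
* :func:`classify_match` / :func:`coverage` — a seed-match is TRUE when at
  least half of its k induced character alignments appear in the
  ground-truth alignment; coverage is the percentage of characters touched
  by at least one true (resp. false) match.
* :func:`overlap_detect` — candidate read pairs sharing a seed-match,
  scored as sensitivity/precision against interval-overlap ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import edlib
import numpy as np

from .alphabet import check_dna
from .simulate import GroundTruthAlignment
from .seeding import SeedMatch
from .subseq_sets import subsequence_set


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


# ---------------------------------------------------------------------------
# AMNED


@dataclass(frozen=True)
class AMNEDResult:
    """Mean over the top-m strings of the min edit distance to 2w neighbors."""

    label: str
    k: int
    w: int
    m: int
    value: float


def amned(order_top_m: Sequence[str], w: int, label: str = "") -> AMNEDResult:
    """AMNED of an order given its top-m strings, ascending.

    For each rank i the minimum edit distance to the strings at ranks
    i-w..i+w (excluding i) is taken; near the ends the window is truncated
    to the available neighbors.  The mean over all m ranks is returned.
    """
    m = len(order_top_m)
    if m <= 1:
        raise ValueError("need at least two strings")
    if w < 1:
        raise ValueError("window parameter w must be >= 1")
    k = len(order_top_m[0])
    # distance between ranks i and i+delta, for delta = 1..w
    mins = np.full(m, np.iinfo(np.int64).max, dtype=np.int64)
    for delta in range(1, w + 1):
        for i in range(m - delta):
            e = edit_distance(order_top_m[i], order_top_m[i + delta])
            if e < mins[i]:
                mins[i] = e
            if e < mins[i + delta]:
                mins[i + delta] = e
    return AMNEDResult(label=label, k=k, w=w, m=m, value=float(mins.mean()))


# ---------------------------------------------------------------------------
# collision probability


def collision_probability(
    pairs_by_bin: Mapping[int, Sequence[tuple[str, str]]],
    collide: Callable[[str, str], bool],
) -> dict[int, float | None]:
    """Empirical collision frequency per edit-distance bin.

    ``collide(x, y)`` decides whether one extraction produces identical
    seeds for the pair.  Bins with no pairs are reported as None (missing),
    never as zero.
    """
    out: dict[int, float | None] = {}
    for e, pairs in sorted(pairs_by_bin.items()):
        if not pairs:
            out[e] = None
            continue
        hits = sum(1 for x, y in pairs if collide(x, y))
        out[e] = hits / len(pairs)
    return out


def random_order_collider(k: int, seed) -> Callable[[str, str], bool]:
    """Collision under a fresh fully random order per call (brute force).

    Only the relative order of the strings in S_k(x) ∪ S_k(y) matters, so
    uniform priorities over the union realize a fully random order exactly;
    the collision indicator then has expectation J(x, y), the subsequence
    Jaccard index (the MinHash property).  Feasible only for small inputs.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    def collide(x: str, y: str) -> bool:
        sx = subsequence_set(x, k)
        sy = subsequence_set(y, k)
        union = sorted(sx | sy)
        if not union:
            return False
        pri = rng.random(len(union))
        winner = union[int(np.argmin(pri))]
        return winner in sx and winner in sy

    return collide


def lexicographic_min_subsequence(x: str, k: int) -> str:
    """Greedy smallest length-k subsequence in lexicographic order."""
    check_dna(x, "string")
    n = len(x)
    if n < k:
        raise ValueError(f"string length {n} < k = {k}")
    out = []
    start = 0
    for r in range(k):
        # leftmost occurrence of the smallest char that leaves k-r-1 behind
        window = x[start : n - (k - r - 1)]
        c = min(window)
        start += window.index(c) + 1
        out.append(c)
    return "".join(out)


# ---------------------------------------------------------------------------
# seed-match truth and coverage


def classify_match(m: SeedMatch, gt: GroundTruthAlignment) -> bool:
    """TRUE iff at least 50% of the k aligned pairs are in the ground truth.

    Implemented literally as 2 * |aligned ∩ gt| >= k, so for odd k a
    strict majority is required (5 of 9 qualifies).
    """
    gt_pairs = set(gt.pairs)
    k = len(m.aligned_pairs)
    good = sum(1 for p in m.aligned_pairs if p in gt_pairs)
    return 2 * good >= k


def label_matches(
    matches: Iterable[SeedMatch], gt: GroundTruthAlignment
) -> list[SeedMatch]:
    """Return matches with their true/false labels filled in."""
    from dataclasses import replace

    return [
        replace(m, label="true" if classify_match(m, gt) else "false")
        for m in matches
    ]


@dataclass(frozen=True)
class CoverageResult:
    """True/false seed-match coverage, in percent of characters."""

    true_coverage: float
    false_coverage: float
    scope: str  # "both" or "read_only"
    n_matches: int = 0
    n_true: int = 0


def coverage(
    matches: Iterable[SeedMatch],
    lengths: tuple[int, int],
    scope: str = "both",
) -> CoverageResult:
    """Percentage of characters covered by >= 1 true (resp. false) match.

    A character is covered by a match if it is one of the match's k
    aligned characters.  ``scope="both"`` counts characters of both
    sequences; ``scope="read_only"`` counts only the second (read) side.
    Matches must already be labeled (see :func:`label_matches`).
    """
    if scope not in ("both", "read_only"):
        raise ValueError("scope must be 'both' or 'read_only'")
    len_x, len_y = lengths
    cov = {
        "true": (np.zeros(len_x, bool), np.zeros(len_y, bool)),
        "false": (np.zeros(len_x, bool), np.zeros(len_y, bool)),
    }
    n_matches = n_true = 0
    for m in matches:
        if m.label not in cov:
            raise ValueError("matches must be labeled true/false first")
        n_matches += 1
        n_true += m.label == "true"
        cx, cy = cov[m.label]
        for i, j in m.aligned_pairs:
            cx[i] = True
            cy[j] = True
    def pct(arrs):
        if scope == "read_only":
            total = len_y
            covered = int(arrs[1].sum())
        else:
            total = len_x + len_y
            covered = int(arrs[0].sum()) + int(arrs[1].sum())
        return 100.0 * covered / total if total else 0.0

    return CoverageResult(
        true_coverage=pct(cov["true"]),
        false_coverage=pct(cov["false"]),
        scope=scope,
        n_matches=n_matches,
        n_true=n_true,
    )


# ---------------------------------------------------------------------------
# overlap detection


@dataclass(frozen=True)
class OverlapResult:
    candidates: frozenset[tuple[int, int]]
    sensitivity: float | None
    precision: float | None


def overlap_detect(
    seed_lists: Sequence[Iterable],
    truth_pairs: set[tuple[int, int]],
) -> OverlapResult:
    """Candidate overlaps = read pairs sharing >= 1 seed-match.

    ``seed_lists[i]`` are the seeds of read i; a pair (i, j), i < j, is a
    candidate if the two reads share a seed string within any repeat index
    (union over repeats).  Sensitivity is the fraction of ground-truth
    pairs recovered; precision the fraction of candidates that are true.
    Empty truth (or no candidates) yields None for the undefined metric.
    """
    buckets: dict[tuple[int, str], set[int]] = {}
    for idx, hits in enumerate(seed_lists):
        for h in hits:
            buckets.setdefault((h.repeat_index, h.subseq), set()).add(idx)
    candidates: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        mem = sorted(members)
        for a in range(len(mem)):
            for b in range(a + 1, len(mem)):
                candidates.add((mem[a], mem[b]))
    correct = len(candidates & truth_pairs)
    sensitivity = correct / len(truth_pairs) if truth_pairs else None
    precision = correct / len(candidates) if candidates else None
    return OverlapResult(
        candidates=frozenset(candidates),
        sensitivity=sensitivity,
        precision=precision,
    )
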