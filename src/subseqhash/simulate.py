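"""Synthetic data generators for all seeding experiments.

Three mutation models are provided, matching the three evaluation designs:

* :func:`evolve_chain` — sequential evolutionary events on one string,
  each event a substitution, deletion, or insertion with probability 1/3,
  with every original position mutated at most once; the intermediate
  strings give pairs spanning a range of true edit distances (used for the
  hash-collision curves).
* :func:`mutate_pair` — an independent per-position error channel with
  rate r, the edit type uniform over substitution / insertion / deletion,
  recording the construction's ground-truth alignment (used for the
  pairwise-alignment coverage benchmark).
* :func:`simulate_reads` — reads sampled uniformly from a random genome
  and pushed through the same error channel, with true source intervals
  kept for overlap-detection ground truth.

Every generator is deterministic in its seed; all draws flow from a single
numpy Generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import ALPHABET


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class GroundTruthAlignment:
    """Monotone set of aligned position pairs between two sequences.

    ``pairs`` is a list of (i, j): position i of x aligned to position j of
    y.  Substituted positions appear as pairs (the characters need not be
    equal); inserted/deleted characters are absent.  Both coordinates are
    0-based and strictly increasing.
    """

    pairs: tuple[tuple[int, int], ...]

    def as_map(self, len_x: int) -> np.ndarray:
        """Array m with m[i] = j for aligned (i, j) and -1 elsewhere."""
        m = np.full(len_x, -1, dtype=np.int64)
        for i, j in self.pairs:
            m[i] = j
        return m


@dataclass(frozen=True)
class MutationChain:
    """A root string with an ordered event list and per-event snapshots.

    ``snapshots[e]`` is the string after the first e+1 events;
    ``edit_distances[e]`` is the TRUE edit distance between the root and
    that snapshot (which can be smaller than e+1: later events may cancel
    earlier ones in the optimal alignment).
    """

    x: str
    events: tuple[tuple[str, int, str], ...]  # (type, locus, payload)
    snapshots: tuple[str, ...]
    edit_distances: tuple[int, ...]


def random_sequence(L: int, seed) -> str:
    """An i.i.d. uniform ACGT string of length L."""
    if L < 0:
        raise ValueError("length must be non-negative")
    rng = _rng(seed)
    return "".join(ALPHABET[c] for c in rng.integers(0, 4, L))


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in ALPHABET if b != base]
    return choices[int(rng.integers(0, 3))]


def evolve_chain(x: str, seed) -> MutationChain:
    """Apply len(x) sequential events to x, snapshotting after each one.

    Event types are substitution / deletion / insertion with probability
    1/3 each.  Each original position is mutated at most once; an insertion
    occupies one of the len(x)+1 inter-position slots of the ORIGINAL
    string (chosen uniformly among unused slots), and inserted characters
    are themselves immutable.  When a type has no remaining legal site the
    event type is redrawn among the feasible ones.
    """
    from .evaluate import edit_distance

    n = len(x)
    if n < 1:
        raise ValueError("root string must be non-empty")
    rng = _rng(seed)
    # token list: original positions interleaved with insertion slots.
    # slot s sits before original position s; tokens ordered slot0, x0,
    # slot1, x1, ..., slotn.
    chars: dict[tuple[int, str], str] = {(i, "pos"): x[i] for i in range(n)}
    mutated = [False] * n  # original positions already touched
    deleted = [False] * n
    slot_used = [False] * (n + 1)
    slot_char: dict[int, str] = {}
    events = []
    snapshots = []
    dists = []
    for _ in range(n):
        live = [i for i in range(n) if not mutated[i]]
        free_slots = [s for s in range(n + 1) if not slot_used[s]]
        while True:
            kind = ("sub", "del", "ins")[int(rng.integers(0, 3))]
            if kind in ("sub", "del") and live:
                break
            if kind == "ins" and free_slots:
                break
        if kind == "sub":
            i = live[int(rng.integers(0, len(live)))]
            new = _other_base(rng, chars[(i, "pos")])
            chars[(i, "pos")] = new
            mutated[i] = True
            events.append(("sub", i, new))
        elif kind == "del":
            i = live[int(rng.integers(0, len(live)))]
            deleted[i] = True
            mutated[i] = True
            events.append(("del", i, ""))
        else:
            s = free_slots[int(rng.integers(0, len(free_slots)))]
            base = ALPHABET[int(rng.integers(0, 4))]
            slot_used[s] = True
            slot_char[s] = base
            events.append(("ins", s, base))
        parts = []
        for i in range(n + 1):
            if i in slot_char:
                parts.append(slot_char[i])
            if i < n and not deleted[i]:
                parts.append(chars[(i, "pos")])
        y = "".join(parts)
        snapshots.append(y)
        dists.append(edit_distance(x, y))
    return MutationChain(
        x=x,
        events=tuple(events),
        snapshots=tuple(snapshots),
        edit_distances=tuple(dists),
    )


def mutate_pair(x: str, r: float, seed) -> tuple[str, GroundTruthAlignment]:
    """Push x through a per-position error channel of rate r.

    Each position independently receives an edit with probability r, the
    edit type uniform over substitution, insertion, and deletion.  An
    insertion places one uniform base BEFORE the position (which itself
    stays aligned); a substitution draws uniformly from the three other
    bases and stays aligned; a deletion drops the position.  The recorded
    alignment is exactly the construction's.
    """
    if not 0 <= r <= 1:
        raise ValueError("error rate must be in [0, 1]")
    rng = _rng(seed)
    L = len(x)
    edited = rng.random(L) < r
    kinds = rng.integers(0, 3, L)  # 0 sub, 1 ins, 2 del; only used where edited
    out = []
    pairs = []
    for i, ch in enumerate(x):
        if not edited[i]:
            pairs.append((i, len(out)))
            out.append(ch)
            continue
        kind = kinds[i]
        if kind == 0:
            pairs.append((i, len(out)))
            out.append(_other_base(rng, ch))
        elif kind == 1:
            out.append(ALPHABET[int(rng.integers(0, 4))])
            pairs.append((i, len(out)))
            out.append(ch)
        # kind == 2: deletion, position dropped
    return "".join(out), GroundTruthAlignment(pairs=tuple(pairs))


@dataclass(frozen=True)
class SimulatedReads:
    """Reads with their true source intervals on a synthetic genome."""

    genome: str
    reads: tuple[str, ...]
    read_ids: tuple[str, ...]
    intervals: tuple[tuple[int, int], ...]  # 0-based half-open on the genome
    alignments: tuple[GroundTruthAlignment, ...]  # genome-interval -> read

    def true_overlap_pairs(self, min_overlap: int = 15) -> set[tuple[int, int]]:
        """Read-index pairs whose source intervals overlap enough."""
        truth = set()
        m = len(self.reads)
        for a in range(m):
            sa, ea = self.intervals[a]
            for b in range(a + 1, m):
                sb, eb = self.intervals[b]
                if min(ea, eb) - max(sa, sb) >= min_overlap:
                    truth.add((a, b))
        return truth


def simulate_reads(
    genome_length: int,
    n_reads: int,
    read_length: int,
    error_rate: float,
    seed,
    genome: str | None = None,
) -> SimulatedReads:
    """Sample error-prone reads with known source intervals.

    Reads are drawn uniformly from a random genome (or a supplied one) and
    pushed through the :func:`mutate_pair` channel, so read lengths vary
    around ``read_length`` with indels.
    """
    if read_length < 1 or genome_length < read_length:
        raise ValueError("need 1 <= read_length <= genome_length")
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    rng = _rng(seed)
    if genome is None:
        genome = random_sequence(genome_length, rng)
    elif len(genome) != genome_length:
        raise ValueError("supplied genome does not match genome_length")
    reads, ids, intervals, aligns = [], [], [], []
    for i in range(n_reads):
        start = int(rng.integers(0, genome_length - read_length + 1))
        template = genome[start : start + read_length]
        read, gt = mutate_pair(template, error_rate, rng)
        reads.append(read)
        ids.append(f"read{i}")
        intervals.append((start, start + read_length))
        aligns.append(gt)
    return SimulatedReads(
        genome=genome,
        reads=tuple(reads),
        read_ids=tuple(ids),
        intervals=tuple(intervals),
        alignments=tuple(aligns),
    )


def collision_pairs(
    n: int, chains: int, seed, max_distance: int = 10
) -> dict[int, list[tuple[str, str]]]:
    """Pairs of strings binned by true edit distance, via mutation chains.

    Runs ``chains`` chains from fresh random roots of length n and bins
    every (root, snapshot) pair with edit distance in 1..max_distance.
    """
    rng = _rng(seed)
    bins: dict[int, list[tuple[str, str]]] = {e: [] for e in range(1, max_distance + 1)}
    for _ in range(chains):
        x = random_sequence(n, rng)
        chain = evolve_chain(x, rng)
        for y, e in zip(chain.snapshots, chain.edit_distances):
            if 1 <= e <= max_distance:
                bins[e].append((x, y))
    return bins
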