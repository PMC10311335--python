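# subseqhash

Subsequence-based seeding for noisy DNA sequence comparison.

Seed-and-extend methods (read mapping, pairwise alignment, overlap
detection for assembly) reduce each sequence to short fixed-length seeds
and work only with seed-matches — identical seeds found in two
sequences. Classic k-mer seeds need k consecutive error-free characters,
which makes them fragile on long reads with 5–20% error: a single indel
kills every k-mer that spans it. This package seeds with *subsequences*
instead: each length-n window is mapped to its minimal length-k
subsequence

    h_π(x) = argmin_{z ∈ S_k(x)} π(z),

under a total order π over Σ^k. Because a subsequence may skip error
positions, similar windows retain a high probability of yielding the
same seed; for a fully random π that probability is exactly the Jaccard
index of the two windows' subsequence sets (the MinHash property).

A fully random order makes h_π intractable, so the package implements
the **ABC order**: a pseudo-random order given by a score
π(z) = (ψ(z), ω(z)) accumulated through random tables A (integer
magnitudes in [2³⁰, 2³¹)), B (sign-pair bijections), and C (residues
mod d), ordered by ψ ascending, then |ω| descending. Under an ABC order
the minimal subsequence of a length-n window is computed exactly by a
dynamic program in O(nkd) time, and t independent repeats (fresh tables)
lift the per-window collision probability p to 1 − (1−p)^t.

The package also ships the substring baselines (random-order minimizers,
all-kmers), exact distinct-subsequence counting, synthetic data
generators with ground-truth alignments, and the full evaluation stack:
collision-probability curves, order randomness (AMNED), true/false
seed-match classification and coverage, and overlap detection.

## Worked example

```python
>>> from subseqhash import (count_distinct_subsequences,
...     count_common_distinct_subsequences, jaccard_subsequences,
...     jaccard_substrings, edit_distance)
>>> s, t = "ACGCCTA", "ACGGCTA"      # one substitution apart
>>> edit_distance(s, t)
1
>>> count_distinct_subsequences(s, 4), count_distinct_subsequences(t, 4)
(21, 24)
>>> count_common_distinct_subsequences(s, t, 4)
14
>>> round(jaccard_subsequences(s, t, 4), 4)   # 14 / (21 + 24 - 14)
0.4516
>>> jaccard_substrings(s, t, 4)               # no shared 4-mer at all
0.0
```

One substitution removes every shared 4-mer, yet 14 of the 21 distinct
length-4 subsequences of `s` survive in `t`: a seed drawn as a minimal
subsequence under a random order collides with probability ≈ 0.45 where
any substring seed gives exactly 0.

Seeding and matching:

```python
from subseqhash import SeedingConfig, seed_sequence, match_seeds, mutate_pair
from subseqhash.simulate import random_sequence

x = random_sequence(2000, seed=1)
y, truth = mutate_pair(x, 0.10, seed=2)       # 10% error channel
cfg = SeedingConfig(method="subseqhash", n=30, k=24, d=11, t=10, base_seed=3)
matches = match_seeds(seed_sequence(x, cfg, sequence_id="x"),
                      seed_sequence(y, cfg, sequence_id="y"))
```

The `examples/` directory holds one short script per capability
(minimal-subsequence DP vs enumeration, Jaccard counts, collision
curves, the coverage benchmark, overlap detection); each prints its
numbers with a note on what they mean. A thin CLI mirrors the library
(`subseqhash seed|jaccard|collide|amned|eval-matches|overlap|tables`).

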