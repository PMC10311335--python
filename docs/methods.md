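# Methods

## The problem

Seed-and-extend pipelines turn each sequence into short fixed-length
seeds and compare sequences only through seed-matches (identical seeds at
known positions, also called anchors). Substring seeds (k-mers) need k
consecutive error-free characters, so their match probability collapses
on long-read data with 5–20% error. This package implements subsequence
seeding: each length-n window is mapped to its minimal length-k
*subsequence* under a pseudo-random total order over Σ^k. A subsequence
can step over errors at arbitrary positions, so similar windows keep a
usable probability of producing the same seed.

Two facts drive the design. If edit(x, y) = e₁ for two length-n strings,
a common subsequence of length k ≤ n − e₁ always exists, so the collision
probability is strictly positive for similar windows; and if
k > n − e₂/2 no common length-k subsequence can exist, which keeps
dissimilar windows apart. With a *fully random* order the collision
probability equals the Jaccard index of the two subsequence sets (the
MinHash argument), but finding the minimum under a fully random order
requires enumerating exponentially many subsequences. The ABC order is a
structured compromise: random enough to behave almost like a fully random
order, structured enough that the minimum is computable in O(nkd) time.

## The ABC order

The order is defined by a score π(z) = (ψ(z), ω(z)) accumulated left to
right over z = z₁…z_k (ψ₀ = ω₀ = 0):

    ψ_i = (ψ_{i-1} + C[i][z_i]) mod d
    ω_i = ω_{i-1} · B[i][ψ_i][z_i]₁ + A[i][ψ_i][z_i] · B[i][ψ_i][z_i]₂

with three random tables: A[i][j][σ] are integer magnitudes uniform in
[2³⁰, 2³¹); B[i][j][·] is, for each (i, j), a uniformly drawn bijection of
the four symbols onto the four sign pairs {±1}²; C[i][σ] are residues in
{0..d−1}, drawn without replacement across the four symbols when d ≥ 4.
Strings are ordered by ψ ascending, then |ω| DEscending, then (for the
astronomically rare exact tie) lexicographically. A holds *integers* and
ω is accumulated in exact 64-bit integer arithmetic (|ω| ≤ k·2³¹), so
scores are platform-independent and ties are well defined rather than
float artifacts.

Parameters: `k` seed length; `d` the ψ modulus, default 11 — with d ≥ 4
the per-position C column is injective, so any single substitution
provably changes ψ (for d ∈ {2, 3} C is drawn with replacement and the
implementation makes no such guarantee; the test suite asserts the
property only for d ≥ 4). Larger d raises the collision probability
toward the fully-random ceiling at O(d) cost; d = 11 is the default
operating point, d = 1 a cheap low-sensitivity fallback. `t` repeats run
the whole seeder with freshly drawn tables; seeds only match within a
repeat, giving the 1 − (1−p)^t boost.

## The dynamic program

`min_subsequence` fills Tmin[l][i][j] / Tmax[l][i][j] — the min/max of ω
over length-i subsequences of x₁..x_l with ψ = j. Both extremes are
needed because a −1 first sign component swaps them, and the final answer
takes the larger |ω|. Cells realized by no subsequence hold an explicit
integer sentinel (±2⁶², far above any real |ω| ≤ k·2³¹), never a float
NaN: min/max arithmetic then handles undefined operands without branches,
and definedness is recovered exactly by a |value| ≥ 2⁶⁰ test. The final
answer takes ψ_opt = the smallest residue with a defined cell and
ω_opt = the extreme of larger absolute value there.

Tie rules the reference enumeration reproduces exactly:

* |Tmin| = |Tmax| at ψ_opt → the positive (Tmax) branch wins;
* during traceback, when skipping x_l preserves the optimum, skip — for
  position sets extracting the same string this reports the leftmost
  embedding, i.e. the lexicographically smallest position tuple. (Which
  optimal position set is reported is otherwise arbitrary; pinning it
  makes seed positions, and hence downstream coverage numbers,
  reproducible across implementations.)

The full (n+1)×(k+1)×d pair of tables is kept for traceback (no rolling
arrays); the window scanner reuses one allocation since every feasible
cell is rewritten per window. Kernels are numba-compiled; the brute-force
enumerator (`brute_force_min_subsequence`) is retained as the independent
oracle and is cross-checked on hundreds of random instances per test run.

## Counting subsequence sets

Distinct-subsequence and distinct-common-subsequence counts walk the
(product) subsequence automaton, where each distinct string corresponds
to exactly one leftmost-embedding path; path counting therefore needs no
inclusion–exclusion and costs O(|x|·k·|Σ|), resp. O(|x|·|y|·k·|Σ|).
Counts are Python integers (they grow combinatorially). Both routines
are validated against explicit enumeration of all position subsets on
small strings.

## Seeding conventions

* Windows slide with stride 1; a window containing a non-ACGT character
  is skipped (logged once per sequence in the CLI path).
* Dedup: two extractions are the same seed iff (repeat index, string,
  absolute position tuple) coincide — identical picks from overlapping
  windows collapse, mirroring the minimizer convention of counting
  distinct selected occurrences, so density = seeds/length stays below 1
  and is comparable across methods.
* Matching: seeds match only within the same repeat index. Each repeat
  is its own hash function; cross-repeat string equality is not a
  collision of that function, and the 1−(1−p)^t analysis relies on the
  per-repeat union.
* The minimizer's "fully random order" is a keyed splitmix64 hash of the
  2-bit-packed k-mer (ties broken leftmost); all-kmers takes every
  window of length k.

## Synthetic data

Three generators emulate the benchmark conditions; none models
platform-specific error profiles (homopolymer artifacts, chimeras,
quality structure), so passing tests demonstrate algorithmic behavior
under uniform errors, not performance on any particular instrument.

* **Mutation chains** (collision curves): n sequential events on a
  length-n string, each sub/del/ins with probability 1/3; each original
  position mutates at most once, insertions occupy one of the n+1
  original inter-position slots (uniform among unused ones) and are
  immutable. Pairs (root, i-th snapshot) are binned by *true* edit
  distance, which can be below i. Where no legal site remains for a
  drawn event type, the type is redrawn among feasible ones.
* **Error channel** (alignment benchmark): every position independently
  edited with probability r; the edit is uniformly a substitution (to
  one of the 3 other bases), a deletion, or an insertion of a uniform
  base placed *before* the position (the position itself stays aligned).
  The construction's alignment — surviving and substituted positions —
  is the ground truth.
* **Reads**: substrings of length `read_length` drawn uniformly from a
  random genome and passed through the error channel; true source
  intervals define overlap ground truth (interval overlap ≥ 15 bp by
  default).

## Metrics

* **AMNED**: for an order's top-m strings, the mean over ranks of the
  minimum edit distance to the 2w ranked neighbors; exactly 1.0 for the
  lexicographic order, higher for more random orders. At the boundary
  (i ≤ w or i > m−w) the window truncates to the available neighbors;
  with m ≫ w the choice is immaterial.
* **Seed-match truth**: a match is true iff at least 50% of its k
  induced character alignments lie in the ground truth — implemented
  literally as 2·|overlap| ≥ k, so odd k needs the strict majority
  (5 of 9 qualifies).
* **Coverage**: percentage of characters under ≥ 1 true (false) match;
  over both sequences for the alignment benchmark, over the read only in
  mapping-style scoring.
* **Collision curves**: empirical frequency per edit-distance bin 1..10;
  empty bins are reported missing, never as zero, to avoid biasing curve
  averages.
* **Overlap detection**: candidates = read pairs sharing ≥ 1 seed-match
  (union over repeats, hence monotone in t); sensitivity and precision
  against the interval ground truth.

## Benchmark scales

The shipped benchmark (`scripts/acceptance.py`, and the corresponding
end-to-end test) runs the 5%-error alignment benchmark on 5 simulated
pairs of length 10 000 — the package's chosen desk scale; coverage
percentages are averages over characters, so they are insensitive to
sequence length well before this size. The subsequence-seed grid uses
window n = 30 with k = 18..29, d = 11, t = 10; the substring grid uses
minimizers with n ∈ {20, 25, 30, 35}, k = 8..n−1, plus all-kmers with
k = 9..25. The headline number is the best true coverage among settings
with false coverage < 5%.

The repeat-law check conditions on a fixed pair of strings (collisions
across independent table draws are then i.i.d. Bernoulli(p)); pooling
heterogeneous pairs would bias the empirical union probability below
1−(1−p̄)^t by Jensen's inequality, so a pooled test would reject the law
even when it holds pair by pair.

## Known limitations

* DNA only (|Σ| = 4); no protein alphabet.
* No chaining, extension, or alignment downstream of seed-matches; the
  package evaluates seeding itself.
* No strobemers/syncmers/spaced seeds; the substring baselines are
  minimizers and all-kmers.
* The O(nkd) scan is orders of magnitude slower than minimizer seeding;
  no A*, SIMD, or multi-threaded acceleration is attempted.
* Exact (ψ, |ω|) ties between *different* strings are broken
  lexicographically in scoring; the DP, which sees only values, may
  report either string's positions in that astronomically unlikely case.
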