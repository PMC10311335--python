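"""Why subsequences beat substrings for similar-but-noisy strings.

Two strings one substitution apart share no 4-mers at all, yet two thirds
of the first string's 21 distinct length-4 subsequences also occur in the
second — the motivation for subsequence seeds.
"""

from subseqhash import (
    count_common_distinct_subsequences,
    count_distinct_subsequences,
    edit_distance,
    jaccard_subsequences,
    jaccard_substrings,
)

s, t = "ACGCCTA", "ACGGCTA"
print(f"s = {s}, t = {t}, edit distance = {edit_distance(s, t)}")
print(f"|S4(s)|            = {count_distinct_subsequences(s, 4)}")
print(f"|S4(t)|            = {count_distinct_subsequences(t, 4)}")
print(f"|S4(s) ∩ S4(t)|    = {count_common_distinct_subsequences(s, t, 4)}")
print(f"subsequence Jaccard = {jaccard_subsequences(s, t, 4):.4f}")
print(f"substring Jaccard   = {jaccard_substrings(s, t, 4):.4f}")
# With a fully random order over length-4 strings, MinHash theory says the
# probability that both strings hash to the same minimal subsequence
# equals the subsequence Jaccard index (~0.45) — versus 0 for any
# substring-based seed of the same length.
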