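"""Find the minimal length-k subsequence of a string under an ABC order.

Builds one random ABC order (k=8, d=11), runs the O(nkd) dynamic program
on a short sequence, and verifies it against exhaustive enumeration of
all C(n, k) subsequences.
"""

from subseqhash import brute_force_min_subsequence, generate_tables, min_subsequence
from subseqhash.simulate import random_sequence

tables = generate_tables(k=8, d=11, seed=42)
x = random_sequence(24, seed=7)

hit = min_subsequence(x, tables)
oracle = brute_force_min_subsequence(x, tables)

print(f"sequence        : {x}")
print(f"minimal subseq  : {hit.subseq}")
print(f"positions       : {hit.positions}")
print(f"score           : psi={hit.score.psi} omega={hit.score.omega}")
print(f"oracle agrees   : {oracle.subseq == hit.subseq and oracle.positions == hit.positions}")
# The seed is the smallest of the 735471 length-8 subsequences of x under
# this order: psi is the primary key (ascending), |omega| the secondary
# (descending).  The DP finds it in O(n*k*d) instead of enumerating.
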