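"""The Chang–Marr q-gram distance index, built with one fixed-length search.

D[r] holds the smallest distance between the q-gram of rank r and any
factor of the pattern.  A de Bruijn sequence contains every q-gram exactly
once, so using it as the search pattern visits all of them in one
bit-parallel pass; the naive build checks every (q-gram, factor) pair.
"""

import numpy as np

from flasm import build_index, build_index_naive, debruijn_sequence, random_dna

print("B(3, {a,b}) =", debruijn_sequence(3, "ab"))

x = random_dna(32, seed=11)
q = 4
idx = build_index(x, q, "ACGT", model="hamming")
naive = build_index_naive(x, q, "ACGT", model="hamming")
print(f"pattern: {x}")
print(f"index entries: {idx.distances.size} (= 4^{q}),",
      "agrees with naive build:", bool(np.array_equal(idx.distances, naive.distances)))
values, counts = np.unique(idx.distances, return_counts=True)
print("distance histogram (value: #q-grams):",
      {int(v): int(c) for v, c in zip(values, counts)})
print("exact factor", x[:q], "-> D =", idx.lookup(x[:q]))
print("its reverse ", x[:q][::-1], "-> D =", idx.lookup(x[:q][::-1]))
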