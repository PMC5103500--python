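"""Approximate circular matching: all rotations of a pattern in one search.

Doubling the pattern (x + x[:-1]) makes every rotation a length-m factor,
so a single fixed-length search covers all of them regardless of the
distance threshold.
"""

from flasm import acsm, double_pattern, rotation_index

text, pattern = "CCGATGAACC", "AAGATG"
m = len(pattern)

print("doubled pattern:", double_pattern(pattern))
print("rotations:", ", ".join(pattern[r:] + pattern[:r] for r in range(m)))

for j, i, e in sorted(acsm(text, pattern, max_distance=1, model="hamming")):
    r = rotation_index(i, m)
    rot = pattern[r:] + pattern[:r]
    print(f"rotation {r} ({rot}) matches text[{j - m + 1}..{j}]="
          f"{text[j - m + 1:j + 1]} at distance {e}")
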