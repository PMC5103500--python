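"""Fixed-length search: factors of a text near any factor of a pattern.

The pattern AAGATG has four factors of length 3 (AAG, AGA, GAT, ATG).  At
k=0 only AAG and ATG occur in the text exactly; allowing one mismatch also
pairs AGA with the text factor AGT.
"""

from flasm import flasm_edit, flasm_hamming

text, pattern = "ATGGCAAGT", "AAGATG"

for k in (0, 1):
    matches = sorted(flasm_hamming(text, pattern, factor_length=3, max_distance=k))
    print(f"Hamming, k={k}:")
    for j, i, e in matches:
        print(f"  text[{j - 2}..{j}]={text[j - 2:j + 1]}  ~  "
              f"pattern[{i - 2}..{i}]={pattern[i - 2:i + 1]}  distance {e}")

# under the edit model a match may also shrink or stretch the text window;
# the reported distance is the minimum over windows ending at each position
best = flasm_edit(text, pattern, factor_length=4, max_distance=2, mode="best")
print("edit model, best length-4 match (j, i, e):", sorted(best)[0])
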