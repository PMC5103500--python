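# flasm

Fixed-length approximate string matching (FLASM) for biological sequences,
with the applications that make it useful in practice: approximate circular
string matching, the Chang–Marr q-gram distance index, single and structured
motif extraction with quorum, and refinement of circular-sequence rotations
prior to multiple alignment.

## The problem

Classic approximate string matching finds all factors (substrings) of a text
*t* within distance *k* of a pattern *x*.  FLASM generalises it: given a text
*t* of length *n*, a pattern *x* of length *m*, a factor length *ℓ* ≤ *m* and
a threshold *k* < *ℓ*, report every factor of *t* within distance *k* of
**any** length-*ℓ* factor of *x*, under the Hamming or the edit distance
model.  Results are sets of tuples ⟨*j*, *i*, *e*⟩ — the 0-based ending
position of the match in *t*, the ending position of the matched factor in
*x*, and the distance.

Both cores are multi-word bit-vector dynamic programmes running in time
O(*m*⌈*ℓ*/*w*⌉*n*) and space O(*m*⌈*ℓ*/*w*⌉), where *w* is the machine word
size — independent of the threshold *k* and of the alphabet, and valid for
factor lengths far beyond one machine word:

- **Hamming core** — one streamed DP column of *ℓ*-bit mismatch vectors
  M[i][j] = shl(M[i−1][j−1]) | (x[i−1] ≠ t[j−1]); once both indices pass
  *ℓ*, popcount(M[i][j]) *is* the Hamming distance of the two windows.
- **Edit core** — a bit-parallel edit-distance matcher (positive/negative
  vertical-delta vectors with a carry-propagating add) run for every
  length-*ℓ* factor of the pattern simultaneously, first DP row pinned to
  zero, so each reported *e* is the minimum over text windows ending at *j*.

Why it matters downstream: circular genomes (plasmids, mitochondria,
viruses) are linearised at arbitrary cut points, so rotation-aware matching
and rotation refinement need factor search that is cheap at high error
ratios; motif discovery for long conserved regions needs *ℓ* > 64; and the
q-gram filtration index needs the minimum distance from every possible
q-gram to a pattern.

## A worked example

```python
>>> from flasm import flasm_hamming
>>> sorted(flasm_hamming("ATGGCAAGT", "AAGATG", factor_length=3, max_distance=0))
[MatchTuple(text_end=2, pattern_end=5, distance=0),
 MatchTuple(text_end=7, pattern_end=2, distance=0)]
```

The pattern's length-3 factors are AAG, AGA, GAT, ATG; only ATG (ending at
text position 2) and AAG (ending at 7) occur exactly.  Raising the threshold
to 1 additionally pairs pattern factor AGA with text factor AGT:

```python
>>> sorted(flasm_hamming("ATGGCAAGT", "AAGATG", 3, 1))[-1]
MatchTuple(text_end=8, pattern_end=3, distance=1)
```

The `examples/` directory holds one short script per capability
(`python examples/01_fixed_length_search.py` and so on): fixed-length
search, circular matching, the q-gram index, motif discovery, and rotation
refinement.  Each prints the numbers it computes and a line on what they
mean.

The same surface is available from a shell:

```
flasm search -t ATGGCAAGT -x AAGATG -l 3 -k 1
flasm acsm -t CCGATGAACC -x AAGATG -k 0
flasm motif-structured input.fa -s '(80,15)[5,15](60,10)[5,20](230,20)' -Q 25
flasm rotate circular.fa refined.fa -l 100 -k 25 --model edit
```

Subcommands `index` and `synth` build the q-gram index and seeded synthetic
datasets; all outputs are TSV/FASTA with a metadata header sufficient to
re-run the command.

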