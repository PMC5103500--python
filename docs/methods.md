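# Methods

## The matching model

Fixed-length approximate string matching takes a text *t* (length *n*), a
pattern *x* (length *m*), a factor length *ℓ* ≤ *m* and a threshold
0 ≤ *k* < *ℓ*, and reports tuples ⟨*j*, *i*, *e*⟩ with at most one tuple per
(*j*, *i*) pair, carrying the minimal distance:

- **Hamming model.**  *e* is the Hamming distance between the length-*ℓ*
  windows of *t* and *x* ending at *j* and *i*; both *j* and *i* range over
  [*ℓ*−1, …] so windows lie fully inside the strings.
- **Edit model.**  For each pattern factor ending at *i* and each text
  position *j* ∈ [0, *n*−1], *e* is the minimum over start positions
  *s* ≤ *j* of the unit-cost edit distance between *t*[*s*..*j*] and the
  factor.  This semi-global, ending-position semantics is a deliberate
  choice: enumerating all (start, end) window pairs would blow up the
  output, and an ending position plus a minimal distance is exactly what
  the three-field tuple can carry.  Positions *j* earlier than *ℓ*−1 are
  reported whenever deletions bring a window within range.

`mode="best"` returns the single tuple minimising (*e*, *j*, *i*)
lexicographically — deterministic, and sufficient for rotation refinement.
`k = 0` (exact matching) is accepted as a well-defined degenerate case used
by the applications.

Sequences are uppercased on ingest; every symbol (including N and gap
characters) is an ordinary letter matching only itself.  The pattern may be
longer than the text: circular matching doubles the pattern, which
routinely makes it longer than the text it is searched in, and nothing in
the dynamic programmes requires *m* ≤ *n* (only *ℓ* ≤ *m* and *ℓ* ≤ *n*).

## Bit-vector engines

Both cores express DP state as *ℓ*-bit vectors stored little-endian across
arrays of 64-bit words (`flasm.bitrows`); all operations truncate to *ℓ*
bits and addition ripples carries across word boundaries, so *ℓ* is
unbounded.  The word size is an internal constant exposed read-only;
correctness never depends on it.

The Hamming engine keeps one column of *m*+1 cells.  Bit *p* of cell
M[i][j] records whether the alignment column *p* positions back mismatched;
the update is a truncating shift plus an OR of the current mismatch bit,
and a population count yields the window distance.  The column is a
(⌈*ℓ*/64⌉, *m*+1) array updated with a handful of vectorised word
operations per text symbol — O(*m*⌈*ℓ*/*w*⌉) space with the text streamed,
O(*m*⌈*ℓ*/*w*⌉*n*) time.  Window distances are collected into blocks of 32
text steps before thresholding to amortise bookkeeping.

The edit engine is the classic bit-parallel edit-distance scan (vertical
delta vectors Pv/Mv, diagonal-zero vector, horizontal deltas extracted at
the factor's last row) with the first DP row pinned to zero so the text
start is free.  All *m*−*ℓ*+1 factors are scanned simultaneously — state
arrays of shape (⌈*ℓ*/64⌉, #factors) — with the per-factor letter masks
built once per factor via windowed bit-packing.  The update order follows
the standard formulation and is validated end-to-end against a quadratic
DP oracle rather than trusted structurally.

Numerical/degenerate details: vectors whose top word is partial are masked
after every complement or add; parameter validation rejects empty strings,
*ℓ* ∉ [1, min(*m*, *n*)] and *k* ∉ [0, *ℓ*).

## Applications

**Circular matching.**  The doubled pattern *x*·*x*[0..*m*−2] has the *m*
rotations of *x* as its length-*m* factors; a tuple's rotation is
(*i* − *m* + 1) mod *m*.  Periodic patterns can report the same rotation
string under distinct *i*; all are retained by default, with dedup by
rotation string available as a reporting option.

**Q-gram index.**  The lexicographically least de Bruijn sequence
B(q, σ) (Lyndon-word concatenation, deterministic output) is linearised by
appending its first *q*−1 letters and searched with *ℓ* = *q*,
*k* = *q*−1 — the largest threshold the cores admit.  Ranks are base-σ
values, leftmost letter most significant, in alphabet order.  Entries never
reported are backfilled with *q*: under Hamming an unreported minimum is
exactly *q* (a length-*q* window is always within *q* substitutions); under
edit it is ≥ *q* and the cap loses nothing for consumers, which threshold
strictly below *q*.  The naive builder minimises over every (q-gram,
factor) pair directly and doubles as the index's independent cross-check.

**Motif extraction.**  Validity is *strict*: candidates are factors (or box
tuples) read off an input sequence with zero errors.  A sequence counts
toward the quorum when it holds at least one k-occurrence; a motif's own
sequence always counts (a factor 0-occurs in itself), since the quorum
counts sequences, not external witnesses.  Counting runs one fixed-length
search per sequence pair; under Hamming, window distances are symmetric, so
each unordered pair is scanned once and transposed.

For structured motifs the gap is measured as the number of spacer letters
strictly between boxes, *g* = start(next) − end(prev) − 1 ∈ [dmin, dmax].
"Distance from an ending position to a starting position" is ambiguous by
±1; the spacer-letter reading matches the biology (a non-conserved spacer
separating dimer contact points) and is stated here so users can shift
intervals if their convention differs.  Candidate box tuples must co-occur
exactly in one source sequence with compliant gaps — the strict-validity
assumption extended to the structured case.  Chains are verified by an
interval join over per-box occurrence lists sorted by start; under the edit
model an occurrence's start is the smallest start attaining the minimal
distance for its ending position, making the join well-defined.  A
necessary condition (every box of a candidate must individually k-occur in
at least `quorum` sequences) prunes the enumeration; it cannot remove true
positives because a chain in a sequence implies each box occurs there.

**Rotation refinement.**  For each ordered pair, a best-mode search of one
sequence against the doubled other yields rotation (*i* − *j*) mod
len(s_i) and distance; pairs whose shorter member cannot hold the factor
get an infinite-distance sentinel and merge last.  Single-linkage
agglomerative clustering (via scipy) on the symmetrised distances
min(e_ij, e_ji) fixes the merge order — single linkage because the matrix
stores exactly one best pair per sequence pair, which is the quantity the
linkage follows.  At each merge the cluster containing the smallest
original index anchors; every member of the joining cluster is rotated by
the minimal-distance cross-pair's rotation (rotations compose modulo each
sequence's length, which also defines behaviour for unequal lengths), so
the first sequence of the final cluster keeps rotation 0.

## Synthetic data

The generators are pure functions of (parameters, seed): uniform ACGT
backgrounds, uniform per-sequence rotations, and motif implantation.
Implantation writes one copy of a single canonical motif per target
sequence at a uniform position where boxes plus sampled gaps fit
(gap lengths uniform within their intervals, spacers left as background),
with an *exact*, stated number of substitutions per box copy —
substitution-only so ground-truth positions stay valid under both models.

The headline implantation experiment uses 50 sequences of 1,000 bp, one
⟨(80,15)[5,15](60,10)[5,20](230,20)⟩ copy in each of 25 sequences, quorum
25, Hamming model.  The per-box corruption is ⌊k_i/2⌋ substitutions: by the
triangle inequality any two copies then differ by at most k_i, so every
copy k_i-occurs in every implanted sequence and full recall is the designed
outcome — the standard planted-motif construction when the detection
threshold is fixed at k.  The test suite runs a proportionally reduced
instance (10 sequences × 600 bp, boxes at half length, quorum 10) and the
acceptance script the full-scale one.

What the generator does *not* emulate: composition bias, repeats,
insertions/deletions within motif copies, or positional preference of
binding sites.  Passing recovery tests therefore demonstrates algorithmic
correctness of extraction and counting, not discovery power on real
genomes, where motif significance (deliberately out of scope here) and
background structure dominate.

Rotation-recovery experiments use rotated copies of a common 500-bp
ancestor, clean (ℓ = 500, k = 0, exact frame restoration expected) and with
5% independent substitutions per copy (ℓ = 100, k = 25, edit model, ≥ 90%
of sequences expected back in a common frame over 20 replicates).  Problem
sizes across the suite (instance counts of the oracle sweeps, sequence
counts and lengths above) were chosen as the smallest at which the
behaviours of interest — word-boundary crossing, quorum pruning, clustered
rotation propagation — are all exercised.

## Known limitations

- The edit model reports ending positions and minimal distances only; no
  alignment traceback or affine gap costs.
- No average-case filtering speedups for circular matching; the point here
  is the k-independent bit-vector method.
- The downstream average-case-optimal search that would consume the q-gram
  index is not included — only the index itself.
- Rotation refinement stops at the refined sequences; multiple alignment,
  tree inference and their evaluation belong to external tools.
- Motif significance statistics are out of scope; recovery guarantees are
  recall-only (precision is data-dependent: near-threshold shifted windows
  of implanted copies can also reach quorum).
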