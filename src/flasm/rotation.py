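"""Refinement of circular sequence rotations before multiple alignment.

Circular genomes are linearised at arbitrary positions, so two homologous
sequences may start at different biological regions and align poorly.  The
refinement finds, for every ordered sequence pair, the best-matching
length-``ell`` factor pair (a fixed-length search of one sequence against
the doubled other), converts it into a candidate rotation, and then applies
rotations cluster-by-cluster following single-linkage agglomerative
clustering of the pairwise distances, so closely related sequences are
brought into a common frame first.  The output is a rotation of each input,
in input order, ready for any multiple-sequence-alignment tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .circular import double_pattern, rotate
from .core import FlasmError, Model, scan

#: distance recorded for pairs with no match within threshold
NO_MATCH = math.inf


def pair_best_rotation(s_i: str, s_j: str, factor_length: int,
                       max_distance: int, model: Model = "edit"
                       ) -> tuple[int, int] | None:
    """Best rotation of ``s_i`` aligning it with ``s_j``, with its distance.

    Runs a best-mode fixed-length search of ``s_j`` against the doubled
    ``s_i``; the winning tuple ``(j, i, e)`` marks a factor of some rotation
    of ``s_i`` matching at position ``j`` of ``s_j``, giving rotation
    ``(i - j) mod len(s_i)``.  Returns ``None`` when no factor pair is
    within ``max_distance``.
    """
    m = len(s_i)
    if factor_length > min(m, len(s_j)):
        raise FlasmError(f"factor length {factor_length} exceeds a sequence "
                         f"length ({min(m, len(s_j))})")
    j, i, e = scan(text=s_j.upper(), pattern=double_pattern(s_i.upper()),
                   factor_length=factor_length, max_distance=max_distance,
                   model=model)
    if j.size == 0:
        return None
    order = np.lexsort((i, j, e))
    b = order[0]
    return (int(i[b]) - int(j[b])) % m, int(e[b])


@dataclass
class RotationMatrix:
    """Pairwise best rotations and distances; the diagonal is unused."""

    n: int
    rotations: np.ndarray   # (n, n) int64
    distances: np.ndarray   # (n, n) float64, NO_MATCH where nothing matched


def build_matrix(seqs: list[str], factor_length: int, max_distance: int,
                 model: Model = "edit") -> RotationMatrix:
    """All ordered pairwise comparisons.

    Pairs whose shorter sequence cannot hold the factor get the no-match
    sentinel (distance infinity, rotation 0).
    """
    N = len(seqs)
    if N < 2:
        raise FlasmError(f"at least 2 sequences are required, got {N}")
    rotations = np.zeros((N, N), np.int64)
    distances = np.full((N, N), NO_MATCH, np.float64)
    np.fill_diagonal(distances, 0.0)
    for a in range(N):
        for b in range(N):
            if a == b or factor_length > min(len(seqs[a]), len(seqs[b])):
                continue
            best = pair_best_rotation(seqs[a], seqs[b], factor_length,
                                      max_distance, model)
            if best is not None:
                rotations[a, b], distances[a, b] = best
    return RotationMatrix(N, rotations, distances)


def refine(seqs: list[str], matrix: RotationMatrix,
           return_rotations: bool = False):
    """Rotate the inputs into a common frame.

    Single-linkage clustering on the symmetrised distances
    ``min(e_ij, e_ji)`` fixes the merge order; at each merge, the joining
    cluster is rotated as a block by the rotation of the minimal-distance
    cross-pair (rotations compose modulo each sequence's length).  The
    cluster holding the smallest original index anchors each merge, so the
    first sequence of the final cluster keeps rotation 0.  Unmatched pairs
    sit at infinity and merge last.  Output preserves input order; each
    output is a rotation of its input.
    """
    N = matrix.n
    if len(seqs) != N:
        raise FlasmError(f"matrix was built over {N} sequences, got {len(seqs)}")
    seqs = [s.upper() for s in seqs]
    sym = np.minimum(matrix.distances, matrix.distances.T)
    np.fill_diagonal(sym, 0.0)
    finite = sym[np.isfinite(sym)]
    big = (finite.max() if finite.size else 0.0) + 1.0
    cond = squareform(np.where(np.isfinite(sym), sym, big), checks=False)
    Z = linkage(cond, method="single")

    members: dict[int, list[int]] = {i: [i] for i in range(N)}
    offsets = [0] * N
    for t, row in enumerate(Z):
        ca, cb = int(row[0]), int(row[1])
        A, B = members.pop(ca), members.pop(cb)
        if min(A) > min(B):
            A, B = B, A   # A anchors
        # minimal-distance cross-pair under the symmetrised metric
        a_best, b_best = min(((a, b) for a in A for b in B),
                             key=lambda ab: (sym[ab[0], ab[1]], ab[0], ab[1]))
        # rotation taking the joining member into the anchor's frame
        if matrix.distances[b_best, a_best] <= matrix.distances[a_best, b_best]:
            r_ba = int(matrix.rotations[b_best, a_best])
        else:
            r_ba = (-int(matrix.rotations[a_best, b_best])) % len(seqs[b_best])
        delta = r_ba + offsets[a_best] - offsets[b_best]
        for c in B:
            offsets[c] = (offsets[c] + delta) % len(seqs[c])
        members[N + t] = A + B
    rotated = [rotate(s, offsets[i]) for i, s in enumerate(seqs)]
    if return_rotations:
        return rotated, offsets
    return rotated


def random_rotate(seqs: list[str], seed: int) -> tuple[list[str], list[int]]:
    """Rotate each sequence by an independent uniform offset (seeded);
    returns the rotated sequences and the applied rotations as ground truth."""
    rng = np.random.default_rng(seed)
    rots = [int(rng.integers(0, len(s))) for s in seqs]
    return [rotate(s, r) for s, r in zip(seqs, rots)], rots
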