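"""Pairwise rotation recovery and clustering-based frame refinement."""

import math

import pytest

from flasm import (FlasmError, build_matrix, pair_best_rotation, random_dna,
                   random_rotate, refine, rotate)

from conftest import random_string


def test_pair_worked_example():
    assert pair_best_rotation("AAGATG", "GATGAA", 6, 0, "hamming") == (2, 0)


def test_pair_identity():
    s = "ACGTTGCA"
    assert pair_best_rotation(s, s, len(s), 0, "hamming") == (0, 0)


def test_pair_recovers_every_rotation(rng):
    s = random_string(rng, 30)
    for r in range(30):
        got = pair_best_rotation(s, rotate(s, r), 30, 0, "hamming")
        assert got == (r, 0)


def test_pair_none_when_out_of_range():
    assert pair_best_rotation("AAAA", "CCCC", 4, 1, "hamming") is None


def test_matrix_identical_sequences():
    M = build_matrix(["ACGTT"] * 4, 5, 0, "hamming")
    for i in range(4):
        for j in range(4):
            if i != j:
                assert M.distances[i, j] == 0 and M.rotations[i, j] == 0


def test_matrix_rotated_pair():
    s = random_dna(40, 13)
    M = build_matrix([s, rotate(s, 5)], 40, 0, "hamming")
    assert M.rotations[0, 1] == 5
    assert M.rotations[1, 0] == 35


def test_matrix_hamming_distance_symmetry(rng):
    # with ell = sequence length, d(rot_r(a), b) = d(a, rot_{m-r}(b)), so the
    # best-rotation distance is symmetric under the Hamming model
    seqs = [random_string(rng, 20) for _ in range(4)]
    M = build_matrix(seqs, 20, 19, "hamming")
    for i in range(4):
        for j in range(4):
            assert M.distances[i, j] == M.distances[j, i]


def test_matrix_sentinel_for_short_sequences():
    M = build_matrix(["ACGTACGT", "ACG"], 5, 1, "hamming")
    assert math.isinf(M.distances[0, 1])
    assert M.rotations[0, 1] == 0


def test_refine_restores_common_frame():
    anc = random_dna(200, 31)
    seqs, _ = random_rotate([anc] * 6, 32)
    M = build_matrix(seqs, 200, 0, "hamming")
    out = refine(seqs, M)
    assert len(set(out)) == 1
    assert out[0] == seqs[0]  # first sequence anchors the frame


def test_refine_two_sequences():
    s = random_dna(50, 41)
    seqs = [s, rotate(s, 7)]
    out = refine(seqs, build_matrix(seqs, 50, 0, "hamming"))
    assert out[0] == s
    assert out[1] == s


def test_refine_outputs_are_rotations_of_inputs(rng):
    seqs = [random_string(rng, 30) for _ in range(4)]
    out = refine(seqs, build_matrix(seqs, 10, 9, "hamming"))
    for before, after in zip(seqs, out):
        assert sorted(before) == sorted(after)
        assert after in (before + before)  # genuine rotation


def test_random_rotate_is_seeded_and_invertible():
    seqs = [random_dna(25, i) for i in range(3)]
    r1, rots1 = random_rotate(seqs, 99)
    r2, rots2 = random_rotate(seqs, 99)
    assert r1 == r2 and rots1 == rots2
    for orig, rotated, r in zip(seqs, r1, rots1):
        assert rotate(rotated, len(orig) - r) == orig


def test_refine_with_mutations_recovers_most_rotations():
    """Rotated copies of a mutated ancestor are brought back into one frame."""
    import random as _random
    prng = _random.Random(5150)
    anc = random_dna(300, 61)
    copies = []
    for _ in range(6):
        s = list(anc)
        for p in range(len(s)):
            if prng.random() < 0.05:
                s[p] = prng.choice([c for c in "ACGT" if c != s[p]])
        copies.append("".join(s))
    seqs, truth = random_rotate(copies, 62)
    M = build_matrix(seqs, 80, 20, "edit")
    _, offsets = refine(seqs, M, return_rotations=True)
    frames = [(r + o) % 300 for r, o in zip(truth, offsets)]
    mode = max(set(frames), key=frames.count)
    assert frames.count(mode) >= 5


def test_matrix_requires_two_sequences():
    with pytest.raises(FlasmError):
        build_matrix(["ACGT"], 2, 1)
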