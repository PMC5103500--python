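"""The fixed-width bit-row contract, checked against Python's big integers."""

import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flasm import bitrows as br
from flasm.bitrows import BitRow, BitRowError

LENGTHS = [1, 7, 63, 64, 65, 128, 200]


def rand_int(rng, ell):
    return rng.getrandbits(ell)


@pytest.mark.parametrize("ell", LENGTHS)
def test_roundtrip_and_bounds(ell):
    assert br.popcount(br.zero(ell)) == 0
    assert br.popcount(br.ones(ell)) == ell
    assert br.ones(ell).to_int() == (1 << ell) - 1
    v = (1 << ell) - 1 if ell < 3 else 0b101
    assert BitRow.from_int(ell, v).to_int() == v


@pytest.mark.parametrize("ell", LENGTHS)
def test_ops_agree_with_arbitrary_precision_integers(ell):
    """Shift, add, boolean ops, popcount and get_bit all match unbounded-int
    arithmetic mod 2**ell on 1000 random operand pairs per width."""
    rng = random.Random(1000 + ell)
    mask = (1 << ell) - 1
    for _ in range(1000):
        va, vb = rand_int(rng, ell), rand_int(rng, ell)
        a, b = BitRow.from_int(ell, va), BitRow.from_int(ell, vb)
        assert br.shift_left_trunc(a).to_int() == (va << 1) & mask
        assert br.add(a, b).to_int() == (va + vb) & mask
        assert br.or_(a, b).to_int() == va | vb
        assert br.and_(a, b).to_int() == va & vb
        assert br.xor(a, b).to_int() == va ^ vb
        assert br.not_(a).to_int() == va ^ mask
        assert br.popcount(a) == bin(va).count("1")
        p = rng.randrange(ell)
        assert br.get_bit(a, p) == (va >> p) & 1


@pytest.mark.parametrize("ell", [3, 64, 70, 200])
def test_shift_ell_times_clears(ell):
    rng = random.Random(ell)
    r = BitRow.from_int(ell, rand_int(rng, ell))
    for _ in range(ell):
        r = br.shift_left_trunc(r)
    assert r == br.zero(ell)


def test_shift_examples():
    assert br.shift_left_trunc(BitRow.from_int(3, 0b011)).to_int() == 0b110
    assert br.shift_left_trunc(BitRow.from_int(3, 0b110)).to_int() == 0b100
    assert br.popcount(br.shift_left_trunc(br.ones(70))) == 69
    assert br.get_bit(br.shift_left_trunc(br.ones(3)), 0) == 0


def test_add_examples():
    assert br.add(BitRow.from_int(4, 0b0111), BitRow.from_int(4, 0b0001)).to_int() == 0b1000
    b = BitRow.from_int(130, (1 << 129) | 7)
    assert br.add(br.zero(130), b) == b


def test_add_carries_across_word_boundaries():
    # all-ones + 1 wraps to zero, exercising the full carry chain
    for ell in (64, 65, 128, 130):
        assert br.add(br.ones(ell), BitRow.from_int(ell, 1)) == br.zero(ell)


@given(st.integers(min_value=0), st.sampled_from([7, 64, 65, 129]))
def test_xor_self_inverse(v, ell):
    a = BitRow.from_int(ell, v)
    assert br.xor(a, a) == br.zero(ell)


def test_errors():
    with pytest.raises(BitRowError):
        BitRow(0)
    with pytest.raises(BitRowError):
        br.add(br.zero(5), br.zero(6))
    with pytest.raises(BitRowError):
        br.get_bit(br.zero(5), 5)
    with pytest.raises(BitRowError):
        br.get_bit(br.zero(5), -1)


def test_word_size_exposed():
    assert br.WORD_SIZE == 64
    assert br.n_words(64) == 1 and br.n_words(65) == 2


def test_word_array_add_matches_bitrow():
    """The vectorised kernel agrees with the scalar contract on stacks."""
    rng = random.Random(7)
    ell = 130
    vals = [(rand_int(rng, ell), rand_int(rng, ell)) for _ in range(50)]
    A = np.stack([BitRow.from_int(ell, a).words for a, _ in vals], axis=1)
    B = np.stack([BitRow.from_int(ell, b).words for _, b in vals], axis=1)
    out = br.add_words(A, B, ell)
    mask = (1 << ell) - 1
    for c, (a, b) in enumerate(vals):
        assert BitRow(ell, out[:, c]).to_int() == (a + b) & mask
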