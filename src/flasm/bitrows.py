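"""Width-``ell`` bit vectors backed by arrays of 64-bit machine words.

Both search cores maintain dynamic-programming state as bit vectors of a
fixed width ``ell`` (the factor length), which may exceed the machine word.
A :class:`BitRow` stores its ``ell`` bits little-endian across a numpy
``uint64`` array: bit ``p`` lives in word ``p // WORD_SIZE`` at in-word
offset ``p % WORD_SIZE``, so bit 0 is the least significant / most recent
alignment column and "shift in the newest mismatch" is a left shift.

Every operation truncates to ``ell`` bits, which is what keeps the sliding
window fixed-length: the bit for the oldest column falls off the top on each
shift.  Addition propagates carries across word boundaries, as required by
the edit-distance core's carry chain.

The module-level helpers (:func:`shl1_words`, :func:`add_words`,
:func:`popcount_words`) operate on arrays whose *first* axis is the word
axis, so the cores can apply them to whole DP columns at once; ``BitRow``
is the single-vector view of the same routines.
"""

from __future__ import annotations

import numpy as np

#: Bits per backing word.  Read-only; correctness never depends on it, but the
#: multi-word scaling of the cores is expressed in units of ``ceil(ell / WORD_SIZE)``.
WORD_SIZE = 64

_S1 = np.uint64(1)
_S63 = np.uint64(WORD_SIZE - 1)
_FULL = np.uint64(0xFFFFFFFFFFFFFFFF)


class BitRowError(ValueError):
    """Invalid BitRow construction or operand mismatch."""


def n_words(length: int) -> int:
    """Number of 64-bit words needed for ``length`` bits."""
    return (length + WORD_SIZE - 1) // WORD_SIZE


def top_word_mask(length: int) -> np.uint64:
    """Mask of the valid bits in the most significant word."""
    r = length % WORD_SIZE
    return _FULL if r == 0 else np.uint64((1 << r) - 1)


# ---------------------------------------------------------------------------
# word-array kernels (word axis first; trailing axes are free)
# ---------------------------------------------------------------------------

def shl1_words(a: np.ndarray, length: int, out: np.ndarray | None = None) -> np.ndarray:
    """Shift every ``length``-bit value in ``a`` left by one bit, truncating.

    ``a`` has shape ``(n_words(length), ...)``; bit ``length - 1`` is discarded,
    bit 0 of the result is zero.
    """
    if out is None:
        out = np.empty_like(a)
    np.left_shift(a, _S1, out=out)
    if a.shape[0] > 1:
        out[1:] |= a[:-1] >> _S63
    if length % WORD_SIZE:
        out[-1] &= top_word_mask(length)
    return out


def add_words(a: np.ndarray, b: np.ndarray, length: int,
              out: np.ndarray | None = None) -> np.ndarray:
    """Add ``length``-bit values elementwise, mod ``2**length``.

    Carries ripple across the word axis (axis 0); the result is truncated to
    ``length`` bits.
    """
    if out is None:
        out = np.empty_like(a)
    nw = a.shape[0]
    if nw == 1:
        np.add(a[0:1], b[0:1], out=out[0:1])
    else:
        carry = np.zeros((1,) + a.shape[1:], dtype=np.uint64)
        for w in range(nw):
            aw, bw = a[w:w + 1], b[w:w + 1]
            s = aw + bw
            wrapped = s < aw
            s2 = s + carry
            wrapped |= s2 < s
            out[w:w + 1] = s2
            carry = wrapped.astype(np.uint64)
    if length % WORD_SIZE:
        out[-1] &= top_word_mask(length)
    return out


def popcount_words(a: np.ndarray) -> np.ndarray:
    """Population count of each value, summed over the word axis."""
    return np.bitwise_count(a).sum(axis=0, dtype=np.int64)


# ---------------------------------------------------------------------------
# BitRow: single fixed-width vector
# ---------------------------------------------------------------------------

class BitRow:
    """An ``ell``-bit vector with truncating shift, carrying add and popcount.

    Parameters
    ----------
    length:
        Number of bits, ``> 0``.
    words:
        Optional backing ``uint64`` array of shape ``(n_words(length),)``,
        little-endian word order.  Defaults to all-zero.
    """

    __slots__ = ("length", "words")

    def __init__(self, length: int, words: np.ndarray | None = None):
        if length <= 0:
            raise BitRowError(f"BitRow length must be positive, got {length}")
        self.length = int(length)
        if words is None:
            words = np.zeros(n_words(length), dtype=np.uint64)
        else:
            words = np.asarray(words, dtype=np.uint64)
            if words.shape != (n_words(length),):
                raise BitRowError(
                    f"expected {n_words(length)} words for length {length}, "
                    f"got shape {words.shape}")
            words = words.copy()
            if length % WORD_SIZE:
                words[-1] &= top_word_mask(length)
        self.words = words

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_int(cls, length: int, value: int) -> "BitRow":
        value &= (1 << length) - 1
        nw = n_words(length)
        words = np.array([(value >> (WORD_SIZE * w)) & 0xFFFFFFFFFFFFFFFF
                          for w in range(nw)], dtype=np.uint64)
        return cls(length, words)

    def to_int(self) -> int:
        v = 0
        for w in range(self.words.size - 1, -1, -1):
            v = (v << WORD_SIZE) | int(self.words[w])
        return v

    # -- dunder ------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        return (isinstance(other, BitRow) and self.length == other.length
                and bool(np.array_equal(self.words, other.words)))

    def __hash__(self) -> int:
        return hash((self.length, self.words.tobytes()))

    def __repr__(self) -> str:  # bits printed MSB first, like binary literals
        return f"BitRow({self.length}, 0b{self.to_int():0{self.length}b})"


def _check_pair(a: BitRow, b: BitRow) -> None:
    if a.length != b.length:
        raise BitRowError(f"length mismatch: {a.length} != {b.length}")


def zero(length: int) -> BitRow:
    return BitRow(length)


def ones(length: int) -> BitRow:
    r = BitRow(length)
    r.words[:] = _FULL
    r.words[-1] = top_word_mask(length)
    return r


def shift_left_trunc(r: BitRow) -> BitRow:
    out = BitRow(r.length)
    shl1_words(r.words, r.length, out=out.words)
    return out


def add(a: BitRow, b: BitRow) -> BitRow:
    _check_pair(a, b)
    out = BitRow(a.length)
    add_words(a.words, b.words, a.length, out=out.words)
    return out


def or_(a: BitRow, b: BitRow) -> BitRow:
    _check_pair(a, b)
    return BitRow(a.length, a.words | b.words)


def and_(a: BitRow, b: BitRow) -> BitRow:
    _check_pair(a, b)
    return BitRow(a.length, a.words & b.words)


def xor(a: BitRow, b: BitRow) -> BitRow:
    _check_pair(a, b)
    return BitRow(a.length, a.words ^ b.words)


def not_(r: BitRow) -> BitRow:
    out = BitRow(r.length, ~r.words)
    return out


def get_bit(r: BitRow, p: int) -> int:
    if not 0 <= p < r.length:
        raise BitRowError(f"bit index {p} outside [0, {r.length})")
    return int((r.words[p // WORD_SIZE] >> np.uint64(p % WORD_SIZE)) & _S1)


def popcount(r: BitRow) -> int:
    return int(np.bitwise_count(r.words).sum())
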