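"""Hamming-model core: shift-and-accumulate bit-vector dynamic programme.

The DP state is one column of ``m + 1`` bit rows, each ``ell`` bits wide:
``M[i][j] = shl(M[i-1][j-1]) | b`` with ``b = 0`` if ``x[i-1] == t[j-1]``
else ``1`` and zero boundary rows.  Bit ``p`` of ``M[i][j]`` records whether
the alignment column ``p`` positions back mismatched, so once both indices
have advanced past ``ell``, ``popcount(M[i][j])`` *is* the Hamming distance
between the two length-``ell`` windows ending at ``i`` and ``j``.  The left
shift truncates at bit ``ell - 1``, which is how the oldest column leaves
the window.

The text is streamed (outer loop over ``t``) holding a single column, giving
``O(m * ceil(ell/w))`` space; the column is a ``(n_words, m+1)`` uint64 array
so each step is a handful of vectorised word operations over the whole
column, realising the ``O(m * ceil(ell/w) * n)`` bound.
"""

from __future__ import annotations

import numpy as np

from .bitrows import _S1, _S63, n_words, top_word_mask
from .core import encode

_EMPTY = (np.empty(0, np.int64),) * 3


def hamming_scan(text: str, pattern: str, ell: int, k: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(j, i, e)`` arrays of all window pairs at distance ``<= k``.

    ``j``/``i`` are 0-based ending positions in text/pattern; both are at
    least ``ell - 1`` (windows lie fully inside the strings).  Inputs are
    assumed validated and uppercased by the caller.
    """
    t = encode(text)
    x = encode(pattern)
    n, m = t.size, x.size
    W = n_words(ell)
    partial = (ell % 64) != 0
    tmask = top_word_mask(ell)

    buf_a = np.zeros((W, m + 1), np.uint64)
    buf_b = np.zeros_like(buf_a)
    carry = np.empty((W - 1, m), np.uint64) if W > 1 else None
    pc = np.empty((W, m + 1), np.uint8)

    # per-letter mismatch rows: 1-bit to OR into word 0 of each cell
    letters = {int(c): (x != c).astype(np.uint64) for c in np.unique(t)}
    mism = [letters[int(c)] for c in t]

    # column 0 of each buffer stays zero throughout (boundary row), so the
    # hot loop only ever touches columns 1..m; views are hoisted out of it
    def views(src, dst):
        v = {
            "shift_src": src[:, :m], "shift_dst": dst[:, 1:],
            "word0": dst[0, 1:],
        }
        if W > 1:
            v["carry_src"] = src[:-1, :m]
            v["carry_dst"] = dst[1:, 1:]
        if partial:
            v["top"] = dst[-1, 1:]
        return v

    va, vb = views(buf_a, buf_b), views(buf_b, buf_a)
    cur, nxt = buf_a, buf_b

    js: list[np.ndarray] = []
    is_: list[np.ndarray] = []
    es: list[np.ndarray] = []

    # distances are checked in blocks of text steps to amortise bookkeeping
    B = 32
    eblock = np.empty((B, m + 1), np.int64)
    jbase = 0
    filled = 0

    def flush() -> None:
        nonlocal filled
        if not filled:
            return
        bi, ii = np.nonzero(eblock[:filled, ell:] <= k)
        if bi.size:
            js.append(jbase + bi.astype(np.int64))
            is_.append(ii + (ell - 1))
            es.append(eblock[bi, ii + ell])
        filled = 0

    lshift, rshift, bitcnt, reduce_ = (np.left_shift, np.right_shift,
                                       np.bitwise_count, np.add.reduce)
    for j in range(n):
        v = va if cur is buf_a else vb
        lshift(v["shift_src"], _S1, out=v["shift_dst"])
        if W > 1:
            rshift(v["carry_src"], _S63, out=carry)
            v["carry_dst"] |= carry
        if partial:
            v["top"] &= tmask
        v["word0"] |= mism[j]
        if j >= ell - 1:
            if filled == 0:
                jbase = j
            bitcnt(nxt, out=pc)
            reduce_(pc, axis=0, dtype=np.int64, out=eblock[filled])
            filled += 1
            if filled == B:
                flush()
        cur, nxt = nxt, cur

    flush()
    if not js:
        return _EMPTY
    return np.concatenate(js), np.concatenate(is_), np.concatenate(es)
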