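"""Edit-model core: multi-word Myers bit-vector matcher, one per factor.

Each length-``ell`` factor of the pattern is searched against the text with
the classic bit-parallel edit-distance scan (positive/negative vertical
delta vectors ``Pv``/``Mv`` plus a running score at the factor's last row).
The first DP row is pinned to zero, so the tracked score at text position
``j`` is the minimum over start positions ``s <= j`` of the edit distance
between ``t[s..j]`` and the factor — semi-global semantics with a free
start in the text.

All ``m - ell + 1`` factors are scanned simultaneously: the state arrays
have shape ``(n_words, n_factors)`` and every cell update is a vectorised
word operation, with :func:`flasm.bitrows.add_words` supplying the carry
chain across word boundaries so ``ell`` may exceed the machine word.
"""

from __future__ import annotations

import numpy as np

from .bitrows import add_words, n_words, shl1_words, top_word_mask
from .core import encode

_EMPTY = (np.empty(0, np.int64),) * 3
_ONE = np.uint64(1)
_FULL = np.uint64(0xFFFFFFFFFFFFFFFF)


def _build_peq(x: np.ndarray, letters: np.ndarray, ell: int, W: int
               ) -> dict[int, np.ndarray]:
    """Per-letter factor masks: ``Peq[c][w, f]`` holds bits ``p`` of factor
    ``f`` (starting at ``f``) where ``x[f + p] == c``."""
    F = x.size - ell + 1
    nbytes = (ell + 7) // 8
    peq: dict[int, np.ndarray] = {}
    for c in letters:
        bits = (x == c)
        win = np.lib.stride_tricks.sliding_window_view(bits, ell)
        packed = np.packbits(win, axis=1, bitorder="little")  # (F, nbytes)
        buf = np.zeros((F, W * 8), np.uint8)
        buf[:, :nbytes] = packed
        peq[int(c)] = np.ascontiguousarray(buf.view("<u8").reshape(F, W).T)
    return peq


def edit_scan(text: str, pattern: str, ell: int, k: int
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(j, i, e)`` arrays with one entry per ``(j, i)`` where the
    minimal edit distance over text windows ending at ``j`` is ``<= k``.

    ``i`` ranges over ``[ell - 1, m - 1]`` (factor ending positions); ``j``
    over ``[0, n - 1]``.  Inputs are assumed validated and uppercased.
    """
    t = encode(text)
    x = encode(pattern)
    n, m = t.size, x.size
    F = m - ell + 1
    W = n_words(ell)
    partial = (ell % 64) != 0
    tmask = top_word_mask(ell)
    wt = W - 1
    bt = np.uint64((ell - 1) % 64)

    peq = _build_peq(x, np.unique(t), ell, W)
    zeros_eq = np.zeros((W, F), np.uint64)

    Pv = np.full((W, F), _FULL, np.uint64)
    Pv[-1] = tmask
    Mv = np.zeros((W, F), np.uint64)
    score = np.full(F, ell, np.int64)

    js: list[np.ndarray] = []
    is_: list[np.ndarray] = []
    es: list[np.ndarray] = []

    add_out = np.empty((W, F), np.uint64)
    shp = np.empty((W, F), np.uint64)
    shn = np.empty((W, F), np.uint64)

    for j in range(n):
        Eq = peq.get(int(t[j]), zeros_eq)
        # D0: diagonal-zero vector; the add propagates matches down runs
        add_words(Eq & Pv, Pv, ell, out=add_out)
        D0 = (add_out ^ Pv) | Eq | Mv
        if partial:
            D0[-1] &= tmask
        Hp = Mv | ~(D0 | Pv)
        if partial:
            Hp[-1] &= tmask
        Hn = Pv & D0
        score += ((Hp[wt] >> bt) & _ONE).astype(np.int64)
        score -= ((Hn[wt] >> bt) & _ONE).astype(np.int64)
        # shift in 0 at the top row: the text start is free
        shl1_words(Hp, ell, out=shp)
        shl1_words(Hn, ell, out=shn)
        Pv = shn | ~(D0 | shp)
        if partial:
            Pv[-1] &= tmask
        Mv = shp & D0

        hit = np.flatnonzero(score <= k)
        if hit.size:
            js.append(np.full(hit.size, j, np.int64))
            is_.append(hit + (ell - 1))
            es.append(score[hit])

    if not js:
        return _EMPTY
    return np.concatenate(js), np.concatenate(is_), np.concatenate(es)
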