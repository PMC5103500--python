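"""The q-gram distance index of Chang and Marr, built via a de Bruijn sequence.

The index is an array ``D`` of ``sigma**q`` entries giving, for every q-gram
over the alphabet, the smallest distance between that q-gram and any factor
of a pattern ``x`` — the precomputed filter behind average-case-optimal
approximate matching.  Building it naively costs ``O(sigma**q * q * m)``
distance evaluations.  A de Bruijn sequence ``B(q, sigma)`` contains every
q-gram exactly once as a factor (read circularly), so a single fixed-length
search — linearised de Bruijn sequence as the pattern, ``x`` as the text,
factor length ``q``, threshold ``q - 1`` — visits every (q-gram, factor)
pair in one bit-parallel pass.

Entries never reported by the search are backfilled with ``q``: a length-q
window is always reachable with ``q`` substitutions, so under Hamming an
unreported minimum is exactly ``q``; under edit it is at least ``q`` and the
index caps there (its consumers threshold strictly below ``q``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FlasmError, Model, scan


def debruijn_sequence(q: int, alphabet: str) -> str:
    """Lexicographically least de Bruijn sequence ``B(q, sigma)``.

    A circular string of length ``sigma**q`` in which every q-gram over the
    alphabet occurs exactly once; built by concatenating the Lyndon words
    whose length divides ``q`` in lexicographic order, in time linear in the
    output.  ``sigma == 1`` degenerates to the single letter repeated ``q``
    times.
    """
    if q < 1:
        raise FlasmError(f"q must be >= 1, got {q}")
    if len(alphabet) == 0:
        raise FlasmError("alphabet must be non-empty")
    if len(set(alphabet)) != len(alphabet):
        raise FlasmError("alphabet letters must be distinct")
    sigma = len(alphabet)
    if sigma == 1:
        return alphabet * q
    seq: list[int] = []
    a = [0] * (sigma * q)

    def db(t: int, p: int) -> None:
        if t > q:
            if q % p == 0:
                seq.extend(a[1:p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for c in range(a[t - p] + 1, sigma):
                a[t] = c
                db(t + 1, t)

    db(1, 1)
    return "".join(alphabet[c] for c in seq)


def qgram_rank(s: str, alphabet: str) -> int:
    """Base-``sigma`` value of a q-gram, leftmost letter most significant."""
    sigma = len(alphabet)
    index = {c: v for v, c in enumerate(alphabet)}
    r = 0
    for c in s:
        if c not in index:
            raise FlasmError(f"letter {c!r} not in alphabet {alphabet!r}")
        r = r * sigma + index[c]
    return r


def qgram_unrank(r: int, q: int, alphabet: str) -> str:
    """Inverse of :func:`qgram_rank`."""
    sigma = len(alphabet)
    out = []
    for _ in range(q):
        out.append(alphabet[r % sigma])
        r //= sigma
    return "".join(reversed(out))


@dataclass(frozen=True)
class ChangMarrIndex:
    """Minimal q-gram-to-pattern distances, addressed by q-gram rank."""

    alphabet: str
    q: int
    model: Model
    distances: np.ndarray  # shape (sigma**q,), values in [0, q]

    def lookup(self, qgram: str) -> int:
        if len(qgram) != self.q:
            raise FlasmError(f"expected a {self.q}-gram, got {qgram!r}")
        return int(self.distances[qgram_rank(qgram, self.alphabet)])


def _digits(s: str, alphabet: str) -> np.ndarray:
    index = {c: v for v, c in enumerate(alphabet)}
    try:
        return np.array([index[c] for c in s], dtype=np.int64)
    except KeyError as exc:
        raise FlasmError(f"letter {exc.args[0]!r} not in alphabet {alphabet!r}") from None


def _all_gram_digits(q: int, sigma: int) -> np.ndarray:
    """Digit matrix of all ``sigma**q`` q-grams in rank order, shape (sigma**q, q)."""
    r = np.arange(sigma ** q, dtype=np.int64)
    pows = sigma ** np.arange(q - 1, -1, -1, dtype=np.int64)
    return (r[:, None] // pows[None, :]) % sigma


def build_index(x: str, q: int, alphabet: str = "ACGT",
                model: Model = "hamming") -> ChangMarrIndex:
    """Build the index with one fixed-length search.

    The de Bruijn sequence is linearised by appending its first ``q - 1``
    letters so that every circular q-gram is a linear factor; it serves as
    the search *pattern* while ``x`` is the *text*, with ``ell = q`` and
    ``k = q - 1`` (the largest threshold the cores admit).
    """
    x = x.upper()
    if q > len(x):
        raise FlasmError(f"q={q} exceeds pattern length {len(x)}")
    _digits(x, alphabet)  # validate letters
    db = debruijn_sequence(q, alphabet)
    linear = db + db[:q - 1]
    sigma = len(alphabet)
    D = np.full(sigma ** q, q, dtype=np.int64)
    j, i, e = scan(text=x, pattern=linear, factor_length=q,
                   max_distance=q - 1, model=model)
    if e.size:
        # rank of the q-gram ending at each position of the linearised sequence
        d = _digits(linear, alphabet)
        pows = sigma ** np.arange(q - 1, -1, -1, dtype=np.int64)
        win = np.lib.stride_tricks.sliding_window_view(d, q)
        ranks = win @ pows  # index by window start = i - q + 1
        np.minimum.at(D, ranks[i - (q - 1)], e)
    return ChangMarrIndex(alphabet, q, model, D)


def build_index_naive(x: str, q: int, alphabet: str = "ACGT",
                      model: Model = "hamming") -> ChangMarrIndex:
    """Direct minimisation over every (q-gram, factor) pair.

    The ``O(sigma**q * q * m)`` baseline; also the independent cross-check
    for :func:`build_index`.  Hamming compares length-q windows; edit takes
    the distance between each q-gram and the closest factor of ``x`` (free
    start and end in ``x``), capped at ``q``.
    """
    x = x.upper()
    if q > len(x):
        raise FlasmError(f"q={q} exceeds pattern length {len(x)}")
    xd = _digits(x, alphabet)
    sigma = len(alphabet)
    grams = _all_gram_digits(q, sigma)
    if model == "hamming":
        win = np.lib.stride_tricks.sliding_window_view(xd, q)  # (nw, q)
        D = np.full(sigma ** q, q, dtype=np.int64)
        # chunked broadcast keeps memory at ~chunk * nw * q bytes
        chunk = max(1, (1 << 22) // max(1, win.shape[0] * q))
        for lo in range(0, grams.shape[0], chunk):
            g = grams[lo:lo + chunk]
            mis = (g[:, None, :] != win[None, :, :]).sum(axis=2)
            D[lo:lo + chunk] = mis.min(axis=1)
    elif model == "edit":
        G = grams.shape[0]
        prev = np.empty((G, q + 1), dtype=np.int64)
        cur = np.empty_like(prev)
        prev[:] = np.arange(q + 1)[None, :]
        best = np.full(G, q, dtype=np.int64)
        for cj in xd:
            cur[:, 0] = 0
            for r in range(1, q + 1):
                sub = prev[:, r - 1] + (grams[:, r - 1] != cj)
                np.minimum(sub, prev[:, r] + 1, out=cur[:, r])
                np.minimum(cur[:, r], cur[:, r - 1] + 1, out=cur[:, r])
            np.minimum(best, cur[:, q], out=best)
            prev, cur = cur, prev
        D = best
    else:
        raise FlasmError(f"unknown model {model!r}")
    return ChangMarrIndex(alphabet, q, model, D)
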