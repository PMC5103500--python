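"""Shared contracts of the two fixed-length search cores.

Fixed-length approximate string matching (FLASM): given a text ``t`` of
length ``n``, a pattern ``x`` of length ``m``, a factor length ``ell <= m``
and a threshold ``k < ell``, report every factor of ``t`` within distance
``k`` of *any* length-``ell`` factor of ``x``.  Results are sets of
``(j, i, e)`` tuples: 0-based ending position in the text, 0-based ending
position in the pattern, and the distance, with at most one tuple per
``(j, i)`` pair carrying the minimal distance.

Both cores run in ``O(m * ceil(ell/w) * n)`` time and ``O(m * ceil(ell/w))``
space, where ``w`` is the machine word size — independent of ``k`` and of
the alphabet.

Note on validation: the pattern may be *longer* than the text.  Circular
matching doubles the pattern, which routinely makes it longer than the text
it is searched in; the dynamic programmes only require ``ell <= m`` and
``ell <= n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple

import numpy as np

Model = Literal["hamming", "edit"]
Mode = Literal["all", "best"]

MODELS = ("hamming", "edit")
MODES = ("all", "best")


class FlasmError(ValueError):
    """Invalid search parameters."""


class MatchTuple(NamedTuple):
    """One reported match ``<j, i, e>``."""

    text_end: int      #: j — 0-based ending position of the match in the text
    pattern_end: int   #: i — 0-based ending position of the matched factor in the pattern
    distance: int      #: e — distance between the two factors


@dataclass(frozen=True)
class FlasmParams:
    """Validated parameter bundle for one fixed-length search.

    ``text`` and ``pattern`` are uppercased on ingest; any symbol (including
    ``N`` or gap characters) is an ordinary letter that matches only itself.
    ``max_distance == 0`` performs exact matching.
    """

    text: str
    pattern: str
    factor_length: int
    max_distance: int
    mode: Mode = "all"

    def __post_init__(self):
        object.__setattr__(self, "text", self.text.upper())
        object.__setattr__(self, "pattern", self.pattern.upper())
        n, m, ell, k = (len(self.text), len(self.pattern),
                        self.factor_length, self.max_distance)
        if n == 0 or m == 0:
            raise FlasmError("text and pattern must be non-empty")
        if ell <= 0:
            raise FlasmError(f"factor length must be positive, got {ell}")
        if ell > m:
            raise FlasmError(f"factor length {ell} exceeds pattern length {m}")
        if ell > n:
            raise FlasmError(f"factor length {ell} exceeds text length {n}")
        if not 0 <= k < ell:
            raise FlasmError(
                f"max distance must satisfy 0 <= k < factor length, got k={k}, ell={ell}")
        if self.mode not in MODES:
            raise FlasmError(f"mode must be one of {MODES}, got {self.mode!r}")


def scan(text: str, pattern: str, factor_length: int, max_distance: int,
         model: Model) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Array-level search: validated, returns ``(j, i, e)`` int64 arrays.

    One entry per ``(j, i)`` pair with distance ``<= max_distance``; used by
    the applications to avoid materialising large Python sets.
    """
    p = FlasmParams(text, pattern, factor_length, max_distance)
    if model == "hamming":
        from .hamming import hamming_scan
        return hamming_scan(p.text, p.pattern, factor_length, max_distance)
    if model == "edit":
        from .edit import edit_scan
        return edit_scan(p.text, p.pattern, factor_length, max_distance)
    raise FlasmError(f"model must be one of {MODELS}, got {model!r}")


def _finalize(arrays: tuple[np.ndarray, np.ndarray, np.ndarray],
              mode: Mode) -> set[MatchTuple]:
    j, i, e = arrays
    if mode == "best":
        if j.size == 0:
            return set()
        # minimal distance, ties broken by smallest j then smallest i
        order = np.lexsort((i, j, e))
        b = order[0]
        return {MatchTuple(int(j[b]), int(i[b]), int(e[b]))}
    return {MatchTuple(int(jj), int(ii), int(ee))
            for jj, ii, ee in zip(j.tolist(), i.tolist(), e.tolist())}


def flasm_hamming(text: str, pattern: str, factor_length: int,
                  max_distance: int, mode: Mode = "all") -> set[MatchTuple]:
    """All factors of ``text`` within Hamming distance ``max_distance`` of a
    length-``factor_length`` factor of ``pattern``.

    Under the Hamming model both factors of a match have length
    ``factor_length``, so ``j`` and ``i`` both range over
    ``[factor_length - 1, ...)``.  ``mode="best"`` returns the single tuple
    with minimal distance (ties: smallest ``j``, then smallest ``i``), or the
    empty set when nothing is within range.
    """
    p = FlasmParams(text, pattern, factor_length, max_distance, mode)
    from .hamming import hamming_scan
    return _finalize(hamming_scan(p.text, p.pattern, factor_length, max_distance),
                     mode)


def flasm_edit(text: str, pattern: str, factor_length: int,
               max_distance: int, mode: Mode = "all") -> set[MatchTuple]:
    """All text ending positions within edit distance ``max_distance`` of a
    length-``factor_length`` factor of ``pattern``.

    For each pattern factor (ending at ``i``) and each text position ``j``,
    the reported ``e`` is the *minimum over start positions* ``s <= j`` of the
    edit distance between ``t[s..j]`` and the factor — the standard
    semi-global semantics: a tuple per ending position rather than one per
    (start, end) pair, which is what the ``<j, i, e>`` contract can carry.
    """
    p = FlasmParams(text, pattern, factor_length, max_distance, mode)
    from .edit import edit_scan
    return _finalize(edit_scan(p.text, p.pattern, factor_length, max_distance),
                     mode)


def run(params: FlasmParams, model: Model) -> set[MatchTuple]:
    """Dispatch a validated parameter bundle to the requested core."""
    fn = {"hamming": flasm_hamming, "edit": flasm_edit}.get(model)
    if fn is None:
        raise FlasmError(f"model must be one of {MODELS}, got {model!r}")
    return fn(params.text, params.pattern, params.factor_length,
              params.max_distance, params.mode)


def encode(s: str) -> np.ndarray:
    """Byte-encode a sequence for the numpy kernels (latin-1, one byte/symbol)."""
    return np.frombuffer(s.encode("latin-1"), dtype=np.uint8)
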