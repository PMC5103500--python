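"""Approximate circular string matching (ACSM) by pattern doubling.

A circular pattern has no distinguished origin: any of its ``m`` rotations
may occur in the text.  Concatenating the pattern with its first ``m - 1``
letters yields a string whose length-``m`` factors are exactly the ``m``
rotations, so one fixed-length search with factor length ``m`` over the
doubled pattern finds every rotation's matches in a single pass —
independent of the distance threshold.
"""

from __future__ import annotations

from .core import FlasmError, MatchTuple, Mode, Model, _finalize, scan


def rotate(s: str, r: int) -> str:
    """The rotation ``s[r..] + s[..r]`` of ``s`` (``r`` taken mod ``len(s)``)."""
    if not s:
        raise FlasmError("cannot rotate an empty string")
    r %= len(s)
    return s[r:] + s[:r]


def double_pattern(x: str) -> str:
    """``x`` concatenated with its first ``m - 1`` letters.

    The result has length ``2m - 1`` and its length-``m`` factors are exactly
    the ``m`` rotations of ``x``.
    """
    if not x:
        raise FlasmError("pattern must be non-empty")
    return x + x[:-1]


def rotation_index(pattern_end: int, m: int) -> int:
    """Rotation identified by a match tuple: the window ending at
    ``pattern_end`` in the doubled pattern starts at ``pattern_end - m + 1``,
    i.e. rotation ``(pattern_end - m + 1) mod m``."""
    return (pattern_end - m + 1) % m


def acsm(text: str, pattern: str, max_distance: int, model: Model = "hamming",
         mode: Mode = "all", dedupe_rotations: bool = False) -> set[MatchTuple]:
    """All factors of ``text`` within ``max_distance`` of any rotation of
    ``pattern``.

    Equivalent to a fixed-length search against :func:`double_pattern` with
    the factor length set to ``len(pattern)``; each tuple's ``pattern_end``
    identifies the matched rotation via :func:`rotation_index`.

    For periodic patterns, distinct ``pattern_end`` values can denote the
    same rotation *string*; all are retained unless ``dedupe_rotations`` is
    set, in which case one tuple per ``(text_end, rotation string)`` is kept
    (minimal distance, then smallest ``pattern_end``).
    """
    m = len(pattern)
    n = len(text)
    if m == 0 or n == 0:
        raise FlasmError("text and pattern must be non-empty")
    if m > n:
        raise FlasmError(f"pattern length {m} exceeds text length {n}")
    if not 0 <= max_distance < m:
        raise FlasmError(
            f"max distance must satisfy 0 <= k < pattern length, got {max_distance}")
    doubled = double_pattern(pattern.upper())
    result = _finalize(scan(text, doubled, m, max_distance, model), mode)
    if dedupe_rotations and mode == "all":
        best: dict[tuple[int, str], MatchTuple] = {}
        for tup in result:
            key = (tup.text_end, rotate(pattern.upper(), rotation_index(tup.pattern_end, m)))
            prev = best.get(key)
            if prev is None or (tup.distance, tup.pattern_end) < (prev.distance, prev.pattern_end):
                best[key] = tup
        result = set(best.values())
    return result
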