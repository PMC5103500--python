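"""Single and structured motif extraction with quorum over sequence sets.

A single motif of length ``ell`` *k-occurs* in a sequence when some window
of that sequence is within distance ``k`` of it; a motif is *valid* when it
k-occurs in at least ``quorum`` of the input sequences.  Extraction is
*strictly valid*: every reported motif is a factor that occurs with zero
errors in at least one input sequence, so candidates are exactly the
factors of the inputs and all pairwise sequence comparisons (one
fixed-length search per ordered pair) determine the per-sequence counts.

A structured motif is a tuple of single motifs (*boxes*) separated by
spacers whose lengths must fall in prescribed intervals — the geometry of
composite transcription-factor binding sites, where a dimer contacts DNA at
two or more conserved points separated by a non-conserved spacer.  The gap
``g`` between consecutive boxes is counted as the number of spacer letters
strictly between them, ``g = start(next) - end(prev) - 1``; occurrence of a
structured motif in a sequence requires a chain of per-box k_i-occurrences
whose gaps all lie within their intervals.  Strict validity extends to the
structured case: candidate box tuples are read off a single source sequence
at exact occurrences with compliant source gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .core import FlasmError, Model, scan


@dataclass(frozen=True)
class StructuredMotifSpec:
    """Box geometry: ``boxes`` are (length, threshold) pairs, ``gaps`` the
    ``len(boxes) - 1`` spacer-letter intervals ``(dmin, dmax)`` between them."""

    boxes: tuple[tuple[int, int], ...]
    gaps: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.boxes) < 1:
            raise FlasmError("at least one box is required")
        if len(self.gaps) != len(self.boxes) - 1:
            raise FlasmError(
                f"{len(self.boxes)} boxes require {len(self.boxes) - 1} gap "
                f"intervals, got {len(self.gaps)}")
        for ell, k in self.boxes:
            if not 0 < ell:
                raise FlasmError(f"box length must be positive, got {ell}")
            if not 0 <= k < ell:
                raise FlasmError(f"box threshold must satisfy 0 <= k < length, "
                                 f"got k={k}, length={ell}")
        for dmin, dmax in self.gaps:
            if not 0 <= dmin <= dmax:
                raise FlasmError(f"gap interval must satisfy 0 <= dmin <= dmax, "
                                 f"got [{dmin}, {dmax}]")

    @classmethod
    def from_notation(cls, notation: str) -> "StructuredMotifSpec":
        """Parse ``(l1,k1)[d1,D1](l2,k2)...`` notation (whitespace ignored)."""
        s = re.sub(r"\s+", "", notation).strip("<>")
        tokens = re.findall(r"\((\d+),(\d+)\)|\[(\d+),(\d+)\]", s)
        consumed = re.sub(r"\((\d+),(\d+)\)|\[(\d+),(\d+)\]", "", s)
        if consumed:
            raise FlasmError(f"cannot parse structured motif notation {notation!r}")
        boxes, gaps = [], []
        expect_box = True
        for l, k, dmin, dmax in tokens:
            if l:
                if not expect_box:
                    raise FlasmError(f"two consecutive boxes in {notation!r}")
                boxes.append((int(l), int(k)))
                expect_box = False
            else:
                if expect_box:
                    raise FlasmError(f"gap interval without preceding box in {notation!r}")
                gaps.append((int(dmin), int(dmax)))
                expect_box = True
        if expect_box and boxes:
            raise FlasmError(f"trailing gap interval in {notation!r}")
        return cls(tuple(boxes), tuple(gaps))

    @property
    def notation(self) -> str:
        parts = [f"({self.boxes[0][0]},{self.boxes[0][1]})"]
        for (dmin, dmax), (ell, k) in zip(self.gaps, self.boxes[1:]):
            parts.append(f"[{dmin},{dmax}]({ell},{k})")
        return "".join(parts)


@dataclass
class MotifRecord:
    """A valid single motif: its string, one exact-occurrence source, the
    per-sequence k-occurrence counts and the number of sequences with at
    least one k-occurrence."""

    motif: str
    source: tuple[int, int]       # (sequence index, 0-based ending position)
    seq_hits: list[int]
    quorum_count: int = field(init=False)

    def __post_init__(self):
        self.quorum_count = sum(1 for h in self.seq_hits if h > 0)


@dataclass
class StructuredMotifRecord:
    """A valid structured motif: box strings, the gap intervals they were
    extracted under, one exact source chain, and per-sequence chain counts."""

    boxes: tuple[str, ...]
    gaps: tuple[tuple[int, int], ...]
    source: tuple[int, tuple[int, ...]]   # (sequence index, box start positions)
    seq_hits: list[int]
    quorum_count: int = field(init=False)

    def __post_init__(self):
        self.quorum_count = sum(1 for h in self.seq_hits if h > 0)

    @property
    def motif(self) -> str:
        parts = [self.boxes[0]]
        for (dmin, dmax), box in zip(self.gaps, self.boxes[1:]):
            parts.append(f"[{dmin},{dmax}]{box}")
        return "".join(parts)


def _edit_min_start(text: str, j: int, box: str, e: int) -> int:
    """Smallest start ``s`` with ``edit(t[s..j], box)`` minimal (= ``e``).

    Runs the alignment right-to-left over the window that can reach
    distance ``e`` (length within ``e`` of ``len(box)``).
    """
    ell = len(box)
    lo = max(0, j - ell - e + 1)
    rt = text[lo:j + 1][::-1]
    rb = box[::-1]
    np_ = len(rt)
    prev = list(range(np_ + 1))
    for r in range(1, ell + 1):
        cur = [r] + [0] * np_
        cb = rb[r - 1]
        for p in range(1, np_ + 1):
            cur[p] = min(prev[p - 1] + (cb != rt[p - 1]),
                         prev[p] + 1, cur[p - 1] + 1)
        prev = cur
    best_p = max(range(np_ + 1), key=lambda p: (prev[p] == min(prev), p))
    return j - best_p + 1


def box_occurrences(seqs: list[str], box: str, max_distance: int,
                    model: Model = "hamming") -> list[list[tuple[int, int]]]:
    """Per-sequence k-occurrence intervals of a box, 0-based inclusive,
    sorted by start.

    Under Hamming the start is ``end - len(box) + 1``; under edit it is the
    start attaining the minimal distance for that ending position (smallest
    such start on ties).  Sequences shorter than the box yield empty lists.
    """
    box = box.upper()
    out: list[list[tuple[int, int]]] = []
    ell = len(box)
    for s in seqs:
        s = s.upper()
        if len(s) < ell:
            out.append([])
            continue
        j, _, e = scan(text=s, pattern=box, factor_length=ell,
                       max_distance=max_distance, model=model)
        if model == "hamming":
            occ = [(int(jj) - ell + 1, int(jj)) for jj in j]
        else:
            occ = [(_edit_min_start(s, int(jj), box, int(ee)), int(jj))
                   for jj, ee in zip(j, e)]
        occ.sort()
        out.append(occ)
    return out


def _pairwise_occurrences(seqs: list[str], ell: int, k: int, model: Model
                          ) -> list[list[dict[int, np.ndarray] | None]]:
    """For each ordered pair (src, tgt): factor start in src -> sorted array
    of k-occurrence ending positions in tgt.  ``None`` marks pairs where the
    factor does not fit either sequence.

    Hamming window distances are symmetric, so each unordered pair is
    scanned once and transposed for the reverse direction.
    """
    N = len(seqs)
    occ: list[list[dict[int, np.ndarray] | None]] = [[None] * N for _ in range(N)]

    def split(j: np.ndarray, i: np.ndarray) -> dict[int, np.ndarray]:
        by: dict[int, np.ndarray] = {}
        if j.size == 0:
            return by
        order = np.lexsort((j, i))
        i, j = i[order], j[order]
        starts, idx = np.unique(i, return_index=True)
        for s, lo, hi in zip(starts.tolist(), idx.tolist(),
                             list(idx[1:]) + [i.size]):
            by[int(s) - ell + 1] = j[lo:hi]
        return by

    for a in range(N):
        for b in range(a, N):
            if ell > len(seqs[a]) or ell > len(seqs[b]):
                continue
            j, i, e = scan(text=seqs[b], pattern=seqs[a], factor_length=ell,
                           max_distance=k, model=model)
            occ[a][b] = split(j, i)
            if b != a:
                if model == "hamming":
                    occ[b][a] = split(i, j)
                else:
                    j2, i2, _ = scan(text=seqs[a], pattern=seqs[b],
                                     factor_length=ell, max_distance=k,
                                     model=model)
                    occ[b][a] = split(j2, i2)
    return occ


def single_motif_extract(seqs: list[str], length: int, max_distance: int,
                         quorum: int, model: Model = "hamming"
                         ) -> list[MotifRecord]:
    """All strictly valid single motifs of the given length that k-occur in
    at least ``quorum`` sequences.

    Records are deduplicated by motif string (the lexicographically least
    (sequence index, ending position) source is kept) and sorted by
    descending quorum count, then motif string.
    """
    N = len(seqs)
    if N < 2:
        raise FlasmError(f"at least 2 sequences are required, got {N}")
    if not 1 <= quorum <= N:
        raise FlasmError(f"quorum must be in [1, {N}], got {quorum}")
    seqs = [s.upper() for s in seqs]
    shortest = min(len(s) for s in seqs)
    if length > shortest:
        raise FlasmError(f"motif length {length} exceeds shortest sequence "
                         f"({shortest})")
    if not 0 <= max_distance < length:
        raise FlasmError(f"max distance must satisfy 0 <= k < length, got "
                         f"{max_distance}")

    occ = _pairwise_occurrences(seqs, length, max_distance, model)
    records: dict[str, MotifRecord] = {}
    for a in range(N):
        sa = seqs[a]
        for start in range(len(sa) - length + 1):
            mstr = sa[start:start + length]
            if mstr in records:
                continue
            hits = [occ[a][b].get(start, _NO_HITS).size if occ[a][b] is not None
                    else 0 for b in range(N)]
            records[mstr] = MotifRecord(mstr, (a, start + length - 1), hits)
    out = [r for r in records.values() if r.quorum_count >= quorum]
    out.sort(key=lambda r: (-r.quorum_count, r.motif))
    return out


_NO_HITS = np.empty(0, np.int64)


def _chain_ends(lists: list[list[tuple[int, int]]],
                gaps: tuple[tuple[int, int], ...]) -> list[int]:
    """Distinct final-box ending positions of complete chains, where
    consecutive occurrences satisfy ``start(next) - end(prev) - 1`` within
    the gap interval."""
    ends = [e for _, e in lists[0]]
    for (dmin, dmax), occs in zip(gaps, lists[1:]):
        nxt = set()
        for s, e in occs:
            for pe in ends:
                if pe + dmin + 1 <= s <= pe + dmax + 1:
                    nxt.add(e)
                    break
        ends = sorted(nxt)
        if not ends:
            break
    return ends


def structured_motif_extract(seqs: list[str], spec: StructuredMotifSpec,
                             quorum: int, model: Model = "hamming"
                             ) -> list[StructuredMotifRecord]:
    """All strictly valid structured motifs with a (k_i)-occurrence chain in
    at least ``quorum`` sequences.

    Candidates are box tuples read off a single source sequence at exact
    occurrences whose source gaps satisfy the intervals; for each candidate,
    a sequence counts when a chain of per-box k_i-occurrences with compliant
    gaps exists in it.  A box-level necessary condition (each box must
    k-occur in >= quorum sequences) prunes the candidate enumeration.
    """
    N = len(seqs)
    if N < 2:
        raise FlasmError(f"at least 2 sequences are required, got {N}")
    if not 1 <= quorum <= N:
        raise FlasmError(f"quorum must be in [1, {N}], got {quorum}")
    seqs = [s.upper() for s in seqs]
    B = len(spec.boxes)

    # per box: ordered-pair occurrence maps and per-(src, start) sequence counts
    occ = [
        _pairwise_occurrences(seqs, ell, k, model) for ell, k in spec.boxes
    ]

    def seq_count(b: int, src: int, start: int) -> int:
        return sum(1 for tgt in range(N)
                   if occ[b][src][tgt] is not None
                   and occ[b][src][tgt].get(start, _NO_HITS).size > 0)

    records: dict[tuple[str, ...], StructuredMotifRecord] = {}
    for src in range(N):
        s = seqs[src]
        # starts whose box could reach the quorum (necessary condition)
        viable: list[list[int]] = []
        for b, (ell, k) in enumerate(spec.boxes):
            if occ[b][src][src] is None:
                viable.append([])
                continue
            viable.append(sorted(
                p for p in occ[b][src][src]
                if 0 <= p <= len(s) - ell and seq_count(b, src, p) >= quorum))
        # enumerate chains of starts with compliant source gaps
        chains: list[tuple[int, ...]] = [(p,) for p in viable[0]]
        for b in range(1, B):
            ell_prev = spec.boxes[b - 1][0]
            dmin, dmax = spec.gaps[b - 1]
            nxt = []
            for ch in chains:
                end_prev = ch[-1] + ell_prev - 1
                for p in viable[b]:
                    if end_prev + dmin + 1 <= p <= end_prev + dmax + 1:
                        nxt.append(ch + (p,))
            chains = nxt
            if not chains:
                break
        for ch in chains:
            boxes = tuple(s[p:p + ell] for p, (ell, _) in zip(ch, spec.boxes))
            if boxes in records:
                continue  # first source in (src asc, position asc) order kept
            hits = []
            for tgt in range(N):
                lists = []
                for b, p in enumerate(ch):
                    m = occ[b][src][tgt]
                    ends = m.get(p, _NO_HITS) if m is not None else _NO_HITS
                    ell_b = spec.boxes[b][0]
                    if model == "hamming":
                        lists.append([(int(e) - ell_b + 1, int(e)) for e in ends])
                    else:
                        kb = spec.boxes[b][1]
                        tseq = seqs[tgt]
                        lists.append(sorted(
                            (_edit_min_start(tseq, int(e), boxes[b], kb), int(e))
                            for e in ends))
                hits.append(len(_chain_ends(lists, spec.gaps)))
            rec = StructuredMotifRecord(boxes, spec.gaps, (src, ch), hits)
            if rec.quorum_count >= quorum:
                records[boxes] = rec
    out = list(records.values())
    out.sort(key=lambda r: (-r.quorum_count, r.motif))
    return out
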