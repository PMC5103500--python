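"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — direct window enumeration and
textbook quadratic dynamic programmes — and shares no code with the
package's bit-vector implementations.
"""

from __future__ import annotations


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def edit(a: str, b: str) -> int:
    """Plain quadratic edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[-1]


def hamming_distance_map(t: str, x: str, ell: int) -> dict[tuple[int, int], int]:
    """(j, i) -> Hamming distance of the two length-ell windows ending there."""
    out = {}
    for j in range(ell - 1, len(t)):
        wt = t[j - ell + 1:j + 1]
        for i in range(ell - 1, len(x)):
            out[(j, i)] = hamming(wt, x[i - ell + 1:i + 1])
    return out


def hamming_flasm(t: str, x: str, ell: int, k: int) -> set[tuple[int, int, int]]:
    return {(j, i, e) for (j, i), e in hamming_distance_map(t, x, ell).items()
            if e <= k}


def edit_distance_map(t: str, x: str, ell: int) -> dict[tuple[int, int], int]:
    """(j, i) -> min over starts s <= j of edit(t[s..j], factor ending at i).

    Semi-global DP with a free text start: first row pinned to zero.
    """
    out = {}
    for i in range(ell - 1, len(x)):
        fac = x[i - ell + 1:i + 1]
        prev = list(range(ell + 1))  # column for the empty text prefix
        for j in range(1, len(t) + 1):
            cur = [0] * (ell + 1)
            for r in range(1, ell + 1):
                cur[r] = min(prev[r - 1] + (fac[r - 1] != t[j - 1]),
                             prev[r] + 1, cur[r - 1] + 1)
            out[(j - 1, i)] = cur[ell]
            prev = cur
    return out


def edit_flasm(t: str, x: str, ell: int, k: int) -> set[tuple[int, int, int]]:
    return {(j, i, e) for (j, i), e in edit_distance_map(t, x, ell).items()
            if e <= k}


def semi_global_edit_ends(t: str, p: str) -> dict[int, int]:
    """j -> min over starts of edit(t[s..j], p)."""
    return {j: e for (j, _), e in edit_distance_map(t, p, len(p)).items()}


def acsm_per_rotation(t: str, x: str, k: int, model: str) -> dict[int, int]:
    """j -> minimal distance over all rotations of x (entries <= k only)."""
    m = len(x)
    best: dict[int, int] = {}
    for r in range(m):
        rot = x[r:] + x[:r]
        if model == "hamming":
            dist = {j: hamming(t[j - m + 1:j + 1], rot)
                    for j in range(m - 1, len(t))}
        else:
            dist = semi_global_edit_ends(t, rot)
        for j, e in dist.items():
            if e <= k and e < best.get(j, k + 1):
                best[j] = e
    return best


def qgram_index_naive(x: str, q: int, alphabet: str, model: str) -> list[int]:
    """Pure-python minimal q-gram distances, capped at q."""
    import itertools
    out = []
    windows = [x[i:i + q] for i in range(len(x) - q + 1)]
    for gram in itertools.product(alphabet, repeat=q):
        g = "".join(gram)
        if model == "hamming":
            d = min(hamming(g, w) for w in windows)
        else:
            d = min(min(semi_global_edit_ends(x, g).values()), q)
        out.append(min(d, q))
    return out


def k_occurs(motif: str, seq: str, k: int, model: str) -> bool:
    ell = len(motif)
    if model == "hamming":
        return any(hamming(motif, seq[p:p + ell]) <= k
                   for p in range(len(seq) - ell + 1))
    return any(e <= k for e in semi_global_edit_ends(seq, motif).values())


def single_motifs_brute(seqs: list[str], ell: int, k: int, quorum: int,
                        model: str) -> dict[str, int]:
    """motif string -> number of sequences with a k-occurrence, for every
    distinct factor reaching the quorum."""
    factors = {s[p:p + ell] for s in seqs for p in range(len(s) - ell + 1)}
    out = {}
    for f in sorted(factors):
        count = sum(k_occurs(f, s, k, model) for s in seqs)
        if count >= quorum:
            out[f] = count
    return out


def _chain_exists(lists: list[list[tuple[int, int]]],
                  gaps: list[tuple[int, int]]) -> bool:
    ends = [e for _, e in lists[0]]
    for (dmin, dmax), occs in zip(gaps, lists[1:]):
        nxt = [e for s, e in occs
               if any(pe + dmin + 1 <= s <= pe + dmax + 1 for pe in ends)]
        ends = nxt
        if not ends:
            return False
    return bool(ends)


def _occ_intervals(box: str, seq: str, k: int, model: str) -> list[tuple[int, int]]:
    ell = len(box)
    out = []
    if model == "hamming":
        for p in range(len(seq) - ell + 1):
            if hamming(box, seq[p:p + ell]) <= k:
                out.append((p, p + ell - 1))
    else:
        for j, e in semi_global_edit_ends(seq, box).items():
            if e <= k:
                # smallest start attaining the minimum for this end
                best = None
                for s in range(j + 1):
                    d = edit(seq[s:j + 1], box)
                    if best is None or d < best[0]:
                        best = (d, s)
                out.append((best[1], j))
    return sorted(out)


def structured_motifs_brute(seqs: list[str], boxes: list[tuple[int, int]],
                            gaps: list[tuple[int, int]], quorum: int,
                            model: str) -> dict[tuple[str, ...], int]:
    """Exhaustive structured extraction: every chain of factor positions in
    every source sequence with compliant source gaps is a candidate; count
    sequences holding a k_i-occurrence chain."""
    candidates: set[tuple[str, ...]] = set()
    for s in seqs:
        def extend(chain_pos: list[int], b: int) -> None:
            if b == len(boxes):
                candidates.add(tuple(
                    s[p:p + ell] for p, (ell, _) in zip(chain_pos, boxes)))
                return
            if b == 0:
                lo, hi = 0, len(s) - boxes[0][0]
                rng = range(lo, hi + 1)
            else:
                end_prev = chain_pos[-1] + boxes[b - 1][0] - 1
                dmin, dmax = gaps[b - 1]
                rng = range(end_prev + dmin + 1, end_prev + dmax + 2)
            for p in rng:
                if 0 <= p and p + boxes[b][0] <= len(s):
                    extend(chain_pos + [p], b + 1)
        extend([], 0)
    out = {}
    for cand in sorted(candidates):
        count = 0
        for s in seqs:
            lists = [_occ_intervals(box, s, k, model)
                     for box, (_, k) in zip(cand, boxes)]
            if all(lists) and _chain_exists(lists, gaps):
                count += 1
        if count >= quorum:
            out[cand] = count
    return out
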