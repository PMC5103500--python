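"""Seeded generators for synthetic test data.

Everything here is a pure function of its parameters and a seed: uniform
random DNA backgrounds, implantation of single or structured motifs with a
controlled number of substitutions per copy, and (in
:func:`flasm.rotation.random_rotate`) random rotations.  Implantation
returns the ground truth — canonical motif, per-copy corrupted strings, box
positions and sampled gaps — so recovery tests can assert exact recall.

Corruption is substitution-only: each implanted copy differs from the
canonical motif by an exact, stated number of substitutions, keeping
ground-truth positions valid under both distance models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FlasmError
from .motifs import StructuredMotifSpec

_DNA = "ACGT"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_dna(n: int, seed) -> str:
    """Uniform random DNA string of length ``n`` (seed-deterministic)."""
    if n < 0:
        raise FlasmError(f"length must be non-negative, got {n}")
    rng = _rng(seed)
    return "".join(np.array(list(_DNA))[rng.integers(0, 4, size=n)])


def random_sequences(count: int, length: int, seed) -> list[str]:
    """``count`` independent uniform DNA strings of the given length."""
    rng = _rng(seed)
    return [random_dna(length, rng) for _ in range(count)]


@dataclass(frozen=True)
class ImplantPlan:
    """What to implant and where.

    ``spec`` is either a single-motif length (int) or a
    :class:`~flasm.motifs.StructuredMotifSpec`; ``targets`` lists the
    sequence indices receiving one copy each; ``corruption`` gives the exact
    number of substitutions applied per box per copy (a single int for a
    single motif).  Gap lengths are sampled uniformly within each interval,
    independently per copy.
    """

    spec: "StructuredMotifSpec | int"
    targets: tuple[int, ...]
    corruption: tuple[int, ...]
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.spec, int):
            boxes = ((self.spec, self.spec - 1),)
        else:
            boxes = self.spec.boxes
        if len(self.corruption) != len(boxes):
            raise FlasmError(f"{len(boxes)} boxes need {len(boxes)} corruption "
                             f"counts, got {len(self.corruption)}")
        for c, (ell, _) in zip(self.corruption, boxes):
            if not 0 <= c < ell:
                raise FlasmError(f"corruption {c} must be in [0, box length {ell})")


@dataclass(frozen=True)
class ImplantRecord:
    """Ground truth for one implanted copy."""

    seq_index: int
    box_starts: tuple[int, ...]
    gaps: tuple[int, ...]
    boxes: tuple[str, ...]            # implanted (corrupted) box strings
    canonical_boxes: tuple[str, ...]  # uncorrupted motif boxes


def _substitute(s: str, count: int, rng: np.random.Generator) -> str:
    """Exactly ``count`` substitutions at distinct positions, each to a
    different letter (the result is at Hamming distance exactly ``count``)."""
    if count == 0:
        return s
    pos = rng.choice(len(s), size=count, replace=False)
    out = list(s)
    for p in pos:
        out[p] = rng.choice([c for c in _DNA if c != out[p]])
    return "".join(out)


def implant(seqs: list[str], plan: ImplantPlan
            ) -> tuple[list[str], list[ImplantRecord]]:
    """Implant one motif copy into each target sequence.

    A single canonical motif is sampled once; each target receives a copy
    with the plan's per-box substitution counts, at a uniformly chosen
    position where the boxes plus sampled gaps fit.  Spacer letters are left
    as background.  Returns the mutated sequences (input order preserved)
    and the ground-truth records.
    """
    rng = _rng(plan.seed)
    if isinstance(plan.spec, int):
        box_lens: tuple[int, ...] = (plan.spec,)
        gap_ivals: tuple[tuple[int, int], ...] = ()
    else:
        box_lens = tuple(ell for ell, _ in plan.spec.boxes)
        gap_ivals = plan.spec.gaps
    canonical = tuple(random_dna(ell, rng) for ell in box_lens)

    out = [s.upper() for s in seqs]
    truth: list[ImplantRecord] = []
    for tgt in plan.targets:
        if not 0 <= tgt < len(seqs):
            raise FlasmError(f"target index {tgt} out of range")
        gaps = tuple(int(rng.integers(dmin, dmax + 1)) for dmin, dmax in gap_ivals)
        span = sum(box_lens) + sum(gaps)
        if span > len(out[tgt]):
            raise FlasmError(f"motif span {span} exceeds sequence {tgt} "
                             f"length {len(out[tgt])}")
        start0 = int(rng.integers(0, len(out[tgt]) - span + 1))
        starts = []
        pos = start0
        copies = []
        s = list(out[tgt])
        for b, ell in enumerate(box_lens):
            copy = _substitute(canonical[b], plan.corruption[b], rng)
            copies.append(copy)
            starts.append(pos)
            s[pos:pos + ell] = copy
            pos += ell + (gaps[b] if b < len(gaps) else 0)
        out[tgt] = "".join(s)
        truth.append(ImplantRecord(tgt, tuple(starts), gaps,
                                   tuple(copies), canonical))
    return out, truth
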