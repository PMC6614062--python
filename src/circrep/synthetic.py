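"""Synthetic circular genomes with planted repeats of known structure.

The generator exists so every stage of the caller can be exercised offline
with unambiguous ground truth: random i.i.d. backgrounds with a controlled
GC fraction, repeats of any class planted at chosen positions with chosen
non-tandem mismatch sets, and rejection-sampled seed-free backgrounds for
false-discovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .finder import RepeatPair, find_seeds
from .genome_io import CircularGenome, Interval, RepeatClass, transform

_BASES = np.array(list("ACGT"))
_NOT = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


@dataclass(frozen=True)
class PlantSpec:
    """A repeat to write into a background genome.

    ``mismatch_offsets`` are positions (within the arm, 0-based) where the
    second arm will be corrupted; they must be non-adjacent and at most
    length/5 of them are allowed, mirroring the caller's constraints.
    """

    repeat_class: RepeatClass
    length: int
    arm1_start: int
    arm2_start: int
    mismatch_offsets: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length < 10:
            raise ValueError("planted repeats must be >= 10 bp")
        offs = sorted(self.mismatch_offsets)
        if any(o < 0 or o >= self.length for o in offs):
            raise ValueError("mismatch offset outside the arm")
        if any(b - a == 1 for a, b in zip(offs, offs[1:])):
            raise ValueError("tandem (adjacent) mismatches are not allowed")
        if len(offs) > self.length // 5:
            raise ValueError("planted degeneracy above 20%")


def random_genome(
    length: int, gc: float = 0.5, rng_seed: int = 0, genome_id: str = "synthetic"
) -> CircularGenome:
    """I.i.d. random circular genome with P(G)+P(C) = *gc* (A/T and G/C
    symmetric within each pair, i.e. zero AT and GC skew)."""
    if length < 50:
        raise ValueError("length must be >= 50")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return CircularGenome(id=genome_id, seq=seq)


def plant(
    g: CircularGenome, spec: PlantSpec, rng_seed: int = 0
) -> tuple[CircularGenome, RepeatPair]:
    """Write a repeat into *g*; return the modified genome and ground truth.

    Arm 1 keeps the background sequence at ``arm1_start``; arm 2 is the
    class transform of arm 1, corrupted at ``mismatch_offsets`` (offsets
    counted along arm 1) with random non-matching bases.
    """
    L = g.length
    arm1 = Interval.from_span(spec.arm1_start, spec.length, L)
    arm2 = Interval.from_span(spec.arm2_start, spec.length, L)
    if arm1.overlaps(arm2, L):
        raise ValueError("planted arms overlap")
    rng = np.random.default_rng(rng_seed)
    seq = list(g.seq)
    arm1_seq = "".join(seq[p] for p in arm1.positions(L))
    arm2_seq = list(transform(arm1_seq, spec.repeat_class))
    for off in spec.mismatch_offsets:
        # offset along arm1 maps to the same or the reflected offset in arm2
        if spec.repeat_class in (RepeatClass.MIRROR, RepeatClass.INVERTED):
            pos2 = spec.length - 1 - off
        else:
            pos2 = off
        good = arm2_seq[pos2]
        arm2_seq[pos2] = rng.choice(_NOT[good])
    for p, b in zip(arm2.positions(L), arm2_seq):
        seq[p] = b
    truth = RepeatPair(
        spec.repeat_class, arm1, arm2, spec.length, frozenset(spec.mismatch_offsets)
    )
    mutated = CircularGenome(id=g.id, seq="".join(seq), genes=list(g.genes))
    return mutated, truth


def repeat_free_background(
    length: int = 200,
    gc: float = 0.5,
    rng_seed: int = 0,
    max_tries: int = 2000,
) -> CircularGenome:
    """Rejection-sample a background in which stage I finds no seed of any
    class, guaranteeing the caller must return nothing on it.

    Chance 10/1-window matches are common already at a few hundred bp and
    essentially certain at 1 kb, so seed-free backgrounds are only
    practical at short lengths (~150-250 bp).
    """
    for t in range(max_tries):
        g = random_genome(length, gc, rng_seed + t, genome_id=f"bg{rng_seed}")
        if all(not find_seeds(g, c) for c in RepeatClass):
            return g
    raise RuntimeError(
        f"no seed-free background of length {length} found in {max_tries} tries"
    )
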