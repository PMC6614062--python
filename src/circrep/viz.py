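"""Arc-diagram visualization with probabilistic arm linking.

Drawing every arm pair of every repeat is unreadable at mitochondrial
repeat densities, so arcs are thinned stochastically: an arc between two
arm midpoints at circular distance d is retained with probability
proportional to an exponential density with mean L/16, truncated to
[0, L/2] (on a circle, two points half a genome apart are maximally
distant).  Close arm pairs are almost always drawn, pairs half a genome
apart essentially never.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotate import midpoint
from .finder import RepeatPair
from .genome_io import CircularGenome, RepeatClass


@dataclass(frozen=True)
class Arc:
    pos1: int
    pos2: int
    repeat_class: RepeatClass
    weight: float


@dataclass
class ArcSet:
    genome_id: str
    length: int
    arcs: list[Arc]
    rng_seed: int


def _circular_distance(a: int, b: int, L: int) -> int:
    d = (b - a) % L
    return min(d, L - d)


def link_probability(distance: float, L: int) -> float:
    """Density at *distance* of Exp(mean = L/16) truncated to [0, L/2].

    The density integrates to 1 over [0, L/2]; its maximum is at 0 and
    density(L/16)/density(0) = exp(-1).
    """
    if distance < 0 or distance > L / 2:
        raise ValueError("distance outside [0, L/2]")
    mean = L / 16.0
    norm = 1.0 - math.exp(-(L / 2.0) / mean)  # = 1 - e^-8
    return math.exp(-distance / mean) / mean / norm


def retention_probability(distance: float, L: int) -> float:
    """Bernoulli retention probability: density(d)/density(0) = e^(-16 d/L)."""
    return link_probability(distance, L) / link_probability(0.0, L)


def sample_arcs(
    repeats: list[RepeatPair], g: CircularGenome, rng_seed: int = 0
) -> ArcSet:
    """Draw retained arcs between arm midpoints, deterministically per seed.

    For each repeat the candidate arcs are the three named inter-arm
    distances (minimal, maximal, and between the most similar arms); with
    exactly two arms per repeat these coincide, so one candidate is drawn
    per repeat.  Each candidate is kept with the Bernoulli retention
    probability for its circular midpoint distance.
    """
    rng = np.random.default_rng(rng_seed)
    L = g.length
    arcs: list[Arc] = []
    for rp in repeats:
        m1 = midpoint(rp.arm1, L)
        m2 = midpoint(rp.arm2, L)
        candidates = {(m1, m2)}  # min-, max- and best-similarity distances coincide
        for p1, p2 in sorted(candidates):
            d = _circular_distance(p1, p2, L)
            w = retention_probability(float(d), L)
            if rng.random() < w:
                arcs.append(Arc(p1, p2, rp.repeat_class, w))
    return ArcSet(genome_id=g.id, length=L, arcs=arcs, rng_seed=rng_seed)


_CLASS_COLORS = {
    RepeatClass.DIRECT: "#1f77b4",
    RepeatClass.INVERTED: "#d62728",
    RepeatClass.MIRROR: "#2ca02c",
    RepeatClass.COMPLEMENTARY: "#9467bd",
}


def plot_arcs(arcset: ArcSet, path: str | Path, title: str | None = None) -> Path:
    """Render the arc set around a genome circle to SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    L = arcset.length
    fig, ax = plt.subplots(figsize=(7, 7))
    theta = np.linspace(0, 2 * math.pi, 512)
    ax.plot(np.cos(theta), np.sin(theta), color="0.6", lw=1.2)
    for arc in arcset.arcs:
        t1 = 2 * math.pi * arc.pos1 / L
        t2 = 2 * math.pi * arc.pos2 / L
        p1 = np.array([math.cos(t1), math.sin(t1)])
        p2 = np.array([math.cos(t2), math.sin(t2)])
        # quadratic Bezier through the circle center side
        ctrl = (p1 + p2) / 4.0
        ts = np.linspace(0, 1, 64)[:, None]
        curve = (1 - ts) ** 2 * p1 + 2 * ts * (1 - ts) * ctrl + ts**2 * p2
        ax.plot(
            curve[:, 0],
            curve[:, 1],
            color=_CLASS_COLORS[arc.repeat_class],
            lw=0.6,
            alpha=0.5,
        )
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    handles = [
        plt.Line2D([0], [0], color=c, lw=2, label=cls.value)
        for cls, c in _CLASS_COLORS.items()
    ]
    ax.legend(handles=handles, loc="upper right", fontsize=8)
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
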