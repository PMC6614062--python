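"""Abundance metrics and the statistical analyses around the repeat calls.

Three analyses: (i) per-genome abundance (per-class counts, bp covered by
the union of arms, and the mean number of repeats overlapping a nucleotide);
(ii) correlations between repeat midpoint density and the physico-chemical
feature tracks within a genome; (iii) across genomes, the 5x5 rank
correlation matrix of {GC content, per-class bp covered} and the
complementary-dinucleotide pair tests (mean ratio, Cohen's d, two-sided
Mann-Whitney U) on dinucleotide frequencies inside repeat-covered regions
of the light (GenBank-deposited) strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import DINUCLEOTIDES, MidpointProfile
from .finder import RepeatPair
from .genome_io import CircularGenome, RepeatClass

#: complementary dinucleotide pairs, ordered numerator/denominator so the
#: strand-skew-driven ratios come out above one on the light strand
COMPLEMENTARY_DINUC_PAIRS = [
    ("CA", "GT"),
    ("CC", "GG"),
    ("AC", "TG"),
    ("CT", "GA"),
    ("AA", "TT"),
    ("TC", "AG"),
    ("GC", "CG"),
    ("TA", "AT"),
]


@dataclass
class AbundanceMetrics:
    """Per-genome repeat abundance summary."""

    genome_id: str
    length: int
    counts: dict[RepeatClass, int]
    bp_covered: dict[RepeatClass, int]
    mean_overlap_density: float
    genome_gc_pct: float


@dataclass(frozen=True)
class DinucPairStat:
    """One complementary-dinucleotide comparison across genomes."""

    pair: str
    ratio: float
    cohen_d: float
    u_p: float


def _class_coverage(repeats: list[RepeatPair], repeat_class: RepeatClass, L: int) -> int:
    covered = np.zeros(L, dtype=bool)
    for rp in repeats:
        if rp.repeat_class is not repeat_class:
            continue
        for arm in (rp.arm1, rp.arm2):
            for p in arm.positions(L):
                covered[p] = True
    return int(covered.sum())


def abundance(repeats: list[RepeatPair], g: CircularGenome) -> AbundanceMetrics:
    """Counts, union bp covered per class, and mean overlap density.

    Mean overlap density is the average over all genome positions of the
    number of repeat arms covering that position — "the number of repeats
    overlapping an average nucleotide".
    """
    L = g.length
    counts = {c: 0 for c in RepeatClass}
    total_arm_bp = 0
    for rp in repeats:
        counts[rp.repeat_class] += 1
        total_arm_bp += 2 * rp.length
    bp_covered = {c: _class_coverage(repeats, c, L) for c in RepeatClass}
    gc = 100.0 * (g.seq.count("G") + g.seq.count("C")) / L
    return AbundanceMetrics(
        genome_id=g.id,
        length=L,
        counts=counts,
        bp_covered=bp_covered,
        mean_overlap_density=total_arm_bp / L,
        genome_gc_pct=gc,
    )


def density_feature_correlation(profile: MidpointProfile) -> pd.DataFrame:
    """Pearson and Spearman correlation of midpoint density against each
    feature track, over positions with nonzero midpoint density.

    Degenerate (constant) inputs yield NaN coefficients with the reason in
    the ``note`` column.
    """
    mask = profile.midpoint_density > 0
    if mask.sum() < 3:
        raise ValueError("need >= 3 positions with nonzero midpoint density")
    dens = profile.midpoint_density[mask]
    rows = []
    for name, track in sorted(profile.feature_tracks.items()):
        vals = track[mask]
        note = ""
        if np.all(dens == dens[0]) or np.all(vals == vals[0]):
            r = rho = p_r = p_rho = float("nan")
            note = "constant input; correlation undefined"
        else:
            r, p_r = sps.pearsonr(dens, vals)
            rho, p_rho = sps.spearmanr(dens, vals)
        rows.append(
            {
                "feature": name,
                "pearson_r": r,
                "pearson_p": p_r,
                "spearman_rho": rho,
                "spearman_p": p_rho,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


_MATRIX_VARS = ["gc_pct", "direct_bp", "complementary_bp", "mirror_bp", "inverted_bp"]


def cross_genome_correlation(metrics: list[AbundanceMetrics]) -> pd.DataFrame:
    """5x5 matrix over {GC%, per-class bp covered}: Spearman rho above the
    diagonal, p-values below, NaN on the diagonal."""
    if len(metrics) < 5:
        raise ValueError("need >= 5 genomes")
    data = pd.DataFrame(
        {
            "gc_pct": [m.genome_gc_pct for m in metrics],
            "direct_bp": [m.bp_covered[RepeatClass.DIRECT] for m in metrics],
            "complementary_bp": [m.bp_covered[RepeatClass.COMPLEMENTARY] for m in metrics],
            "mirror_bp": [m.bp_covered[RepeatClass.MIRROR] for m in metrics],
            "inverted_bp": [m.bp_covered[RepeatClass.INVERTED] for m in metrics],
        }
    )
    out = pd.DataFrame(
        np.full((5, 5), np.nan), index=_MATRIX_VARS, columns=_MATRIX_VARS
    )
    for i, a in enumerate(_MATRIX_VARS):
        for j, b in enumerate(_MATRIX_VARS):
            if i == j:
                continue
            rho, p = sps.spearmanr(data[a], data[b])
            if i < j:
                out.iloc[i, j] = rho
            else:
                out.iloc[i, j] = p
    return out


def cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-standard-deviation effect size."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    pooled = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def dinuc_pair_test(samples_a, samples_b, pair: str = "") -> DinucPairStat:
    """Compare two per-genome frequency samples: mean ratio, Cohen's d and
    a two-sided Mann-Whitney U p-value (exact for small untied samples,
    normal approximation with tie correction otherwise)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired sample lists must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 genomes per sample")
    if b.mean() == 0:
        raise ValueError("denominator sample has zero mean; ratio undefined")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 20 and not has_ties) else "asymptotic"
    u = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return DinucPairStat(
        pair=pair,
        ratio=float(a.mean() / b.mean()),
        cohen_d=cohen_d(a, b),
        u_p=float(u.pvalue),
    )


def dinuc_frequencies_in_repeats(
    repeats: list[RepeatPair], g: CircularGenome
) -> dict[str, float]:
    """Overlapping-dinucleotide frequencies over the union of repeat arms.

    Counted on the forward (light) strand; a dinucleotide position is in
    the region when both of its bases are repeat-covered; N-containing
    steps are excluded from the denominator.
    """
    L = g.length
    covered = np.zeros(L, dtype=bool)
    for rp in repeats:
        for arm in (rp.arm1, rp.arm2):
            for p in arm.positions(L):
                covered[p] = True
    counts = {dn: 0 for dn in DINUCLEOTIDES}
    total = 0
    for p in range(L):
        q = (p + 1) % L
        if not (covered[p] and covered[q]):
            continue
        dn = g.seq[p] + g.seq[q]
        if dn in counts:
            counts[dn] += 1
            total += 1
    if total == 0:
        return {dn: 0.0 for dn in DINUCLEOTIDES}
    return {dn: c / total for dn, c in counts.items()}


def dinuc_pair_table(freqs_per_genome: list[dict[str, float]]) -> pd.DataFrame:
    """Table of the eight complementary-dinucleotide comparisons across a
    genome collection, with the significance band annotation (``**`` for
    p < 1e-10, ``*`` for 1e-10 <= p < 1e-5)."""
    rows = []
    for num, den in COMPLEMENTARY_DINUC_PAIRS:
        a = [f[num] for f in freqs_per_genome]
        b = [f[den] for f in freqs_per_genome]
        st = dinuc_pair_test(a, b, pair=f"{num}/{den}")
        band = "**" if st.u_p < 1e-10 else ("*" if st.u_p < 1e-5 else "")
        rows.append(
            {
                "pair": st.pair,
                "ratio": st.ratio,
                "cohen_d": st.cohen_d,
                "u_p": st.u_p,
                "significance": band,
            }
        )
    return pd.DataFrame(rows)
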