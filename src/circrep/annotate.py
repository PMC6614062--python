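"""Midpoint tracks and per-arm physico-chemical features.

Each repeat arm is assigned a single genome position — its midpoint,
``Sgp + floor((Egp - Sgp)/2)`` over start/end genome positions — and the
arm's physico-chemical feature bundle is averaged over all arms sharing a
midpoint, yielding per-nucleotide genome tracks (midpoint density, repeat
overlap density, and one track per feature).

Feature definitions follow the classical B-DNA per-dinucleotide tables:

* helical twist per dinucleotide step (degrees), Kabsch, Sander & Trifonov
  (1982) B-DNA values; total twist, turns (= twist/360) and bases per turn
  derive from it;
* base-stacking energy per dinucleotide step (kcal/mol), Ornstein et al.
  (1978);
* duplex-formation thermodynamics (dH kcal/mol, dS cal/(mol K)) by
  nearest-neighbor summation with the Breslauer et al. (1986) parameter
  set; dG at 25 C; melting temperature by the standard nearest-neighbor
  formula with 50 nM DNA and 50 mM Na+ defaults.

Energies are stored with their thermodynamic sign (formation is negative);
track output flips dG/dH/dS and stacking to positive magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .finder import RepeatPair
from .genome_io import CircularGenome, Interval, write_gff3, write_wig

# B-DNA helical twist per dinucleotide step, degrees
TWIST_DEG = {
    "AA": 35.62, "AC": 34.4, "AG": 27.7, "AT": 31.5,
    "CA": 34.5, "CC": 33.67, "CG": 29.8, "CT": 27.7,
    "GA": 36.9, "GC": 40.0, "GG": 33.67, "GT": 34.4,
    "TA": 36.0, "TC": 36.9, "TG": 34.5, "TT": 35.62,
}

# base-stacking energy per dinucleotide step, kcal/mol (negative = stabilizing)
STACKING_KCAL = {
    "AA": -5.37, "AC": -10.51, "AG": -6.78, "AT": -6.57,
    "CA": -6.57, "CC": -8.26, "CG": -9.69, "CT": -6.78,
    "GA": -9.81, "GC": -14.59, "GG": -8.26, "GT": -10.51,
    "TA": -3.82, "TC": -9.81, "TG": -6.57, "TT": -5.37,
}

# nearest-neighbor duplex formation: (dH kcal/mol, dS cal/(mol K)),
# magnitudes of the exothermic formation reaction
NN_DH_DS = {
    "AA": (9.1, 24.0), "TT": (9.1, 24.0),
    "AT": (8.6, 23.9),
    "TA": (6.0, 16.9),
    "CA": (5.8, 12.9), "TG": (5.8, 12.9),
    "GT": (6.5, 17.3), "AC": (6.5, 17.3),
    "CT": (7.8, 20.8), "AG": (7.8, 20.8),
    "GA": (5.6, 13.5), "TC": (5.6, 13.5),
    "CG": (11.9, 27.8),
    "GC": (11.1, 26.7),
    "GG": (11.0, 26.6), "CC": (11.0, 26.6),
}

#: defaults of the nearest-neighbor melting-temperature formula
DNA_CONC_NM = 50.0   # total strand concentration, nanomolar
SALT_CONC_M = 0.05   # monovalent cation concentration, molar
_R = 1.987           # gas constant, cal/(mol K)
_T_REF = 298.15      # dG reference temperature, K (25 C)

DINUCLEOTIDES = ["".join(p) for p in product("ACGT", repeat=2)]

#: feature tracks whose sign is flipped (reported as positive magnitudes)
NEGATED_TRACKS = {"dG", "dH", "dS", "stack_total", "stack_per_dinuc"}


@dataclass(frozen=True)
class PhysChem:
    """Per-arm feature bundle."""

    gc_pct: float
    tm: float
    dG: float
    dH: float
    dS: float
    stack_total: float
    stack_per_dinuc: float
    twist_total: float
    turns: float
    bases_per_turn: float
    dinuc_frac: dict[str, float] = field(hash=False, default_factory=dict)

    def as_track_values(self) -> dict[str, float]:
        """Scalar features keyed by track name, with the sign convention
        used for track output (energies as positive magnitudes)."""
        vals = {
            "gc_pct": self.gc_pct,
            "tm": self.tm,
            "dG": self.dG,
            "dH": self.dH,
            "dS": self.dS,
            "stack_total": self.stack_total,
            "stack_per_dinuc": self.stack_per_dinuc,
            "twist_total": self.twist_total,
            "turns": self.turns,
            "bases_per_turn": self.bases_per_turn,
        }
        for k in NEGATED_TRACKS:
            vals[k] = -vals[k]
        for dn in DINUCLEOTIDES:
            vals[f"dinuc_{dn}"] = self.dinuc_frac.get(dn, 0.0)
        return vals


def midpoint(arm: Interval, length: int) -> int:
    """Arm midpoint: Sgp + floor((Egp - Sgp)/2), reduced modulo L for
    wrapping arms.  Egp is the last covered position (inclusive)."""
    span = arm.span(length)
    return (arm.start + (span - 1) // 2) % length


def physchem(seq: str) -> PhysChem:
    """Compute the feature bundle for one arm sequence.

    Dinucleotide steps containing N are skipped and denominators adjusted.
    """
    if len(seq) < 2:
        raise ValueError("physico-chemical features need at least 2 bases")
    seq = seq.upper()
    n = len(seq)
    gc_pct = 100.0 * (seq.count("G") + seq.count("C")) / n

    steps = [seq[i : i + 2] for i in range(n - 1)]
    valid = [s for s in steps if s in TWIST_DEG]
    n_steps = len(valid)

    twist_total = sum(TWIST_DEG[s] for s in valid)
    turns = twist_total / 360.0
    bases_per_turn = 360.0 * n / twist_total if twist_total else float("nan")

    stack_total = sum(STACKING_KCAL[s] for s in valid)
    stack_per_dinuc = stack_total / n_steps if n_steps else float("nan")

    dh_mag = sum(NN_DH_DS[s][0] for s in valid)
    ds_mag = sum(NN_DH_DS[s][1] for s in valid)
    dH = -dh_mag                    # kcal/mol
    dS = -ds_mag / 1000.0           # kcal/(mol K)
    dG = dH - _T_REF * dS           # kcal/mol at 25 C
    if n_steps and ds_mag:
        denom = -ds_mag + _R * math.log(DNA_CONC_NM * 1e-9 / 4.0)
        tm = (1000.0 * -dh_mag) / denom - 273.15 + 16.6 * math.log10(SALT_CONC_M)
    else:
        tm = float("nan")

    counts = {dn: 0 for dn in DINUCLEOTIDES}
    for s in valid:
        counts[s] += 1
    frac = {
        dn: (counts[dn] / n_steps if n_steps else 0.0) for dn in DINUCLEOTIDES
    }
    return PhysChem(
        gc_pct=gc_pct,
        tm=tm,
        dG=dG,
        dH=dH,
        dS=dS,
        stack_total=stack_total,
        stack_per_dinuc=stack_per_dinuc,
        twist_total=twist_total,
        turns=turns,
        bases_per_turn=bases_per_turn,
        dinuc_frac=frac,
    )


@dataclass
class MidpointProfile:
    """Per-position genome tracks derived from called repeats."""

    genome_id: str
    length: int
    midpoint_density: np.ndarray
    overlap_density: np.ndarray
    feature_tracks: dict[str, np.ndarray]
    distance_min: np.ndarray
    distance_max: np.ndarray
    distance_best: np.ndarray


def _arm_distance(arm1: Interval, arm2: Interval, length: int) -> int:
    """Minimal circular distance between the closest endpoints of two arms."""
    gaps = []
    d1 = (arm2.start - arm1.end) % length
    d2 = (arm1.start - arm2.end) % length
    gaps.extend([d1, d2])
    return min(gaps)


def build_profile(repeats: list[RepeatPair], g: CircularGenome) -> MidpointProfile:
    """Midpoint density, overlap density and midpoint-averaged feature
    tracks for one genome.

    Feature values at a midpoint are unweighted arithmetic means over all
    arms sharing that midpoint; energy features carry the track sign
    convention (positive magnitudes).
    """
    L = g.length
    mp_density = np.zeros(L)
    ov_density = np.zeros(L)
    sums: dict[str, np.ndarray] = {}
    dist_sums = {"min": np.zeros(L), "max": np.zeros(L), "best": np.zeros(L)}

    for rp in repeats:
        for arm in (rp.arm1, rp.arm2):
            if arm.span(L) > L or min(arm.start, max(arm.end - 1, 0)) >= L:
                raise ValueError("repeat coordinates out of genome range")
        d = _arm_distance(rp.arm1, rp.arm2, L)
        for arm in (rp.arm1, rp.arm2):
            for p in arm.positions(L):
                ov_density[p] += 1
            mp = midpoint(arm, L)
            mp_density[mp] += 1
            arm_seq = "".join(g.seq[p] for p in arm.positions(L))
            vals = physchem(arm_seq).as_track_values()
            for name, v in vals.items():
                if name not in sums:
                    sums[name] = np.zeros(L)
                sums[name][mp] += v
            # with two arms the minimal, maximal and best-similarity
            # inter-arm distances coincide
            for key in dist_sums:
                dist_sums[key][mp] += d

    feature_tracks = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for name, total in sums.items():
            feature_tracks[name] = np.where(mp_density > 0, total / np.maximum(mp_density, 1), 0.0)
        dists = {
            k: np.where(mp_density > 0, v / np.maximum(mp_density, 1), 0.0)
            for k, v in dist_sums.items()
        }
    return MidpointProfile(
        genome_id=g.id,
        length=L,
        midpoint_density=mp_density,
        overlap_density=ov_density,
        feature_tracks=feature_tracks,
        distance_min=dists["min"],
        distance_max=dists["max"],
        distance_best=dists["best"],
    )


def write_tracks(
    profile: MidpointProfile,
    outdir: str | Path,
    repeats: list[RepeatPair] | None = None,
    genome: CircularGenome | None = None,
) -> list[Path]:
    """Write one fixed-step WIG per track (plus the repeats GFF3 when the
    repeat list and genome are given).  Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    tracks: dict[str, np.ndarray] = {
        "midpoint_density": profile.midpoint_density,
        "overlap_density": profile.overlap_density,
        "distance_min": profile.distance_min,
        "distance_max": profile.distance_max,
        "distance_best_similarity": profile.distance_best,
    }
    tracks.update(profile.feature_tracks)
    for name, values in tracks.items():
        path = outdir / f"{name}.wig"
        write_wig(values, profile.genome_id, path, name=name)
        written.append(path)
    if repeats is not None and genome is not None:
        gff = outdir / "repeats.gff3"
        write_gff3(repeats, genome, gff)
        written.append(gff)
    return written
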