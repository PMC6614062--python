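"""Two-stage dot-plot repeat finder for circular genomes.

Stage I slides a short window (default 10 bp, at most one mismatch) over
every pair of genome positions — conceptually the half of the L x L
symmetric dot-plot matrix built against one of four supplementary sequences
(copy / complement / reverse / reverse-complement), one per repeat class.
The genome is circularly extended by one window length so origin-spanning
windows are seen.

Stage II merges seeds that share the class-specific displacement key and
whose arms overlap, elongating them into maximal imperfect repeats, subject
to a global degeneracy cap (default 20%) and the no-tandem-mismatch rule
(no two adjacent mismatched positions).  Merging is run to a fixpoint per
displacement key; conceptually it operates on the doubled genome and the
results are reduced back to circular coordinates with duplicates removed.

Geometry of the displacement key: for same-direction classes (direct,
complementary) every matched position pair (p, q) of one repeat satisfies
q - p = const (mod L); for opposite-direction classes (mirror, inverted)
it satisfies p + q = const (mod L).  Seeds of one repeat therefore live on
one (anti)diagonal of the dot plot, which is what makes collinear merging
a 1-D interval problem per key.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_io import WINDOW, CircularGenome, Interval, RepeatClass

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_N = 4

#: classes whose two arms run in the same direction (diagonal key = difference)
SAME_DIRECTION = frozenset({RepeatClass.DIRECT, RepeatClass.COMPLEMENTARY})
#: classes whose arms run in opposite directions (antidiagonal key = sum)
OPPOSITE_DIRECTION = frozenset({RepeatClass.MIRROR, RepeatClass.INVERTED})
#: classes whose predicate is base equality (vs base complementarity)
_EQUALITY = frozenset({RepeatClass.DIRECT, RepeatClass.MIRROR})


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SeedHit:
    """A stage-I window match: two disjoint genome windows related by one class."""

    repeat_class: RepeatClass
    q: Interval
    t: Interval
    mismatch_offsets: frozenset[int]
    diag: int


@dataclass(frozen=True)
class RepeatPair:
    """One called repeat: two equal-span disjoint arms plus its mismatch map.

    ``mismatch_offsets`` are offsets within arm1 (in arm order) where the
    class predicate between the two arms fails.  ``degeneracy`` is the
    mismatch fraction; ``perfect`` means zero mismatches.
    """

    repeat_class: RepeatClass
    arm1: Interval
    arm2: Interval
    length: int
    mismatch_offsets: frozenset[int]

    @property
    def degeneracy(self) -> float:
        return len(self.mismatch_offsets) / self.length

    @property
    def perfect(self) -> bool:
        return not self.mismatch_offsets

    def key(self) -> tuple:
        return (
            self.repeat_class,
            self.arm1.start,
            self.arm1.end,
            self.arm1.wraps,
            self.arm2.start,
            self.arm2.end,
            self.arm2.wraps,
        )


def match_offsets(a: str, b: str, repeat_class: RepeatClass) -> set[int]:
    """Offsets where arm *a* fails the class predicate against arm *b*.

    Position i of *a* is compared against the class transform of *b*:
    its copy (direct), complement (complementary), reversal (mirror) or
    reverse-complement (inverted).  Any position involving N mismatches.
    """
    if len(a) != len(b):
        raise ValueError("arms must have equal length")
    ca = encode(a)
    cb = encode(b)
    if repeat_class in OPPOSITE_DIRECTION:
        cb = cb[::-1]
    if repeat_class not in _EQUALITY:
        cb = _COMP[cb]
    ok = (ca == cb) & (ca != _N) & (cb != _N)
    return set(np.nonzero(~ok)[0].tolist())


# ---------------------------------------------------------------------------
# stage I — seed detection
# ---------------------------------------------------------------------------

def _match_vector(code: np.ndarray, repeat_class: RepeatClass, key: int) -> np.ndarray:
    """Boolean per-position match vector for one displacement key.

    For same-direction classes ``M[p]`` compares position p with p+key;
    for opposite-direction classes it compares p with key-p (all mod L).
    """
    L = len(code)
    if repeat_class in SAME_DIRECTION:
        partner = np.roll(code, -key)
    else:
        partner = np.roll(code[::-1], (key + 1) % L)
    if repeat_class not in _EQUALITY:
        partner = _COMP[partner]
    return (code == partner) & (code != _N) & (partner != _N)


def _window_mismatches(match: np.ndarray, w: int) -> np.ndarray:
    """Circular windowed mismatch counts: mm[p] = mismatches in [p, p+w)."""
    ext = np.concatenate([match, match[: w - 1]]).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(ext)])
    return w - (cs[w:] - cs[:-w])


def find_seeds(
    g: CircularGenome,
    repeat_class: RepeatClass,
    window: int = WINDOW,
    max_mm: int = 1,
) -> list[SeedHit]:
    """Stage I: all canonical window pairs with at most *max_mm* mismatches.

    Scans the half-matrix of ordered position pairs over the circularly
    extended genome; window pairs that coincide or overlap on the circle
    are not emitted (repeats must be interspersed).  The returned ``diag``
    is (t-q) mod L for same-direction classes and (q+t) mod L for
    opposite-direction classes.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if max_mm >= window:
        raise ValueError("max_mm must be < window")
    if g.length < window:
        raise ValueError("genome shorter than window")
    L = g.length
    w = window
    code = encode(g.seq)
    seeds: list[SeedHit] = []

    if repeat_class in SAME_DIRECTION:
        for d in range(w, L // 2 + 1):
            if L - d < w:
                continue
            M = _match_vector(code, repeat_class, d)
            mm = _window_mismatches(M, w)
            starts = np.nonzero(mm <= max_mm)[0]
            if d * 2 == L:
                starts = starts[starts < d]
            for p in starts.tolist():
                q = Interval.from_span(p, w, L)
                t = Interval.from_span((p + d) % L, w, L)
                offs = frozenset(
                    k for k in range(w) if not M[(p + k) % L]
                )
                if t.start < q.start:
                    q, t = t, q
                seeds.append(
                    SeedHit(repeat_class, q, t, offs, (t.start - q.start) % L)
                )
    else:
        for s in range(L):
            M = _match_vector(code, repeat_class, s)
            mm = _window_mismatches(M, w)
            p = np.arange(L)
            q2 = (s - p - (w - 1)) % L
            delta = (q2 - p) % L
            ok = (mm <= max_mm) & (delta >= w) & (delta <= L - w) & (p < q2)
            for p0 in np.nonzero(ok)[0].tolist():
                q = Interval.from_span(p0, w, L)
                t = Interval.from_span(int(q2[p0]), w, L)
                offs = frozenset(k for k in range(w) if not M[(p0 + k) % L])
                seeds.append(SeedHit(repeat_class, q, t, offs, (q.start + t.start) % L))
    return seeds


# ---------------------------------------------------------------------------
# stage II — collinear merging
# ---------------------------------------------------------------------------

def _group_key(seed: SeedHit, L: int, w: int) -> tuple[int, int]:
    """(key, arm1_start) in the canonical per-diagonal representation.

    Same-direction: key is the smaller of the two circular displacements;
    the representative arm start is chosen so that partner = start + key.
    Opposite-direction: key is the conserved position sum of paired
    positions, q.start + t.start + w - 1 (mod L); both window starts lie on
    that antidiagonal.
    """
    if seed.repeat_class in SAME_DIRECTION:
        delta = (seed.t.start - seed.q.start) % L
        if delta <= L - delta:
            return delta, seed.q.start
        return L - delta, seed.t.start
    return (seed.q.start + seed.t.start + w - 1) % L, seed.q.start


def _chains(starts: list[int], w: int, L: int) -> list[list[int]]:
    """Split sorted window starts into chains of transitively overlapping
    windows on the circle.  A wrapping chain is unwrapped by adding L to its
    leading part; a chain covering the whole circle is returned doubled so
    candidate intervals may cross any point (capped later by arm
    disjointness)."""
    starts = sorted(set(starts))
    if not starts:
        return []
    breaks = [
        i + 1
        for i in range(len(starts) - 1)
        if starts[i + 1] - starts[i] > w - 1
    ]
    wrap_linked = (starts[0] + L) - starts[-1] <= w - 1
    if not breaks:
        if wrap_linked and len(starts) > 1:
            # full-circle chain: double it so intervals may cross anywhere
            return [starts + [s + L for s in starts]]
        return [starts]
    chains = [starts[a:b] for a, b in zip([0] + breaks, breaks + [len(starts)])]
    if wrap_linked and len(chains) > 1:
        last = chains.pop()
        chains[0] = last + [s + L for s in chains[0]]
    return chains


def _arm2_interval(
    repeat_class: RepeatClass, start: int, span: int, key: int, L: int
) -> Interval:
    if repeat_class in SAME_DIRECTION:
        return Interval.from_span((start + key) % L, span, L)
    return Interval.from_span((key - (start + span - 1)) % L, span, L)


def _canonical_pair(
    repeat_class: RepeatClass,
    arm1: Interval,
    arm2: Interval,
    offsets: frozenset[int],
    span: int,
) -> tuple[Interval, Interval, frozenset[int]]:
    """Arm with the smaller start becomes arm1; offsets follow arm order."""
    if arm2.start < arm1.start:
        if repeat_class in OPPOSITE_DIRECTION:
            offsets = frozenset(span - 1 - k for k in offsets)
        arm1, arm2 = arm2, arm1
    return arm1, arm2, offsets


def merge_seeds(
    seeds: Sequence[SeedHit],
    g: CircularGenome,
    max_degeneracy: float = 0.2,
    window: int = WINDOW,
) -> list[RepeatPair]:
    """Stage II: elongate overlapping collinear seeds into maximal repeats.

    Seeds are grouped by displacement key; within a key, runs of mutually
    overlapping windows are extended into the longest intervals that keep
    degeneracy <= *max_degeneracy*, contain no adjacent mismatches, and
    keep the two arms disjoint on the circle.  Repeats are reported with
    terminal mismatches trimmed (a repeat neither starts nor ends on a
    mismatched position), which is what lets an unextendable exact core
    stay a perfect repeat.  Non-maximal (contained) repeats on the same
    key are dropped; output is deduplicated as unordered arm pairs in
    circular coordinates.
    """
    if not seeds:
        return []
    classes = {s.repeat_class for s in seeds}
    if len(classes) > 1:
        raise ValueError("seeds from mixed repeat classes")
    repeat_class = classes.pop()
    L = g.length
    w = window
    code = encode(g.seq)
    eps = 1e-12

    groups: dict[int, set[int]] = {}
    for sd in seeds:
        key, p = _group_key(sd, L, w)
        groups.setdefault(key, set()).add(p)
        if repeat_class in OPPOSITE_DIRECTION:
            groups[key].add(sd.t.start)

    out: dict[tuple, RepeatPair] = {}
    for key, startset in sorted(groups.items()):
        M = _match_vector(code, repeat_class, key)
        max_span = min(key, L - key) if repeat_class in SAME_DIRECTION else L // 2
        key_reps: dict[tuple, RepeatPair] = {}
        for chain in _chains(sorted(startset), w, L):
            base = chain[0]
            extent = chain[-1] + w - base
            mvals = M[(np.arange(base, base + extent)) % L]
            mism = ~mvals
            csum = np.concatenate([[0], np.cumsum(mism)])
            # starts (relative to base) of adjacent mismatch pairs
            tandem = np.nonzero(mism[:-1] & mism[1:])[0]
            candidates: list[tuple[int, int]] = []
            n = len(chain)
            for a in range(n):
                A = chain[a]
                ra = A - base
                ti = np.searchsorted(tandem, ra)
                # interval end (exclusive, relative) must not exceed this
                end_cap = tandem[ti] + 1 if ti < len(tandem) else extent
                best = None
                for b in range(a, n):
                    E = chain[b] + w
                    span = E - A
                    if span > max_span or E - base > end_cap:
                        break
                    arm1 = Interval.from_span(A % L, span, L)
                    arm2 = _arm2_interval(repeat_class, A % L, span, key, L)
                    if arm1.overlaps(arm2, L):
                        break
                    nmm = int(csum[E - base] - csum[ra])
                    if nmm <= max_degeneracy * span + eps:
                        best = E
                if best is not None:
                    candidates.append((A, best))
            # drop contained candidates (same key)
            candidates.sort()
            kept: list[tuple[int, int]] = []
            max_end = -(10 * L)
            for A, E in candidates:
                if E > max_end:
                    kept.append((A, E))
                    max_end = E
            # a repeat must not begin or end on a mismatched position:
            # trim terminal mismatches (at most one per side, since
            # mismatches are non-tandem), then re-apply the length floor
            # and containment filter
            trimmed: list[tuple[int, int]] = []
            for A, E in kept:
                if not M[A % L]:
                    A += 1
                if not M[(E - 1) % L]:
                    E -= 1
                if E - A >= w:
                    trimmed.append((A, E))
            trimmed = sorted(set(trimmed))
            max_end = -(10 * L)
            for A, E in trimmed:
                if E <= max_end:
                    continue
                max_end = E
                span = E - A
                arm1 = Interval.from_span(A % L, span, L)
                arm2 = _arm2_interval(repeat_class, A % L, span, key, L)
                offs = frozenset(
                    k for k in range(span) if not M[(A + k) % L]
                )
                arm1, arm2, offs = _canonical_pair(repeat_class, arm1, arm2, offs, span)
                rp = RepeatPair(repeat_class, arm1, arm2, span, offs)
                key_reps.setdefault(rp.key(), rp)
        for rp in _drop_contained(list(key_reps.values()), L):
            out.setdefault(rp.key(), rp)
    return sorted(out.values(), key=lambda r: (r.arm1.start, r.arm2.start, r.length))


def _drop_contained(reps: list[RepeatPair], L: int) -> list[RepeatPair]:
    """Remove repeats whose both arms are sub-intervals of a longer repeat
    (same class and displacement key); arm roles may be swapped, since a
    repeat is an unordered pair of arms."""
    kept = []
    for r in reps:
        contained = any(
            o.length > r.length
            and (
                (o.arm1.contains(r.arm1, L) and o.arm2.contains(r.arm2, L))
                or (o.arm1.contains(r.arm2, L) and o.arm2.contains(r.arm1, L))
            )
            for o in reps
            if o is not r
        )
        if not contained:
            kept.append(r)
    return kept


def call_repeats(
    g: CircularGenome,
    classes: Iterable[RepeatClass] = tuple(RepeatClass),
    window: int = WINDOW,
    max_mm: int = 1,
    max_degeneracy: float = 0.2,
) -> list[RepeatPair]:
    """Run stage I and stage II for each requested class.

    Output is deduplicated (unordered arm pairs in circular coordinates;
    no repeat contained in a longer same-class repeat on the same
    displacement key) and each repeat is flagged perfect iff its
    degeneracy is zero.
    """
    repeats: list[RepeatPair] = []
    for repeat_class in sorted(set(classes), key=lambda c: c.value):
        seeds = find_seeds(g, repeat_class, window=window, max_mm=max_mm)
        repeats.extend(
            merge_seeds(seeds, g, max_degeneracy=max_degeneracy, window=window)
        )
    return repeats
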