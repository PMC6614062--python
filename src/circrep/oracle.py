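"""Independent brute-force reference implementations, used only in tests.

Both routines re-derive repeats from first principles — per-key match
vectors built by explicit index arithmetic, candidate intervals enumerated
pairwise and validated position-by-position — sharing none of the seed/
chain machinery of :mod:`circrep.finder`.  They follow the same output
conventions (disjoint arms, per-displacement-key maximality, unordered
arm-pair deduplication) so set comparison against the finder is exact.
"""

from __future__ import annotations

import numpy as np

from .finder import (
    OPPOSITE_DIRECTION,
    SAME_DIRECTION,
    _EQUALITY,
    RepeatPair,
    encode,
)
from .genome_io import WINDOW, CircularGenome, Interval, RepeatClass

_MAX_ORACLE_LEN = 5000


def _match_array(code: np.ndarray, repeat_class: RepeatClass, key: int) -> np.ndarray:
    """Per-position match vector via fancy indexing (not the finder's rolls)."""
    L = len(code)
    p = np.arange(L)
    if repeat_class in SAME_DIRECTION:
        partner = code[(p + key) % L]
    else:
        partner = code[(key - p) % L]
    if repeat_class not in _EQUALITY:
        partner = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[partner]
    return (code == partner) & (code != 4) & (partner != 4)


def _keys(repeat_class: RepeatClass, L: int, w: int) -> list[int]:
    """Distinct displacement keys, each unordered position-pairing once.

    Same-direction: circular displacements w..L/2 (smaller of the two).
    Opposite-direction: every position-sum 0..L-1 (self-symmetric).
    """
    if repeat_class in SAME_DIRECTION:
        return list(range(w, L // 2 + 1))
    return list(range(L))


def _arm2(repeat_class: RepeatClass, A: int, span: int, key: int, L: int) -> Interval:
    if repeat_class in SAME_DIRECTION:
        return Interval.from_span((A + key) % L, span, L)
    return Interval.from_span((key - (A + span - 1)) % L, span, L)


def brute_force_repeats(
    g: CircularGenome,
    repeat_class: RepeatClass,
    min_len: int = WINDOW,
    max_degeneracy: float = 0.2,
    window: int = WINDOW,
    max_mm: int = 1,
) -> list[RepeatPair]:
    """Exhaustively enumerate maximal imperfect repeats of one class.

    For every displacement key, every interval bounded by legal seed
    windows is tested against the full constraint set (length, degeneracy,
    non-tandem mismatches, disjoint equal arms, every position covered by
    a legal seed window); maximal survivors per key are returned.
    """
    if g.length > _MAX_ORACLE_LEN:
        raise ValueError("genome too long for exhaustive enumeration")
    L = g.length
    w = window
    code = encode(g.seq)
    eps = 1e-12
    out: dict[tuple, RepeatPair] = {}
    for key in _keys(repeat_class, L, w):
        m = _match_array(code, repeat_class, key)
        mism_ext = (~np.concatenate([m, m[: w - 1]])).astype(int)
        win_mm = np.convolve(mism_ext, np.ones(w, dtype=int), mode="valid")
        starts = [int(p) for p in np.nonzero(win_mm <= max_mm)[0]]
        starts = [
            p
            for p in starts
            if not Interval.from_span(p, w, L).overlaps(_arm2(repeat_class, p, w, key, L), L)
        ]
        if not starts:
            continue
        ext = starts + [s + L for s in starts]
        k_n = len(starts)
        candidates: list[tuple[int, int]] = []
        for i in range(k_n):
            A = starts[i]
            best = None
            for j in range(i, i + k_n):
                B = ext[j]
                if j > i and ext[j] - ext[j - 1] > w - 1:
                    break  # coverage gap: not a union of overlapping windows
                E = B + w
                span = E - A
                if span > L // 2 + 1:
                    break
                arm1 = Interval.from_span(A, span, L)
                arm2 = _arm2(repeat_class, A, span, key, L)
                if arm1.overlaps(arm2, L):
                    break
                mismatch_pos = [
                    k for k in range(span) if not m[(A + k) % L]
                ]
                if any(
                    b2 - b1 == 1
                    for b1, b2 in zip(mismatch_pos, mismatch_pos[1:])
                ):
                    break  # tandem mismatch; supersets inherit it
                if span >= min_len and len(mismatch_pos) <= max_degeneracy * span + eps:
                    best = (A, E)
            if best is not None:
                candidates.append(best)
        # reported repeats may not begin/end on a mismatch: clip one
        # mismatched terminal position per side (non-tandem guarantees at
        # most one), then re-apply length floor and containment
        clipped = []
        for A, E in candidates:
            A2 = A + (0 if m[A % L] else 1)
            E2 = E - (0 if m[(E - 1) % L] else 1)
            if E2 - A2 >= min_len:
                clipped.append((A2, E2))
        clipped = sorted(set(clipped))
        key_reps: dict[tuple, RepeatPair] = {}
        for A, E in clipped:
            span = E - A
            arm1 = Interval.from_span(A, span, L)
            arm2 = _arm2(repeat_class, A, span, key, L)
            offs = frozenset(k for k in range(span) if not m[(A + k) % L])
            if arm2.start < arm1.start:
                if repeat_class in OPPOSITE_DIRECTION:
                    offs = frozenset(span - 1 - k for k in offs)
                arm1, arm2 = arm2, arm1
            rp = RepeatPair(repeat_class, arm1, arm2, span, offs)
            key_reps.setdefault(rp.key(), rp)
        # maximality as unordered arm pairs: drop any repeat whose arms are
        # both sub-arcs of a longer repeat on this key, in either role order
        items = list(key_reps.values())
        for rp in items:
            bigger = any(
                o.length > rp.length
                and (
                    (o.arm1.contains(rp.arm1, L) and o.arm2.contains(rp.arm2, L))
                    or (o.arm1.contains(rp.arm2, L) and o.arm2.contains(rp.arm1, L))
                )
                for o in items
                if o is not rp
            )
            if not bigger:
                out.setdefault(rp.key(), rp)
    return sorted(out.values(), key=lambda r: (r.arm1.start, r.arm2.start, r.length))


def exact_repeat_scan(
    g: CircularGenome,
    repeat_class: RepeatClass,
    min_len: int = WINDOW,
    max_len: int = _MAX_ORACLE_LEN,
) -> list[RepeatPair]:
    """Maximal perfect (exact) repeats of one class, by run-length scanning.

    A second independent route: per key, maximal runs of matching positions
    of length >= *min_len* are reported, truncated where the two arms would
    meet on the circle.  Equals :func:`brute_force_repeats` at
    ``max_degeneracy=0`` wherever runs are shorter than the disjointness
    cap (the generic situation).
    """
    if g.length > max_len:
        raise ValueError("genome too long for exhaustive enumeration")
    L = g.length
    code = encode(g.seq)
    out: dict[tuple, RepeatPair] = {}
    for key in _keys(repeat_class, L, min_len):
        m = _match_array(code, repeat_class, key)
        if not m.any():
            continue
        # cheap skip: any window of min_len consecutive matches at all?
        cs = np.concatenate([[0], np.cumsum(np.concatenate([m, m[: min_len - 1]]))])
        if not np.any(cs[min_len:] - cs[:-min_len] == min_len):
            continue
        # maximal circular runs of True, delimited by False positions
        false_idx = np.nonzero(~m)[0].tolist()
        if not false_idx:
            runs = [(0, L)]
        else:
            runs = []
            nf = len(false_idx)
            for i in range(nf):
                s = false_idx[i] + 1
                e = false_idx[(i + 1) % nf] + (L if i == nf - 1 else 0)
                if e > s:
                    runs.append((s, e))
        for A0, E0 in runs:
            for A, E in _clip_run(repeat_class, A0, E0, key, L, min_len):
                span = E - A
                arm1 = Interval.from_span(A % L, span, L)
                arm2 = _arm2(repeat_class, A % L, span, key, L)
                if arm2.start < arm1.start:
                    arm1, arm2 = arm2, arm1
                rp = RepeatPair(repeat_class, arm1, arm2, span, frozenset())
                out.setdefault(rp.key(), rp)
    return sorted(out.values(), key=lambda r: (r.arm1.start, r.arm2.start, r.length))


def _clip_run(
    repeat_class: RepeatClass, A: int, E: int, key: int, L: int, min_len: int
) -> list[tuple[int, int]]:
    """Truncate a perfect match run so the two arms stay disjoint.

    Opposite-direction keys have a fixed end cap (the reflection point);
    same-direction keys cap the span, yielding a sliding family when the
    run is longer than the cap (degenerate periodic sequences only).
    """
    span = E - A
    if span < min_len:
        return []
    if repeat_class in SAME_DIRECTION:
        cap = min(key, L - key)
        if span <= cap:
            return [(A, E)]
        return [(a, a + cap) for a in range(A, E - cap + 1)]
    # arms [A,E) and [key-E+1, key-A+1): find the largest E' with no overlap
    result = []
    for Ep in range(E, A + min_len - 1, -1):
        arm1 = Interval.from_span(A % L, Ep - A, L)
        arm2 = _arm2(repeat_class, A % L, Ep - A, key, L)
        if not arm1.overlaps(arm2, L):
            result.append((A, Ep))
            break
    # symmetric clip from the left for the mirror-image arm
    for Ap in range(A, E - min_len + 1):
        arm1 = Interval.from_span(Ap % L, E - Ap, L)
        arm2 = _arm2(repeat_class, Ap % L, E - Ap, key, L)
        if not arm1.overlaps(arm2, L):
            if (Ap, E) not in result:
                result.append((Ap, E))
            break
    return result
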