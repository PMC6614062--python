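"""Shared helpers for the test suite."""

from __future__ import annotations

from circrep import CircularGenome, RepeatClass, RepeatPair
from circrep.finder import SAME_DIRECTION

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_transform(seq: str, cls: RepeatClass) -> str:
    """Straight-line re-implementation of the four arm transforms."""
    if cls is RepeatClass.DIRECT:
        return seq
    if cls is RepeatClass.COMPLEMENTARY:
        return "".join(COMP[c] for c in seq)
    if cls is RepeatClass.MIRROR:
        return seq[::-1]
    return "".join(COMP[c] for c in reversed(seq))


def naive_match_offsets(a: str, b: str, cls: RepeatClass) -> set[int]:
    tb = naive_transform(b, cls)
    return {
        i
        for i, (x, y) in enumerate(zip(a, tb))
        if x != y or x == "N" or y == "N"
    }


def canonical_pairs(repeats, L, with_offsets=False):
    """Order-free representation of a repeat set for equality checks."""
    out = set()
    for r in repeats:
        a = (r.arm1.start, r.arm1.span(L))
        b = (r.arm2.start, r.arm2.span(L))
        item = (r.repeat_class.value, tuple(sorted([a, b])))
        if with_offsets:
            item = item + (frozenset(r.mismatch_offsets),)
        out.add(item)
    return out


def assert_repeat_invariants(r: RepeatPair, g: CircularGenome, max_degeneracy=0.2):
    """The output contract every called repeat must satisfy."""
    L = g.length
    assert r.length >= 10, "repeat shorter than the 10 bp floor"
    assert r.arm1.span(L) == r.arm2.span(L) == r.length, "unequal arm spans"
    assert not r.arm1.overlaps(r.arm2, L), "arms overlap on the circle"
    assert r.degeneracy <= max_degeneracy + 1e-12, "degeneracy above the cap"
    offs = sorted(r.mismatch_offsets)
    assert all(b - a > 1 for a, b in zip(offs, offs[1:])), "tandem mismatches"
    assert all(0 <= o < r.length for o in offs)
    assert 0 not in r.mismatch_offsets and r.length - 1 not in r.mismatch_offsets, (
        "repeat begins or ends on a mismatch"
    )
    # the mismatch map must agree with the sequences themselves
    s1 = "".join(g.seq[p] for p in r.arm1.positions(L))
    s2 = "".join(g.seq[p] for p in r.arm2.positions(L))
    assert naive_match_offsets(s1, s2, r.repeat_class) == set(r.mismatch_offsets)
    assert r.perfect == (len(offs) == 0)


def displacement_key(r: RepeatPair, L: int) -> int:
    if r.repeat_class in SAME_DIRECTION:
        d = (r.arm2.start - r.arm1.start) % L
        return min(d, L - d)
    return (r.arm1.start + r.arm2.start + r.length - 1) % L
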