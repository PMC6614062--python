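"""Genome input/output and circular-coordinate primitives.

Mitochondrial genomes are circular molecules a few tens of kilobases long.
All internal coordinates are 0-based half-open on the forward ("light",
GenBank-deposited) strand; file output (GFF3, WIG) converts to 1-based.
A segment that crosses the origin of the circle is represented as a single
:class:`Interval` with ``wraps=True`` and is emitted in GFF3 as two
part-lines sharing one ID, since GFF3 has no native wrap notation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger("circrep")

#: Sliding-window width of the seed stage; also the circular extension length.
WINDOW = 10

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


class RepeatClass(str, Enum):
    """The four interspersed repeat classes.

    The second arm equals a fixed transform of the first arm (up to allowed
    mismatches): ``direct`` = identical copy, ``complementary`` (everted) =
    base-wise complement in the same direction, ``mirror`` = reversed without
    complementation, ``inverted`` = reverse complement.
    """

    DIRECT = "direct"
    INVERTED = "inverted"
    MIRROR = "mirror"
    COMPLEMENTARY = "complementary"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on a circular genome.

    ``start`` is always in ``[0, L)``.  When ``wraps`` is true the segment
    crosses the origin and ``end`` is the (exclusive) endpoint after the
    wrap, i.e. ``end <= start``.
    """

    start: int
    end: int
    wraps: bool = False

    def span(self, length: int) -> int:
        s = (self.end - self.start) % length
        return s if s else length

    def positions(self, length: int) -> list[int]:
        """All genome positions covered, in arm order."""
        return [(self.start + k) % length for k in range(self.span(length))]

    def contains(self, other: "Interval", length: int) -> bool:
        """True when *other* is a (not necessarily proper) sub-arc of self."""
        off = (other.start - self.start) % length
        return off + other.span(length) <= self.span(length)

    def overlaps(self, other: "Interval", length: int) -> bool:
        a0, asp = self.start, self.span(length)
        b0, bsp = other.start, other.span(length)
        d = (b0 - a0) % length
        if d < asp:
            return True
        return (a0 - b0) % length < bsp

    @staticmethod
    def from_span(start: int, span: int, length: int) -> "Interval":
        start %= length
        end = start + span
        if end <= length:
            return Interval(start, end, False)
        return Interval(start, end - length, True)


@dataclass
class CircularGenome:
    """An uppercase nucleotide sequence with circular topology."""

    id: str
    seq: str
    genes: list[tuple[str, Interval, int]] = field(default_factory=list)
    circular: bool = True

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty sequence")
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"sequence contains invalid characters: {sorted(bad)!r}")


def normalize_sequence(raw: str) -> str:
    """Uppercase; map IUPAC ambiguity codes (except N) to N; drop gap chars.

    A warning is logged when characters are dropped or remapped.
    """
    up = raw.upper()
    out = []
    dropped = 0
    mapped = 0
    for ch in up:
        if ch in _VALID:
            out.append(ch)
        elif ch in "-. ":
            dropped += 1
        elif ch.isalpha():
            out.append("N")
            mapped += 1
        else:
            dropped += 1
    if dropped:
        log.warning("dropped %d gap/other characters during normalization", dropped)
    if mapped:
        log.warning("mapped %d ambiguity characters to N", mapped)
    return "".join(out)


def _genbank_genes(record) -> list[tuple[str, Interval, int]]:
    genes = []
    L = len(record.seq)
    for feat in record.features:
        if feat.type not in {"gene", "CDS", "tRNA", "rRNA"}:
            continue
        name = (
            feat.qualifiers.get("gene", feat.qualifiers.get("product", [feat.type]))
        )[0]
        start = int(feat.location.start) % L
        span = (int(feat.location.end) - int(feat.location.start)) % L or L
        strand = feat.location.strand or 1
        genes.append((name, Interval.from_span(start, span, L), strand))
    return genes


def read_genome(path: str | Path, format: str | None = None) -> CircularGenome:
    """Read a single genome record from GenBank or FASTA.

    *format* is inferred from the file suffix when not given.  GenBank
    gene/CDS/tRNA/rRNA features are retained; FASTA yields an empty gene
    list.  Records that are empty or >50% non-ACGT (a sign of a protein or
    corrupt entry) are rejected.
    """
    path = Path(path)
    if format is None:
        format = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
    record = next(SeqIO.parse(str(path), format), None)
    if record is None or len(record.seq) == 0:
        raise ValueError(f"no sequence found in {path}")
    raw = str(record.seq)
    n_acgt = sum(raw.upper().count(b) for b in "ACGT")
    if n_acgt < 0.5 * len(raw):
        raise ValueError(f"{path}: >50% non-ACGT characters; not a nucleotide genome?")
    seq = normalize_sequence(raw)
    genes = _genbank_genes(record) if format == "genbank" else []
    acc = record.id or path.stem
    return CircularGenome(id=acc, seq=seq, genes=genes)


def load_human_mtdna() -> CircularGenome:
    """The bundled human mitochondrial genome (NC_001807.4, 16,571 bp).

    This is the pre-rCRS Cambridge reference assembly; it differs from the
    revised reference NC_012920 by roughly forty substitutions and two
    positions of length.  Bundled so reference runs work offline.
    """
    from importlib import resources

    path = resources.files("circrep") / "data" / "human_mtdna_NC_001807.fa"
    with resources.as_file(path) as p:
        return read_genome(p, format="fasta")


def transform(seq: str, repeat_class: RepeatClass) -> str:
    """Apply the class-defining arm transform.

    direct -> copy; complementary -> base-wise complement (same order);
    mirror -> reversal (no complementation); inverted -> reverse complement.
    N complements to N.  Each transform is an involution.
    """
    if repeat_class is RepeatClass.DIRECT:
        return seq
    if repeat_class is RepeatClass.COMPLEMENTARY:
        return seq.translate(_COMPLEMENT)
    if repeat_class is RepeatClass.MIRROR:
        return seq[::-1]
    return seq.translate(_COMPLEMENT)[::-1]


def extend_for_circularity(g: CircularGenome, w: int = WINDOW) -> str:
    """Append the first *w* bases to the end, linearizing origin-spanning windows."""
    if g.length <= w:
        raise ValueError(f"genome ({g.length} bp) not longer than window ({w})")
    return g.seq + g.seq[:w]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _gff_lines_for_arm(
    seqid: str, rid: str, arm_idx: int, arm: Interval, length: int, attrs: str
) -> list[str]:
    """One GFF3 line per arm; a wrapping arm becomes two part-lines."""
    lines = []
    segments: list[tuple[int, int]]
    if arm.wraps:
        segments = [(arm.start, length), (0, arm.end)]
    else:
        segments = [(arm.start, arm.end)]
    for k, (s, e) in enumerate(segments):
        part = f"{rid}.arm{arm_idx}" + (f".part{k+1}" if len(segments) > 1 else "")
        lines.append(
            "\t".join(
                [
                    seqid,
                    "circrep",
                    "repeat_arm",
                    str(s + 1),
                    str(e),
                    ".",
                    "+",
                    ".",
                    f"ID={part};Parent={rid};{attrs}",
                ]
            )
        )
    return lines


def write_gff3(repeats: Sequence, g: CircularGenome, path: str | Path) -> None:
    """Write called repeats as GFF3: one ``repeat_pair`` parent per repeat,
    one ``repeat_arm`` child per arm (two part-lines when an arm wraps)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {g.id} 1 {g.length}\n")
        for i, rp in enumerate(sorted(repeats, key=lambda r: (r.repeat_class.value, r.arm1.start, r.arm2.start))):
            rid = f"rep{i:06d}"
            mism = ",".join(str(o) for o in sorted(rp.mismatch_offsets)) or "."
            attrs = (
                f"class={rp.repeat_class.value};length={rp.length};"
                f"degeneracy={rp.degeneracy:.4f};perfect={int(rp.perfect)};"
                f"mismatches={mism}"
            )
            span_min = min(
                rp.arm1.start if not rp.arm1.wraps else 0,
                rp.arm2.start if not rp.arm2.wraps else 0,
            )
            span_max = g.length if (rp.arm1.wraps or rp.arm2.wraps) else max(rp.arm1.end, rp.arm2.end)
            fh.write(
                "\t".join(
                    [
                        g.id,
                        "circrep",
                        "repeat_pair",
                        str(span_min + 1),
                        str(span_max),
                        ".",
                        "+",
                        ".",
                        f"ID={rid};{attrs}",
                    ]
                )
                + "\n"
            )
            for j, arm in enumerate((rp.arm1, rp.arm2), start=1):
                for line in _gff_lines_for_arm(g.id, rid, j, arm, g.length, attrs):
                    fh.write(line + "\n")


def write_wig(
    track: Iterable[float], chrom: str, path: str | Path, name: str | None = None
) -> None:
    """Fixed-step WIG (step=1, span=1, 1-based start)."""
    path = Path(path)
    with path.open("w") as fh:
        if name:
            fh.write(f'track type=wiggle_0 name="{name}"\n')
        fh.write(f"fixedStep chrom={chrom} start=1 step=1 span=1\n")
        for v in track:
            if float(v).is_integer():
                fh.write(f"{int(v)}\n")
            else:
                fh.write(f"{v:.6g}\n")
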