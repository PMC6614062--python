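# Methods

## The problem

Mitochondrial genomes are short circular DNA molecules whose instability
(somatic deletions, inversions) is associated with interspersed repeats —
pairs of similar segments ("arms") at distant genomic positions.  Four
repeat classes exist, defined by which strand the second arm lives on and
the direction it runs in relative to the first:

| class          | arm2 relative to arm1                | strand   | direction |
|----------------|--------------------------------------|----------|-----------|
| direct         | identical copy                       | same     | same      |
| complementary  | base-wise complement (everted)       | opposite | same      |
| mirror         | reversal, no complementation         | same     | opposite  |
| inverted       | reverse complement (palindrome-like) | opposite | opposite  |

`circrep` calls all four classes, both perfect (identical arms) and
imperfect (mismatched arms), in circular genomes, starting from a minimum
length of 10 bp.  Insertions/deletions between arms and tandem repeats /
microsatellites are deliberately out of scope: mitochondrial interspersed
repeats are short (the mean called repeat length on human mtDNA is ~10.6
bp), so a fixed-length mismatch model is adequate and keeps duplex
thermodynamics additive.

## Repeat calling

**Dot-plot geometry.** Every matched position pair (p, q) of one repeat
satisfies a conservation law: q − p ≡ const (mod L) for the same-direction
classes (direct, complementary), and p + q ≡ const (mod L) for the
opposite-direction classes (mirror, inverted).  All seeds of one repeat
therefore share one (anti)diagonal of the L×L comparison matrix, reducing
merging to a 1-D interval problem per *displacement key*.

**Stage I (seeding).** For each class and each displacement key, a boolean
per-position match vector is computed on the circle (the genome is
conceptually extended by one window length so origin-spanning windows
exist).  A *seed* is a 10 bp window pair with at most 1 mismatch (10%
of the window) whose two windows are disjoint on the circle — repeats are
interspersed, so self-overlapping window pairs are discarded.  Each
unordered pair is scanned once (half-matrix): same-direction keys run over
displacements w..L/2, opposite-direction keys over all L position sums.
The implementation vectorizes each key as a rolled comparison plus a
cumulative-sum window count (numpy), so a 16.6 kb genome takes seconds
per class rather than the quartic cost of a literal four-loop scan.

**Stage II (merging).** Within a key, seeds whose windows overlap by at
least 1 bp form chains; the caller reports the longest chain intervals
(unions of overlapping seed windows) that satisfy all of:

* overall degeneracy ≤ 20% (mismatches / length);
* no *tandem* mismatch (two adjacent mismatched positions) — in practice
  this is enforced structurally: no ≤1-mismatch window can bridge an
  adjacent mismatch pair, so chains always break there;
* both arms disjoint on the circle (for opposite-direction classes this
  caps extension at the reflection point of the antidiagonal);
* **terminal trimming**: a reported repeat neither starts nor ends on a
  mismatched position.  At most one position per side can be trimmed
  (mismatches are non-adjacent), and the 10 bp length floor is re-applied
  afterwards.  Without trimming, every maximal repeat on real mtDNA
  absorbs a flanking mismatch and *no* repeat is ever classified perfect;
  with it, an unextendable exact core stays a perfect repeat, which is the
  only reading consistent with published perfect/imperfect accounting for
  this algorithm family.

Maximality and deduplication: a repeat is dropped when both arms are
sub-arcs of a longer same-class repeat on the same displacement key — as
an *unordered* pair, since on an antidiagonal a short repeat can sit
inside a longer one with arm roles swapped.  Sub-repeats on *different*
keys are kept (they are distinct dot-plot diagonals).  Output order and
content are deterministic; repeated runs produce byte-identical GFF3.

**Conventions for degenerate inputs.** `N` (and any IUPAC ambiguity code,
which normalization maps to N) matches nothing — conservative, so
ambiguity never inflates repeat counts.  On a fully matching key of a
periodic sequence (e.g. a homopolymer circle) the chain wraps the whole
genome; candidates are then enumerated over one doubled period and capped
by arm disjointness.  Canonical arm order is by smaller start position on
the forward strand.

**Parameters.** window = 10 bp, seed mismatch cap = 1, merge degeneracy
cap = 0.20, all exposed as CLI flags (`--window`, `--seed-mm`,
`--max-degeneracy`).  The defaults reflect DNA helical periodicity (~10
bp/turn) and the shortest biologically meaningful pairing lengths; they
define the reference surface used in all tests.

## Independent references (test-only)

`circrep.oracle` re-derives repeats from first principles: match vectors
by explicit index arithmetic, candidate intervals enumerated pairwise and
validated position-by-position against the full constraint set, with the
same output conventions.  `brute_force_repeats` is exhaustive (guarded to
≤5 kb genomes); `exact_repeat_scan` is a second route for perfect repeats
(run-length scanning of match vectors) usable up to mtDNA sizes.  The
test suite asserts exact set equality between the caller and
`brute_force_repeats` on synthetic genomes, and containment of every
maximal exact repeat in the called set on both synthetic genomes and the
bundled human genome.

## Annotation layer

Each arm is assigned its **midpoint** `Sgp + floor((Egp − Sgp)/2)` (start/
end genome positions, inclusive; reduced mod L for origin-spanning arms).
Per-nucleotide tracks: midpoint density (arms per position), overlap
density (repeat arms covering a position), arm-feature averages at shared
midpoints (unweighted arithmetic means), and the minimal / maximal /
best-similarity inter-arm distances (for two-armed repeats these
coincide; distance is the minimal circular gap between closest arm
endpoints).

Physico-chemical features per arm, from classical per-dinucleotide B-DNA
tables embedded in `circrep.annotate`:

* **Twist** (degrees per step; Kabsch, Sander & Trifonov 1982): total
  twist, turns = twist/360, bases per turn = 360·len/twist.
* **Stacking energy** (kcal/mol per step; Ornstein et al. 1978): total
  and per-dinucleotide average.
* **Duplex thermodynamics** (Breslauer et al. 1986 nearest-neighbor set):
  ΔH (kcal/mol) and ΔS (kcal/mol/K) as sums of step magnitudes with the
  formation sign (negative); ΔG = ΔH − 298.15·ΔS (25 °C); melting
  temperature by the standard nearest-neighbor formula
  Tm = ΔH / (ΔS + R·ln(C/4)) − 273.15 + 16.6·log10([Na+]) with defaults
  C = 50 nM strand concentration and 50 mM Na+.  These tables satisfy
  reverse-complement symmetry, so Tm/ΔG/ΔH/ΔS are strand-independent
  (property-tested).
* **Dinucleotide fractions**: overlapping counts over len−1 steps;
  N-containing steps are excluded from numerator and denominator.

Track output flips ΔG/ΔH/ΔS and stacking to positive magnitudes (energy
*released*), matching the display convention of the track set this format
follows.  Writers emit fixed-step WIG (step=1, 1-based) and GFF3 with one
`repeat_pair` parent and one `repeat_arm` child per arm; an arm crossing
the origin becomes two part-lines sharing an ID, since GFF3 has no native
wrap.

## Statistics

* **Abundance**: per-class repeat counts; per-class bp covered as the
  *union* of arm intervals (summed-with-multiplicity is available via the
  overlap-density track); mean overlap density = total arm bp / L = the
  number of repeats overlapping an average nucleotide.
* **Density–feature correlations**: Pearson r and Spearman ρ of midpoint
  density against each feature track over positions with nonzero midpoint
  density; constant inputs are reported as missing with a reason.
* **Cross-genome matrix**: 5×5 over {GC%, per-class bp covered} with
  Spearman ρ above the diagonal and p-values below (≥5 genomes).
* **Complementary dinucleotide pairs**: the unit of analysis is one
  genome (its dinucleotide frequencies inside repeat-covered regions of
  the forward/light strand).  For each complementary pair: ratio of
  means, Cohen's d with pooled SD, two-sided Mann-Whitney U (exact for
  tie-free samples of ≤20, normal approximation with tie correction
  otherwise).  No multiple-testing correction; the table writer annotates
  raw significance bands (p < 1e-10, 1e-10 ≤ p < 1e-5).  Statistical
  routines are scipy-backed and cross-checked in the tests against
  closed-form/enumerative re-implementations to 1e-10.

## Arc visualization

Drawing every arm pair is unreadable at mitochondrial repeat densities,
so arcs between arm midpoints are thinned stochastically.  The weight at
circular distance d is the density of an exponential with mean L/16
truncated to [0, L/2] (half the circle is the maximal distance).  The
published rule gives the distribution but not the accept/reject step; we
retain an arc with Bernoulli probability density(d)/density(0) =
exp(−16·d/L), which is 1 at distance 0, e⁻¹ at L/16 and e⁻⁸ ≈ 3·10⁻⁴ at
L/2 — preserving the stated monotone decay with a well-defined maximum.
Sampling is deterministic given the seed.

## Synthetic data

`random_genome(length, gc, seed)` draws i.i.d. bases with P(G)=P(C)=gc/2
and P(A)=P(T)=(1−gc)/2 — zero AT and GC strand skew by construction,
which is what makes the TA/AT ratio test meaningful (those dinucleotides
are unaffected by replication skew).  `plant` writes a repeat of chosen
class, length and non-tandem mismatch set and returns exact ground truth;
`repeat_free_background` rejection-samples genomes with no seed of any
class.  Chance 10 bp/1-mismatch matches are essentially certain at 1 kb
(expected ≈15 per class), so seed-free backgrounds are only practical at
~150–250 bp; recovery tests therefore use ordinary 1–2 kb backgrounds
(chance repeats do not affect a covers-both-arms recovery criterion)
while false-discovery tests use short verified-clean backgrounds.

Recovery tests sample mismatch layouts inside the method's design
envelope: every arm position must be covered by some 10 bp window with
≤1 mismatch, otherwise stage I can never seed the repeat (e.g. mismatches
at offsets {6, 8} of a 12-mer are undetectable by construction, not by
defect).

What the generator does *not* emulate: base composition heterogeneity
along the molecule (D-loop vs coding), gene structure, homopolymer runs,
and evolutionary correlation between repeats — so passing recovery tests
demonstrates algorithmic correctness, not calling accuracy on any
particular biological genome.  The bundled real human mitochondrial
genome (NC_001807.4) covers the realistic-composition case.

## Reference run

The packaged human mtDNA is NC_001807.4 (16,571 bp), the pre-rCRS
Cambridge reference assembly — bundled because reference runs must work
offline.  It differs from the revised human reference (NC_012920) by
about forty substitutions and two positions of length; per-class totals
agree with published counts for this algorithm's conventions to ~1%
(6312/1672/5408/1947 direct/complementary/mirror/inverted; 163/40/119/67
perfect) and the mean overlap density (19.6 repeats per nucleotide) falls
in the published 18–28 vertebrate range.  A full four-class call takes
~15–20 s on one core.

## Problem sizes used by the test and acceptance runs

Oracle-equivalence uses 20 genomes of 0.7–1.5 kb; perfect-completeness 50
genomes of 0.6–1.8 kb; planted recovery 100 plants on 1–2 kb backgrounds
(60 in the acceptance script, 0.9–1.5 kb); the TA/AT check 50 (tests) or
30 (script) skew-free 800 bp genomes.  These sizes give each check
hundreds-to-thousands of informative events while keeping the whole suite
in minutes.

## Known limitations

* No gapped (indel) repeats and no tandem repeats/microsatellites, by
  design.
* Repeats are reported as arm *pairs*; a segment repeated k times appears
  as the pairs of its occurrences, not as one k-arm family.
* The Mann-Whitney exact path assumes tie-free samples below n=21;
  heavily tied small samples fall back to the tie-corrected normal
  approximation.
* The brute-force oracle is exhaustive and guarded to ≤5 kb; it is a
  test instrument, not a caller.
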