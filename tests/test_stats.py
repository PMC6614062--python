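import math

import numpy as np
import pytest

from circrep import (
    CircularGenome,
    Interval,
    RepeatClass,
    abundance,
    build_profile,
    cross_genome_correlation,
    dinuc_frequencies_in_repeats,
    dinuc_pair_test,
    density_feature_correlation,
)
from circrep.finder import RepeatPair
from circrep.stats import AbundanceMetrics, cohen_d


def _repeat(cls, s1, s2, n, L):
    return RepeatPair(
        cls, Interval.from_span(s1, n, L), Interval.from_span(s2, n, L), n, frozenset()
    )


# ---------------------------------------------------------------------------
# independent statistics oracles (closed forms / enumeration, no scipy)
# ---------------------------------------------------------------------------

def hand_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def hand_rank(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v), float)
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def hand_spearman(x, y):
    return hand_pearson(hand_rank(x), hand_rank(y))


def hand_cohen_d(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    pooled = math.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    return (a.mean() - b.mean()) / pooled


def hand_exact_u_pvalue(a, b):
    """Two-sided exact Mann-Whitney p for tie-free samples, by counting
    rank-sum subsets with a dynamic program (independent of scipy)."""
    a = list(a)
    b = list(b)
    assert len(set(a + b)) == len(a) + len(b), "oracle assumes no ties"
    n, N = len(a), len(a) + len(b)
    pooled = sorted(a + b)
    ranks_a = [pooled.index(x) + 1 for x in a]
    obs_u = sum(ranks_a) - n * (n + 1) / 2.0
    mu = n * len(b) / 2.0
    # f[k][s]: number of k-subsets of ranks 1..N with rank sum s
    max_s = sum(range(N - n + 1, N + 1))
    f = [[0] * (max_s + 1) for _ in range(n + 1)]
    f[0][0] = 1
    for r in range(1, N + 1):
        for k in range(min(r, n), 0, -1):
            for s in range(max_s, r - 1, -1):
                f[k][s] += f[k - 1][s - r]
    total = math.comb(N, n)
    count = 0
    for s in range(max_s + 1):
        u = s - n * (n + 1) / 2.0
        if f[n][s] and abs(u - mu) >= abs(obs_u - mu) - 1e-12:
            count += f[n][s]
    return count / total


class TestAbundance:
    def test_empty(self):
        g = CircularGenome(id="g", seq="ACGT" * 50)
        m = abundance([], g)
        assert m.mean_overlap_density == 0
        assert all(v == 0 for v in m.counts.values())
        assert all(v == 0 for v in m.bp_covered.values())

    def test_single_repeat_density(self):
        g = CircularGenome(id="g", seq="ACGT" * 25)  # L = 100
        rp = _repeat(RepeatClass.DIRECT, 0, 50, 10, 100)
        m = abundance([rp], g)
        assert m.mean_overlap_density == pytest.approx(0.2)
        assert m.bp_covered[RepeatClass.DIRECT] == 20
        assert m.counts[RepeatClass.DIRECT] == 1

    def test_mean_density_equals_profile_sum(self):
        from circrep import call_repeats, random_genome

        g = random_genome(700, 0.45, rng_seed=4)
        reps = call_repeats(g)
        m = abundance(reps, g)
        prof = build_profile(reps, g)
        assert m.mean_overlap_density == pytest.approx(
            prof.overlap_density.sum() / g.length
        )

    def test_rotation_invariant_coverage(self):
        from circrep import call_repeats, random_genome

        g = random_genome(500, 0.45, rng_seed=14)
        rot = 211
        gr = CircularGenome(id="r", seq=g.seq[rot:] + g.seq[:rot])
        a = abundance(call_repeats(g), g)
        b = abundance(call_repeats(gr), gr)
        assert a.bp_covered == b.bp_covered


class TestDensityFeatureCorrelation:
    def _profile(self, dens, feat):
        L = len(dens)
        return type(
            "P",
            (),
            {
                "midpoint_density": np.asarray(dens, float),
                "feature_tracks": {"f": np.asarray(feat, float)},
                "genome_id": "t",
                "length": L,
            },
        )()

    def test_identical_track_is_perfectly_correlated(self):
        d = [0, 2, 0, 3, 1, 0, 5, 2, 0, 4]
        tab = density_feature_correlation(self._profile(d, d))
        assert tab.loc[0, "pearson_r"] == pytest.approx(1.0)

    def test_negated_track(self):
        d = np.array([0, 2, 0, 3, 1, 0, 5, 2, 0, 4], float)
        tab = density_feature_correlation(self._profile(d, -d))
        assert tab.loc[0, "pearson_r"] == pytest.approx(-1.0)

    def test_matches_hand_computation_on_noisy_linear_relation(self):
        rng = np.random.default_rng(2024)
        dens = rng.integers(1, 8, size=40).astype(float)
        feat = 2.5 * dens + rng.normal(0, 1.0, size=40)
        tab = density_feature_correlation(self._profile(dens, feat))
        assert tab.loc[0, "pearson_r"] == pytest.approx(
            hand_pearson(dens, feat), abs=1e-10
        )
        assert tab.loc[0, "spearman_rho"] == pytest.approx(
            hand_spearman(dens, feat), abs=1e-10
        )

    def test_constant_feature_flagged(self):
        d = [0, 2, 1, 3, 2, 4]
        tab = density_feature_correlation(self._profile(d, [1] * 6))
        assert math.isnan(tab.loc[0, "pearson_r"])
        assert "constant" in tab.loc[0, "note"]

    def test_too_few_midpoints(self):
        with pytest.raises(ValueError):
            density_feature_correlation(self._profile([0, 0, 1, 0, 2], [1, 2, 3, 4, 5]))


def _metrics(gc, d, c, m, i, name="g"):
    return AbundanceMetrics(
        genome_id=name,
        length=16000,
        counts={cls: 0 for cls in RepeatClass},
        bp_covered={
            RepeatClass.DIRECT: d,
            RepeatClass.COMPLEMENTARY: c,
            RepeatClass.MIRROR: m,
            RepeatClass.INVERTED: i,
        },
        mean_overlap_density=0.0,
        genome_gc_pct=gc,
    )


class TestCrossGenomeCorrelation:
    def test_identical_columns_give_rho_one(self):
        ms = [_metrics(40 + k, 100 + 7 * k, 50 + k, 100 + 7 * k, 60 + 2 * k) for k in range(6)]
        out = cross_genome_correlation(ms)
        assert out.loc["direct_bp", "mirror_bp"] == pytest.approx(1.0)

    def test_monotone_pair_gives_rho_one(self):
        rng = np.random.default_rng(5)
        comp = rng.integers(100, 900, size=8)
        inv = comp**2 + 3  # monotone function of comp
        ms = [
            _metrics(40 + k, int(rng.integers(100, 500)), int(c), int(rng.integers(100, 500)), int(v))
            for k, (c, v) in enumerate(zip(comp, inv))
        ]
        out = cross_genome_correlation(ms)
        assert out.loc["complementary_bp", "inverted_bp"] == pytest.approx(1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        ms = [
            _metrics(
                float(rng.uniform(35, 50)),
                *(int(rng.integers(50, 400)) for _ in range(4)),
                name=f"g{k}",
            )
            for k in range(7)
        ]
        a = cross_genome_correlation(ms)
        b = cross_genome_correlation(ms[::-1])
        assert np.allclose(a.values, b.values, equal_nan=True)

    def test_matches_hand_spearman(self):
        rng = np.random.default_rng(77)
        ms = [
            _metrics(
                float(rng.uniform(30, 55)),
                *(int(rng.integers(100, 2000)) for _ in range(4)),
            )
            for _ in range(10)
        ]
        out = cross_genome_correlation(ms)
        gc = [m.genome_gc_pct for m in ms]
        direct = [m.bp_covered[RepeatClass.DIRECT] for m in ms]
        assert out.loc["gc_pct", "direct_bp"] == pytest.approx(
            hand_spearman(gc, direct), abs=1e-10
        )

    def test_needs_five_genomes(self):
        with pytest.raises(ValueError):
            cross_genome_correlation([_metrics(40, 1, 2, 3, 4)] * 4)


class TestDinucPairTest:
    def test_identical_samples(self):
        a = [0.1, 0.2, 0.3, 0.15]
        st = dinuc_pair_test(a, list(a))
        assert st.ratio == pytest.approx(1.0)
        assert st.cohen_d == 0.0

    def test_doubling_gives_ratio_two(self):
        b = [0.1, 0.2, 0.15, 0.12, 0.3]
        st = dinuc_pair_test([2 * x for x in b], b)
        assert st.ratio == pytest.approx(2.0)

    def test_swap_inverts_ratio_and_negates_d(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.1, 0.3, 9)
        b = rng.uniform(0.05, 0.25, 9)
        fwd = dinuc_pair_test(a, b)
        rev = dinuc_pair_test(b, a)
        assert fwd.ratio == pytest.approx(1.0 / rev.ratio)
        assert fwd.cohen_d == pytest.approx(-rev.cohen_d)
        assert fwd.u_p == pytest.approx(rev.u_p)

    def test_matches_independent_oracles_on_fixed_samples(self):
        """Cohen's d (closed form) and the exact U p-value (full label
        enumeration) recomputed independently on two fixed 10-value samples."""
        a = [0.21, 0.18, 0.25, 0.22, 0.19, 0.27, 0.23, 0.20, 0.24, 0.26]
        b = [0.171, 0.162, 0.213, 0.184, 0.155, 0.226, 0.197, 0.148, 0.209, 0.238]
        st = dinuc_pair_test(a, b)
        assert st.cohen_d == pytest.approx(hand_cohen_d(a, b), abs=1e-10)
        assert st.ratio == pytest.approx(np.mean(a) / np.mean(b), abs=1e-12)
        assert st.u_p == pytest.approx(hand_exact_u_pvalue(a, b), abs=1e-10)

    def test_zero_denominator_flagged(self):
        with pytest.raises(ValueError, match="ratio undefined"):
            dinuc_pair_test([0.1, 0.2], [0.0, 0.0])

    def test_cohen_d_zero_for_equal_constant_samples(self):
        assert cohen_d(np.array([1.0, 1.0]), np.array([1.0, 1.0])) == 0.0


class TestDinucFrequencies:
    def test_counts_on_known_region(self):
        g = CircularGenome(id="g", seq="AATTGGCCAA" + "T" * 90)
        L = g.length
        rp = _repeat(RepeatClass.DIRECT, 0, 50, 10, L)
        # covered: [0,10) and [50,60); [50,60) is all T
        f = dinuc_frequencies_in_repeats([rp], g)
        # steps in [0,10): AA AT TT TG GG GC CC CA AA ; in [50,60): TTx9
        assert f["AA"] == pytest.approx(2 / 18)
        assert f["TT"] == pytest.approx(10 / 18)
        assert sum(f.values()) == pytest.approx(1.0)

    def test_empty_without_repeats(self):
        g = CircularGenome(id="g", seq="ACGT" * 30)
        assert set(dinuc_frequencies_in_repeats([], g).values()) == {0.0}
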