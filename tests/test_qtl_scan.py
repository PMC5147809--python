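"""Genome scans: quantile transform, LOD regression, peaks, support intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qtlmediate import (
    ChromSpec, LodCurve, best_per_chromosome, calc_genoprob, fit_lod, lod_from_group_stats,
    lod_support_interval, make_marker_map, normal_quantile_transform, scanone,
    simulate_f2_genotypes, synthesize_group_data,
)
from qtlmediate.errors import AlignmentError, DegenerateTraitError
from qtlmediate.qtl_scan import _lod_matrix

from conftest import single_chrom_map


class TestQuantileTransform:
    def test_three_point_example(self):
        out = normal_quantile_transform([5.0, 1.0, 9.0])
        expected = stats.norm.ppf([3 / 6, 1 / 6, 5 / 6])
        assert out == pytest.approx(expected, abs=1e-12)

    def test_rank_preservation(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(2.0, size=50)
        out = normal_quantile_transform(y)
        assert np.array_equal(np.argsort(y), np.argsort(out))

    def test_idempotence(self):
        y = stats.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        rng = np.random.default_rng(1)
        y = y[rng.permutation(20)]
        assert normal_quantile_transform(y) == pytest.approx(y, abs=1e-12)

    def test_ties_get_average_quantile(self):
        out = normal_quantile_transform([1.0, 1.0, 2.0, 3.0])
        q = stats.norm.ppf((np.array([1, 2, 3, 4]) - 0.5) / 4)
        assert out[0] == out[1] == pytest.approx((q[0] + q[1]) / 2)

    def test_missing_stays_missing(self):
        out = normal_quantile_transform([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out[1]) and not np.isnan(out[[0, 2, 3]]).any()

    def test_degenerate_traits_rejected(self):
        with pytest.raises(DegenerateTraitError):
            normal_quantile_transform([1.0, np.nan])
        with pytest.raises(DegenerateTraitError):
            normal_quantile_transform([2.0] * 10)


def _informative_probs(codes):
    p = np.zeros((len(codes), 3))
    p[np.arange(len(codes)), np.asarray(codes, dtype=int)] = 1.0
    return p


def _anova_lod(codes, y):
    """Closed-form one-way ANOVA LOD: independent oracle for fit_lod."""
    codes = np.asarray(codes)
    y = np.asarray(y, dtype=float)
    tss = np.sum((y - y.mean()) ** 2)
    rss = sum(np.sum((y[codes == g] - y[codes == g].mean()) ** 2) for g in (0, 1, 2))
    return 0.5 * len(y) * np.log10(tss / rss)


class TestFitLod:
    def test_equals_anova_at_informative_marker(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, size=200)
        y = 0.3 * (codes - 1) + rng.standard_normal(200)
        lod = fit_lod(_informative_probs(codes), y)
        assert lod == pytest.approx(_anova_lod(codes, y), abs=1e-9)

    def test_reconstructed_printed_group_stats_give_lod_near_70(self):
        # per-genotype means 0.096/-0.017/-0.161, SEMs 0.008/0.006/0.009,
        # N = 127/260/104 -> the cis-eQTL LOD these summaries encode is ~70
        ns = np.array([127, 260, 104])
        sds = np.array([0.008, 0.006, 0.009]) * np.sqrt(ns)
        codes, y = synthesize_group_data([0.096, -0.017, -0.161], sds, ns)
        lod = fit_lod(_informative_probs(codes), y)
        assert lod == pytest.approx(
            lod_from_group_stats([0.096, -0.017, -0.161],
                                 [0.008, 0.006, 0.009], ns), abs=1e-6)
        assert abs(lod - 70) / 70 < 0.10

    def test_null_mean_lod_matches_chi_square(self):
        # 2 ln(10) LOD ~ chi2_2 under the null: E[LOD] = log10(e) ~ 0.87
        rng = np.random.default_rng(5)
        n, reps = 200, 1000
        codes = rng.integers(0, 3, size=n)
        P = _informative_probs(codes)
        Y = rng.standard_normal((n, reps))
        lods = _lod_matrix((P[:, 2] - P[:, 0])[:, None], P[:, 1][:, None], Y,
                           np.empty((n, 0)), np.empty((n, 0)))
        assert abs(lods.mean() - 2 * np.log10(np.e) / 2) / 0.87 < 0.20

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        codes = rng.integers(0, 3, size=150)
        y = 0.2 * codes + rng.standard_normal(150)
        P = _informative_probs(codes)
        assert fit_lod(P, y) == pytest.approx(fit_lod(P, 5.0 - 3.0 * y), abs=1e-9)

    def test_true_dosage_as_covariate_kills_lod(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 3, size=491)
        s = codes - 1.0
        y = 0.5 * s  # zero-noise additive trait
        P = _informative_probs(codes)
        lod = fit_lod(P, y, addcovar=s[:, None])
        assert lod < 0.2

    def test_interactive_covariate_products_enter_alt_model(self):
        # with a sex x QTL interaction present, the interactive model beats
        # the additive-only model
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 3, size=400)
        sex = rng.integers(0, 2, size=400).astype(float)
        s = codes - 1.0
        y = 0.5 * s * sex + rng.standard_normal(400) * 0.3
        P = _informative_probs(codes)
        lod_int = fit_lod(P, y, intcovar=sex[:, None])
        lod_add = fit_lod(P, y, addcovar=sex[:, None])
        assert lod_int > lod_add

    def test_listwise_deletion(self):
        rng = np.random.default_rng(10)
        codes = rng.integers(0, 3, size=100)
        y = 0.4 * (codes - 1.0) + rng.standard_normal(100) * 0.5
        y[:10] = np.nan
        lod_full = fit_lod(_informative_probs(codes)[10:], y[10:])
        lod_nan = fit_lod(_informative_probs(codes), y)
        assert lod_nan == pytest.approx(lod_full, abs=1e-12)


class TestScanone:
    @pytest.fixture(scope="class")
    def small_gp(self):
        m = make_marker_map([ChromSpec("1", 60.0, 90.0, 13),
                             ChromSpec("2", 80.0, 120.0, 17)])
        geno = simulate_f2_genotypes(m, 250, seed=42)
        return geno, calc_genoprob(geno, m, step_cm=2.0, error_rate=0.0)

    def test_self_mapping(self, small_gp):
        geno, gp = small_gp
        locus = gp.grid.locus_index("c2m009")
        s = gp.probs[:, locus, 2] - gp.probs[:, locus, 0]
        curve = scanone(gp, pd.Series(s, index=geno.index, name="t"))[0]
        assert int(np.argmax(curve.lod)) == locus

    def test_permutation_null_rarely_exceeds_threshold(self, small_gp):
        geno, gp = small_gp
        rng = np.random.default_rng(11)
        locus = gp.grid.locus_index("c1m007")
        s = gp.probs[:, locus, 2] - gp.probs[:, locus, 0]
        y = s + rng.standard_normal(len(s)) * 0.5
        perms = pd.DataFrame(
            {f"p{i}": rng.permutation(y) for i in range(100)}, index=geno.index)
        curves = scanone(gp, perms)
        frac = np.mean([c.lod.max() >= 5 for c in curves])
        assert frac <= 0.05

    def test_no_overlap_raises(self, small_gp):
        geno, gp = small_gp
        y = pd.Series(np.zeros(5), index=[f"X{i}" for i in range(5)])
        with pytest.raises(AlignmentError):
            scanone(gp, y)

    def test_chromosome_restriction_matches_full_scan(self, small_gp):
        geno, gp = small_gp
        rng = np.random.default_rng(13)
        y = pd.Series(rng.standard_normal(len(geno)), index=geno.index, name="t")
        full = scanone(gp, y)[0]
        part = scanone(gp, y, chrom="2")[0]
        sub = gp.grid.chromosome("2")
        assert part.lod == pytest.approx(full.lod[sub.index.to_numpy()], abs=1e-12)


def _curve_from(lods, length_cm=100.0):
    m = single_chrom_map(length_cm=length_cm, n_markers=len(lods))
    return LodCurve(trait="t", grid=m, lod=np.asarray(lods, dtype=float))


class TestPeaks:
    def test_monotone_curve_peaks_rightmost(self):
        pk = best_per_chromosome(_curve_from(np.linspace(0, 6, 11)))[0]
        assert pk.pos_cM == 100.0 and pk.significant

    def test_below_threshold_not_significant(self):
        pk = best_per_chromosome(_curve_from(np.full(11, 4.9)))[0]
        assert not pk.significant

    def test_tie_broken_leftmost(self):
        lods = np.zeros(11)
        lods[[3, 7]] = 6.0
        pk = best_per_chromosome(_curve_from(lods))[0]
        assert pk.pos_cM == 30.0

    def test_support_interval_triangular(self):
        # peak 50 cM, slope 0.5 LOD/cM: the 1.5-LOD drop crosses at 47 and 53
        cm = np.linspace(0, 100, 101)
        lods = np.maximum(0.0, 10.0 - 0.5 * np.abs(cm - 50.0))
        lo, hi = lod_support_interval(_curve_from(lods), "1")
        assert (lo, hi) == (47.0, 53.0)

    def test_support_interval_spike_and_flat(self):
        lods = np.zeros(11)
        lods[5] = 8.0
        assert lod_support_interval(_curve_from(lods), "1") == (50.0, 50.0)
        assert lod_support_interval(_curve_from(np.full(11, 3.0)), "1") == (0.0, 100.0)

    def test_interval_contains_peak_and_lies_on_grid(self):
        rng = np.random.default_rng(17)
        lods = rng.random(11) * 6
        curve = _curve_from(lods)
        pk = best_per_chromosome(curve)[0]
        grid_cm = curve.grid.table["cM"].to_numpy()
        assert pk.ci_lo_cM <= pk.pos_cM <= pk.ci_hi_cM
        assert pk.ci_lo_cM in grid_cm and pk.ci_hi_cM in grid_cm
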