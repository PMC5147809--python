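"""Simulator correctness: maps, meiosis, corruption, phenotype architecture."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qtlmediate import (
    ChromSpec, SimDesign, corrupt_genotypes, default_chromosomes, make_marker_map,
    simulate_cross, simulate_f2_genotypes, simulate_phenotypes,
)
from qtlmediate.errors import InvalidDesignError
from qtlmediate.markers import MarkerMap
from qtlmediate.synthetic_cross import _simulate_gametes

from conftest import compact_design, single_chrom_map


class TestMarkerMap:
    def test_even_spacing(self):
        m = make_marker_map([ChromSpec("1", 100.0, 150.0, 11)])
        cm = m.table["cM"].to_numpy()
        assert np.allclose(np.diff(cm), 10.0)
        assert np.allclose(m.table["Mbp"], cm * 1.5)

    def test_default_genome_has_about_2000_markers(self):
        m = make_marker_map(default_chromosomes())
        assert len(m.chromosomes) == 19
        assert 1950 <= m.n_markers <= 2050

    def test_deterministic(self):
        a = make_marker_map(default_chromosomes(), seed=3)
        b = make_marker_map(default_chromosomes(), seed=3)
        assert a == b

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InvalidDesignError):
            make_marker_map([ChromSpec("1", 0.0, 10.0, 5)])
        with pytest.raises(InvalidDesignError):
            make_marker_map([ChromSpec("1", 50.0, 10.0, 1)])

    def test_tied_positions_jittered_in_input_order(self):
        df = pd.DataFrame({"chrom": "1", "marker": ["a", "b", "c"],
                           "cM": [5.0, 5.0, 5.0], "Mbp": [1.0, 1.0, 1.0]})
        m = MarkerMap(df)
        cm = m.table["cM"].to_numpy()
        assert list(m.table["marker"]) == ["a", "b", "c"]
        assert np.all(np.diff(cm) > 0)
        assert cm[2] - cm[0] == pytest.approx(2e-6)


class TestMeiosis:
    def test_zero_distance_no_recombinants(self):
        # two markers at the same cM position (tie-jittered to 1e-6 cM apart)
        m = MarkerMap(pd.DataFrame({"chrom": "1", "marker": ["a", "b"],
                                    "cM": [0.0, 0.0], "Mbp": [0.0, 0.0]}))
        cm = m.table["cM"].to_numpy()
        g = _simulate_gametes(cm, 20_000, np.random.default_rng(0))
        assert np.array_equal(g[:, 0], g[:, 1])

    def test_haldane_recombinant_fraction(self):
        # 10 cM: r = (1 - e^-0.2)/2 = 0.090634...; 3 binomial SEs at 50,000 gametes
        cm = np.array([0.0, 10.0])
        g = _simulate_gametes(cm, 50_000, np.random.default_rng(1))
        r_hat = np.mean(g[:, 0] != g[:, 1])
        r = 0.5 * (1 - np.exp(-0.2))
        se = np.sqrt(r * (1 - r) / 50_000)
        assert abs(r_hat - r) < 3 * se

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mendelian_segregation_491_mice(self, seed):
        m = single_chrom_map(n_markers=3)
        geno = simulate_f2_genotypes(m, 491, seed=seed)
        counts = geno.iloc[:, 0].value_counts().reindex([0.0, 1.0, 2.0], fill_value=0)
        chi2 = stats.chisquare(counts, f_exp=np.array([0.25, 0.5, 0.25]) * 491)
        assert chi2.pvalue > 0.001

    def test_segregation_converges_large_n(self):
        m = single_chrom_map(n_markers=2)
        geno = simulate_f2_genotypes(m, 50_000, seed=5)
        freqs = geno.iloc[:, 0].value_counts(normalize=True)
        assert abs(freqs[0.0] - 0.25) < 0.01
        assert abs(freqs[1.0] - 0.50) < 0.01

    def test_map_distance_recovery(self):
        # among double-homozygote mice the discordant fraction is r^2/((1-r)^2+r^2);
        # inverting it recovers the Haldane r of the simulated 20 cM interval
        m = single_chrom_map(length_cm=20.0, n_markers=2)
        geno = simulate_f2_genotypes(m, 30_000, seed=9).to_numpy()
        hom = (geno % 2 == 0).all(axis=1)
        g = geno[hom] // 2
        f = np.mean(g[:, 0] != g[:, 1])
        q = np.sqrt(f / (1 - f))
        r_hat = q / (1 + q)
        r_true = 0.5 * (1 - np.exp(-0.4))
        assert abs(r_hat - r_true) < 0.015

    def test_determinism_and_nmice_validation(self):
        m = single_chrom_map()
        assert simulate_f2_genotypes(m, 50, seed=2).equals(
            simulate_f2_genotypes(m, 50, seed=2))
        with pytest.raises(InvalidDesignError):
            simulate_f2_genotypes(m, 0)


class TestCorruption:
    def test_identity_at_zero_rates(self):
        m = single_chrom_map()
        geno = simulate_f2_genotypes(m, 100, seed=0)
        assert corrupt_genotypes(geno, 0.0, 0.0, seed=1).equals(geno)

    def test_high_missing_limit(self):
        m = single_chrom_map()
        geno = simulate_f2_genotypes(m, 200, seed=0)
        out = corrupt_genotypes(geno, 0.0, 0.499, seed=1)
        assert out.isna().to_numpy().mean() > 0.45

    def test_error_rate_binomial(self):
        # 1e5 calls at eps = 0.01 -> 900..1,100 flipped (3-SE band)
        m = single_chrom_map(n_markers=100)
        geno = simulate_f2_genotypes(m, 1000, seed=0)
        out = corrupt_genotypes(geno, 0.01, 0.0, seed=3)
        flipped = int((out != geno).to_numpy().sum())
        assert 900 <= flipped <= 1100

    def test_rate_validation(self):
        m = single_chrom_map()
        geno = simulate_f2_genotypes(m, 10, seed=0)
        with pytest.raises(InvalidDesignError):
            corrupt_genotypes(geno, 0.6, 0.0)


class TestPhenotypes:
    def test_zero_noise_mediated_equals_driver(self):
        d = compact_design(driver_sd=0.0, mediated_sd=0.0,
                           mediation_coef_range=(1.0, 1.0), batch_sd=0.0,
                           sex_effect=0.0, n_mediated=2, n_direct=0,
                           n_decoy_cis=0, n_null=0)
        mmap = make_marker_map(d.chromosomes)
        geno = simulate_f2_genotypes(mmap, d.n_mice, seed=11)
        cross = simulate_phenotypes(geno, mmap, d)
        drv = cross.pheno["driver"].to_numpy()
        med = cross.pheno["med001"].to_numpy()
        # b = +1 or -1 by alternating sign; med001 has positive sign
        assert np.allclose(med, drv)

    def test_driver_moment_recovery(self):
        d = compact_design(n_mice=491, seed=21)
        mmap = make_marker_map(d.chromosomes)
        geno = simulate_f2_genotypes(mmap, 491, seed=21)
        cross = simulate_phenotypes(geno, mmap, d)
        drv_marker = cross.annot.loc["driver"]
        sub = mmap.chromosome(str(drv_marker["chrom"]))
        mk = sub.loc[(sub["cM"] - drv_marker["cM"]).abs().idxmin(), "marker"]
        g = geno[mk].to_numpy()
        y = cross.pheno["driver"].to_numpy()
        m0, m2 = y[g == 0].mean(), y[g == 2].mean()
        a_hat = (m2 - m0) / 2
        se = d.driver_sd * np.sqrt(1 / (g == 0).sum() + 1 / (g == 2).sum()) / 2
        # residual sd inflated slightly by batch effects; allow 3 SEs + margin
        assert abs(a_hat - d.driver_additive) < 3 * se + 0.01

    def test_two_fold_allelic_difference_by_default(self):
        # default additive effect encodes a log10(2) homozygote contrast
        d = SimDesign()
        assert abs(-2 * d.driver_additive - np.log10(2)) < 1e-12

    def test_mediation_partial_correlation(self):
        # given the driver trait, a mediated target carries no genotype signal
        d = compact_design(n_mice=5000, driver_sd=0.0, batch_sd=0.0, sex_effect=0.0,
                           n_mediated=3, n_direct=0, n_decoy_cis=0, n_null=0, seed=4)
        mmap = make_marker_map(d.chromosomes)
        geno = simulate_f2_genotypes(mmap, 5000, seed=4)
        cross = simulate_phenotypes(geno, mmap, d)
        drv_ann = cross.annot.loc["driver"]
        sub = mmap.chromosome(str(drv_ann["chrom"]))
        mk = sub.loc[(sub["cM"] - drv_ann["cM"]).abs().idxmin(), "marker"]
        s = geno[mk].to_numpy() - 1.0
        drv = cross.pheno["driver"].to_numpy()
        for t in ("med001", "med002", "med003"):
            y = cross.pheno[t].to_numpy()
            resid_y = y - np.polyval(np.polyfit(drv, y, 1), drv)
            resid_s = s - np.polyval(np.polyfit(drv, s, 1), drv)
            r = np.corrcoef(resid_y, resid_s)[0, 1]
            assert abs(r) < 0.05

    def test_cross_determinism(self):
        a = simulate_cross(compact_design(seed=13))
        b = simulate_cross(compact_design(seed=13))
        assert a.geno.equals(b.geno) and a.pheno.equals(b.pheno)
        assert a.covar.equals(b.covar) and a.annot.equals(b.annot)

    def test_annotations_complete_and_labelled(self):
        cross = simulate_cross(compact_design(seed=2))
        assert set(cross.pheno.columns) == set(cross.annot.index)
        assert cross.annot.loc["insulin", "truth_label"] == "clinical"
        assert np.isnan(cross.annot.loc["insulin", "cM"])
        gwas = cross.annot["is_gwas_candidate"]
        assert gwas.sum() == 8 + 2  # mediated + direct targets carry the flag

    def test_design_validation(self):
        with pytest.raises(InvalidDesignError):
            SimDesign(n_mice=0)
        with pytest.raises(InvalidDesignError):
            SimDesign(mediated_sd=-1.0)
        with pytest.raises(InvalidDesignError):
            SimDesign(missing_rate=0.7)
        with pytest.raises(InvalidDesignError):
            SimDesign(hotspot_chrom="99")
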