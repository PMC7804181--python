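"""Synthetic-cohort generator: sampling model, scenarios, ascertainment."""

import math

import numpy as np
import pytest
from scipy import stats

import mlcbias as mb
from mlcbias.simcohort import (
    ILLNESS_OR_DOCTOR,
    LESS,
    SAME,
    ConfigurationError,
    default_positions,
)


class TestSimulateGenotypes:
    def test_empty_snp_set_gives_zero_columns(self):
        g = mb.simulate_genotypes(5, 0, seed=0)
        assert g.shape == (5, 0)

    def test_allele_frequencies_match_binomial_sampling(self):
        n, m = 10_000, 500
        g = mb.simulate_genotypes(n, m, maf_range=(0.5, 0.5), seed=1)
        freqs = g.mean(axis=0) / 2.0
        tol = 4.0 * math.sqrt(0.25 / (2 * n))
        assert np.mean(np.abs(freqs - 0.5) <= tol) >= 0.99

    def test_same_seed_is_bit_identical(self):
        a = mb.simulate_genotypes(200, 50, seed=7)
        b = mb.simulate_genotypes(200, 50, seed=7)
        assert np.array_equal(a, b)

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ConfigurationError):
            mb.simulate_genotypes(10, 10, maf_range=(0.0, 0.6))

    def test_positions_fixed_spacing_one_based(self):
        pos = default_positions(4)
        assert pos[0] == 1 and np.all(np.diff(pos) == 100_000)

    def test_ld_generator_creates_within_block_correlation(self):
        g = mb.simulate_genotypes_ld(4000, 40, block_size=20, rho=0.9, seed=2)
        r_adjacent = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        r_cross_block = np.corrcoef(g[:, 10], g[:, 30])[0, 1]
        assert r_adjacent**2 > 0.3
        assert abs(r_cross_block) < 0.1


class TestSimulateScenario:
    def test_scenario_i_liability_independent_of_behaviour(self):
        slopes = []
        for seed in range(50):
            c = mb.simulate_scenario(
                mb.ScenarioConfig("I", n_individuals=1500, n_snps=120, seed=seed)
            )
            slopes.append(stats.linregress(c.true_y, c.liability_d).slope)
        sem = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * sem

    def test_scenario_ii_covariance_matches_causal_effect(self):
        covs = []
        for seed in range(50):
            c = mb.simulate_scenario(
                mb.ScenarioConfig("II", n_individuals=1500, n_snps=120, b_yd=0.3, seed=seed)
            )
            covs.append(np.cov(c.true_y, c.liability_d)[0, 1])
        sem = np.std(covs, ddof=1) / math.sqrt(len(covs))
        assert abs(np.mean(covs) - 0.3) < 3 * sem

    def test_null_heritability_gives_uniform_pvalues(self):
        c = mb.simulate_scenario(
            mb.ScenarioConfig("I", n_individuals=5000, n_snps=500, h2_y=0.0, seed=3)
        )
        scan = mb.run_gwas(c.genotypes, c.true_y)
        assert stats.kstest(scan["p"], "uniform").pvalue > 0.01

    def test_unit_variances_and_prevalence(self):
        vy, vd, prev = [], [], []
        for seed in range(30):
            c = mb.simulate_scenario(
                mb.ScenarioConfig("IV", n_individuals=2000, n_snps=250, seed=seed)
            )
            vy.append(c.true_y.var(ddof=1))
            vd.append(c.liability_d.var(ddof=1))
            prev.append(c.disease.mean())
        for vals, target in ((vy, 1.0), (vd, 1.0)):
            sem = np.std(vals, ddof=1) / math.sqrt(len(vals))
            assert abs(np.mean(vals) - target) < 3 * sem
        # realised prevalence within the binomial 99% CI of the configured 0.15
        total_n = 30 * 2000
        half = 2.576 * math.sqrt(0.15 * 0.85 / total_n)
        assert abs(np.mean(prev) - 0.15) < half

    def test_determinism_given_config(self):
        cfg = mb.ScenarioConfig("III", n_individuals=500, n_snps=150, seed=9)
        a, b = mb.simulate_scenario(cfg), mb.simulate_scenario(cfg)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.true_y, b.true_y)
        assert np.array_equal(a.liability_d, b.liability_d)

    def test_causal_sets_exceeding_snps_rejected(self):
        with pytest.raises(ConfigurationError):
            mb.ScenarioConfig("IV", n_snps=150, n_causal_y=100, n_causal_d=100)

    @pytest.mark.parametrize("scenario,y_gen,d_gen", [
        ("I", True, False), ("II", True, False), ("III", False, True), ("IV", True, True),
    ])
    def test_scenario_architecture(self, scenario, y_gen, d_gen):
        c = mb.simulate_scenario(
            mb.ScenarioConfig(scenario, n_individuals=300, n_snps=250, seed=4)
        )
        assert (len(c.causal_idx_y) > 0) == y_gen
        assert (len(c.causal_idx_d) > 0) == d_gen


class TestAscertainment:
    def test_zero_threshold_is_identity(self):
        c = mb.simulate_scenario(mb.ScenarioConfig("I", n_individuals=400, n_snps=120, seed=5))
        a = mb.apply_ascertainment(c, mb.AscertainmentConfig(0.0, 3.0))
        assert np.array_equal(a.reported_y, c.reported_y)
        assert np.all(a.change_group == SAME)

    def test_exact_count_shift_and_labels(self):
        c = mb.simulate_scenario(mb.ScenarioConfig("I", n_individuals=1000, n_snps=120, seed=6))
        a = mb.apply_ascertainment(c, mb.AscertainmentConfig(0.10, 2.0))
        less = a.change_group == LESS
        assert less.sum() == 100
        sd = np.std(c.true_y, ddof=1)
        assert np.allclose(a.reported_y[less], c.true_y[less] - 2.0 * sd)
        assert np.all(a.reason[less] == ILLNESS_OR_DOCTOR)
        # conservation: nothing else moved
        assert np.array_equal(a.reported_y[~less], c.reported_y[~less])
        assert a.liability_d[less].min() >= a.liability_d[~less].max()

    def test_mean_shift_arithmetic(self):
        c = mb.simulate_scenario(mb.ScenarioConfig("I", n_individuals=1000, n_snps=120, seed=7))
        q, shift = 0.10, 2.0
        a = mb.apply_ascertainment(c, mb.AscertainmentConfig(q, shift))
        k = math.ceil(q * c.n)
        expected = -k / c.n * shift * np.std(c.true_y, ddof=1)
        assert np.isclose(a.reported_y.mean() - c.true_y.mean(), expected)

    def test_illness_subfraction_splits_reasons(self):
        c = mb.simulate_scenario(mb.ScenarioConfig("I", n_individuals=1000, n_snps=120, seed=8))
        a = mb.apply_ascertainment(c, mb.AscertainmentConfig(0.2, 1.0, illness_fraction=0.5))
        less = a.change_group == LESS
        assert (a.reason[less] == ILLNESS_OR_DOCTOR).sum() == 100


class TestMisreport:
    def test_zero_fractions_identity(self):
        c = mb.simulate_scenario(mb.ScenarioConfig("I", n_individuals=400, n_snps=120, seed=9))
        out = mb.apply_misreport(c, mb.MisreportConfig())
        assert np.array_equal(out.reported_y, c.reported_y)

    def test_nonresponse_rate_calibrated(self):
        frac = 0.156
        hits, total = 0, 0
        for seed in range(10):
            c = mb.simulate_scenario(
                mb.ScenarioConfig("I", n_individuals=2000, n_snps=120, seed=seed)
            )
            out = mb.apply_misreport(
                c, mb.MisreportConfig(nonresponse_frac=frac), seed=seed
            )
            hits += int(np.isnan(out.reported_y).sum())
            total += c.n
        half = 2.576 * math.sqrt(frac * (1 - frac) / total)
        assert abs(hits / total - frac) < half

    def test_liability_dependent_underreporting_targets_sick(self):
        diffs = []
        for seed in range(30):
            c = mb.simulate_scenario(
                mb.ScenarioConfig("II", n_individuals=2000, n_snps=120, seed=seed)
            )
            out = mb.apply_misreport(
                c,
                mb.MisreportConfig(
                    underreport_frac=0.021, underreport_liability_dependence=1.0
                ),
                seed=seed,
            )
            under = out.reported_y == 0
            if under.any():
                diffs.append(c.liability_d[under].mean() - c.liability_d.mean())
        t, p = stats.ttest_1samp(diffs, 0.0, alternative="greater")
        assert p < 0.01


class TestJShapeWorld:
    def test_linear_curve_gives_monotone_binned_means(self):
        df = mb.simulate_jshape_world(8000, lambda x: 0.8 * x, seed=0, noise_sd=0.1)
        mc = mb.binned_mean_curve(df["genetic_predictor_x"], df["y"], bins=6)
        assert np.all(np.diff(mc["mean_y"]) > 0)

    def test_jcurve_minimum_is_interior_in_exposure(self):
        from mlcbias.jshape import interior_minimum

        df = mb.simulate_jshape_world(
            6000, mb.JCurve(x_min=1.0, left_coef=1.0, right_coef=0.5), seed=1
        )
        mc = mb.binned_mean_curve(df["x"], df["y"], bins=10)
        assert interior_minimum(mc["mean_y"].to_numpy())

    def test_genetic_predictor_inherits_interior_minimum(self):
        from mlcbias.jshape import interior_minimum

        hits = 0
        for seed in range(10):
            df = mb.simulate_jshape_world(
                4000,
                mb.JCurve(x_min=0.5, left_coef=2.0, right_coef=1.0),
                seed=seed,
                h2=0.5,
                noise_sd=0.25,
            )
            mc = mb.binned_mean_curve(df["genetic_predictor_x"], df["y"], bins=8)
            hits += interior_minimum(mc["mean_y"].to_numpy())
        assert hits >= 8

    def test_jcurve_requires_positive_curvature(self):
        with pytest.raises(ConfigurationError):
            mb.JCurve(x_min=0.0, left_coef=-1.0, right_coef=1.0)


def test_cohort_roundtrip(tmp_path):
    c = mb.simulate_scenario(mb.ScenarioConfig("II", n_individuals=60, n_snps=40, n_causal_y=10, seed=2))
    c = mb.apply_ascertainment(c, mb.AscertainmentConfig(0.1, 2.0))
    mb.write_cohort(c, tmp_path)
    back = mb.read_cohort(tmp_path)
    assert np.array_equal(back.genotypes, c.genotypes)
    assert np.allclose(back.reported_y, c.reported_y, equal_nan=True)
    assert np.array_equal(back.change_group, c.change_group)
    assert np.array_equal(back.causal_idx_y, c.causal_idx_y)
    assert back.config == c.config
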