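"""Mendelian randomisation: Wald/IVW/median estimators and IV selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mlcbias as mb
from mlcbias import causal as causal_mod
from mlcbias.causal import (
    IVW,
    SIMPLE_MEDIAN,
    WALD,
    WEIGHTED_MEDIAN,
    InsufficientInstrumentsError,
    NoInstrumentError,
)
from mlcbias.mlc import SIMULATION_RULES


def _scan(betas, ses):
    b = np.asarray(betas, float)
    s = np.asarray(ses, float)
    return pd.DataFrame(
        {
            "snp": [f"snp{j}" for j in range(len(b))],
            "pos": 1 + 100_000 * np.arange(len(b)),
            "a1": "A",
            "a2": "G",
            "freq": 0.3,
            "beta": b,
            "se": s,
            "p": 2 * stats.norm.sf(np.abs(b / s)),
            "n": 1000,
            "monomorphic": False,
        }
    )


class TestIvwEstimate:
    def test_single_iv_is_wald_ratio(self):
        exp = _scan([0.5], [0.05])
        out = _scan([0.15], [0.02])
        est = mb.ivw_estimate(["snp0"], exp, out)
        assert est.method == WALD
        assert abs(est.b_xy - 0.3) < 1e-12
        assert abs(est.se - 0.02 / 0.5) < 1e-12
        assert est.ci95 == (est.b_xy - 1.96 * est.se, est.b_xy + 1.96 * est.se)

    def test_two_ivs_match_closed_form(self):
        exp = _scan([0.5, 0.2], [0.05, 0.05])
        out = _scan([0.15, 0.08], [0.02, 0.03])
        est = mb.ivw_estimate(["snp0", "snp1"], exp, out)
        w = np.array([0.5**2 / 0.02**2, 0.2**2 / 0.03**2])
        r = np.array([0.15 / 0.5, 0.08 / 0.2])
        assert abs(est.b_xy - np.sum(w * r) / np.sum(w)) < 1e-12
        assert abs(est.se - 1 / np.sqrt(np.sum(w))) < 1e-12
        assert est.method == IVW

    def test_exposure_rescaling_scales_estimate_inversely(self):
        exp = _scan([0.5, 0.2, 0.4], [0.05, 0.05, 0.04])
        out = _scan([0.15, 0.08, 0.1], [0.02, 0.03, 0.02])
        ivs = ["snp0", "snp1", "snp2"]
        a = mb.ivw_estimate(ivs, exp, out)
        exp2 = exp.copy()
        exp2["beta"] *= 4.0
        exp2["se"] *= 4.0
        b = mb.ivw_estimate(ivs, exp2, out)
        assert abs(b.b_xy - a.b_xy / 4.0) < 1e-12

    def test_outlier_screen_drops_deviant_instrument(self):
        exp = _scan([0.5, 0.5, 0.5, 0.5], [0.01] * 4)
        out = _scan([0.15, 0.15, 0.15, 0.21], [0.01] * 4)
        est = mb.ivw_estimate(["snp0", "snp1", "snp2", "snp3"], exp, out,
                              outlier_screen=True)
        assert est.removed_outliers == ["snp3"]
        assert abs(est.b_xy - 0.3) < 1e-9


class TestMedianEstimates:
    def test_equal_ratios_give_the_ratio(self):
        exp = _scan([0.5, 0.2, 0.4], [0.05] * 3)
        out = _scan([0.25, 0.10, 0.20], [0.02] * 3)
        sm, wm = mb.median_estimates(["snp0", "snp1", "snp2"], exp, out, n_boot=50)
        assert abs(sm.b_xy - 0.5) < 1e-12
        assert abs(wm.b_xy - 0.5) < 1e-12
        assert sm.method == SIMPLE_MEDIAN and wm.method == WEIGHTED_MEDIAN

    def test_simple_median_odd_count(self):
        exp = _scan([1.0, 1.0, 1.0], [0.1] * 3)
        out = _scan([0.1, 0.3, 0.5], [0.1] * 3)
        sm, _ = mb.median_estimates(["snp0", "snp1", "snp2"], exp, out, n_boot=50)
        assert abs(sm.b_xy - 0.3) < 1e-12

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_weighted_median_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 12))
        ratios = rng.normal(0.3, 0.5, k)
        weights = rng.uniform(0.1, 2.0, k)
        from mlcbias.causal import _weighted_median

        got = _weighted_median(ratios, weights)
        # brute-force: interpolate the weighted ECDF at probability one half
        order = np.argsort(ratios)
        r, w = ratios[order], weights[order] / weights.sum()
        cum = np.cumsum(w) - w / 2
        if 0.5 <= cum[0]:
            want = r[0]
        elif 0.5 >= cum[-1]:
            want = r[-1]
        else:
            j = int(np.searchsorted(cum, 0.5)) - 1
            want = r[j] + (0.5 - cum[j]) / (cum[j + 1] - cum[j]) * (r[j + 1] - r[j])
        assert abs(got - want) < 1e-10

    def test_fewer_than_three_ivs_rejected(self):
        exp = _scan([0.5, 0.2], [0.05] * 2)
        out = _scan([0.15, 0.08], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mb.median_estimates(["snp0", "snp1"], exp, out)

    def test_bootstrap_se_is_seeded(self):
        exp = _scan([0.5, 0.2, 0.4, 0.3], [0.05] * 4)
        out = _scan([0.15, 0.08, 0.1, 0.07], [0.02] * 4)
        ivs = ["snp0", "snp1", "snp2", "snp3"]
        a = mb.median_estimates(ivs, exp, out, n_boot=200, seed=5)
        b = mb.median_estimates(ivs, exp, out, n_boot=200, seed=5)
        assert a[1].se == b[1].se


class TestIvSelection:
    def test_no_significant_snps_raises(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, size=(100, 4)).astype(np.int8)
        exp = _scan([0.01] * 4, [0.05] * 4)
        with pytest.raises(NoInstrumentError):
            mb.select_ivs(exp, g)

    def test_defaults_echo_standard_criteria(self):
        cfg = mb.ClumpConfig()
        assert (cfg.p_threshold, cfg.window_bp, cfg.r2_threshold) == (5e-8, 1_000_000, 0.01)

    def test_selected_ivs_are_true_causal_snps(self):
        c = mb.simulate_scenario(
            mb.ScenarioConfig("II", n_individuals=8000, n_snps=200, n_causal_y=50,
                              h2_y=0.4, seed=2)
        )
        scan = mb.run_gwas(c.genotypes, c.true_y, snp_ids=c.snp_ids, positions=c.positions)
        # linkage equilibrium + 100 kb spacing: disable the distance window so
        # selection reflects significance alone
        ivs = mb.select_ivs(scan, c.genotypes, mb.ClumpConfig(window_bp=1))
        causal = set(c.snp_ids[c.causal_idx_y])
        assert len(ivs) >= 10
        assert set(ivs) <= causal


class TestRecoveryAndDirection:
    def test_ivw_recovers_causal_effect_without_ascertainment(self):
        hits = 0
        for seed in range(10):
            c = mb.simulate_scenario(
                mb.ScenarioConfig("II", n_individuals=8000, n_snps=200, n_causal_y=50,
                                  h2_y=0.4, b_yd=0.3, seed=seed)
            )
            y_scan = mb.run_gwas(c.genotypes, c.true_y, snp_ids=c.snp_ids,
                                 positions=c.positions)
            d_scan = mb.run_gwas(c.genotypes, c.liability_d, snp_ids=c.snp_ids,
                                 positions=c.positions)
            ivs = mb.select_ivs(y_scan, c.genotypes, mb.ClumpConfig(window_bp=1))
            est = mb.ivw_estimate(ivs, y_scan, d_scan)
            hits += est.ci95[0] <= 0.3 <= est.ci95[1]
        assert hits >= 8

    def test_reverse_direction_recorded_and_null_symmetric(self):
        c = mb.simulate_scenario(
            mb.ScenarioConfig("IV", b_yd=0.0, n_individuals=8000, n_snps=300,
                              n_causal_y=50, n_causal_d=50, h2_y=0.4, h2_d=0.4, seed=3)
        )
        y_scan = mb.run_gwas(c.genotypes, c.true_y, snp_ids=c.snp_ids, positions=c.positions)
        d_scan = mb.run_gwas(c.genotypes, c.liability_d, snp_ids=c.snp_ids, positions=c.positions)
        cfg = mb.ClumpConfig(window_bp=1)
        fwd = mb.ivw_estimate(mb.select_ivs(y_scan, c.genotypes, cfg), y_scan, d_scan)
        rev = mb.reverse_analysis(y_scan, d_scan, c.genotypes, cfg)
        assert rev.direction == "reverse" and fwd.direction == "forward"
        assert abs(fwd.b_xy) < 2 * fwd.se
        assert abs(rev.b_xy) < 2 * rev.se

    def test_reverse_effect_negative_in_ascertainment_world(self):
        """Disease genetics → reported behaviour acquires a negative effect."""
        ests = []
        for seed in range(5):
            c = mb.simulate_scenario(
                mb.ScenarioConfig("III", n_individuals=8000, n_snps=200, n_causal_d=50,
                                  h2_d=0.4, seed=seed)
            )
            a = mb.apply_ascertainment(c, mb.AscertainmentConfig(0.3, 3.0))
            from mlcbias import mlc

            y_scan = mlc.uncorrected_gwas(a)
            d_scan = mb.run_gwas(a.genotypes, a.liability_d, snp_ids=a.snp_ids,
                                 positions=a.positions)
            rev = mb.reverse_analysis(y_scan, d_scan, a.genotypes, mb.ClumpConfig(window_bp=1))
            ests.append(rev.b_xy)
        assert np.mean(ests) < 0

    def test_estimators_agree_in_sign_after_correction(self):
        from mlcbias import mlc

        c = mb.simulate_scenario(
            mb.ScenarioConfig("II", n_individuals=8000, n_snps=200, n_causal_y=50,
                              h2_y=0.4, b_yd=0.3, seed=4)
        )
        a = mb.apply_ascertainment(c, mb.AscertainmentConfig(0.3, 3.0))
        meta = mb.ivw_meta(mb.stratified_gwas(a, SIMULATION_RULES))
        d_scan = mb.run_gwas(a.genotypes, a.liability_d, snp_ids=a.snp_ids,
                             positions=a.positions)
        ivs = mb.select_ivs(meta, a.genotypes, mb.ClumpConfig(window_bp=1))
        ivw = mb.ivw_estimate(ivs, meta, d_scan)
        sm, wm = mb.median_estimates(ivs, meta, d_scan, n_boot=100)
        assert ivw.b_xy > 0 and sm.b_xy > 0 and wm.b_xy > 0
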