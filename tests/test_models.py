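"""Wiring-rule regressions, cohort tests, binning, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from liketolike import models
from liketolike.glm import conditional_slopes, fit_glm


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert np.isclose(models.bh_adjust([0.03])[0], 0.03)

    def test_hand_stepup_case(self):
        # (0.01, 0.02, 0.03): adjusted = min over step-up of p*m/rank = all 0.03
        got = models.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(got, [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged_and_range_checked(self):
        assert np.allclose(models.bh_adjust([0.2, 0.2, 0.2]), 0.2)
        with pytest.raises(ValueError):
            models.bh_adjust([1.2])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        assert np.all(models.bh_adjust(p) >= p - 1e-12)


class TestDensityOffset:
    def test_scaling_ld_shifts_only_intercept(self, small_pairs):
        pairs, _ = small_pairs
        pos = pairs[pairs["ld_um"] > 0].reset_index(drop=True)
        fit1 = models.fit_density_model(pos, "signal_corr")
        doubled = pos.assign(ld_um=pos["ld_um"] * 2.0)
        fit2 = models.fit_density_model(doubled, "signal_corr")
        assert np.isclose(
            fit2.params["intercept"] - fit1.params["intercept"], -np.log(2.0), atol=1e-6
        )
        for name in fit1.params.index:
            if name != "intercept" and not name.startswith("grp:"):
                assert np.isclose(fit1.params[name], fit2.params[name], atol=1e-6)

    def test_zero_ld_records_rejected(self, small_pairs):
        pairs, _ = small_pairs
        with pytest.raises(ValueError):
            models.fit_density_model(pairs, "signal_corr")


class TestConditionalSlopes:
    def test_reference_level_slope_is_beta1_and_contrast_oracle(self, small_pairs):
        pairs, _ = small_pairs
        fit = models.fit_nsyn_model(pairs, "signal_corr")
        slopes = conditional_slopes(fit, adjust=False).set_index("projection")
        ref = fit.reference_level
        assert np.isclose(slopes.loc[ref, "slope"], fit.params["signal_corr"])
        assert np.isclose(slopes.loc[ref, "se"], np.sqrt(fit.cov.loc["signal_corr", "signal_corr"]))
        # independent contrast-matrix computation for a non-reference level
        other = [p for p in fit.projection_levels if p != ref][0]
        c = pd.Series(0.0, index=fit.params.index)
        c["signal_corr"] = 1.0
        c[f"signal_corr:{other}"] = 1.0
        want = float(c @ fit.params)
        want_se = float(np.sqrt(c @ fit.cov @ c))
        assert np.isclose(slopes.loc[other, "slope"], want)
        assert np.isclose(slopes.loc[other, "se"], want_se)

    def test_bh_adjustment_applied_across_levels(self, small_pairs):
        pairs, _ = small_pairs
        fit = models.fit_ld_model(pairs, "signal_corr")
        slopes = conditional_slopes(fit)
        assert np.all(slopes["p_adj"] >= slopes["p"] - 1e-12)


class TestFilterProjections:
    def test_hand_counts(self):
        rows = []
        # level A: 40 synapses spread over 7 presyns (passes)
        for pre in range(7):
            rows.append({"pre_id": pre, "post_id": 100 + pre, "projection": "A",
                         "nsyn": 6 if pre < 6 else 4})
        # level B: exactly 30 synapses (fails: strict >)
        for pre in range(6):
            rows.append({"pre_id": pre, "post_id": 200 + pre, "projection": "B", "nsyn": 5})
        # level C: 60% from one presyn (fails the share rule)
        rows += [{"pre_id": 0, "post_id": 300, "projection": "C", "nsyn": 30}]
        for pre in range(1, 7):
            rows.append({"pre_id": pre, "post_id": 300 + pre, "projection": "C", "nsyn": 20 // 6})
        # level D: only 3 presyns contributing (fails)
        for pre in range(3):
            rows.append({"pre_id": pre, "post_id": 400 + pre, "projection": "D", "nsyn": 20})
        pairs = pd.DataFrame(rows)
        assert models.filter_projections(pairs) == ["A"]


class TestPairedCohortTest:
    def build(self, shift=0.0, n_pre=15, rng=None):
        rng = rng or np.random.default_rng(1)
        rows = []
        for pre in range(n_pre):
            for k in range(12):
                for cohort, delta in [("connected", shift), ("adp_control", 0.0),
                                      ("same_region_control", 0.0)]:
                    rows.append(
                        {"pre_id": pre, "post_id": f"{cohort}{k}", "projection": "V1->V1",
                         "sim_signal_corr": rng.normal(delta, 0.3), "cohort": cohort}
                    )
        df = pd.DataFrame(rows)
        pairs = df.drop(columns="cohort")
        cohorts = df[["pre_id", "post_id", "cohort"]]
        return pairs, cohorts

    def test_identical_cohorts_give_t0_p1(self):
        pairs, cohorts = self.build()
        merged = pairs.copy()
        merged["sim_signal_corr"] = 0.5  # identical means per presyn
        out = models.paired_cohort_test(merged, cohorts)
        assert np.allclose(out["t"], 0.0) and np.allclose(out["p"], 1.0)

    def test_positive_shift_detected_and_matches_formula(self):
        pairs, cohorts = self.build(shift=0.3)
        out = models.paired_cohort_test(pairs, cohorts).set_index(["cohort_a", "cohort_b"])
        row = out.loc[("connected", "adp_control")]
        assert row["p"] < 0.01 and row["mean_diff"] > 0
        # direct formula oracle
        merged = pairs.merge(cohorts, on=["pre_id", "post_id"])
        means = merged.groupby(["pre_id", "cohort"])["sim_signal_corr"].mean().unstack()
        t, p = stats.ttest_rel(means["connected"], means["adp_control"])
        assert np.isclose(row["t"], t) and np.isclose(row["p"], p)

    def test_min_target_filter_skips_sparse_presyns(self):
        pairs, cohorts = self.build(shift=0.3, n_pre=3)
        # only 12 targets each -> qualifies; cut connected targets below 10
        drop = pairs[(pairs["post_id"].str.startswith("connected")) & (pairs["pre_id"] > 0)].index[:60]
        out = models.paired_cohort_test(pairs.drop(drop[:0]), cohorts, min_targets=12)
        assert out["skipped"].all() or out["p"].isna().all()


class TestResidualRegression:
    def test_orthogonality_when_anatomy_uninformative(self):
        rng = np.random.default_rng(2)
        n = 400
        ld = rng.uniform(1, 30, n)
        simv = 0.02 * ld + rng.normal(0, 0.05, n)
        pairs = pd.DataFrame(
            {"pre_id": 0, "post_id": np.arange(n), "ld_um": ld,
             "nsyn": rng.poisson(1.5, n) + 1, "sim_signal_corr": simv,
             "mean_log10_cleft_volume": rng.normal(3.3, 0.3, n)}
        )
        out = models.residual_anatomy_regression(pairs).set_index("term")
        assert out.loc["nsyn", "p"] > 0.01
        assert out.loc["mean_log10_cleft_volume", "p"] > 0.01

    def test_planted_cleft_and_multisynaptic_effects_recovered(self):
        rng = np.random.default_rng(3)
        n = 600
        ld = rng.uniform(1, 30, n)
        nsyn = rng.poisson(1.5, n) + 1
        cleft = rng.normal(3.3, 0.3, n)
        simv = 0.02 * ld + 0.2 * (cleft - 3.3) + 0.05 * nsyn + rng.normal(0, 0.05, n)
        pairs = pd.DataFrame(
            {"pre_id": 0, "post_id": np.arange(n), "ld_um": ld, "nsyn": nsyn,
             "sim_signal_corr": simv, "mean_log10_cleft_volume": cleft}
        )
        out = models.residual_anatomy_regression(pairs).set_index("term")
        assert out.loc["mean_log10_cleft_volume", "coef"] > 0 and out.loc["mean_log10_cleft_volume", "p"] < 1e-4
        assert out.loc["nsyn", "coef"] > 0 and out.loc["nsyn", "p"] < 1e-4
        assert np.isclose(out.loc["mean_log10_cleft_volume", "coef"], 0.2, atol=0.05)


class TestCenterAndBin:
    def test_two_presyn_hand_computation(self):
        # presyn 0: dx = -1, +1 with dy = -2, +2 ; presyn 1: dx = -1, +1 with dy = -4, +4
        pairs = pd.DataFrame(
            {
                "pre_id": [0] * 12 + [1] * 12,
                "post_id": np.arange(24),
                "nsyn": 0,
                "ld_um": ([8.0] * 6 + [12.0] * 6) + ([6.0] * 6 + [14.0] * 6),
                "sim_signal_corr": ([0.0] * 6 + [2.0] * 6) * 2,
            }
        )
        out = models.center_and_bin(
            pairs, y="ld", bins=np.array([-1.5, 0.0, 1.5]), n_boot=10,
            min_pairs=2, min_presyns=1, rng=np.random.default_rng(4),
        )
        assert len(out) == 2
        # bin [-1.5, 0): presyn0 dy=-2 (x6), presyn1 dy=-4 (x6) -> mean -3
        assert np.isclose(out.iloc[0]["mean_dy"], -3.0)
        assert np.isclose(out.iloc[1]["mean_dy"], 3.0)
        assert (out["sd_boot"] >= 0).all()

    def test_small_input_filtered_to_empty(self):
        pairs = pd.DataFrame(
            {"pre_id": [0] * 8, "post_id": range(8), "nsyn": 0, "ld_um": 5.0,
             "sim_signal_corr": np.linspace(0, 1, 8)}
        )
        out = models.center_and_bin(pairs, y="ld", n_boot=5)
        assert len(out) == 0

    def test_density_variant_restricts_to_positive_ld(self, small_pairs):
        pairs, _ = small_pairs
        out = models.center_and_bin(
            pairs, y="density", n_boot=20, rng=np.random.default_rng(5)
        )
        assert (out["n_pairs"] > 10).all() and (out["n_presyn"] > 10).all()


class TestBackendAgreement:
    def test_ridge_and_fixed_slopes_agree_within_one_se(self, small_pairs):
        pairs, _ = small_pairs
        fixed = fit_glm(pairs, "signal_corr", "nsyn", "poisson", re_mode="fixed")
        ridge = fit_glm(pairs, "signal_corr", "nsyn", "poisson", re_mode="ridge")
        b_f, b_r = fixed.params["signal_corr"], ridge.params["signal_corr"]
        assert np.sign(b_f) == np.sign(b_r)
        assert abs(b_f - b_r) < np.sqrt(fixed.cov.loc["signal_corr", "signal_corr"])
        assert ridge.group_var > 0


class TestProfileXi:
    def test_profile_recovers_generating_index(self, small_pairs):
        from liketolike.glm import profile_xi

        pairs, truth = small_pairs
        best, prof = profile_xi(pairs, "signal_corr", grid=np.arange(1.2, 1.85, 0.1))
        assert np.isclose(best, truth.tweedie.xi, atol=0.1)
        assert len(prof) == 7 and prof["loglik"].notna().all()
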