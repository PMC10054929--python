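"""Functional similarity metrics, reliability statistics, tuning fits, STA."""

import numpy as np
import pytest

from liketolike import similarity as sim
from liketolike.synthetic import generate_sparse_noise_experiment


class TestSignalCorrelation:
    def test_identical_traces_give_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((3, 40))
        assert np.isclose(sim.signal_correlation(a, a, sampling_rate_hz=8), 1.0)

    def test_negated_traces_give_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((2, 40))
        a -= a.mean()
        assert np.isclose(sim.signal_correlation(a, -a, sampling_rate_hz=8), -1.0)

    def test_matches_direct_pearson_on_binned_vectors(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((4, 64))
        b = rng.standard_normal((4, 64))
        got = sim.signal_correlation(a, b, sampling_rate_hz=8, bin_ms=500)
        # independent recomputation: 4 samples per 500 ms bin at 8 Hz
        ab = a.reshape(4, 16, 4).mean(axis=2).ravel()
        bb = b.reshape(4, 16, 4).mean(axis=2).ravel()
        want = np.corrcoef(ab, bb)[0, 1]
        assert np.isclose(got, want)

    def test_zero_variance_returns_nan(self):
        a = np.ones((2, 16))
        b = np.random.default_rng(3).standard_normal((2, 16))
        assert np.isnan(sim.signal_correlation(a, b, sampling_rate_hz=8))

    def test_matrix_agrees_with_pairwise_calls(self):
        rng = np.random.default_rng(4)
        rm = sim.ResponseMatrix(rng.standard_normal((4, 3, 32)), sampling_rate_hz=8)
        mat = sim.signal_correlation_matrix(rm)
        got = sim.signal_correlation(rm.values[1], rm.values[2], sampling_rate_hz=8)
        assert np.isclose(mat[1, 2], got)


class TestReliability:
    def test_identical_trials_give_one(self):
        trace = np.sin(np.linspace(0, 6, 50))
        trials = np.tile(trace, (5, 1))
        assert np.isclose(sim.cc_max(trials), 1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(5)
        vals = [sim.cc_max(rng.standard_normal((20, 200))) for _ in range(50)]
        assert np.nanmean(vals) < 0.35  # clipped at 0, so the mean sits just above

    def test_matches_analytic_form_under_signal_plus_noise(self):
        # y_trial = s + noise: CCmax estimates sqrt(s2 / (s2 + sigma2/N))
        rng = np.random.default_rng(6)
        s2, sigma2, n_trials = 1.0, 2.0, 10
        want = np.sqrt(s2 / (s2 + sigma2 / n_trials))
        ests = []
        for _ in range(300):
            s = np.sqrt(s2) * rng.standard_normal(100)
            trials = s + np.sqrt(sigma2) * rng.standard_normal((n_trials, 100))
            ests.append(sim.cc_max(trials))
        assert abs(np.mean(ests) - want) < 0.01

    def test_cc_abs_is_pearson(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        assert np.isclose(sim.cc_abs(x, y), np.corrcoef(x, y)[0, 1])
        assert np.isclose(sim.cc_abs(y, y), 1.0)
        assert np.isnan(sim.cc_abs(np.ones(50), y[:50]))


class TestFeatureSimilarity:
    def test_closed_forms(self):
        w = np.array([1.0, 2.0, 3.0])
        assert np.isclose(sim.feature_similarity(w, w), 1.0)
        assert np.isclose(sim.feature_similarity(w, -w), -1.0)
        assert np.isclose(sim.feature_similarity([1, 0], [0, 1]), 0.0)

    def test_scale_invariance_and_zero_vector(self):
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal(16), rng.standard_normal(16)
        assert np.isclose(sim.feature_similarity(a, b), sim.feature_similarity(3 * a, 0.1 * b))
        with pytest.raises(ValueError):
            sim.feature_similarity(np.zeros(16), b)


class TestRfDistance:
    def test_identity_and_lateral_45_degrees(self):
        geom = sim.MonitorGeometry(distance_cm=15.0)
        assert sim.rf_center_distance((0, 0), (0, 0), geom) == 0.0
        assert np.isclose(sim.rf_center_distance((0, 0), (15, 0), geom), 45.0)

    def test_matches_vector_algebra_oracle_and_metric_axioms(self):
        rng = np.random.default_rng(9)
        geom = sim.MonitorGeometry()
        pts = rng.uniform(-20, 20, size=(12, 2))

        def oracle(p, q):
            rp = np.array([p[0], p[1], 15.0])
            rq = np.array([q[0], q[1], 15.0])
            return np.degrees(np.arccos(rp @ rq / np.linalg.norm(rp) / np.linalg.norm(rq)))

        for p in pts[:4]:
            for q in pts[4:8]:
                assert np.isclose(sim.rf_center_distance(p, q, geom), oracle(p, q))
                assert np.isclose(
                    sim.rf_center_distance(p, q, geom), sim.rf_center_distance(q, p, geom)
                )
        for p, q, r in zip(pts[:4], pts[4:8], pts[8:]):
            assert sim.rf_center_distance(p, r, geom) <= (
                sim.rf_center_distance(p, q, geom) + sim.rf_center_distance(q, r, geom) + 1e-9
            )


class TestOrientationMetrics:
    def test_gosi_closed_forms(self):
        assert np.isclose(sim.gosi(np.ones(16)), 0.0, atol=1e-12)
        single = np.zeros(16)
        single[3] = 2.0
        assert np.isclose(sim.gosi(single), 1.0)
        theta = np.radians(sim.direction_grid())
        assert np.isclose(sim.gosi(1 + np.cos(2 * theta)), 0.5)

    def test_gosi_scale_invariant_and_degenerate(self):
        rng = np.random.default_rng(10)
        r = rng.uniform(0.1, 1, 16)
        assert np.isclose(sim.gosi(r), sim.gosi(10 * r))
        assert np.isnan(sim.gosi(np.zeros(16)))

    def test_osi_peaked_curve(self):
        theta = np.radians(sim.direction_grid())
        r = 1 + np.cos(2 * theta)  # preferred orientation 0
        got = sim.osi(r, preferred_orientation=0.0)
        # R_po = 2 (directions 0/180), R_ortho = 0 (90/270)
        assert np.isclose(got, 1.0)

    @pytest.mark.parametrize("mu,kappa,p", [(30.0, 2.0, 0.7), (120.0, 5.0, 0.4), (77.0, 1.0, 0.5)])
    def test_von_mises_recovery_on_noiseless_curves(self, mu, kappa, p):
        theta = sim.direction_grid()
        curve = sim.von_mises_curve(theta, mu, kappa, p, 0.05)
        fit = sim.fit_von_mises(curve)
        assert fit.converged and not fit.degenerate
        err = min(abs(fit.preferred_orientation - mu % 180), 180 - abs(fit.preferred_orientation - mu % 180))
        assert err <= 1.0

    def test_symmetric_curve_orientation_invariant_under_peak_swap(self):
        theta = sim.direction_grid()
        curve = sim.von_mises_curve(theta, 40.0, 3.0, 0.5, 0.0)
        fit = sim.fit_von_mises(curve)
        assert np.isclose(fit.preferred_orientation % 180, 40.0, atol=1.0) or np.isclose(
            fit.preferred_orientation % 180, 40.0 + 180, atol=1.0
        )

    def test_flat_curve_flagged_degenerate(self):
        fit = sim.fit_von_mises(np.full(16, 0.4))
        assert fit.degenerate

    @pytest.mark.parametrize("a,b,want", [(10, 10, 0), (5, 175, 10), (0, 90, 90), (179, 1, 2)])
    def test_delta_orientation(self, a, b, want):
        assert np.isclose(sim.delta_orientation(a, b), want)


class TestSta:
    def test_gaussian_rf_recovered_within_one_cell(self):
        rng = np.random.default_rng(11)
        stim, resp = generate_sparse_noise_experiment((7.0, 4.0), rng=rng)
        fit = sim.sta_fit(stim, resp)
        assert fit.well_characterized and fit.well_fit
        assert abs(fit.center[0] - 7.0) <= 1.0
        assert abs(fit.center[1] - 4.0) <= 1.0

    def test_delta_response_centers_on_the_cell(self):
        rng = np.random.default_rng(12)
        stim, _ = generate_sparse_noise_experiment((5.0, 5.0), rng=rng, noise_sd=0.0)
        resp = (np.abs(stim[:, 5, 5]) > 0).astype(float)
        fit = sim.sta_fit(stim, resp)
        assert np.isclose(fit.center[0], 5.0, atol=0.5)
        assert np.isclose(fit.center[1], 5.0, atol=0.5)

    def test_noise_only_neuron_excluded(self):
        rng = np.random.default_rng(13)
        stim, _ = generate_sparse_noise_experiment((5.0, 5.0), rng=rng)
        resp = rng.standard_normal(stim.shape[0])
        fit = sim.sta_fit(stim, resp)
        assert not fit.well_characterized

    def test_combined_sta_is_pixelwise_max(self):
        rng = np.random.default_rng(14)
        stim, resp = generate_sparse_noise_experiment((3.0, 8.0), rng=rng)
        fit = sim.sta_fit(stim, resp)
        assert np.array_equal(fit.combined, np.maximum(fit.on_sta, fit.off_sta))


class TestPropertyBased:
    from hypothesis import given, settings, strategies as st

    @given(
        a=st.floats(min_value=0, max_value=180, exclude_max=True),
        b=st.floats(min_value=0, max_value=180, exclude_max=True),
    )
    @settings(max_examples=60, derandomize=True)
    def test_delta_orientation_is_a_metric_on_the_half_circle(self, a, b):
        d = sim.delta_orientation(a, b)
        assert 0 <= d <= 90
        assert np.isclose(d, sim.delta_orientation(b, a))
        assert sim.delta_orientation(a, a) == 0

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=40, derandomize=True)
    def test_gosi_invariant_to_uniform_rescaling(self, scale, seed):
        r = np.random.default_rng(seed).uniform(0.01, 1.0, 16)
        assert np.isclose(sim.gosi(r), sim.gosi(scale * r), atol=1e-9)
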