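"""Tests for waveform statistics: cluster permutation test, contrasts,
repeated-measures ANOVA, reference epochs."""

import numpy as np
import pytest
from scipy import stats

from gradedsdt.simulate import SimulationConfig, simulate_evoked_stream
from gradedsdt.waveforms import (WaveformSet, build_reference_epochs,
                                 cluster_permutation_test, gg_epsilon,
                                 polynomial_contrast_test,
                                 polynomial_contrasts, rm_anova_oneway,
                                 window_mean)


def wset(data, dt_ms=10.0, t0=0.0):
    data = np.atleast_2d(np.asarray(data, float))
    times = t0 + dt_ms * np.arange(data.shape[1])
    return WaveformSet(data=data, times_ms=times)


class TestWindowMean:
    def test_constant_waveform(self):
        ws = wset(np.full((3, 50), 4.2))
        np.testing.assert_allclose(window_mean(ws, (100, 400)), 4.2)

    def test_single_sample_window(self):
        ws = wset(np.arange(50.0)[None, :])
        assert window_mean(ws, (100, 100))[0] == 10.0

    def test_ramp_mean_is_half(self):
        ws = wset(np.linspace(0, 1, 101)[None, :], dt_ms=1.0)
        assert window_mean(ws, (0, 100))[0] == pytest.approx(0.5, abs=0.01)

    def test_empty_window_raises(self):
        ws = wset(np.zeros((2, 10)))
        with pytest.raises(ValueError):
            window_mean(ws, (1000, 2000))


class TestClusterTest:
    def test_identical_condition_and_reference_yield_no_clusters(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((10, 40))
        res = cluster_permutation_test(wset(data), wset(data.copy()),
                                       n_permutations=200, seed=1)
        assert res.clusters == []

    def test_strong_offset_spans_window_with_floor_p(self):
        rng = np.random.default_rng(1)
        data = 1.0 + 0.1 * rng.standard_normal((12, 40))
        res = cluster_permutation_test(wset(data), None,
                                       n_permutations=500, seed=2)
        assert len(res.clusters) == 1
        start, end, mass, p = res.clusters[0]
        assert start == res.times_ms[0] and end == res.times_ms[-1]
        assert mass > 0
        assert p <= 1 / 500

    def test_negative_going_effect_detected(self):
        rng = np.random.default_rng(2)
        data = 0.1 * rng.standard_normal((14, 60))
        data[:, 20:30] -= 1.0
        res = cluster_permutation_test(wset(data), None,
                                       n_permutations=500, seed=3)
        sig = res.significant
        assert len(sig) == 1 and sig[0][2] < 0

    def test_seeded_runs_are_reproducible(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((9, 30)) + 0.4
        a = cluster_permutation_test(wset(data), None, n_permutations=300,
                                     seed=42)
        b = cluster_permutation_test(wset(data), None, n_permutations=300,
                                     seed=42)
        assert a.clusters == b.clusters

    def test_mismatched_participants_raise(self):
        with pytest.raises(ValueError):
            cluster_permutation_test(wset(np.zeros((5, 20))),
                                     wset(np.zeros((6, 20))))

    def test_family_wise_error_under_null_is_near_alpha(self):
        """Quick calibration: i.i.d. null data should produce a significant
        cluster in roughly 5% of experiments."""
        rng = np.random.default_rng(4)
        n_exp, hits = 150, 0
        for _ in range(n_exp):
            data = rng.standard_normal((10, 30))
            res = cluster_permutation_test(wset(data), None,
                                           n_permutations=300,
                                           seed=int(rng.integers(2 ** 31)))
            hits += bool(res.significant)
        assert 0.005 <= hits / n_exp <= 0.12


class TestContrasts:
    def test_weights_are_orthonormal(self):
        lin, quad = polynomial_contrasts(6)
        assert lin @ quad == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(lin) == pytest.approx(1.0)
        assert np.sum(lin) == pytest.approx(0.0, abs=1e-12)

    def test_pure_linear_trend_has_no_quadratic_component(self):
        y = np.tile(np.arange(5.0), (8, 1)) + 0.5
        res = polynomial_contrast_test(y)
        assert res.quadratic_f == pytest.approx(0.0, abs=1e-12)
        assert res.linear_f > 1e3 or np.isinf(res.linear_f)

    def test_inverted_u_has_no_linear_component(self):
        bins = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        y = np.tile(bins, (8, 1))
        res = polynomial_contrast_test(y)
        assert res.linear_f == pytest.approx(0.0, abs=1e-12)
        assert res.quadratic_f > 1e3 or np.isinf(res.quadratic_f)

    def test_contrast_scores_uncorrelated_on_balanced_noise(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((10000, 5))
        lin, quad = polynomial_contrasts(5)
        r = np.corrcoef(y @ lin, y @ quad)[0, 1]
        assert abs(r) < 0.05

    def test_power_matches_noncentral_f(self):
        """Empirical power of the linear contrast at a known slope equals the
        analytic noncentral-t/F power."""
        rng = np.random.default_rng(6)
        n, k, slope, sigma = 17, 5, 0.15, 1.0
        lin, _ = polynomial_contrasts(k)
        mu = slope * np.arange(k)
        ncp = np.sqrt(n) * (lin @ mu) / sigma
        tcrit = stats.t.ppf(0.975, n - 1)
        analytic = stats.nct.sf(tcrit, n - 1, ncp) \
            + stats.nct.cdf(-tcrit, n - 1, ncp)
        reps, hits = 400, 0
        for _ in range(reps):
            y = mu + sigma * rng.standard_normal((n, k))
            hits += polynomial_contrast_test(y).linear_p < 0.05
        se = np.sqrt(analytic * (1 - analytic) / reps)
        assert abs(hits / reps - analytic) < 3.5 * se

    def test_missing_cells_rejected(self):
        y = np.ones((5, 4))
        y[0, 0] = np.nan
        with pytest.raises(ValueError):
            polynomial_contrast_test(y)


class TestRmAnova:
    def test_identical_bins_give_zero_f(self):
        y = np.tile(np.arange(8.0)[:, None], (1, 4))
        res = rm_anova_oneway(y)
        assert res["F"] == 0.0

    def test_two_bins_have_unit_epsilon(self):
        rng = np.random.default_rng(7)
        y = rng.standard_normal((12, 2))
        res = rm_anova_oneway(y)
        assert res["epsilon"] == pytest.approx(1.0)

    def test_detects_strong_within_subject_effect(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal((15, 4)) + np.array([0, 0.5, 1.0, 1.5])
        res = rm_anova_oneway(y)
        assert res["p_gg"] < 0.01 and res["F"] > 5

    def test_epsilon_recovery_from_known_covariance(self):
        """Estimated GG epsilon approaches the population value computed
        directly from the generating covariance matrix."""
        k = 4
        base = 0.9 ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        cov = base + np.diag([0.0, 0.5, 1.0, 1.5])  # break sphericity
        # population epsilon from the double-centered covariance
        h = np.eye(k) - np.ones((k, k)) / k
        s = h @ cov @ h
        eig = np.linalg.eigvalsh(s)[::-1][:k - 1]
        eps_true = eig.sum() ** 2 / ((k - 1) * (eig ** 2).sum())
        rng = np.random.default_rng(9)
        chol = np.linalg.cholesky(cov)
        y = rng.standard_normal((200, k)) @ chol.T
        eps_hat = rm_anova_oneway(y)["epsilon"]
        assert abs(eps_hat - eps_true) < 0.1
        assert gg_epsilon(y) == pytest.approx(eps_hat, abs=1e-6)


class TestReferenceEpochs:
    def test_zero_stream_gives_zero_epochs(self):
        fs = 500.0
        onsets = (np.arange(5) * 3.2 * fs).astype(int) + 100
        stream = np.zeros(int(onsets[-1] + 3.5 * fs))
        ws = build_reference_epochs(stream, onsets, fs=fs)
        assert ws.data.shape[0] == 5
        np.testing.assert_allclose(ws.data, 0.0)
        # the 2.0 s point maps to t = 0
        assert ws.times_ms[0] == pytest.approx(-100.0)
        assert 0.0 in ws.times_ms

    def test_onset_near_stream_end_skipped(self):
        fs = 500.0
        stream = np.zeros(int(10 * fs))
        onsets = [100, int(8 * fs)]  # second window would end at 11 s
        with pytest.warns(UserWarning):
            ws = build_reference_epochs(stream, onsets, fs=fs)
        assert ws.data.shape[0] == 1

    def test_decaying_evoked_responses_leave_quiet_reference(self):
        cfg = SimulationConfig()
        stream, onsets = simulate_evoked_stream(cfg, seed=1, n_onsets=30,
                                                fs=500.0, peak=1.0,
                                                decay_ms=300.0)
        ws = build_reference_epochs(stream, onsets, fs=500.0)
        assert np.abs(ws.data.mean(axis=1)).max() < 0.02 * 1.0
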