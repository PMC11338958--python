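"""Unit and property tests for the unequal-variance SDT machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from gradedsdt.sdt_core import (CriterionSet, GaussianSdtModel,
                                RatingProbabilities, UnderdeterminedError,
                                clip_rate, criterion_from_rates,
                                cumulative_response_rates, estimate_sigma_ratio,
                                fit_participant_criteria,
                                fit_signal_distribution, goodness_of_fit,
                                normalize_profiles, predicted_amplitudes,
                                solve_criterion)


class TestCriterionFromRates:
    @pytest.mark.parametrize("h, fa, expected, tol", [
        (0.5, 0.5, 0.0, 1e-12),
        (0.841, 0.159, 0.0, 1e-3),
        # frozen oracle: -(Phi^-1(0.594) + Phi^-1(0.099)) / 2
        (0.594, 0.099, 0.5247119, 1e-4),
    ])
    def test_known_values(self, h, fa, expected, tol):
        assert criterion_from_rates(h, fa) == pytest.approx(expected, abs=tol)

    def test_rate_outside_unit_interval_raises(self):
        with pytest.raises(ValueError):
            criterion_from_rates(1.2, 0.5)

    def test_extreme_rates_are_clipped_finite(self, caplog):
        c = criterion_from_rates(1.0, 0.0, n_signal=100, n_noise=100)
        assert np.isfinite(c) and c == pytest.approx(0.0, abs=1e-9)

    @given(h=st.floats(0.01, 0.99), fa=st.floats(0.01, 0.99))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_antisymmetry(self, h, fa):
        """c(H, FA) = -c(1-FA, 1-H): mirror-imaging the task flips the bias."""
        assert criterion_from_rates(h, fa) == pytest.approx(
            -criterion_from_rates(1 - fa, 1 - h), abs=1e-10)


class TestCumulativeRates:
    def test_uniform_probabilities(self):
        p = RatingProbabilities("signal", np.full(6, 1 / 6))
        roc = cumulative_response_rates(p, p)
        np.testing.assert_allclose(roc.hit_rates,
                                   [5 / 6, 4 / 6, 3 / 6, 2 / 6, 1 / 6])

    def test_all_mass_on_top_rating(self):
        p = RatingProbabilities("signal", np.array([0, 0, 0, 0, 0, 1.0]))
        roc = cumulative_response_rates(p, p)
        np.testing.assert_allclose(roc.hit_rates, np.ones(5))

    def test_direct_summation(self):
        p = RatingProbabilities("signal",
                                np.array([0.2, 0.1, 0.1, 0.1, 0.2, 0.3]))
        n = RatingProbabilities("noise", np.full(6, 1 / 6))
        roc = cumulative_response_rates(p, n)
        np.testing.assert_allclose(roc.hit_rates, [0.8, 0.7, 0.6, 0.5, 0.3])

    def test_conservation_differences_recover_probabilities(self):
        probs = np.array([0.05, 0.15, 0.2, 0.25, 0.2, 0.15])
        p = RatingProbabilities("signal", probs)
        roc = cumulative_response_rates(p, p)
        full = np.concatenate(([1.0], roc.hit_rates, [0.0]))
        np.testing.assert_allclose(-np.diff(full), probs, atol=1e-12)

    def test_length_mismatch_raises(self):
        a = RatingProbabilities("signal", np.full(6, 1 / 6))
        b = RatingProbabilities("noise", np.full(4, 0.25))
        with pytest.raises(ValueError):
            cumulative_response_rates(a, b)


class TestSolveCriterion:
    def test_median_of_standard_normal(self):
        assert solve_criterion(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_tail(self):
        # Phi(1) = 0.8413 so the upper tail 0.1587 cuts at ~1.0
        assert solve_criterion(0.1587) == pytest.approx(1.0, abs=1e-3)

    def test_signal_median(self, fitted_model):
        c = solve_criterion(0.5, *fitted_model.component("signal"))
        assert c == pytest.approx(1.385, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_tail_raises(self, p):
        with pytest.raises(ValueError):
            solve_criterion(p)


class TestSigmaRatio:
    def test_equal_variance_slope_is_one(self, criteria5):
        m = GaussianSdtModel(1.0, 1.0)
        roc = cumulative_response_rates(
            RatingProbabilities.analytic("signal", m, criteria5),
            RatingProbabilities.analytic("noise", m, criteria5))
        assert estimate_sigma_ratio(roc) == pytest.approx(1.0, abs=1e-6)

    def test_unequal_variance_analytic_slope(self, fitted_model, criteria5,
                                             analytic_probs):
        roc = cumulative_response_rates(*analytic_probs)
        assert estimate_sigma_ratio(roc) == pytest.approx(1 / 1.344, abs=1e-6)

    def test_identical_points_underdetermined(self):
        from gradedsdt.sdt_core import RocPoints
        roc = RocPoints(hit_rates=np.full(5, 0.6), fa_rates=np.full(5, 0.2))
        with pytest.raises(UnderdeterminedError):
            estimate_sigma_ratio(roc)


class TestFitSignalDistribution:
    def test_recovers_reported_parameters_exactly(self, analytic_probs):
        fit = fit_signal_distribution(*analytic_probs)
        assert fit.mu_signal == pytest.approx(1.385, abs=0.01)
        assert fit.sigma_signal == pytest.approx(1.344, abs=0.01)
        assert fit.delta_ratio == pytest.approx(1.385 / 0.344, abs=0.15)

    def test_equal_variance_self_consistency(self, criteria5):
        m = GaussianSdtModel(1.0, 1.0)
        fit = fit_signal_distribution(
            RatingProbabilities.analytic("signal", m, criteria5),
            RatingProbabilities.analytic("noise", m, criteria5))
        assert fit.mu_signal == pytest.approx(1.0, abs=0.01)
        assert fit.sigma_signal == pytest.approx(1.0, abs=0.01)

    @given(mu=st.floats(0.5, 3.0), sigma=st.floats(1.0, 2.0),
           gaps=st.tuples(*[st.floats(0.3, 0.8)] * 4),
           c1=st.floats(-0.5, 0.8))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_parameter_recovery_property(self, mu, sigma, gaps, c1):
        """Any unequal-variance model is recovered from exact probabilities."""
        crit = CriterionSet(c1 + np.concatenate(([0.0], np.cumsum(gaps))))
        m = GaussianSdtModel(mu, sigma)
        fit = fit_signal_distribution(
            RatingProbabilities.analytic("signal", m, crit),
            RatingProbabilities.analytic("noise", m, crit),
            mu_bounds=(0.0, 5.0))
        assert fit.mu_signal == pytest.approx(mu, abs=0.01)
        assert fit.sigma_signal == pytest.approx(sigma, abs=0.01)


class TestParticipantCriteria:
    def test_round_trip_recovers_generating_criteria(self, fitted_model,
                                                     criteria5, analytic_probs):
        cs = fit_participant_criteria(*analytic_probs, fitted_model)
        np.testing.assert_allclose(cs.criteria, criteria5.criteria, atol=1e-4)

    def test_round_trip_with_shifted_criteria(self, fitted_model):
        gen = CriterionSet(np.array([-0.2, 0.5, 0.9, 1.3, 2.6]))
        s = RatingProbabilities.analytic("signal", fitted_model, gen)
        n = RatingProbabilities.analytic("noise", fitted_model, gen)
        cs = fit_participant_criteria(s, n, fitted_model)
        np.testing.assert_allclose(cs.criteria, gen.criteria, atol=1e-4)

    def test_equal_classes_match_noise_only_solution(self):
        m = GaussianSdtModel(mu_signal=1e-9, sigma_signal=1.0)
        probs = np.array([0.1, 0.2, 0.2, 0.2, 0.2, 0.1])
        p = RatingProbabilities("signal", probs)
        q = RatingProbabilities("noise", probs)
        cs = fit_participant_criteria(p, q, m)
        expected = norm.isf(q.upper_tail())
        np.testing.assert_allclose(cs.criteria, expected, atol=1e-6)

    def test_degenerate_probabilities_are_flagged(self, fitted_model):
        s = RatingProbabilities("signal", np.array([0, 0, 0, 0, 0, 1.0]))
        n = RatingProbabilities("noise", np.array([1.0, 0, 0, 0, 0, 0]))
        cs = fit_participant_criteria(s, n, fitted_model)
        assert cs.repaired or cs.at_bounds


class TestPredictedAmplitudes:
    def test_half_line_truncation(self):
        m = GaussianSdtModel(1.0, 1.0)  # noise component N(0,1) is used
        prof = predicted_amplitudes(m, CriterionSet(np.array([0.0])), "noise")
        assert prof.values[1] == pytest.approx(0.7978845608, abs=1e-9)
        assert prof.values[0] == pytest.approx(-0.7978845608, abs=1e-9)

    def test_symmetric_central_bin_is_zero(self):
        m = GaussianSdtModel(1.0, 1.0)
        prof = predicted_amplitudes(m, CriterionSet(np.array([-1.0, 1.0])),
                                    "noise")
        assert prof.values[1] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_matches_quadrature(self, fitted_model, criteria5):
        """Truncated-mean closed form vs direct numerical integration."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            mu = rng.uniform(0, 3)
            sigma = rng.uniform(0.5, 2)
            crit = CriterionSet(np.sort(rng.uniform(-2, mu + 2, size=5)))
            m = GaussianSdtModel(mu, sigma)
            prof = predicted_amplitudes(m, crit, "signal")
            edges = crit.edges
            for i in range(6):
                lo = edges[i] if np.isfinite(edges[i]) else mu - 12 * sigma
                hi = edges[i + 1] if np.isfinite(edges[i + 1]) else mu + 12 * sigma
                mass, _ = quad(lambda x: norm.pdf(x, mu, sigma), lo, hi)
                if mass < 1e-6:
                    continue
                num, _ = quad(lambda x: x * norm.pdf(x, mu, sigma), lo, hi)
                assert prof.values[i] == pytest.approx(num / mass, abs=1e-8)

    def test_monotone_in_rating_for_unimodal_model(self, fitted_model,
                                                   criteria5):
        for cls in ("signal", "noise"):
            prof = predicted_amplitudes(fitted_model, criteria5, cls)
            assert np.all(np.diff(prof.values) > 0)

    def test_empty_bins_flagged_not_nan(self):
        m = GaussianSdtModel(1.0, 1.0)
        prof = predicted_amplitudes(
            m, CriterionSet(np.array([8.0, 8.5, 9.0, 9.5, 10.0])), "noise")
        assert np.all(np.isfinite(prof.values))
        assert prof.degenerate[1:].all() and not prof.degenerate[0]


class TestNormalization:
    def _raw(self, cls, values):
        from gradedsdt.sdt_core import AmplitudeProfile
        return AmplitudeProfile(cls, np.asarray(values, dtype=float))

    def test_linear_profile_arithmetic(self):
        noise = self._raw("noise", [1, 2, 3, 4, 5, 6])
        signal = self._raw("signal", [1, 2, 3, 4, 5, 6])
        n, s = normalize_profiles(noise, signal, shift=1.0, divisor=5.0)
        np.testing.assert_allclose(s.values, [0, 0.2, 0.4, 0.6, 0.8, 1.0])
        assert s.state == "shifted_and_scaled"

    def test_noise_anchor_maps_to_zero(self):
        noise = self._raw("noise", [-0.5, 0.1, 0.5, 1.0, 1.5, 2.0])
        signal = self._raw("signal", [0.2, 0.6, 1.0, 1.5, 2.0, 3.0])
        n, s = normalize_profiles(noise, signal, shift=-0.5)
        assert n.values[0] == pytest.approx(0.0, abs=1e-12)
        assert s.values[0] == pytest.approx(1.0, abs=1e-12)  # A_H1 anchor

    def test_profile_equal_to_shift_is_all_zero(self):
        prof = self._raw("noise", np.full(6, 2.5))
        n, s = normalize_profiles(prof, self._raw("signal", np.full(6, 2.5)),
                                  shift=2.5, divisor=1.0)
        assert np.all(n.values == 0) and np.all(s.values == 0)

    def test_nonpositive_divisor_raises(self):
        from gradedsdt.sdt_core import NormalizationError
        noise = self._raw("noise", [1, 2, 3, 4, 5, 6])
        signal = self._raw("signal", [0, 2, 3, 4, 5, 6])
        with pytest.raises(NormalizationError):
            normalize_profiles(noise, signal, shift=1.0)  # divisor = -1


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        y = np.array([0.0, 1, 2, 3, 4, 5])
        assert goodness_of_fit(y, y) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        y = np.array([0.0, 1, 2, 3, 4, 5])
        assert goodness_of_fit(np.full(6, y.mean()), y) == pytest.approx(0.0)

    def test_partial_fit_arithmetic(self):
        measured = np.array([0.0, 1, 2, 3, 4, 5])
        predicted = np.array([0.0, 0, 0, 3, 4, 5])
        assert goodness_of_fit(predicted, measured) == pytest.approx(
            1 - 5 / 17.5, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            goodness_of_fit(np.zeros(6), np.ones(6))


def test_clip_rate_uses_half_count_rule():
    assert clip_rate(0.0, 50) == pytest.approx(0.01)
    assert clip_rate(1.0, 50) == pytest.approx(0.99)
    assert clip_rate(0.4, 50) == pytest.approx(0.4)
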