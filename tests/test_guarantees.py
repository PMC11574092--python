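"""Privacy-accuracy calculators, loss accounting, and the DP audit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from privmob import (
    PrivacyLedger,
    difference_detection_error,
    empirical_dp_audit,
    epsilon_for_error_bound,
    expected_privacy_loss,
    heuristic_epsilon_for_error,
    laplace_cell_std,
    suppression_probability,
    tau_from_standard,
    total_privacy_loss,
)
from privmob.guarantees import _privatize_counts


class TestEpsilonCalculators:
    def test_heuristic_worked_examples(self):
        assert heuristic_epsilon_for_error(10, T=1) == pytest.approx(math.sqrt(2) / 10)
        assert round(heuristic_epsilon_for_error(10, T=1), 2) == 0.14
        assert round(heuristic_epsilon_for_error(50, T=1), 3) == 0.028

    def test_heuristic_linear_in_T(self):
        assert heuristic_epsilon_for_error(7.0, T=2) == pytest.approx(
            2 * heuristic_epsilon_for_error(7.0, T=1)
        )

    def test_tail_bound_worked_example(self):
        eps = epsilon_for_error_bound(alpha=10, delta=0.05, T=1)
        assert eps == pytest.approx(-math.log(0.05) / 10.5)
        assert round(eps, 3) == 0.285

    def test_tail_bound_vacuous_confidence(self):
        assert epsilon_for_error_bound(alpha=3, delta=1.0, T=5) == 0.0

    def test_tail_bound_permits_larger_epsilon_than_heuristic(self):
        """Same goal (error <= 10), but the tail bound allows epsilon 0.285 > 0.14."""
        assert epsilon_for_error_bound(10, 0.05) > heuristic_epsilon_for_error(10)

    @settings(max_examples=50, deadline=None)
    @given(
        alpha=st.floats(0.0, 100.0),
        delta=st.floats(0.001, 1.0),
        T=st.integers(1, 5),
    )
    def test_tail_bound_monotonicity(self, alpha, delta, T):
        eps = epsilon_for_error_bound(alpha, delta, T)
        assert eps >= 0
        assert eps >= epsilon_for_error_bound(alpha + 1, delta, T)
        assert eps <= epsilon_for_error_bound(alpha, delta / 2, T)

    def test_tail_bound_calibration_monte_carlo(self):
        """At the returned epsilon, the rounded error exceeds alpha with frequency <= delta."""
        alpha, delta = 10, 0.05
        eps = epsilon_for_error_bound(alpha, delta, T=1)
        rng = np.random.default_rng(0)
        reps = 1_000_000
        released = _privatize_counts(np.full(reps, 500.0), eps, 1, 0, rng)
        exceed = np.abs(released - 500.0) > alpha
        band = 3 * math.sqrt(delta * (1 - delta) / reps)
        assert exceed.mean() <= delta + band

    def test_cell_std_formula(self):
        assert laplace_cell_std(1, 1.0) == pytest.approx(math.sqrt(2))
        assert laplace_cell_std(1, 0.1) == pytest.approx(14.142, abs=0.001)
        x = np.random.default_rng(1).laplace(scale=1 / 0.1, size=1_000_000)
        assert laplace_cell_std(1, 0.1) == pytest.approx(x.std(), rel=0.01)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            heuristic_epsilon_for_error(0.0)
        with pytest.raises(ValueError):
            epsilon_for_error_bound(10, 0.0)
        with pytest.raises(ValueError):
            laplace_cell_std(1, 0.0)


class TestTauFromStandard:
    def test_unchanged_keeps_standard(self):
        assert tau_from_standard(15, epsilon=0.5, direction="unchanged") == 15

    def test_maximize_protection_adds_noise_std(self):
        # 15 + sqrt(2)/0.5 = 17.83 -> 18
        assert tau_from_standard(15, epsilon=0.5, direction="maximize-protection") == 18

    def test_minimize_suppression_clamped_at_zero(self):
        assert tau_from_standard(1, epsilon=0.1, direction="minimize-suppression") == 0


class TestPrivacyLedger:
    def test_trip_level_composition_printed_examples(self):
        """eps=0.5 with 14 or 52 mean trips gives losses 7 and 26."""
        admin2 = PrivacyLedger("trip-level", epsilon=0.5, releases=(14,))
        admin3 = PrivacyLedger("trip-level", epsilon=0.5, releases=(52,))
        assert total_privacy_loss(admin2) == pytest.approx(7.0)
        assert total_privacy_loss(admin3) == pytest.approx(26.0)

    def test_daily_loss_accumulation(self):
        """A 2.64/day deployment costs 18.48 over 7 days and 805.2 over 305."""
        week = PrivacyLedger("individual-level", epsilon=2.64, releases=(1,) * 7)
        year = PrivacyLedger("individual-level", epsilon=2.64, releases=(1,) * 305)
        assert total_privacy_loss(week) == pytest.approx(18.48)
        assert total_privacy_loss(year) == pytest.approx(805.2)

    def test_no_data_no_loss(self):
        assert total_privacy_loss(PrivacyLedger("trip-level", epsilon=0.5)) == 0.0

    def test_individual_level_costs_epsilon_per_release(self):
        ledger = PrivacyLedger("individual-level", epsilon=0.3, releases=(99, 1))
        assert total_privacy_loss(ledger) == pytest.approx(0.6)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.lists(st.floats(0, 20), max_size=10),
        b=st.lists(st.floats(0, 20), max_size=10),
    )
    def test_additivity_under_concatenation(self, a, b):
        la = PrivacyLedger("trip-level", 0.5, tuple(a))
        lb = PrivacyLedger("trip-level", 0.5, tuple(b))
        assert total_privacy_loss(la + lb) == pytest.approx(
            total_privacy_loss(la) + total_privacy_loss(lb)
        )

    def test_negative_contribution_rejected(self):
        with pytest.raises(ValueError):
            PrivacyLedger("trip-level", 0.5, (-1,))


class TestExpectedLoss:
    @pytest.mark.parametrize(
        "epsilon,mean_trips,expected",
        [(0.5, 2.88, 1.44), (0.5, 0.26, 0.13), (0.5, 1.53, 0.765), (1.0, 0.0, 0.0)],
    )
    def test_expected_loss_examples(self, epsilon, mean_trips, expected):
        assert expected_privacy_loss(epsilon, mean_trips) == pytest.approx(expected)


class TestSuppressionProbability:
    def test_count_at_threshold_is_fifty_fifty(self):
        assert suppression_probability(15, tau=15, epsilon=0.5) == pytest.approx(0.5)

    def test_empty_cell_closed_form(self):
        # P(Laplace(10) < 15) = 1 - exp(-1.5)/2
        assert suppression_probability(0, tau=15, epsilon=0.1) == pytest.approx(
            1 - 0.5 * math.exp(-1.5)
        )

    def test_large_count_never_suppressed(self):
        assert suppression_probability(100, tau=15, epsilon=1.0) == pytest.approx(
            0.5 * math.exp(-85), abs=1e-12
        )

    def test_agrees_with_mechanism_monte_carlo(self):
        """Closed form matches the empirical suppression frequency of the release rule."""
        rng = np.random.default_rng(5)
        reps = 100_000
        for count, tau, eps in [(0, 15, 0.1), (10, 15, 0.5), (20, 15, 1.0)]:
            noisy = count + rng.laplace(scale=1 / eps, size=reps)
            freq = (noisy < tau).mean()
            p = suppression_probability(count, tau, eps)
            band = 3 * math.sqrt(max(p * (1 - p), 1e-12) / reps)
            assert abs(freq - p) < band + 1e-9


class TestDifferenceDetection:
    def test_vanishing_noise(self):
        err = difference_detection_error((500, 300), epsilon=1e9, reps=100, seed=0)
        assert err == pytest.approx(0.0, abs=1e-6)

    def test_error_decreases_with_epsilon(self):
        errs = {
            eps: difference_detection_error((5000, 3000), eps, reps=100_000, seed=1)
            for eps in (0.5, 1.0, 2.0)
        }
        assert errs[2.0] < errs[1.0] < errs[0.5]

    def test_scale_equivariance_in_T(self):
        e1 = difference_detection_error((5000, 3000), 1.0, T=1, reps=200_000, seed=2)
        e2 = difference_detection_error((5000, 3000), 1.0, T=2, reps=200_000, seed=2)
        assert e2 == pytest.approx(2 * e1, rel=0.05)


class TestEmpiricalAudit:
    def test_mechanism_respects_epsilon_bound(self):
        """Output histograms on neighboring data differ by at most e^epsilon."""
        report = empirical_dp_audit(
            count=2, neighbor_count=3, epsilon=1.0, tau=2, reps=200_000, seed=3
        )
        assert report.passed
        assert report.max_abs_log_ratio <= report.bound + report.tolerance

    def test_non_neighboring_inputs_rejected(self):
        with pytest.raises(ValueError):
            empirical_dp_audit(count=2, neighbor_count=5, epsilon=1.0)
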