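"""IPCW machinery: reverse KM, weights, Brier score, R^2, calibration."""

import numpy as np
import pytest

from jointpredict.cohort import Cohort
from jointpredict.validation import (
    CensoringEstimate,
    brier_error,
    calibration_table,
    censoring_km,
    ipcw_weight,
    ipcw_weights,
    km_conditional_death,
    km_reference_error,
    prediction_error_curve,
    r_squared,
)
from conftest import constant_joint_params, make_subject


def brier_brute_force(P, T, delta, s, w, G):
    """Independent double-loop coding of the IPCW Brier score."""
    total = 0.0
    gs = float(G(s))
    for p, t, d in zip(P, T, delta):
        if t <= s + w and d == 1:
            h = gs / float(G.left_limit(t))
        elif t > s + w:
            h = gs / float(G(s + w))
        else:
            h = 0.0
        total += ((1.0 if t > s + w else 0.0) - (1.0 - p)) ** 2 * h
    return total / len(P)


class TestCensoringKm:
    def test_no_censoring_gives_unit_survival(self):
        G = censoring_km(np.array([2.0, 4.0, 6.0]), np.array([1, 1, 1]))
        assert float(G(5.9)) == 1.0

    def test_all_censored_at_single_time(self):
        G = censoring_km(np.array([3.0, 3.0, 3.0]), np.array([0, 0, 0]))
        assert float(G(2.9)) == 1.0
        assert float(G(3.0)) == 0.0

    def test_hand_computed_three_point_example(self):
        # times 2, 4, 6 with deaths at 2 and 6, censoring at 4:
        # the censoring process has one event at t=4 with 2 at risk
        G = censoring_km(np.array([2.0, 4.0, 6.0]), np.array([1, 0, 1]))
        assert float(G.left_limit(4.0)) == 1.0
        assert float(G(4.0)) == pytest.approx(0.5)


class TestIpcwWeights:
    def test_no_censoring_all_weights_one(self):
        G = CensoringEstimate(np.array([99.0]), np.array([1.0]))
        T = np.array([3.0, 12.0, 7.0])
        d = np.array([1, 0, 1])
        np.testing.assert_allclose(ipcw_weights(T, d, 2.0, 6.0, G), 1.0)

    def test_censored_inside_window_gets_zero(self):
        G = CensoringEstimate(np.array([99.0]), np.array([1.0]))
        assert ipcw_weight(5.0, 0, 2.0, 6.0, G) == 0.0

    def test_direct_substitution_example(self):
        # G(s)=1, G(T-)=0.8 for a death inside the window -> 1/0.8
        G = CensoringEstimate(np.array([3.0, 20.0]), np.array([0.8, 0.1]))
        assert ipcw_weight(4.0, 1, 2.0, 6.0, G) == pytest.approx(1.25)

    def test_positivity_violation_raises(self):
        G = CensoringEstimate(np.array([5.0]), np.array([0.0]))
        with pytest.raises(ZeroDivisionError):
            ipcw_weights(np.array([12.0]), np.array([0]), 2.0, 6.0, G)

    def test_subject_not_at_risk_rejected(self):
        G = CensoringEstimate(np.array([99.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            ipcw_weights(np.array([1.0]), np.array([1]), 2.0, 6.0, G)


class TestBrierScore:
    def test_perfect_foresight_zero_error(self):
        G = CensoringEstimate(np.array([99.0]), np.array([1.0]))
        T = np.array([3.0, 12.0, 4.0, 20.0])
        d = np.array([1, 1, 1, 1])
        P = (T <= 8.0).astype(float)
        assert brier_error(P, T, d, 2.0, 6.0, G) == 0.0

    def test_constant_half_prediction_quarter_error(self):
        G = CensoringEstimate(np.array([99.0]), np.array([1.0]))
        T = np.array([3.0, 4.0, 12.0, 20.0])
        d = np.array([1, 1, 1, 1])
        assert brier_error(np.full(4, 0.5), T, d, 2.0, 6.0, G) == pytest.approx(0.25)

    def test_matches_brute_force_with_censoring(self):
        rng = np.random.default_rng(17)
        T = 2.0 + rng.exponential(6.0, 50)
        d = rng.integers(0, 2, 50)
        G = censoring_km(T, d)
        P = rng.uniform(0, 1, 50)
        s, w = 2.0, 5.0
        assert brier_error(P, T, d, s, w, G) == pytest.approx(
            brier_brute_force(P, T, d, s, w, G), abs=1e-12
        )

    def test_unweighted_mse_when_censoring_free(self):
        rng = np.random.default_rng(18)
        T = 2.0 + rng.exponential(6.0, 80)
        d = np.ones(80, dtype=int)
        G = censoring_km(T, d)
        P = rng.uniform(0, 1, 80)
        s, w = 2.0, 4.0
        mse = np.mean(((T > s + w).astype(float) - (1 - P)) ** 2)
        assert brier_error(P, T, d, s, w, G) == pytest.approx(mse, abs=1e-12)

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(19)
        T = 2.0 + rng.exponential(6.0, 40)
        d = rng.integers(0, 2, 40)
        G = censoring_km(T, d)
        P = rng.uniform(0, 1, 40)
        perm = rng.permutation(40)
        assert brier_error(P, T, d, 2.0, 5.0, G) == pytest.approx(
            brier_error(P[perm], T[perm], d[perm], 2.0, 5.0, G), abs=1e-14
        )

    def test_prediction_outside_unit_interval_rejected(self):
        G = CensoringEstimate(np.array([99.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            brier_error(np.array([1.2]), np.array([9.0]), np.array([1]), 2.0, 5.0, G)


class TestReferenceErrorAndR2:
    def test_km_reference_matches_brute_force(self):
        rng = np.random.default_rng(20)
        T = rng.exponential(8.0, 60) + 0.5
        d = np.ones(60, dtype=int)
        G = censoring_km(T, d)
        s, w = 1.0, 4.0
        at = T > s
        p_km = km_conditional_death(T, d, s, w)
        want = brier_brute_force(np.full(at.sum(), p_km), T[at], d[at], s, w, G)
        assert km_reference_error(T, d, s, w, G) == pytest.approx(want, abs=1e-12)

    def test_all_survivors_zero_reference(self):
        T = np.full(30, 20.0)
        d = np.zeros(30, dtype=int)
        G = censoring_km(T, d)
        assert km_conditional_death(T, np.ones(30, dtype=int), 2.0, 5.0) == 0.0

    def test_r2_arithmetic_and_edge_cases(self):
        assert r_squared(0.15, 0.20) == pytest.approx(0.25)
        assert r_squared(0.2, 0.2) == 0.0
        assert r_squared(0.0, 0.2) == 1.0
        with pytest.warns(UserWarning):
            assert np.isnan(r_squared(0.1, 0.0))


class TestPredictionErrorCurve:
    def test_single_point_matches_direct_call(self):
        rng = np.random.default_rng(23)
        subs = [
            make_subject(f"s{i}", (), 0.5 + rng.exponential(7.0), int(rng.random() < 0.7))
            for i in range(60)
        ]
        cohort = Cohort(subs)
        probs = {s.id: rng.uniform(0, 1) for s in cohort}
        res = prediction_error_curve(cohort, lambda s_, a, b: probs[s_.id], [(2.0, 4.0)])
        G = censoring_km(cohort)
        at = [s for s in cohort if s.followup_time > 2.0]
        direct = brier_error(
            np.array([probs[s.id] for s in at]),
            np.array([s.followup_time for s in at]),
            np.array([s.death_indicator for s in at]),
            2.0, 4.0, G,
        )
        assert res[0].error == direct
        assert res[0].n_eval == len(at)

    def test_empty_risk_set_skipped_with_warning(self, toy_cohort):
        with pytest.warns(UserWarning, match="empty"):
            res = prediction_error_curve(toy_cohort, lambda s, a, b: 0.1, [(50.0, 1.0)])
        assert res == []


class TestCalibration:
    def test_decile_counts_partition_sample(self):
        rng = np.random.default_rng(25)
        P = rng.uniform(0, 1, 500)
        T = 2.0 + rng.exponential(6.0, 500)
        d = np.ones(500, dtype=int)
        ct = calibration_table(P, T, d, 2.0, 5.0)
        assert ct.counts.sum() == 500
        assert len(ct.counts) == 10
        assert ct.histogram_counts.sum() == 500

    def test_all_survivors_zero_predictions(self):
        P = np.zeros(50)
        T = np.full(50, 30.0)
        d = np.zeros(50, dtype=int)
        with pytest.warns(UserWarning, match="collapse"):
            ct = calibration_table(P, T, d, 2.0, 5.0)
        assert len(ct.counts) == 1
        assert ct.mean_predicted[0] == 0.0 and ct.observed[0] == 0.0

    def test_self_calibrated_outcomes_fall_in_ci(self):
        # outcomes drawn from the predictions themselves: death before s+w
        # with probability P, otherwise survival past the window
        rng = np.random.default_rng(26)
        n = 10_000
        P = rng.beta(1.2, 4.0, n)
        dies = rng.random(n) < P
        s, w = 2.0, 5.0
        T = np.where(dies, s + rng.uniform(0.05, 0.95, n) * w, s + w + 5.0)
        d = dies.astype(int)
        ct = calibration_table(P, T, d, s, w)
        inside = np.sum((ct.mean_predicted >= ct.ci_low) & (ct.mean_predicted <= ct.ci_high))
        assert inside >= 9
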