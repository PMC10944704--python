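"""Detection layer: generator, diel intensity, segments, history likelihood."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given
from hypothesis import strategies as st

from ctocc.errors import ValidationError
from ctocc.mmpp import (CondDetectionParams, IntensityParams, SwitchParams,
                        build_generator, history_loglik, log_intensity,
                        prop_detectable, stationary_dist, transition_segment)
from ctocc.simulate import mc_segment_probs, mc_zero_detection_prob

mus = st.floats(min_value=-5, max_value=3, allow_nan=False)


class TestGenerator:
    def test_unit_rates(self):
        Q = build_generator(SwitchParams(0.0, 0.0))
        assert np.array_equal(Q, [[-1, 1], [1, -1]])

    @given(mus, mus)
    def test_rows_sum_to_zero(self, m1, m2):
        Q = build_generator(SwitchParams(m1, m2))
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert Q[0, 1] > 0 and Q[1, 0] > 0

    def test_stationary_three_to_one(self):
        sw = SwitchParams(np.log(3.0), 0.0)
        assert stationary_dist(sw) == pytest.approx([0.25, 0.75])


class TestPropDetectable:
    def test_symmetric_rates(self):
        assert prop_detectable(SwitchParams(1.3, 1.3)) == 0.5

    def test_one_in_ten(self):
        assert prop_detectable(SwitchParams(np.log(1.0), np.log(9.0))) == \
            pytest.approx(0.1)

    def test_matches_null_vector_of_generator(self, rng):
        # linear-algebra oracle: left null vector of Q, normalized
        for _ in range(100):
            sw = SwitchParams(*rng.normal(0, 2, 2))
            Q = build_generator(sw)
            ns = scipy.linalg.null_space(Q.T).ravel()
            ns = ns / ns.sum()
            assert prop_detectable(sw) == pytest.approx(ns[1], abs=1e-10)


class TestLogIntensity:
    def test_zero_coefficients_unit_rate(self):
        ip = IntensityParams(0.0, (0, 0, 0, 0), {})
        t = np.linspace(0, 23.9, 50)
        assert np.allclose(log_intensity(t, {}, ip), 0.0)

    def test_halved_intercept_convention(self):
        ip = IntensityParams(2.0, (), {})
        assert np.exp(log_intensity(0.0, {}, ip)) == pytest.approx(np.e)

    def test_periodicity(self, rng):
        ip = IntensityParams(0.3, tuple(rng.normal(0, 1, 4)), {})
        t = rng.uniform(0, 24, 40)
        assert np.allclose(log_intensity(t, {}, ip),
                           log_intensity(t + 24.0, {}, ip), atol=1e-12)


class TestTransitionSegment:
    Q = build_generator(SwitchParams(np.log(0.4), np.log(2.0)))

    def test_zero_intensity_is_stochastic(self):
        seg = transition_segment(self.Q, lambda c: 0.0, 0.0, 5.0)
        assert np.allclose(seg.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(seg >= 0)

    def test_constant_intensity_exact_for_any_grid(self):
        lam = 1.3
        ref = scipy.linalg.expm((self.Q - np.diag([0.0, lam])) * 7.7)
        for grid in (10.0, 0.25, 0.01):
            seg = transition_segment(self.Q, lambda c: lam, 1.1, 8.8, grid,
                                     start_clock=3.0)
            assert np.allclose(seg, ref, atol=1e-12)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValidationError):
            transition_segment(self.Q, lambda c: 1.0, 2.0, 2.0)

    def test_substochastic_for_random_parameters(self, rng):
        for _ in range(30):
            Q = build_generator(SwitchParams(*rng.normal(0, 1.5, 2)))
            lam0 = np.exp(rng.normal(0, 1))
            seg = transition_segment(Q, lambda c: lam0 * (1.2 + np.cos(c)),
                                     0.0, rng.uniform(0.5, 40.0), 0.5,
                                     start_clock=rng.uniform(0, 24))
            assert np.all(seg >= -1e-15)
            assert np.all(seg.sum(axis=1) <= 1.0 + 1e-12)

    def test_monte_carlo_oracle_sinusoidal(self):
        # P(start detectable, no detection over a day, end detectable)
        cond = CondDetectionParams(
            SwitchParams(np.log(0.25), np.log(1.2)),
            IntensityParams(-1.0, (0.8, -0.4, 0.0, 0.0), {}),
        )
        Q = build_generator(cond.switch)
        seg = transition_segment(
            Q, lambda c: float(np.exp(log_intensity(c, {}, cond.intensity))),
            0.0, 24.0, 0.25)
        (p0, p1), se = mc_segment_probs(cond, 24.0, 0.0, {}, 30_000, rng=5,
                                        init_state=1)
        assert seg[1, 1] == pytest.approx(p1, abs=3 * max(se, 1e-4))
        assert seg[1, 0] == pytest.approx(p0, abs=3 * max(se, 1e-4))


class TestHistoryLoglik:
    def test_zero_intensity_nothing_detectable(self):
        cond = CondDetectionParams(SwitchParams(0.0, 0.0),
                                   IntensityParams(-2000.0, (), {}))
        assert history_loglik([], 100.0, cond) == pytest.approx(0.0, abs=1e-12)

    def test_poisson_collapse(self):
        # absorbing detectable state: the MMPP degenerates to a Poisson process
        cond = CondDetectionParams(SwitchParams(0.0, -25.0),
                                   IntensityParams(0.0, (), {}))
        ll = history_loglik([0.5, 1.5], 2.0, cond)
        assert ll == pytest.approx(-2.0, abs=1e-6)

    def test_zero_detection_matches_monte_carlo(self):
        cond = CondDetectionParams(SwitchParams(0.0, 0.0),
                                   IntensityParams(2 * np.log(2.0), (), {}))
        ll0 = history_loglik([], 1.0, cond)
        p, se = mc_zero_detection_prob(cond, 1.0, 0.0, {}, 20_000, rng=3)
        assert np.exp(ll0) == pytest.approx(p, abs=3 * se)

    def test_grid_convergence_is_second_order(self):
        # piecewise-constant midpoint scheme: halving the grid shrinks the
        # change by ~4x, so successive differences form a Cauchy sequence
        cond = CondDetectionParams(
            SwitchParams(-1.0, 1.5),
            IntensityParams(1.0, (0.6, -0.3, 0.4, 0.2), {}),
        )
        events = [3.3, 10.1, 26.7, 30.2]
        lls = [history_loglik(events, 48.0, cond, grid_hours=h, start_clock=6.0)
               for h in (0.5, 0.25, 0.125, 0.0625)]
        d1, d2, d3 = (abs(lls[1] - lls[0]), abs(lls[2] - lls[1]),
                      abs(lls[3] - lls[2]))
        assert d2 < 0.5 * d1 and d3 < 0.5 * d2
        assert d3 < 1e-4

    def test_phase_shift_invariance_with_constant_intensity(self):
        cond = CondDetectionParams(SwitchParams(-0.5, 0.8),
                                   IntensityParams(0.6, (), {}))
        events = [1.0, 7.5, 20.0]
        lls = [history_loglik(events, 30.0, cond, start_clock=c)
               for c in (0.0, 5.5, 13.0, 23.9)]
        assert np.allclose(lls, lls[0], atol=1e-10)

    def test_total_probability_via_monte_carlo(self):
        # sum over n of P(n detections) = 1: compare P(>=1) with MC frequency
        cond = CondDetectionParams(SwitchParams(-0.7, 0.3),
                                   IntensityParams(1.2, (0.5, 0, 0, 0), {}))
        ll0 = history_loglik([], 24.0, cond, start_clock=4.0)
        p, se = mc_zero_detection_prob(cond, 24.0, 4.0, {}, 20_000, rng=11)
        assert 1.0 - np.exp(ll0) == pytest.approx(1.0 - p, abs=3 * se)

    def test_event_outside_window_rejected(self):
        cond = CondDetectionParams(SwitchParams(0.0, 0.0),
                                   IntensityParams(0.0, (), {}))
        with pytest.raises(ValidationError):
            history_loglik([2.0], 2.0, cond)
        with pytest.raises(ValidationError):
            history_loglik([1.0, 0.5], 2.0, cond)

    def test_many_events_no_underflow(self):
        cond = CondDetectionParams(SwitchParams(1.0, 1.0),
                                   IntensityParams(4.0, (), {}))
        events = np.linspace(0.01, 999.9, 10_000)
        ll = history_loglik(events, 1000.0, cond, grid_hours=24.0)
        assert np.isfinite(ll)
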