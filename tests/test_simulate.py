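"""Synthetic-data generator: determinism, distributional checks, oracles."""

import numpy as np
import pytest

from ctocc.io import Deployment
from ctocc.mmpp import (CondDetectionParams, IntensityParams, SwitchParams,
                        history_loglik)
from ctocc.occupancy import StateProbs, compute_state_probs
from ctocc.params import FullParams
from ctocc.occupancy import OccupancyParams
from ctocc.simulate import (default_config, mc_zero_detection_prob,
                            scaled_config, simulate_dataset,
                            simulate_detections, simulate_occupancy)


class TestSimulateOccupancy:
    def test_degenerate_psi_all_cooccur(self, rng):
        z = simulate_occupancy(StateProbs(np.array([1.0, 0, 0, 0])), 50, rng)
        assert all(zi == (1, 1) for zi in z)

    def test_uniform_psi_frequencies(self, rng):
        n = 100_000
        z = np.array(simulate_occupancy(StateProbs(np.full(4, 0.25)), n, rng))
        counts = np.array([
            np.sum((z[:, 0] == a) & (z[:, 1] == b))
            for a, b in ((1, 1), (1, 0), (0, 1), (0, 0))]) / n
        assert np.all(np.abs(counts - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n))

    def test_frequencies_match_state_probs(self, rng):
        psi = compute_state_probs(0.8, -0.4, 0.9)
        n = 100_000
        z = np.array(simulate_occupancy(psi, n, rng))
        counts = np.array([
            np.sum((z[:, 0] == a) & (z[:, 1] == b))
            for a, b in ((1, 1), (1, 0), (0, 1), (0, 0))]) / n
        se = np.sqrt(psi.psi * (1 - psi.psi) / n)
        assert np.all(np.abs(counts - psi.psi) < 3 * se + 1e-9)


def _dep(T=48.0, clock=6.0):
    import pandas as pd
    start = pd.Timestamp("2021-04-01") + pd.Timedelta(hours=clock)
    return Deployment("s1", start, T, {"ndvi": 0.0})


def _full(prey_cond, pred_cond=None):
    pred_cond = pred_cond or prey_cond
    return FullParams(occ=OccupancyParams(), prey_present=prey_cond,
                      prey_absent=prey_cond, predator=pred_cond)


class TestSimulateDetections:
    def test_zero_intensity_never_detects(self, rng):
        cond = CondDetectionParams(SwitchParams(0.0, 0.0),
                                   IntensityParams(-2000.0, (), {}))
        out = simulate_detections((1, 1), _dep(), _full(cond), rng)
        assert out == {}

    def test_absent_species_yield_no_history(self, rng):
        cond = CondDetectionParams(SwitchParams(2.0, -2.0),
                                   IntensityParams(2.0, (), {}))
        out = simulate_detections((0, 0), _dep(), _full(cond), rng)
        assert out == {}
        out = simulate_detections((1, 0), _dep(), _full(cond), rng)
        assert set(out) <= {"prey"}

    def test_poisson_limit_mean_count(self, rng):
        # absorbing detectable state, constant rate 2/h over 10 h -> mean 20
        cond = CondDetectionParams(SwitchParams(0.0, -25.0),
                                   IntensityParams(2 * np.log(2.0), (), {}))
        counts = []
        for _ in range(2000):
            out = simulate_detections((1, 0), _dep(T=10.0), _full(cond), rng)
            counts.append(out["prey"].n_events if "prey" in out else 0)
        mean = np.mean(counts)
        assert abs(mean - 20.0) < 3 * np.sqrt(20.0 / 2000)

    def test_zero_detection_prob_matches_likelihood(self):
        # the central oracle, run from the simulator's side
        cond = CondDetectionParams(
            SwitchParams(-1.5, 0.5),
            IntensityParams(1.0, (0.6, -0.2, 0.3, 0.0), {}))
        ll0 = history_loglik([], 36.0, cond, {}, 0.25, "stationary", 8.0)
        p, se = mc_zero_detection_prob(cond, 36.0, 8.0, {}, 30_000, rng=17)
        assert np.exp(ll0) == pytest.approx(p, abs=3 * se)


class TestSimulateDataset:
    def test_seed_determinism(self):
        cfg = scaled_config(n_sites=15, seed=42)
        a, ta = simulate_dataset(cfg)
        b, tb = simulate_dataset(cfg)
        assert ta.z == tb.z
        assert set(a.histories) == set(b.histories)
        for key in a.histories:
            assert np.array_equal(a.histories[key].event_times_hours,
                                  b.histories[key].event_times_hours)

    def test_z_consistent_with_detections(self):
        cfg = scaled_config(n_sites=60, seed=5)
        ds, truth = simulate_dataset(cfg)
        for i, d in enumerate(ds.deployments):
            if ds.history(d.site_id, "prey") is not None:
                assert truth.z[i][0] == 1
            if ds.history(d.site_id, "predator") is not None:
                assert truth.z[i][1] == 1

    def test_impossible_predator_never_detected(self):
        cfg = scaled_config(n_sites=40, seed=6)
        cfg.f2 = -40.0
        ds, truth = simulate_dataset(cfg)
        assert ds.n_events("predator") == 0
        assert all(z[1] == 0 for z in truth.z)

    def test_prey_commoner_than_predator_in_replicates(self):
        # generating truth orders the naive occupancies
        wins = 0
        for r in range(10):
            cfg = scaled_config(n_sites=100, seed=900 + r)
            ds, _ = simulate_dataset(cfg)
            wins += (ds.naive_occupancy("prey") >= ds.naive_occupancy("predator"))
        assert wins >= 9

    def test_study_scale_structure(self):
        cfg = default_config(n_sites=120, seed=8)
        ds, truth = simulate_dataset(cfg)
        days = ds.camera_days() / 120
        assert 10 < days < 60  # multi-study mixture of 2-76 day deployments
        assert ds.n_events("prey") > 20 * ds.n_events("predator")
        assert ds.naive_occupancy("prey") > 0.75
        for d in ds.deployments:
            assert 0 <= d.start_clock < 24
            assert "ndvi" in d.covariates
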