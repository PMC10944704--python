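"""Parameter packing, optimization behavior, Wald tests, factorization."""

import numpy as np
import pytest

from ctocc.errors import ConfigurationError
from ctocc.fit import FitResult, fit_mle, wald_test
from ctocc.io import Dataset
from ctocc.likelihood import LikelihoodWorkspace
from ctocc.mmpp import history_loglik
from ctocc.occupancy import compute_state_probs, marginal_occupancy
from ctocc.params import ModelSpec
from ctocc.simulate import scaled_config, scaled_spec, simulate_dataset


class TestPacking:
    @pytest.mark.parametrize("spec", [
        ModelSpec(),
        ModelSpec(intensity_covariates=(), n_harmonics=0, grid_hours=24.0),
        ModelSpec(intensity_covariates=("ndvi", "elev"), n_harmonics=1,
                  f1_covariates=("elev",)),
    ])
    def test_round_trip(self, spec, rng):
        theta = rng.normal(0, 1, spec.n_params)
        assert np.allclose(spec.pack(spec.unpack(theta)), theta)
        assert len(spec.param_names()) == len(set(spec.param_names()))

    def test_prey_fourier_shared_by_construction(self, rng):
        spec = ModelSpec()
        full = spec.unpack(rng.normal(0, 1, spec.n_params))
        assert np.array_equal(full.prey_present.intensity.fourier,
                              full.prey_absent.intensity.fourier)

    def test_grid_must_divide_day(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(grid_hours=0.7)


class TestWald:
    def _fake_fit(self, names, theta, vcov):
        return FitResult(names=names, theta=np.asarray(theta, float),
                         vcov=np.asarray(vcov, float), loglik=0.0,
                         converged=True, n_sites=1, n_events={},
                         spec=ModelSpec())

    def test_identity_vcov_gives_unit_se(self):
        fit = self._fake_fit(["a", "b"], [1.0, 2.0], np.eye(2))
        w = wald_test(fit, {"a": 1.0})
        assert w.se == pytest.approx(1.0)
        assert w.estimate == pytest.approx(1.0)

    def test_equal_estimates_difference_is_null(self):
        fit = self._fake_fit(["a", "b"], [1.3, 1.3], np.eye(2))
        w = wald_test(fit, {"a": 1.0, "b": -1.0})
        assert w.estimate == pytest.approx(0.0)
        assert w.p_value == pytest.approx(1.0)

    def test_unknown_contrast_name(self):
        fit = self._fake_fit(["a"], [0.0], np.eye(1))
        with pytest.raises(ConfigurationError):
            wald_test(fit, {"zz": 1.0})


class TestFitBehavior:
    def test_small_fit_converges_with_sane_vcov(self, small_fit):
        fit, ds, cfg, spec = small_fit
        assert fit.converged
        assert fit.vcov is not None
        assert np.allclose(fit.vcov, fit.vcov.T)
        assert np.all(np.diag(fit.vcov) > 0)
        assert fit.n_sites == 40
        tab = fit.summary_table()
        assert set(tab["parameter"]) == set(fit.names)

    def test_refit_from_optimum_is_fixed_point(self, small_fit):
        fit, ds, cfg, spec = small_fit
        again = fit_mle(ds, spec, start=fit.theta, compute_vcov=False)
        assert abs(again.loglik - fit.loglik) < 1e-6

    def test_truth_beats_perturbed_intensity(self):
        # the likelihood should prefer the generating intensity intercepts
        wins = 0
        spec = scaled_spec()
        for r in range(8):
            cfg = scaled_config(n_sites=60, seed=600 + r)
            ds, _ = simulate_dataset(cfg)
            ws = LikelihoodWorkspace(ds, spec)
            theta = spec.pack(cfg.full_params())
            bad = theta.copy()
            names = spec.param_names()
            for nm in ("prey_b0_pres", "prey_b0_abs", "pred_b0"):
                bad[names.index(nm)] += 3.0
            wins += ws.loglik(theta) > ws.loglik(bad)
        assert wins >= 7

    def test_species_never_detected_warns_but_fits(self):
        cfg = scaled_config(n_sites=25, seed=1, f3=0.0)
        cfg.f2 = -40.0  # predator never occurs, hence never detected
        ds, _ = simulate_dataset(cfg)
        assert ds.n_events("predator") == 0
        spec = scaled_spec(maxiter=150)
        with pytest.warns(UserWarning, match="predator"):
            fit = fit_mle(ds, spec, compute_vcov=False)
        assert np.isfinite(fit.loglik)
        # predator occupancy driven low
        psi = compute_state_probs(fit.estimates["f1"], fit.estimates["f2"],
                                  fit.estimates["f3"])
        assert marginal_occupancy(psi, "predator") < 0.2


def test_marginal_occupancy_consistent_at_large_n():
    """Estimated occupancy marginals approach simulation truth as sites grow."""
    cfg = scaled_config(n_sites=2000, seed=4, duration_days=(1.0, 2.5))
    ds, _ = simulate_dataset(cfg)
    fit = fit_mle(ds, scaled_spec(seed=0), compute_vcov=False)
    psi = compute_state_probs(fit.estimates["f1"], fit.estimates["f2"],
                              fit.estimates["f3"])
    assert marginal_occupancy(psi, "prey") == pytest.approx(0.85, abs=0.03)
    assert marginal_occupancy(psi, "predator") == pytest.approx(0.45, abs=0.03)


def _single_species_loglik(ds, cond, species, occ_prob, spec):
    """Independent single-species occupancy-MMPP log likelihood."""
    out = 0.0
    for d in ds.deployments:
        h = ds.history(d.site_id, species)
        t = h.event_times_hours if h is not None else np.empty(0)
        ll_det = history_loglik(t, d.duration_hours, cond, d.covariates,
                                spec.grid_hours, spec.init, d.start_clock)
        if t.size:
            out += np.log(occ_prob) + ll_det
        else:
            out += np.log(occ_prob * np.exp(ll_det) + (1 - occ_prob))
    return out


def test_factorization_with_tied_prey_and_no_interaction(small_dataset):
    """With both prey parameter sets equal and f3 = 0, the joint likelihood
    factorizes into two independent single-species models."""
    ds, truth, cfg = small_dataset
    spec = scaled_spec()
    names = spec.param_names()
    theta = spec.pack(cfg.full_params())
    idx = {n: i for i, n in enumerate(names)}
    theta[idx["f3"]] = 0.0
    for a, b in (("prey_mu1_abs", "prey_mu1_pres"),
                 ("prey_mu2_abs", "prey_mu2_pres"),
                 ("prey_b0_abs", "prey_b0_pres")):
        theta[idx[a]] = theta[idx[b]]
    joint = LikelihoodWorkspace(ds, spec).loglik(theta)

    full = spec.unpack(theta)
    psi = compute_state_probs(theta[idx["f1"]], theta[idx["f2"]], 0.0)
    lp = _single_species_loglik(ds, full.prey_present, "prey",
                                marginal_occupancy(psi, "prey"), spec)
    lc = _single_species_loglik(ds, full.predator, "predator",
                                marginal_occupancy(psi, "predator"), spec)
    assert joint == pytest.approx(lp + lc, abs=1e-8)
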