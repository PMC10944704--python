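"""Maximum-likelihood fitting of the joint occupancy + detection model.

Optimization is quasi-Newton (L-BFGS-B) with numerical gradients from a small
number of jittered starts around a data-driven initialization.  The variance
matrix is the inverse of the numerically differentiated Hessian of the
negative log likelihood (observed information); Wald tests on linear
combinations of raw parameters use the normal approximation.  Confidence
intervals for nonlinear derived quantities come from the parametric bootstrap
instead (see :mod:`ctocc.derived`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.special import logit, logsumexp
from statsmodels.tools.numdiff import approx_hess

from .errors import ConfigurationError, FittingError
from .io import Dataset, Deployment, DetectionHistory
from .likelihood import LikelihoodWorkspace, total_neg_loglik  # noqa: F401
from .mmpp import history_loglik
from .params import FullParams, ModelSpec

__all__ = [
    "FitResult",
    "WaldResult",
    "fit_mle",
    "wald_test",
    "site_log_likelihood",
    "total_neg_loglik",
]

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Estimates, covariance and bookkeeping from a maximum-likelihood fit."""

    names: list[str]
    theta: np.ndarray
    vcov: np.ndarray | None
    loglik: float
    converged: bool
    n_sites: int
    n_events: dict[str, int]
    spec: ModelSpec
    message: str = ""

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.theta)))

    @property
    def params(self) -> FullParams:
        return self.spec.unpack(self.theta)

    def se(self) -> dict[str, float]:
        if self.vcov is None:
            return {n: np.nan for n in self.names}
        return dict(zip(self.names, np.sqrt(np.clip(np.diag(self.vcov), 0, None))))

    def summary_table(self) -> pd.DataFrame:
        se = self.se()
        z = scipy.stats.norm.ppf(0.975)
        rows = []
        for name, est in self.estimates.items():
            s = se[name]
            rows.append({"parameter": name, "estimate": est, "se": s,
                         "ci_lower": est - z * s, "ci_upper": est + z * s})
        return pd.DataFrame(rows)


@dataclass
class WaldResult:
    """Normal-approximation inference for a linear combination of parameters."""

    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    z: float
    p_value: float


def _heuristic_start(dataset: Dataset, spec: ModelSpec) -> np.ndarray:
    """Data-driven initialization: naive occupancy for f1/f2 and a sparse-bout
    guess (detectable ~2% of the time, 10-minute bouts) for the detection layer,
    with the intensity intercept matched to the observed event rate."""
    n = len(dataset.deployments)
    hours = sum(d.duration_hours for d in dataset.deployments)

    def napp(species):
        return float(np.clip(dataset.naive_occupancy(species), 0.05, 0.95))

    prop0 = 0.02
    mu2 = np.log(6.0)
    mu1 = mu2 + logit(prop0)
    values = {}
    for name in spec.param_names():
        values[name] = 0.0
    values["f1"] = float(logit(napp("prey")))
    values["f2"] = float(logit(napp("predator")))
    for sp, prefix in (("prey", "prey"), ("predator", "pred")):
        rate = dataset.n_events(sp) / max(hours, 1.0)
        lam0 = float(np.clip(rate / prop0, 0.1, 50.0))
        if prefix == "prey":
            values["prey_b0_pres"] = values["prey_b0_abs"] = 2.0 * np.log(lam0)
            values["prey_mu1_pres"] = values["prey_mu1_abs"] = mu1
            values["prey_mu2_pres"] = values["prey_mu2_abs"] = mu2
        else:
            values["pred_b0"] = 2.0 * np.log(lam0)
            values["pred_mu1"] = mu1
            values["pred_mu2"] = mu2
    return spec.theta_from_dict(values)


def fit_mle(
    dataset: Dataset,
    spec: ModelSpec,
    start: np.ndarray | None = None,
    compute_vcov: bool = True,
) -> FitResult:
    """Fit the joint model by maximum likelihood.

    Runs ``spec.n_starts`` L-BFGS-B minimizations (the first from ``start`` or
    the data-driven heuristic, the rest from seeded jitters of it) and keeps
    the best optimum.  Non-convergence is reported in the result, never
    silently ignored.
    """
    ws = LikelihoodWorkspace(dataset, spec)
    for sp in ("prey", "predator"):
        if dataset.n_events(sp) == 0:
            warnings.warn(
                f"no detections of {sp!r} anywhere: its occupancy and detection "
                "parameters are at or near a likelihood boundary",
                stacklevel=2,
            )

    x0 = np.asarray(start, dtype=float) if start is not None \
        else _heuristic_start(dataset, spec)
    rng = np.random.default_rng(spec.seed)
    starts = [x0] + [x0 + rng.normal(0.0, 0.5, x0.size)
                     for _ in range(max(spec.n_starts - 1, 0))]

    best = None
    failures = []
    for k, s0 in enumerate(starts):
        try:
            res = scipy.optimize.minimize(
                ws.neg_loglik, s0, method="L-BFGS-B",
                options={"maxiter": spec.maxiter, "ftol": spec.ftol,
                         "maxcor": 20},
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"start {k}: {exc}")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FittingError("all optimizer starts failed: " + "; ".join(failures))

    vcov = None
    message = str(best.message)
    if compute_vcov:
        try:
            H = approx_hess(best.x, ws.neg_loglik)
            vcov = np.linalg.inv(H)
            vcov = 0.5 * (vcov + vcov.T)
            if np.any(np.diag(vcov) <= 0):
                logger.warning("Hessian not positive definite; vcov unavailable")
                vcov = None
        except np.linalg.LinAlgError:
            logger.warning("singular Hessian; vcov unavailable")
            vcov = None

    return FitResult(
        names=spec.param_names(),
        theta=np.asarray(best.x, dtype=float),
        vcov=vcov,
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_sites=len(dataset.deployments),
        n_events=dict(ws.n_events),
        spec=spec,
        message=message,
    )


def wald_test(fit: FitResult, contrast: dict[str, float]) -> WaldResult:
    """Wald test of c'theta = 0 for a named linear combination ``contrast``."""
    if fit.vcov is None:
        raise ConfigurationError("fit has no covariance matrix available")
    unknown = [k for k in contrast if k not in fit.names]
    if unknown:
        raise ConfigurationError(f"contrast names not in fit: {unknown}")
    c = np.array([contrast.get(n, 0.0) for n in fit.names])
    est = float(c @ fit.theta)
    se = float(np.sqrt(c @ fit.vcov @ c))
    zq = scipy.stats.norm.ppf(0.975)
    z = est / se if se > 0 else np.inf * np.sign(est)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return WaldResult(estimate=est, se=se, ci_lower=est - zq * se,
                      ci_upper=est + zq * se, z=float(z), p_value=float(p))


def site_log_likelihood(
    deployment: Deployment,
    prey_history: DetectionHistory | None,
    predator_history: DetectionHistory | None,
    occupancy: tuple[float, float, float],
    det_params: FullParams,
    spec: ModelSpec,
) -> float:
    """Reference (non-vectorized) joint log likelihood of one site.

    Marginalizes the four latent states with log-sum-exp; detections of an
    absent species zero out the corresponding latent-state terms.  Used as
    the readable counterpart (and test oracle) of the batched engine.
    """
    from .occupancy import _log_state_probs

    f1, f2, f3 = occupancy
    T = deployment.duration_hours
    clock = deployment.start_clock
    cov = deployment.covariates
    prey_t = prey_history.event_times_hours if prey_history is not None \
        else np.empty(0)
    pred_t = predator_history.event_times_hours if predator_history is not None \
        else np.empty(0)

    def hl(events, cond):
        return history_loglik(events, T, cond, cov, spec.grid_hours,
                              spec.init, clock)

    lp_pres = hl(prey_t, det_params.prey_present)
    lp_abs = hl(prey_t, det_params.prey_absent)
    lpred = hl(pred_t, det_params.predator)
    ninf = -np.inf
    cand = np.array([
        lp_pres + lpred,
        lp_abs + (ninf if pred_t.size else 0.0),
        (ninf if prey_t.size else 0.0) + lpred,
        ninf if (prey_t.size or pred_t.size) else 0.0,
    ])
    logpsi = _log_state_probs(f1, f2, f3)
    return float(logsumexp(logpsi + cand))
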