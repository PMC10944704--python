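"""Multivariate Bernoulli co-occurrence layer for two species.

The latent presence/absence pair Z = (z_prey, z_pred) at a site follows a
four-category distribution parameterized by natural (log-odds) parameters:
f1 and f2 are the log odds of the prey (resp. predator) occurring when the
other species is absent, and f3 is the change in log odds when the other
species is present (f3 = 0 means spatial independence).  With
D = 1 + e^{f1} + e^{f2} + e^{f1+f2+f3}:

    psi11 = e^{f1+f2+f3}/D,  psi10 = e^{f1}/D,
    psi01 = e^{f2}/D,        psi00 = 1/D.

State order is fixed as (11, 10, 01, 00) with species order (prey, predator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import root
from scipy.special import logit, logsumexp

from .errors import ConfigurationError, ValidationError

__all__ = [
    "STATE_ORDER",
    "OccupancyParams",
    "StateProbs",
    "compute_state_probs",
    "marginal_occupancy",
    "natural_params_from_design",
    "natural_params_for_marginals",
]

#: latent-state order: (prey, predator) presence pairs
STATE_ORDER = ((1, 1), (1, 0), (0, 1), (0, 0))


@dataclass
class OccupancyParams:
    """Coefficients for the natural parameters, keyed by design column.

    Each mapping is ``{column_name: coefficient}``; the column ``"intercept"``
    always evaluates to 1.  By default all three natural parameters are
    intercept-only; f3 covariates are rejected unless ``allow_f3_covariates``
    is set (interactions are assumed constant across space by default).
    """

    f1: Mapping[str, float] = field(default_factory=lambda: {"intercept": 0.0})
    f2: Mapping[str, float] = field(default_factory=lambda: {"intercept": 0.0})
    f3: Mapping[str, float] = field(default_factory=lambda: {"intercept": 0.0})
    allow_f3_covariates: bool = False

    def __post_init__(self):
        extra = [k for k in self.f3 if k != "intercept"]
        if extra and not self.allow_f3_covariates:
            raise ConfigurationError(
                f"f3 covariates {extra} require allow_f3_covariates=True"
            )


@dataclass
class StateProbs:
    """Probability vector over the four latent states, ordered (11, 10, 01, 00)."""

    psi: np.ndarray

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        if self.psi.shape != (4,):
            raise ValidationError("psi must have length 4")
        if np.any(self.psi < 0) or abs(self.psi.sum() - 1.0) > 1e-9:
            raise ValidationError("psi must be a probability vector")

    @property
    def psi11(self) -> float:
        return float(self.psi[0])

    @property
    def psi10(self) -> float:
        return float(self.psi[1])

    @property
    def psi01(self) -> float:
        return float(self.psi[2])

    @property
    def psi00(self) -> float:
        return float(self.psi[3])


def _log_state_probs(f1, f2, f3):
    logs = np.stack(
        [np.asarray(f1) + f2 + f3, np.asarray(f1) + 0 * f2, np.asarray(f2) + 0 * f1,
         np.zeros(np.broadcast(f1, f2, f3).shape)],
        axis=-1,
    )
    return logs - logsumexp(logs, axis=-1, keepdims=True)


def compute_state_probs(f1: float, f2: float, f3: float) -> StateProbs:
    """State probabilities (psi11, psi10, psi01, psi00) from natural parameters.

    Computed in log space, so it is stable for |f| up to several hundred.
    """
    for name, v in (("f1", f1), ("f2", f2), ("f3", f3)):
        if not np.isfinite(v):
            raise ValidationError(f"natural parameter {name} must be finite")
    return StateProbs(np.exp(_log_state_probs(f1, f2, f3)))


def marginal_occupancy(psi: StateProbs, species: str) -> float:
    """Marginal occupancy probability of ``"prey"`` or ``"predator"``."""
    if species == "prey":
        return psi.psi11 + psi.psi10
    if species == "predator":
        return psi.psi11 + psi.psi01
    raise ValidationError(f"unknown species {species!r}")


def natural_params_from_design(
    params: OccupancyParams, covariates: Mapping[str, float]
) -> tuple[float, float, float]:
    """Evaluate (f1, f2, f3) for one site's covariate row."""

    def lin(coefs):
        out = 0.0
        for name, beta in coefs.items():
            if name == "intercept":
                out += beta
            elif name in covariates:
                out += beta * covariates[name]
            else:
                raise ConfigurationError(f"occupancy covariate {name!r} missing")
        return out

    return lin(params.f1), lin(params.f2), lin(params.f3)


def natural_params_for_marginals(
    prey_marginal: float, predator_marginal: float, f3: float
) -> tuple[float, float]:
    """Solve for (f1, f2) so the two marginals match given an interaction f3.

    Used to parameterize simulations by interpretable occupancy targets.
    """
    for m in (prey_marginal, predator_marginal):
        if not 0 < m < 1:
            raise ValidationError("marginals must lie strictly inside (0, 1)")

    def resid(x):
        p = compute_state_probs(x[0], x[1], f3)
        return [
            marginal_occupancy(p, "prey") - prey_marginal,
            marginal_occupancy(p, "predator") - predator_marginal,
        ]

    x0 = [float(logit(prey_marginal)), float(logit(predator_marginal))]
    sol = root(resid, x0, tol=1e-12)
    if not sol.success:
        raise ValidationError("root finding for (f1, f2) failed")
    return float(sol.x[0]), float(sol.x[1])
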