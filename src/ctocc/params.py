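"""Model specification and the packed parameter vector.

The joint model has three conditional detection-parameter sets -- prey with
the predator present, prey with the predator absent, and the predator itself
-- plus the occupancy natural parameters (f1, f2, f3).  The prey's two sets
share their diel Fourier coefficients (the diel activity shape is common;
only the intercept and covariate slopes may shift with predator presence),
which is enforced structurally by the packing layer: the shared coefficients
occupy a single slot each.

Packed order (stable, round-trip tested):

    [f1 coefs] [f2 coefs] [f3 coefs]
    prey_mu1_pres prey_mu2_pres prey_mu1_abs prey_mu2_abs
    prey_b0_pres prey_b0_abs [prey fourier cos1 sin1 ...]
    [prey covariate slopes, present] [.., absent]
    pred_mu1 pred_mu2 pred_b0 [pred fourier] [pred covariate slopes]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .mmpp import CondDetectionParams, IntensityParams, SwitchParams
from .occupancy import OccupancyParams

__all__ = ["ModelSpec", "FullParams"]


@dataclass
class FullParams:
    """Structured parameter set for the joint two-species model."""

    occ: OccupancyParams
    prey_present: CondDetectionParams
    prey_absent: CondDetectionParams
    predator: CondDetectionParams


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the joint model and its optimizer.

    ``grid_hours`` is the resolution of the piecewise-constant diel intensity
    inside matrix exponentials (must divide 24 evenly); ``init`` chooses the
    initial distribution of the switching chain (``stationary`` or
    ``uniform``).  Occupancy covariates are off by default (intercept-only
    natural parameters); f3 covariates additionally require
    ``allow_f3_covariates``.
    """

    intensity_covariates: tuple[str, ...] = ("ndvi",)
    n_harmonics: int = 2
    grid_hours: float = 0.25
    init: str = "stationary"
    f1_covariates: tuple[str, ...] = ()
    f2_covariates: tuple[str, ...] = ()
    f3_covariates: tuple[str, ...] = ()
    allow_f3_covariates: bool = False
    n_starts: int = 5
    seed: int = 0
    maxiter: int = 1000
    ftol: float = 1e-11

    def __post_init__(self):
        c = 24.0 / self.grid_hours
        if abs(c - round(c)) > 1e-9 or self.grid_hours <= 0:
            raise ConfigurationError("grid_hours must divide 24 evenly")
        if self.init not in ("stationary", "uniform"):
            raise ConfigurationError("init must be 'stationary' or 'uniform'")
        if self.f3_covariates and not self.allow_f3_covariates:
            raise ConfigurationError(
                "f3 covariates require allow_f3_covariates=True"
            )
        if self.n_harmonics not in (0, 1, 2):
            raise ConfigurationError("n_harmonics must be 0, 1 or 2")

    # -- layout ----------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return round(24.0 / self.grid_hours)

    def fourier_names(self, prefix: str) -> list[str]:
        out = []
        for k in range(1, self.n_harmonics + 1):
            out += [f"{prefix}_cos{k}", f"{prefix}_sin{k}"]
        return out

    def param_names(self) -> list[str]:
        names = []
        for f, covs in (("f1", self.f1_covariates), ("f2", self.f2_covariates),
                        ("f3", self.f3_covariates)):
            names.append(f)
            names += [f"{f}_{c}" for c in covs]
        names += ["prey_mu1_pres", "prey_mu2_pres", "prey_mu1_abs", "prey_mu2_abs"]
        names += ["prey_b0_pres", "prey_b0_abs"]
        names += self.fourier_names("prey")
        names += [f"prey_{c}_pres" for c in self.intensity_covariates]
        names += [f"prey_{c}_abs" for c in self.intensity_covariates]
        names += ["pred_mu1", "pred_mu2", "pred_b0"]
        names += self.fourier_names("pred")
        names += [f"pred_{c}" for c in self.intensity_covariates]
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names())

    # -- pack / unpack ---------------------------------------------------

    def pack(self, full: FullParams) -> np.ndarray:
        occ = full.occ
        theta = []
        for coefs, covs, name in (
            (occ.f1, self.f1_covariates, "f1"),
            (occ.f2, self.f2_covariates, "f2"),
            (occ.f3, self.f3_covariates, "f3"),
        ):
            theta.append(coefs.get("intercept", 0.0))
            for c in covs:
                theta.append(coefs.get(c, 0.0))
        pp, pa, pr = full.prey_present, full.prey_absent, full.predator
        theta += [pp.switch.mu1, pp.switch.mu2, pa.switch.mu1, pa.switch.mu2]
        theta += [pp.intensity.intercept, pa.intensity.intercept]
        four = np.asarray(pp.intensity.fourier, dtype=float)
        if len(four) != 2 * self.n_harmonics:
            raise ValidationError("prey fourier length does not match spec")
        if not np.allclose(four, np.asarray(pa.intensity.fourier, dtype=float)):
            raise ValidationError(
                "prey fourier coefficients must be shared across predator states"
            )
        theta += list(four)
        theta += [pp.intensity.covariates.get(c, 0.0)
                  for c in self.intensity_covariates]
        theta += [pa.intensity.covariates.get(c, 0.0)
                  for c in self.intensity_covariates]
        theta += [pr.switch.mu1, pr.switch.mu2, pr.intensity.intercept]
        prf = np.asarray(pr.intensity.fourier, dtype=float)
        if len(prf) != 2 * self.n_harmonics:
            raise ValidationError("predator fourier length does not match spec")
        theta += list(prf)
        theta += [pr.intensity.covariates.get(c, 0.0)
                  for c in self.intensity_covariates]
        out = np.asarray(theta, dtype=float)
        if out.size != self.n_params:
            raise ValidationError("packed parameter length mismatch")
        return out

    def unpack(self, theta) -> FullParams:
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValidationError(
                f"theta has length {theta.size}, expected {self.n_params}"
            )
        pos = 0

        def take(k):
            nonlocal pos
            out = theta[pos:pos + k]
            pos += k
            return out

        occ_coefs = {}
        for f, covs in (("f1", self.f1_covariates), ("f2", self.f2_covariates),
                        ("f3", self.f3_covariates)):
            vals = take(1 + len(covs))
            occ_coefs[f] = {"intercept": float(vals[0]),
                            **{c: float(v) for c, v in zip(covs, vals[1:])}}
        occ = OccupancyParams(f1=occ_coefs["f1"], f2=occ_coefs["f2"],
                              f3=occ_coefs["f3"],
                              allow_f3_covariates=self.allow_f3_covariates)
        mu = take(4)
        b0 = take(2)
        four = tuple(take(2 * self.n_harmonics))
        k = len(self.intensity_covariates)
        sl_p = dict(zip(self.intensity_covariates, take(k)))
        sl_a = dict(zip(self.intensity_covariates, take(k)))
        prey_present = CondDetectionParams(
            switch=SwitchParams(float(mu[0]), float(mu[1])),
            intensity=IntensityParams(float(b0[0]), four,
                                      {c: float(v) for c, v in sl_p.items()}),
        )
        prey_absent = CondDetectionParams(
            switch=SwitchParams(float(mu[2]), float(mu[3])),
            intensity=IntensityParams(float(b0[1]), four,
                                      {c: float(v) for c, v in sl_a.items()}),
        )
        pmu = take(2)
        pb0 = take(1)
        pfour = tuple(take(2 * self.n_harmonics))
        psl = dict(zip(self.intensity_covariates, take(k)))
        predator = CondDetectionParams(
            switch=SwitchParams(float(pmu[0]), float(pmu[1])),
            intensity=IntensityParams(float(pb0[0]), pfour,
                                      {c: float(v) for c, v in psl.items()}),
        )
        return FullParams(occ=occ, prey_present=prey_present,
                          prey_absent=prey_absent, predator=predator)

    def theta_from_dict(self, values: dict[str, float]) -> np.ndarray:
        names = self.param_names()
        missing = [n for n in names if n not in values]
        if missing:
            raise ConfigurationError(f"missing parameter values: {missing}")
        return np.asarray([values[n] for n in names], dtype=float)
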