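"""Synthetic camera-trap data with the statistical structure the model assumes.

The generator draws, per site: a deployment (duration from a three-component
mixture mimicking a multi-study design of short, long and intermediate
deployments; start clock uniform on [0, 24) so diel coverage is
unconfounded; a standard-normal "ndvi" covariate), a latent occupancy pair
from the four-state distribution, and then -- for each species present -- a
two-state detectability chain simulated by exponential holding times, with
detections laid down on detectable sojourns by thinning an upper-bounding
homogeneous Poisson process against the diel intensity.

The default truth reproduces the study conditions this model family targets:
~319 deployments of 2-76 days, prey marginal occupancy 0.96, predator 0.47,
interaction f3 = 1.56, prey detectable 0.9% of the time with the predator
present vs 0.4% without (ratio 2.25), predator detectable 0.2% of the time,
crepuscular prey and nocturnal predator diel intensity, and a small negative
NDVI effect on prey intensity where the predator is present.

The same path simulator doubles as the Monte-Carlo oracle for the likelihood
(:func:`mc_zero_detection_prob`, :func:`mc_segment_probs`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Dataset, Deployment, DetectionHistory
from .mmpp import (CondDetectionParams, IntensityParams, SwitchParams,
                   initial_dist, log_intensity)
from .occupancy import (STATE_ORDER, StateProbs, compute_state_probs,
                        natural_params_for_marginals)
from .params import FullParams, ModelSpec
from .occupancy import OccupancyParams

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_config",
    "scaled_config",
    "simulate_occupancy",
    "simulate_detections",
    "simulate_dataset",
    "simulate_histories_for_deployments",
    "mc_zero_detection_prob",
    "mc_segment_probs",
]


def _logit(p):
    return float(np.log(p / (1.0 - p)))


def default_detection_truth() -> dict[str, CondDetectionParams]:
    """Study-scale detection truth (rates per hour, intensities per hour).

    Detectable bouts last ~6 min (exit rate 10/h); entry rates are set so the
    stationary detectable proportions are 0.009 (prey, predator present),
    0.004 (prey, predator absent) and 0.002 (predator).  Intensity intercepts
    give ~8 detections/h (prey near predators), ~3.7/h (prey otherwise) and
    ~0.7/h (predator) while detectable; the prey diel shape is crepuscular
    (negative second cosine harmonic), the predator's nocturnal (positive
    first cosine harmonic).
    """
    bout_exit = np.log(10.0)
    return {
        "prey_present": CondDetectionParams(
            switch=SwitchParams(bout_exit + _logit(0.009), bout_exit),
            intensity=IntensityParams(4.2, (-0.1, 0.0, -0.8, 0.0),
                                      {"ndvi": -0.05}),
        ),
        "prey_absent": CondDetectionParams(
            switch=SwitchParams(bout_exit + _logit(0.004), bout_exit),
            intensity=IntensityParams(2.6, (-0.1, 0.0, -0.8, 0.0),
                                      {"ndvi": 0.02}),
        ),
        "predator": CondDetectionParams(
            switch=SwitchParams(bout_exit + _logit(0.002), bout_exit),
            intensity=IntensityParams(-0.7, (0.8, 0.0, 0.0, 0.0),
                                      {"ndvi": 0.0}),
        ),
    }


@dataclass
class SimConfig:
    """Generating truth and design of a synthetic camera-trap study."""

    n_sites: int = 319
    #: (weight, low_days, high_days) mixture for deployment durations
    duration_components: tuple = (
        (0.404, 2.0, 12.0), (0.433, 40.0, 76.0), (0.163, 2.0, 56.0),
    )
    f1: float = 0.0
    f2: float = 0.0
    f3: float = 1.56
    detection: dict = field(default_factory=default_detection_truth)
    #: covariate name -> (dist, *params); only "normal" is supported
    covariates: dict = field(default_factory=lambda: {"ndvi": ("normal", 0.0, 1.0)})
    init: str = "stationary"
    origin: str = "2021-04-01"
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValidationError("n_sites must be at least 1")
        for w, lo, hi in self.duration_components:
            if not (0 < lo <= hi):
                raise ValidationError("duration components must have 0 < lo <= hi")

    def state_probs(self) -> StateProbs:
        return compute_state_probs(self.f1, self.f2, self.f3)

    def full_params(self) -> FullParams:
        return FullParams(
            occ=OccupancyParams(f1={"intercept": self.f1},
                                f2={"intercept": self.f2},
                                f3={"intercept": self.f3}),
            prey_present=self.detection["prey_present"],
            prey_absent=self.detection["prey_absent"],
            predator=self.detection["predator"],
        )


@dataclass
class SimTruth:
    """Latent states and generating parameters written alongside a dataset."""

    z: list[tuple[int, int]]
    config: SimConfig

    def occupied(self, species: str) -> np.ndarray:
        i = 0 if species == "prey" else 1
        return np.array([s[i] for s in self.z], dtype=bool)


def default_config(n_sites: int = 319, seed: int = 0, **kw) -> SimConfig:
    """Study-scale configuration with marginals 0.96 / 0.47 and f3 = 1.56."""
    f3 = kw.pop("f3", 1.56)
    f1, f2 = natural_params_for_marginals(0.96, 0.47, f3)
    return SimConfig(n_sites=n_sites, f1=f1, f2=f2, f3=f3, seed=seed, **kw)


def scaled_config(n_sites: int = 100, seed: int = 0, f3: float = 1.56,
                  ratio: float = 2.25, prey_marginal: float = 0.85,
                  pred_marginal: float = 0.45,
                  duration_days: tuple[float, float] = (2.0, 5.0)) -> SimConfig:
    """Reduced study design for simulation experiments.

    Short deployments (2-5 days by default) with time-constant intensities,
    no covariates, higher detectable proportions (so event counts stay
    informative at small scale) and milder occupancy marginals (0.85 / 0.45).
    The prey detectable-proportion ratio (present/absent) defaults to the
    study-scale value 2.25.
    """
    f1, f2 = natural_params_for_marginals(prey_marginal, pred_marginal, f3)
    bout_exit = np.log(10.0)
    p_abs = 0.04
    p_pres = min(p_abs * ratio, 0.9)
    detection = {
        "prey_present": CondDetectionParams(
            switch=SwitchParams(bout_exit + _logit(p_pres), bout_exit),
            intensity=IntensityParams(4.2, (), {}),
        ),
        "prey_absent": CondDetectionParams(
            switch=SwitchParams(bout_exit + _logit(p_abs), bout_exit),
            intensity=IntensityParams(2.6, (), {}),
        ),
        "predator": CondDetectionParams(
            switch=SwitchParams(bout_exit + _logit(0.05), bout_exit),
            intensity=IntensityParams(0.8, (), {}),
        ),
    }
    return SimConfig(
        n_sites=n_sites,
        duration_components=((1.0, duration_days[0], duration_days[1]),),
        f1=f1, f2=f2, f3=f3,
        detection=detection,
        covariates={},
        seed=seed,
    )


def scaled_spec(**kw) -> ModelSpec:
    """Model specification matching :func:`scaled_config` datasets."""
    kw.setdefault("intensity_covariates", ())
    kw.setdefault("n_harmonics", 0)
    kw.setdefault("grid_hours", 24.0)
    kw.setdefault("n_starts", 1)
    return ModelSpec(**kw)


def simulate_occupancy(psi: StateProbs, n_sites: int, rng) -> list[tuple[int, int]]:
    """Draw i.i.d. latent (prey, predator) presence pairs from psi."""
    rng = np.random.default_rng(rng)
    idx = rng.choice(4, size=n_sites, p=psi.psi)
    return [STATE_ORDER[i] for i in idx]


def _lambda_max(cond: CondDetectionParams, covariates) -> float:
    """Finite upper bound of the diel intensity (grid max, 1.001 safety)."""
    grid = np.arange(0.0, 24.0, 0.01)
    ll = log_intensity(grid, covariates, cond.intensity)
    mx = float(np.max(ll))
    if not np.isfinite(mx):
        if mx == -np.inf:  # intensity identically zero
            return 0.0
        raise ValidationError("diel intensity is unbounded on [0, 24)")
    return float(np.exp(mx)) * 1.001


def _simulate_one_path(cond, T, start_clock, covariates, rng, init):
    """One detectability-chain path with thinned detections; returns times."""
    lam_max = _lambda_max(cond, covariates)
    q = (np.exp(cond.switch.mu1), np.exp(cond.switch.mu2))
    state = int(rng.random() < initial_dist(cond.switch, init)[1])
    t = 0.0
    times = []
    while t < T:
        t_end = min(t + rng.exponential(1.0 / q[state]), T)
        if state == 1 and lam_max > 0:
            n = rng.poisson(lam_max * (t_end - t))
            if n:
                cand = np.sort(rng.uniform(t, t_end, n))
                lam = np.exp(log_intensity((start_clock + cand) % 24.0,
                                           covariates, cond.intensity))
                keep = rng.uniform(0.0, 1.0, n) < lam / lam_max
                times.extend(cand[keep])
        t = t_end
        state = 1 - state
    return np.asarray(times, dtype=float)


def simulate_detections(
    z: tuple[int, int],
    deployment: Deployment,
    det_params: FullParams,
    rng,
    init: str = "stationary",
) -> dict[str, DetectionHistory]:
    """Simulate detection histories at one site given its latent state ``z``.

    The prey uses the predator-present or -absent parameter set according to
    the site's latent predator flag; absent species yield no history.
    """
    rng = np.random.default_rng(rng)
    out = {}
    plans = []
    if z[0]:
        cond = det_params.prey_present if z[1] else det_params.prey_absent
        plans.append(("prey", cond))
    if z[1]:
        plans.append(("predator", det_params.predator))
    for species, cond in plans:
        times = _simulate_one_path(cond, deployment.duration_hours,
                                   deployment.start_clock,
                                   deployment.covariates, rng, init)
        if times.size:
            out[species] = DetectionHistory(
                site_id=deployment.site_id,
                species=species,
                event_times_hours=times,
                event_clock_hours=(deployment.start_clock + times) % 24.0,
            )
    return out


def _draw_deployments(cfg: SimConfig, rng) -> list[Deployment]:
    weights = np.array([w for w, _, _ in cfg.duration_components], dtype=float)
    weights /= weights.sum()
    comps = rng.choice(len(weights), size=cfg.n_sites, p=weights)
    deps = []
    origin = pd.Timestamp(cfg.origin)
    for i in range(cfg.n_sites):
        _, lo, hi = cfg.duration_components[comps[i]]
        dur_h = float(rng.uniform(lo, hi) * 24.0)
        start_day = int(rng.integers(0, 150))
        clock = float(rng.uniform(0.0, 24.0))
        start = origin + pd.Timedelta(days=start_day) + pd.Timedelta(hours=clock)
        covs = {}
        for name, (dist, *p) in cfg.covariates.items():
            if dist != "normal":
                raise ValidationError(f"unsupported covariate distribution {dist!r}")
            covs[name] = float(rng.normal(p[0], p[1]))
        deps.append(Deployment(site_id=f"site{i:04d}", start=start,
                               duration_hours=dur_h, covariates=covs))
    return deps


def simulate_dataset(config: SimConfig) -> tuple[Dataset, SimTruth]:
    """Full reproducible synthetic dataset; identical seeds, identical output."""
    rng = np.random.default_rng(config.seed)
    deps = _draw_deployments(config, rng)
    z = simulate_occupancy(config.state_probs(), config.n_sites, rng)
    full = config.full_params()
    histories = {}
    for dep, zi in zip(deps, z):
        for sp, h in simulate_detections(zi, dep, full, rng, config.init).items():
            histories[(dep.site_id, sp)] = h
    return Dataset(deployments=deps, histories=histories), SimTruth(z=z,
                                                                    config=config)


def simulate_histories_for_deployments(
    deployments: list[Deployment],
    full: FullParams,
    f_params: tuple[float, float, float],
    rng,
    init: str = "stationary",
) -> tuple[Dataset, list[tuple[int, int]]]:
    """Parametric-bootstrap generator: re-simulate latent states and histories
    on the *observed* deployments (durations, start clocks, covariates)."""
    rng = np.random.default_rng(rng)
    psi = compute_state_probs(*f_params)
    z = simulate_occupancy(psi, len(deployments), rng)
    histories = {}
    for dep, zi in zip(deployments, z):
        for sp, h in simulate_detections(zi, dep, full, rng, init).items():
            histories[(dep.site_id, sp)] = h
    return Dataset(deployments=list(deployments), histories=histories), z


# ---------------------------------------------------------------------------
# Monte-Carlo oracles (vectorized over replicates)


def _simulate_paths_vec(cond, T, start_clock, covariates, n_rep, rng,
                        init="stationary", init_state=None):
    """Vectorized chain+thinning simulator; returns (any_detection, end_state).

    Replicates that have already produced a detection stop being advanced
    (their end state is irrelevant for zero-detection probabilities).
    """
    rng = np.random.default_rng(rng)
    lam_max = _lambda_max(cond, covariates)
    q = np.array([np.exp(cond.switch.mu1), np.exp(cond.switch.mu2)])
    if init_state is None:
        p1 = initial_dist(cond.switch, init)[1]
        state = (rng.random(n_rep) < p1).astype(np.int8)
    else:
        state = np.full(n_rep, init_state, dtype=np.int8)
    t = np.zeros(n_rep)
    detected = np.zeros(n_rep, dtype=bool)
    end_state = state.copy()
    alive = np.ones(n_rep, dtype=bool)
    guard = 0
    while alive.any():
        guard += 1
        if guard > 10_000_000:  # pragma: no cover - safety net
            raise RuntimeError("CTMC simulation failed to terminate")
        idx = np.nonzero(alive)[0]
        s = state[idx]
        dt = rng.exponential(1.0, idx.size) / q[s]
        t_end = np.minimum(t[idx] + dt, T)
        det_idx = idx[s == 1]
        if det_idx.size and lam_max > 0:
            seg = t_end[s == 1] - t[det_idx]
            counts = rng.poisson(lam_max * seg)
            pos = counts > 0
            if pos.any():
                rep = np.repeat(det_idx[pos], counts[pos])
                lo = np.repeat(t[det_idx[pos]], counts[pos])
                span = np.repeat(seg[pos], counts[pos])
                cand = lo + rng.uniform(0.0, 1.0, rep.size) * span
                lam = np.exp(log_intensity((start_clock + cand) % 24.0,
                                           covariates, cond.intensity))
                hit = rng.uniform(0.0, 1.0, rep.size) < lam / lam_max
                detected[rep[hit]] = True
        finished = t_end >= T
        end_state[idx[finished]] = state[idx[finished]]
        t[idx] = t_end
        state[idx] = 1 - state[idx]
        alive[idx] = ~finished & ~detected[idx]
    return detected, end_state


def mc_zero_detection_prob(cond, T, start_clock, covariates, n_rep, rng,
                           init="stationary"):
    """Monte-Carlo estimate (phat, se) of P(no detections in [0, T) | present)."""
    detected, _ = _simulate_paths_vec(cond, T, start_clock, covariates,
                                      n_rep, rng, init=init)
    p = 1.0 - detected.mean()
    return p, np.sqrt(p * (1.0 - p) / n_rep)


def mc_segment_probs(cond, T, start_clock, covariates, n_rep, rng,
                     init_state=1):
    """Monte-Carlo row of the no-detection transition matrix from one state.

    Returns ((p_end_nondet, p_end_det), se) where each p is the probability
    of zero detections AND ending in that state, starting from ``init_state``.
    """
    detected, end_state = _simulate_paths_vec(cond, T, start_clock, covariates,
                                              n_rep, rng, init_state=init_state)
    ok = ~detected
    p0 = float(np.mean(ok & (end_state == 0)))
    p1 = float(np.mean(ok & (end_state == 1)))
    se = np.sqrt(np.maximum(p0 * (1 - p0), p1 * (1 - p1)) / n_rep)
    return (p0, p1), se
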