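"""Vectorized joint log likelihood over sites and latent occupancy states.

The per-site likelihood mixes four latent states: with psi the state
probabilities, L^p/L^a the prey detection likelihood under the
predator-present/absent parameter sets, and L^c the predator likelihood,

    L_i = psi11 L^p_i L^c_i
        + psi10 L^a_i 1[no predator detections]
        + psi01 1[no prey detections] L^c_i
        + psi00 1[no detections at all],

computed with log-sum-exp.  Detections of a species rule out the latent
states in which it is absent.

Evaluating this inside an optimizer requires thousands of likelihood
evaluations, so the engine exploits the structure of the problem:

* because the jump matrix diag(0, lambda) collapses the state vector onto the
  detectable state at each detection, the log likelihood of a history is a sum
  over inter-detection intervals of logs of scalars, and all intervals across
  all sites and conditional parameter sets can be processed together;
* the piecewise-constant diel intensity repeats every 24 h, so the per-cell
  transition matrices form a cycle of length 24/grid_hours per (site,
  condition); multi-day gaps are assembled from prefix/suffix products of the
  daily cycle and binary powers of the full-day product, all in log-scaled
  2x2 arithmetic inside a compiled kernel.

The interval decomposition depends only on the data, never on the parameters,
so it is precomputed once per dataset in :class:`LikelihoodWorkspace`.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import expit, logsumexp

from ._linalg import expm2_scaled
from .errors import ConfigurationError
from .io import Dataset
from .mmpp import fourier_design
from .params import ModelSpec

__all__ = ["LikelihoodWorkspace", "total_neg_loglik"]

_TOL = 1e-9


@njit(cache=True)
def _propagate(Gc, lG, pi, E1, lE1, E2, lE2, blk, first, last, within, cross,
               j0, runlen, powe, ppre, max_bits):  # pragma: no cover - compiled
    """Per-interval scalar contributions of the no-detection segments.

    ``Gc``/``lG`` are the log-scaled per-cell transition matrices (B, C);
    ``E1``/``E2`` the left/right partial-cell factors per interval (identity
    where unused).  Returns log of the interval scalar (detectable-state
    component, or total mass for each history's final interval).
    """
    B, C = lG.shape
    N = blk.size

    # prefix products P[b, j] = G_0 ... G_{j-1}; suffix S[b, j] = G_j ... G_{C-1}
    P = np.empty((B, C + 1, 2, 2))
    lP = np.empty((B, C + 1))
    S = np.empty((B, C + 1, 2, 2))
    lS = np.empty((B, C + 1))
    for b in range(B):
        P[b, 0, 0, 0] = 1.0; P[b, 0, 0, 1] = 0.0
        P[b, 0, 1, 0] = 0.0; P[b, 0, 1, 1] = 1.0
        lP[b, 0] = 0.0
        for j in range(C):
            a00, a01 = P[b, j, 0, 0], P[b, j, 0, 1]
            a10, a11 = P[b, j, 1, 0], P[b, j, 1, 1]
            n00 = a00 * Gc[b, j, 0, 0] + a01 * Gc[b, j, 1, 0]
            n01 = a00 * Gc[b, j, 0, 1] + a01 * Gc[b, j, 1, 1]
            n10 = a10 * Gc[b, j, 0, 0] + a11 * Gc[b, j, 1, 0]
            n11 = a10 * Gc[b, j, 0, 1] + a11 * Gc[b, j, 1, 1]
            s = max(max(abs(n00), abs(n01)), max(abs(n10), abs(n11)))
            if s > 0:
                inv = 1.0 / s
                P[b, j + 1, 0, 0] = n00 * inv; P[b, j + 1, 0, 1] = n01 * inv
                P[b, j + 1, 1, 0] = n10 * inv; P[b, j + 1, 1, 1] = n11 * inv
                lP[b, j + 1] = lP[b, j] + lG[b, j] + np.log(s)
            else:
                P[b, j + 1, 0, 0] = 0.0; P[b, j + 1, 0, 1] = 0.0
                P[b, j + 1, 1, 0] = 0.0; P[b, j + 1, 1, 1] = 0.0
                lP[b, j + 1] = -np.inf
        S[b, C, 0, 0] = 1.0; S[b, C, 0, 1] = 0.0
        S[b, C, 1, 0] = 0.0; S[b, C, 1, 1] = 1.0
        lS[b, C] = 0.0
        for j in range(C - 1, -1, -1):
            b00, b01 = S[b, j + 1, 0, 0], S[b, j + 1, 0, 1]
            b10, b11 = S[b, j + 1, 1, 0], S[b, j + 1, 1, 1]
            n00 = Gc[b, j, 0, 0] * b00 + Gc[b, j, 0, 1] * b10
            n01 = Gc[b, j, 0, 0] * b01 + Gc[b, j, 0, 1] * b11
            n10 = Gc[b, j, 1, 0] * b00 + Gc[b, j, 1, 1] * b10
            n11 = Gc[b, j, 1, 0] * b01 + Gc[b, j, 1, 1] * b11
            s = max(max(abs(n00), abs(n01)), max(abs(n10), abs(n11)))
            if s > 0:
                inv = 1.0 / s
                S[b, j, 0, 0] = n00 * inv; S[b, j, 0, 1] = n01 * inv
                S[b, j, 1, 0] = n10 * inv; S[b, j, 1, 1] = n11 * inv
                lS[b, j] = lS[b, j + 1] + lG[b, j] + np.log(s)
            else:
                S[b, j, 0, 0] = 0.0; S[b, j, 0, 1] = 0.0
                S[b, j, 1, 0] = 0.0; S[b, j, 1, 1] = 0.0
                lS[b, j] = -np.inf

    # binary powers of the full-day product
    nb = max_bits if max_bits > 0 else 1
    Dp = np.empty((nb, B, 2, 2))
    lDp = np.empty((nb, B))
    if max_bits > 0:
        for b in range(B):
            Dp[0, b] = P[b, C]
            lDp[0, b] = lP[b, C]
        for k in range(1, max_bits):
            for b in range(B):
                a00, a01 = Dp[k - 1, b, 0, 0], Dp[k - 1, b, 0, 1]
                a10, a11 = Dp[k - 1, b, 1, 0], Dp[k - 1, b, 1, 1]
                n00 = a00 * a00 + a01 * a10
                n01 = a00 * a01 + a01 * a11
                n10 = a10 * a00 + a11 * a10
                n11 = a10 * a01 + a11 * a11
                s = max(max(abs(n00), abs(n01)), max(abs(n10), abs(n11)))
                if s > 0:
                    inv = 1.0 / s
                    Dp[k, b, 0, 0] = n00 * inv; Dp[k, b, 0, 1] = n01 * inv
                    Dp[k, b, 1, 0] = n10 * inv; Dp[k, b, 1, 1] = n11 * inv
                    lDp[k, b] = 2.0 * lDp[k - 1, b] + np.log(s)
                else:
                    Dp[k, b, 0, 0] = 0.0; Dp[k, b, 0, 1] = 0.0
                    Dp[k, b, 1, 0] = 0.0; Dp[k, b, 1, 1] = 0.0
                    lDp[k, b] = -np.inf

    ll = np.empty(N)
    for i in range(N):
        b = blk[i]
        if first[i]:
            v0, v1 = pi[b, 0], pi[b, 1]
        else:
            v0, v1 = 0.0, 1.0
        lv = lE1[i]
        w0 = v0 * E1[i, 0, 0] + v1 * E1[i, 1, 0]
        w1 = v0 * E1[i, 0, 1] + v1 * E1[i, 1, 1]
        s = max(abs(w0), abs(w1))
        if s > 0:
            w0 /= s; w1 /= s; lv += np.log(s)
        else:
            lv = -np.inf
        if within[i]:
            for r in range(runlen[i]):
                c = j0[i] + r
                n0 = w0 * Gc[b, c, 0, 0] + w1 * Gc[b, c, 1, 0]
                n1 = w0 * Gc[b, c, 0, 1] + w1 * Gc[b, c, 1, 1]
                lv += lG[b, c]
                s = max(abs(n0), abs(n1))
                if s > 0:
                    w0 = n0 / s; w1 = n1 / s; lv += np.log(s)
                else:
                    w0 = 0.0; w1 = 0.0; lv = -np.inf
                    break
        elif cross[i]:
            j = j0[i]
            n0 = w0 * S[b, j, 0, 0] + w1 * S[b, j, 1, 0]
            n1 = w0 * S[b, j, 0, 1] + w1 * S[b, j, 1, 1]
            lv += lS[b, j]
            s = max(abs(n0), abs(n1))
            if s > 0:
                w0 = n0 / s; w1 = n1 / s; lv += np.log(s)
            else:
                w0 = 0.0; w1 = 0.0; lv = -np.inf
            e = powe[i]
            for k in range(max_bits):
                if (e >> k) & 1:
                    n0 = w0 * Dp[k, b, 0, 0] + w1 * Dp[k, b, 1, 0]
                    n1 = w0 * Dp[k, b, 0, 1] + w1 * Dp[k, b, 1, 1]
                    lv += lDp[k, b]
                    s = max(abs(n0), abs(n1))
                    if s > 0:
                        w0 = n0 / s; w1 = n1 / s; lv += np.log(s)
                    else:
                        w0 = 0.0; w1 = 0.0; lv = -np.inf
            p = ppre[i]
            n0 = w0 * P[b, p, 0, 0] + w1 * P[b, p, 1, 0]
            n1 = w0 * P[b, p, 0, 1] + w1 * P[b, p, 1, 1]
            lv += lP[b, p]
            s = max(abs(n0), abs(n1))
            if s > 0:
                w0 = n0 / s; w1 = n1 / s; lv += np.log(s)
            else:
                w0 = 0.0; w1 = 0.0; lv = -np.inf
        n0 = w0 * E2[i, 0, 0] + w1 * E2[i, 1, 0]
        n1 = w0 * E2[i, 0, 1] + w1 * E2[i, 1, 1]
        lv += lE2[i]
        scal = n0 + n1 if last[i] else n1
        if scal > 0.0 and lv > -np.inf:
            ll[i] = np.log(scal) + lv
        else:
            ll[i] = -np.inf
    return ll


class LikelihoodWorkspace:
    """Parameter-independent structure of the joint likelihood for a dataset."""

    def __init__(self, dataset: Dataset, spec: ModelSpec):
        self.spec = spec
        deps = dataset.deployments
        n = len(deps)
        self.n_sites = n
        C = spec.n_cells
        self.C = C
        h = spec.grid_hours
        nh = spec.n_harmonics

        for d in deps:
            for c in spec.intensity_covariates:
                if c not in d.covariates:
                    raise ConfigurationError(
                        f"site {d.site_id!r} lacks intensity covariate {c!r}"
                    )
        self.int_cov = np.array(
            [[d.covariates[c] for c in spec.intensity_covariates] for d in deps]
        ).reshape(n, len(spec.intensity_covariates))

        def occ_design(covs):
            for d in deps:
                for c in covs:
                    if c not in d.covariates:
                        raise ConfigurationError(
                            f"site {d.site_id!r} lacks occupancy covariate {c!r}"
                        )
            return np.column_stack(
                [np.ones(n)] + [np.array([d.covariates[c] for d in deps])
                                for c in covs]
            )

        self.X1 = occ_design(spec.f1_covariates)
        self.X2 = occ_design(spec.f2_covariates)
        self.X3 = occ_design(spec.f3_covariates)

        prey_ev, pred_ev = [], []
        for d in deps:
            hp = dataset.history(d.site_id, "prey")
            hc = dataset.history(d.site_id, "predator")
            prey_ev.append(hp.event_times_hours if hp is not None else np.empty(0))
            pred_ev.append(hc.event_times_hours if hc is not None else np.empty(0))
        self.has_prey = np.array([e.size > 0 for e in prey_ev])
        self.has_pred = np.array([e.size > 0 for e in pred_ev])
        self.n_events = {"prey": int(sum(e.size for e in prey_ev)),
                         "predator": int(sum(e.size for e in pred_ev))}

        B = 3 * n
        self.B = B
        # per-block event sums for the jump-intensity term
        self.ev_count = np.zeros(B)
        self.ev_sumF = np.zeros((B, 2 * nh))
        # clock midpoints of the C cells (same for every block)
        self.cellF = fourier_design((np.arange(C) + 0.5) * h % 24.0, nh)

        rows = {k: [] for k in
                ("blk", "first", "last", "within", "cross",
                 "dt1", "mid1", "j0", "runlen", "powe", "ppre",
                 "dt2", "mid2")}

        for cond in range(3):
            for i, d in enumerate(deps):
                b = cond * n + i
                ev = prey_ev[i] if cond < 2 else pred_ev[i]
                s_i = d.start_clock
                if ev.size:
                    clocks = (s_i + ev) % 24.0
                    self.ev_count[b] = ev.size
                    if nh:
                        self.ev_sumF[b] = fourier_design(clocks, nh).sum(axis=0)
                bounds = np.concatenate([[0.0], ev, [d.duration_hours]])
                m = len(bounds) - 1
                for k in range(m):
                    u0 = s_i + bounds[k]
                    u1 = s_i + bounds[k + 1]
                    i0 = int(np.floor(u0 / h + _TOL))
                    i1 = int(np.floor(u1 / h + _TOL))
                    single = i0 == i1 or (u1 - u0) <= _TOL
                    rows["blk"].append(b)
                    rows["first"].append(k == 0)
                    rows["last"].append(k == m - 1)
                    if single:
                        rows["dt1"].append(max(u1 - u0, 0.0))
                        rows["mid1"].append(((u0 + u1) / 2.0) % 24.0)
                        rows["within"].append(False)
                        rows["cross"].append(False)
                        for key in ("j0", "runlen", "powe", "ppre"):
                            rows[key].append(0)
                        rows["dt2"].append(0.0)
                        rows["mid2"].append(0.0)
                        continue
                    left_hi = (i0 + 1) * h
                    rows["dt1"].append(left_hi - u0)
                    rows["mid1"].append(((u0 + left_hi) / 2.0) % 24.0)
                    a, bb = i0 + 1, i1
                    nfull = bb - a
                    if nfull > 0:
                        da, db = a // C, (bb - 1) // C
                        if da == db:
                            rows["within"].append(True)
                            rows["cross"].append(False)
                            rows["j0"].append(a % C)
                            rows["runlen"].append(nfull)
                            rows["powe"].append(0)
                            rows["ppre"].append(0)
                        else:
                            rows["within"].append(False)
                            rows["cross"].append(True)
                            rows["j0"].append(a % C)
                            rows["runlen"].append(0)
                            rows["powe"].append(db - da - 1)
                            rows["ppre"].append(bb - db * C)
                    else:
                        rows["within"].append(False)
                        rows["cross"].append(False)
                        for key in ("j0", "runlen", "powe", "ppre"):
                            rows[key].append(0)
                    r0 = u1 - i1 * h
                    if r0 > _TOL:
                        rows["dt2"].append(r0)
                        rows["mid2"].append(((i1 * h + u1) / 2.0) % 24.0)
                    else:
                        rows["dt2"].append(0.0)
                        rows["mid2"].append(0.0)

        self.blk = np.asarray(rows["blk"], dtype=np.int64)
        for key in ("first", "last", "within", "cross"):
            setattr(self, key, np.asarray(rows[key], dtype=np.bool_))
        self.dt1 = np.asarray(rows["dt1"], dtype=float)
        self.dt2 = np.asarray(rows["dt2"], dtype=float)
        self.F1 = np.ascontiguousarray(
            fourier_design(np.asarray(rows["mid1"], dtype=float), nh))
        self.F2 = np.ascontiguousarray(
            fourier_design(np.asarray(rows["mid2"], dtype=float), nh))
        self.j0 = np.asarray(rows["j0"], dtype=np.int64)
        self.runlen = np.asarray(rows["runlen"], dtype=np.int64)
        self.powe = np.asarray(rows["powe"], dtype=np.int64)
        self.ppre = np.asarray(rows["ppre"], dtype=np.int64)
        mx = int(self.powe.max()) if self.powe.size else 0
        self.max_bits = mx.bit_length()

    # -----------------------------------------------------------------

    def _block_params(self, full):
        """Per-block (3 conditions x n sites) rate/intensity arrays."""
        n = self.n_sites
        conds = (full.prey_present, full.prey_absent, full.predator)
        mu1 = np.array([c.switch.mu1 for c in conds])
        mu2 = np.array([c.switch.mu2 for c in conds])
        rate1 = np.repeat(np.exp(mu1), n)
        rate2 = np.repeat(np.exp(mu2), n)
        if self.spec.init == "stationary":
            pdet = np.repeat(expit(mu1 - mu2), n)
            pi = np.column_stack([1.0 - pdet, pdet])
        else:
            pi = np.full((3 * n, 2), 0.5)
        base = np.concatenate([
            c.intensity.intercept / 2.0
            + self.int_cov @ np.array(
                [c.intensity.covariates.get(nm, 0.0)
                 for nm in self.spec.intensity_covariates])
            for c in conds
        ])
        fourC = np.repeat(
            np.array([np.asarray(c.intensity.fourier, dtype=float) for c in conds]),
            n, axis=0,
        )
        return rate1, rate2, pi, base, fourC

    def loglik(self, theta) -> float:
        spec = self.spec
        full = spec.unpack(theta)
        n, B = self.n_sites, self.B
        rate1, rate2, pi, base, fourC = self._block_params(full)
        blk = self.blk

        with np.errstate(over="ignore", under="ignore", divide="ignore",
                         invalid="ignore"):
            # per-cell transition matrices, (B, C, 2, 2) in scaled form
            loglam = np.clip(base[:, None] + fourC @ self.cellF.T, -np.inf, 300.0)
            G, lG = expm2_scaled(
                -rate1[:, None], rate1[:, None], rate2[:, None],
                -(rate2[:, None] + np.exp(loglam)), spec.grid_hours,
            )
            # left and right partial-cell factors per interval
            r1, r2 = rate1[blk], rate2[blk]
            lam1 = np.exp(np.clip(base[blk] + np.einsum(
                "nj,nj->n", self.F1, fourC[blk]), -np.inf, 300.0))
            E1, lE1 = expm2_scaled(-r1, r1, r2, -(r2 + lam1), self.dt1)
            lam2 = np.exp(np.clip(base[blk] + np.einsum(
                "nj,nj->n", self.F2, fourC[blk]), -np.inf, 300.0))
            E2, lE2 = expm2_scaled(-r1, r1, r2, -(r2 + lam2), self.dt2)

            ll_int = _propagate(
                G, lG, pi, E1, lE1, E2, lE2, blk, self.first, self.last,
                self.within, self.cross, self.j0, self.runlen, self.powe,
                self.ppre, self.max_bits,
            )
            block_ll = np.bincount(blk, weights=ll_int, minlength=B)
            # jump intensities at the detections themselves
            block_ll += self.ev_count * base + np.einsum(
                "bj,bj->b", self.ev_sumF, fourC)

            # latent-state mixture
            occ = full.occ
            f1 = self.X1 @ np.array(
                [occ.f1.get("intercept", 0.0)]
                + [occ.f1.get(c, 0.0) for c in spec.f1_covariates])
            f2 = self.X2 @ np.array(
                [occ.f2.get("intercept", 0.0)]
                + [occ.f2.get(c, 0.0) for c in spec.f2_covariates])
            f3 = self.X3 @ np.array(
                [occ.f3.get("intercept", 0.0)]
                + [occ.f3.get(c, 0.0) for c in spec.f3_covariates])
            logs = np.stack([f1 + f2 + f3, f1, f2, np.zeros(n)], axis=1)
            logpsi = logs - logsumexp(logs, axis=1, keepdims=True)

            lp_pres, lp_abs, lpred = (block_ll[:n], block_ll[n:2 * n],
                                      block_ll[2 * n:])
            neg_inf = np.float64(-np.inf)
            cand = np.stack([
                lp_pres + lpred,
                lp_abs + np.where(self.has_pred, neg_inf, 0.0),
                np.where(self.has_prey, neg_inf, 0.0) + lpred,
                np.where(self.has_prey | self.has_pred, neg_inf, 0.0),
            ], axis=1)
            site_ll = logsumexp(logpsi + cand, axis=1)
            return float(site_ll.sum())

    def neg_loglik(self, theta) -> float:
        """Objective for the optimizer; non-finite values mapped to 1e10."""
        val = -self.loglik(theta)
        if not np.isfinite(val):
            return 1e10
        return val


def total_neg_loglik(theta, dataset: Dataset, spec: ModelSpec,
                     workspace: LikelihoodWorkspace | None = None) -> float:
    """Negative joint log likelihood of the dataset at packed parameters."""
    ws = workspace if workspace is not None else LikelihoodWorkspace(dataset, spec)
    return -ws.loglik(theta)
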