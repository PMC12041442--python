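"""Gompertz nonlinear mixed-effects model for a single flowering flush.

The structural model for bed *i* at day t' within a flush is

    y'_ij = A_i * exp(-exp(B_i - C * t'_ij)) + eps_ij,   eps_ij ~ N(0, sigma^2 / w_ij)

with treatment fixed effects and additive normal random effects on the
natural scale,

    A_i = a_{trt(i)} + u_{blk(i),A} + v_{i,A}
    B_i = b_{trt(i)} + u_{blk(i),B} + v_{i,B}

where block effects u and bed effects v have independent (diagonal)
variances and the shift rate C is shared by all beds.  Observation weights
``w`` implement down-weighting of harvest-pause artifacts: they multiply the
per-observation log-likelihood contributions, equivalently inflating the
residual variance by 1/w.

Estimation is by SAEM (stochastic approximation EM): a Metropolis-within-
Gibbs E-step samples the random effects, stochastic averaging builds
smoothed sufficient statistics, and the M-step updates the fixed effects by
damped Gauss-Newton steps on the smoothed complete-data objective, with
closed-form variance updates.  Standard errors come from the Fisher
information of the marginal model linearized at the estimates.  A
deterministic two-stage fallback (per-bed nonlinear least squares, then
moment estimates across beds) is available for small or degenerate data;
results always name the estimator used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .gompertz import GompertzParams, efron_r2, gompertz

__all__ = [
    "NlmeSpec",
    "ConvergenceError",
    "GompertzMixedModel",
    "GompertzMixedResults",
    "treatment_table",
    "contrast_vs_control",
]

_REQUIRED_COLS = ["bed_id", "block_id", "treatment", "t_prime", "y_prime"]


@dataclass(frozen=True)
class NlmeSpec:
    """Settings for the mixed-effects Gompertz fit.

    ``start`` holds the initial (A, B, C); the classical defaults
    (1000, 2, 0.1) suit bed-scale stem counts.  ``data_driven_start``
    replaces them with A0 = 1.05 * max y', and (B0, C0) from the linear
    regression of -log(-log(y'/A0)) on t', which is exact for noiseless
    Gompertz data.  SAEM runs ``n_burnin`` iterations at step size 1
    followed by ``n_smooth`` averaging iterations with step 1/m.
    """

    start: GompertzParams = GompertzParams(1000.0, 2.0, 0.1)
    data_driven_start: bool = False
    n_burnin: int = 300
    n_smooth: int = 100
    n_kernel: int = 2          # Metropolis sweeps per SAEM iteration
    seed: int = 0
    block_on_b: bool = True    # block random effect on B as well as A
    convergence_rtol: float = 1e-4  # per-iteration relative drift over final 50 iters
    check_convergence: bool = True

    def __post_init__(self) -> None:
        if self.n_burnin <= 0 or self.n_smooth <= 0 or self.n_kernel <= 0:
            raise ValueError("iteration counts must be positive")


class ConvergenceError(RuntimeError):
    """SAEM fixed-effect trace has not stabilized; carries the trace."""

    def __init__(self, message: str, trace: pd.DataFrame):
        super().__init__(message)
        self.trace = trace


class GompertzMixedModel:
    """Per-flush Gompertz mixed model (statsmodels-style: build, then fit).

    Parameters
    ----------
    data : DataFrame with columns bed_id, block_id, treatment, t_prime, y_prime
        One flush of transformed per-bed cumulative yield.
    weights : array-like, optional
        Per-observation weights (default all ones).
    spec : NlmeSpec, optional
    flush : int, optional
        Flush index carried through to results tables.
    """

    def __init__(self, data: pd.DataFrame, weights=None,
                 spec: NlmeSpec | None = None, flush: int | None = None):
        missing = [c for c in _REQUIRED_COLS if c not in data.columns]
        if missing:
            raise ValueError(f"flush data missing columns: {missing}")
        data = data.sort_values(["bed_id", "t_prime"], kind="stable").reset_index(drop=True)
        self.data = data
        self.spec = spec or NlmeSpec()
        self.flush = flush if flush is not None else (
            int(data["flush"].iloc[0]) if "flush" in data.columns else None)

        self.t = data["t_prime"].to_numpy(dtype=float)
        self.y = data["y_prime"].to_numpy(dtype=float)
        if weights is None:
            self.weights = np.ones(len(data))
        else:
            self.weights = np.asarray(weights, dtype=float)
            if self.weights.shape != self.y.shape:
                raise ValueError("weights length must match number of observations")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")

        beds = pd.unique(data["bed_id"])
        self.bed_ids = list(beds)
        self.bed_index = data["bed_id"].map({b: i for i, b in enumerate(beds)}).to_numpy()
        bed_meta = data.drop_duplicates("bed_id").set_index("bed_id").loc[beds]
        self.treatments = list(pd.unique(bed_meta["treatment"]))
        self.blocks = list(pd.unique(bed_meta["block_id"]))
        self.bed_trt = bed_meta["treatment"].map(
            {t: i for i, t in enumerate(self.treatments)}).to_numpy()
        self.bed_block = bed_meta["block_id"].map(
            {b: i for i, b in enumerate(self.blocks)}).to_numpy()

        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_flush_table(cls, flush_table: pd.DataFrame, flush: int,
                         weights=None, spec: NlmeSpec | None = None):
        """Select one flush from a split_flushes table."""
        sub = flush_table[flush_table["flush"] == flush]
        if sub.empty:
            raise ValueError(f"no observations for flush {flush}")
        return cls(sub, weights=weights, spec=spec, flush=flush)

    def _validate(self) -> None:
        if not np.any(self.y > 0):
            raise ValueError("degenerate flush: all y' are zero")
        obs_per_bed = np.bincount(self.bed_index, minlength=len(self.bed_ids))
        thin = [self.bed_ids[i] for i in np.flatnonzero(obs_per_bed < 5)]
        if thin:
            raise ValueError(f"beds with fewer than 5 observations: {thin}")
        counts = np.bincount(self.bed_trt, minlength=len(self.treatments))
        lonely = [self.treatments[i] for i in np.flatnonzero(counts < 2)]
        if lonely:
            warnings.warn(f"treatments represented by a single bed: {lonely}; "
                          "random effects are weakly identified")

    # -- helpers ----------------------------------------------------------

    def _start_values(self) -> tuple[float, float, float]:
        sp = self.spec
        if not sp.data_driven_start:
            return sp.start.A, sp.start.B, sp.start.C
        a0 = 1.05 * float(self.y.max())
        frac = np.clip(self.y / a0, 1e-9, 1 - 1e-9)
        z = -np.log(-np.log(frac))
        keep = (self.y > 0.02 * a0) & (self.y < 0.98 * a0)
        if keep.sum() < 3:
            keep = slice(None)
        slope, intercept = np.polyfit(self.t[keep], z[keep], 1)
        c0 = max(float(slope), 1e-4)
        b0 = float(-intercept)
        return a0, b0, c0

    def _mean(self, a, b, C, offA, offB):
        """Structural mean for all observations given per-bed offsets."""
        A_i = a[self.bed_trt] + offA
        B_i = b[self.bed_trt] + offB
        g = B_i[self.bed_index] - C * self.t
        return A_i[self.bed_index] * np.exp(-np.exp(g))

    def _bed_ssr(self, a, b, C, offA, offB):
        r = self.y - self._mean(a, b, C, offA, offB)
        return np.bincount(self.bed_index, weights=self.weights * r * r,
                           minlength=len(self.bed_ids))

    # -- fitting ----------------------------------------------------------

    def fit(self, method: str = "saem") -> "GompertzMixedResults":
        if method == "saem":
            return self._fit_saem()
        if method == "two_stage":
            return self._fit_two_stage()
        raise ValueError(f"unknown method {method!r}")

    def _fit_saem(self) -> "GompertzMixedResults":
        sp = self.spec
        rng = np.random.default_rng(sp.seed)
        n_t, n_g, n_b = len(self.treatments), len(self.blocks), len(self.bed_ids)
        n_obs = len(self.y)

        a0, b0, c0 = self._start_values()
        a = np.full(n_t, a0)
        b = np.full(n_t, b0)
        C = c0

        u = np.zeros((n_g, 2))   # block effects on (A, B)
        v = np.zeros((n_b, 2))   # bed effects on (A, B)
        om_u = np.array([(0.05 * a0) ** 2, 0.05 ** 2])
        om_v = np.array([(0.10 * a0) ** 2, 0.10 ** 2])
        if not sp.block_on_b:
            om_u[1] = 0.0
        floor_u = np.array([1e-8 * a0 ** 2, 1e-10])
        floor_v = np.array([1e-8 * a0 ** 2, 1e-10])

        r0 = self.y - self._mean(a, b, C, np.zeros(n_b), np.zeros(n_b))
        sig2 = max(float(np.mean(self.weights * r0 ** 2)), 1e-6)

        H = np.zeros((n_b, 2))         # smoothed per-bed total offsets
        s_u = om_u.copy()
        s_v = om_v.copy()
        s_ssr = sig2 * n_obs
        step_u, step_v = 0.4, 0.4

        n_iter = sp.n_burnin + sp.n_smooth
        trace = np.empty((n_iter, 2 * n_t + 1))
        blk_of_bed = self.bed_block

        def offsets(u, v):
            offA = u[blk_of_bed, 0] + v[:, 0]
            offB = (u[blk_of_bed, 1] if sp.block_on_b else 0.0) + v[:, 1]
            return offA, offB

        for m in range(n_iter):
            gamma = 1.0 if m < sp.n_burnin else 1.0 / (m - sp.n_burnin + 1)

            # --- E-step: Metropolis-within-Gibbs over bed and block effects
            acc_v = acc_u = prop_v = prop_u = 0
            for _ in range(sp.n_kernel):
                # bed effects: independent accept/reject per bed
                sd_v = np.sqrt(np.maximum(om_v, floor_v))
                cand = v + step_v * sd_v * rng.standard_normal((n_b, 2))
                offA, offB = offsets(u, v)
                coffA, coffB = offsets(u, cand)
                ssr_cur = self._bed_ssr(a, b, C, offA, offB)
                ssr_new = self._bed_ssr(a, b, C, coffA, coffB)
                pri_cur = (v ** 2 / np.maximum(om_v, floor_v)).sum(axis=1)
                pri_new = (cand ** 2 / np.maximum(om_v, floor_v)).sum(axis=1)
                logr = -(ssr_new - ssr_cur) / (2 * sig2) - 0.5 * (pri_new - pri_cur)
                accept = np.log(rng.random(n_b)) < logr
                v[accept] = cand[accept]
                acc_v += accept.sum(); prop_v += n_b

                # block effects: aggregate over the block's beds
                sd_u = np.sqrt(np.maximum(om_u, floor_u))
                candu = u + step_u * sd_u * rng.standard_normal((n_g, 2))
                if not sp.block_on_b:
                    candu[:, 1] = 0.0
                offA, offB = offsets(u, v)
                coffA, coffB = offsets(candu, v)
                ssr_cur = np.bincount(blk_of_bed, weights=self._bed_ssr(a, b, C, offA, offB),
                                      minlength=n_g)
                ssr_new = np.bincount(blk_of_bed, weights=self._bed_ssr(a, b, C, coffA, coffB),
                                      minlength=n_g)
                pri_cur = (u ** 2 / np.maximum(om_u, floor_u)).sum(axis=1)
                pri_new = (candu ** 2 / np.maximum(om_u, floor_u)).sum(axis=1)
                logr = -(ssr_new - ssr_cur) / (2 * sig2) - 0.5 * (pri_new - pri_cur)
                accept = np.log(rng.random(n_g)) < logr
                u[accept] = candu[accept]
                acc_u += accept.sum(); prop_u += n_g

            if m < sp.n_burnin:  # adapt proposal scales toward ~35% acceptance
                step_v = float(np.clip(step_v * np.exp(0.3 * (acc_v / prop_v - 0.35)), 0.02, 2.0))
                step_u = float(np.clip(step_u * np.exp(0.3 * (acc_u / prop_u - 0.35)), 0.02, 2.0))

            # --- recentre: absorb random-effect means into the fixed effects.
            # At the MLE the sampled effects average to zero within each
            # grouping; moving the means explicitly decouples the slow
            # fixed-effect/random-mean direction of the chain.
            for k in range(n_t):
                sel = self.bed_trt == k
                mA, mB = v[sel, 0].mean(), v[sel, 1].mean()
                a[k] += mA
                b[k] += mB
                v[sel, 0] -= mA
                v[sel, 1] -= mB
            mA = u[:, 0].mean()
            a += mA
            u[:, 0] -= mA
            if sp.block_on_b:
                mB = u[:, 1].mean()
                b += mB
                u[:, 1] -= mB

            # --- stochastic approximation of sufficient statistics
            offA, offB = offsets(u, v)
            H[:, 0] = (1 - gamma) * H[:, 0] + gamma * offA
            H[:, 1] = (1 - gamma) * H[:, 1] + gamma * offB
            s_u = (1 - gamma) * s_u + gamma * (u ** 2).mean(axis=0)
            s_v = (1 - gamma) * s_v + gamma * (v ** 2).mean(axis=0)
            r = self.y - self._mean(a, b, C, offA, offB)
            s_ssr = (1 - gamma) * s_ssr + gamma * float(np.sum(self.weights * r * r))

            # --- M-step: variances closed-form, fixed effects by damped GN
            sig2 = max(s_ssr / n_obs, 1e-10)
            om_u = np.maximum(s_u, floor_u)
            om_v = np.maximum(s_v, floor_v)
            if not sp.block_on_b:
                om_u[1] = 0.0
            a, b, C = self._gn_update(a, b, C, H[:, 0], H[:, 1], n_steps=3)

            trace[m, :n_t] = a
            trace[m, n_t:2 * n_t] = b
            trace[m, -1] = C

        # REML-style degrees-of-freedom correction: the recentring removes
        # the treatment means from the bed effects and the grand mean from
        # the block effects, so the raw second moments underestimate the
        # variance components by (n - p)/n exactly as ML does.
        if n_b > n_t:
            om_v = om_v * n_b / (n_b - n_t)
        if n_g > 1:
            om_u = om_u * n_g / (n_g - 1)
        if not sp.block_on_b:
            om_u[1] = 0.0

        cols = ([f"A[{t}]" for t in self.treatments]
                + [f"B[{t}]" for t in self.treatments] + ["C"])
        trace_df = pd.DataFrame(trace, columns=cols)
        converged, drift = self._check_trace(trace)
        if sp.check_convergence and not converged:
            raise ConvergenceError(
                f"SAEM trace not stabilized: max per-iteration relative drift "
                f"{drift:.2e} exceeds {sp.convergence_rtol:.0e}", trace_df)

        return self._package(a, b, C, sig2, om_u, om_v, H, trace_df,
                             method="saem", converged=converged)

    def _gn_update(self, a, b, C, offA, offB, n_steps=3):
        """Damped Gauss-Newton (Levenberg-Marquardt) on the fixed effects."""
        n_t = len(self.treatments)
        theta = np.concatenate([a, b, [C]])
        w = self.weights

        def unpack(th):
            return th[:n_t], th[n_t:2 * n_t], th[-1]

        def resid(th):
            aa, bb, cc = unpack(th)
            return self.y - self._mean(aa, bb, cc, offA, offB)

        def jac(th):
            aa, bb, cc = unpack(th)
            A_i = aa[self.bed_trt] + offA
            B_i = bb[self.bed_trt] + offB
            g = B_i[self.bed_index] - cc * self.t
            eg = np.exp(g)
            core = np.exp(-eg)
            J = np.zeros((len(self.y), 2 * n_t + 1))
            trt_obs = self.bed_trt[self.bed_index]
            dA = core
            dB = -A_i[self.bed_index] * core * eg
            for k in range(n_t):
                sel = trt_obs == k
                J[sel, k] = dA[sel]
                J[sel, n_t + k] = dB[sel]
            J[:, -1] = A_i[self.bed_index] * core * eg * self.t
            return J

        lam = 1e-3
        r = resid(theta)
        ssr = float(np.sum(w * r * r))
        for _ in range(n_steps):
            J = jac(theta)
            JtW = J.T * w
            M = JtW @ J
            rhs = JtW @ r
            for _try in range(8):
                try:
                    delta = np.linalg.solve(M + lam * np.diag(np.maximum(np.diag(M), 1e-12)), rhs)
                except np.linalg.LinAlgError:
                    lam *= 10
                    continue
                cand = theta + delta
                if cand[-1] <= 0:  # C must stay positive
                    lam *= 10
                    continue
                rc = resid(cand)
                ssr_c = float(np.sum(w * rc * rc))
                if ssr_c <= ssr:
                    theta, r, ssr = cand, rc, ssr_c
                    lam = max(lam / 3, 1e-8)
                    break
                lam *= 10
        return unpack(theta)[0].copy(), unpack(theta)[1].copy(), float(theta[-1])

    def _check_trace(self, trace: np.ndarray) -> tuple[bool, float]:
        tail = trace[-min(50, trace.shape[0]):]
        x = np.arange(tail.shape[0])
        worst = 0.0
        for j in range(tail.shape[1]):
            slope = np.polyfit(x, tail[:, j], 1)[0]
            scale = max(abs(tail[-1, j]), 1e-8)
            worst = max(worst, abs(slope) / scale)
        return worst < self.spec.convergence_rtol, worst

    # -- two-stage fallback ----------------------------------------------

    def _fit_two_stage(self) -> "GompertzMixedResults":
        """Per-bed NLS, shared C by averaging, then moment estimates across beds."""
        a0, b0, c0 = self._start_values()
        n_b = len(self.bed_ids)
        per_bed = np.zeros((n_b, 3))
        for i in range(n_b):
            sel = self.bed_index == i
            t, y, w = self.t[sel], self.y[sel], self.weights[sel]
            sw = np.sqrt(w)

            def f(th):
                return sw * (y - th[0] * np.exp(-np.exp(th[1] - th[2] * t)))

            res = optimize.least_squares(
                f, x0=[max(a0, y.max() * 1.05), b0, c0],
                bounds=([1e-6, -np.inf, 1e-6], [np.inf, np.inf, np.inf]))
            per_bed[i] = res.x
        C = float(np.mean(per_bed[:, 2]))
        for i in range(n_b):  # refit (A, B) with shared C
            sel = self.bed_index == i
            t, y, w = self.t[sel], self.y[sel], self.weights[sel]
            sw = np.sqrt(w)

            def f2(th):
                return sw * (y - th[0] * np.exp(-np.exp(th[1] - C * t)))

            res = optimize.least_squares(f2, x0=per_bed[i, :2],
                                         bounds=([1e-6, -np.inf], [np.inf, np.inf]))
            per_bed[i, :2] = res.x

        n_t = len(self.treatments)
        a = np.zeros(n_t); b = np.zeros(n_t)
        se_a = np.zeros(n_t); se_b = np.zeros(n_t)
        for k in range(n_t):
            sel = self.bed_trt == k
            a[k] = per_bed[sel, 0].mean()
            b[k] = per_bed[sel, 1].mean()
            n_k = sel.sum()
            if n_k > 1:
                se_a[k] = per_bed[sel, 0].std(ddof=1) / np.sqrt(n_k)
                se_b[k] = per_bed[sel, 1].std(ddof=1) / np.sqrt(n_k)

        resA = per_bed[:, 0] - a[self.bed_trt]
        resB = per_bed[:, 1] - b[self.bed_trt]
        blkA = np.array([resA[self.bed_block == g].mean() for g in range(len(self.blocks))])
        om_u = np.array([max(blkA.var(ddof=1) if len(blkA) > 1 else 0.0, 0.0), 0.0])
        om_v = np.array([max(resA.var(ddof=1) - om_u[0], 0.0) if n_b > 1 else 0.0,
                         resB.var(ddof=1) if n_b > 1 else 0.0])

        offA = resA
        offB = resB
        H = np.column_stack([offA, offB])
        r = self.y - self._mean(a, b, C, offA, offB)
        sig2 = float(np.sum(self.weights * r * r) / len(self.y))
        res = self._package(a, b, C, sig2, om_u, om_v, H, trace=None,
                            method="two_stage", converged=True)
        # marginal SEs only: no joint covariance between treatments
        bse = res.bse.copy()
        for k, t in enumerate(self.treatments):
            bse[f"A[{t}]"] = se_a[k] if se_a[k] > 0 else bse[f"A[{t}]"]
            bse[f"B[{t}]"] = se_b[k] if se_b[k] > 0 else bse[f"B[{t}]"]
        res.bse = bse
        res.cov_is_marginal = True
        return res

    # -- packaging --------------------------------------------------------

    def _package(self, a, b, C, sig2, om_u, om_v, H, trace, method, converged):
        n_t = len(self.treatments)
        names = ([f"A[{t}]" for t in self.treatments]
                 + [f"B[{t}]" for t in self.treatments] + ["C"])
        params = pd.Series(np.concatenate([a, b, [C]]), index=names)
        cov = self._linearized_cov(a, b, C, sig2, om_u, om_v, H)
        bse = pd.Series(np.sqrt(np.maximum(np.diag(cov), 0.0)), index=names)
        fitted = self._mean(a, b, C, H[:, 0], H[:, 1])
        pop_fitted = self._mean(a, b, C, np.zeros(len(self.bed_ids)),
                                np.zeros(len(self.bed_ids)))
        return GompertzMixedResults(
            model=self, method=method, params=params, bse=bse,
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            vcomp={"block_A": float(om_u[0]), "block_B": float(om_u[1]),
                   "bed_A": float(om_v[0]), "bed_B": float(om_v[1])},
            scale=float(sig2), fittedvalues=fitted, pop_fittedvalues=pop_fitted,
            trace=trace, converged=bool(converged), flush=self.flush,
        )

    def _linearized_cov(self, a, b, C, sig2, om_u, om_v, H):
        """Fixed-effect covariance from the marginal Fisher information,
        linearizing the model at the estimated random-effect means."""
        n_t, n_b, n_g = len(self.treatments), len(self.bed_ids), len(self.blocks)
        n = len(self.y)
        A_i = a[self.bed_trt] + H[:, 0]
        B_i = b[self.bed_trt] + H[:, 1]
        g = B_i[self.bed_index] - C * self.t
        eg = np.exp(g)
        core = np.exp(-eg)
        dA = core
        dB = -A_i[self.bed_index] * core * eg

        X = np.zeros((n, 2 * n_t + 1))
        trt_obs = self.bed_trt[self.bed_index]
        for k in range(n_t):
            sel = trt_obs == k
            X[sel, k] = dA[sel]
            X[sel, n_t + k] = dB[sel]
        X[:, -1] = A_i[self.bed_index] * core * eg * self.t

        Zb = np.zeros((n, 2 * n_b))
        Zb[np.arange(n), 2 * self.bed_index] = dA
        Zb[np.arange(n), 2 * self.bed_index + 1] = dB
        Zg = np.zeros((n, 2 * n_g))
        blk_obs = self.bed_block[self.bed_index]
        Zg[np.arange(n), 2 * blk_obs] = dA
        Zg[np.arange(n), 2 * blk_obs + 1] = dB

        V = np.diag(sig2 / self.weights)
        V += (Zb * np.tile(om_v, n_b)) @ Zb.T
        V += (Zg * np.tile(om_u, n_g)) @ Zg.T
        try:
            cf = linalg.cho_factor(V)
            VinvX = linalg.cho_solve(cf, X)
        except linalg.LinAlgError:
            VinvX = np.linalg.lstsq(V, X, rcond=None)[0]
        info = X.T @ VinvX
        try:
            return np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(info)


class GompertzMixedResults:
    """Estimates, uncertainties and diagnostics of a per-flush Gompertz fit."""

    def __init__(self, model, method, params, bse, cov_params, vcomp, scale,
                 fittedvalues, pop_fittedvalues, trace, converged, flush):
        self.model = model
        self.method = method
        self.params = params
        self.bse = bse
        self.cov_params = cov_params
        self.vcomp = vcomp
        self.scale = scale
        self.fittedvalues = fittedvalues
        self.pop_fittedvalues = pop_fittedvalues
        self.trace = trace
        self.converged = converged
        self.flush = flush
        self.cov_is_marginal = False  # True when only marginal SEs are available

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    @property
    def efron_r2(self) -> float:
        """Efron's R-squared of the conditional (bed-level) fit."""
        return efron_r2(self.model.y, self.fittedvalues)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse})

    def treatment_estimates(self) -> pd.DataFrame:
        """Population-level (random effects at zero) estimates per treatment."""
        rows = []
        for t in self.model.treatments:
            for p in ("A", "B"):
                rows.append({"flush": self.flush, "treatment": t, "parameter": p,
                             "estimate": self.params[f"{p}[{t}]"],
                             "se": self.bse[f"{p}[{t}]"]})
        rows.append({"flush": self.flush, "treatment": "(shared)", "parameter": "C",
                     "estimate": self.params["C"], "se": self.bse["C"]})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Gompertz mixed model, flush {self.flush} "
            f"(estimator: {self.method}, converged: {self.converged})",
            f"obs: {len(self.model.y)}  beds: {len(self.model.bed_ids)}  "
            f"blocks: {len(self.model.blocks)}",
            f"Efron R2: {self.efron_r2:.4f}  residual SD: {np.sqrt(self.scale):.2f}",
            "",
            f"{'param':<12}{'estimate':>12}{'SE':>10}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<12}{self.params[name]:>12.4g}{self.bse[name]:>10.3g}")
        lines.append("")
        lines.append("variance components: "
                     + "  ".join(f"{k}={v:.3g}" for k, v in self.vcomp.items()))
        return "\n".join(lines)


def treatment_table(fits: list[GompertzMixedResults]) -> pd.DataFrame:
    """Long-format per-flush per-treatment (A, B, C) estimates with SEs."""
    if not fits:
        raise ValueError("need at least one fit")
    return pd.concat([f.treatment_estimates() for f in fits], ignore_index=True)


def contrast_vs_control(fits: list[GompertzMixedResults], control: str = "Control",
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-flush treatment-minus-control differences in A and B with Wald CIs.

    The SE of a difference uses the joint fixed-effect covariance when the
    estimator provides it; otherwise the covariance term is set to zero and
    the row is flagged (``cov_used`` False), which is conservative for
    positively correlated estimates.
    """
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for fit in fits:
        if control not in fit.model.treatments:
            raise ValueError(f"control label {control!r} absent from flush {fit.flush}")
        for trt in fit.model.treatments:
            if trt == control:
                continue
            for p in ("A", "B"):
                k1, k0 = f"{p}[{trt}]", f"{p}[{control}]"
                diff = fit.params[k1] - fit.params[k0]
                if fit.cov_is_marginal:
                    var = fit.bse[k1] ** 2 + fit.bse[k0] ** 2
                    cov_used = False
                else:
                    var = (fit.cov_params.loc[k1, k1] + fit.cov_params.loc[k0, k0]
                           - 2 * fit.cov_params.loc[k1, k0])
                    cov_used = True
                se = float(np.sqrt(max(var, 0.0)))
                rows.append({
                    "flush": fit.flush, "treatment": trt, "parameter": p,
                    "difference": float(diff), "se": se,
                    "lower": float(diff - z * se), "upper": float(diff + z * se),
                    "significant": bool(abs(diff) > z * se), "cov_used": cov_used,
                })
    return pd.DataFrame(rows)
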