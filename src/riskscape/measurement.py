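"""Latent executive-function measurement model, fitted by FIML.

Four tests (Stroop, Hayling, Brixton, Color Trails analogues) observed
at three waves load on one latent EF factor per wave (optionally two:
inhibition = Stroop + Hayling, shifting = Brixton + Color Trails). The
model is estimated casewise by full-information maximum likelihood
(FIML), valid under missing-at-random attrition: each participant
contributes the multivariate-normal log-density of their observed
subset of the 12 indicator variables.

Identification uses the marker convention: the first loading per factor
is fixed to 1 and factor means are 0 at wave 1 (free at later waves once
intercepts are constrained). Cross-wave covariances among factors and
among same-indicator residuals are free, as is standard in longitudinal
CFA. The invariance ladder tests configural -> metric (equal loadings)
-> scalar (equal intercepts, with a partial-scalar fallback freeing at
most two intercepts) -> residual (equal residual variances), each step a
likelihood-ratio chi-square.

Model chi-square is the likelihood ratio against the FIML-saturated
model (estimated by EM); RMSEA, CFI (against the independence baseline)
and an SRMR analogue on saturated-vs-implied correlations follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .config import EF_INDICATORS

__all__ = [
    "MeasurementSpec",
    "FitIndices",
    "MeasurementFit",
    "LadderStep",
    "InvarianceReport",
    "fiml_loglik",
    "fiml_saturated",
    "fit_measurement",
    "invariance_ladder",
    "estimate_factor_scores",
]

N_IND = 4
N_WAVES = 3
N_OBS = N_IND * N_WAVES  # 12 observed variables
SATURATED_K = N_OBS + N_OBS * (N_OBS + 1) // 2  # 90

INVARIANCE_LEVELS = ("configural", "metric", "scalar", "partial_scalar", "residual")


@dataclass(frozen=True)
class MeasurementSpec:
    """Structure of one measurement model.

    ``freed_intercepts`` lists (indicator, wave) pairs (0-based) whose
    intercepts are released from the scalar equality constraint; only
    meaningful for ``invariance='partial_scalar'`` and for the residual
    model reached through a partial-scalar solution.
    """

    n_factors: int = 1
    invariance: str = "configural"
    freed_intercepts: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n_factors not in (1, 2):
            raise ValueError("n_factors must be 1 or 2")
        if self.invariance not in INVARIANCE_LEVELS:
            raise ValueError(f"invariance must be one of {INVARIANCE_LEVELS}")
        for i, w in self.freed_intercepts:
            if not (0 <= i < N_IND and 0 <= w < N_WAVES):
                raise ValueError(f"freed intercept ({i}, {w}) out of range")

    @property
    def factor_of_indicator(self) -> tuple[int, ...]:
        return (0, 0, 0, 0) if self.n_factors == 1 else (0, 0, 1, 1)

    @property
    def markers(self) -> tuple[int, ...]:
        # first indicator loading on each within-wave factor
        return (0,) if self.n_factors == 1 else (0, 2)

    @property
    def n_total_factors(self) -> int:
        return N_WAVES * self.n_factors


# ---------------------------------------------------------------------------
# parameter mapping


class _ParamMap:
    """Maps a flat unconstrained vector to structured model matrices.

    Variances go through log transforms and covariance blocks through
    Cholesky factors, except the residual-invariance model's residual
    blocks (equal variances, free covariances) which are penalised if
    they leave the positive-definite cone.
    """

    def __init__(self, spec: MeasurementSpec):
        self.spec = spec
        idx = 0
        fac = spec.factor_of_indicator
        K = spec.n_total_factors
        self.K = K

        # loadings: -1 marks the fixed marker loadings
        self.lmap = -np.ones((N_WAVES, N_IND), dtype=int)
        if spec.invariance == "configural":
            for w in range(N_WAVES):
                for i in range(N_IND):
                    if i not in spec.markers:
                        self.lmap[w, i] = idx
                        idx += 1
        else:
            shared = {}
            for i in range(N_IND):
                if i not in spec.markers:
                    shared[i] = idx
                    idx += 1
            for w in range(N_WAVES):
                for i in shared:
                    self.lmap[w, i] = shared[i]

        # intercepts
        self.tmap = np.zeros((N_WAVES, N_IND), dtype=int)
        if spec.invariance in ("configural", "metric"):
            for w in range(N_WAVES):
                for i in range(N_IND):
                    self.tmap[w, i] = idx
                    idx += 1
        else:
            shared_t = {}
            for i in range(N_IND):
                shared_t[i] = idx
                idx += 1
            for w in range(N_WAVES):
                for i in range(N_IND):
                    self.tmap[w, i] = shared_t[i]
            for (i, w) in spec.freed_intercepts:
                self.tmap[w, i] = idx
                idx += 1

        # factor means: fixed 0 until intercepts are constrained
        self.amap = -np.ones(K, dtype=int)
        if spec.invariance not in ("configural", "metric"):
            for w in range(1, N_WAVES):
                for d in range(spec.n_factors):
                    self.amap[w * spec.n_factors + d] = idx
                    idx += 1

        # factor covariance Cholesky (log diagonal)
        self.psi_idx = np.arange(idx, idx + K * (K + 1) // 2)
        idx += K * (K + 1) // 2

        # residual blocks: one 3x3 across waves per indicator
        self.theta_mode = "var_cov" if spec.invariance == "residual" else "chol"
        if self.theta_mode == "chol":
            self.theta_idx = np.arange(idx, idx + 6 * N_IND).reshape(N_IND, 6)
            idx += 6 * N_IND
        else:
            self.theta_var_idx = np.arange(idx, idx + N_IND)
            idx += N_IND
            self.theta_cov_idx = np.arange(idx, idx + 3 * N_IND).reshape(N_IND, 3)
            idx += 3 * N_IND

        self.n_params = idx
        self._tril = np.tril_indices(K)
        # observed-variable index of (wave, indicator)
        self.vidx = np.arange(N_OBS).reshape(N_WAVES, N_IND)

    # -- structure -----------------------------------------------------

    def lambda_matrix(self, lam: np.ndarray) -> np.ndarray:
        spec = self.spec
        L = np.zeros((N_OBS, self.K))
        for w in range(N_WAVES):
            for i in range(N_IND):
                col = w * spec.n_factors + spec.factor_of_indicator[i]
                L[self.vidx[w, i], col] = lam[w, i]
        return L

    def unpack(self, x: np.ndarray):
        spec = self.spec
        lam = np.ones((N_WAVES, N_IND))
        mask = self.lmap >= 0
        lam[mask] = x[self.lmap[mask]]
        tau = x[self.tmap]
        alpha = np.zeros(self.K)
        amask = self.amap >= 0
        alpha[amask] = x[self.amap[amask]]

        Lpsi = np.zeros((self.K, self.K))
        Lpsi[self._tril] = x[self.psi_idx]
        np.fill_diagonal(Lpsi, np.exp(np.diag(Lpsi)))
        psi = Lpsi @ Lpsi.T

        theta_blocks = np.zeros((N_IND, 3, 3))
        theta_chols = []
        if self.theta_mode == "chol":
            tl = np.tril_indices(3)
            for j in range(N_IND):
                Lj = np.zeros((3, 3))
                Lj[tl] = x[self.theta_idx[j]]
                np.fill_diagonal(Lj, np.exp(np.diag(Lj)))
                theta_blocks[j] = Lj @ Lj.T
                theta_chols.append(Lj)
        else:
            for j in range(N_IND):
                v = np.exp(x[self.theta_var_idx[j]])
                B = np.full((3, 3), 0.0)
                B[0, 1] = B[1, 0] = x[self.theta_cov_idx[j, 0]]
                B[0, 2] = B[2, 0] = x[self.theta_cov_idx[j, 1]]
                B[1, 2] = B[2, 1] = x[self.theta_cov_idx[j, 2]]
                np.fill_diagonal(B, v)
                theta_blocks[j] = B
        return lam, tau, alpha, psi, Lpsi, theta_blocks, theta_chols

    def implied_moments(self, x: np.ndarray):
        lam, tau, alpha, psi, _, theta_blocks, _ = self.unpack(x)
        Lambda = self.lambda_matrix(lam)
        mu = tau.ravel() + Lambda @ alpha
        Theta = np.zeros((N_OBS, N_OBS))
        for j in range(N_IND):
            rows = self.vidx[:, j]
            Theta[np.ix_(rows, rows)] = theta_blocks[j]
        sigma = Lambda @ psi @ Lambda.T + Theta
        return mu, sigma, Lambda, psi, alpha

    # -- gradient back-propagation --------------------------------------

    def pack_grad(self, x, g_mu: np.ndarray, G: np.ndarray) -> np.ndarray:
        """Chain dlogL/dmu and dlogL/dSigma back to the flat vector."""
        lam, tau, alpha, psi, Lpsi, theta_blocks, theta_chols = self.unpack(x)
        Lambda = self.lambda_matrix(lam)
        grad = np.zeros(self.n_params)

        np.add.at(grad, self.tmap.ravel(), g_mu)

        gA = Lambda.T @ g_mu
        amask = self.amap >= 0
        np.add.at(grad, self.amap[amask], gA[amask])

        GL = 2.0 * G @ Lambda @ psi + np.outer(g_mu, alpha)
        for w in range(N_WAVES):
            for i in range(N_IND):
                p = self.lmap[w, i]
                if p >= 0:
                    col = w * self.spec.n_factors + self.spec.factor_of_indicator[i]
                    grad[p] += GL[self.vidx[w, i], col]

        M = Lambda.T @ G @ Lambda
        gpsiL = 2.0 * M @ Lpsi
        gpsiL[np.triu_indices(self.K, 1)] = 0.0
        dd = np.diag(gpsiL) * np.diag(Lpsi)  # log-diagonal chain
        gpsiL = gpsiL.copy()
        np.fill_diagonal(gpsiL, dd)
        grad[self.psi_idx] += gpsiL[self._tril]

        tl = np.tril_indices(3)
        for j in range(N_IND):
            rows = self.vidx[:, j]
            Mj = G[np.ix_(rows, rows)]
            if self.theta_mode == "chol":
                Lj = theta_chols[j]
                gL = 2.0 * Mj @ Lj
                gL[np.triu_indices(3, 1)] = 0.0
                dj = np.diag(gL) * np.diag(Lj)
                np.fill_diagonal(gL, dj)
                grad[self.theta_idx[j]] += gL[tl]
            else:
                v = theta_blocks[j][0, 0]
                grad[self.theta_var_idx[j]] += np.trace(Mj) * v
                grad[self.theta_cov_idx[j, 0]] += 2.0 * Mj[0, 1]
                grad[self.theta_cov_idx[j, 1]] += 2.0 * Mj[0, 2]
                grad[self.theta_cov_idx[j, 2]] += 2.0 * Mj[1, 2]
        return grad


# ---------------------------------------------------------------------------
# FIML likelihood machinery


class _PatternData:
    """Per-missing-pattern sufficient statistics for casewise FIML."""

    def __init__(self, Y: np.ndarray):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != N_OBS:
            raise ValueError(f"data must be (n, {N_OBS})")
        obs = ~np.isnan(Y)
        keep = obs.any(axis=1)
        self.n_dropped = int((~keep).sum())
        Y, obs = Y[keep], obs[keep]
        self.n = Y.shape[0]
        self.patterns = []
        codes = obs @ (1 << np.arange(N_OBS))
        for code in np.unique(codes):
            rows = np.where(codes == code)[0]
            o = np.where(obs[rows[0]])[0]
            block = Y[np.ix_(rows, o)]
            ybar = block.mean(axis=0)
            dev = block - ybar
            self.patterns.append(
                {"o": o, "n": len(rows), "ybar": ybar, "scatter": dev.T @ dev,
                 "rows": rows})

    def loglik_and_grads(self, mu: np.ndarray, sigma: np.ndarray):
        """FIML logL plus dlogL/dmu and dlogL/dSigma (full matrices)."""
        total = 0.0
        g_mu = np.zeros(N_OBS)
        G = np.zeros((N_OBS, N_OBS))
        log2pi = np.log(2.0 * np.pi)
        for pat in self.patterns:
            o, m, ybar, S0 = pat["o"], pat["n"], pat["ybar"], pat["scatter"]
            sub = sigma[np.ix_(o, o)]
            try:
                c = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return None
            logdet = 2.0 * np.log(np.diag(c)).sum()
            inv = np.linalg.inv(sub)
            d = ybar - mu[o]
            quad = float(np.trace(inv @ S0)) + m * float(d @ inv @ d)
            total += -0.5 * (m * len(o) * log2pi + m * logdet + quad)
            gm = m * inv @ d
            Gp = 0.5 * (inv @ (S0 + m * np.outer(d, d)) @ inv - m * inv)
            g_mu[o] += gm
            G[np.ix_(o, o)] += Gp
        return total, g_mu, G


def fiml_loglik(Y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Casewise FIML log-likelihood of ``Y`` (NaN = missing) under a
    multivariate normal with the given mean and covariance."""
    res = _PatternData(Y).loglik_and_grads(np.asarray(mu, float),
                                           np.asarray(sigma, float))
    if res is None:
        raise np.linalg.LinAlgError(
            "model-implied covariance not positive definite on an "
            "observed-variable subset")
    return res[0]


def fiml_saturated(Y: np.ndarray, tol: float = 1e-9, max_iter: int = 5000):
    """Saturated-model FIML estimates (mu, sigma, logL) by EM."""
    pat = _PatternData(Y)
    Y = np.asarray(Y, float)
    Y = Y[~np.isnan(Y).all(axis=1)]
    n = pat.n
    mu = np.nanmean(Y, axis=0)
    var = np.nanvar(Y, axis=0)
    sigma = np.diag(np.maximum(var, 1e-6))
    last = -np.inf
    for _ in range(max_iter):
        S1 = np.zeros(N_OBS)
        S2 = np.zeros((N_OBS, N_OBS))
        for p in pat.patterns:
            o = p["o"]
            m = np.setdiff1d(np.arange(N_OBS), o)
            rows = p["rows"]
            block = Y[np.ix_(rows, o)]
            if m.size == 0:
                S1[o] += block.sum(axis=0)
                S2[np.ix_(o, o)] += block.T @ block
                continue
            inv = np.linalg.inv(sigma[np.ix_(o, o)])
            B = sigma[np.ix_(m, o)] @ inv
            cond_cov = sigma[np.ix_(m, m)] - B @ sigma[np.ix_(o, m)]
            xm = mu[m] + (block - mu[o]) @ B.T
            full = np.zeros((len(rows), N_OBS))
            full[:, o] = block
            full[:, m] = xm
            S1 += full.sum(axis=0)
            S2 += full.T @ full
            S2[np.ix_(m, m)] += len(rows) * cond_cov
        mu = S1 / n
        sigma = S2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        res = pat.loglik_and_grads(mu, sigma)
        if res is None:
            sigma += 1e-8 * np.eye(N_OBS)
            continue
        ll = res[0]
        if abs(ll - last) < tol * (1.0 + abs(ll)):
            last = ll
            break
        last = ll
    return mu, sigma, last


def _baseline_loglik(Y: np.ndarray) -> tuple[float, int]:
    """Independence baseline: free means/variances, zero covariances."""
    Y = np.asarray(Y, float)
    total = 0.0
    for v in range(N_OBS):
        col = Y[:, v]
        col = col[~np.isnan(col)]
        m = col.size
        var = max(col.var(), 1e-12)
        total += -0.5 * m * (np.log(2 * np.pi * var) + 1.0)
    return total, 2 * N_OBS


# ---------------------------------------------------------------------------
# results containers


@dataclass(frozen=True)
class FitIndices:
    chi2: float
    df: int
    p: float
    cfi: float
    rmsea: float
    srmr: float
    logL: float
    n_free_params: int
    aic: float
    bic: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("chi2", "df", "p", "cfi", "rmsea", "srmr", "logL",
                 "n_free_params", "aic", "bic")}


@dataclass
class MeasurementFit:
    spec: MeasurementSpec
    loadings: np.ndarray  # (3, 4)
    intercepts: np.ndarray  # (3, 4)
    residual_blocks: np.ndarray  # (4, 3, 3) same-indicator cross-wave cov
    factor_means: np.ndarray  # (K,)
    factor_cov: np.ndarray  # (K, K)
    logL: float
    n_params: int
    n_obs: int
    converged: bool
    indices: FitIndices | None = None
    heywood: bool = False
    _x: np.ndarray | None = field(default=None, repr=False)
    _pmap: _ParamMap | None = field(default=None, repr=False)

    _se: np.ndarray | None = field(default=None, repr=False)

    @property
    def implied_mean(self) -> np.ndarray:
        return self._pmap.implied_moments(self._x)[0]

    @property
    def implied_cov(self) -> np.ndarray:
        return self._pmap.implied_moments(self._x)[1]

    def standard_errors(self, Y: np.ndarray) -> np.ndarray:
        """Observed-information SEs of the free parameters (on their
        unconstrained scale), via finite differences of the analytic
        gradient. Cached after the first call."""
        if self._se is not None:
            return self._se
        pat = _PatternData(Y)
        x = self._x
        h = 1e-5 * np.maximum(1.0, np.abs(x))
        H = np.zeros((x.size, x.size))
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += h[i]
            xm[i] -= h[i]
            gp = _neg_loglik_and_grad(xp, self._pmap, pat)[1]
            gm = _neg_loglik_and_grad(xm, self._pmap, pat)[1]
            H[i] = (gp - gm) / (2 * h[i])
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(x.size, np.nan)
        self._se = se
        return se

    def to_dict(self) -> dict:
        return {
            "spec": {"n_factors": self.spec.n_factors,
                     "invariance": self.spec.invariance,
                     "freed_intercepts": list(map(list, self.spec.freed_intercepts))},
            "loadings": self.loadings.tolist(),
            "intercepts": self.intercepts.tolist(),
            "residual_blocks": self.residual_blocks.tolist(),
            "factor_means": self.factor_means.tolist(),
            "factor_cov": self.factor_cov.tolist(),
            "logL": self.logL,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "heywood": self.heywood,
            "indices": self.indices.to_dict() if self.indices else None,
            "param_se_unconstrained": (None if self._se is None
                                       else self._se.tolist()),
            "constraint_map": {
                "loading_params": self._pmap.lmap.tolist(),
                "intercept_params": self._pmap.tmap.tolist(),
                "factor_mean_params": self._pmap.amap.tolist(),
            },
        }


# ---------------------------------------------------------------------------
# fitting


def _start_values(pmap: _ParamMap, Y: np.ndarray) -> np.ndarray:
    """Moment-based starting vector."""
    x = np.zeros(pmap.n_params)
    means = np.nanmean(Y, axis=0).reshape(N_WAVES, N_IND)
    var = np.nanvar(Y, axis=0).reshape(N_WAVES, N_IND)
    var = np.maximum(var, 1e-3)

    seen = set()
    for w in range(N_WAVES):
        for i in range(N_IND):
            p = pmap.tmap[w, i]
            if p not in seen:
                x[p] = means[w, i]
                seen.add(p)
            p = pmap.lmap[w, i]
            if p >= 0 and p not in seen:
                x[p] = 1.0
                seen.add(p)
    # factor variances ~ half the marker variance; zero covariances
    Lpsi = np.zeros((pmap.K, pmap.K))
    for w in range(N_WAVES):
        for d in range(pmap.spec.n_factors):
            k = w * pmap.spec.n_factors + d
            marker_var = var[w, pmap.spec.markers[d]]
            Lpsi[k, k] = np.sqrt(0.5 * marker_var)
    packed = Lpsi[pmap._tril].copy()
    diag_positions = np.cumsum(np.arange(1, pmap.K + 1)) - 1
    packed[diag_positions] = np.log(np.diag(Lpsi))
    x[pmap.psi_idx] = packed

    if pmap.theta_mode == "chol":
        tl_diag = [0, 2, 5]
        for j in range(N_IND):
            vals = np.zeros(6)
            for w, pos in enumerate(tl_diag):
                vals[pos] = 0.5 * np.log(0.5 * var[w, j])
            x[pmap.theta_idx[j]] = vals
    else:
        for j in range(N_IND):
            x[pmap.theta_var_idx[j]] = np.log(0.5 * var[:, j].mean())
    return x


def _neg_loglik_and_grad(x, pmap: _ParamMap, pat: _PatternData):
    mu, sigma, *_ = pmap.implied_moments(x)
    res = pat.loglik_and_grads(mu, sigma)
    if res is None:  # non-PD only reachable in the residual-model block
        return 1e12, np.zeros_like(x)
    ll, g_mu, G = res
    return -ll, -pmap.pack_grad(x, g_mu, G)


def fit_measurement(
    Y: np.ndarray,
    spec: MeasurementSpec | None = None,
    compute_indices: bool = True,
    saturated: tuple[np.ndarray, np.ndarray, float] | None = None,
    x0: np.ndarray | None = None,
    n_starts: int = 3,
    seed: int = 0,
    gtol: float = 1e-7,
) -> MeasurementFit:
    """Fit one measurement model by FIML.

    ``Y`` is the (n, 12) indicator matrix (wave-major, NaN = missing).
    ``saturated`` optionally carries precomputed saturated-model moments
    so ladder runs do not repeat the EM step. ``x0`` warm-starts the
    optimiser (extra random restarts are skipped when it is supplied).
    """
    spec = spec or MeasurementSpec()
    pmap = _ParamMap(spec)
    pat = _PatternData(Y)
    n = pat.n
    if n <= pmap.n_params:
        raise ValueError(
            f"n = {n} cases cannot identify {pmap.n_params} free parameters")

    rng = np.random.default_rng(seed)
    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, float))
    base = _start_values(pmap, Y)
    starts.append(base)
    while len(starts) < max(n_starts, len(starts)):
        starts.append(base + 0.1 * rng.standard_normal(base.size))

    best = None
    for start in starts:
        res = optimize.minimize(
            _neg_loglik_and_grad, start, args=(pmap, pat), jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": gtol})
        if best is None or res.fun < best.fun:
            best = res
        # extra starts are insurance against local optima; skip them
        # once a start has converged cleanly
        if best.fun < 1e11 and np.max(np.abs(best.jac)) < 1e-3:
            break
    # polish: L-BFGS often stops on ftol with a loose gradient; a second
    # round from the optimum with a larger memory tightens it cheaply
    polish = optimize.minimize(
        _neg_loglik_and_grad, best.x, args=(pmap, pat), jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-16, "gtol": 1e-9, "maxcor": 30})
    if polish.fun <= best.fun:
        best = polish
    x = best.x
    grad_norm = float(np.max(np.abs(best.jac)))
    converged = bool(best.fun < 1e11 and grad_norm < 1e-3)

    lam, tau, alpha, psi, _, theta_blocks, _ = pmap.unpack(x)
    heywood = bool(min(np.diag(b).min() for b in theta_blocks) < 1e-6)
    logL = -float(best.fun)

    fit = MeasurementFit(
        spec=spec, loadings=lam, intercepts=tau,
        residual_blocks=theta_blocks, factor_means=alpha, factor_cov=psi,
        logL=logL, n_params=pmap.n_params, n_obs=n, converged=converged,
        heywood=heywood, _x=x, _pmap=pmap)

    if compute_indices:
        if saturated is None:
            saturated = fiml_saturated(Y)
        fit.indices = _fit_indices(fit, Y, saturated)
    return fit


def _fit_indices(fit: MeasurementFit, Y, saturated) -> FitIndices:
    mu_s, sigma_s, ll_sat = saturated
    chi2 = max(0.0, 2.0 * (ll_sat - fit.logL))
    df = SATURATED_K - fit.n_params
    n = fit.n_obs
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n))) if df > 0 else 0.0
    ll_base, k_base = _baseline_loglik(Y)
    chi2_base = max(0.0, 2.0 * (ll_sat - ll_base))
    df_base = SATURATED_K - k_base
    denom = max(chi2_base - df_base, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))

    sd_s = np.sqrt(np.diag(sigma_s))
    corr_s = sigma_s / np.outer(sd_s, sd_s)
    sigma_m = fit.implied_cov
    sd_m = np.sqrt(np.diag(sigma_m))
    corr_m = sigma_m / np.outer(sd_m, sd_m)
    tril = np.tril_indices(N_OBS)
    resid = np.concatenate([(corr_s - corr_m)[tril], (sd_s - sd_m) / sd_s])
    srmr = float(np.sqrt(np.mean(resid ** 2)))

    aic = -2.0 * fit.logL + 2.0 * fit.n_params
    bic = -2.0 * fit.logL + fit.n_params * np.log(n)
    return FitIndices(chi2=chi2, df=df, p=p, cfi=cfi, rmsea=rmsea, srmr=srmr,
                      logL=fit.logL, n_free_params=fit.n_params,
                      aic=float(aic), bic=float(bic))


# ---------------------------------------------------------------------------
# invariance ladder


@dataclass(frozen=True)
class LadderStep:
    level: str
    fit: MeasurementFit
    delta_chi2: float | None
    delta_df: int | None
    p: float | None


@dataclass(frozen=True)
class InvarianceReport:
    steps: tuple[LadderStep, ...]
    accepted_level: str
    freed_intercepts: tuple[tuple[int, int], ...]

    @property
    def accepted_fit(self) -> MeasurementFit:
        for step in reversed(self.steps):
            if step.level == self.accepted_level:
                return step.fit
        raise RuntimeError("accepted level missing from ladder steps")


def _delta_test(looser: MeasurementFit, tighter: MeasurementFit):
    delta = max(0.0, 2.0 * (looser.logL - tighter.logL))
    ddf = looser.n_params - tighter.n_params
    p = float(stats.chi2.sf(delta, ddf)) if ddf > 0 else 1.0
    return delta, ddf, p


def _rank_intercept_candidates(fit: MeasurementFit, pat: _PatternData):
    """Approximate one-parameter likelihood gain of freeing each
    still-constrained intercept, via a score/curvature quotient."""
    pmap, x = fit._pmap, fit._x
    mu, sigma, *_ = pmap.implied_moments(x)
    res = pat.loglik_and_grads(mu, sigma)
    _, g_mu, _ = res
    gains = []
    h = 1e-4
    for w in range(N_WAVES):
        for i in range(N_IND):
            if (i, w) in fit.spec.freed_intercepts:
                continue
            score = g_mu[pmap.vidx[w, i]]  # d logL / d tau_wi deviation
            # curvature by central difference along this single intercept
            def ll_at(delta):
                mu2 = mu.copy()
                mu2[pmap.vidx[w, i]] += delta
                r = pat.loglik_and_grads(mu2, sigma)
                return r[0]
            curv = (ll_at(h) - 2.0 * ll_at(0.0) + ll_at(-h)) / h ** 2
            gain = 0.5 * score ** 2 / max(-curv, 1e-12)
            gains.append(((i, w), float(gain)))
    # largest approximate gain first; ties -> lowest indicator index
    gains.sort(key=lambda t: (-round(t[1], 10), t[0][0], t[0][1]))
    return gains


def invariance_ladder(
    Y: np.ndarray,
    n_factors: int = 1,
    alpha: float = 0.05,
    max_freed: int = 2,
    seed: int = 0,
) -> InvarianceReport:
    """Run configural -> metric -> scalar (-> partial scalar) -> residual.

    Each step is a likelihood-ratio test against the previous accepted
    model; if scalar invariance is rejected at ``alpha``, intercepts are
    freed one at a time (largest score-test gain first, at most
    ``max_freed``) until the test against the metric model is
    non-significant.
    """
    saturated = fiml_saturated(Y)
    pat = _PatternData(Y)

    conf = fit_measurement(Y, MeasurementSpec(n_factors, "configural"),
                           saturated=saturated, seed=seed)
    if not conf.converged:
        raise RuntimeError("configural model did not converge; ladder aborted")
    steps = [LadderStep("configural", conf, None, None, None)]

    metric = fit_measurement(Y, MeasurementSpec(n_factors, "metric"),
                             saturated=saturated, seed=seed,
                             x0=_project_start(conf, MeasurementSpec(n_factors, "metric")))
    steps.append(LadderStep("metric", metric, *_delta_test(conf, metric)))

    scalar_spec = MeasurementSpec(n_factors, "scalar")
    scalar = fit_measurement(Y, scalar_spec, saturated=saturated, seed=seed,
                             x0=_project_start(metric, scalar_spec))
    d, ddf, p = _delta_test(metric, scalar)
    steps.append(LadderStep("scalar", scalar, d, ddf, p))

    freed: tuple[tuple[int, int], ...] = ()
    accepted = scalar
    accepted_level = "scalar"
    if p < alpha:
        current = scalar
        while p < alpha and len(freed) < max_freed:
            candidates = _rank_intercept_candidates(current, pat)
            if not candidates:
                break
            freed = freed + (candidates[0][0],)
            pspec = MeasurementSpec(n_factors, "partial_scalar", freed)
            current = fit_measurement(Y, pspec, saturated=saturated, seed=seed,
                                      x0=_project_start(metric, pspec))
            d, ddf, p = _delta_test(metric, current)
            steps.append(LadderStep("partial_scalar", current, d, ddf, p))
        if p < alpha:
            accepted_level = "metric"  # scalar unattainable even partially
            accepted = metric
        else:
            accepted_level = "partial_scalar"
            accepted = current

    if accepted_level in ("scalar", "partial_scalar"):
        rspec = MeasurementSpec(n_factors, "residual", freed)
        resid = fit_measurement(Y, rspec, saturated=saturated, seed=seed,
                                x0=_project_start(accepted, rspec))
        d, ddf, p = _delta_test(accepted, resid)
        steps.append(LadderStep("residual", resid, d, ddf, p))
        if p >= alpha and resid.converged:
            accepted_level, accepted = "residual", resid

    return InvarianceReport(steps=tuple(steps), accepted_level=accepted_level,
                            freed_intercepts=freed)


def _project_start(fit: MeasurementFit, spec: MeasurementSpec) -> np.ndarray:
    """Warm-start a constrained model from a looser fitted one."""
    pmap = _ParamMap(spec)
    x = np.zeros(pmap.n_params)
    lam, tau = fit.loadings, fit.intercepts
    for w in range(N_WAVES):
        for i in range(N_IND):
            p = pmap.lmap[w, i]
            if p >= 0:
                x[p] = lam[:, i].mean() if spec.invariance != "configural" else lam[w, i]
            pt = pmap.tmap[w, i]
            shared = spec.invariance not in ("configural", "metric")
            x[pt] = tau[:, i].mean() if shared and (i, w) not in spec.freed_intercepts \
                else tau[w, i]
    K = pmap.K
    amask = pmap.amap >= 0
    if amask.any() and fit.factor_means.size == K:
        x[pmap.amap[amask]] = fit.factor_means[amask]
    psi = fit.factor_cov + 1e-8 * np.eye(K)
    Lpsi = np.linalg.cholesky(psi)
    packed = Lpsi[pmap._tril].copy()
    diag_positions = np.cumsum(np.arange(1, K + 1)) - 1
    packed[diag_positions] = np.log(np.diag(Lpsi))
    x[pmap.psi_idx] = packed
    tl = np.tril_indices(3)
    for j in range(N_IND):
        B = fit.residual_blocks[j] + 1e-8 * np.eye(3)
        if pmap.theta_mode == "chol":
            Lj = np.linalg.cholesky(B)
            vals = Lj[tl].copy()
            vals[[0, 2, 5]] = np.log(np.diag(Lj))
            x[pmap.theta_idx[j]] = vals
        else:
            x[pmap.theta_var_idx[j]] = np.log(np.diag(B).mean())
            x[pmap.theta_cov_idx[j]] = [B[0, 1], B[0, 2], B[1, 2]]
    return x


# ---------------------------------------------------------------------------
# factor scores


def estimate_factor_scores(
    fit: MeasurementFit,
    Y: np.ndarray,
    method: str = "bartlett",
) -> np.ndarray:
    """Per-person factor scores, (n, K), NaN where a wave has no
    observed indicator.

    ``bartlett`` scores are conditionally unbiased (E[score | eta] =
    eta), the appropriate choice when the scores feed a downstream
    growth model as the outcome; ``regression`` scores are the
    empirical-Bayes shrinkage estimates.
    """
    if method not in ("bartlett", "regression"):
        raise ValueError("method must be 'bartlett' or 'regression'")
    if not fit.converged:
        raise ValueError("factor scores require a converged measurement fit")
    pmap = fit._pmap
    mu, sigma, Lambda, psi, alpha = pmap.implied_moments(fit._x)
    tau = fit.intercepts.ravel()
    Theta = sigma - Lambda @ psi @ Lambda.T

    Y = np.asarray(Y, float)
    n = Y.shape[0]
    K = pmap.K
    scores = np.full((n, K), np.nan)
    obs = ~np.isnan(Y)
    codes = obs @ (1 << np.arange(N_OBS))
    spec = fit.spec
    for code in np.unique(codes):
        rows = np.where(codes == code)[0]
        o = np.where(obs[rows[0]])[0]
        if o.size == 0:
            continue
        # factors identified by >= 1 observed indicator
        live = np.unique([(v // N_IND) * spec.n_factors
                          + spec.factor_of_indicator[v % N_IND] for v in o])
        block = Y[np.ix_(rows, o)]
        if method == "regression":
            inv = np.linalg.inv(sigma[np.ix_(o, o)])
            W = psi @ Lambda[o].T @ inv  # (K, |o|)
            f = alpha[None, :] + (block - mu[o]) @ W.T
        else:
            A = Lambda[np.ix_(o, live)]
            Th_inv = np.linalg.inv(Theta[np.ix_(o, o)])
            Minfo = A.T @ Th_inv @ A
            try:
                Minv = np.linalg.inv(Minfo)
            except np.linalg.LinAlgError:
                continue
            f_live = (block - tau[o]) @ (Th_inv @ A @ Minv)
            f = np.full((len(rows), K), np.nan)
            f[:, live] = f_live
        mask = np.zeros(K, dtype=bool)
        mask[live] = True
        f[:, ~mask] = np.nan
        scores[rows] = f
    return scores


def factor_scores_frame(scores: np.ndarray, ids: Sequence) -> "pd.DataFrame":
    """One-factor scores as an id + ef_w1..ef_w3 table."""
    import pandas as pd

    if scores.shape[1] != N_WAVES:
        raise ValueError("per-wave frame only defined for one-factor scores")
    return pd.DataFrame({"id": np.asarray(ids),
                         **{f"ef_w{w + 1}": scores[:, w] for w in range(N_WAVES)}})
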