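"""Latent growth models for executive function on an age metric.

Each participant contributes up to three EF factor scores observed at
person-specific ages; chronological age centred at 75 years is the time
metric (accelerated longitudinal design), never the wave index. The
model is the standard random-coefficients formulation

    y_iw = (b0 + g0' u_i + a_i) + (b1 + g1' u_i + c_i) * t_iw [+ b2 t^2] + e_iw

with (a_i, c_i) ~ N(0, G), e_iw ~ N(0, sigma^2_w) (per-wave residuals by
default), u_i the predictor vector (risk score, sex). Estimation is
marginal maximum likelihood: each person's observed waves contribute a
multivariate-normal density with covariance Z_i G Z_i' + R_i. Fixed
effects are profiled out by GLS inside the variance optimisation;
standard errors come from the inverse observed information (numerical
Hessian of the full likelihood) and inference is two-sided Wald z.

The model-building ladder mirrors standard practice: null -> random
intercept -> + fixed slope -> + random slope -> + fixed quadratic, with
likelihood-ratio chi-square tests between consecutive stages (variance
additions sit on the parameter boundary; those tests are flagged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GrowthParams",
    "GrowthFit",
    "ConditionalGrowthFit",
    "ModerationTable",
    "growth_loglik",
    "fit_growth",
    "model_building_ladder",
    "fit_conditional_growth",
    "fit_stratified",
    "information_criteria",
]

STAGES = ("null", "random_intercept", "fixed_slope", "random_slope",
          "fixed_quadratic")


def information_criteria(logL: float, k: int, n: int) -> tuple[float, float, float]:
    """(-2LL, AIC, BIC) with AIC = -2LL + 2k and BIC = -2LL + k ln(n)."""
    if k < 1 or n < 1:
        raise ValueError("k and n must be >= 1")
    m2ll = -2.0 * logL
    return m2ll, m2ll + 2.0 * k, m2ll + k * np.log(n)


# ---------------------------------------------------------------------------
# data blocks


class _Blocks:
    """Per-missing-pattern tensors for vectorised person likelihoods."""

    def __init__(self, scores, times, U=None):
        y = np.asarray(scores, float)
        t = np.asarray(times, float)
        if y.shape != t.shape or y.ndim != 2 or y.shape[1] != 3:
            raise ValueError("scores and times must both be (n, 3)")
        obs = ~np.isnan(y)
        # a score without a time is unusable
        obs &= ~np.isnan(t)
        keep = obs.any(axis=1)
        self.n = int(keep.sum())
        if self.n == 0:
            raise ValueError("no participant has any observed score")
        y, t, obs = y[keep], t[keep], obs[keep]
        self.keep = keep
        if U is not None:
            U = np.asarray(U, float)[keep]
            if np.isnan(U).any():
                raise ValueError("predictors must be complete (drop missing first)")
        self.U = U
        self.n_obs_total = int(obs.sum())
        self.patterns = []
        codes = obs @ np.array([1, 2, 4])
        for code in np.unique(codes):
            rows = np.where(codes == code)[0]
            waves = np.where(obs[rows[0]])[0]
            self.patterns.append({
                "waves": waves,
                "y": y[np.ix_(rows, waves)],
                "t": t[np.ix_(rows, waves)],
                "U": None if U is None else U[rows],
                "n": len(rows),
            })
        self.max_waves = max(len(p["waves"]) for p in self.patterns)


def _design(pat, structure) -> np.ndarray:
    """(m, k, p) fixed-effect design for one pattern."""
    t = pat["t"]
    m, k = t.shape
    ones = np.ones((m, k))
    cols = [ones]
    if pat["U"] is not None:
        for j in range(pat["U"].shape[1]):
            cols.append(np.repeat(pat["U"][:, j:j + 1], k, axis=1))
    if structure["slope"]:
        base = len(cols)
        for j in range(base):
            cols.append(cols[j] * t)
    if structure["quad"]:
        cols.append(t ** 2)
    return np.stack(cols, axis=2)


def _marginal_cov_fixed(pat, G, resid):
    """(m, k, k) person covariance Z G Z' + R on the observed waves."""
    t = pat["t"]
    m, k = t.shape
    Z = np.stack([np.ones((m, k)), t], axis=2)
    V = np.einsum("mka,ab,mlb->mkl", Z, G, Z)
    diag = resid[pat["waves"]]
    V[:, np.arange(k), np.arange(k)] += diag[None, :]
    return V


def _pattern_nll(pat, structure, G, resid, beta=None):
    """Returns (nll_terms, X, V) for a pattern; if beta is None the
    residual quadratic term is left to the GLS caller."""
    V = _marginal_cov_fixed(pat, G, resid)
    try:
        C = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return None
    logdet = 2.0 * np.log(np.diagonal(C, axis1=1, axis2=2)).sum()
    return logdet, V


def _profiled(phi, blocks: _Blocks, structure):
    """Profiled negative log-likelihood over variance parameters, plus
    the GLS fixed effects and their GLS covariance."""
    G, resid = structure["unpack"](phi)
    p = structure["n_fixed"]
    A = np.zeros((p, p))
    b = np.zeros(p)
    logdet_total = 0.0
    yVy = 0.0
    cache = []
    for pat in blocks.patterns:
        res = _pattern_nll(pat, structure, G, resid)
        if res is None:
            return None
        logdet, V = res
        X = _design(pat, structure)
        try:
            Vi_X = np.linalg.solve(V, X)
            Vi_y = np.linalg.solve(V, pat["y"][..., None])[..., 0]
        except np.linalg.LinAlgError:
            return None  # numerically singular at extreme trial values
        A += np.einsum("mkp,mkq->pq", X, Vi_X)
        b += np.einsum("mkp,mk->p", X, Vi_y)
        yVy += float(np.einsum("mk,mk->", pat["y"], Vi_y))
        logdet_total += logdet
        cache.append((X, V))
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular information for fixed effects "
            f"(columns {structure['labels']}); predictors may be collinear")
    quad = yVy - float(beta @ b)
    nll = 0.5 * (blocks.n_obs_total * np.log(2 * np.pi) + logdet_total + quad)
    return nll, beta, A


def _full_nll(theta, blocks: _Blocks, structure):
    """Negative log-likelihood as a function of (beta, phi) jointly."""
    p = structure["n_fixed"]
    beta, phi = theta[:p], theta[p:]
    G, resid = structure["unpack"](phi)
    total = 0.0
    for pat in blocks.patterns:
        res = _pattern_nll(pat, structure, G, resid)
        if res is None:
            return 1e12
        logdet, V = res
        X = _design(pat, structure)
        r = pat["y"] - np.einsum("mkp,p->mk", X, beta)
        try:
            Vi_r = np.linalg.solve(V, r[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return 1e12
        total += 0.5 * (r.size * np.log(2 * np.pi) + logdet
                        + float(np.einsum("mk,mk->", r, Vi_r)))
    return total


# ---------------------------------------------------------------------------
# parameter structures per ladder stage


def _make_structure(stage: str, predictors: list[str], per_wave_resid: bool = True):
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    slope = stage in ("fixed_slope", "random_slope", "fixed_quadratic")
    quad = stage == "fixed_quadratic"
    labels = ["intercept"] + [f"{p}_on_intercept" for p in predictors]
    if slope:
        labels += ["slope"] + [f"{p}_on_slope" for p in predictors]
    if quad:
        labels += ["quadratic"]
    n_resid = 3 if per_wave_resid else 1

    if stage == "null":
        n_var = 0

        def unpack(phi):
            return np.zeros((2, 2)), _expand_resid(phi, per_wave_resid)
    elif stage in ("random_intercept", "fixed_slope"):
        n_var = 1

        def unpack(phi):
            G = np.zeros((2, 2))
            G[0, 0] = np.exp(phi[0]) ** 2
            return G, _expand_resid(phi[n_var:], per_wave_resid)
    else:  # random_slope, fixed_quadratic
        n_var = 3

        def unpack(phi):
            L = np.array([[np.exp(phi[0]), 0.0], [phi[1], np.exp(phi[2])]])
            return L @ L.T, _expand_resid(phi[n_var:], per_wave_resid)

    n_fixed = len(labels)
    return {
        "stage": stage,
        "slope": slope,
        "quad": quad,
        "labels": labels,
        "n_fixed": n_fixed,
        "n_var": n_var,
        "n_resid": n_resid,
        "unpack": unpack,
        "k": n_fixed + n_var + n_resid,
        "per_wave_resid": per_wave_resid,
    }


def _expand_resid(phi_resid, per_wave: bool) -> np.ndarray:
    v = np.exp(np.asarray(phi_resid, float))
    return v if per_wave else np.repeat(v[0], 3)


# ---------------------------------------------------------------------------
# public containers


@dataclass(frozen=True)
class GrowthParams:
    """Explicit parameter set for direct likelihood evaluation."""

    beta: np.ndarray  # fixed effects in structure label order
    G: np.ndarray  # 2x2 random-effect covariance
    resid: np.ndarray  # per-wave residual variances (3,)
    stage: str = "random_slope"
    predictors: tuple[str, ...] = ()


@dataclass
class GrowthFit:
    stage: str
    labels: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    G: np.ndarray
    resid: np.ndarray
    logL: float
    k: int
    n: int
    converged: bool
    boundary: bool = False
    flags: list[str] = field(default_factory=list)
    #: variance-parameter vector at the optimum (warm-start reuse)
    phi: np.ndarray | None = None

    def coef(self, label: str) -> tuple[float, float, float]:
        """(beta, SE, p) for one fixed-effect label."""
        i = self.labels.index(label)
        return float(self.beta[i]), float(self.se[i]), float(self.p[i])

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.logL

    @property
    def aic(self) -> float:
        return information_criteria(self.logL, self.k, self.n)[1]

    @property
    def bic(self) -> float:
        return information_criteria(self.logL, self.k, self.n)[2]

    def to_dict(self) -> dict:
        return {
            "stage": self.stage, "labels": self.labels,
            "beta": self.beta.tolist(), "se": self.se.tolist(),
            "p": self.p.tolist(), "G": self.G.tolist(),
            "resid": self.resid.tolist(), "logL": self.logL, "k": self.k,
            "n": self.n, "converged": self.converged, "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# likelihood evaluation and fitting


def growth_loglik(params: GrowthParams, scores, times, predictors=None) -> float:
    """Marginal log-likelihood at explicit parameter values.

    ``predictors`` is an (n, q) array matching ``params.predictors``.
    Raises if the implied covariance is singular (degenerate variances),
    where the likelihood diverges rather than attains a maximum.
    """
    structure = _make_structure(params.stage, list(params.predictors))
    blocks = _Blocks(scores, times, predictors)
    eig_ok = np.linalg.eigvalsh(params.G).min() >= -1e-10
    if not eig_ok:
        raise ValueError("random-effect covariance G is not PSD")
    if np.any(params.resid < 0):
        raise ValueError("residual variances must be >= 0")
    total = 0.0
    for pat in blocks.patterns:
        V = _marginal_cov_fixed(pat, params.G, np.asarray(params.resid, float))
        try:
            C = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular marginal covariance: degenerate variance "
                "parameters, log-likelihood diverges") from None
        logdet = 2.0 * np.log(np.diagonal(C, axis1=1, axis2=2)).sum()
        X = _design(pat, structure)
        if X.shape[2] != params.beta.size:
            raise ValueError(
                f"beta has {params.beta.size} entries but stage "
                f"{params.stage!r} with predictors {params.predictors} "
                f"needs {X.shape[2]}")
        r = pat["y"] - np.einsum("mkp,p->mk", X, params.beta)
        Vi_r = np.linalg.solve(V, r[..., None])[..., 0]
        total += -0.5 * (r.size * np.log(2 * np.pi) + logdet
                         + float(np.einsum("mk,mk->", r, Vi_r)))
    return total


def _check_identifiable(blocks: _Blocks, structure) -> None:
    if structure["slope"] and blocks.max_waves < 2:
        raise ValueError(
            "slope stages are not identified: no participant has two or "
            "more observed waves")


def _numerical_hessian(f, theta, h0=1e-4):
    p = theta.size
    h = h0 * np.maximum(1.0, np.abs(theta))
    H = np.zeros((p, p))
    f0 = f(theta)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        fpp = f(theta + ei); fmm = f(theta - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit_growth(
    scores,
    times,
    stage: str = "random_slope",
    predictors: dict[str, np.ndarray] | None = None,
    per_wave_resid: bool = True,
    se_method: str = "hessian",
    phi0: np.ndarray | None = None,
) -> GrowthFit:
    """Maximum-likelihood fit of one growth-model stage.

    ``predictors`` maps names to complete per-person arrays; rows with a
    missing score everywhere are dropped automatically, rows with a
    missing predictor must be dropped by the caller (mirroring
    listwise removal of missing predictor values).
    """
    pred_names = list(predictors) if predictors else []
    flags = []
    U = None
    if pred_names:
        U = np.column_stack([np.asarray(predictors[nm], float)
                             for nm in pred_names])
        # constant columns cannot be estimated; drop with a warning
        keeps = []
        for j, nm in enumerate(pred_names):
            if np.nanstd(U[:, j]) == 0:
                warnings.warn(f"predictor {nm!r} is constant; dropped")
                flags.append(f"dropped_constant:{nm}")
            else:
                keeps.append(j)
        pred_names = [pred_names[j] for j in keeps]
        U = U[:, keeps] if keeps else None

    structure = _make_structure(stage, pred_names, per_wave_resid)
    blocks = _Blocks(scores, times, U)
    _check_identifiable(blocks, structure)

    if phi0 is not None:
        phi0 = np.asarray(phi0, float)
        if phi0.size != structure["n_var"] + structure["n_resid"]:
            raise ValueError("phi0 has the wrong length for this stage")
    else:
        # moment-based start: residual variance from the raw score spread
        all_scores = np.asarray(scores, float)
        svar = max(np.nanvar(all_scores), 1e-4)
        start = []
        if structure["n_var"] == 1:
            start.append(0.5 * np.log(0.5 * svar))
        elif structure["n_var"] == 3:
            start += [0.5 * np.log(0.5 * svar), 0.0, 0.5 * np.log(1e-4 * svar)]
        start += [np.log(0.5 * svar)] * structure["n_resid"]
        phi0 = np.array(start)

    def objective(phi):
        out = _profiled(phi, blocks, structure)
        if out is None:
            return 1e12
        return out[0]

    if phi0.size:
        # bounds keep log-variances and the covariance entry in a range
        # where the marginal covariance stays numerically regular
        bounds = [(-15.0, 15.0)] * structure["n_var"]
        if structure["n_var"] == 3:
            bounds[1] = (-50.0, 50.0)  # raw Cholesky off-diagonal
        bounds += [(-15.0, 15.0)] * structure["n_resid"]
        opt = optimize.minimize(objective, phi0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-13})
        phi = opt.x
        converged = bool(opt.fun < 1e11)
    else:
        phi = phi0
        converged = True
    nll, beta, A = _profiled(phi, blocks, structure)
    G, resid = structure["unpack"](phi)

    theta = np.concatenate([beta, phi])
    se = np.full(beta.size, np.nan)
    if se_method == "hessian":
        H = _numerical_hessian(lambda th: _full_nll(th, blocks, structure), theta)
        try:
            cov = np.linalg.inv(H)
            dvar = np.diag(cov)[:beta.size]
            if np.all(dvar > 0):
                se = np.sqrt(dvar)
            else:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            se = np.sqrt(np.diag(np.linalg.inv(A)))
            flags.append("se_from_gls")
    else:
        se = np.sqrt(np.diag(np.linalg.inv(A)))

    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    # random-effect variance estimated at (numerically) zero sits on the
    # parameter boundary; flag for the mixture-chi-square caveat
    active = np.diag(G)[:1] if structure["n_var"] == 1 else np.diag(G)
    boundary = structure["n_var"] > 0 and bool(np.any(active < 1e-8))
    return GrowthFit(
        stage=stage, labels=structure["labels"], beta=beta, se=se, z=z,
        p=pvals, G=G, resid=resid, logL=-float(nll), k=structure["k"],
        n=blocks.n, converged=converged, boundary=bool(boundary), flags=flags,
        phi=phi.copy())


# ---------------------------------------------------------------------------
# model-building ladder


@dataclass(frozen=True)
class LadderStage:
    stage: str
    fit: GrowthFit
    delta_chi2: float | None
    delta_df: int | None
    p: float | None
    boundary_caveat: bool


def model_building_ladder(scores, times, per_wave_resid: bool = True
                          ) -> list[LadderStage]:
    """Fit the five nested stages in order with chi-square difference
    tests; variance-addition steps carry a boundary (mixture chi-square)
    caveat flag rather than an adjusted p-value."""
    out = []
    prev: GrowthFit | None = None
    boundary_steps = {"random_intercept", "random_slope"}
    for stage in STAGES:
        try:
            # GLS standard errors suffice here: the ladder decisions use
            # only log-likelihoods, not the Wald inference
            fit = fit_growth(scores, times, stage=stage,
                             per_wave_resid=per_wave_resid,
                             se_method="gls")
        except ValueError:
            if stage in ("null", "random_intercept"):
                raise
            # slope stages unidentified: stop the ladder here
            break
        if prev is None:
            out.append(LadderStage(stage, fit, None, None, None, False))
        else:
            delta = max(0.0, 2.0 * (fit.logL - prev.logL))
            ddf = fit.k - prev.k
            p = float(stats.chi2.sf(delta, ddf)) if ddf > 0 else 1.0
            out.append(LadderStage(stage, fit, delta, ddf, p,
                                   stage in boundary_steps))
        prev = fit
    return out


# ---------------------------------------------------------------------------
# conditional and stratified models


@dataclass
class ConditionalGrowthFit:
    risk_name: str
    fit: GrowthFit

    @property
    def risk_on_intercept(self):
        return self.fit.coef(f"{self.risk_name}_on_intercept")

    @property
    def risk_on_slope(self):
        return self.fit.coef(f"{self.risk_name}_on_slope")

    @property
    def sex_on_intercept(self):
        try:
            return self.fit.coef("sex_on_intercept")
        except ValueError:
            return (np.nan, np.nan, np.nan)

    @property
    def sex_on_slope(self):
        try:
            return self.fit.coef("sex_on_slope")
        except ValueError:
            return (np.nan, np.nan, np.nan)


def fit_conditional_growth(
    scores,
    times,
    risk: np.ndarray,
    sex: np.ndarray,
    risk_name: str = "risk",
    stage: str = "random_slope",
    phi0: np.ndarray | None = None,
) -> ConditionalGrowthFit:
    """Conditional growth model regressing intercept and slope on a
    risk score and sex; participants with a missing predictor are
    removed (listwise on predictors)."""
    risk = np.asarray(risk, float)
    sex = np.asarray(sex, float)
    keep = ~(np.isnan(risk) | np.isnan(sex))
    fit = fit_growth(np.asarray(scores, float)[keep],
                     np.asarray(times, float)[keep],
                     stage=stage,
                     predictors={risk_name: risk[keep], "sex": sex[keep]},
                     phi0=phi0)
    return ConditionalGrowthFit(risk_name=risk_name, fit=fit)


@dataclass
class ModerationTable:
    """Per-stratum conditional fits plus combined model-level fit
    statistics, one printed-table row group per stratum."""

    risk_name: str
    strata: dict[str, ConditionalGrowthFit]
    logL: float
    k: int
    n_total: int

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.logL

    @property
    def aic(self) -> float:
        return information_criteria(self.logL, self.k, self.n_total)[1]

    @property
    def bic(self) -> float:
        return information_criteria(self.logL, self.k, self.n_total)[2]

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, cond in self.strata.items():
            b, se, p = cond.risk_on_intercept
            bs, ses, ps = cond.risk_on_slope
            xb, xse, xp = cond.sex_on_intercept
            xbs, xses, xps = cond.sex_on_slope
            rows.append({
                "stratum": name, "risk_score": self.risk_name,
                "n": cond.fit.n,
                "intercept_beta": b, "intercept_se": se, "intercept_p": p,
                "slope_beta": bs, "slope_se": ses, "slope_p": ps,
                "sex_intercept_beta": xb, "sex_intercept_se": xse,
                "sex_intercept_p": xp,
                "sex_slope_beta": xbs, "sex_slope_se": xses,
                "sex_slope_p": xps,
                "H0": self.logL, "free_parameters": self.k,
                "minus2LL": self.minus2ll, "AIC": self.aic, "BIC": self.bic,
                "flags": ";".join(cond.fit.flags),
            })
        return pd.DataFrame(rows)


def fit_stratified(
    scores,
    times,
    risk: np.ndarray,
    sex: np.ndarray,
    strata: np.ndarray,
    risk_name: str = "risk",
    min_stratum_n: int = 15,
) -> ModerationTable:
    """Multiple-group conditional growth model: every parameter is
    stratum-specific (separate fits), combined into a single model-level
    log-likelihood, parameter count and AIC/BIC on the total n."""
    strata = np.asarray(strata)
    labels = [s for s in pd_unique(strata) if s == s and s is not None]
    if len(labels) < 1:
        raise ValueError("no strata labels provided")
    fits: dict[str, ConditionalGrowthFit] = {}
    logL, k, n_total = 0.0, 0, 0
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    risk = np.asarray(risk, float)
    sex = np.asarray(sex, float)
    for lab in labels:
        mask = strata == lab
        cond = fit_conditional_growth(scores[mask], times[mask], risk[mask],
                                      sex[mask], risk_name=risk_name)
        if cond.fit.n < min_stratum_n:
            cond.fit.flags.append(f"low_n:{cond.fit.n}")
        fits[str(lab)] = cond
        logL += cond.fit.logL
        k += cond.fit.k
        n_total += cond.fit.n
    return ModerationTable(risk_name=risk_name, strata=fits, logL=logL,
                           k=k, n_total=n_total)


def pd_unique(values):
    """Order-preserving unique (first-appearance order)."""
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out
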