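"""Synthetic longitudinal cohort: container, generator and CSV round-trip.

The generator emulates an accelerated longitudinal design: participants
enter at uniformly distributed baseline ages (53-85 by default), are
seen for up to three waves roughly 4.4/4.5 years apart, and drop out
monotonically with configurable missing-at-random attrition. Executive
function is generated from a random-intercept/random-slope process on
age centred at 75, shifted by a realised modifiable risk score and sex,
and observed through four test indicators with measurement noise.
Indicators are oriented so that higher = better EF throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import risk as risk_mod
from .config import EF_INDICATORS, GeneratorConfig, TrueParameters
from .genetics import classify_apoe, ApoeGroup

__all__ = [
    "LongitudinalCohort",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "ef_indicator_columns",
]

WAVES = (1, 2, 3)
INDICATOR_ORDER = ("pp", "bmi", "grip", "act_phys", "act_soc",
                   "act_integ", "act_novel", "edu_years", "mmse")
FLAG_COLUMNS = ("antipsychotic_med", "uncontrolled_htn",
                "insulin_diabetes", "head_injury")

MANDATORY_COLUMNS = (
    ("id", "sex")
    + tuple(f"age_w{w}" for w in WAVES)
    + tuple(f"{ind}_w{w}" for w in WAVES for ind in EF_INDICATORS)
    + ("pp", "grip", "bmi", "act_phys", "act_soc", "act_integ", "act_novel",
       "edu_years", "apoe", "clu", "cr1", "picalm")
)
OPTIONAL_COLUMNS = ("mmse", "wave3_opportunity") + FLAG_COLUMNS


def ef_indicator_columns() -> list[str]:
    """Observed-variable order used by the measurement model: wave-major
    blocks of the four tests (stroop_w1 ... ctrails_w3)."""
    return [f"{ind}_w{w}" for w in WAVES for ind in EF_INDICATORS]


@dataclass(frozen=True)
class LongitudinalCohort:
    """Wide per-participant table of a three-wave cohort.

    One row per participant; EF indicator and age cells are NaN at
    attrited waves. Construction validates the schema, uniqueness of
    ids, strictly increasing observed ages and finiteness of observed
    EF values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table lacks mandatory column(s) {missing}")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate participant id {dup!r}")
        ages = df[[f"age_w{w}" for w in WAVES]].to_numpy(dtype=float)
        diffs = np.diff(ages, axis=1)
        bad = np.where(np.nan_to_num(diffs, nan=1.0) <= 0)[0]
        if bad.size:
            raise ValueError(
                f"wave ages not strictly increasing for row {int(bad[0])} "
                f"(id {df['id'].iloc[int(bad[0])]!r})")
        ef = df[ef_indicator_columns()].to_numpy(dtype=float)
        if np.isinf(ef).any():
            raise ValueError("observed EF values must be finite")

    def __len__(self) -> int:
        return len(self.data)

    def ef_matrix(self) -> np.ndarray:
        """(n, 12) array of EF indicators, wave-major, NaN = missing."""
        return self.data[ef_indicator_columns()].to_numpy(dtype=float)

    def ages(self) -> np.ndarray:
        """(n, 3) array of per-wave ages, NaN at attrited waves."""
        return self.data[[f"age_w{w}" for w in WAVES]].to_numpy(dtype=float)

    def wave_n(self) -> tuple[int, int, int]:
        ef = self.ef_matrix()
        return tuple(int(np.any(~np.isnan(ef[:, 4 * w:4 * w + 4]), axis=1).sum())
                     for w in range(3))  # type: ignore[return-value]


def _solve_e4_freq(target_carrier: float, e2: float) -> float:
    """Risk-allele frequency q such that, conditional on not being an
    e2/e4 heterozygote, the e4-carrier proportion equals the target."""

    def gap(q: float) -> float:
        carrier = 1.0 - (1.0 - q) ** 2
        e2e4 = 2.0 * e2 * q
        return (carrier - e2e4) / (1.0 - e2e4) - target_carrier

    return brentq(gap, 1e-6, 0.9)


def _calibrated_bernoulli(rng, lin: np.ndarray, target: float) -> np.ndarray:
    """Draw indicators with per-person P = sigmoid(a + lin), with the
    offset a solved so that the mean probability equals ``target``."""
    if target >= 1.0:
        return np.ones(lin.size, dtype=bool)
    if target <= 0.0:
        return np.zeros(lin.size, dtype=bool)
    lin = np.nan_to_num(lin, nan=0.0)

    def gap(a: float) -> float:
        return expit(a + lin).mean() - target

    a = brentq(gap, -30.0, 30.0)
    return rng.random(lin.size) < expit(a + lin)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x)
    if sd == 0 or np.isnan(sd):
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


def generate_cohort(config: GeneratorConfig,
                    truth: TrueParameters | None = None,
                    return_latent: bool = False):
    """Draw one seeded synthetic cohort.

    Identical ``config`` + ``truth`` always produce an identical cohort.
    With ``return_latent=True`` also returns a dict of the underlying
    latent quantities (per-person intercept/slope, per-wave latent EF,
    centred risk) for oracle tests.
    """
    truth = truth or TrueParameters()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    sex = (rng.random(n) < config.prop_female).astype(int)  # female = 1

    lo, hi = config.baseline_age_range
    age1 = rng.uniform(lo, hi, size=n)
    gaps = np.column_stack([
        np.clip(rng.normal(m, config.wave_interval_sd, size=n), 1.0, None)
        for m in config.wave_interval_means])
    ages = np.column_stack([age1, age1 + gaps[:, 0], age1 + gaps[:, 0] + gaps[:, 1]])

    # --- genotypes -------------------------------------------------------
    e2 = config.apoe_e2_freq
    e4 = _solve_e4_freq(config.apoe_e4_prop, e2)
    apoe_alleles = rng.choice(["e2", "e3", "e4"], p=[e2, 1 - e2 - e4, e4],
                              size=(n, 2))
    apoe = np.array(["/".join(sorted(pair)) for pair in apoe_alleles])

    snp_letters = {"clu": ("C", "T"), "cr1": ("A", "G"), "picalm": ("T", "C")}
    snp_calls: dict[str, np.ndarray] = {}
    for snp, (risk_allele, other) in snp_letters.items():
        f = config.allele_freqs[snp]
        draws = rng.random((n, 2)) < f
        calls = []
        for has_risk in draws:
            alleles = sorted(risk_allele if r else other for r in has_risk)
            calls.append("/".join(alleles))
        snp_calls[snp] = np.array(calls)

    apoe_group = np.array([classify_apoe(a).value for a in apoe])
    # e2/e4 carriers (later excluded) draw indicators from the e4+ stratum
    gen_stratum = np.where(apoe_group == ApoeGroup.E4_MINUS.value,
                           "e4_minus", "e4_plus")

    # --- baseline risk indicators ---------------------------------------
    if config.indicator_corr is not None:
        corr = np.asarray(config.indicator_corr, dtype=float)
        if corr.shape != (len(INDICATOR_ORDER), len(INDICATOR_ORDER)):
            raise ValueError("indicator_corr must be 9x9 over "
                             f"{INDICATOR_ORDER}")
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((n, len(INDICATOR_ORDER))) @ chol.T
    else:
        z = rng.standard_normal((n, len(INDICATOR_ORDER)))
    indicators = {}
    for j, name in enumerate(INDICATOR_ORDER):
        vals = np.empty(n)
        for stratum in ("e4_minus", "e4_plus"):
            mean, sd = config.indicator_means_sds[stratum][name]
            mask = gen_stratum == stratum
            vals[mask] = mean + sd * z[mask, j]
        indicators[name] = vals
    indicators["edu_years"] = np.clip(np.round(indicators["edu_years"]), 0, 25)
    indicators["mmse"] = np.clip(np.round(indicators["mmse"]), 10, 30)
    indicators["grip"] = np.clip(indicators["grip"], 1.0, None)
    indicators["bmi"] = np.clip(indicators["bmi"], 13.0, None)
    indicators["pp"] = np.clip(indicators["pp"], 10.0, None)
    for act in ("act_phys", "act_soc", "act_integ", "act_novel"):
        indicators[act] = np.clip(indicators[act], 0.0, None)

    flags = {name: rng.random(n) < rate
             for name, rate in config.exclusion_rates.items()}

    # --- realised risk score carrying the planted effect ----------------
    base = pd.DataFrame({"id": np.arange(n), "apoe_group": gen_stratum,
                         **{k: indicators[k] for k in INDICATOR_ORDER}})
    try:
        scored = risk_mod.score_cohort(base, stratifier="apoe_group")
    except ValueError:
        # a tiny cohort can leave a stratum with <2 members; fall back to
        # pooled cutoffs so generation still succeeds
        base["_pooled"] = "all"
        scored = risk_mod.score_cohort(base, stratifier="_pooled")
    risk_values = scored[truth.risk_variable].to_numpy(dtype=float)
    centre = np.nanmean(risk_values) if np.isfinite(risk_values).any() else 0.0
    risk_centred = np.nan_to_num(risk_values - centre, nan=0.0)

    # --- latent growth process ------------------------------------------
    g_chol = np.linalg.cholesky(
        truth.growth_cov_array + 1e-12 * np.eye(2))
    rand_eff = rng.standard_normal((n, 2)) @ g_chol.T
    intercept = (truth.growth_means[0]
                 + truth.beta_risk_on_intercept * risk_centred
                 + truth.beta_sex_on_intercept * sex + rand_eff[:, 0])
    slope = (truth.growth_means[1]
             + truth.beta_risk_on_slope * risk_centred
             + truth.beta_sex_on_slope * sex + rand_eff[:, 1])
    t = ages - 75.0
    zeta = rng.standard_normal((n, 3)) * np.sqrt(
        np.asarray(truth.ef_residual_variance))
    eta = intercept[:, None] + slope[:, None] * t + zeta

    # --- measurement layer ----------------------------------------------
    lam = np.asarray(truth.loadings)
    tau = np.asarray(truth.indicator_intercepts)  # (3, 4)
    theta = np.asarray(truth.residual_variances)  # (3, 4)
    rho = truth.residual_cross_corr
    ef_values = np.empty((n, 3, 4))
    for j in range(4):
        sds = np.sqrt(theta[:, j])
        cov = np.outer(sds, sds) * (np.full((3, 3), rho) + (1 - rho) * np.eye(3))
        eps = rng.standard_normal((n, 3)) @ np.linalg.cholesky(cov).T
        ef_values[:, :, j] = tau[None, :, j] + lam[j] * eta + eps

    # --- attrition -------------------------------------------------------
    mech = config.attrition_mechanism
    observed = np.ones((n, 3), dtype=bool)

    def mar_predictor(wave: int) -> np.ndarray:
        # depends only on *observed* previous-wave data (and age): MAR
        z_age = _zscore(ages[:, wave])
        prev = ef_values[:, wave - 1, :]
        prev_std = np.column_stack([_zscore(prev[:, j]) for j in range(4)])
        z_ef = prev_std.mean(axis=1)
        if mech == "MCAR":
            return np.zeros(n)
        if mech == "MAR_on_age":
            return config.attrition_age_weight * z_age
        if mech == "MAR_on_EF":
            return config.attrition_ef_weight * z_ef
        return config.attrition_age_weight * z_age + config.attrition_ef_weight * z_ef

    observed[:, 1] = _calibrated_bernoulli(rng, mar_predictor(1),
                                           config.retention[0])
    # third wave: an opportunity subset of wave-2 completers, retained at
    # the opportunity-adjusted rate so the marginal rate matches config
    w2 = observed[:, 1]
    opp_frac = (config.retention[1] / config.wave3_opportunity_retention
                if config.wave3_opportunity_retention > 0 else 0.0)
    opportunity = np.zeros(n, dtype=bool)
    opportunity[w2] = rng.random(int(w2.sum())) < opp_frac
    observed[:, 2] = False
    if opportunity.any():
        lin = mar_predictor(2)[opportunity]
        observed[opportunity, 2] = _calibrated_bernoulli(
            rng, lin, config.wave3_opportunity_retention)
    observed[:, 2] &= w2  # monotone by construction

    ef_values[~observed] = np.nan
    ages_out = ages.copy()
    ages_out[~observed] = np.nan

    # --- assemble --------------------------------------------------------
    data = {"id": np.arange(n), "sex": sex}
    for w in range(3):
        data[f"age_w{w + 1}"] = ages_out[:, w]
    for w in range(3):
        for j, ind in enumerate(EF_INDICATORS):
            data[f"{ind}_w{w + 1}"] = ef_values[:, w, j]
    for name in INDICATOR_ORDER:
        data[name] = indicators[name]
    data["apoe"] = apoe
    for snp in ("clu", "cr1", "picalm"):
        data[snp] = snp_calls[snp]
    for name in FLAG_COLUMNS:
        data[name] = flags.get(name, np.zeros(n, dtype=bool)).astype(int)
    data["wave3_opportunity"] = opportunity.astype(int)

    df = pd.DataFrame(data)
    # MCAR item nonresponse on baseline predictors (post truth injection)
    if config.predictor_missing_rate > 0:
        for col in ("pp", "bmi", "grip", "act_phys", "act_soc",
                    "act_integ", "act_novel", "edu_years"):
            blank = rng.random(n) < config.predictor_missing_rate
            df.loc[blank, col] = np.nan
    cohort = LongitudinalCohort(df)
    if return_latent:
        latent = {"intercept": intercept, "slope": slope, "eta": eta,
                  "risk_values": risk_values, "risk_centred": risk_centred,
                  "observed": observed}
        return cohort, latent
    return cohort


def write_cohort(cohort: LongitudinalCohort, path) -> None:
    """Write the wide CSV dialect (missing values as empty cells)."""
    cohort.data.to_csv(path, index=False)


def read_cohort(path) -> LongitudinalCohort:
    """Read a wide-format cohort CSV, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks column(s) {missing}")
    return LongitudinalCohort(df)
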