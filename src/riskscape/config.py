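"""Configuration objects for the synthetic cohort generator.

``GeneratorConfig`` holds the study-design quantities (sample size, age
band, wave spacing, retention, sex split, genotype frequencies, baseline
indicator moments); ``TrueParameters`` holds the data-generating
measurement and growth parameters whose recovery the test suite checks.
Both load from YAML/JSON mappings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

__all__ = ["GeneratorConfig", "TrueParameters", "load_config"]

EF_INDICATORS = ("stroop", "hayling", "brixton", "ctrails")

#: baseline indicator (mean, sd) per APOE stratum; grip and the four
#: activity scales are the ones later dichotomised at the stratum mean.
DEFAULT_INDICATOR_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "e4_minus": {
        "pp": (51.56, 10.13),
        "bmi": (27.10, 4.38),
        "grip": (29.21, 9.53),
        "act_phys": (15.58, 5.19),
        "act_soc": (22.76, 6.61),
        "act_integ": (18.73, 8.87),
        "act_novel": (74.65, 17.27),
        "edu_years": (15.19, 2.97),
        "mmse": (28.66, 1.24),
    },
    "e4_plus": {
        "pp": (51.61, 9.52),
        "bmi": (26.61, 3.74),
        "grip": (29.82, 9.01),
        "act_phys": (16.13, 5.15),
        "act_soc": (21.85, 7.16),
        "act_integ": (20.20, 9.25),
        "act_novel": (76.78, 15.63),
        "edu_years": (15.55, 3.07),
        "mmse": (28.68, 1.25),
    },
}

#: per-SNP risk-allele frequencies implied by the printed genotype
#: counts (CR1, PICALM) and typical population frequency (CLU C allele).
DEFAULT_ALLELE_FREQS = {"clu": 0.62, "cr1": 0.398, "picalm": 0.575}

#: rates at which health-history exclusion violators are planted, so the
#: exclusion filter has something to remove (roughly the printed counts
#: relative to the pre-exclusion sample).
DEFAULT_EXCLUSION_RATES = {
    "antipsychotic_med": 0.006,
    "uncontrolled_htn": 0.0015,
    "insulin_diabetes": 0.006,
    "head_injury": 0.012,
}

ATTRITION_MECHANISMS = ("MCAR", "MAR_on_age", "MAR_on_EF", "MAR_age_ef")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for one synthetic cohort draw."""

    n_participants: int = 602
    seed: int = 0
    baseline_age_range: tuple[float, float] = (53.0, 85.0)
    wave_interval_means: tuple[float, float] = (4.4, 4.5)
    wave_interval_sd: float = 0.5
    #: wave1->2 and wave2->3 marginal retention proportions
    retention: tuple[float, float] = (0.81, 0.56)
    #: wave2->3 retention among participants with a third-wave
    #: opportunity; the opportunity fraction is retention[1] / this.
    wave3_opportunity_retention: float = 0.88
    prop_female: float = 0.66
    allele_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALLELE_FREQS))
    apoe_e4_prop: float = 149 / 602
    apoe_e2_freq: float = 0.08
    indicator_means_sds: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INDICATOR_MOMENTS.items()})
    #: optional correlation matrix across the 9 numeric baseline
    #: indicators (order: pp, bmi, grip, act_phys, act_soc, act_integ,
    #: act_novel, edu_years, mmse); None = independent draws.
    indicator_corr: tuple[tuple[float, ...], ...] | None = None
    attrition_mechanism: str = "MAR_age_ef"
    #: logit weights (per SD) for the missingness model
    attrition_age_weight: float = -0.5
    attrition_ef_weight: float = 0.5
    #: MCAR blanking rate applied to baseline predictor columns
    predictor_missing_rate: float = 0.02
    exclusion_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_RATES))

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        lo, hi = self.baseline_age_range
        if not (53.0 <= lo < hi <= 95.0):
            raise ValueError("baseline age range must lie within [53, 95]")
        for name, p in [
            ("retention[0]", self.retention[0]),
            ("retention[1]", self.retention[1]),
            ("wave3_opportunity_retention", self.wave3_opportunity_retention),
            ("prop_female", self.prop_female),
            ("apoe_e4_prop", self.apoe_e4_prop),
            ("apoe_e2_freq", self.apoe_e2_freq),
            ("predictor_missing_rate", self.predictor_missing_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1]")
        for snp, f in self.allele_freqs.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"allele frequency for {snp} must be in (0, 1)")
        if self.attrition_mechanism not in ATTRITION_MECHANISMS:
            raise ValueError(
                f"attrition_mechanism must be one of {ATTRITION_MECHANISMS}")
        if self.retention[1] > self.wave3_opportunity_retention:
            raise ValueError(
                "marginal wave-3 retention cannot exceed the opportunity-"
                "adjusted retention")


@dataclass(frozen=True)
class TrueParameters:
    """Data-generating measurement and growth parameters.

    The latent executive-function (EF) process is linear in age centred
    at 75: eta_iw = I_i + S_i * (age_iw - 75) + zeta_w, with person
    (I_i, S_i) bivariate normal around means shifted by the centred risk
    score and sex (female = 1). Indicators are generated already
    oriented so that higher = better EF, and are
    x_ij = tau_wj + lambda_j * eta_iw + eps (first loading 1, marker).
    """

    loadings: tuple[float, ...] = (1.0, 0.9, 0.8, 0.9)
    #: per wave, per indicator
    indicator_intercepts: tuple[tuple[float, ...], ...] = (
        (0.0, 0.2, -0.1, 0.1),) * 3
    residual_variances: tuple[tuple[float, ...], ...] = ((0.2,) * 4,) * 3
    #: correlation of the same indicator's residual across waves
    residual_cross_corr: float = 0.3
    growth_means: tuple[float, float] = (0.0, -0.02)
    growth_covariance: tuple[tuple[float, float], tuple[float, float]] = (
        (0.35, -0.005), (-0.005, 0.0016))
    ef_residual_variance: tuple[float, ...] = (0.10, 0.10, 0.10)
    beta_risk_on_intercept: float = -0.161
    beta_risk_on_slope: float = -0.007
    beta_sex_on_intercept: float = 0.275
    beta_sex_on_slope: float = 0.015
    #: which computed risk score carries the planted effect
    risk_variable: str = "mcrs"

    def __post_init__(self) -> None:
        if len(self.loadings) != 4:
            raise ValueError("exactly four indicator loadings required")
        for w, (taus, thetas) in enumerate(
                zip(self.indicator_intercepts, self.residual_variances)):
            if len(taus) != 4 or len(thetas) != 4:
                raise ValueError(f"wave {w + 1} needs 4 intercepts and 4 residuals")
            if min(thetas) <= 0:
                raise ValueError("residual variances must be positive")
        if min(self.ef_residual_variance) < 0:
            raise ValueError("EF wave residual variances must be >= 0")
        g = np.asarray(self.growth_covariance, dtype=float)
        if g.shape != (2, 2) or abs(g[0, 1] - g[1, 0]) > 1e-12:
            raise ValueError("growth covariance must be symmetric 2x2")
        eig = np.linalg.eigvalsh(g)
        if eig.min() < -1e-10:
            raise ValueError(
                f"growth covariance is not positive semi-definite (eigenvalues {eig})")
        if not -1.0 < self.residual_cross_corr < 1.0:
            raise ValueError("residual_cross_corr must be in (-1, 1)")

    @property
    def growth_cov_array(self) -> np.ndarray:
        return np.asarray(self.growth_covariance, dtype=float)


def _coerce(mapping: Mapping, cls):
    known = set(cls.__dataclass_fields__)
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")

    def fix(v):
        if isinstance(v, list):
            return tuple(fix(x) for x in v)
        return v

    return cls(**{k: fix(v) for k, v in mapping.items()})


def load_config(path) -> tuple[GeneratorConfig, TrueParameters]:
    """Read a YAML/JSON file with ``generator:`` and ``truth:`` sections.

    YAML is a superset of JSON, so both serialisations parse here. The
    generator section must carry a seed for pipeline runs.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    gen = _coerce(raw.get("generator", {}), GeneratorConfig)
    truth = _coerce(raw.get("truth", {}), TrueParameters)
    return gen, truth


def dump_config(config: GeneratorConfig, truth: TrueParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"generator": asdict(config), "truth": asdict(truth)}, fh)
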