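"""Modifiable risk scores: functional-health, lifestyle-reserve, M-CRS.

Each indicator is banded into an integer weight (0 = lowest risk). Three
functional-health indicators (pulse pressure, grip strength, BMI) sum to
a 0-5 functional-health risk score (FRS); four lifestyle-activity
frequencies plus education sum to a 0-6 lifestyle-reserve risk score
(LRS); their sum is the 0-11 modifiable-composite risk score (M-CRS).

Grip strength and the four activity scores are dichotomised at the
baseline mean of the participant's APOE stratum (value >= stratum mean
counts as "strong"/"high", i.e. weight 0); pulse pressure, BMI and
education use fixed bands.

Boundary conventions (the published bands abut):
pulse pressure [0,52) -> 0, [52,72] -> 1, (72,inf) -> 2;
BMI [18.5,25) -> 0, (0,18.5) or [25,30] -> 1, (30,inf) -> 2;
education > 11 years -> 0, [8,11] -> 1, < 8 -> 2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "ACTIVITY_INDICATORS",
    "STRATIFIED_INDICATORS",
    "RiskWeightTable",
    "StratifiedCutoffs",
    "RiskScores",
    "categorize_indicator",
    "compute_stratified_cutoffs",
    "functional_health_score",
    "lifestyle_reserve_score",
    "combined_mcrs",
    "score_cohort",
]

ACTIVITY_INDICATORS = ("act_phys", "act_soc", "act_integ", "act_novel")
#: indicators dichotomised at the APOE-stratum baseline mean
STRATIFIED_INDICATORS = ("grip",) + ACTIVITY_INDICATORS

FRS_INDICATORS = ("pp", "grip", "bmi")
LRS_INDICATORS = ACTIVITY_INDICATORS + ("education",)


@dataclass(frozen=True)
class RiskWeightTable:
    """Thresholds for the fixed-band indicators.

    The defaults reproduce the published weighting scheme; alternative
    thresholds can be loaded from a JSON/YAML mapping for audit runs.

    * ``pp_moderate``/``pp_high``: pulse pressure < moderate -> 0,
      moderate..high (inclusive) -> 1, > high -> 2 (mm Hg).
    * ``bmi_normal``: [low, high) -> 0; ``bmi_obese``: > obese -> 2;
      anything else (underweight or overweight) -> 1 (kg/m^2).
    * ``edu_low``/``edu_high``: > high -> 0, low..high -> 1, < low -> 2
      (completed years).
    """

    pp_moderate: float = 52.0
    pp_high: float = 72.0
    bmi_normal: tuple[float, float] = (18.5, 25.0)
    bmi_obese: float = 30.0
    edu_low: float = 8.0
    edu_high: float = 11.0

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RiskWeightTable":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        kwargs = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in mapping.items() if k in known}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown risk-weight keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "pp_moderate": self.pp_moderate,
                "pp_high": self.pp_high,
                "bmi_normal": self.bmi_normal,
                "bmi_obese": self.bmi_obese,
                "edu_low": self.edu_low,
                "edu_high": self.edu_high,
            }
        )


@dataclass(frozen=True)
class StratifiedCutoffs:
    """Per-stratum baseline means used to dichotomise grip/activities.

    ``means[stratum][indicator]`` is the arithmetic mean of observed
    baseline values in that APOE stratum.
    """

    means: Mapping[str, Mapping[str, float]]

    def cutoff(self, indicator: str, stratum: str) -> float:
        try:
            by_ind = self.means[str(stratum)]
        except KeyError:
            raise KeyError(f"no cutoffs for stratum {stratum!r}") from None
        try:
            return float(by_ind[indicator])
        except KeyError:
            raise KeyError(f"no cutoff for indicator {indicator!r}") from None


@dataclass(frozen=True)
class RiskScores:
    """Scores plus the per-indicator weights that produced them."""

    frs: int | None
    lrs: int | None
    mcrs: int | None
    component_weights: dict = field(default_factory=dict)


def categorize_indicator(
    indicator: str,
    value: float | None,
    cutoffs: StratifiedCutoffs | None = None,
    stratum: str | None = None,
    weights: RiskWeightTable | None = None,
) -> int | None:
    """Integer risk weight for one indicator value; None when missing.

    ``indicator`` is one of ``pp``, ``bmi``, ``education``, ``grip`` or
    an activity name; the last five require ``cutoffs`` and ``stratum``.
    """
    w = weights or RiskWeightTable()
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"non-finite {indicator} value {value}")
    if indicator == "pp":
        if value < w.pp_moderate:
            return 0
        return 1 if value <= w.pp_high else 2
    if indicator == "bmi":
        if w.bmi_normal[0] <= value < w.bmi_normal[1]:
            return 0
        return 2 if value > w.bmi_obese else 1
    if indicator == "education":
        if value > w.edu_high:
            return 0
        return 1 if value >= w.edu_low else 2
    if indicator in STRATIFIED_INDICATORS:
        if cutoffs is None or stratum is None:
            raise ValueError(f"{indicator} requires stratified cutoffs and a stratum")
        return 0 if value >= cutoffs.cutoff(indicator, stratum) else 1
    raise ValueError(f"unknown risk indicator {indicator!r}")


def compute_stratified_cutoffs(
    frame: pd.DataFrame,
    stratifier: str = "apoe_group",
    indicators: tuple[str, ...] = STRATIFIED_INDICATORS,
) -> StratifiedCutoffs:
    """Baseline mean of each dichotomised indicator within each stratum.

    ``frame`` is a wide per-participant table carrying the baseline
    indicator columns and a stratum label column.
    """
    means: dict[str, dict[str, float]] = {}
    for stratum, sub in frame.groupby(stratifier, observed=True):
        row = {}
        for ind in indicators:
            observed = sub[ind].dropna()
            if len(observed) < 2:
                raise ValueError(
                    f"stratum {stratum!r} has fewer than 2 observed values for {ind!r}"
                )
            row[ind] = float(observed.mean())
        means[str(stratum)] = row
    if not means:
        raise ValueError("no strata found when computing cutoffs")
    return StratifiedCutoffs(means=means)


def _sum_or_none(parts: list[int | None]) -> int | None:
    if any(p is None for p in parts):
        return None
    return int(sum(parts))  # type: ignore[arg-type]


def functional_health_score(
    pp: float | None,
    grip: float | None,
    bmi: float | None,
    cutoffs: StratifiedCutoffs,
    stratum: str,
    weights: RiskWeightTable | None = None,
) -> RiskScores:
    """0-5 functional-health score; None if any component is missing."""
    w = {
        "pp": categorize_indicator("pp", pp, weights=weights),
        "grip": categorize_indicator("grip", grip, cutoffs, stratum, weights),
        "bmi": categorize_indicator("bmi", bmi, weights=weights),
    }
    return RiskScores(frs=_sum_or_none(list(w.values())), lrs=None, mcrs=None,
                      component_weights=w)


def lifestyle_reserve_score(
    activities: Mapping[str, float | None],
    education: float | None,
    cutoffs: StratifiedCutoffs,
    stratum: str,
    weights: RiskWeightTable | None = None,
) -> RiskScores:
    """0-6 lifestyle-reserve score; None if any component is missing."""
    w: dict[str, int | None] = {}
    for ind in ACTIVITY_INDICATORS:
        w[ind] = categorize_indicator(ind, activities.get(ind), cutoffs, stratum, weights)
    w["education"] = categorize_indicator("education", education, weights=weights)
    return RiskScores(frs=None, lrs=_sum_or_none(list(w.values())), mcrs=None,
                      component_weights=w)


def combined_mcrs(frs: int | None, lrs: int | None) -> int | None:
    """0-11 modifiable-composite score; None if either part is missing."""
    if frs is None or lrs is None:
        return None
    return int(frs) + int(lrs)


def score_cohort(
    frame: pd.DataFrame,
    cutoffs: StratifiedCutoffs | None = None,
    stratifier: str = "apoe_group",
    weights: RiskWeightTable | None = None,
) -> pd.DataFrame:
    """Score every participant in a wide table.

    Returns a copy of ``frame`` with ``frs``, ``lrs``, ``mcrs`` columns
    (nullable integers; missing where any component is unobserved) and
    ``w_<indicator>`` audit columns holding the assigned weights.
    """
    if cutoffs is None:
        cutoffs = compute_stratified_cutoffs(frame, stratifier)
    out = frame.copy()
    frs_col, lrs_col, mcrs_col = [], [], []
    audit: dict[str, list] = {f"w_{ind}": [] for ind in FRS_INDICATORS + LRS_INDICATORS}
    for _, row in frame.iterrows():
        stratum = row[stratifier]
        f = functional_health_score(row.get("pp"), row.get("grip"), row.get("bmi"),
                                    cutoffs, stratum, weights)
        activities = {ind: row.get(ind) for ind in ACTIVITY_INDICATORS}
        l = lifestyle_reserve_score(activities, row.get("edu_years"),
                                    cutoffs, stratum, weights)
        frs_col.append(f.frs)
        lrs_col.append(l.lrs)
        mcrs_col.append(combined_mcrs(f.frs, l.lrs))
        for ind in FRS_INDICATORS:
            audit[f"w_{ind}"].append(f.component_weights[ind])
        for ind in LRS_INDICATORS:
            audit[f"w_{ind}"].append(l.component_weights[ind])
    out["frs"] = pd.array(frs_col, dtype="Int64")
    out["lrs"] = pd.array(lrs_col, dtype="Int64")
    out["mcrs"] = pd.array(mcrs_col, dtype="Int64")
    for col, vals in audit.items():
        out[col] = pd.array(vals, dtype="Int64")
    return out
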