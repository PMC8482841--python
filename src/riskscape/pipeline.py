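"""End-to-end orchestration: simulate -> exclude -> score -> measure -> grow.

``run_pipeline`` sequences the whole analysis on a cohort (generated or
read from CSV): participant exclusions, genetic grouping, modifiable
risk scoring, the EF measurement model with its invariance ladder,
factor scores, the unconditional growth ladder, and the three
moderation analyses — RQ1 (each risk score predicting EF level and
slope), RQ2 (stratified by APOE e4 carrier status) and RQ3 (further
stratified by low/high AD-GRS). All artifacts are written as CSV/JSON
plus a markdown report with a provenance stamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import LongitudinalCohort, generate_cohort, read_cohort, write_cohort
from .config import GeneratorConfig, TrueParameters
from .genetics import GeneticProfile, classify_cohort_genetics
from .growth import (ModerationTable, fit_conditional_growth, fit_stratified,
                     model_building_ladder)
from .measurement import (MeasurementSpec, estimate_factor_scores,
                          factor_scores_frame, fiml_saturated, fit_measurement,
                          invariance_ladder)
from .risk import score_cohort

logger = logging.getLogger("riskscape")

__all__ = [
    "PipelineConfig",
    "RunReport",
    "EXCLUSION_RULES",
    "apply_exclusions",
    "annotate_genetics",
    "describe_cohort",
    "run_pipeline",
]

DESCRIBE_INDICATORS = (
    "age_w1", "edu_years", "act_phys", "act_soc", "act_integ", "act_novel",
    "pp", "bmi", "grip", "mmse",
)

#: exclusion rules: name -> (required column, predicate on the table)
EXCLUSION_RULES = {
    "antipsychotic_med": ("antipsychotic_med", lambda df: df["antipsychotic_med"] == 1),
    "mmse_lt_24": ("mmse", lambda df: df["mmse"] < 24),
    "uncontrolled_htn": ("uncontrolled_htn", lambda df: df["uncontrolled_htn"] == 1),
    "insulin_diabetes": ("insulin_diabetes", lambda df: df["insulin_diabetes"] == 1),
    "head_injury": ("head_injury", lambda df: df["head_injury"] == 1),
    "apoe_e2e4": ("apoe", lambda df: df["apoe_group"] == "excluded_e2e4"),
}


def annotate_genetics(cohort: LongitudinalCohort) -> pd.DataFrame:
    """Cohort table plus apoe_group / adgrs_score / adgrs_group columns."""
    df = cohort.data.copy()
    groups = [classify_cohort_genetics(
        GeneticProfile(r.apoe, r.clu, r.cr1, r.picalm))
        for r in df.itertuples()]
    df["apoe_group"] = [g.apoe_group.value for g in groups]
    df["adgrs_score"] = pd.array(
        [g.adgrs_score for g in groups], dtype="Int64")
    df["adgrs_group"] = [None if g.adgrs_group is None else g.adgrs_group.value
                         for g in groups]
    return df


def apply_exclusions(cohort: LongitudinalCohort,
                     rules: list[str] | None = None
                     ) -> tuple[LongitudinalCohort, dict]:
    """Remove participants failing any active exclusion rule.

    Returns the filtered cohort and a log with per-rule counts (a
    participant failing two rules is removed once but tallied under
    both) and the remaining n.
    """
    if rules is None:
        rules = list(EXCLUSION_RULES)
    df = annotate_genetics(cohort)
    log: dict = {"per_rule": {}, "n_before": len(df)}
    drop = np.zeros(len(df), dtype=bool)
    for name in rules:
        if name not in EXCLUSION_RULES:
            raise ValueError(f"unknown exclusion rule {name!r}")
        col, pred = EXCLUSION_RULES[name]
        if col not in df.columns:
            raise ValueError(f"exclusion rule {name!r} needs column {col!r}")
        mask = pred(df).fillna(False).to_numpy(dtype=bool)
        log["per_rule"][name] = int(mask.sum())
        drop |= mask
    log["n_removed"] = int(drop.sum())
    log["n_after"] = int((~drop).sum())
    kept = cohort.data.loc[~drop].reset_index(drop=True)
    return LongitudinalCohort(kept), log


def describe_cohort(cohort: LongitudinalCohort | pd.DataFrame,
                    strata: str | None = "apoe_group") -> pd.DataFrame:
    """Baseline descriptives by stratum: n, sex counts, mean (SD) per
    indicator. A single-participant stratum reports a blank SD."""
    df = cohort.data if isinstance(cohort, LongitudinalCohort) else cohort
    if strata is not None and strata not in df.columns:
        if isinstance(cohort, LongitudinalCohort):
            df = annotate_genetics(cohort)
        if strata not in df.columns:
            raise ValueError(f"stratum column {strata!r} not present")
    groups = [("all", df)] if strata is None else list(
        df.groupby(strata, observed=True))
    rows = []
    for label, sub in groups:
        row: dict = {"stratum": label, "n": len(sub)}
        if len(sub):
            sex = sub["sex"].to_numpy()
            row["n_male"] = int((sex == 0).sum())
            row["n_female"] = int((sex == 1).sum())
        for ind in DESCRIBE_INDICATORS:
            if ind not in sub.columns:
                continue
            vals = sub[ind].dropna()
            row[f"{ind}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{ind}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one end-to-end run."""

    seed: int = 0
    cohort_path: str | None = None  # read instead of simulate when set
    generator: GeneratorConfig | None = None
    truth: TrueParameters | None = None
    apply_exclusion_rules: bool = True
    analyses: tuple[str, ...] = ("RQ1", "RQ2", "RQ3")
    risk_scores: tuple[str, ...] = ("frs", "lrs", "mcrs")
    centering_age: float = 75.0
    factor_score_method: str = "bartlett"
    min_stratum_n: int = 15
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not self.analyses:
            raise ValueError("at least one analysis (RQ1-RQ3) must be selected")
        bad = set(self.analyses) - {"RQ1", "RQ2", "RQ3"}
        if bad:
            raise ValueError(f"unknown analyses {sorted(bad)}")
        bad = set(self.risk_scores) - {"frs", "lrs", "mcrs"}
        if bad:
            raise ValueError(f"unknown risk scores {sorted(bad)}")

    def content_hash(self) -> str:
        payload = {
            "seed": self.seed, "cohort_path": self.cohort_path,
            "generator": None if self.generator is None else asdict(self.generator),
            "truth": None if self.truth is None else asdict(self.truth),
            "apply_exclusion_rules": self.apply_exclusion_rules,
            "analyses": self.analyses, "risk_scores": self.risk_scores,
            "centering_age": self.centering_age,
            "factor_score_method": self.factor_score_method,
            "min_stratum_n": self.min_stratum_n,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config: PipelineConfig
    cohort: LongitudinalCohort
    exclusion_log: dict
    descriptives: pd.DataFrame
    factor_comparison: dict
    invariance: object
    scores_frame: pd.DataFrame
    growth_ladder: list
    moderation: dict  # {"RQ1": {risk: ConditionalGrowthFit}, "RQ2"/"RQ3": {risk: ModerationTable}}
    provenance: dict = field(default_factory=dict)

    def moderation_frame(self) -> pd.DataFrame:
        rows = []
        for rq, by_risk in self.moderation.items():
            for risk_name, obj in by_risk.items():
                if isinstance(obj, ModerationTable):
                    sub = obj.to_frame()
                else:  # ConditionalGrowthFit (RQ1)
                    tab = ModerationTable(risk_name=risk_name,
                                          strata={"all": obj},
                                          logL=obj.fit.logL, k=obj.fit.k,
                                          n_total=obj.fit.n)
                    sub = tab.to_frame()
                sub.insert(0, "research_question", rq)
                rows.append(sub)
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(self.cohort, out / "cohort.csv")
        self.scores_frame.to_csv(out / "scores.csv", index=False)
        self.descriptives.to_csv(out / "descriptives.csv", index=False)
        self.moderation_frame().to_csv(out / "moderation_table.csv", index=False)
        with open(out / "measurement.json", "w") as fh:
            json.dump({
                "factor_comparison": self.factor_comparison,
                "accepted_level": self.invariance.accepted_level,
                "freed_intercepts": [list(t) for t in self.invariance.freed_intercepts],
                "steps": [{
                    "level": s.level, "logL": s.fit.logL, "k": s.fit.n_params,
                    "converged": s.fit.converged,
                    "delta_chi2": s.delta_chi2, "delta_df": s.delta_df, "p": s.p,
                } for s in self.invariance.steps],
                "accepted_fit": self.invariance.accepted_fit.to_dict(),
            }, fh, indent=1)
        with open(out / "growth.json", "w") as fh:
            json.dump([{
                "stage": s.stage, "logL": s.fit.logL, "k": s.fit.k,
                "converged": s.fit.converged, "delta_chi2": s.delta_chi2,
                "delta_df": s.delta_df, "p": s.p,
                "boundary_caveat": s.boundary_caveat,
                "fit": s.fit.to_dict(),
            } for s in self.growth_ladder], fh, indent=1)
        with open(out / "exclusions.json", "w") as fh:
            json.dump(self.exclusion_log, fh, indent=1)
        with open(out / "report.md", "w") as fh:
            fh.write(self.render_markdown())

    def render_markdown(self) -> str:
        lines = ["# riskscape run report", ""]
        lines.append(f"- config hash: `{self.provenance.get('config_hash')}`")
        lines.append(f"- seed: {self.provenance.get('seed')}")
        lines.append(f"- package version: {self.provenance.get('version')}")
        lines.append("")
        lines.append("## Cohort")
        lines.append(f"- n after exclusions: {self.exclusion_log.get('n_after')}"
                     f" (removed {self.exclusion_log.get('n_removed')})")
        for rule, cnt in self.exclusion_log.get("per_rule", {}).items():
            lines.append(f"  - {rule}: {cnt}")
        lines.append("")
        lines.append("## Measurement")
        fc = self.factor_comparison
        lines.append(f"- one-factor AIC {fc['one_factor_aic']:.1f} vs "
                     f"two-factor AIC {fc['two_factor_aic']:.1f} -> "
                     f"{fc['preferred']} preferred")
        lines.append(f"- invariance accepted: {self.invariance.accepted_level}"
                     f" (freed intercepts: {list(self.invariance.freed_intercepts)})")
        lines.append("")
        lines.append("## Growth ladder")
        for s in self.growth_ladder:
            p = "" if s.p is None else f", p={s.p:.4f}"
            caveat = " [boundary]" if s.boundary_caveat else ""
            lines.append(f"- {s.stage}: logL={s.fit.logL:.3f}, k={s.fit.k}"
                         f"{p}{caveat} conv={s.fit.converged}")
        lines.append("")
        lines.append("## Moderation")
        frame = self.moderation_frame()
        if len(frame):
            lines.append(frame.to_string(index=False,
                                         float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines) + "\n"


def _growth_inputs(df: pd.DataFrame, scores_frame: pd.DataFrame,
                   centering_age: float):
    merged = df.merge(scores_frame, on="id", how="left")
    scores = merged[[f"ef_w{w}" for w in (1, 2, 3)]].to_numpy(dtype=float)
    times = merged[[f"age_w{w}" for w in (1, 2, 3)]].to_numpy(dtype=float) \
        - centering_age
    return merged, scores, times


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis; deterministic for a fixed config."""
    t_start = time.perf_counter()

    def stage_done(name: str, **info) -> None:
        logger.info("stage=%s elapsed=%.1fs %s", name,
                    time.perf_counter() - t_start,
                    " ".join(f"{k}={v}" for k, v in info.items()))

    # ---- cohort ----------------------------------------------------------
    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
    else:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        if gen.seed != config.seed:
            gen = GeneratorConfig(**{**asdict(gen), "seed": config.seed})
        cohort = generate_cohort(gen, config.truth)

    if config.apply_exclusion_rules:
        rules = [r for r in EXCLUSION_RULES
                 if EXCLUSION_RULES[r][0] in cohort.data.columns
                 or r == "apoe_e2e4"]
        cohort, excl_log = apply_exclusions(cohort, rules)
    else:
        excl_log = {"per_rule": {}, "n_before": len(cohort),
                    "n_removed": 0, "n_after": len(cohort)}

    stage_done("cohort", n=len(cohort),
               removed=excl_log.get("n_removed"))

    df = annotate_genetics(cohort)
    descriptives = describe_cohort(df, "apoe_group")

    # ---- risk scores -----------------------------------------------------
    df = score_cohort(df, stratifier="apoe_group")
    stage_done("risk_scores", n_scored=int(df["mcrs"].notna().sum()))

    # ---- measurement -----------------------------------------------------
    Y = cohort.ef_matrix()
    saturated = fiml_saturated(Y)
    one = fit_measurement(Y, MeasurementSpec(1, "configural"),
                          saturated=saturated, seed=config.seed)
    two = fit_measurement(Y, MeasurementSpec(2, "configural"),
                          saturated=saturated, seed=config.seed)
    factor_comparison = {
        "one_factor_aic": one.indices.aic, "two_factor_aic": two.indices.aic,
        "one_factor": one.indices.to_dict(), "two_factor": two.indices.to_dict(),
        "preferred": "one_factor" if one.indices.aic <= two.indices.aic
        else "two_factor",
    }
    invariance = invariance_ladder(Y, n_factors=1, seed=config.seed)
    invariance.accepted_fit.standard_errors(Y)  # into the serialized fit
    scores = estimate_factor_scores(invariance.accepted_fit, Y,
                                    method=config.factor_score_method)
    scores_frame = factor_scores_frame(scores, df["id"])
    stage_done("measurement", level=invariance.accepted_level,
               converged=invariance.accepted_fit.converged)

    merged, score_mat, times = _growth_inputs(df, scores_frame,
                                              config.centering_age)

    # ---- unconditional growth ladder ------------------------------------
    ladder = model_building_ladder(score_mat, times)
    stage_done("growth_ladder",
               final=ladder[-1].stage, converged=ladder[-1].fit.converged)

    # ---- moderation ------------------------------------------------------
    sex = merged["sex"].to_numpy(dtype=float)
    moderation: dict = {}
    for rq in config.analyses:
        moderation[rq] = {}
        for risk_name in config.risk_scores:
            risk = merged[risk_name].to_numpy(dtype=float)
            if rq == "RQ1":
                moderation[rq][risk_name] = fit_conditional_growth(
                    score_mat, times, risk, sex, risk_name=risk_name)
            elif rq == "RQ2":
                strata = merged["apoe_group"].to_numpy()
                moderation[rq][risk_name] = fit_stratified(
                    score_mat, times, risk, sex, strata,
                    risk_name=risk_name, min_stratum_n=config.min_stratum_n)
            else:
                # RQ3: a separate low/high AD-GRS two-group model inside
                # each APOE stratum (each with its own combined logL/k)
                for apoe in ("e4_minus", "e4_plus"):
                    mask = (merged["apoe_group"] == apoe).to_numpy()
                    lab = (apoe + "/" + merged["adgrs_group"].astype(str)
                           ).to_numpy(dtype=object)
                    lab[merged["adgrs_group"].isna().to_numpy()] = None
                    lab[~mask] = None
                    moderation[rq][f"{risk_name}|{apoe}"] = fit_stratified(
                        score_mat, times, risk, sex, strata=lab,
                        risk_name=risk_name,
                        min_stratum_n=config.min_stratum_n)

    stage_done("moderation", analyses=",".join(config.analyses))
    report = RunReport(
        config=config, cohort=cohort, exclusion_log=excl_log,
        descriptives=descriptives, factor_comparison=factor_comparison,
        invariance=invariance, scores_frame=merged,
        growth_ladder=ladder, moderation=moderation,
        provenance={"config_hash": config.content_hash(), "seed": config.seed,
                    "version": __version__},
    )
    return report


def plot_trajectories(report: RunReport, risk_name: str = "mcrs",
                      rq: str = "RQ1", path=None):
    """Predicted EF-versus-age trajectories by risk-score level (and by
    stratum for RQ2/RQ3), colour-graded from low to high risk."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entry = report.moderation[rq][risk_name]
    if hasattr(entry, "strata"):
        panels = list(entry.strata.items())
    else:
        panels = [("all", entry)]
    fig, axes = plt.subplots(1, len(panels), figsize=(5 * len(panels), 4),
                             squeeze=False, sharey=True)
    ages = np.linspace(53, 95, 100)
    t = ages - report.config.centering_age
    cmap = plt.get_cmap("coolwarm")
    levels = np.arange(0, 12 if risk_name == "mcrs" else 7)
    for ax, (label, cond) in zip(axes[0], panels):
        fit = cond.fit
        b0, _, _ = fit.coef("intercept")
        b1, _, _ = fit.coef("slope")
        bri, _, _ = cond.risk_on_intercept
        brs, _, _ = cond.risk_on_slope
        for lev in levels:
            y = (b0 + bri * lev) + (b1 + brs * lev) * t
            ax.plot(ages, y, color=cmap(lev / levels.max()), lw=1.5)
        ax.set_title(f"{risk_name.upper()} | {label}")
        ax.set_xlabel("age (years)")
    axes[0][0].set_ylabel("predicted EF (latent units)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
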