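import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riskscape.risk import (ACTIVITY_INDICATORS, RiskWeightTable,
                            StratifiedCutoffs, categorize_indicator,
                            combined_mcrs, compute_stratified_cutoffs,
                            functional_health_score, lifestyle_reserve_score,
                            score_cohort)

CUTS = StratifiedCutoffs(means={"s": {
    "grip": 30.0, "act_phys": 15.0, "act_soc": 22.0,
    "act_integ": 19.0, "act_novel": 75.0}})


@pytest.mark.parametrize("indicator,value,weight", [
    ("pp", 45, 0), ("pp", 51.9, 0), ("pp", 52, 1), ("pp", 60, 1),
    ("pp", 72, 1), ("pp", 72.1, 2), ("pp", 80, 2),
    ("bmi", 22.0, 0), ("bmi", 18.5, 0), ("bmi", 18.4, 1), ("bmi", 25.0, 1),
    ("bmi", 27, 1), ("bmi", 30.0, 1), ("bmi", 30.1, 2), ("bmi", 32, 2),
    ("education", 12, 0), ("education", 16, 0), ("education", 11, 1),
    ("education", 8, 1), ("education", 10, 1), ("education", 7, 2),
    ("education", 6, 2),
])
def test_fixed_band_weights(indicator, value, weight):
    assert categorize_indicator(indicator, value) == weight


def test_mean_cutoff_boundary_is_low_risk():
    # a value exactly at the stratum mean counts as strong/high (weight 0)
    assert categorize_indicator("grip", 30.0, CUTS, "s") == 0
    assert categorize_indicator("grip", 29.99, CUTS, "s") == 1
    assert categorize_indicator("act_soc", 22.0, CUTS, "s") == 0


def test_missing_value_gives_missing_weight():
    assert categorize_indicator("pp", None) is None
    assert categorize_indicator("grip", float("nan"), CUTS, "s") is None


def test_unknown_indicator_rejected():
    with pytest.raises(ValueError, match="unknown risk indicator"):
        categorize_indicator("smoking", 1.0)


def test_score_range_brute_force():
    """Enumerate representative values in every band of every indicator:
    attainable maxima are exactly 5 (FRS), 6 (LRS), 11 (M-CRS), minima 0."""
    pp_vals, grip_vals, bmi_vals = [45, 60, 80], [35, 25], [22, 27, 32]
    act_vals = {a: [CUTS.cutoff(a, "s") + 1, CUTS.cutoff(a, "s") - 1]
                for a in ACTIVITY_INDICATORS}
    edu_vals = [16, 10, 6]
    frs_all, lrs_all, mcrs_all = [], [], []
    for pp, grip, bmi in itertools.product(pp_vals, grip_vals, bmi_vals):
        frs_all.append(functional_health_score(pp, grip, bmi, CUTS, "s").frs)
    for combo in itertools.product(*(act_vals[a] for a in ACTIVITY_INDICATORS)):
        acts = dict(zip(ACTIVITY_INDICATORS, combo))
        for edu in edu_vals:
            lrs_all.append(
                lifestyle_reserve_score(acts, edu, CUTS, "s").lrs)
    for f in set(frs_all):
        for l in set(lrs_all):
            mcrs_all.append(combined_mcrs(f, l))
    assert (min(frs_all), max(frs_all)) == (0, 5)
    assert (min(lrs_all), max(lrs_all)) == (0, 6)
    assert (min(mcrs_all), max(mcrs_all)) == (0, 11)
    assert set(frs_all) == set(range(6))
    assert set(lrs_all) == set(range(7))


def test_scores_missing_propagation():
    incomplete = functional_health_score(60, None, 27, CUTS, "s")
    assert incomplete.frs is None
    assert combined_mcrs(None, 3) is None
    assert combined_mcrs(2, 3) == 5


def test_stratified_cutoffs_mean_and_errors():
    frame = pd.DataFrame({
        "apoe_group": ["a", "a", "b", "b"],
        "grip": [20.0, 40.0, 10.0, 30.0],
        **{act: [1.0, 3.0, 5.0, 7.0] for act in ACTIVITY_INDICATORS},
    })
    cuts = compute_stratified_cutoffs(frame)
    assert cuts.cutoff("grip", "a") == 30.0
    assert cuts.cutoff("grip", "b") == 20.0
    with pytest.raises(KeyError, match="no cutoffs for stratum"):
        cuts.cutoff("grip", "c")
    with pytest.raises(ValueError, match="fewer than 2"):
        compute_stratified_cutoffs(frame.iloc[:1])


def test_cutoffs_permutation_invariant():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame({
        "apoe_group": rng.choice(["x", "y"], 40),
        "grip": rng.uniform(10, 50, 40),
        **{act: rng.uniform(0, 30, 40) for act in ACTIVITY_INDICATORS},
    })
    shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = compute_stratified_cutoffs(frame)
    b = compute_stratified_cutoffs(shuffled)
    for s in ("x", "y"):
        assert a.cutoff("grip", s) == pytest.approx(b.cutoff("grip", s))


def test_identical_values_classify_everyone_strong():
    frame = pd.DataFrame({
        "apoe_group": ["s"] * 3, "grip": [30.0] * 3,
        **{act: [5.0] * 3 for act in ACTIVITY_INDICATORS},
    })
    cuts = compute_stratified_cutoffs(frame)
    assert categorize_indicator("grip", 30.0, cuts, "s") == 0


@given(st.integers(0, 5), st.integers(0, 6))
@settings(max_examples=30, deadline=None)
def test_mcrs_conservation(frs, lrs):
    assert combined_mcrs(frs, lrs) == frs + lrs


def test_score_cohort_audit_columns_sum(small_complete_cohort):
    from riskscape.pipeline import annotate_genetics

    df = annotate_genetics(small_complete_cohort)
    df.loc[df.apoe_group == "excluded_e2e4", "apoe_group"] = "e4_plus"
    scored = score_cohort(df)
    frs_sum = scored[["w_pp", "w_grip", "w_bmi"]].sum(axis=1)
    lrs_sum = scored[[f"w_{a}" for a in ACTIVITY_INDICATORS]
                     + ["w_education"]].sum(axis=1)
    ok = scored["frs"].notna()
    assert (scored.loc[ok, "frs"] == frs_sum[ok]).all()
    ok = scored["lrs"].notna()
    assert (scored.loc[ok, "lrs"] == lrs_sum[ok]).all()
    ok = scored["mcrs"].notna()
    assert (scored.loc[ok, "mcrs"]
            == scored.loc[ok, "frs"] + scored.loc[ok, "lrs"]).all()
    assert scored["frs"].max() <= 5 and scored["lrs"].max() <= 6
    assert scored["mcrs"].max() <= 11


def test_weight_table_from_mapping_roundtrip():
    table = RiskWeightTable.from_mapping({"pp_moderate": 50.0})
    assert table.pp_moderate == 50.0
    assert categorize_indicator("pp", 51, weights=table) == 1
    with pytest.raises(ValueError, match="unknown risk-weight"):
        RiskWeightTable.from_mapping({"nope": 1})
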