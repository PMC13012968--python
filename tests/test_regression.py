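"""Design coding, logistic fit, separation handling, fit indices."""

import numpy as np
import pandas as pd
import pytest

from pvsignals.errors import DegenerateOutcomeError
from pvsignals.regression import (
    IRAELogit,
    RegressionSpec,
    build_design,
    fit_indices,
    fit_logistic,
)


def _reports(rows):
    return pd.DataFrame(
        rows,
        columns=["report_id", "case_id", "case_version", "receive_date", "database_tag",
                 "sex", "age_group", "weight_group", "reporter_type"],
    )


def test_design_hand_coding():
    reports = _reports([
        ("R1", "C1", 1, "", "FAERS", "female", "65-85", "50-100kg", "MD"),
        ("R2", "C2", 1, "", "FAERS", "male", "18-64", "<50kg", "PH"),
        ("R3", "C3", 1, "", "FAERS", "unknown", "unknown", ">100kg", "OT"),
    ])
    groups = pd.Series(["COMBO", "DRUG_B_MONO", "DRUG_A_MONO"])
    outcome = pd.Series([1, 0, 1])
    design, y = build_design(reports, groups, outcome, RegressionSpec())
    assert design.loc[0, "sex[female]"] == 1 and design.loc[0, "age_band[>=65]"] == 1
    assert design.loc[0, "regimen[COMBO]"] == 1
    assert design.loc[1, "reporter_type[PH]"] == 1 and design.loc[1, "weight_group[<50kg]"] == 1
    # reference levels absorbed: row 2 (male? no - unknown) -> sex[unknown]
    assert design.loc[2, "sex[unknown]"] == 1
    assert (design["const"] == 1).all()
    # DRUG_B_MONO is the reference regimen: no indicator column for it
    assert "regimen[DRUG_B_MONO]" not in design.columns


def test_design_reference_absorption_all_reference():
    reports = _reports([
        ("R1", "C1", 1, "", "F", "male", "18-64", "50-100kg", "MD"),
        ("R2", "C2", 1, "", "F", "male", "18-64", "50-100kg", "MD"),
    ])
    design, _ = build_design(
        reports, pd.Series(["DRUG_B_MONO", "DRUG_B_MONO"]), pd.Series([0, 1]), RegressionSpec()
    )
    assert list(design.columns) == ["const"]


def test_constant_outcome_raises():
    reports = _reports([
        ("R1", "C1", 1, "", "F", "male", "18-64", "50-100kg", "MD"),
        ("R2", "C2", 1, "", "F", "female", "18-64", "50-100kg", "MD"),
    ])
    with pytest.raises(DegenerateOutcomeError):
        build_design(reports, pd.Series(["COMBO", "COMBO"]), pd.Series([1, 1]), RegressionSpec())


def _simulate_design(rng, n, betas):
    x_combo = rng.random(n) < 0.2
    x_a = (~x_combo) & (rng.random(n) < 0.4)
    x_f = rng.random(n) < 0.45
    eta = betas["const"] + betas["combo"] * x_combo + betas["a"] * x_a + betas["female"] * x_f
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    design = pd.DataFrame(
        {"const": 1.0, "regimen[COMBO]": x_combo.astype(float),
         "regimen[DRUG_A_MONO]": x_a.astype(float), "sex[female]": x_f.astype(float)}
    )
    return design, pd.Series(y.astype(int))


def test_null_data_gives_unit_odds_ratios():
    rng = np.random.default_rng(21)
    covered = 0
    n_seeds = 20
    for _ in range(n_seeds):
        design, y = _simulate_design(rng, 2000, {"const": -1.0, "combo": 0.0, "a": 0.0, "female": 0.0})
        res = fit_logistic(design, y)
        ors = res.frame.set_index("term")
        ok = True
        for term in ("regimen[COMBO]", "regimen[DRUG_A_MONO]", "sex[female]"):
            ok &= ors.loc[term, "ci_lower"] <= 1.0 <= ors.loc[term, "ci_upper"]
        covered += ok
    assert covered >= 0.9 * n_seeds * 0.9  # all three CIs cover 1 in >= ~81% of runs


def test_log_or_recovery():
    rng = np.random.default_rng(22)
    estimates = []
    for _ in range(10):
        design, y = _simulate_design(rng, 5000, {"const": -1.5, "combo": 1.2, "a": 0.3, "female": 0.0})
        res = fit_logistic(design, y)
        estimates.append(np.log(res.frame.set_index("term").loc["regimen[COMBO]", "odds_ratio"]))
    assert np.mean(estimates) == pytest.approx(1.2, abs=0.2)


def test_zero_event_category_non_estimable():
    rng = np.random.default_rng(23)
    design, y = _simulate_design(rng, 1000, {"const": -1.0, "combo": 0.5, "a": 0.0, "female": 0.0})
    # construct quasi-complete separation: a level with zero events
    sep = (rng.random(1000) < 0.05) & (y == 0)
    design["weight_group[>100kg]"] = sep.astype(float)
    y = y.where(~sep, 0)
    res = fit_logistic(design, y)
    row = res.frame.set_index("term").loc["weight_group[>100kg]"]
    assert row["estimable"] == False  # noqa: E712
    assert pd.isna(row["odds_ratio"]) and pd.isna(row["ci_lower"])  # no numeric OR leaks
    # other terms still estimated
    assert res.frame.set_index("term").loc["regimen[COMBO]", "estimable"] == True  # noqa: E712


def test_fit_indices_formulas():
    ll_full, ll_null, k, n = -52.3, -60.0, 4, 8
    r2, aic, bic = fit_indices(ll_full, ll_null, k, n)
    assert r2 == pytest.approx(1 - ll_full / ll_null)
    assert aic == pytest.approx(2 * k - 2 * ll_full)
    assert bic == pytest.approx(k * np.log(n) - 2 * ll_full)


def test_full_equals_null_gives_zero_r2():
    r2, _, _ = fit_indices(-60.0, -60.0, 1, 100)
    assert r2 == 0.0


def test_likelihood_monotone_in_nested_models():
    rng = np.random.default_rng(24)
    design, y = _simulate_design(rng, 2000, {"const": -1.0, "combo": 0.8, "a": 0.0, "female": 0.0})
    full = fit_logistic(design, y)
    noise = design.copy()
    noise["noise"] = rng.random(len(design))
    bigger = fit_logistic(noise, y)
    assert bigger.llf >= full.llf - 1e-8


def test_permutation_invariance():
    rng = np.random.default_rng(25)
    design, y = _simulate_design(rng, 1000, {"const": -1.0, "combo": 0.6, "a": 0.2, "female": 0.1})
    res1 = fit_logistic(design, y)
    perm = rng.permutation(len(design))
    res2 = fit_logistic(design.iloc[perm].reset_index(drop=True), y.iloc[perm].reset_index(drop=True))
    f1 = res1.frame.set_index("term")["odds_ratio"]
    f2 = res2.frame.set_index("term")["odds_ratio"]
    assert np.allclose(f1, f2, atol=1e-10)


def test_from_cohort_secondary_contrast(demo_bundle):
    """Refitting with the other monotherapy as regimen reference yields the
    combination-vs-that-monotherapy contrast with an identical likelihood."""
    _, bundle, _ = demo_bundle
    primary = IRAELogit.from_cohort(bundle.cohort, RegressionSpec(regimen_reference="DRUG_B_MONO")).fit()
    secondary = IRAELogit.from_cohort(bundle.cohort, RegressionSpec(regimen_reference="DRUG_A_MONO")).fit()
    assert primary.llf == pytest.approx(secondary.llf, abs=1e-6)
    assert "regimen[COMBO]" in set(secondary.frame["term"])
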