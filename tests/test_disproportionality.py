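"""Disproportionality statistics: hand oracles, shrinkage, flags, grades."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import hand_tables
from pvsignals.cohort import build_cohort
from pvsignals.disproportionality import (
    ContingencyTable,
    build_contingency,
    compute_omega,
    compute_prr,
    compute_ror,
    flag_signals,
    grade_consistency,
    grade_priority,
    run_screen,
    DisproportionalityResult,
)
from pvsignals.errors import UndefinedInputError


def result_from(table, min_n=3):
    prr, chi2, prr_ci, c1 = compute_prr(table)
    ror, ror_ci, c2 = compute_ror(table)
    omega, lo, hi, e = compute_omega(table)
    res = DisproportionalityResult(
        group="G", event_term="T", n=table.a, expected_e=e, omega=omega,
        omega_lower=lo, omega_upper=hi, prr=prr, prr_chi2=chi2, prr_ci=prr_ci,
        ror=ror, ror_ci=ror_ci, corrected=c1 or c2,
    )
    return flag_signals(res, min_n)


def test_prr_hand_arithmetic():
    prr, chi2, ci, corrected = compute_prr(ContingencyTable(5, 95, 10, 990))
    assert prr == pytest.approx(5.0)
    assert not corrected
    assert ci[0] < 5.0 < ci[1]


def test_prr_equal_proportions_is_one():
    prr, chi2, _, _ = compute_prr(ContingencyTable(10, 90, 100, 900))
    assert prr == pytest.approx(1.0)
    assert chi2 == pytest.approx(0.0, abs=1e-12)


def test_prr_zero_cell_corrected_finite():
    prr, chi2, ci, corrected = compute_prr(ContingencyTable(3, 7, 0, 990))
    assert corrected
    assert math.isfinite(prr) and prr > 0
    # corrected-formula oracle
    a, b, c, d = 3.5, 7.5, 0.5, 990.5
    assert prr == pytest.approx((a / (a + b)) / (c / (c + d)), rel=1e-12)


def test_ror_symmetry_and_hand_value():
    ror, _, _ = compute_ror(ContingencyTable(10, 10, 10, 10))
    assert ror == pytest.approx(1.0)
    ror, _, _ = compute_ror(ContingencyTable(20, 80, 10, 890))
    assert ror == pytest.approx(22.25)


def test_ror_zero_cell_corrected():
    ror, ci, corrected = compute_ror(ContingencyTable(5, 0, 10, 990))
    assert corrected and math.isfinite(ror)


def test_empty_margin_raises():
    with pytest.raises(UndefinedInputError):
        compute_prr(ContingencyTable(0, 0, 5, 5))
    with pytest.raises(UndefinedInputError):
        compute_ror(ContingencyTable(5, 5, 0, 0))


def test_omega_log_of_one_is_zero():
    # choose cells so a = E: a=4, b=4, c=4, d=4 -> E = 8*8/16 = 4
    omega, lo, hi, e = compute_omega(ContingencyTable(4, 4, 4, 4))
    assert e == pytest.approx(4.0)
    assert omega == pytest.approx(0.0, abs=1e-12)
    assert lo < 0 < hi


def test_omega_hand_arithmetic():
    # E = (a+b)(a+c)/N = 7*8/128 = 0.4375 -> omega = log2(7.5/0.9375) = 3
    t = ContingencyTable(7, 0, 1, 120)
    omega, lo, hi, e = compute_omega(t)
    assert e == pytest.approx(0.4375)
    assert omega == pytest.approx(3.0)
    assert lo <= omega <= hi


def test_omega_monte_carlo_posterior_oracle():
    """Gamma-quantile credibility bounds match a sampled gamma posterior."""
    rng = np.random.default_rng(1)
    t = ContingencyTable(7, 93, 55, 2000)
    _, lo, hi, e = compute_omega(t)
    draws = rng.gamma(t.a + 0.5, size=10**6)
    mc_lo, mc_hi = np.percentile(np.log2(draws / (e + 0.5)), [2.5, 97.5])
    assert lo == pytest.approx(mc_lo, abs=0.02)
    assert hi == pytest.approx(mc_hi, abs=0.02)


@given(
    a=st.integers(1, 200), b=st.integers(1, 2000),
    c=st.integers(1, 200), d=st.integers(1, 5000),
)
@settings(deadline=None, max_examples=60)
def test_prr_ror_monotone_in_a(a, b, c, d):
    """For fixed b, c, d the ratio statistics are non-decreasing in a."""
    t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
    assert compute_prr(t2)[0] >= compute_prr(t1)[0]
    assert compute_ror(t2)[0] >= compute_ror(t1)[0]


@given(
    a=st.integers(1, 199), n_index=st.integers(200, 500),
    c=st.integers(0, 200), d=st.integers(1, 5000),
)
@settings(deadline=None, max_examples=60)
def test_omega_monotone_in_a_at_fixed_group_size(a, n_index, c, d):
    """With the index-group size held fixed (the screen's actual geometry),
    omega is non-decreasing in the observed count."""
    t1 = ContingencyTable(a, n_index - a, c, d)
    t2 = ContingencyTable(a + 1, n_index - a - 1, c, d)
    assert compute_omega(t2)[0] >= compute_omega(t1)[0] - 1e-12


@given(a=st.integers(1, 300), b=st.integers(1, 3000), c=st.integers(1, 300), d=st.integers(1, 5000))
@settings(deadline=None, max_examples=60)
def test_omega_shrinks_toward_zero(a, b, c, d):
    omega, _, _, e = compute_omega(ContingencyTable(a, b, c, d))
    raw = math.log2(a / e)
    if a > e:
        assert omega < raw
    elif a < e:
        assert omega > raw


@pytest.mark.parametrize(
    "prr, chi2, n, expected",
    [
        (2.5, 5.0, 10, True),
        (2.5, 5.0, 2, False),  # below the case-count floor
        (1.9, 50.0, 10, False),
        (2.5, 3.9, 10, False),
    ],
)
def test_prr_flag_rule(prr, chi2, n, expected):
    res = DisproportionalityResult(
        group="G", event_term="T", n=n, expected_e=1.0, omega=0, omega_lower=-1,
        omega_upper=1, prr=prr, prr_chi2=chi2, prr_ci=(1, 1), ror=1, ror_ci=(0.5, 2),
        corrected=False,
    )
    assert flag_signals(res).prr_sig is expected


def test_omega_flag_boundary_strict():
    res = DisproportionalityResult(
        group="G", event_term="T", n=10, expected_e=1.0, omega=0.5, omega_lower=0.0,
        omega_upper=1.0, prr=9, prr_chi2=9, prr_ci=(2, 20), ror=9, ror_ci=(2, 20),
        corrected=False,
    )
    assert flag_signals(res).omega_sig is False  # lower bound exactly 0


@pytest.mark.parametrize(
    "flags, expected",
    [
        ((True, True, True), "Strong"),
        ((True, False, True), "Moderate"),
        ((True, True, False), "Moderate"),
        ((False, True, False), "Weak"),
        ((False, False, True), "Weak"),
        ((False, True, True), "Weak"),
        ((True, False, False), "None"),  # omega alone: no enumerated pattern
        ((False, False, False), "None"),
    ],
)
def test_consistency_grading(flags, expected):
    assert grade_consistency(*flags) == expected


@pytest.mark.parametrize(
    "consistency, prr, expected",
    [
        ("Strong", 6.0, "High"),
        ("Strong", 3.0, "Medium"),
        ("Strong", 1.5, "Low"),
        ("Moderate", 6.0, "Medium"),
        ("Moderate", 4.0, "Low"),
        ("Weak", 10.0, "Low"),
        ("None", 10.0, "None"),
    ],
)
def test_priority_grading(consistency, prr, expected):
    assert grade_priority(consistency, prr) == expected


def _tiny_cohort():
    """Hand-countable 20-report cohort."""
    reports, drugs, events = [], [], []
    spec = [
        ("COMBO", 5, [("Diarrhoea", 3)]),
        ("DRUG_A_MONO", 5, [("Diarrhoea", 1)]),
        ("DRUG_B_MONO", 5, [("Diarrhoea", 1)]),
        ("BACKGROUND", 5, [("Diarrhoea", 0)]),
    ]
    k = 0
    for group, n, terms in spec:
        for i in range(n):
            rid = f"R{k}"
            k += 1
            reports.append((rid, rid, 1, "2020-01-01", "FAERS", "male", "18-64", "unknown", "MD"))
            if group == "COMBO":
                drugs.append((rid, "BEVACIZUMAB", "PS", "", "glioblastoma"))
                drugs.append((rid, "TEMOZOLOMIDE", "C", "", "glioblastoma"))
            elif group == "DRUG_A_MONO":
                drugs.append((rid, "BEVACIZUMAB", "PS", "", "glioblastoma"))
            elif group == "DRUG_B_MONO":
                drugs.append((rid, "TEMOZOLOMIDE", "PS", "", "glioblastoma"))
            else:
                drugs.append((rid, "OTHER", "PS", "", "glioblastoma"))
            for term, count in terms:
                if i < count:
                    events.append((rid, term, ""))
    return build_cohort(hand_tables(reports, drugs, events))


def test_build_contingency_matches_manual_count():
    cohort = _tiny_cohort()
    t = build_contingency(cohort, "COMBO", "Diarrhoea")
    assert (t.a, t.b, t.c, t.d) == (3, 2, 2, 13)
    t2 = build_contingency(cohort, "COMBO", "Diarrhoea", "other_cohort_groups")
    assert (t2.a, t2.b, t2.c, t2.d) == (3, 2, 2, 8)
    absent = build_contingency(cohort, "COMBO", "Nonexistent term")
    assert absent.a == 0 and absent.c == 0


def test_screen_whitelist_of_absent_term_is_empty():
    cohort = _tiny_cohort()
    res = run_screen(cohort, min_n=1, event_whitelist=["Nonexistent term"])
    assert len(res.frame) == 0


def test_screen_counts_reports_once_per_term():
    """A report carrying the same term twice counts once."""
    cohort = _tiny_cohort()
    cohort.tables.events = pytest.importorskip("pandas").concat(
        [cohort.tables.events, cohort.tables.events.iloc[[0]]], ignore_index=True
    )
    t = build_contingency(cohort, "COMBO", "Diarrhoea")
    assert t.a == 3
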