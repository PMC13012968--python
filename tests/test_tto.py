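"""Time-to-onset computation, summaries, Weibull fitting and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import weibull_min

from pvsignals.tto import classify_shape, compute_tto, fit_weibull, summarize_tto


@pytest.mark.parametrize(
    "start, onset, expected",
    [
        ("2020-01-01", "2020-01-15", 14),
        ("2020-01-01", "2020-01-01", 0),  # same day is valid
        ("2020-01-15", "2020-01-01", None),  # negative interval
        ("2020-01", "2020-01-15", None),  # partial start
        ("2020-01-01", "2020", None),  # partial onset
        ("", "2020-01-15", None),
        ("2020-01-01", None, None),
    ],
)
def test_compute_tto(start, onset, expected):
    assert compute_tto(start, onset) == expected


@pytest.mark.parametrize(
    "values, median, q1, q3, vmin, vmax",
    [
        ([14, 14, 14], 14.0, 14.0, 14.0, 14, 14),
        ([24], 24.0, 24.0, 24.0, 24, 24),
        ([483], 483.0, 483.0, 483.0, 483, 483),
        ([27, 293, 293, 293, 293], 293.0, 293.0, 293.0, 27, 293),
        ([34] * 8 + [62], 34.0, 34.0, 34.0, 34, 62),
    ],
)
def test_summary_reproduces_degenerate_rows(values, median, q1, q3, vmin, vmax):
    s = summarize_tto(values)
    assert (s.median, s.q1, s.q3, s.min, s.max) == (median, q1, q3, vmin, vmax)


def test_summary_type7_interpolation():
    s = summarize_tto([1, 2, 3, 4])
    assert s.q1 == pytest.approx(1.75)
    assert s.median == pytest.approx(2.5)
    assert s.q3 == pytest.approx(3.25)


def test_summary_empty_raises():
    with pytest.raises(ValueError):
        summarize_tto([])


@given(st.lists(st.integers(0, 1000), min_size=1, max_size=50))
@settings(deadline=None, max_examples=100)
def test_summary_order_invariants(values):
    s = summarize_tto(values)
    assert s.min <= s.q1 <= s.median <= s.q3 <= s.max


def test_weibull_recovery_from_simulation():
    rng = np.random.default_rng(0)
    x = 35.0 * rng.weibull(1.5, size=500)
    fit = fit_weibull(x)
    assert fit.converged and not fit.below_threshold
    assert fit.shape_beta == pytest.approx(1.5, abs=0.15)
    assert fit.scale_eta == pytest.approx(35.0, abs=3.0)


def test_weibull_exponential_special_case():
    rng = np.random.default_rng(1)
    x = rng.exponential(40.0, size=500)
    fit = fit_weibull(x)
    assert 0.85 <= fit.shape_beta <= 1.15


def test_weibull_matches_reference_mle():
    """Profile-equation solution agrees with an independent MLE (scipy)."""
    rng = np.random.default_rng(2)
    x = 50.0 * rng.weibull(0.8, size=300)
    fit = fit_weibull(x)
    shape_ref, _, scale_ref = weibull_min.fit(x, floc=0)
    assert fit.shape_beta == pytest.approx(shape_ref, rel=1e-4)
    assert fit.scale_eta == pytest.approx(scale_ref, rel=1e-4)


def test_weibull_degenerate_sample_not_converged():
    fit = fit_weibull([14.0, 14.0, 14.0])
    assert not fit.converged
    assert fit.classification is None


def test_weibull_refuses_tiny_samples():
    with pytest.raises(ValueError):
        fit_weibull([5.0, 6.0])


def test_weibull_below_threshold_flag():
    rng = np.random.default_rng(3)
    fit = fit_weibull(40 * rng.weibull(1.0, size=5))
    assert fit.below_threshold
    fit = fit_weibull(40 * rng.weibull(1.0, size=20))
    assert not fit.below_threshold


def test_weibull_zero_substitution_counted():
    rng = np.random.default_rng(4)
    x = np.concatenate([[0.0, 0.0], 30 * rng.weibull(1.0, size=30)])
    fit = fit_weibull(x)
    assert fit.n == 32
    assert fit.n_zeros_substituted == 2


def test_weibull_scale_equivariance():
    rng = np.random.default_rng(5)
    x = 20.0 * rng.weibull(1.2, size=200)
    f1 = fit_weibull(x)
    f2 = fit_weibull(3.0 * x)
    assert f2.shape_beta == pytest.approx(f1.shape_beta, abs=1e-6)
    assert f2.scale_eta == pytest.approx(3.0 * f1.scale_eta, rel=1e-6)


@pytest.mark.parametrize(
    "beta, expected",
    [
        (1.501, "Increasing"),
        (1.21, "Increasing"),
        (1.2, "Constant"),  # closed band
        (1.004, "Constant"),
        (0.8, "Constant"),  # closed band
        (0.799, "Decreasing"),
        (0.725, "Decreasing"),
    ],
)
def test_classify_shape_bands(beta, expected):
    assert classify_shape(beta) == expected


def test_classify_shape_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_shape(0.0)


def test_run_tto_analysis_accounting(demo_bundle):
    _, bundle, _ = demo_bundle
    tto = bundle.tto
    a = tto.accounting
    assert a.valid + a.missing_start + a.partial_start + a.missing_or_partial_onset + a.negative_interval == a.total_event_mentions
    # fits only where n >= 3, and flagged below the pre-specified threshold
    assert (tto.fits["n"] >= 3).all()
    assert ((tto.fits["n"] < 10) == tto.fits["below_threshold"]).all()
    # summary rows obey the order invariants
    s = tto.summaries
    assert (s["min"] <= s["q1"]).all() and (s["q3"] <= s["max"]).all()


def test_all_dates_missing_yields_empty_tables():
    from pvsignals.cohort import build_cohort
    from pvsignals.config import SimulationConfig
    from pvsignals.simulate import generate_dataset
    from pvsignals.tto import run_tto_analysis

    config = SimulationConfig(
        group_sizes={"COMBO": 100, "BEV_MONO": 100, "TMZ_MONO": 100, "BACKGROUND": 100},
        missingness={"start_date": 1.0},
        duplicate_rate=0.0,
        seed=6,
    )
    tables, _ = generate_dataset(config)
    cohort = build_cohort(tables)
    res = run_tto_analysis(cohort)
    assert len(res.summaries) == 0 and len(res.fits) == 0
    assert res.accounting.valid == 0
    assert res.accounting.missing_start == res.accounting.total_event_mentions


def test_configured_decreasing_shape_recovered():
    """A group generated with Weibull(0.7, 40) onsets — rounded to whole days
    with a 1-day floor, as reports record them — classifies Decreasing in at
    least 90% of runs at n = 200. The rounding truncates the early tail and
    biases the fitted shape up by about +0.04, so recovery sits near 93%,
    not the ~99% of continuous draws."""
    hits = 0
    n_seeds = 100
    rng = np.random.default_rng(11)
    for _ in range(n_seeds):
        x = np.maximum(1, np.floor(40.0 * rng.weibull(0.7, size=200) + 0.5))
        fit = fit_weibull(x)
        hits += fit.classification == "Decreasing"
    assert hits >= 0.9 * n_seeds
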