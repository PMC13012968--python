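"""Time-to-onset (TTO) description and exploratory Weibull shape modelling.

TTO is the number of days between the reported therapy start date and the
reported event onset date. Spontaneous reports carry no follow-up time for
exposed patients without the event, so no censoring structure exists and
survival methods do not apply; TTO summaries are report-based, case-only
descriptives. Where counts allow, a two-parameter Weibull distribution is
fitted to the positive onset intervals and its shape parameter beta is used
as a descriptive indicator of onset clustering:

* beta > 1.2 — onsets cluster later in treatment ("Increasing");
* 0.8 <= beta <= 1.2 — approximately constant over time ("Constant");
* beta < 0.8 — onsets cluster early ("Decreasing").

Fits are produced from n >= 3 but flagged ``below_threshold`` below the
pre-specified n >= 10; sparse fits are descriptive only.

The maximum-likelihood shape solves the profile-likelihood equation

    g(k) = sum(x^k ln x)/sum(x^k) - 1/k - mean(ln x) = 0

(the scale then follows in closed form), solved by bracketed root finding to
|g(k)| < 1e-8. Samples with zero spread have no root and are reported as
non-converged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Cohort
from .dates import parse_date
from .errors import EmptyGroupError

PROFILE_TOL = 1e-8


def compute_tto(start_date, onset_date) -> Optional[int]:
    """Calendar-day difference, or None when invalid.

    Only full-precision dates qualify; partial (year / year-month) or missing
    dates and negative intervals are invalid. Zero days is valid.
    """
    start = parse_date(start_date)
    onset = parse_date(onset_date)
    if not start.full or not onset.full:
        return None
    delta = (onset.date - start.date).days
    return delta if delta >= 0 else None


@dataclass(frozen=True)
class TTOSummary:
    n: int
    median: float
    q1: float
    q3: float
    min: float
    max: float


def summarize_tto(values: Sequence[float], quantile_method: str = "linear") -> TTOSummary:
    """Median / IQR / min / max of onset intervals.

    Quartiles use linear interpolation between order statistics (type-7) by
    default; ``quantile_method`` accepts any numpy interpolation method for
    sensitivity analyses.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_tto requires at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method=quantile_method)
    return TTOSummary(int(arr.size), float(med), float(q1), float(q3), float(arr.min()), float(arr.max()))


@dataclass
class WeibullFit:
    n: int
    shape_beta: float
    scale_eta: float
    log_likelihood: float
    converged: bool
    below_threshold: bool
    classification: Optional[str]
    n_zeros_substituted: int = 0


def _weibull_loglik(x: np.ndarray, shape: float, scale: float) -> float:
    z = x / scale
    return float(
        len(x) * (math.log(shape) - shape * math.log(scale))
        + (shape - 1) * np.sum(np.log(x))
        - np.sum(z**shape)
    )


def fit_weibull(values: Sequence[float], min_n: int = 10) -> WeibullFit:
    """Maximum-likelihood Weibull fit of onset intervals.

    Zeros are substituted with 0.5 day (counted in the result) so the sample
    size stays consistent with the descriptive summaries. Degenerate
    all-equal samples are returned non-converged with NaN parameters.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 3:
        raise ValueError(f"Weibull fit requires n >= 3, got {arr.size}")
    if np.any(arr < 0):
        raise ValueError("onset intervals must be non-negative")
    n_zeros = int(np.sum(arr == 0))
    x = np.where(arr == 0, 0.5, arr)
    below = arr.size < min_n

    logx = np.log(x)
    mean_logx = float(np.mean(logx))

    def profile(k: float) -> float:
        xk = np.exp(k * (logx - logx.max()))  # scaled to avoid overflow
        return float(np.sum(xk * logx) / np.sum(xk) - 1.0 / k - mean_logx)

    if np.allclose(x, x[0]):
        return WeibullFit(arr.size, float("nan"), float("nan"), float("nan"),
                          False, below, None, n_zeros)

    lo, hi = 1e-3, 1e3
    flo, fhi = profile(lo), profile(hi)
    if not (flo < 0 < fhi or fhi < 0 < flo):
        return WeibullFit(arr.size, float("nan"), float("nan"), float("nan"),
                          False, below, None, n_zeros)
    shape = brentq(profile, lo, hi, xtol=1e-12, rtol=8.9e-16)
    converged = abs(profile(shape)) < PROFILE_TOL
    scale = float(np.mean(x**shape) ** (1.0 / shape))
    ll = _weibull_loglik(x, shape, scale)
    cls = classify_shape(shape) if converged else None
    return WeibullFit(arr.size, float(shape), scale, ll, converged, below, cls, n_zeros)


def classify_shape(shape_beta: float) -> str:
    """Map the Weibull shape onto the onset-clustering bands (the 0.8-1.2
    constant band is closed on both ends)."""
    if not shape_beta > 0:
        raise ValueError(f"shape must be positive, got {shape_beta}")
    if shape_beta > 1.2:
        return "Increasing"
    if shape_beta >= 0.8:
        return "Constant"
    return "Decreasing"


def _report_start_dates(cohort: Cohort) -> Dict[str, object]:
    """Earliest full-precision therapy start among a report's study-drug
    mentions (the exposure whose onset clock the TTO measures)."""
    drugs = cohort.tables.drugs
    study = drugs.loc[drugs["drug_name"].isin([cohort.drug_a, cohort.drug_b])]
    starts: Dict[str, object] = {}
    partials: Dict[str, bool] = {}
    for row in study.itertuples(index=False):
        parsed = parse_date(row.therapy_start_date)
        if parsed.full:
            prev = starts.get(row.report_id)
            if prev is None or parsed.date < prev:
                starts[row.report_id] = parsed.date
        elif parsed.partial:
            partials.setdefault(row.report_id, True)
    return {"starts": starts, "partials": partials}


@dataclass
class TTOAccounting:
    total_event_mentions: int = 0
    missing_start: int = 0
    partial_start: int = 0
    missing_or_partial_onset: int = 0
    negative_interval: int = 0
    valid: int = 0


class TTOAnalysis:
    """Per-(group, term) TTO descriptives and exploratory Weibull fits.

    One summary row per (group, term) with >= 1 valid interval; one fit row
    per (group, term) with >= 3, flagged below the ``fit_min_n`` threshold.
    """

    def __init__(
        self,
        cohort: Cohort,
        groups: Sequence[str] = ("COMBO", "DRUG_A_MONO", "DRUG_B_MONO"),
        fit_min_n: int = 10,
        quantile_method: str = "linear",
    ):
        self.cohort = cohort
        self.groups = list(groups)
        self.fit_min_n = fit_min_n
        self.quantile_method = quantile_method

    def fit(self) -> "TTOResults":
        info = _report_start_dates(self.cohort)
        starts, partial_start = info["starts"], info["partials"]
        assign = self.cohort.assignments.set_index("report_id")["group"]
        accounting = TTOAccounting()
        values: Dict[Tuple[str, str], List[int]] = {}
        events = self.cohort.tables.events.drop_duplicates(subset=["report_id", "event_term"])
        for row in events.itertuples(index=False):
            group = assign.get(row.report_id)
            if group not in self.groups:
                continue
            accounting.total_event_mentions += 1
            start = starts.get(row.report_id)
            if start is None:
                if partial_start.get(row.report_id):
                    accounting.partial_start += 1
                else:
                    accounting.missing_start += 1
                continue
            onset = parse_date(row.onset_date)
            if not onset.full:
                accounting.missing_or_partial_onset += 1
                continue
            delta = (onset.date - start).days
            if delta < 0:
                accounting.negative_interval += 1
                continue
            accounting.valid += 1
            values.setdefault((group, row.event_term), []).append(delta)

        summary_rows, fit_rows = [], []
        for (group, term) in sorted(values):
            vals = values[(group, term)]
            s = summarize_tto(vals, self.quantile_method)
            summary_rows.append(
                {"group": group, "event_term": term, "n": s.n, "median": s.median,
                 "q1": s.q1, "q3": s.q3, "min": s.min, "max": s.max}
            )
            if s.n >= 3:
                f = fit_weibull(vals, self.fit_min_n)
                fit_rows.append(
                    {"group": group, "event_term": term, "n": f.n,
                     "shape_beta": f.shape_beta, "scale_eta": f.scale_eta,
                     "log_likelihood": f.log_likelihood, "converged": f.converged,
                     "below_threshold": f.below_threshold,
                     "classification": f.classification,
                     "n_zeros_substituted": f.n_zeros_substituted}
                )
        summaries = pd.DataFrame(
            summary_rows,
            columns=["group", "event_term", "n", "median", "q1", "q3", "min", "max"],
        )
        fits = pd.DataFrame(
            fit_rows,
            columns=["group", "event_term", "n", "shape_beta", "scale_eta",
                     "log_likelihood", "converged", "below_threshold",
                     "classification", "n_zeros_substituted"],
        )
        return TTOResults(self, summaries, fits, accounting)


class TTOResults:
    def __init__(self, model: TTOAnalysis, summaries: pd.DataFrame, fits: pd.DataFrame,
                 accounting: TTOAccounting):
        self.model = model
        self.summaries = summaries
        self.fits = fits
        self.accounting = accounting

    def summary(self) -> str:
        a = self.accounting
        lines = [
            "Time-to-onset analysis",
            f"  event mentions: {a.total_event_mentions}; valid intervals: {a.valid}",
            f"  excluded - missing start: {a.missing_start}, partial start: {a.partial_start}, "
            f"missing/partial onset: {a.missing_or_partial_onset}, negative: {a.negative_interval}",
            f"  summary rows: {len(self.summaries)}; Weibull fits: {len(self.fits)}",
        ]
        return "\n".join(lines)


def run_tto_analysis(
    cohort: Cohort,
    groups: Sequence[str] = ("COMBO", "DRUG_A_MONO", "DRUG_B_MONO"),
    fit_min_n: int = 10,
) -> TTOResults:
    """Functional wrapper over :class:`TTOAnalysis`."""
    return TTOAnalysis(cohort, groups, fit_min_n).fit()


__all__ = [
    "compute_tto",
    "summarize_tto",
    "fit_weibull",
    "classify_shape",
    "TTOSummary",
    "WeibullFit",
    "TTOAnalysis",
    "TTOResults",
    "TTOAccounting",
    "run_tto_analysis",
]
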