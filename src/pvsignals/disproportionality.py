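"""Disproportionality statistics and the multi-algorithm signal screen.

Three statistics are computed per (exposure group, preferred term) 2x2 table
with cells a (index group, event), b (index, no event), c (comparator,
event), d (comparator, no event):

* **PRR** = (a/(a+b)) / (c/(c+d)), with the Pearson chi-square of the table
  and a log-normal 95% CI. Signal rule: PRR >= 2, chi2 >= 4, n >= 3.
* **ROR** = (a d)/(b c) with log-normal 95% CI. Signal rule: CI lower
  bound > 1, n >= 3.
* **Omega** — an observed-to-expected log2 shrinkage statistic:
  E = (a+b)(a+c)/N is the expected count under independence and
  Omega = log2((a + 0.5)/(E + 0.5)); the +0.5 smoothing pulls sparse-cell
  estimates toward 0. 95% credibility bounds come from the exact
  gamma posterior of the observed count:
  Omega_q = log2(GammaInv(q; shape=a+0.5, rate=1)/(E + 0.5)).
  Signal rule: lower bound > 0 (strict), n >= 3.

Zero cells in PRR/ROR are handled with the Haldane-Anscombe correction
(+0.5 to all four cells, flagged ``corrected``). Consistency across the
three rules is graded Strong / Moderate / Weak / None and combined with the
PRR magnitude into a High / Medium / Low clinical priority.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, gamma

from .cohort import Cohort
from .errors import EmptyGroupError, UndefinedInputError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts for one (group, term)."""

    a: int  # index group with the event
    b: int  # index group without
    c: int  # comparator with
    d: int  # comparator without

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _corrected_cells(t: ContingencyTable) -> Tuple[float, float, float, float, bool]:
    if min(t.a, t.b, t.c, t.d) == 0:
        return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, True
    return float(t.a), float(t.b), float(t.c), float(t.d), False


def _pearson_chi2(t: ContingencyTable) -> float:
    """Pearson statistic without continuity correction; 0 for degenerate margins."""
    m = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
        return 0.0
    stat, _, _, _ = chi2_contingency(m, correction=False)
    return float(stat)


def compute_prr(table: ContingencyTable) -> Tuple[float, float, Tuple[float, float], bool]:
    """Proportional reporting ratio with chi-square and 95% CI.

    Returns (prr, chi2, (ci_lower, ci_upper), corrected). The chi-square is
    computed on the raw table; the PRR and its CI use Haldane-Anscombe
    corrected cells when any raw cell is zero.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise UndefinedInputError("PRR undefined: an exposure margin is empty")
    chi2 = _pearson_chi2(table)
    a, b, c, d, corrected = _corrected_cells(table)
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    ci = (prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se))
    return prr, chi2, ci, corrected


def compute_ror(table: ContingencyTable) -> Tuple[float, Tuple[float, float], bool]:
    """Reporting odds ratio with log-normal 95% CI; zero-cell handling as PRR."""
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise UndefinedInputError("ROR undefined: an exposure margin is empty")
    a, b, c, d, corrected = _corrected_cells(table)
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    ci = (ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))
    return ror, ci, corrected


def compute_omega(table: ContingencyTable) -> Tuple[float, float, float, float]:
    """Observed-to-expected log2 shrinkage statistic with exact gamma-posterior
    95% credibility bounds. Returns (omega, lower, upper, expected_E)."""
    if table.total == 0:
        raise UndefinedInputError("omega undefined: empty analysis set")
    e = (table.a + table.b) * (table.a + table.c) / table.total
    omega = math.log2((table.a + 0.5) / (e + 0.5))
    lower = math.log2(gamma.ppf(0.025, table.a + 0.5) / (e + 0.5))
    upper = math.log2(gamma.ppf(0.975, table.a + 0.5) / (e + 0.5))
    return omega, lower, upper, e


@dataclass
class DisproportionalityResult:
    group: str
    event_term: str
    n: int
    expected_e: float
    omega: float
    omega_lower: float
    omega_upper: float
    prr: float
    prr_chi2: float
    prr_ci: Tuple[float, float]
    ror: float
    ror_ci: Tuple[float, float]
    corrected: bool
    omega_sig: bool = False
    prr_sig: bool = False
    ror_sig: bool = False
    consistency: str = "None"
    priority: str = "None"


def flag_signals(result: DisproportionalityResult, min_n: int = 3) -> DisproportionalityResult:
    """Apply the three signal rules (all require n >= min_n; the omega rule
    uses a strict > 0 on the credibility lower bound)."""
    n_ok = result.n >= min_n
    result.omega_sig = bool(n_ok and result.omega_lower > 0)
    result.prr_sig = bool(n_ok and result.prr >= 2 and result.prr_chi2 >= 4)
    result.ror_sig = bool(n_ok and result.ror_ci[0] > 1)
    return result


def grade_consistency(omega_sig: bool, prr_sig: bool, ror_sig: bool) -> str:
    """Strong = all three rules; Moderate = omega plus one traditional rule;
    Weak = traditional rule(s) without omega; None otherwise (an omega-only
    flag grades None: the rule set enumerates no such pattern, and the gap is
    closed conservatively)."""
    traditional = prr_sig or ror_sig
    if omega_sig and prr_sig and ror_sig:
        return "Strong"
    if omega_sig and traditional:
        return "Moderate"
    if traditional:
        return "Weak"
    return "None"


def grade_priority(consistency: str, prr_value: float) -> str:
    """High = Strong and PRR > 5; Medium = Strong and PRR > 2, or Moderate and
    PRR > 5; Low = Moderate and PRR <= 5, or Weak."""
    if consistency == "Strong":
        if prr_value > 5:
            return "High"
        if prr_value > 2:
            return "Medium"
        return "Low"
    if consistency == "Moderate":
        return "Medium" if prr_value > 5 else "Low"
    if consistency == "Weak":
        return "Low"
    return "None"


def build_contingency(
    cohort: Cohort, group: str, event_term: str, comparator_mode: str = "rest_of_database"
) -> ContingencyTable:
    """Report-level 2x2 counts for (group, term). The comparator is either
    every other analysis-set report (``rest_of_database``) or only the other
    study groups (``other_cohort_groups``)."""
    pairs = cohort.event_pairs()
    sizes = cohort.group_sizes()
    if sizes.get(group, 0) == 0:
        raise EmptyGroupError(f"index group {group!r} is empty")
    if comparator_mode == "other_cohort_groups":
        comp_groups = [g for g in ("COMBO", "DRUG_A_MONO", "DRUG_B_MONO") if g != group]
    else:
        comp_groups = [g for g in sizes if g != group]
    a = int(((pairs["group"] == group) & (pairs["event_term"] == event_term)).sum())
    c = int((pairs["group"].isin(comp_groups) & (pairs["event_term"] == event_term)).sum())
    n_index = sizes[group]
    n_comp = sum(sizes.get(g, 0) for g in comp_groups)
    return ContingencyTable(a, n_index - a, c, n_comp - c)


def benjamini_hochberg(pvalues: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """BH step-up rejection flags (used only when multiplicity adjustment is
    explicitly enabled; screening is exploratory by default)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    flags = np.zeros(m, dtype=bool)
    flags[order[:k]] = True
    return flags


class DisproportionalityScreen:
    """Multi-algorithm disproportionality screen over a cohort.

    Parameters
    ----------
    cohort : Cohort
        Built cohort (indication-restricted, exposure-classified).
    groups : sequence of str
        Index groups to screen (default: the three study groups).
    min_n : int
        Minimum report count per (group, term) row.
    comparator_mode : str
        ``rest_of_database`` (default) or ``other_cohort_groups``.
    event_whitelist : sequence of str, optional
        Restrict the screen to these terms (rows below ``min_n`` excluded).
    bh_adjust : bool
        Append a Benjamini-Hochberg-adjusted flag column (off by default).
    """

    def __init__(
        self,
        cohort: Cohort,
        groups: Sequence[str] = ("COMBO", "DRUG_A_MONO", "DRUG_B_MONO"),
        min_n: int = 3,
        comparator_mode: str = "rest_of_database",
        event_whitelist: Optional[Sequence[str]] = None,
        bh_adjust: bool = False,
    ):
        self.cohort = cohort
        self.groups = list(groups)
        self.min_n = min_n
        self.comparator_mode = comparator_mode
        self.event_whitelist = list(event_whitelist) if event_whitelist is not None else None
        self.bh_adjust = bh_adjust

    def fit(self) -> "ScreenResults":
        pairs = self.cohort.event_pairs()
        sizes = self.cohort.group_sizes()
        counts = pairs.groupby(["group", "event_term"]).size()
        results: List[DisproportionalityResult] = []
        for group in self.groups:
            if sizes.get(group, 0) == 0:
                continue
            if self.comparator_mode == "other_cohort_groups":
                comp_groups = [g for g in ("COMBO", "DRUG_A_MONO", "DRUG_B_MONO") if g != group]
            else:
                comp_groups = [g for g in sizes if g != group]
            n_index = sizes[group]
            n_comp = sum(sizes.get(g, 0) for g in comp_groups)
            group_counts = counts.get(group, pd.Series(dtype=int))
            terms = self.event_whitelist
            if terms is None:
                terms = [t for t, n in group_counts.items() if n >= self.min_n]
            for term in sorted(terms):
                a = int(group_counts.get(term, 0))
                if a < self.min_n:
                    continue
                c = int(
                    sum(counts.get((g, term), 0) for g in comp_groups)
                )
                table = ContingencyTable(a, n_index - a, c, n_comp - c)
                prr, chi2, prr_ci, corr1 = compute_prr(table)
                ror, ror_ci, corr2 = compute_ror(table)
                omega, lo, hi, e = compute_omega(table)
                res = DisproportionalityResult(
                    group=group, event_term=term, n=a, expected_e=e,
                    omega=omega, omega_lower=lo, omega_upper=hi,
                    prr=prr, prr_chi2=chi2, prr_ci=prr_ci,
                    ror=ror, ror_ci=ror_ci, corrected=corr1 or corr2,
                )
                flag_signals(res, self.min_n)
                res.consistency = grade_consistency(res.omega_sig, res.prr_sig, res.ror_sig)
                res.priority = grade_priority(res.consistency, res.prr)
                results.append(res)
        return ScreenResults(self, results)


class ScreenResults:
    """Screen output; ``frame`` is sorted by group then descending count."""

    def __init__(self, model: DisproportionalityScreen, results: List[DisproportionalityResult]):
        self.model = model
        self.results = results
        rows = [
            {
                "group": r.group,
                "event_term": r.event_term,
                "n": r.n,
                "expected_e": r.expected_e,
                "omega": r.omega,
                "omega_lower": r.omega_lower,
                "omega_upper": r.omega_upper,
                "prr": r.prr,
                "prr_chi2": r.prr_chi2,
                "prr_ci_lower": r.prr_ci[0],
                "prr_ci_upper": r.prr_ci[1],
                "ror": r.ror,
                "ror_ci_lower": r.ror_ci[0],
                "ror_ci_upper": r.ror_ci[1],
                "omega_sig": r.omega_sig,
                "prr_sig": r.prr_sig,
                "ror_sig": r.ror_sig,
                "corrected": r.corrected,
                "consistency": r.consistency,
                "priority": r.priority,
            }
            for r in results
        ]
        frame = pd.DataFrame(
            rows,
            columns=[
                "group", "event_term", "n", "expected_e", "omega", "omega_lower",
                "omega_upper", "prr", "prr_chi2", "prr_ci_lower", "prr_ci_upper",
                "ror", "ror_ci_lower", "ror_ci_upper", "omega_sig", "prr_sig",
                "ror_sig", "corrected", "consistency", "priority",
            ],
        )
        if len(frame):
            frame["group"] = pd.Categorical(frame["group"], categories=model.groups, ordered=True)
            frame = frame.sort_values(
                ["group", "n", "event_term"], ascending=[True, False, True], kind="mergesort"
            ).reset_index(drop=True)
            frame["group"] = frame["group"].astype(str)
            if model.bh_adjust:
                # two-sided normal p-values from the ROR log-scale Wald statistic
                z = np.log(frame["ror"]) / (
                    (np.log(frame["ror_ci_upper"]) - np.log(frame["ror_ci_lower"])) / (2 * Z95)
                )
                from scipy.stats import norm

                pvals = 2 * norm.sf(np.abs(z))
                frame["bh_flag"] = benjamini_hochberg(pvals)
        self.frame = frame

    def publication_frame(self) -> pd.DataFrame:
        """Columns laid out the way signal tables are printed: term, N, omega,
        95% CI, PRR/ROR flags, consistency and priority."""
        f = self.frame
        out = pd.DataFrame(
            {
                "Group": f["group"],
                "Adverse event": f["event_term"],
                "N": f["n"],
                "Omega": f["omega"].round(3),
                "95% CI": [
                    f"({lo:.2f}-{hi:.2f})" for lo, hi in zip(f["omega_lower"], f["omega_upper"])
                ],
                "PRR": np.where(f["prr_sig"], "Yes", "No"),
                "ROR": np.where(f["ror_sig"], "Yes", "No"),
                "Omega Sig": np.where(f["omega_sig"], "Yes", "No"),
                "Consistency": f["consistency"],
                "Priority": f["priority"],
            }
        )
        return out

    def summary(self) -> str:
        lines = ["Disproportionality screen",
                 f"  comparator: {self.model.comparator_mode}; min n: {self.model.min_n}",
                 f"  rows: {len(self.frame)}"]
        for grade in ("Strong", "Moderate", "Weak"):
            k = int((self.frame["consistency"] == grade).sum()) if len(self.frame) else 0
            lines.append(f"  {grade}: {k}")
        if len(self.frame):
            lines.append(self.publication_frame().to_string(index=False))
        return "\n".join(lines)


def run_screen(
    cohort: Cohort,
    groups: Sequence[str] = ("COMBO", "DRUG_A_MONO", "DRUG_B_MONO"),
    min_n: int = 3,
    comparator_mode: str = "rest_of_database",
    event_whitelist: Optional[Sequence[str]] = None,
    bh_adjust: bool = False,
) -> ScreenResults:
    """Functional wrapper over :class:`DisproportionalityScreen`."""
    return DisproportionalityScreen(
        cohort, groups, min_n, comparator_mode, event_whitelist, bh_adjust
    ).fit()


__all__ = [
    "ContingencyTable",
    "DisproportionalityResult",
    "DisproportionalityScreen",
    "ScreenResults",
    "build_contingency",
    "compute_prr",
    "compute_ror",
    "compute_omega",
    "flag_signals",
    "grade_consistency",
    "grade_priority",
    "benjamini_hochberg",
    "run_screen",
]
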