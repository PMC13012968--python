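"""Drug-drug interaction signal analysis on the 2x2x2 reporting table.

For each event term the analysis set is stratified by exposure to each study
drug: (1,1) = combination, (1,0) / (0,1) = the two monotherapies, (0,0) =
reports with neither drug (the background stratum). Two families of measures
are reported:

* **Combination-vs-monotherapy PRRs** — the combination group's reporting
  proportion relative to each monotherapy, plus each monotherapy's PRR
  against the background (to check the monotherapies are themselves quiet).
* **Interaction OR** — the multiplicative-interaction contrast
  OR(1,1) / (OR(1,0) x OR(0,1)), each OR taken against the (0,0) stratum;
  this equals the interaction-term odds ratio of a saturated case/non-case
  logistic model. Values above 1 indicate more-than-multiplicative
  co-reporting. Estimates are descriptive: with sparse cells they can be
  extreme, which is why every row carries a ``sparse_warning``.

A zero anywhere in the eight cells triggers a +0.5 continuity correction on
all eight (flagged ``corrected``). Priority grading follows pre-specified
heuristics: High needs both combination PRRs >= 2, interaction OR >= 3 and
quiet monotherapies; Moderate needs both combination PRRs >= 1.8 or an
interaction OR in [2.0, 2.9], with at least one combination CI excluding 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .cohort import Cohort
from .disproportionality import Z95, ContingencyTable, compute_prr
from .errors import EmptyGroupError, UndefinedInputError


@dataclass(frozen=True)
class InteractionStrata:
    """Eight counts n(A-exposure, B-exposure, event): e = with event,
    o = without, per stratum (1,1), (1,0), (0,1), (0,0)."""

    e11: int
    o11: int
    e10: int
    o10: int
    e01: int
    o01: int
    e00: int
    o00: int

    def __post_init__(self):
        if min(self.cells()) < 0:
            raise ValueError("strata counts must be non-negative")

    def cells(self) -> Tuple[int, ...]:
        return (self.e11, self.o11, self.e10, self.o10, self.e01, self.o01, self.e00, self.o00)

    def stratum_totals(self) -> Tuple[int, int, int, int]:
        return (
            self.e11 + self.o11,
            self.e10 + self.o10,
            self.e01 + self.o01,
            self.e00 + self.o00,
        )

    def swapped(self) -> "InteractionStrata":
        """Relabel drug A as drug B (swaps the two monotherapy strata)."""
        return InteractionStrata(
            self.e11, self.o11, self.e01, self.o01, self.e10, self.o10, self.e00, self.o00
        )


def interaction_odds_ratio(
    strata: InteractionStrata,
) -> Tuple[float, Tuple[float, float], bool]:
    """Ratio-of-odds-ratios interaction contrast with a Wald 95% CI.

    Returns (interaction_or, (ci_lower, ci_upper), corrected).
    """
    if min(strata.stratum_totals()) == 0:
        raise EmptyGroupError("interaction OR undefined: a stratum has zero total")
    cells = strata.cells()
    corrected = min(cells) == 0
    e11, o11, e10, o10, e01, o01, e00, o00 = (
        (v + 0.5 for v in cells) if corrected else (float(v) for v in cells)
    )
    # OR(x) against the (0,0) stratum; the baseline odds cancel:
    ior = (e11 / o11) * (e00 / o00) / ((e10 / o10) * (e01 / o01))
    se = math.sqrt(sum(1.0 / v for v in (e11, o11, e10, o10, e01, o01, e00, o00)))
    ci = (ior * math.exp(-Z95 * se), ior * math.exp(Z95 * se))
    return ior, ci, corrected


def prr_between_groups(
    events_index: int, n_index: int, events_comp: int, n_comp: int
) -> Tuple[float, Tuple[float, float], bool]:
    """PRR of an event between two report groups (index vs comparator)."""
    if n_index == 0 or n_comp == 0:
        raise EmptyGroupError("PRR undefined: empty group")
    table = ContingencyTable(events_index, n_index - events_index, events_comp, n_comp - events_comp)
    prr, _, ci, corrected = compute_prr(table)
    return prr, ci, corrected


@dataclass
class InteractionResult:
    event_term: str
    n_combo: int
    prr_combo_vs_a: float
    prr_combo_vs_a_ci: Tuple[float, float]
    prr_combo_vs_b: float
    prr_combo_vs_b_ci: Tuple[float, float]
    prr_mono_a: float
    prr_mono_a_ci: Tuple[float, float]
    prr_mono_b: float
    prr_mono_b_ci: Tuple[float, float]
    interaction_or: float
    interaction_ci: Tuple[float, float]
    corrected: bool
    sparse_warning: bool
    priority: str = "None"


def prioritize_interaction(
    result: InteractionResult,
    mono_prr_cap: float = 1.5,
    require_combo_ci: bool = True,
) -> str:
    """Heuristic High / Moderate / None interaction priority.

    The quiet-monotherapy condition is applied to the monotherapy PRR point
    estimates (< ``mono_prr_cap``); the CI condition is applied to the
    combination comparisons (at least one CI excluding 1), switchable via
    ``require_combo_ci``.
    """
    combo_ci_excludes_1 = (
        result.prr_combo_vs_a_ci[0] > 1 or result.prr_combo_vs_b_ci[0] > 1
    )
    ci_ok = combo_ci_excludes_1 if require_combo_ci else True
    high = (
        result.prr_combo_vs_a >= 2.0
        and result.prr_combo_vs_b >= 2.0
        and result.interaction_or >= 3.0
        and result.prr_mono_a < mono_prr_cap
        and result.prr_mono_b < mono_prr_cap
        and ci_ok
    )
    if high:
        return "High"
    moderate = (
        (result.prr_combo_vs_a >= 1.8 and result.prr_combo_vs_b >= 1.8)
        or (2.0 <= result.interaction_or <= 2.9)
    ) and ci_ok
    return "Moderate" if moderate else "None"


class InteractionScreen:
    """Interaction screen over a cohort: one row per event term with at least
    ``min_n`` combination reports, ordered by descending combination count.

    The (0,0) background stratum is the cohort's BACKGROUND group (analysis-set
    reports listing neither study drug); the three study groups supply the
    other strata.
    """

    def __init__(self, cohort: Cohort, min_n: int = 3):
        self.cohort = cohort
        self.min_n = min_n

    def strata_for(self, term_counts: Dict[str, Dict[str, int]], term: str) -> InteractionStrata:
        sizes = self.cohort.group_sizes()
        c = term_counts.get(term, {})
        get = lambda g: int(c.get(g, 0))
        return InteractionStrata(
            e11=get("COMBO"), o11=sizes.get("COMBO", 0) - get("COMBO"),
            e10=get("DRUG_A_MONO"), o10=sizes.get("DRUG_A_MONO", 0) - get("DRUG_A_MONO"),
            e01=get("DRUG_B_MONO"), o01=sizes.get("DRUG_B_MONO", 0) - get("DRUG_B_MONO"),
            e00=get("BACKGROUND"), o00=sizes.get("BACKGROUND", 0) - get("BACKGROUND"),
        )

    def fit(self) -> "InteractionResults":
        sizes = self.cohort.group_sizes()
        for g in ("COMBO", "DRUG_A_MONO", "DRUG_B_MONO", "BACKGROUND"):
            if sizes.get(g, 0) == 0:
                raise EmptyGroupError(f"interaction screen needs a non-empty {g} group")
        pairs = self.cohort.event_pairs()
        counts = (
            pairs.groupby(["event_term", "group"]).size().unstack("group", fill_value=0)
        )
        term_counts = {t: row.to_dict() for t, row in counts.iterrows()}
        results: List[InteractionResult] = []
        for term, c in term_counts.items():
            n_combo = int(c.get("COMBO", 0))
            if n_combo < self.min_n:
                continue
            strata = self.strata_for(term_counts, term)
            ior, ior_ci, corrected = interaction_odds_ratio(strata)
            prr_a, ci_a, corr_a = prr_between_groups(
                strata.e11, strata.e11 + strata.o11, strata.e10, strata.e10 + strata.o10
            )
            prr_b, ci_b, corr_b = prr_between_groups(
                strata.e11, strata.e11 + strata.o11, strata.e01, strata.e01 + strata.o01
            )
            mono_a, mci_a, corr_ma = prr_between_groups(
                strata.e10, strata.e10 + strata.o10, strata.e00, strata.e00 + strata.o00
            )
            mono_b, mci_b, corr_mb = prr_between_groups(
                strata.e01, strata.e01 + strata.o01, strata.e00, strata.e00 + strata.o00
            )
            res = InteractionResult(
                event_term=term,
                n_combo=n_combo,
                prr_combo_vs_a=prr_a, prr_combo_vs_a_ci=ci_a,
                prr_combo_vs_b=prr_b, prr_combo_vs_b_ci=ci_b,
                prr_mono_a=mono_a, prr_mono_a_ci=mci_a,
                prr_mono_b=mono_b, prr_mono_b_ci=mci_b,
                interaction_or=ior, interaction_ci=ior_ci,
                corrected=corrected or corr_a or corr_b or corr_ma or corr_mb,
                sparse_warning=min(strata.e11, strata.e10, strata.e01, strata.e00) < 5,
            )
            res.priority = prioritize_interaction(res)
            results.append(res)
        results.sort(key=lambda r: (-r.n_combo, r.event_term))
        return InteractionResults(self, results)


class InteractionResults:
    def __init__(self, model: InteractionScreen, results: List[InteractionResult]):
        self.model = model
        self.results = results
        self.frame = pd.DataFrame(
            [
                {
                    "event_term": r.event_term,
                    "n_combo": r.n_combo,
                    "prr_combo_vs_a": r.prr_combo_vs_a,
                    "prr_combo_vs_a_ci_lower": r.prr_combo_vs_a_ci[0],
                    "prr_combo_vs_a_ci_upper": r.prr_combo_vs_a_ci[1],
                    "prr_combo_vs_b": r.prr_combo_vs_b,
                    "prr_combo_vs_b_ci_lower": r.prr_combo_vs_b_ci[0],
                    "prr_combo_vs_b_ci_upper": r.prr_combo_vs_b_ci[1],
                    "prr_mono_a": r.prr_mono_a,
                    "prr_mono_b": r.prr_mono_b,
                    "interaction_or": r.interaction_or,
                    "interaction_ci_lower": r.interaction_ci[0],
                    "interaction_ci_upper": r.interaction_ci[1],
                    "corrected": r.corrected,
                    "sparse_warning": r.sparse_warning,
                    "priority": r.priority,
                }
                for r in results
            ],
            columns=[
                "event_term", "n_combo", "prr_combo_vs_a", "prr_combo_vs_a_ci_lower",
                "prr_combo_vs_a_ci_upper", "prr_combo_vs_b", "prr_combo_vs_b_ci_lower",
                "prr_combo_vs_b_ci_upper", "prr_mono_a", "prr_mono_b", "interaction_or",
                "interaction_ci_lower", "interaction_ci_upper", "corrected",
                "sparse_warning", "priority",
            ],
        )

    def summary(self) -> str:
        lines = [
            "Interaction screen (combination vs monotherapies)",
            f"  rows: {len(self.frame)}; min combo n: {self.model.min_n}",
        ]
        if len(self.frame):
            show = self.frame[
                ["event_term", "n_combo", "prr_combo_vs_a", "prr_combo_vs_b",
                 "interaction_or", "sparse_warning", "priority"]
            ].round(2)
            lines.append(show.to_string(index=False))
        return "\n".join(lines)


def run_interaction_screen(cohort: Cohort, min_n: int = 3) -> InteractionResults:
    """Functional wrapper over :class:`InteractionScreen`."""
    return InteractionScreen(cohort, min_n).fit()


__all__ = [
    "InteractionStrata",
    "InteractionResult",
    "InteractionScreen",
    "InteractionResults",
    "interaction_odds_ratio",
    "prr_between_groups",
    "prioritize_interaction",
    "run_interaction_screen",
]
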