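"""Cohort construction: exposure-role classification, indication matching,
flow accounting, and baseline tables with Pearson chi-square comparisons.

Exposure groups follow the case/non-case design used in disproportionality
studies of a two-drug regimen:

* ``COMBO`` — both study drugs in the report. Under the *primary* definition
  one drug must carry the Primary Suspect (PS) role and the other the
  Concomitant (C) role; under *any_role* mere presence (PS/SS/C/I) counts.
* ``DRUG_A_MONO`` / ``DRUG_B_MONO`` — the drug is PS (primary) or present
  under any role (any_role) and the other study drug is absent.
* ``BACKGROUND`` — neither study drug appears.
* ``EXCLUDED`` — study-drug mentions that fit none of the above patterns
  (e.g. a lone Secondary Suspect under the primary definition).

Reports whose indication text matches no dictionary term are excluded from
the cohort before exposure classification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .config import STUDY_DRUG_A, STUDY_DRUG_B
from .errors import DegenerateTableError
from .tables import SRSTables

#: Broad and core glioblastoma dictionaries; fully user-overridable.
DEFAULT_BROAD_TERMS = (
    "glioblastoma",
    "glioblastoma multiforme",
    "gbm",
    "gliosarcoma",
    "malignant glioma",
)
DEFAULT_CORE_TERMS = ("glioblastoma", "glioblastoma multiforme")


@dataclass(frozen=True)
class IndicationDictionary:
    broad: Tuple[str, ...] = DEFAULT_BROAD_TERMS
    core: Tuple[str, ...] = DEFAULT_CORE_TERMS

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "IndicationDictionary":
        broad, core = [], []
        for term, tier in pairs:
            tier = tier.strip().lower()
            if tier == "core":
                core.append(term)
                broad.append(term)  # core implies broad
            elif tier == "broad":
                broad.append(term)
            else:
                raise ValueError(f"unknown dictionary tier {tier!r} for term {term!r}")
        return cls(tuple(dict.fromkeys(broad)), tuple(dict.fromkeys(core)))


@dataclass(frozen=True)
class ExposureAssignment:
    report_id: str
    group: str  # COMBO / DRUG_A_MONO / DRUG_B_MONO / BACKGROUND / EXCLUDED
    mode: str
    ps_drug: Optional[str]


@dataclass(frozen=True)
class IndicationMatch:
    report_id: str
    tier: str  # core / broad / none
    matched_term: Optional[str]


def _normalize_text(text: str) -> str:
    text = re.sub(r"[^\w\s]", " ", str(text).casefold())
    return re.sub(r"\s+", " ", text).strip()


def match_indication(
    indication_text, dictionary: IndicationDictionary, report_id: str = ""
) -> IndicationMatch:
    """Tiered substring match of normalized indication text against the
    dictionary; missing text matches nothing."""
    if indication_text is None or (isinstance(indication_text, float) and np.isnan(indication_text)):
        return IndicationMatch(report_id, "none", None)
    text = _normalize_text(indication_text)
    if not text:
        return IndicationMatch(report_id, "none", None)
    for term in dictionary.core:
        if _normalize_text(term) in text:
            return IndicationMatch(report_id, "core", term)
    for term in dictionary.broad:
        if _normalize_text(term) in text:
            return IndicationMatch(report_id, "broad", term)
    return IndicationMatch(report_id, "none", None)


def classify_exposure(
    drug_mentions: pd.DataFrame,
    drug_a: str = STUDY_DRUG_A,
    drug_b: str = STUDY_DRUG_B,
    mode: str = "primary",
    both_ps_policy: str = "exclude",
    report_id: str = "",
) -> ExposureAssignment:
    """Classify one report's drug mentions into an exposure group.

    ``both_ps_policy`` decides whether a report listing both drugs as PS is
    EXCLUDED (strict combination definition: one PS + one C) or counted as
    COMBO; the strict reading is the default.
    """
    roles_a = set(drug_mentions.loc[drug_mentions["drug_name"] == drug_a, "role"])
    roles_b = set(drug_mentions.loc[drug_mentions["drug_name"] == drug_b, "role"])
    if not roles_a and not roles_b:
        return ExposureAssignment(report_id, "BACKGROUND", mode, None)

    if mode == "any_role":
        if roles_a and roles_b:
            ps = drug_a if "PS" in roles_a else (drug_b if "PS" in roles_b else None)
            return ExposureAssignment(report_id, "COMBO", mode, ps)
        if roles_a:
            return ExposureAssignment(report_id, "DRUG_A_MONO", mode, drug_a if "PS" in roles_a else None)
        return ExposureAssignment(report_id, "DRUG_B_MONO", mode, drug_b if "PS" in roles_b else None)

    # primary definition
    if roles_a and roles_b:
        a_ps_b_c = "PS" in roles_a and "C" in roles_b
        b_ps_a_c = "PS" in roles_b and "C" in roles_a
        if a_ps_b_c and not b_ps_a_c:
            return ExposureAssignment(report_id, "COMBO", mode, drug_a)
        if b_ps_a_c and not a_ps_b_c:
            return ExposureAssignment(report_id, "COMBO", mode, drug_b)
        if a_ps_b_c and b_ps_a_c:
            return ExposureAssignment(report_id, "COMBO", mode, drug_a)
        if "PS" in roles_a and "PS" in roles_b and both_ps_policy == "combo":
            return ExposureAssignment(report_id, "COMBO", mode, drug_a)
        return ExposureAssignment(report_id, "EXCLUDED", mode, None)
    if "PS" in roles_a and not roles_b:
        return ExposureAssignment(report_id, "DRUG_A_MONO", mode, drug_a)
    if "PS" in roles_b and not roles_a:
        return ExposureAssignment(report_id, "DRUG_B_MONO", mode, drug_b)
    return ExposureAssignment(report_id, "EXCLUDED", mode, None)


@dataclass
class Cohort:
    """Per-report exposure assignments over the indication-matched analysis
    set, together with the report/drug/event tables restricted to it."""

    assignments: pd.DataFrame  # report_id, group, tier, ps_drug
    tables: SRSTables
    mode: str
    flow: Dict[str, int]
    drug_a: str = STUDY_DRUG_A
    drug_b: str = STUDY_DRUG_B

    def report_ids(self, group: str) -> pd.Series:
        return self.assignments.loc[self.assignments["group"] == group, "report_id"]

    def group_sizes(self) -> Dict[str, int]:
        return self.assignments["group"].value_counts().to_dict()

    def event_pairs(self) -> pd.DataFrame:
        """Report-level (group, report_id, event_term) pairs (deduplicated)."""
        ev = self.tables.events.merge(
            self.assignments[["report_id", "group"]], on="report_id", how="inner"
        )
        return ev.drop_duplicates(subset=["report_id", "event_term"])


def build_cohort(
    tables: SRSTables,
    dictionary: Optional[IndicationDictionary] = None,
    mode: str = "primary",
    drug_a: str = STUDY_DRUG_A,
    drug_b: str = STUDY_DRUG_B,
    both_ps_policy: str = "exclude",
    tier: str = "broad",
) -> Cohort:
    """Restrict to the indication cohort and classify exposure.

    ``tier='core'`` keeps only core-dictionary matches (the stricter a-priori
    subgroup); ``'broad'`` keeps both tiers. Flow accounting records the
    report counts surviving each stage.
    """
    dictionary = dictionary or IndicationDictionary()
    flow = {"input_reports": len(tables.reports)}

    # indication tier per report: best tier over its drug mentions
    tiers: Dict[str, str] = {}
    rank = {"none": 0, "broad": 1, "core": 2}
    for row in tables.drugs.itertuples(index=False):
        m = match_indication(row.indication_text, dictionary, row.report_id)
        if rank[m.tier] > rank.get(tiers.get(row.report_id, "none"), 0):
            tiers[row.report_id] = m.tier
    keep_tiers = {"core"} if tier == "core" else {"core", "broad"}
    matched_ids = [rid for rid in tables.reports["report_id"] if tiers.get(rid, "none") in keep_tiers]
    flow["indication_matched"] = len(matched_ids)

    matched_set = set(matched_ids)
    drugs = tables.drugs.loc[tables.drugs["report_id"].isin(matched_set)]
    study = drugs.loc[drugs["drug_name"].isin([drug_a, drug_b])]
    by_report = {rid: grp for rid, grp in study.groupby("report_id")}

    rows = []
    for rid in matched_ids:
        grp = by_report.get(rid)
        if grp is None:  # no study-drug mention
            rows.append({"report_id": rid, "group": "BACKGROUND", "tier": tiers[rid], "ps_drug": None})
            continue
        a = classify_exposure(grp, drug_a, drug_b, mode, both_ps_policy, report_id=rid)
        rows.append({"report_id": rid, "group": a.group, "tier": tiers[rid], "ps_drug": a.ps_drug})
    assignments = pd.DataFrame(rows, columns=["report_id", "group", "tier", "ps_drug"])
    analysis = assignments.loc[assignments["group"] != "EXCLUDED"].reset_index(drop=True)
    flow["exposure_classified"] = len(analysis)
    flow["excluded_exposure"] = len(assignments) - len(analysis)

    keep = set(analysis["report_id"])
    sub = SRSTables(
        tables.reports.loc[tables.reports["report_id"].isin(keep)].reset_index(drop=True),
        tables.drugs.loc[tables.drugs["report_id"].isin(keep)].reset_index(drop=True),
        tables.events.loc[tables.events["report_id"].isin(keep)].reset_index(drop=True),
    )
    return Cohort(analysis, sub, mode, flow, drug_a, drug_b)


# ---------------------------------------------------------------------------
# Baseline tables
# ---------------------------------------------------------------------------

@dataclass
class BaselineTable:
    variable: str
    counts: pd.DataFrame  # category x group count matrix
    chi_square: float
    df: int
    p_value: float


def baseline_chi_square(counts) -> Tuple[float, int, float]:
    """Pearson chi-square without continuity correction on a category x group
    count matrix; all-zero rows/columns are dropped first."""
    m = np.asarray(counts, dtype=float)
    if m.ndim != 2 or np.any(m < 0):
        raise DegenerateTableError("counts must be a non-negative 2-D matrix")
    m = m[m.sum(axis=1) > 0][:, m.sum(axis=0) > 0] if m.size else m
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise DegenerateTableError(
            f"need at least 2 rows and 2 columns with positive margins, got {m.shape}"
        )
    stat, p, df, _ = chi2_contingency(m, correction=False)
    return float(stat), int(df), float(p)


def baseline_tables(
    cohort: Cohort,
    groups: Sequence[str] = ("COMBO", "DRUG_A_MONO", "DRUG_B_MONO"),
    variables: Sequence[str] = ("sex", "weight_group", "age_group", "reporter_type"),
) -> List[BaselineTable]:
    """Category x group baseline tables (unknown categories included) with
    Pearson chi-square comparisons; categories absent in a group are
    zero-filled."""
    merged = cohort.tables.reports.merge(cohort.assignments[["report_id", "group"]], on="report_id")
    merged = merged.loc[merged["group"].isin(groups)]
    out = []
    for var in variables:
        counts = (
            merged.groupby([var, "group"], sort=True).size().unstack("group", fill_value=0)
        )
        counts = counts.reindex(columns=list(groups), fill_value=0)
        stat, df, p = baseline_chi_square(counts.to_numpy())
        out.append(BaselineTable(var, counts, stat, df, p))
    return out


__all__ = [
    "IndicationDictionary",
    "ExposureAssignment",
    "IndicationMatch",
    "Cohort",
    "BaselineTable",
    "match_indication",
    "classify_exposure",
    "build_cohort",
    "baseline_chi_square",
    "baseline_tables",
    "DEFAULT_BROAD_TERMS",
    "DEFAULT_CORE_TERMS",
]
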