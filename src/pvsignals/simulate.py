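"""Synthetic spontaneous-report generator with known ground truth.

Emulates the structure of a spontaneous reporting system extract: reports
carrying role-coded drug mentions (PS/SS/C/I), preferred-term event mentions,
indication text, therapy-start and event-onset dates with configurable
missingness, demographics, duplicate case versions, and injectable
drug-event and drug-drug-interaction reporting-rate multipliers. Because the
injected truth is recorded, every downstream stage (deduplication, cohort
construction, disproportionality screening, interaction analysis,
time-to-onset modelling, regression) can be validated without any external
database.

Events are sampled independently per term within a report (no term
correlation model). Onset times are continuous Weibull draws rounded
half-up to whole days with a 1-day floor.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from .config import STUDY_DRUG_A, STUDY_DRUG_B, SimulationConfig
from .tables import DRUG_COLUMNS, EVENT_COLUMNS, GROUPS, REPORT_COLUMNS, SRSTables

_EPOCH = dt.date(2015, 1, 1)
_START_WINDOW_DAYS = 3000  # therapy starts spread over ~8 years
_BACKGROUND_DRUGS = ("CARBOPLATIN", "LEVETIRACETAM", "DEXAMETHASONE", "LOMUSTINE")


@dataclass
class SyntheticTruth:
    """Ground truth recorded during generation."""

    injected_signal_set: Set[Tuple[str, str]] = field(default_factory=set)
    injected_interaction_set: Set[str] = field(default_factory=set)
    tto_parameters: Dict[Tuple[str, str], Tuple[float, float]] = field(default_factory=dict)
    duplicated_case_ids: List[str] = field(default_factory=list)
    group_of_report: Dict[str, str] = field(default_factory=dict)
    combo_ps_drug: Dict[str, str] = field(default_factory=dict)

    @property
    def n_duplicates(self) -> int:
        return len(self.duplicated_case_ids)


def _sample_categorical(rng: np.random.Generator, dist: Dict[str, float], n: int) -> np.ndarray:
    cats = np.array(list(dist.keys()), dtype=object)
    probs = np.array(list(dist.values()), dtype=float)
    probs = probs / probs.sum()
    return rng.choice(cats, size=n, p=probs)


def _mask_unknown(rng: np.random.Generator, values: np.ndarray, p_missing: float) -> np.ndarray:
    if p_missing <= 0:
        return values
    out = values.copy()
    out[rng.random(len(values)) < p_missing] = "unknown"
    return out


def _iso(days_from_epoch: np.ndarray) -> List[str]:
    return [(_EPOCH + dt.timedelta(days=int(d))).isoformat() for d in days_from_epoch]


def generate_dataset(config: SimulationConfig) -> Tuple[SRSTables, SyntheticTruth]:
    """Generate normalized SRS tables plus the injected ground truth.

    One base report per configured unit, plus duplicate case versions at
    ``duplicate_rate``. Identical configuration (including seed) yields
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    terms = list(config.event_catalog)
    truth = SyntheticTruth()
    for group in GROUPS:
        for term in terms:
            mult = config.signal_multipliers.get(group, {}).get(term, 1.0)
            if mult > 1.0:
                truth.injected_signal_set.add((group, term))
            truth.tto_parameters[(group, term)] = config.tto_model_for(group, term)
    truth.injected_interaction_set = {
        t for t, m in config.interaction_multipliers.items() if m > 1.0
    }

    report_rows: List[dict] = []
    drug_rows: List[dict] = []
    event_rows: List[dict] = []
    counter = 0

    for group in GROUPS:
        n = int(config.group_sizes.get(group, 0))
        if n == 0:
            continue
        case_ids = [f"C{counter + i:07d}" for i in range(n)]
        counter += n
        report_ids = [f"{c}.1" for c in case_ids]
        for rid in report_ids:
            truth.group_of_report[rid] = group

        start_days = rng.integers(0, _START_WINDOW_DAYS, size=n)
        receive_days = start_days + rng.integers(30, 730, size=n)
        latent_start = _iso(start_days)

        demo = {}
        for fld in ("sex", "age_group", "weight_group", "reporter_type"):
            vals = _sample_categorical(rng, config.demographics[fld], n)
            demo[fld] = _mask_unknown(rng, vals, config.missingness.get(fld, 0.0))

        # recorded start dates: missing / partial masking of the latent dates
        recorded_start = np.array(latent_start, dtype=object)
        miss_start = rng.random(n) < config.missingness.get("start_date", 0.0)
        recorded_start[miss_start] = ""
        if config.partial_date_rate > 0:
            partial = (~miss_start) & (rng.random(n) < config.partial_date_rate)
            recorded_start[partial] = [s[:7] for s in recorded_start[partial]]

        indication = _sample_categorical(rng, config.indication_labels[group], n)

        for i in range(n):
            report_rows.append(
                {
                    "report_id": report_ids[i],
                    "case_id": case_ids[i],
                    "case_version": 1,
                    "receive_date": (_EPOCH + dt.timedelta(days=int(receive_days[i]))).isoformat(),
                    "database_tag": config.database_tag,
                    "sex": demo["sex"][i],
                    "age_group": demo["age_group"][i],
                    "weight_group": demo["weight_group"][i],
                    "reporter_type": demo["reporter_type"][i],
                }
            )

        # drug mentions with group-consistent roles
        if group == "COMBO":
            ps_to_a = rng.random(n) < 0.5
            for i in range(n):
                a_role, b_role = ("PS", "C") if ps_to_a[i] else ("C", "PS")
                truth.combo_ps_drug[report_ids[i]] = STUDY_DRUG_A if ps_to_a[i] else STUDY_DRUG_B
                drug_rows.append(
                    {"report_id": report_ids[i], "drug_name": STUDY_DRUG_A, "role": a_role,
                     "therapy_start_date": recorded_start[i], "indication_text": indication[i]}
                )
                drug_rows.append(
                    {"report_id": report_ids[i], "drug_name": STUDY_DRUG_B, "role": b_role,
                     "therapy_start_date": recorded_start[i], "indication_text": indication[i]}
                )
        elif group in ("BEV_MONO", "TMZ_MONO"):
            name = STUDY_DRUG_A if group == "BEV_MONO" else STUDY_DRUG_B
            for i in range(n):
                drug_rows.append(
                    {"report_id": report_ids[i], "drug_name": name, "role": "PS",
                     "therapy_start_date": recorded_start[i], "indication_text": indication[i]}
                )
        else:  # BACKGROUND: neither study drug
            decoys = rng.choice(np.array(_BACKGROUND_DRUGS, dtype=object), size=n)
            for i in range(n):
                drug_rows.append(
                    {"report_id": report_ids[i], "drug_name": decoys[i], "role": "PS",
                     "therapy_start_date": recorded_start[i], "indication_text": indication[i]}
                )

        # event mentions: independent Bernoulli per term, Weibull onset
        miss_onset_p = config.missingness.get("onset_date", 0.0)
        for term in terms:
            p = min(1.0, config.event_catalog[term] * config.effective_multiplier(group, term))
            hits = np.flatnonzero(rng.random(n) < p)
            if len(hits) == 0:
                continue
            shape, scale = config.tto_model_for(group, term)
            draws = scale * rng.weibull(shape, size=len(hits))
            days = np.maximum(1, np.floor(draws + 0.5).astype(int))  # half-up, 1-day floor
            onset_missing = rng.random(len(hits)) < miss_onset_p
            for j, i in enumerate(hits):
                onset = ""
                if not onset_missing[j]:
                    onset = (_EPOCH + dt.timedelta(days=int(start_days[i]) + int(days[j]))).isoformat()
                event_rows.append(
                    {"report_id": report_ids[i], "event_term": term, "onset_date": onset}
                )

    reports = pd.DataFrame(report_rows, columns=REPORT_COLUMNS)
    drugs = pd.DataFrame(drug_rows, columns=DRUG_COLUMNS)
    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)

    # duplicate case versions: re-emit selected cases as version 2
    if config.duplicate_rate > 0 and len(reports):
        dup_mask = rng.random(len(reports)) < config.duplicate_rate
        dup_reports = reports.loc[dup_mask].copy()
        if len(dup_reports):
            truth.duplicated_case_ids = list(dup_reports["case_id"])
            old_ids = dup_reports["report_id"].to_numpy()
            dup_reports["case_version"] = 2
            dup_reports["report_id"] = dup_reports["case_id"] + ".2"
            dup_reports["receive_date"] = [
                (dt.date.fromisoformat(d) + dt.timedelta(days=30)).isoformat()
                for d in dup_reports["receive_date"]
            ]
            id_map = dict(zip(old_ids, dup_reports["report_id"]))
            for old, new in id_map.items():
                truth.group_of_report[new] = truth.group_of_report[old]
                if old in truth.combo_ps_drug:
                    truth.combo_ps_drug[new] = truth.combo_ps_drug[old]
            dup_drugs = drugs[drugs["report_id"].isin(id_map)].copy()
            dup_drugs["report_id"] = dup_drugs["report_id"].map(id_map)
            dup_events = events[events["report_id"].isin(id_map)].copy()
            dup_events["report_id"] = dup_events["report_id"].map(id_map)
            reports = pd.concat([reports, dup_reports], ignore_index=True)
            drugs = pd.concat([drugs, dup_drugs], ignore_index=True)
            events = pd.concat([events, dup_events], ignore_index=True)

    tables = SRSTables(reports, drugs, events)
    tables.check_referential_integrity()
    return tables, truth


__all__ = ["generate_dataset", "SyntheticTruth"]
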