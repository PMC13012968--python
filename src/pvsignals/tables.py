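"""The normalized spontaneous-reporting-system (SRS) data model.

Every pipeline stage consumes three flat tables:

``reports`` — one row per individual case safety report *version*:
    report_id, case_id, case_version, receive_date, database_tag,
    sex, age_group, weight_group, reporter_type

``drugs`` — one row per drug mention:
    report_id, drug_name, role, therapy_start_date, indication_text

``events`` — one row per adverse-event mention (MedDRA-style preferred term):
    report_id, event_term, onset_date

Dates are ISO strings (``YYYY-MM-DD`` full, ``YYYY-MM``/``YYYY`` partial,
``""`` missing); see :mod:`pvsignals.dates`. Categorical enumerations follow
FAERS conventions: drug roles PS/SS/C/I (primary suspect, secondary suspect,
concomitant, interacting); reporter types MD/PH/HP/CN/OT plus
database-specific codes; unknown values are the literal string ``unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REPORT_COLUMNS = [
    "report_id",
    "case_id",
    "case_version",
    "receive_date",
    "database_tag",
    "sex",
    "age_group",
    "weight_group",
    "reporter_type",
]
DRUG_COLUMNS = ["report_id", "drug_name", "role", "therapy_start_date", "indication_text"]
EVENT_COLUMNS = ["report_id", "event_term", "onset_date"]

DRUG_ROLES = ("PS", "SS", "C", "I")
SEXES = ("male", "female", "unknown")
AGE_GROUPS = ("<2", "2-11", "12-17", "18-64", "65-85", ">85", "unknown")
WEIGHT_GROUPS = ("<50kg", "50-100kg", ">100kg", "unknown")
REPORTER_TYPES = ("MD", "PH", "HP", "CN", "OT", "unknown")

GROUPS = ("COMBO", "BEV_MONO", "TMZ_MONO", "BACKGROUND")


def _empty(columns) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class SRSTables:
    """Container for the three normalized SRS tables."""

    reports: pd.DataFrame = field(default_factory=lambda: _empty(REPORT_COLUMNS))
    drugs: pd.DataFrame = field(default_factory=lambda: _empty(DRUG_COLUMNS))
    events: pd.DataFrame = field(default_factory=lambda: _empty(EVENT_COLUMNS))

    def __post_init__(self):
        self.reports = self.reports.reindex(columns=REPORT_COLUMNS)
        self.drugs = self.drugs.reindex(columns=DRUG_COLUMNS)
        self.events = self.events.reindex(columns=EVENT_COLUMNS)

    def copy(self) -> "SRSTables":
        return SRSTables(self.reports.copy(), self.drugs.copy(), self.events.copy())

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def check_referential_integrity(self) -> None:
        """Raise AssertionError if any mention references a missing report."""
        ids = set(self.reports["report_id"])
        orphan_drugs = set(self.drugs["report_id"]) - ids
        orphan_events = set(self.events["report_id"]) - ids
        if orphan_drugs or orphan_events:
            raise AssertionError(
                f"orphan mentions: drugs {sorted(orphan_drugs)[:5]}, "
                f"events {sorted(orphan_events)[:5]}"
            )

    def semantically_equal(self, other: "SRSTables") -> bool:
        """Equality up to row order (mention tables carry no intrinsic order)."""

        def canon(df: pd.DataFrame) -> pd.DataFrame:
            out = df.astype(object)
            out = out.mask(out.isna(), "").map(str)
            return out.sort_values(list(out.columns)).reset_index(drop=True)

        return (
            canon(self.reports).equals(canon(other.reports))
            and canon(self.drugs).equals(canon(other.drugs))
            and canon(self.events).equals(canon(other.events))
        )
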