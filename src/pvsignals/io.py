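"""Reading and writing SRS dialect files, deduplication, term normalization.

Two text dialects are supported, mirroring the public extract formats of the
two source databases:

* **FAERS dialect** — five ``$``-delimited tables with one header line each:
  ``DEMO`` (report/demographics), ``DRUG`` (name + role), ``THER`` (therapy
  start dates), ``INDI`` (indication text), ``REAC`` (event term + onset).
  A literal ``$`` inside free text is escaped as ``&#36;`` on write and
  unescaped on read.
* **CVARD dialect** — a single flat RFC-4180 CSV with one row per
  drug-mention x event-mention pair (drug or event fields empty when a
  report lacks one side). Reporter types are written as CVARD labels
  ("Physician", "Pharmacist", ...) and mapped back to the shared
  MD/PH/HP/CN/OT enumeration on read.

Malformed rows are never silently dropped: every rejected row is logged with
a reason and per-file counts satisfy ingested + rejected = data rows.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .dates import parse_date
from .errors import DialectIOError
from .tables import (
    AGE_GROUPS,
    DRUG_COLUMNS,
    DRUG_ROLES,
    EVENT_COLUMNS,
    REPORT_COLUMNS,
    REPORTER_TYPES,
    SEXES,
    SRSTables,
    WEIGHT_GROUPS,
)

_DOLLAR_ESCAPE = "&#36;"

_FAERS_SCHEMAS = {
    "DEMO": REPORT_COLUMNS,
    "DRUG": ["report_id", "drug_name", "role"],
    "THER": ["report_id", "drug_name", "therapy_start_date"],
    "INDI": ["report_id", "drug_name", "indication_text"],
    "REAC": EVENT_COLUMNS,
}

CVARD_COLUMNS = REPORT_COLUMNS + [
    "drug_name",
    "role",
    "therapy_start_date",
    "indication_text",
    "event_term",
    "onset_date",
]

#: CVARD reporter-type labels <-> shared enumeration
CVARD_REPORTER_LABELS = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "HP": "Health professional",
    "CN": "Consumer",
    "OT": "Other",
    "unknown": "",
}
_CVARD_REPORTER_CODES = {v.casefold(): k for k, v in CVARD_REPORTER_LABELS.items() if v}

#: reporter codes recognised verbatim (incl. database-specific LW/RN)
_KNOWN_REPORTER_CODES = set(REPORTER_TYPES) | {"LW", "RN"}

#: default study-drug synonym map (brand -> generic)
DEFAULT_DRUG_SYNONYMS = {"AVASTIN": "BEVACIZUMAB", "TEMODAR": "TEMOZOLOMIDE"}


@dataclass
class IngestionLog:
    """Accounting of every row seen during ingestion."""

    rows: Dict[str, int] = field(default_factory=dict)
    ingested: Dict[str, int] = field(default_factory=dict)
    rejections: List[dict] = field(default_factory=list)
    unknown_categories: Counter = field(default_factory=Counter)
    unmapped_terms: Counter = field(default_factory=Counter)
    removed_duplicates: List[Tuple[str, int]] = field(default_factory=list)

    def rejected(self, fname: str) -> int:
        return sum(1 for r in self.rejections if r["file"] == fname)

    def reject(self, fname: str, line: int, reason: str) -> None:
        self.rejections.append({"file": fname, "line": line, "reason": reason})

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for fname in self.rows:
                fh.write(json.dumps({
                    "event": "file", "file": fname, "rows": self.rows[fname],
                    "ingested": self.ingested.get(fname, 0), "rejected": self.rejected(fname),
                }) + "\n")
            for r in self.rejections:
                fh.write(json.dumps({"event": "rejection", **r}) + "\n")
            for key, n in self.unknown_categories.items():
                fh.write(json.dumps({"event": "unknown_category", "key": key, "count": n}) + "\n")


def _escape(value) -> str:
    return str(value if value is not None else "").replace("$", _DOLLAR_ESCAPE)


def _unescape(value: str) -> str:
    return value.replace(_DOLLAR_ESCAPE, "$")


# ---------------------------------------------------------------------------
# FAERS dialect
# ---------------------------------------------------------------------------

def write_faers_dialect(tables: SRSTables, directory) -> Dict[str, Path]:
    """Write the five ``$``-delimited dialect files; returns the file map."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DialectIOError(f"cannot create directory {directory}: {exc}") from exc

    frames = {
        "DEMO": tables.reports,
        "DRUG": tables.drugs[["report_id", "drug_name", "role"]],
        "THER": tables.drugs[["report_id", "drug_name", "therapy_start_date"]],
        "INDI": tables.drugs[["report_id", "drug_name", "indication_text"]],
        "REAC": tables.events,
    }
    paths = {}
    for name, frame in frames.items():
        path = directory / f"{name}.txt"
        cols = _FAERS_SCHEMAS[name]
        try:
            with open(path, "w", newline="") as fh:
                fh.write("$".join(cols) + "\n")
                for row in frame.itertuples(index=False):
                    fh.write("$".join(_escape(v) for v in row) + "\n")
        except OSError as exc:
            raise DialectIOError(f"cannot write {path}: {exc}") from exc
        paths[name] = path
    return paths


def _normalize_report_categories(row: dict, log: IngestionLog) -> dict:
    for fld, allowed in (
        ("sex", SEXES),
        ("age_group", AGE_GROUPS),
        ("weight_group", WEIGHT_GROUPS),
    ):
        if row[fld] not in allowed:
            log.unknown_categories[f"{fld}:{row[fld]}"] += 1
            row[fld] = "unknown"
    if row["reporter_type"] not in _KNOWN_REPORTER_CODES:
        log.unknown_categories[f"reporter_type:{row['reporter_type']}"] += 1
        row["reporter_type"] = "unknown"
    return row


def read_faers_dialect(directory, log: Optional[IngestionLog] = None) -> Tuple[SRSTables, IngestionLog]:
    """Read the five dialect files back into normalized tables.

    Rows with a wrong field count, an unparseable case version, or an
    unknown drug-role code are rejected and logged with a reason.
    """
    directory = Path(directory)
    log = log if log is not None else IngestionLog()
    raw: Dict[str, List[dict]] = {}
    for name, cols in _FAERS_SCHEMAS.items():
        path = directory / f"{name}.txt"
        if not path.exists():
            raise DialectIOError(f"missing dialect file: {path}")
        rows: List[dict] = []
        with open(path) as fh:
            lines = fh.read().splitlines()
        fname = path.name
        log.rows[fname] = max(0, len(lines) - 1)
        for lineno, line in enumerate(lines[1:], start=2):
            fields = line.split("$")
            if len(fields) != len(cols):
                log.reject(fname, lineno, f"expected {len(cols)} fields, got {len(fields)}")
                continue
            row = dict(zip(cols, (_unescape(f) for f in fields)))
            if name == "DEMO":
                try:
                    row["case_version"] = int(row["case_version"])
                except ValueError:
                    log.reject(fname, lineno, f"unparseable case version {row['case_version']!r}")
                    continue
                row = _normalize_report_categories(row, log)
            if name == "DRUG" and row["role"] not in DRUG_ROLES:
                log.reject(fname, lineno, f"unknown drug role code {row['role']!r}")
                continue
            rows.append(row)
        log.ingested[fname] = len(rows)
        raw[name] = rows

    reports = pd.DataFrame(raw["DEMO"], columns=REPORT_COLUMNS)
    drug = pd.DataFrame(raw["DRUG"], columns=_FAERS_SCHEMAS["DRUG"])
    ther = pd.DataFrame(raw["THER"], columns=_FAERS_SCHEMAS["THER"]).drop_duplicates(
        subset=["report_id", "drug_name"]
    )
    indi = pd.DataFrame(raw["INDI"], columns=_FAERS_SCHEMAS["INDI"]).drop_duplicates(
        subset=["report_id", "drug_name"]
    )
    drugs = drug.merge(ther, on=["report_id", "drug_name"], how="left").merge(
        indi, on=["report_id", "drug_name"], how="left"
    )
    drugs = drugs.reindex(columns=DRUG_COLUMNS).fillna("")
    events = pd.DataFrame(raw["REAC"], columns=EVENT_COLUMNS)
    return SRSTables(reports, drugs, events), log


# ---------------------------------------------------------------------------
# CVARD dialect
# ---------------------------------------------------------------------------

def write_cvard_dialect(tables: SRSTables, path) -> Path:
    """Write a single flat CSV, one row per drug x event mention pair."""
    path = Path(path)
    rows: List[list] = []
    drugs_by_rid: Dict[str, list] = {}
    for row in tables.drugs.itertuples(index=False):
        drugs_by_rid.setdefault(row.report_id, []).append(row)
    events_by_rid: Dict[str, list] = {}
    for row in tables.events.itertuples(index=False):
        events_by_rid.setdefault(row.report_id, []).append(row)

    empty_drug = ("", "", "", "")
    empty_event = ("", "")
    for rep in tables.reports.itertuples(index=False):
        base = list(rep)
        base[REPORT_COLUMNS.index("reporter_type")] = CVARD_REPORTER_LABELS.get(
            rep.reporter_type, rep.reporter_type
        )
        dlist = [
            (d.drug_name, d.role, d.therapy_start_date, d.indication_text)
            for d in drugs_by_rid.get(rep.report_id, [])
        ] or [empty_drug]
        elist = [
            (e.event_term, e.onset_date) for e in events_by_rid.get(rep.report_id, [])
        ] or [empty_event]
        for d in dlist:
            for e in elist:
                rows.append(base + list(d) + list(e))
    try:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CVARD_COLUMNS)
            writer.writerows(rows)
    except OSError as exc:
        raise DialectIOError(f"cannot write {path}: {exc}") from exc
    return path


def read_cvard_dialect(path, log: Optional[IngestionLog] = None) -> Tuple[SRSTables, IngestionLog]:
    """Read the flat CVARD-dialect CSV back into normalized tables."""
    path = Path(path)
    if not path.exists():
        raise DialectIOError(f"missing dialect file: {path}")
    log = log if log is not None else IngestionLog()
    fname = path.name
    report_rows, drug_rows, event_rows = [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DialectIOError(f"{path} is empty (no header)")
        if header != CVARD_COLUMNS:
            raise DialectIOError(f"{path} has unexpected columns {header}")
        n_rows = 0
        for lineno, fields in enumerate(reader, start=2):
            n_rows += 1
            if len(fields) != len(CVARD_COLUMNS):
                log.reject(fname, lineno, f"expected {len(CVARD_COLUMNS)} fields, got {len(fields)}")
                continue
            row = dict(zip(CVARD_COLUMNS, fields))
            try:
                row["case_version"] = int(row["case_version"])
            except ValueError:
                log.reject(fname, lineno, f"unparseable case version {row['case_version']!r}")
                continue
            label = row["reporter_type"]
            if label.casefold() in _CVARD_REPORTER_CODES:
                row["reporter_type"] = _CVARD_REPORTER_CODES[label.casefold()]
            elif label in _KNOWN_REPORTER_CODES:
                pass  # verbatim shared-enumeration code
            elif label == "":
                row["reporter_type"] = "unknown"
            else:
                log.unknown_categories[f"reporter_type:{label}"] += 1
                row["reporter_type"] = "unknown"
            row = _normalize_report_categories(row, log)
            if row["drug_name"] and row["role"] not in DRUG_ROLES:
                log.reject(fname, lineno, f"unknown drug role code {row['role']!r}")
                continue
            report_rows.append({c: row[c] for c in REPORT_COLUMNS})
            if row["drug_name"]:
                drug_rows.append({c: row[c] for c in DRUG_COLUMNS})
            if row["event_term"]:
                event_rows.append({c: row[c] for c in EVENT_COLUMNS})
        log.rows[fname] = n_rows
        log.ingested[fname] = n_rows - log.rejected(fname)

    reports = pd.DataFrame(report_rows, columns=REPORT_COLUMNS).drop_duplicates(
        subset=["report_id"], ignore_index=True
    )
    drugs = pd.DataFrame(drug_rows, columns=DRUG_COLUMNS).drop_duplicates(ignore_index=True)
    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS).drop_duplicates(ignore_index=True)
    return SRSTables(reports, drugs, events), log


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def deduplicate(
    tables: SRSTables,
    probabilistic: bool = False,
    log: Optional[IngestionLog] = None,
) -> Tuple[SRSTables, IngestionLog]:
    """Keep one version per case: highest case_version, ties broken by latest
    receive date, then by largest report_id (a total order).

    An optional second *probabilistic* pass collapses distinct case ids that
    share sex, age group, receive date, drug set and event set; it is OFF by
    default.
    """
    log = log if log is not None else IngestionLog()
    reports = tables.reports
    if len(reports) == 0:
        return tables.copy(), log

    def receive_key(value):
        parsed = parse_date(value)
        return parsed.date.toordinal() if parsed.full else -1

    ranked = reports.assign(
        _rd=reports["receive_date"].map(receive_key),
        _ver=pd.to_numeric(reports["case_version"]),
    ).sort_values(
        ["case_id", "_ver", "_rd", "report_id"], ascending=[True, False, False, False],
        kind="mergesort",
    )
    keep = ranked.drop_duplicates(subset=["case_id"], keep="first")
    removed = ranked.loc[~ranked["report_id"].isin(keep["report_id"])]
    log.removed_duplicates.extend(
        (r.case_id, int(r.case_version)) for r in removed.itertuples(index=False)
    )
    kept_ids = set(keep["report_id"])
    out = SRSTables(
        reports.loc[reports["report_id"].isin(kept_ids)].reset_index(drop=True),
        tables.drugs.loc[tables.drugs["report_id"].isin(kept_ids)].reset_index(drop=True),
        tables.events.loc[tables.events["report_id"].isin(kept_ids)].reset_index(drop=True),
    )

    if probabilistic:
        drug_sets = out.drugs.groupby("report_id")["drug_name"].agg(frozenset)
        event_sets = out.events.groupby("report_id")["event_term"].agg(frozenset)
        sig = out.reports.assign(
            _drugs=out.reports["report_id"].map(lambda r: drug_sets.get(r, frozenset())),
            _events=out.reports["report_id"].map(lambda r: event_sets.get(r, frozenset())),
        )
        sig = sig.sort_values("report_id", ascending=False, kind="mergesort")
        keep2 = sig.drop_duplicates(
            subset=["sex", "age_group", "receive_date", "_drugs", "_events"], keep="first"
        )
        removed2 = sig.loc[~sig["report_id"].isin(keep2["report_id"])]
        log.removed_duplicates.extend(
            (r.case_id, int(r.case_version)) for r in removed2.itertuples(index=False)
        )
        kept_ids = set(keep2["report_id"])
        out = SRSTables(
            out.reports.loc[out.reports["report_id"].isin(kept_ids)].reset_index(drop=True),
            out.drugs.loc[out.drugs["report_id"].isin(kept_ids)].reset_index(drop=True),
            out.events.loc[out.events["report_id"].isin(kept_ids)].reset_index(drop=True),
        )
    return out, log


# ---------------------------------------------------------------------------
# Term and drug-name normalization
# ---------------------------------------------------------------------------

def _sentence_case(term: str) -> str:
    term = re.sub(r"\s+", " ", term.strip())
    return term[:1].upper() + term[1:].lower() if term else term


def normalize_terms(
    events: pd.DataFrame,
    term_map: Optional[Dict[str, str]] = None,
    log: Optional[IngestionLog] = None,
) -> Tuple[pd.DataFrame, IngestionLog]:
    """Map verbatim event strings onto preferred terms (case-insensitive).

    Unmapped terms pass through sentence-cased and are counted. Mapped
    preferred terms are fixed points, so the operation is idempotent.
    """
    log = log if log is not None else IngestionLog()
    lookup = {k.casefold(): v for k, v in (term_map or {}).items()}
    for v in list(lookup.values()):
        lookup.setdefault(v.casefold(), v)

    def one(term: str) -> str:
        key = str(term).casefold().strip()
        key = re.sub(r"\s+", " ", key)
        if key in lookup:
            return lookup[key]
        log.unmapped_terms[_sentence_case(str(term))] += 1
        return _sentence_case(str(term))

    out = events.copy()
    out["event_term"] = out["event_term"].map(one)
    return out, log


def normalize_drug_names(
    drugs: pd.DataFrame, synonym_map: Optional[Dict[str, str]] = None
) -> pd.DataFrame:
    """Uppercase/trim/collapse whitespace, then resolve synonyms (brand names)."""
    synonyms = dict(DEFAULT_DRUG_SYNONYMS)
    if synonym_map:
        synonyms.update({k.upper(): v.upper() for k, v in synonym_map.items()})
    out = drugs.copy()
    canon = out["drug_name"].map(lambda s: re.sub(r"\s+", " ", str(s).strip().upper()))
    out["drug_name"] = canon.map(lambda s: synonyms.get(s, s))
    return out


def load_two_column_csv(path) -> List[Tuple[str, str]]:
    """Load a two-column CSV (term map, synonym map, dictionary) as pairs."""
    pairs = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise DialectIOError(f"{path}: expected two columns, got {row}")
            pairs.append((row[0].strip(), row[1].strip()))
    return pairs


__all__ = [
    "IngestionLog",
    "write_faers_dialect",
    "read_faers_dialect",
    "write_cvard_dialect",
    "read_cvard_dialect",
    "deduplicate",
    "normalize_terms",
    "normalize_drug_names",
    "load_two_column_csv",
    "CVARD_COLUMNS",
    "CVARD_REPORTER_LABELS",
    "DEFAULT_DRUG_SYNONYMS",
]
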