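"""Calendar-date handling for spontaneous reports.

Spontaneous-report dates arrive as full dates, partial dates (year or
year-month), or missing. Partial dates are retained at ingestion and only
excluded where an analysis needs day precision (time-to-onset), so every
parser here distinguishes *invalid*, *partial* and *full*.

Canonical string forms: ``YYYY-MM-DD`` (full), ``YYYY-MM`` / ``YYYY``
(partial), empty string or None (missing). FAERS-style compact digits
(``YYYYMMDD``, ``YYYYMM``, ``YYYY``) are accepted on input.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Optional

_FULL_ISO = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")
_YM_ISO = re.compile(r"^(\d{4})-(\d{2})$")
_Y = re.compile(r"^(\d{4})$")
_FULL_COMPACT = re.compile(r"^(\d{4})(\d{2})(\d{2})$")
_YM_COMPACT = re.compile(r"^(\d{4})(\d{2})$")


@dataclass(frozen=True)
class ParsedDate:
    """Outcome of parsing a report date field."""

    date: Optional[dt.date]  # set only for full dates
    partial: bool  # True for year / year-month values
    missing: bool

    @property
    def full(self) -> bool:
        return self.date is not None


MISSING = ParsedDate(None, False, True)


def parse_date(value) -> ParsedDate:
    """Parse a date field into full / partial / missing.

    Unparseable garbage is treated as missing (it carries no usable
    day information), matching how downstream validity rules exclude it.
    """
    if value is None:
        return MISSING
    if isinstance(value, dt.datetime):
        return ParsedDate(value.date(), False, False)
    if isinstance(value, dt.date):
        return ParsedDate(value, False, False)
    s = str(value).strip()
    if not s or s.lower() in {"nan", "none", "nat"}:
        return MISSING
    m = _FULL_ISO.match(s) or _FULL_COMPACT.match(s)
    if m:
        try:
            return ParsedDate(dt.date(int(m[1]), int(m[2]), int(m[3])), False, False)
        except ValueError:
            return MISSING
    if _YM_ISO.match(s) or _YM_COMPACT.match(s) or _Y.match(s):
        return ParsedDate(None, True, False)
    return MISSING


def format_date(d: Optional[dt.date]) -> str:
    return "" if d is None else d.isoformat()
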