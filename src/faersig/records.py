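"""Typed records for the five FAERS quarterly tables and the assembled report.

FAERS quarterly extracts are flat "$"-delimited tables keyed by PRIMARYID
(one row per report *version*); CASEID identifies the underlying safety
case across versions. A ``Report`` is one deduplicated case with its child
rows (drugs, reactions, outcomes, therapy dates) attached.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
AGE_UNITS = frozenset({"YR", "DEC", "MON", "WK", "DY", "HR"})
SEX_CODES = frozenset({"F", "M"})
OCCUPATION_CODES = frozenset({"MD", "PH", "CN", "HP", "OT"})


@dataclass(frozen=True, slots=True)
class DemoRecord:
    """One DEMO row: demographics and administrative dates for a report version."""

    primaryid: str
    caseid: str
    fda_dt: _dt.date
    event_dt: _dt.date | None = None
    age: float | None = None
    age_unit: str | None = None
    sex: str | None = None
    occp_cod: str | None = None
    occr_country: str | None = None

    @property
    def report_year(self) -> int:
        return self.fda_dt.year


@dataclass(frozen=True, slots=True)
class DrugRecord:
    """One DRUG row: a drug mention with its suspect role."""

    primaryid: str
    drugname: str
    role_cod: str
    prod_ai: str | None = None
    drug_seq: int | None = None


@dataclass(frozen=True, slots=True)
class ReacRecord:
    """One REAC row: a MedDRA preferred-term event mention."""

    primaryid: str
    pt: str


@dataclass(frozen=True, slots=True)
class OutcRecord:
    """One OUTC row: a serious-outcome code for the report."""

    primaryid: str
    outc_cod: str


@dataclass(frozen=True, slots=True)
class TherRecord:
    """One THER row: therapy start date linked to a drug sequence number."""

    primaryid: str
    dsg_drug_seq: int | None = None
    start_dt: _dt.date | None = None


@dataclass(frozen=True, slots=True)
class Report:
    """One deduplicated safety report with all child rows attached."""

    primaryid: str
    caseid: str
    fda_dt: _dt.date
    event_dt: _dt.date | None = None
    age: float | None = None
    age_unit: str | None = None
    sex: str | None = None
    occp_cod: str | None = None
    occr_country: str | None = None
    drugs: tuple[DrugRecord, ...] = field(default=())
    pts: tuple[str, ...] = field(default=())
    outcomes: tuple[str, ...] = field(default=())
    therapies: tuple[TherRecord, ...] = field(default=())

    @property
    def report_year(self) -> int:
        return self.fda_dt.year
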