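"""Descriptive summaries of a target-drug report cohort.

Covers the standard pharmacovigilance report-characteristics table: sex,
age bins, reporter occupation, occurrence country, receipt year, serious
outcomes, and time to onset (event date minus therapy start date of the
target drug). Percentages are over the total number of deduplicated
reports, rounded half-up to 2 decimals. Outcomes and countries need not
partition the cohort (a report can carry several outcome codes); all other
sections do, with missing data pooled under "Unknown".
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import exact_percent
from .cohort import normalize_term
from .records import Report

logger = logging.getLogger(__name__)

# FAERS age-unit codes to years. WK uses the mean Gregorian year of 52.18
# weeks; HR uses 8766 h = 365.25 d.
_AGE_UNIT_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

AGE_BIN_LABELS = ("<18", "≥18,<45", "≥45,<65", "≥65,<75", "≥75", "Unknown")
ONSET_BIN_LABELS = ("0–7", "7–28", "28–60", "≥60", "Unknown")

_REPORTER_LABELS = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "CN": "Consumer",
    "HP": "Other health professionals",
    "OT": "Other health professionals",
}

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization—initial or prolonged",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other serious",
}


def percent(count: int, total: int) -> float:
    """100*count/total, rounded half-up to 2 decimals."""
    return exact_percent(count, total)


def age_in_years(age: float, unit: str | None) -> float | None:
    """Convert an age with a FAERS unit code to years; unknown unit -> None."""
    if unit is None or unit not in _AGE_UNIT_YEARS:
        if unit is not None:
            logger.warning("unknown age unit %r treated as missing", unit)
        return None
    return age * _AGE_UNIT_YEARS[unit]


def bin_age(years: float | None) -> str:
    """Half-open age bins [0,18), [18,45), [45,65), [65,75), [75,inf)."""
    if years is None:
        return "Unknown"
    if years < 0:
        logger.warning("negative age %r treated as missing", years)
        return "Unknown"
    for upper, label in ((18, "<18"), (45, "≥18,<45"), (65, "≥45,<65"), (75, "≥65,<75")):
        if years < upper:
            return label
    return "≥75"


def time_to_onset_days(event_dt: _dt.date | None, start_dt: _dt.date | None) -> int | None:
    """Whole days from therapy start to event; negative gaps and missing dates -> None."""
    if event_dt is None or start_dt is None:
        return None
    days = (event_dt - start_dt).days
    return days if days >= 0 else None


def bin_onset(days: int | None) -> str:
    """Half-open onset bins [0,7), [7,28), [28,60), [60,inf) in days."""
    if days is None:
        return "Unknown"
    for upper, label in ((7, "0–7"), (28, "7–28"), (60, "28–60")):
        if days < upper:
            return label
    return "≥60"


@dataclass(frozen=True)
class DescriptiveSummary:
    total_reports: int
    categories: dict[str, list[tuple[str, int, float]]]


def _tally(labels: Iterable[str], total: int, order: Sequence[str] | None = None):
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    if order is not None:
        keys = [k for k in order if k in counts]
    else:
        keys = sorted(counts, key=lambda k: (-counts[k], k))
    return [(k, counts[k], percent(counts[k], total)) for k in keys]


def _onset_days(report: Report, target_names: set[str] | None) -> int | None:
    """Earliest target-drug therapy start vs. the report's event date."""
    if target_names is None:
        seqs = None
    else:
        seqs = {
            d.drug_seq
            for d in report.drugs
            if d.drug_seq is not None
            and (
                normalize_term(d.drugname) in target_names
                or (d.prod_ai is not None and normalize_term(d.prod_ai) in target_names)
            )
        }
    starts = [
        t.start_dt
        for t in report.therapies
        if t.start_dt is not None and (seqs is None or t.dsg_drug_seq in seqs)
    ]
    if not starts:
        return None
    return time_to_onset_days(report.event_dt, min(starts))


def summarize_reports(
    reports: Sequence[Report],
    target_names: Iterable[str] | None = None,
) -> DescriptiveSummary:
    """Build the report-characteristics table for a deduplicated cohort.

    ``target_names`` (normalized drug names) restricts the time-to-onset
    computation to therapy rows of the target drug; when None, the earliest
    therapy start of any drug in the report is used.
    """
    total = len(reports)
    if total == 0:
        return DescriptiveSummary(total_reports=0, categories={})
    names = {normalize_term(n) for n in target_names} if target_names is not None else None

    sex = _tally(
        ({"F": "Female", "M": "Male"}.get(r.sex, "Unknown") for r in reports),
        total,
        order=("Female", "Male", "Unknown"),
    )
    age = _tally(
        (
            bin_age(age_in_years(r.age, r.age_unit) if r.age is not None else None)
            for r in reports
        ),
        total,
        order=AGE_BIN_LABELS,
    )
    reporter = _tally(
        (_REPORTER_LABELS.get(r.occp_cod, "Unknown") for r in reports),
        total,
        order=("Pharmacist", "Consumer", "Physician", "Other health professionals", "Unknown"),
    )
    country = _tally(
        ((r.occr_country or "Unknown") for r in reports),
        total,
    )
    year = _tally((str(r.report_year) for r in reports), total, order=None)
    year.sort(key=lambda row: row[0])

    outcome_labels: list[str] = []
    for r in reports:
        for cod in sorted(set(r.outcomes)):  # once per report per code
            if cod in OUTCOME_LABELS:
                outcome_labels.append(OUTCOME_LABELS[cod])
    outcomes = _tally(outcome_labels, total, order=tuple(OUTCOME_LABELS.values()))

    onset = _tally(
        (bin_onset(_onset_days(r, names)) for r in reports),
        total,
        order=ONSET_BIN_LABELS,
    )

    return DescriptiveSummary(
        total_reports=total,
        categories={
            "sex": sex,
            "age": age,
            "reporter": reporter,
            "country": country,
            "year": year,
            "outcomes": outcomes,
            "onset": onset,
        },
    )
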