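"""Reading and writing FAERS-quarterly-style delimited tables.

The quarterly ASCII dialect is one "$"-delimited header row followed by one
row per record, with no quoting; an embedded "$" inside a free-text field is
therefore not representable and not supported. Column names are matched
case-insensitively because header case varies across quarters. Rows whose
mandatory fields fail validation (e.g. a 7-digit FDA_DT) are skipped and
reported, never silently dropped.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import format_compact_date, parse_compact_date, round_half_up
from .records import (
    AGE_UNITS,
    OCCUPATION_CODES,
    OUTCOME_CODES,
    ROLE_CODES,
    SEX_CODES,
    DemoRecord,
    DrugRecord,
    OutcRecord,
    ReacRecord,
    TherRecord,
)

logger = logging.getLogger(__name__)

DELIMITER = "$"

# mandatory columns per table kind; aliases absorb header drift across quarters
_MANDATORY: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "drugname", "role_cod"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "ther": ("primaryid", "dsg_drug_seq"),
}
_ALIASES: dict[str, str] = {
    "age_cod": "age_unit",
    "gndr_cod": "sex",
    "sex": "sex",
    "outc_code": "outc_cod",
}


class TableFormatError(ValueError):
    """Raised when a table is missing a mandatory column for its kind."""


@dataclass(frozen=True)
class RowSkip:
    line: int
    reason: str


@dataclass(frozen=True)
class ParseResult:
    records: list
    skipped: list[RowSkip]


def _get(row: dict, col: str) -> str:
    v = row.get(col, "")
    return v.strip() if isinstance(v, str) else ("" if pd.isna(v) else str(v).strip())


def _opt(row: dict, col: str) -> str | None:
    v = _get(row, col)
    return v or None

def _code(row: dict, col: str, allowed: frozenset[str]) -> str | None:
    v = _opt(row, col)
    if v is None:
        return None
    v = v.upper()
    return v if v in allowed else None


def _int_or_none(row: dict, col: str) -> int | None:
    v = _opt(row, col)
    if v is None:
        return None
    try:
        return int(float(v))
    except ValueError:
        return None


def _demo_row(row: dict) -> DemoRecord:
    primaryid = _get(row, "primaryid")
    if not primaryid:
        raise ValueError("empty primaryid")
    fda_dt = parse_compact_date(_get(row, "fda_dt"))
    if fda_dt is None:
        raise ValueError("missing fda_dt")
    age_raw = _opt(row, "age")
    age = None
    if age_raw is not None:
        try:
            age = float(age_raw)
        except ValueError:
            age = None
    age_unit = _code(row, "age_unit", AGE_UNITS)
    if age_unit is None:
        age = None  # age without a unit is uninterpretable
    event_raw = _get(row, "event_dt")
    try:
        event_dt = parse_compact_date(event_raw, allow_partial=True)
    except ValueError:
        event_dt = None
    return DemoRecord(
        primaryid=primaryid,
        caseid=_get(row, "caseid"),
        fda_dt=fda_dt,
        event_dt=event_dt,
        age=age,
        age_unit=age_unit if age is not None else None,
        sex=_code(row, "sex", SEX_CODES),
        occp_cod=_code(row, "occp_cod", OCCUPATION_CODES),
        occr_country=_opt(row, "occr_country"),
    )


def _drug_row(row: dict) -> DrugRecord:
    name = _get(row, "drugname")
    if not name:
        raise ValueError("empty drugname")
    role = _get(row, "role_cod").upper()
    if role not in ROLE_CODES:
        raise ValueError(f"invalid role_cod {role!r}")
    return DrugRecord(
        primaryid=_get(row, "primaryid"),
        drugname=name,
        role_cod=role,
        prod_ai=_opt(row, "prod_ai"),
        drug_seq=_int_or_none(row, "drug_seq"),
    )


def _reac_row(row: dict) -> ReacRecord:
    pt = _get(row, "pt")
    if not pt:
        raise ValueError("empty pt")
    return ReacRecord(primaryid=_get(row, "primaryid"), pt=pt)


def _outc_row(row: dict) -> OutcRecord:
    cod = _get(row, "outc_cod").upper()
    if cod not in OUTCOME_CODES:
        raise ValueError(f"invalid outc_cod {cod!r}")
    return OutcRecord(primaryid=_get(row, "primaryid"), outc_cod=cod)


def _ther_row(row: dict) -> TherRecord:
    try:
        start_dt = parse_compact_date(_get(row, "start_dt"), allow_partial=True)
    except ValueError:
        start_dt = None
    return TherRecord(
        primaryid=_get(row, "primaryid"),
        dsg_drug_seq=_int_or_none(row, "dsg_drug_seq"),
        start_dt=start_dt,
    )


_ROW_PARSERS = {
    "demo": _demo_row,
    "drug": _drug_row,
    "reac": _reac_row,
    "outc": _outc_row,
    "ther": _ther_row,
}


def records_from_frame(frame: pd.DataFrame, kind: str, source: str = "<frame>") -> ParseResult:
    """Convert a string DataFrame in the quarterly dialect to typed records.

    Shared by file parsing and the synthetic generator, so that in-memory
    tables and their on-disk round trip produce identical records.
    """
    if kind not in _MANDATORY:
        raise ValueError(f"unknown table kind {kind!r}")
    frame = frame.rename(
        columns={c: _ALIASES.get(c.strip().lower(), c.strip().lower()) for c in frame.columns}
    )
    missing = [c for c in _MANDATORY[kind] if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{source}: missing mandatory column(s) {', '.join(missing)}")
    parser = _ROW_PARSERS[kind]
    records: list = []
    skipped: list[RowSkip] = []
    for idx, row in enumerate(frame.to_dict("records")):
        try:
            records.append(parser(row))
        except ValueError as exc:  # line 1 is the header
            skipped.append(RowSkip(line=idx + 2, reason=str(exc)))
    if skipped:
        logger.warning("%s: skipped %d malformed row(s)", source, len(skipped))
    return ParseResult(records=records, skipped=skipped)


def parse_table(path: str | Path, kind: str) -> ParseResult:
    """Parse one quarterly table, collecting per-row failures.

    Returns the parsed records plus a list of skipped rows with 1-based file
    line numbers, so that ``len(records) + len(skipped)`` equals the number
    of data lines in the file.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=DELIMITER, dtype=str, keep_default_na=False)
    return records_from_frame(frame, kind, source=str(path))


def read_table(path: str | Path, kind: str) -> list:
    """Read one quarterly table into typed records (skipped rows logged)."""
    return parse_table(path, kind).records


def read_deleted_cases(paths: Iterable[str | Path]) -> set[str]:
    """Union of case IDs across deleted-report list files (one ID per line)."""
    deleted: set[str] = set()
    for path in paths:
        text = Path(path).read_text()
        deleted.update(line.strip() for line in text.splitlines() if line.strip())
    return deleted


SIGNAL_TABLE_COLUMNS = (
    "level", "event", "soc_code", "a",
    "ror", "ror_low", "ror_high",
    "prr", "prr_low", "prr_high",
    "chi2", "ic_raw", "ic_expect", "ic025",
    "ebgm", "ebgm_low", "ebgm_high",
    "ror_signal", "prr_signal", "bcpnn_signal", "ebgm_signal", "all_four",
)


def _fmt(x: float) -> str:
    return f"{round_half_up(float(x), 2):.2f}"


def write_signal_table(results: Sequence, path: str | Path) -> None:
    """Write disproportionality results as CSV, statistics at 2 decimals."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SIGNAL_TABLE_COLUMNS)
        for r in results:
            writer.writerow([
                r.level, r.event,
                "" if r.soc_code is None else r.soc_code,
                r.a,
                _fmt(r.ror), _fmt(r.ror_ci[0]), _fmt(r.ror_ci[1]),
                _fmt(r.prr), _fmt(r.prr_ci[0]), _fmt(r.prr_ci[1]),
                _fmt(r.chi2), _fmt(r.ic_raw), _fmt(r.ic_expect), _fmt(r.ic025),
                _fmt(r.ebgm), _fmt(r.ebgm_ci[0]), _fmt(r.ebgm_ci[1]),
                r.flags.ror_signal, r.flags.prr_signal,
                r.flags.bcpnn_signal, r.flags.ebgm_signal, r.flags.all_four,
            ])


def write_descriptives_table(summary, path: str | Path) -> None:
    """Write a descriptive summary as CSV: section, label, count, percent."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["section", "label", "count", "percent"])
        for section, rows in summary.categories.items():
            for label, count, pct in rows:
                writer.writerow([section, label, count, f"{pct:.2f}"])


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame in the quarterly "$"-delimited dialect."""
    frame.to_csv(path, sep=DELIMITER, index=False)


__all__ = [
    "DELIMITER",
    "ParseResult",
    "RowSkip",
    "TableFormatError",
    "parse_table",
    "read_table",
    "read_deleted_cases",
    "write_signal_table",
    "write_descriptives_table",
    "write_table",
    "SIGNAL_TABLE_COLUMNS",
    "format_compact_date",
]
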