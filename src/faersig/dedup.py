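"""Case-level deduplication and deleted-case removal.

FAERS publishes one row per report *version*; the FDA-recommended cleaning
keeps, per CASEID, the version with the latest FDA receipt date, breaking
receipt-date ties by the largest PRIMARYID (numeric-aware). Deleted-case
lists shipped with each quarter are applied after deduplication and remove
the whole case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import id_sort_key
from .records import DemoRecord


@dataclass(frozen=True)
class DedupOutcome:
    kept: list[DemoRecord]
    removed_as_duplicate: int
    removed_as_deleted: int


def deduplicate_reports(records: Sequence[DemoRecord]) -> DedupOutcome:
    """Keep one version per case: latest fda_dt, then largest primaryid.

    Output is sorted by caseid (numeric-aware) so the result is independent
    of input row order.
    """
    best: dict[str, DemoRecord] = {}
    for rec in records:
        cur = best.get(rec.caseid)
        if cur is None or (rec.fda_dt, id_sort_key(rec.primaryid)) > (
            cur.fda_dt,
            id_sort_key(cur.primaryid),
        ):
            best[rec.caseid] = rec
    kept = sorted(best.values(), key=lambda r: id_sort_key(r.caseid))
    return DedupOutcome(
        kept=kept,
        removed_as_duplicate=len(records) - len(kept),
        removed_as_deleted=0,
    )


def drop_deleted(records: Sequence[DemoRecord], deleted: Iterable[str]) -> list[DemoRecord]:
    """Remove every record whose caseid appears in the deleted-case list."""
    deleted = set(deleted)
    return [r for r in records if r.caseid not in deleted]


def clean_reports(records: Sequence[DemoRecord], deleted: Iterable[str]) -> DedupOutcome:
    """Deduplicate, then remove deleted cases; account for every input row."""
    outcome = deduplicate_reports(records)
    kept = drop_deleted(outcome.kept, deleted)
    return DedupOutcome(
        kept=kept,
        removed_as_duplicate=outcome.removed_as_duplicate,
        removed_as_deleted=len(outcome.kept) - len(kept),
    )
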