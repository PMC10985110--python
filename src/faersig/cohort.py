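"""Target-drug cohort construction, term normalization, and PT/SOC pair counts.

The disproportionality 2x2 tables count unique (report, event) pairs: a
report mentioning the same preferred term (PT) twice contributes once, and
at system-organ-class (SOC) level a report with several PTs in one SOC
contributes once to that SOC. Reports are classified as target-drug reports
when any drug row matches a target name (drugname or active ingredient,
after normalization) in an accepted suspect role — by default primary
suspect only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._util import id_sort_key
from .records import DemoRecord, DrugRecord, OutcRecord, ReacRecord, Report, TherRecord

logger = logging.getLogger(__name__)

UNMAPPED_SOC = "UNMAPPED"


def normalize_term(raw: str) -> str:
    """Trim, collapse internal whitespace, and uppercase a free-text term."""
    return " ".join(raw.split()).upper()


@dataclass(frozen=True)
class Vocabulary:
    """PT -> primary SOC mapping (MedDRA-style, one SOC per PT)."""

    pt_to_soc: Mapping[str, tuple[str, int]]

    @classmethod
    def from_file(cls, path: str | Path) -> "Vocabulary":
        """Load a tab-separated mapping with columns pt, soc_name, soc_code."""
        mapping: dict[str, tuple[str, int]] = {}
        lines = Path(path).read_text().splitlines()
        for i, line in enumerate(lines):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{i + 1}: expected 3 tab-separated columns")
            if i == 0 and parts[0].strip().lower() == "pt":
                continue
            pt, soc_name, soc_code = (p.strip() for p in parts)
            mapping[normalize_term(pt)] = (normalize_term(soc_name), int(soc_code))
        return cls(pt_to_soc=mapping)

    def soc_of(self, pt: str) -> tuple[str, int] | None:
        return self.pt_to_soc.get(normalize_term(pt))

    @property
    def soc_codes(self) -> dict[str, int]:
        return {name: code for name, code in self.pt_to_soc.values()}


def load_synonyms(path: str | Path) -> set[str]:
    """Load a drug-synonym list (one name per line) as normalized names."""
    return {
        normalize_term(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def select_target_reports(
    drugs: Sequence[DrugRecord],
    names: Iterable[str],
    roles: Iterable[str] = ("PS",),
) -> set[str]:
    """Primaryids whose any drug row matches a target name in an accepted role."""
    names = {normalize_term(n) for n in names}
    if not names:
        raise ValueError("target drug name set must be non-empty")
    roles = set(roles)
    out: set[str] = set()
    for d in drugs:
        if d.role_cod not in roles:
            continue
        if normalize_term(d.drugname) in names or (
            d.prod_ai is not None and normalize_term(d.prod_ai) in names
        ):
            out.add(d.primaryid)
    return out


@dataclass(frozen=True)
class PairCounts:
    """Unique (report, event) pair counts split by target-drug status."""

    level: str  # "pt" or "soc"
    target_event_counts: dict[str, int]
    other_event_counts: dict[str, int]
    n_target_pairs: int
    n_other_pairs: int


def _events_for_report(pts: Iterable[str], vocab: Vocabulary | None, level: str) -> set[str]:
    terms = {normalize_term(p) for p in pts if p.strip()}
    if level == "pt":
        return terms
    events: set[str] = set()
    for t in terms:
        hit = vocab.soc_of(t) if vocab is not None else None
        if hit is None:
            events.add(UNMAPPED_SOC)
        else:
            events.add(hit[0])
    return events


def build_pair_counts(
    kept_reports: Sequence,
    target_ids: set[str],
    reac: Sequence[ReacRecord],
    vocab: Vocabulary | None,
    level: str = "pt",
) -> PairCounts:
    """Count unique (report, event) pairs at PT or SOC level.

    ``kept_reports`` may be DemoRecord/Report objects or bare primaryid
    strings; only reactions belonging to kept reports are counted. PTs
    missing from the vocabulary at SOC level are pooled under ``UNMAPPED``
    (with a warning) so the 2x2 margins stay intact.
    """
    if level not in ("pt", "soc"):
        raise ValueError(f"level must be 'pt' or 'soc', got {level!r}")
    kept_ids = {r if isinstance(r, str) else r.primaryid for r in kept_reports}
    pts_by_report: dict[str, list[str]] = {}
    for rec in reac:
        if rec.primaryid in kept_ids:
            pts_by_report.setdefault(rec.primaryid, []).append(rec.pt)

    target_counts: dict[str, int] = {}
    other_counts: dict[str, int] = {}
    n_unmapped = 0
    for pid, pts in pts_by_report.items():
        events = _events_for_report(pts, vocab, level)
        if UNMAPPED_SOC in events:
            n_unmapped += 1
        counts = target_counts if pid in target_ids else other_counts
        for ev in events:
            counts[ev] = counts.get(ev, 0) + 1
    if level == "soc" and n_unmapped:
        logger.warning("%d report(s) had PTs missing from the vocabulary (pooled as UNMAPPED)", n_unmapped)
    return PairCounts(
        level=level,
        target_event_counts=target_counts,
        other_event_counts=other_counts,
        n_target_pairs=sum(target_counts.values()),
        n_other_pairs=sum(other_counts.values()),
    )


def assemble_reports(
    demo: Sequence[DemoRecord],
    drugs: Sequence[DrugRecord] = (),
    reac: Sequence[ReacRecord] = (),
    outc: Sequence[OutcRecord] = (),
    ther: Sequence[TherRecord] = (),
) -> list[Report]:
    """Attach child rows to deduplicated DEMO records, dropping orphans.

    Child rows whose primaryid belongs to a discarded report version are
    dropped along with it.
    """
    by_pid: dict[str, dict[str, list]] = {
        d.primaryid: {"drugs": [], "pts": [], "outcomes": [], "ther": []} for d in demo
    }
    for d in drugs:
        if d.primaryid in by_pid:
            by_pid[d.primaryid]["drugs"].append(d)
    for r in reac:
        if r.primaryid in by_pid:
            by_pid[r.primaryid]["pts"].append(r.pt)
    for o in outc:
        if o.primaryid in by_pid:
            by_pid[o.primaryid]["outcomes"].append(o.outc_cod)
    for t in ther:
        if t.primaryid in by_pid:
            by_pid[t.primaryid]["ther"].append(t)
    reports = []
    for d in demo:
        child = by_pid[d.primaryid]
        reports.append(
            Report(
                primaryid=d.primaryid,
                caseid=d.caseid,
                fda_dt=d.fda_dt,
                event_dt=d.event_dt,
                age=d.age,
                age_unit=d.age_unit,
                sex=d.sex,
                occp_cod=d.occp_cod,
                occr_country=d.occr_country,
                drugs=tuple(child["drugs"]),
                pts=tuple(child["pts"]),
                outcomes=tuple(child["outcomes"]),
                therapies=tuple(child["ther"]),
            )
        )
    reports.sort(key=lambda r: id_sort_key(r.caseid))
    return reports
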