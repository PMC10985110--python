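"""End-to-end analysis: raw quarterly tables to descriptive and signal CSVs.

Flow: read tables -> deduplicate case versions -> drop deleted cases ->
select target-drug reports (primary suspect) -> count unique (report, event)
pairs -> descriptive summary of the target cohort -> disproportionality
statistics per PT and/or SOC -> write CSVs. Stage counts are logged in a
machine-readable form (``stage=<name> in=<n> out=<m>``) and written to
``run.log`` in the output directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import io as fio
from .cohort import (
    Vocabulary,
    assemble_reports,
    build_pair_counts,
    load_synonyms,
    select_target_reports,
)
from .dedup import clean_reports
from .descriptives import summarize_reports
from .stats import BcpnnHyperparameters, SignalCriteria, analyze_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    demo: Sequence[str | Path]
    drug: Sequence[str | Path]
    reac: Sequence[str | Path]
    outc: Sequence[str | Path] = ()
    ther: Sequence[str | Path] = ()
    deleted: Sequence[str | Path] = ()
    vocabulary: str | Path | None = None
    synonyms: str | Path | None = None
    drug_names: Sequence[str] = ()
    roles: Sequence[str] = ("PS",)
    level: str = "both"  # pt, soc, or both
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    bcpnn: BcpnnHyperparameters = field(default_factory=BcpnnHyperparameters)
    yates: bool = False
    outdir: str | Path = "."

    def target_names(self) -> set[str]:
        names = set(self.drug_names)
        if self.synonyms is not None:
            names |= load_synonyms(self.synonyms)
        if not names:
            raise ValueError("no target drug names given (use drug_names or a synonym file)")
        return names


def _read_many(paths: Sequence[str | Path], kind: str) -> list:
    records: list = []
    for p in paths:
        records.extend(fio.read_table(p, kind))
    return records


def run_analysis(cfg: RunConfig) -> dict[str, int]:
    """Execute the full pipeline; returns the stage-count ledger."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    def stage(name: str, n_in: int, n_out: int) -> None:
        line = f"stage={name} in={n_in} out={n_out}"
        stages.append(line)
        logger.info(line)

    demo = _read_many(cfg.demo, "demo")
    drug = _read_many(cfg.drug, "drug")
    reac = _read_many(cfg.reac, "reac")
    outc = _read_many(cfg.outc, "outc")
    ther = _read_many(cfg.ther, "ther")
    stage("read_demo", len(demo), len(demo))
    deleted = fio.read_deleted_cases(cfg.deleted) if cfg.deleted else set()

    outcome = clean_reports(demo, deleted)
    stage("dedup", len(demo), len(demo) - outcome.removed_as_duplicate)
    stage(
        "drop_deleted",
        len(demo) - outcome.removed_as_duplicate,
        len(outcome.kept),
    )
    kept = outcome.kept

    names = cfg.target_names()
    kept_ids = {r.primaryid for r in kept}
    target_ids = select_target_reports(
        [d for d in drug if d.primaryid in kept_ids], names, cfg.roles
    )
    stage("select_target", len(kept), len(target_ids))

    reports = assemble_reports(kept, drug, reac, outc, ther)
    target_reports = [r for r in reports if r.primaryid in target_ids]
    summary = summarize_reports(target_reports, target_names=names)
    fio.write_descriptives_table(summary, outdir / "descriptives.csv")

    vocab = Vocabulary.from_file(cfg.vocabulary) if cfg.vocabulary else None
    ledger = {
        "reports_read": len(demo),
        "duplicates_removed": outcome.removed_as_duplicate,
        "deleted_removed": outcome.removed_as_deleted,
        "kept": len(kept),
        "target_reports": len(target_ids),
    }
    levels = ("pt", "soc") if cfg.level == "both" else (cfg.level,)
    for level in levels:
        pc = build_pair_counts(kept, target_ids, reac, vocab, level=level)
        stage(f"pairs_{level}", len(kept), pc.n_target_pairs + pc.n_other_pairs)
        results = analyze_all(pc, crit=cfg.criteria, hp=cfg.bcpnn, yates=cfg.yates, vocab=vocab)
        fio.write_signal_table(results, outdir / f"signals_{level}.csv")
        ledger[f"{level}_pairs"] = pc.n_target_pairs + pc.n_other_pairs
        ledger[f"{level}_events"] = len(results)

    (outdir / "run.log").write_text("".join(s + "\n" for s in stages))
    return ledger
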