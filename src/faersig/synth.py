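"""Synthetic FAERS-like data with known ground truth.

The generator emulates the structural features of FAERS quarterly extracts
that the pipeline must survive: duplicate case versions across quarters,
quarterly deleted-case lists, primary-suspect role codes, very heavy
demographic missingness (about 98.5% unknown sex/age, pharmacist-dominated
reporting), multi-PT reports, and configurable drug-event reporting-rate
multipliers used as parameter-recovery targets.

Generative model, per base report:

1. A primary-suspect (PS) drug: the target drug with probability
   ``target_prevalence``, otherwise a comparator drawn from ``drug_vocab``;
   plus a Poisson number of concomitant (role C) drugs.
2. K preferred terms, K = 1 + Poisson(pts_per_report_mean - 1) truncated at
   ``pts_per_report_max``, drawn i.i.d. from the event vocabulary. Reports
   whose PS drug has entries in ``signal_effects`` draw from the tilted
   distribution p_j * rho_j / sum_k(p_k * rho_k); within-report repeats are
   allowed (the pipeline deduplicates report-event pairs).
3. Demographics, outcomes, and therapy/event dates with configurable
   per-field missingness.
4. With probability ``duplicate_rate`` the case gains a second version with
   a strictly later FDA receipt date and a larger PRIMARYID (or the same
   receipt date when ``tie_mode`` is set, to exercise the PRIMARYID
   tie-break); with probability ``deleted_rate`` the case is listed in the
   deleted-case file.

The same seed always yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio

_EPOCH = np.datetime64("2019-07-01")

_DEFAULT_SOCS: tuple[tuple[str, int], ...] = (
    ("NERVOUS SYSTEM DISORDERS", 10029205),
    ("PSYCHIATRIC DISORDERS", 10037175),
    ("GASTROINTESTINAL DISORDERS", 10017947),
    ("GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS", 10018065),
    ("INJURY, POISONING AND PROCEDURAL COMPLICATIONS", 10022117),
    ("SURGICAL AND MEDICAL PROCEDURES", 10042613),
    ("CARDIAC DISORDERS", 10007541),
    ("INVESTIGATIONS", 10022891),
)


def default_event_vocab() -> tuple[tuple[str, str, int, float], ...]:
    """(pt, soc_name, soc_code, baseline probability) for 64 synthetic PTs.

    Sixty common PTs follow a Zipf-like frequency profile; four rare PTs
    (baseline 2e-3) are reserved as clean signal-injection targets — rare
    enough that tilting them leaves the rest of the distribution almost
    untouched, common enough that injected signals accumulate double-digit
    case counts in cohorts of a few tens of thousands of reports.
    """
    weights = [1.0 / (k + 5) for k in range(60)]
    entries = []
    for k, w in enumerate(weights):
        soc_name, soc_code = _DEFAULT_SOCS[k % len(_DEFAULT_SOCS)]
        entries.append((f"PT_{k + 1:03d}", soc_name, soc_code, w))
    total_common = sum(w for *_, w in entries)
    rare_w = 0.002 / (1 - 4 * 0.002) * total_common  # -> 2e-3 after normalization
    for j in range(4):
        soc_name, soc_code = _DEFAULT_SOCS[j]
        entries.append((f"PT_RARE_{j + 1}", soc_name, soc_code, rare_w))
    total = sum(w for *_, w in entries)
    return tuple((pt, sn, sc, w / total) for pt, sn, sc, w in entries)


def default_drug_vocab() -> tuple[tuple[str, float], ...]:
    """Comparator drug names with Zipf-like marginal probabilities."""
    weights = [1.0 / (k + 2) for k in range(20)]
    total = sum(weights)
    return tuple((f"DRUG_{k + 1:02d}", w / total) for k, w in enumerate(weights))


def _default_missingness() -> dict[str, float]:
    # sex/age/occupation/country levels mirror the heavy missingness of
    # spontaneous-report demographics; date missingness is set so about a
    # quarter of reports have a computable time to onset
    return {
        "sex": 0.985,
        "age": 0.985,
        "occupation": 0.003,
        "country": 0.003,
        "event_dt": 0.40,
        "start_dt": 0.60,
    }


@dataclass
class SyntheticConfig:
    n_reports: int = 50_000
    n_quarters: int = 15  # receipt-date window, ~91 days per quarter
    duplicate_rate: float = 0.05
    deleted_rate: float = 0.01
    target_drug: str = "ISTRADEFYLLINE"
    target_synonyms: tuple[str, ...] = ("ISTRADEFYLLINE", "NOURIANZ")
    target_prevalence: float = 0.02
    drug_vocab: tuple[tuple[str, float], ...] = field(default_factory=default_drug_vocab)
    event_vocab: tuple[tuple[str, str, int, float], ...] = field(
        default_factory=default_event_vocab
    )
    signal_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    pts_per_report_mean: float = 3.0
    pts_per_report_max: int = 10
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    tie_mode: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if self.n_quarters <= 0:
            raise ValueError("n_quarters must be positive")
        for name in ("duplicate_rate", "deleted_rate", "target_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.drug_vocab:
            raise ValueError("drug_vocab must be non-empty")
        if not self.event_vocab:
            raise ValueError("event_vocab must be non-empty")
        if any(p < 0 for _, p in self.drug_vocab):
            raise ValueError("drug_vocab probabilities must be non-negative")
        if any(p < 0 for *_, p in self.event_vocab):
            raise ValueError("event_vocab probabilities must be non-negative")
        if any(rho <= 0 for rho in self.signal_effects.values()):
            raise ValueError("signal_effects multipliers must be positive")
        known_pts = {pt for pt, *_ in self.event_vocab}
        for _, pt in self.signal_effects:
            if pt not in known_pts:
                raise ValueError(f"signal_effects references unknown pt {pt!r}")
        if self.pts_per_report_mean < 1:
            raise ValueError("pts_per_report_mean must be >= 1")
        if self.pts_per_report_max < 1:
            raise ValueError("pts_per_report_max must be >= 1")
        for k, v in self.missingness.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"missingness[{k!r}] must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        """Load a config from YAML; signal_effects as a list of {drug, pt, rho}."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        effects = raw.pop("signal_effects", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**raw)
        if effects:
            cfg.signal_effects = {
                (e["drug"], e["pt"]): float(e["rho"]) for e in effects
            }
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth bookkeeping emitted alongside a synthetic dataset."""

    expected_rates: dict[tuple[str, str], float]
    duplicate_caseids: tuple[str, ...]
    deleted_caseids: tuple[str, ...]
    target_caseids: tuple[str, ...]
    n_reports: int


def expected_pair_rates(cfg: SyntheticConfig) -> dict[tuple[str, str], float]:
    """Closed-form expected relative reporting rate per (drug, pt) pair.

    For a drug with multipliers rho_j, its per-draw PT probability is
    p_j*rho_j / Z with Z = sum_k p_k*rho_k, so the rate relative to the
    baseline reporting process is rho_j / Z (1 for every PT when the drug
    has no effects).
    """
    pts = [pt for pt, *_ in cfg.event_vocab]
    probs = np.array([p for *_, p in cfg.event_vocab], dtype=float)
    probs = probs / probs.sum()
    drugs = {d for d, _ in cfg.signal_effects} or {cfg.target_drug}
    out: dict[tuple[str, str], float] = {}
    for drug in sorted(drugs):
        rho = np.ones(len(pts))
        for j, pt in enumerate(pts):
            rho[j] = cfg.signal_effects.get((drug, pt), 1.0)
        z = float(np.sum(probs * rho))
        for j, pt in enumerate(pts):
            out[(drug, pt)] = float(rho[j] / z)
    return out


def _dates_to_str(days: np.ndarray, missing: np.ndarray | None = None) -> np.ndarray:
    if days.size == 0:
        return np.array([], dtype="<U8")
    dates = _EPOCH + days.astype("timedelta64[D]")
    s = np.char.replace(np.datetime_as_string(dates, unit="D"), "-", "")
    if missing is not None:
        s = np.where(missing, "", s)
    return s


def sample_tables(cfg: SyntheticConfig) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Draw one synthetic dataset as in-memory string DataFrames plus truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    m = cfg.missingness

    caseids = np.arange(1_000_001, 1_000_001 + n)
    primaryids = caseids * 10 + 1
    window = cfg.n_quarters * 91
    fda_days = rng.integers(0, window, size=n)

    # --- drugs -----------------------------------------------------------
    is_target = rng.random(n) < cfg.target_prevalence
    comp_names = np.array([d for d, _ in cfg.drug_vocab])
    comp_p = np.array([p for _, p in cfg.drug_vocab], dtype=float)
    comp_p = comp_p / comp_p.sum()
    ps_drug = comp_names[rng.choice(len(comp_names), size=n, p=comp_p)]
    synonyms = np.array(cfg.target_synonyms)
    target_names = synonyms[rng.integers(0, len(synonyms), size=n)]
    ps_drugname = np.where(is_target, target_names, ps_drug)
    ps_ai = np.where(is_target, cfg.target_drug, ps_drug)
    ps_key = np.where(is_target, cfg.target_drug, ps_drug)  # effect lookup key

    n_con = rng.poisson(0.7, size=n)
    con_report = np.repeat(np.arange(n), n_con)
    con_drug = comp_names[rng.choice(len(comp_names), size=con_report.size, p=comp_p)]
    con_seq = np.concatenate([np.arange(2, 2 + k) for k in n_con]) if n_con.sum() else np.array([], dtype=int)

    # --- reactions -------------------------------------------------------
    pts = np.array([pt for pt, *_ in cfg.event_vocab])
    base_p = np.array([p for *_, p in cfg.event_vocab], dtype=float)
    base_p = base_p / base_p.sum()
    k_pts = np.minimum(
        1 + rng.poisson(cfg.pts_per_report_mean - 1.0, size=n), cfg.pts_per_report_max
    )
    reac_report = np.repeat(np.arange(n), k_pts)
    reac_idx = rng.choice(len(pts), size=reac_report.size, p=base_p)
    effect_drugs = sorted({d for d, _ in cfg.signal_effects})
    for drug in effect_drugs:
        tilt = base_p.copy()
        for j, pt in enumerate(pts):
            tilt[j] *= cfg.signal_effects.get((drug, str(pt)), 1.0)
        tilt = tilt / tilt.sum()
        rows = np.flatnonzero(ps_key[reac_report] == drug)
        if rows.size:
            reac_idx[rows] = rng.choice(len(pts), size=rows.size, p=tilt)

    # --- demographics ----------------------------------------------------
    sex = np.where(rng.random(n) < 1 / 3, "F", "M")
    sex = np.where(rng.random(n) < m["sex"], "", sex)
    age_years = np.clip(np.round(rng.normal(72, 12, size=n)), 1, 100).astype(int)
    use_mon = rng.random(n) < 0.1
    age_val = np.where(use_mon, age_years * 12, age_years).astype(str)
    age_cod = np.where(use_mon, "MON", "YR")
    age_missing = rng.random(n) < m["age"]
    age_val = np.where(age_missing, "", age_val)
    age_cod = np.where(age_missing, "", age_cod)
    occ_codes = np.array(["PH", "CN", "MD", "HP", "OT"])
    occ_p = np.array([0.88, 0.084, 0.017, 0.010, 0.009])
    occp = occ_codes[rng.choice(5, size=n, p=occ_p / occ_p.sum())]
    occp = np.where(rng.random(n) < m["occupation"], "", occp)
    ctry_codes = np.array(["US", "JP", "DE"])
    ctry = ctry_codes[rng.choice(3, size=n, p=[0.988, 0.009, 0.003])]
    ctry = np.where(rng.random(n) < m["country"], "", ctry)

    # --- dates -----------------------------------------------------------
    start_lag = rng.exponential(120, size=n).astype(int) + 1
    start_days = fda_days - start_lag
    onset = rng.exponential(60, size=n).astype(int)
    event_days = start_days + onset
    start_missing = rng.random(n) < m["start_dt"]
    event_missing = rng.random(n) < m["event_dt"]

    # --- outcomes --------------------------------------------------------
    outc_rows: list[tuple[np.ndarray, str]] = []
    for cod, p in (("DE", 0.107), ("HO", 0.082), ("DS", 0.003), ("LT", 0.002), ("OT", 0.10)):
        mask = np.flatnonzero(rng.random(n) < p)
        outc_rows.append((mask, cod))

    # --- duplicates and deletions ---------------------------------------
    dup = np.flatnonzero(rng.random(n) < cfg.duplicate_rate)
    dup_pids = caseids[dup] * 10 + 2
    if cfg.tie_mode:
        dup_fda = fda_days[dup]
    else:
        dup_fda = fda_days[dup] + rng.integers(1, 120, size=dup.size)
    deleted = np.flatnonzero(rng.random(n) < cfg.deleted_rate)

    # --- assemble string frames ------------------------------------------
    pid_str = primaryids.astype(str)
    case_str = caseids.astype(str)
    demo = pd.DataFrame(
        {
            "primaryid": np.concatenate([pid_str, dup_pids.astype(str)]),
            "caseid": np.concatenate([case_str, case_str[dup]]),
            "fda_dt": np.concatenate(
                [_dates_to_str(fda_days), _dates_to_str(dup_fda)]
            ),
            "event_dt": np.concatenate(
                [
                    _dates_to_str(event_days, event_missing),
                    _dates_to_str(event_days[dup], event_missing[dup]),
                ]
            ),
            "age": np.concatenate([age_val, age_val[dup]]),
            "age_cod": np.concatenate([age_cod, age_cod[dup]]),
            "sex": np.concatenate([sex, sex[dup]]),
            "occp_cod": np.concatenate([occp, occp[dup]]),
            "occr_country": np.concatenate([ctry, ctry[dup]]),
        }
    )

    def _with_dups(report_idx: np.ndarray, cols: dict[str, np.ndarray]) -> pd.DataFrame:
        in_dup = np.isin(report_idx, dup)
        dup_rows = np.flatnonzero(in_dup)
        dup_pid_of = dict(zip(dup.tolist(), dup_pids.astype(str).tolist()))
        frame_cols = {
            "primaryid": np.concatenate(
                [
                    pid_str[report_idx],
                    np.array([dup_pid_of[i] for i in report_idx[dup_rows]], dtype=object),
                ]
            )
        }
        for name, arr in cols.items():
            frame_cols[name] = np.concatenate([arr, arr[dup_rows]])
        return pd.DataFrame(frame_cols)

    drug_idx = np.concatenate([np.arange(n), con_report])
    drug = _with_dups(
        drug_idx,
        {
            "drug_seq": np.concatenate(
                [np.ones(n, dtype=int), con_seq]
            ).astype(str),
            "drugname": np.concatenate([ps_drugname, con_drug]),
            "prod_ai": np.concatenate([ps_ai, con_drug]),
            "role_cod": np.concatenate(
                [np.full(n, "PS"), np.full(con_report.size, "C")]
            ),
        },
    )
    reac = _with_dups(reac_report, {"pt": pts[reac_idx]})
    outc_idx = np.concatenate([idx for idx, _ in outc_rows])
    outc_cod = np.concatenate(
        [np.full(idx.size, cod) for idx, cod in outc_rows]
    )
    outc = _with_dups(outc_idx, {"outc_cod": outc_cod})
    ther = _with_dups(
        np.arange(n),
        {
            "dsg_drug_seq": np.ones(n, dtype=int).astype(str),
            "start_dt": _dates_to_str(start_days, start_missing),
        },
    )

    truth = SyntheticTruth(
        expected_rates=expected_pair_rates(cfg),
        duplicate_caseids=tuple(case_str[dup]),
        deleted_caseids=tuple(case_str[deleted]),
        target_caseids=tuple(case_str[is_target]),
        n_reports=n,
    )
    frames = {"demo": demo, "drug": drug, "reac": reac, "outc": outc, "ther": ther}
    return frames, truth


def sample_records(cfg: SyntheticConfig) -> tuple[dict[str, list], SyntheticTruth]:
    """Draw one dataset directly as typed records (no disk round trip)."""
    frames, truth = sample_tables(cfg)
    records = {
        kind: fio.records_from_frame(frame, kind, source=f"<synthetic {kind}>").records
        for kind, frame in frames.items()
    }
    return records, truth


def write_vocabulary(cfg: SyntheticConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pt\tsoc_name\tsoc_code\n")
        for pt, soc_name, soc_code, _ in cfg.event_vocab:
            fh.write(f"{pt}\t{soc_name}\t{soc_code}\n")


def generate_dataset(cfg: SyntheticConfig, outdir: str | Path) -> SyntheticTruth:
    """Write a full synthetic dataset in the quarterly dialect.

    Emits demo/drug/reac/outc/ther tables, a deleted-case list, a PT->SOC
    vocabulary, and a target-drug synonym list. Identical seeds yield
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames, truth = sample_tables(cfg)
    for kind, frame in frames.items():
        fio.write_table(frame, outdir / f"{kind}.txt")
    (outdir / "deleted_cases.txt").write_text(
        "".join(f"{c}\n" for c in truth.deleted_caseids)
    )
    write_vocabulary(cfg, outdir / "vocabulary.tsv")
    (outdir / "synonyms.txt").write_text(
        "".join(f"{s}\n" for s in cfg.target_synonyms)
    )
    return truth
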