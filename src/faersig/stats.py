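"""Disproportionality statistics for 2x2 reporting tables.

For a drug-event pair, the table cells are

    a  reports with the target drug and the target event
    b  reports with the target drug and other events
    c  reports with other drugs and the target event
    d  reports with other drugs and other events

and N = a+b+c+d. Four screening statistics are computed:

* ROR = ad/bc with a Woolf log-normal 95% CI.
* PRR = (a/(a+b)) / (c/(c+d)) with its log-normal 95% CI.
* BCPNN information component: the raw IC is log2 of the observed-to-
  expected joint reporting probability, IC = log2(aN/((a+b)(a+c))); the
  Bayesian posterior expectation E(IC) and variance V(IC) use Dirichlet
  prior counts (gamma11, alpha, alpha1, beta, beta1), and the screening
  bound is IC025 = E(IC) - 2*sqrt(V(IC)).
* EBGM, here the unshrunk observed/expected relative reporting ratio
  aN/((a+b)(a+c)) (identical to 2**IC_raw), with the same log-normal CI
  form as the ROR; no gamma-mixture shrinkage is applied.

Default signal thresholds: ROR/PRR require a >= 3 and CI lower bound > 1;
BCPNN requires IC025 > 0; EBGM requires EBGM05 (CI lower bound) > 2.

Zero-cell policy: any statistic whose formula would divide by a zero cell
is computed on a Haldane-Anscombe corrected table (+0.5 to all four cells,
for that statistic only) and flagged ``corrected``. The raw IC is always
computed from the uncorrected cells (it is -inf when a = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from ._util import id_sort_key

Z95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane-Anscombe +0.5 correction applied to all four cells."""
        return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class BcpnnHyperparameters:
    """Dirichlet prior counts for the BCPNN posterior (classical defaults)."""

    gamma11: float = 1.0
    alpha: float = 2.0
    alpha1: float = 1.0
    beta: float = 2.0
    beta1: float = 1.0

    def __post_init__(self) -> None:
        if min(self.gamma11, self.alpha, self.alpha1, self.beta, self.beta1) <= 0:
            raise ValueError("BCPNN prior counts must be positive")


@dataclass(frozen=True)
class SignalCriteria:
    min_a: int = 3
    ror_ci_low_gt: float = 1.0
    prr_ci_low_gt: float = 1.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


class EstimateCI(NamedTuple):
    value: float
    low: float
    high: float
    corrected: bool


class BcpnnResult(NamedTuple):
    ic_raw: float
    ic_expect: float
    ic_var: float
    ic025: float
    degenerate: bool


class SignalFlags(NamedTuple):
    ror_signal: bool
    prr_signal: bool
    bcpnn_signal: bool
    ebgm_signal: bool
    all_four: bool


def build_contingency(pc, event: str) -> ContingencyTable:
    """2x2 table for one event from pair counts (unique report-event pairs)."""
    a = pc.target_event_counts.get(event, 0)
    c = pc.other_event_counts.get(event, 0)
    return ContingencyTable(a=a, b=pc.n_target_pairs - a, c=c, d=pc.n_other_pairs - c)


def _needs_correction(ct: ContingencyTable) -> bool:
    return min(ct.a, ct.b, ct.c, ct.d) == 0


def _log_ci(point: float, se: float) -> tuple[float, float]:
    log = math.log(point)
    return (math.exp(log - Z95 * se), math.exp(log + Z95 * se))


def compute_ror(ct: ContingencyTable) -> EstimateCI:
    """Reporting odds ratio ad/bc with Woolf 95% CI."""
    corrected = _needs_correction(ct)
    a, b, c, d = ct.corrected() if corrected else (ct.a, ct.b, ct.c, ct.d)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    low, high = _log_ci(ror, se)
    return EstimateCI(ror, low, high, corrected)


def compute_prr(ct: ContingencyTable) -> EstimateCI:
    """Proportional reporting ratio with log-normal 95% CI."""
    corrected = _needs_correction(ct)
    a, b, c, d = ct.corrected() if corrected else (ct.a, ct.b, ct.c, ct.d)
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    low, high = _log_ci(prr, se)
    return EstimateCI(prr, low, high, corrected)


def compute_chi2(ct: ContingencyTable, yates: bool = False) -> tuple[float, bool]:
    """Pearson chi-squared of the 2x2 table; optionally Yates-corrected.

    Returns (chi2, degenerate); a zero margin makes the statistic undefined
    and yields (0.0, True) by convention.
    """
    a, b, c, d = ct.a, ct.b, ct.c, ct.d
    n = ct.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, True
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    return n * diff * diff / denom, False


def compute_bcpnn(
    ct: ContingencyTable, hp: BcpnnHyperparameters = BcpnnHyperparameters()
) -> BcpnnResult:
    """BCPNN information component with posterior expectation and variance.

    gamma, the joint-cell prior count, is tied to the margins so that the
    prior is centred on independence:
    gamma = gamma11*(N+alpha)(N+beta)/((a+b+alpha1)(a+c+beta1)).
    """
    a, b, c, d = ct.a, ct.b, ct.c, ct.d
    n = ct.n
    drug_margin = a + b
    event_margin = a + c
    degenerate = drug_margin == 0 or event_margin == 0
    if degenerate:
        ic_raw = math.nan
    elif a == 0:
        ic_raw = -math.inf
    else:
        ic_raw = math.log2(a * n / (drug_margin * event_margin))

    g11, al, al1, be, be1 = hp.gamma11, hp.alpha, hp.alpha1, hp.beta, hp.beta1
    gamma = g11 * (n + al) * (n + be) / ((drug_margin + al1) * (event_margin + be1))
    ic_expect = math.log2(
        (a + g11) * (n + al) * (n + be)
        / ((n + gamma) * (drug_margin + al1) * (event_margin + be1))
    )
    ic_var = (1 / math.log(2) ** 2) * (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - drug_margin + al - al1) / ((drug_margin + al1) * (1 + n + al))
        + (n - event_margin + be - be1) / ((event_margin + be1) * (1 + n + be))
    )
    ic025 = ic_expect - 2 * math.sqrt(ic_var)
    return BcpnnResult(ic_raw, ic_expect, ic_var, ic025, degenerate)


def ic_expect_large_n(a: float, ebgm: float, gamma11: float = 1.0) -> float:
    """Large-N limit of E(IC) at fixed case count a and observed/expected ratio.

    As N grows with lambda = aN/((a+b)(a+c)) held fixed, gamma -> gamma11 *
    lambda * N / a, and E(IC) -> log2((a+gamma11)*lambda/(a+gamma11*lambda))
    — with gamma11 = 1, log2((a+1)*lambda/(a+lambda)). This lets E(IC) be
    recovered from a published (a, EBGM) pair without the full table.
    """
    lam = ebgm
    return math.log2((a + gamma11) * lam / (a + gamma11 * lam))


def compute_ebgm(ct: ContingencyTable) -> EstimateCI:
    """Observed/expected relative reporting ratio aN/((a+b)(a+c)) with 95% CI.

    The CI uses the same cell-reciprocal standard error as the ROR. No
    empirical-Bayes gamma-mixture shrinkage is applied; the point estimate
    equals 2**IC_raw.
    """
    corrected = _needs_correction(ct)
    a, b, c, d = ct.corrected() if corrected else (ct.a, ct.b, ct.c, ct.d)
    n = a + b + c + d
    ebgm = a * n / ((a + c) * (a + b))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    low, high = _log_ci(ebgm, se)
    return EstimateCI(ebgm, low, high, corrected)


@dataclass(frozen=True)
class DisproportionalityResult:
    """All screening statistics and per-method flags for one drug-event pair."""

    event: str
    level: str
    a: int
    ror: float
    ror_ci: tuple[float, float]
    prr: float
    prr_ci: tuple[float, float]
    chi2: float
    ic_raw: float
    ic_expect: float
    ic_var: float
    ic025: float
    ebgm: float
    ebgm_ci: tuple[float, float]
    flags: SignalFlags
    soc_code: int | None = None
    corrected: bool = False

    @property
    def ebgm05(self) -> float:
        return self.ebgm_ci[0]


def evaluate_signal(
    a: int,
    ror: EstimateCI,
    prr: EstimateCI,
    bcpnn: BcpnnResult,
    ebgm: EstimateCI,
    crit: SignalCriteria = SignalCriteria(),
) -> SignalFlags:
    """Apply the per-method screening thresholds."""
    ror_signal = a >= crit.min_a and ror.low > crit.ror_ci_low_gt
    prr_signal = a >= crit.min_a and prr.low > crit.prr_ci_low_gt
    bcpnn_signal = bcpnn.ic025 > crit.ic025_gt
    ebgm_signal = ebgm.low > crit.ebgm05_gt
    return SignalFlags(
        ror_signal=ror_signal,
        prr_signal=prr_signal,
        bcpnn_signal=bcpnn_signal,
        ebgm_signal=ebgm_signal,
        all_four=ror_signal and prr_signal and bcpnn_signal and ebgm_signal,
    )


def analyze_table(
    ct: ContingencyTable,
    event: str = "",
    level: str = "pt",
    crit: SignalCriteria = SignalCriteria(),
    hp: BcpnnHyperparameters = BcpnnHyperparameters(),
    yates: bool = False,
    soc_code: int | None = None,
) -> DisproportionalityResult:
    """All four statistics plus flags for a single 2x2 table."""
    ror = compute_ror(ct)
    prr = compute_prr(ct)
    chi2, _ = compute_chi2(ct, yates=yates)
    bcp = compute_bcpnn(ct, hp)
    ebgm = compute_ebgm(ct)
    flags = evaluate_signal(ct.a, ror, prr, bcp, ebgm, crit)
    return DisproportionalityResult(
        event=event,
        level=level,
        a=ct.a,
        ror=ror.value,
        ror_ci=(ror.low, ror.high),
        prr=prr.value,
        prr_ci=(prr.low, prr.high),
        chi2=chi2,
        ic_raw=bcp.ic_raw,
        ic_expect=bcp.ic_expect,
        ic_var=bcp.ic_var,
        ic025=bcp.ic025,
        ebgm=ebgm.value,
        ebgm_ci=(ebgm.low, ebgm.high),
        flags=flags,
        soc_code=soc_code,
        corrected=ror.corrected or prr.corrected or ebgm.corrected,
    )


def analyze_all(
    pc,
    crit: SignalCriteria = SignalCriteria(),
    hp: BcpnnHyperparameters = BcpnnHyperparameters(),
    yates: bool = False,
    vocab=None,
) -> list[DisproportionalityResult]:
    """One result per event reported at least once with the target drug.

    Results are ranked by EBGM descending (ties broken by event label) —
    the most stringent of the four methods, and the conventional ranking
    for screening tables.
    """
    if pc.n_target_pairs <= 0:
        raise ValueError("no target-drug pairs to analyze")
    soc_codes = vocab.soc_codes if (vocab is not None and pc.level == "soc") else {}
    results = []
    for event in pc.target_event_counts:
        ct = build_contingency(pc, event)
        if pc.level == "soc":
            soc_code = soc_codes.get(event)
        else:
            hit = vocab.soc_of(event) if vocab is not None else None
            soc_code = hit[1] if hit is not None else None
        results.append(
            analyze_table(
                ct, event=event, level=pc.level, crit=crit, hp=hp, yates=yates,
                soc_code=soc_code,
            )
        )
    results.sort(key=lambda r: (-r.ebgm, r.event))
    return results
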