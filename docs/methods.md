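# Methods

## Data model and cleaning

FAERS quarterly extracts are flat "$"-delimited ASCII tables with one
header row and no quoting; an embedded "$" in free text is not
representable and is documented as unsupported. One row of DEMO is one
*report version* (PRIMARYID); CASEID identifies the safety case across
versions and quarters. Cleaning follows the FDA-recommended convention:

1. **Deduplication.** Per CASEID, keep the version with the largest FDA
   receipt date (FDA_DT); among receipt-date ties, keep the largest
   PRIMARYID. IDs are compared numerically when all-digit, otherwise
   lexicographically after all numeric IDs — a deterministic total order
   that matches the intended "largest PRIMARYID" semantics on FAERS-style
   numeric IDs while tolerating mixed identifiers.
2. **Deleted cases.** Quarterly deleted-case lists are applied after
   deduplication and remove the whole case. Child rows (DRUG/REAC/OUTC/
   THER) of discarded versions are dropped with their version.

FDA_DT must be a full, valid YYYYMMDD date because it drives the
deduplication order; rows violating this are skipped and counted, never
silently dropped. Event and therapy-start dates may be partial (YYYY or
YYYYMM) and are padded to the first day of the period.

## Counting convention

The unit of analysis is the unique (report, event) pair: a report
mentioning a preferred term (PT) twice contributes once, and at
system-organ-class (SOC) level a report with several PTs in one SOC
contributes once to that SOC. The 2×2 margins are therefore pair totals:
a+b is the number of unique pairs in target-drug reports and a+c the
event's total across all reports. A report is a *target-drug report* when
any drug row matches a target name (drug name or active-ingredient text,
normalized by trimming, whitespace collapse, and uppercasing) in an
accepted role — primary suspect (PS) only, by default; reports mentioning
the target in other roles count as background. PTs missing from the PT→SOC
vocabulary are pooled under an explicit `UNMAPPED` SOC rather than dropped,
preserving the table margins. Because MedDRA itself is licensed, the
vocabulary is always a user-supplied (or synthetic) two-column mapping.

## The four statistics

With cells a, b, c, d and N = a+b+c+d:

- **ROR** = ad/bc; 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
- **PRR** = [a/(a+b)]/[c/(c+d)];
  95% CI = exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))).
- **Pearson χ²** = N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)]; the Yates-corrected
  variant replaces |ad−bc| with max(0, |ad−bc| − N/2). The default is
  uncorrected; a zero margin yields χ² = 0 and a degenerate flag.
- **BCPNN.** Raw information component IC = log₂ aN/((a+b)(a+c)). The
  posterior expectation and variance under Dirichlet prior counts
  (γ₁₁, α, α₁, β, β₁) are

      γ = γ₁₁ (N+α)(N+β) / [(a+b+α₁)(a+c+β₁)]
      E(IC) = log₂ (a+γ₁₁)(N+α)(N+β) / [(N+γ)(a+b+α₁)(a+c+β₁)]
      V(IC) = (1/ln²2) · [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                         + (N−(a+b)+α−α₁)/((a+b+α₁)(1+N+α))
                         + (N−(a+c)+β−β₁)/((a+c+β₁)(1+N+β)) ]

  with the screening bound IC025 = E(IC) − 2·√V(IC) (exactly 2 standard
  deviations, not 1.96). Defaults are the classical priors γ₁₁ = 1,
  α = β = 2, α₁ = β₁ = 1; at reporting-database scale the choice of
  α, β, α₁, β₁ is numerically irrelevant, and γ₁₁ = 1 is corroborated by
  the large-N closure below. All five are configurable.
- **EBGM**, implemented as the unshrunk observed/expected relative
  reporting ratio aN/((a+b)(a+c)) — identical to 2^IC — with the same
  log-normal CI form as the ROR. This is the common reporting convention
  in screening tables; a full MGPS (two-component gamma-mixture empirical
  Bayes with posterior quantiles) is deliberately out of scope. The
  identity IC = log₂ EBGM holds to machine precision on uncorrected
  tables and is enforced by tests.

**Large-N closure.** Holding a and λ = aN/((a+b)(a+c)) fixed while N → ∞,
γ → γ₁₁λN/a and E(IC) → log₂((a+γ₁₁)λ/(a+γ₁₁λ)). With γ₁₁ = 1 this lets
E(IC) be recovered from a published (case count, EBGM) pair alone; the
acceptance script uses it to reproduce published IC values to 2 decimals.

**Ordering law.** For positive cells, sign(ROR−1) = sign(PRR−1) =
sign(EBGM−1) = sign(ad−bc), and ad > bc implies ROR > PRR > EBGM > 1
(ROR/PRR = (1+a/b)/(1+c/d); EBGM/PRR = Nc/((a+c)(c+d))). EBGM is thus the
most conservative statistic and is used as the ranking key (descending,
ties broken by event label).

**Thresholds.** ROR and PRR flag a signal when a ≥ 3 and the CI lower
bound exceeds 1; BCPNN when IC025 > 0; EBGM when EBGM05 (its CI lower
bound) exceeds 2; `all_four` is their conjunction. All cutoffs are
configurable.

## Numerical conventions

- **Zero cells.** Any statistic whose formula would divide by a zero cell
  is computed on a Haldane–Anscombe corrected table (+0.5 to all four
  cells, for that statistic only) and flagged `corrected`. The raw IC is
  always computed from the uncorrected cells (−∞ when a = 0; NaN with a
  degenerate flag when a margin is empty — the Bayesian quantities remain
  finite because the priors regularize them). The IC = log₂ EBGM identity
  and the ordering law are asserted only for uncorrected tables.
- **Rounding.** Printed percentages and CSV statistics are rounded half-up
  (away from zero on ties), computed through exact decimal/rational
  arithmetic for percentages so that printed two-decimal values are
  reproduced exactly.
- **Percent denominators.** All descriptive percentages use the total
  number of deduplicated target reports, including multi-valued sections
  (outcomes, countries), which therefore need not sum to 100%.
- **Binning.** Age bins [0,18), [18,45), [45,65), [65,75), [75,∞) in
  years (unit conversions: DEC×10, MON/12, WK/52.18, DY/365.25, HR/8766);
  onset bins [0,7), [7,28), [28,60), [60,∞) days, lower-inclusive —
  printed ranges like "0–7, 7–28" are ambiguous at the boundary, so the
  half-open convention is fixed and documented. Negative onsets (event
  before therapy start) are treated as missing/outliers. Time to onset
  uses the earliest therapy-start date linked (via drug sequence number)
  to the target drug, against the report's event date. Occurrence country
  (OCCR_COUNTRY) is used for the country section.

## Synthetic data

The generator emulates the structural hazards of FAERS that the pipeline
must survive, with known ground truth:

- duplicate case versions (default rate 0.05) with strictly later receipt
  dates and larger PRIMARYIDs, or equal receipt dates in `tie_mode` to
  exercise the PRIMARYID tie-break;
- quarterly deleted-case lists (default rate 0.01);
- primary-suspect role codes plus Poisson(0.7) concomitant drug mentions;
- heavy demographic missingness matching spontaneous-report data
  (98.5% unknown sex/age, pharmacist-dominated reporting, ~99% US origin,
  and date missingness leaving roughly a quarter of reports with a
  computable onset);
- multi-PT reports: K = 1 + Poisson(mean−1) PTs per report, truncated at
  10, with default mean 3 — typical of spontaneous reports;
- a 64-PT vocabulary over 8 SOCs with Zipf-like baseline frequencies,
  including four rare PTs (baseline 2×10⁻³) reserved for signal
  injection: rare enough that tilting them barely perturbs the remaining
  distribution, common enough that injected signals accumulate
  double-digit case counts at desk scale;
- configurable reporting-rate multipliers ρ per (drug, PT): reports whose
  primary-suspect drug has effects draw PTs from the tilted distribution
  p_j·ρ_j / Σ_k p_k·ρ_k, so the closed-form expected relative rate of a
  pair is ρ_j / Σ_k p_k·ρ_k (`expected_pair_rates`); for rare PTs the
  renormalization correction is below 1%.

Default cohort shape: 50,000 base reports per dataset with target-drug
prevalence 0.02 — large enough for stable double-digit case counts on
rare injected signals, small enough that one replicate generates and
analyzes in a few seconds. Identical seeds yield byte-identical files.

What the generator does **not** emulate: free-text drug-name noise beyond
case/whitespace, drug co-prescription correlation, event–demographic
dependence, reporting trends over time, and duplicate reports with
*different* CASEIDs (probabilistic duplicate detection is out of scope).
Passing recovery tests therefore demonstrates correctness of the counting
and estimation machinery under the stated generative model, not robustness
to real-world name noise or cross-case duplication.

## Validation experiments

The acceptance-grade tests (tests/test_acceptance.py) run:

- **Published worked examples**: the large-N E(IC) closure against five
  published (case count, EBGM, IC) triples; exact two-decimal percentage
  reproduction for a 3633-report cohort's printed summary counts.
- **Oracle equivalence**: 1,000 random tables with cells in [0, 500]
  against an independent literal-transcription oracle computed in exact
  rational arithmetic (tests/_oracle.py), at relative tolerance 1e−10.
- **Algebraic invariants**: the IC/EBGM identity and the ordering law on
  random tables and on every uncorrected row of an end-to-end synthetic
  run.
- **Parameter recovery**: 50 replicates of 50,000 reports with injected
  multipliers ρ ∈ {2, 5, 10} on the three rare PTs (duplication and
  deletion disabled to isolate estimation; their accounting is validated
  separately); median ROR/PRR/EBGM per pair must fall within 15% of the
  generator's expected rates. One caveat is visible here: EBGM's
  observed/expected reference includes the target cohort's own excess, so
  its estimand sits below the drug-conditional rate by a factor
  ≈ c/(a+c); at desk-scale prevalence (2%) and ρ = 10 this is a ~15%
  deflation — at real-database prevalence (~10⁻⁴–10⁻³) it is negligible.
  ROR and PRR do not share this contamination.
- **Null calibration**: with no injected effects, fewer than 1% of
  target-margin events trip all four thresholds simultaneously (pooled
  over three 50,000-report replicates).
- **Conservation**: deduplication/deletion counts equal the generator's
  ledgers exactly; dedup is idempotent and input-order-invariant.

The separate `scripts/acceptance.py` recomputes only the deterministic
closed-form E(IC) worked examples and writes them as JSON.

## Known limitations

- EBGM here is the unshrunk relative reporting ratio; small-count EBGM
  values are noisier than a true MGPS posterior mean would be, and EBGM05
  is a log-normal CI bound, not a posterior quantile.
- No stratified (age/sex/year) analyses and no multiple-comparison
  adjustment — conventional for screening, but the per-method flags are
  screening aids, not causal claims.
- Printed χ² values in external tables cannot be cross-checked without
  the underlying margins, and whether they carry a continuity correction
  is often unstated; both variants are provided.
- The "$" dialect reader does not support embedded delimiters or the
  legacy SGML/XML FAERS formats, and RxNorm ingredient resolution is
  out of scope (drug matching is by normalized name/ingredient text
  against a user-supplied synonym list).
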