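# faersig

Disproportionality signal mining for spontaneous adverse-event reports in
the FAERS quarterly-extract format.

Post-market drug safety surveillance asks: among the adverse events (AEs)
reported for a drug of interest, which are reported *disproportionately*
often compared with the background of all other drugs? `faersig` implements
the standard screening pipeline used in pharmacovigilance studies of the
FDA Adverse Event Reporting System (FAERS): ingestion of the "$"-delimited
quarterly tables (DEMO, DRUG, REAC, OUTC, THER), case-level deduplication
and deleted-case removal, target-drug cohort construction restricted to
primary-suspect drug mentions, MedDRA preferred-term (PT) and
system-organ-class (SOC) aggregation, descriptive cohort summaries, and
four disproportionality statistics with their conventional signal
thresholds. A synthetic-data module generates FAERS-like datasets with
known ground truth so the whole pipeline can be validated without FAERS
access or a MedDRA license.

It is intended for pharmacoepidemiologists and biostatisticians running
drug-event signal screens, and for methodologists who need a tested,
scriptable reference implementation of the classical statistics.

## The statistics

For a drug–event pair, reports are cross-classified into the 2×2 table

|                | target AE | other AEs |
|----------------|-----------|-----------|
| target drug    | a         | b         |
| other drugs    | c         | d         |

with N = a+b+c+d, counting each deduplicated report at most once per event
(PTs are merged within a report; at SOC level a report counts once per SOC).
Four statistics are screened:

- **ROR** (reporting odds ratio): ROR = ad/bc, with the Woolf 95% CI
  exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)).
  Signal: a ≥ 3 and CI lower bound > 1.
- **PRR** (proportional reporting ratio): PRR = [a/(a+b)] / [c/(c+d)], with
  95% CI exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))), plus the
  Pearson χ² of the table (Yates correction optional).
  Signal: a ≥ 3 and CI lower bound > 1.
- **BCPNN information component**: IC = log₂ aN/((a+b)(a+c)), the
  observed/expected joint reporting probability in bits, with a Bayesian
  posterior expectation E(IC) and variance V(IC) under Dirichlet prior
  counts (defaults γ₁₁ = 1, α = β = 2, α₁ = β₁ = 1).
  Signal: IC025 = E(IC) − 2·√V(IC) > 0.
- **EBGM**, here the unshrunk relative reporting ratio aN/((a+b)(a+c))
  (identical to 2^IC), with the same log-normal CI form as the ROR.
  Signal: EBGM05 (CI lower bound) > 2.

For any table with positive cells and ad > bc, the statistics obey
ROR > PRR > EBGM > 1, so EBGM is the most conservative ranking criterion;
result tables are ranked by EBGM descending.

## Worked example

All statistics for the table a=10, b=20, c=30, d=240:

```bash
$ faersig stats --a 10 --b 20 --c 30 --d 240
a,b,c,d,n,ror,ror_low,ror_high,prr,prr_low,prr_high,chi2,ic_raw,ic_expect,ic_var,ic025,ebgm,ebgm_low,ebgm_high,ror_signal,prr_signal,bcpnn_signal,ebgm_signal,all_four,corrected
10,20,30,240,300,4,1.71188,9.34647,3,1.63296,5.51148,11.5385,1.32193,1.08627,0.286903,0.0150084,2.5,1.06992,5.84155,True,True,True,False,False,False
```

Reading the row: the event is reported 4.00 times as often (odds scale)
with the target drug as without (ROR 4.00, CI 1.71–9.35), 3.00 times as
often on the proportion scale (PRR), and 2.50 times as often relative to
the whole-database expectation (EBGM, equal to 2^1.32 from the raw IC of
1.32 bits). The Bayesian expectation E(IC) = 1.09 bits is shrunk toward 0,
and its lower bound IC025 = 0.02 > 0 still flags the pair; EBGM05 = 1.07
does not clear the stricter EBGM threshold of 2, so `all_four` is False.

End to end on synthetic data:

```bash
$ faersig synth --out data --seed 42 --n-reports 5000
n_reports=5000
target_reports=100
duplicate_cases=255
deleted_cases=51

$ faersig analyze --demo data/demo.txt --drug data/drug.txt --reac data/reac.txt \
    --outc data/outc.txt --ther data/ther.txt --deleted data/deleted_cases.txt \
    --vocab data/vocabulary.tsv --synonyms data/synonyms.txt --out out
reports_read=5255
duplicates_removed=255
deleted_removed=51
kept=4949
target_reports=99
pt_pairs=14436
pt_events=60
soc_pairs=12613
soc_events=8
```

The stage ledger shows the accounting: 5255 report versions collapse to
4949 kept cases (255 superseded versions plus 51 deleted cases removed —
matching the generator's ground truth), of which 99 name the target drug
as primary suspect (one of the 100 planted target cases was itself
deleted). `out/` contains `descriptives.csv` (sex, age bins, reporter,
country, year, serious outcomes, time to onset, with percentages),
`signals_pt.csv` and `signals_soc.csv` (one row per event, all statistics,
CIs, and per-method flags, ranked by EBGM), and `run.log`.

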