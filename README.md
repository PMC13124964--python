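# faersig

Disproportionality signal detection for spontaneous adverse-event report
databases distributed as FAERS-style quarterly extracts.

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) collect voluntary safety reports on marketed drugs. A
*signal* is a drug–event pair reported more often than expected under
independence — a hypothesis for further review, never a causal claim.
`faersig` implements the standard small-cohort pharmacovigilance workflow
end to end for analysts studying a single target drug (the bundled
defaults are set up for potassium citrate, an oral alkali used to prevent
recurrent kidney stones):

1. **Ingestion** — parse the dollar-delimited quarterly tables (DEMO,
   DRUG, REAC, OUTC, INDI, THER) with explicit malformed-row accounting.
2. **Deduplication** — one report version per CASEID: latest FDA_DT,
   ties broken by the highest PRIMARYID.
3. **Cohort construction** — reports where the target drug is the
   primary suspect (PS) versus the remaining background, with
   confounding-by-indication PTs harvested from the drug's own INDI rows
   and removed from the cohort's reaction sets.
4. **Contingency tables** — for every MedDRA Preferred Term (PT) and
   System Organ Class (SOC), the 2×2 report counts (a, b, c, d), keeping
   only events with more than 3 target-drug reports.
5. **Disproportionality** — four algorithms computed in parallel on each
   table, with an event called a signal when at least two methods meet
   their threshold:

   | Method | Statistic | Threshold |
   |---|---|---|
   | ROR | (a·d)/(b·c), 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` | CI lower bound > 1 |
   | PRR | [a/(a+b)]/[c/(c+d)], χ² = (ad−bc)²·N / [(a+b)(c+d)(a+c)(b+d)] | PRR ≥ 2 and χ² ≥ 4 |
   | BCPNN | IC = log₂[a·N/((a+c)(a+b))], interval IC ± 2·√V(IC) | IC025 > 0 |
   | MGPS | EBGM = a·N/((a+c)(a+b)) (closed form), CI as for ROR | EBGM05 > 2 |

6. **Descriptives** — age/sex/weight bands, reporter occupation, top
   reporting countries, and serious-outcome tallies.

A synthetic FAERS generator with analytic ground truth (background event
frequencies, injected relative reporting rates, duplicate versions,
missingness) makes every stage testable without any download. MedDRA is
licensed and is **not** bundled: real analyses need a user-supplied
two-column PT→SOC file; a small toy dictionary ships for tests and demos.

## Worked example

One-shot statistics for a single 2×2 table — 20 of 100 target-drug
reports mention the event, versus 100 of 9 900 background reports:

```
$ faersig stats --table 20,80,100,9800
 a  ror  ror_low  ror_high  prr   chi2   ic  ic025  ebgm  ebgm05  corrected  methods_met  is_signal
20 24.5    14.45     41.55 19.8 301.12 4.06   3.54 16.67    9.83      False            4       True
```

The event is reported 24.5 times more often with the target drug than
its odds in the background (CI 14.45–41.55); all four methods meet their
threshold, so the pair is flagged as a signal.

A full synthetic run — 5 000 cases, ~400 of them with the target drug as
primary suspect, and one planted association (relative reporting rate 8
for the PT "Product residue present"):

```
$ faersig run --config demo.yaml
retrieved=5689 duplicates_removed=689 unique=5000 drug_reports=402 pt_signals=1 soc_signals=1
```

The planted PT is the only signal and tops the ranked output
(`signals_pt.tsv`), with all four methods firing:

```
level  event_label              a   ror   ror_low  ror_high  prr   chi2   ic    ic025  ebgm  ebgm05  methods_met  is_signal
PT     Product residue present  16  7.29  3.88     13.70     7.04  51.75  2.24  1.69   4.74  2.52    4            True
```

where `demo.yaml` is:

```yaml
input:
  mode: synthetic
  scenario:
    n_cases: 5000
    injected_signals: [["Product residue present", 8.0]]
output:
  directory: demo_out
seed: 1
```

Real quarterly extracts are analysed the same way with
`input.mode: quarters`, `input.directory`, `input.quarters: [2014Q1, ...]`
and `meddra.dictionary_path` pointing at your PT→SOC file. The
`faersig simulate` subcommand writes a synthetic quarter to disk together
with its `ground_truth.tsv`.

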