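# Methods

## Setting and data model

The package analyses spontaneous adverse-event reports of the kind the
FDA distributes as FAERS quarterly ASCII extracts: per-quarter,
dollar-delimited tables for demographics (DEMO), drugs with role codes
(DRUG), MedDRA-coded reactions (REAC), outcomes (OUTC), indications
(INDI) and therapy dates (THER). A safety report is identified by CASEID;
each submitted version of it has its own PRIMARYID and FDA receipt date
(FDA_DT). The parser is header-driven, skips rows whose field count
disagrees with the header (counted and logged, never silent), treats
DEMO/DRUG/REAC as mandatory and the rest as optional, and refuses to
write any field containing the `$` delimiter because the dialect has no
quoting or escape mechanism.

Unit handling at assembly: ages are converted to years from the FAERS
age codes (DEC ×10, YR ×1, MON ÷12, WK ÷52, DY ÷365.25, HR ÷8766),
weights to kilograms (LBS ×0.453592, KG ×1, GMS ÷1000); anything
unparseable becomes absent rather than a guess. Occupation codes map to
the three conventional reporter buckets (MD → physician; PH/OT/HP/RN →
other health professional; CN/LW → consumer; otherwise unknown).

## Deduplication and cohort

One version per CASEID is retained: the maximal FDA_DT, ties broken by
the numerically largest PRIMARYID. The rule is a pure function of the
case set, hence order-independent and idempotent; a non-integer
PRIMARYID is treated as corrupt input and is a hard error. Deduplication
runs before drug restriction.

The cohort is the deduplicated reports in which the target drug appears
with role PS (primary suspect). Because FAERS drug names are free text,
matching is case-insensitive after trimming and whitespace collapsing,
against both the verbatim name and the active-ingredient field,
substring by default (exact mode and a synonym list are available in
configuration).

Confounding by indication — e.g. flank pain reported for a stone-disease
drug — is mitigated by harvesting the indication PTs attached to the
target drug's own INDI rows across the cohort and removing exactly those
PT strings from the cohort's reaction sets. Reports are never removed:
a case whose only reaction is indication-linked stays in the cohort
denominator with an empty reaction set. The harvested set can be
extended, overridden or disabled in configuration for reproducibility.

## Counting

For each event label (PT, or SOC via a user-supplied PT→primary-SOC
dictionary) a 2×2 table is built: `a` = distinct target-drug reports
with the event, `c` = distinct background reports with it, `b` and `d`
the complements. Distinct-*report* counting is the default: a report
contributes at most one count per event even if a PT is coded twice or
two of its PTs map to the same SOC, so the margins a+b and c+d are the
cohort and background sizes for every table of a run. A report–event
*pair* counting unit is available behind `analysis.counting_unit` for
sensitivity analyses. Only events with more than 3 target-drug reports
(a > 3) are analysed; the cut is configurable.

A PT maps to its single primary SOC (no multi-axial fan-out), so
SOC-level counts partition PT-level counts. Unknown PTs either pool into
an `UNMAPPED` bucket (default) or are dropped with logging.

## Statistics

All four disproportionality statistics are closed-form functions of
(a, b, c, d), N = a+b+c+d:

* ROR = (a·d)/(b·c) with the Wald log-scale interval
  exp(ln ROR ± 1.96·se), se = √(1/a + 1/b + 1/c + 1/d);
* PRR = [a/(a+b)]/[c/(c+d)] with the uncorrected χ² =
  (ad − bc)²·N / [(a+b)(c+d)(a+c)(b+d)] (no Yates continuity term);
* the BCPNN information component IC = log₂[a·N/((a+c)(a+b))] with the
  interval IC ± 2·√V(IC). V(IC) is the delta-method variance
  V(IC) = (1/ln 2)²·(1/a − 1/(a+b) − 1/(a+c) + 1/N); the plug-in IC is
  used as E(IC). The multiplier is 2, not 1.96, following common BCPNN
  reporting practice;
* EBGM = a·N/((a+c)(a+b)) in its closed form — the same
  observed/expected ratio, so IC = log₂(EBGM) holds identically — with
  the approximate interval exp(ln EBGM ± 1.96·se). No gamma-Poisson
  mixture shrinkage is applied; true MGPS shrinkage is out of scope, and
  the EBGM here should be read as a plain relative reporting ratio.

Thresholds: ROR CI lower bound > 1; PRR ≥ 2 together with χ² ≥ 4;
IC025 > 0; EBGM05 > 2. An event meeting at least two of the four is
classified a signal. Output is ranked by descending ROR, ties by
descending `a` then label.

Zero cells: the ratio statistics are undefined when any cell is zero.
The default policy applies the Haldane–Anscombe correction (+0.5 to all
four cells) for statistic and interval computation only, and flags the
row as corrected; the alternative `undefined` policy leaves all
statistics NaN, which no threshold treats as met. Report output rounds
to 2 decimals half-up; internal computation is full precision.

## Descriptives

Age bands <18 / 18–64 / >64 (closed at both ends of the middle band) and
weight bands <80 / 80–100 / >100 kg partition the cohort together with an
`unknown` band for missing values. Outcome tallies count distinct
reports per outcome code; a report with several codes counts once per
code and once toward the any-outcome and any-serious totals. Percentages
are half-up at 1 decimal in prose-style output and 2 decimals in the
tidy table.

## Synthetic generator

The generator emulates the quarterly extract structure with a reporting
model chosen to admit closed-form expectations. Each case is a
target-drug case with probability `target_drug_fraction`, draws
k ~ zero-truncated Poisson (stated mean) distinct reaction PTs from the
catalog with sampling weight background-probability × injected relative
rate (target cases) or background-probability alone (background cases),
and with probability `duplicate_rate` emits an additional earlier
version: identical content, distinct PRIMARYID, strictly earlier FDA_DT,
so deduplication is checkable exactly against the ground-truth version
map.

Defaults describe the reference small-cohort study setting: 5 000 cases
with target fraction 0.08 (≈400 target reports), mean 1.86 reaction
entries per report, duplicate rate 0.139, outcome information on 25% of
reports, 79% of target cases with concomitant medication, and
missingness of age 25.5%, sex 11.8%, weight 89.7% and country 5.4% —
magnitudes typical of spontaneous-report demographics. The indication PT
"Nephrolithiasis" attaches to half of the target cases' PS drug rows, so
the indication-exclusion stage is exercised by default.

The analytic expectation used in recovery tests computes, for each PT,
the inclusion probability p = 1 − (e^{λ(1−q)} − 1)/(e^{λ} − 1) with q
the renormalized sampling weight and λ the underlying Poisson parameter
— the exact expression for independent draws, a mild approximation to
the generator's without-replacement sampling that is accurate for small
q (a few percent relative error at the weights used in the tests).

What the generator does *not* emulate: drug co-prescription structure,
reporting-rate time dynamics and stimulated reporting, correlated
missingness, misspelled drug names, fragmented duplicates with
non-identical content, and multi-axial MedDRA coding. Passing recovery
tests therefore demonstrate correctness of the pipeline's counting and
statistics under a known reporting model, not robustness to real-world
reporting artefacts.

## Problem sizes and numerical choices

Seeded simulation suites use 20 replicates of 3 000–5 000 cases, sizes
at which the injected-association tests have comfortable power while the
whole suite runs in well under a minute. Statistic equivalence against an
independent straight-line arithmetic oracle is checked on 1 000 random
tables at relative tolerance 1e-12 (pure closed forms; no iterative
numerics anywhere). Ranking ties are broken deterministically, pipeline
runs are byte-reproducible given a configuration and seed, and the run
ledger enforces retrieved − duplicates = unique and
drug-reports ≤ unique at the end of every run.

## Known limitations

* EBGM without shrinkage overstates disproportionality for very small
  `a` relative to true MGPS; interpret EBGM05 accordingly.
* The delta-method V(IC) is one of several published IC variance
  approximations; a fully Bayesian interval would be wider at small
  counts.
* Indication-PT exclusion removes only exact PT strings recorded in
  INDI; clinically related but differently coded terms remain.
* SOC results depend entirely on the user-supplied dictionary; the
  bundled toy mapping exists for tests and demos, not analysis.
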