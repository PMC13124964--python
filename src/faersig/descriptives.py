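"""Descriptive summary of a report cohort: age/sex/weight bands, reporter
occupation, reporting countries and serious-outcome tallies."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .io import OUTCOME_CODES, FaersCase

AGE_BANDS = ("<18", "18-64", ">64", "unknown")
WEIGHT_BANDS = ("<80", "80-100", ">100", "unknown")
SEX_LEVELS = ("male", "female", "unknown")
REPORTER_LEVELS = ("physician", "other_health_professional", "consumer", "unknown")

#: outcome codes conventionally treated as serious
SERIOUS_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Half-up percentage; 0.0 for an empty denominator."""
    if total == 0:
        return 0.0
    q = Decimal(10) ** -decimals
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


def age_band(age_years: float | None) -> str:
    # 18-64 is closed on both ends; the three bands partition known ages
    if age_years is None:
        return "unknown"
    if age_years < 18:
        return "<18"
    if age_years <= 64:
        return "18-64"
    return ">64"


def weight_band(weight_kg: float | None) -> str:
    if weight_kg is None:
        return "unknown"
    if weight_kg < 80:
        return "<80"
    if weight_kg <= 100:
        return "80-100"
    return ">100"


@dataclass(frozen=True)
class DescriptiveSummary:
    n_total: int
    age_bands: dict[str, int]
    sex: dict[str, int]
    weight_bands_kg: dict[str, int]
    reporter: dict[str, int]
    countries: tuple[tuple[str, int], ...]  # top-k (country, count), desc
    outcomes: dict[str, int]  # per outcome code, distinct reports
    n_outcome_reports: int  # reports with >=1 outcome code
    n_serious_reports: int  # reports with >=1 serious code

    def pct(self, count: int, decimals: int = 1) -> float:
        return percent(count, self.n_total, decimals)


def summarize(drug_cases: Sequence[FaersCase], top_k_countries: int = 5) -> DescriptiveSummary:
    """Tally the cohort's demographics, reporters, countries and outcomes.

    Banded categories each sum to the cohort size (missing values fall in
    the ``unknown`` band).  Outcome tallies count distinct reports per
    code; a report carrying several codes counts once per code and once
    toward the any-outcome total.
    """
    ages = {band: 0 for band in AGE_BANDS}
    sexes = {level: 0 for level in SEX_LEVELS}
    weights = {band: 0 for band in WEIGHT_BANDS}
    reporters = {level: 0 for level in REPORTER_LEVELS}
    countries: dict[str, int] = {}
    outcomes = {code: 0 for code in sorted(OUTCOME_CODES)}
    n_outcome = 0
    n_serious = 0
    for case in drug_cases:
        ages[age_band(case.age_years)] += 1
        sexes[case.sex if case.sex in sexes else "unknown"] += 1
        weights[weight_band(case.weight_kg)] += 1
        reporters[case.reporter if case.reporter in reporters else "unknown"] += 1
        countries[case.country] = countries.get(case.country, 0) + 1
        if case.outcomes:
            n_outcome += 1
            for code in case.outcomes:
                outcomes[code] += 1
            if case.outcomes & SERIOUS_CODES:
                n_serious += 1
    top = tuple(sorted(countries.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k_countries])
    return DescriptiveSummary(
        n_total=len(drug_cases),
        age_bands=ages, sex=sexes, weight_bands_kg=weights, reporter=reporters,
        countries=top, outcomes=outcomes,
        n_outcome_reports=n_outcome, n_serious_reports=n_serious,
    )


def summary_frame(summary: DescriptiveSummary) -> pd.DataFrame:
    """Tidy (section, category, n, pct) frame; table-style 2-dp percentages."""
    rows = []

    def add(section: str, category: str, n: int):
        rows.append({"section": section, "category": category,
                     "n": n, "pct": summary.pct(n, decimals=2)})

    add("total", "reports", summary.n_total)
    for band in AGE_BANDS:
        add("age", band, summary.age_bands[band])
    for level in SEX_LEVELS:
        add("sex", level, summary.sex[level])
    for band in WEIGHT_BANDS:
        add("weight_kg", band, summary.weight_bands_kg[band])
    for level in REPORTER_LEVELS:
        add("reporter", level, summary.reporter[level])
    for country, n in summary.countries:
        add("country", country, n)
    for code, n in summary.outcomes.items():
        add("outcome", code, n)
    add("outcome", "any_outcome_report", summary.n_outcome_reports)
    add("outcome", "any_serious_report", summary.n_serious_reports)
    return pd.DataFrame(rows, columns=["section", "category", "n", "pct"])


def format_text(summary: DescriptiveSummary) -> str:
    """Plain-text rendering of the summary (prose-style 1-dp percentages)."""
    lines = [f"Reports: {summary.n_total} (100%)", "Age (years)"]
    for band in AGE_BANDS:
        n = summary.age_bands[band]
        lines.append(f"  {band:>8}  {n:6d}  {summary.pct(n):5.1f}%")
    lines.append("Sex")
    for level in SEX_LEVELS:
        n = summary.sex[level]
        lines.append(f"  {level:>8}  {n:6d}  {summary.pct(n):5.1f}%")
    lines.append("Weight (kg)")
    for band in WEIGHT_BANDS:
        n = summary.weight_bands_kg[band]
        lines.append(f"  {band:>8}  {n:6d}  {summary.pct(n):5.1f}%")
    lines.append("Reporter")
    for level in REPORTER_LEVELS:
        n = summary.reporter[level]
        lines.append(f"  {level:>26}  {n:6d}  {summary.pct(n):5.1f}%")
    lines.append(f"Top reporting countries")
    for country, n in summary.countries:
        lines.append(f"  {country:>26}  {n:6d}  {summary.pct(n):5.1f}%")
    lines.append("Outcomes (distinct reports per code)")
    for code, n in summary.outcomes.items():
        if n:
            lines.append(f"  {code:>8}  {n:6d}  {summary.pct(n):5.1f}%")
    lines.append(f"  reports with any outcome code: {summary.n_outcome_reports} "
                 f"({summary.pct(summary.n_outcome_reports):.1f}%)")
    lines.append(f"  reports with any serious code: {summary.n_serious_reports} "
                 f"({summary.pct(summary.n_serious_reports):.1f}%)")
    return "\n".join(lines)
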