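"""2x2 contingency tables for drug-event pairs at PT or SOC level.

For each event label the table is

    =============  ==========  ==============
                   event       other events
    target drug    a           b
    other drugs    c           d
    =============  ==========  ==============

with distinct-report counting by default: a report contributes at most one
count to ``a`` (or ``c``) per event, and the margins a+b / c+d are the
cohort and background report counts, identical across all tables of a run.
An alternative report-event pair counting unit (margins are total event
entries) is available for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .dedup import Cohort
from .io import FaersCase
from .meddra import DROPPED, PtSocDictionary, soc_of

logger = logging.getLogger(__name__)

PT_LEVEL = "PT"
SOC_LEVEL = "SOC"


@dataclass(frozen=True)
class ContingencyTable:
    event_label: str
    level: str  # "PT" | "SOC"
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


def case_events(case: FaersCase, level: str,
                dictionary: PtSocDictionary | None = None,
                unknown_policy: str = "unmapped-bucket") -> set[str]:
    """Distinct event labels of one report at the requested level."""
    if level == PT_LEVEL:
        return set(case.reactions)
    if level == SOC_LEVEL:
        if dictionary is None:
            raise ValueError("SOC-level counting requires a PT->SOC dictionary")
        socs = {soc_of(pt, dictionary, unknown_policy) for pt in case.reactions}
        socs.discard(DROPPED)
        return socs
    raise ValueError(f"unknown level: {level!r}")


def count_tables(cohort: Cohort, dictionary: PtSocDictionary | None, level: str,
                 unknown_policy: str = "unmapped-bucket",
                 counting_unit: str = "reports") -> list[ContingencyTable]:
    """One table per event label observed anywhere in the cohort or background.

    ``counting_unit="reports"`` (default): cells count distinct reports,
    so a+b = number of target-drug reports for every table.
    ``counting_unit="pairs"``: margins are total report-event pairs
    instead, for sensitivity analyses.
    """
    if counting_unit not in ("reports", "pairs"):
        raise ValueError(f"unknown counting unit: {counting_unit!r}")
    if not cohort.drug_cases and not cohort.background_cases:
        logger.warning("empty cohort: no contingency tables to build")
        return []

    def tally(cases) -> tuple[dict[str, int], int]:
        counts: dict[str, int] = {}
        pairs = 0
        for case in cases:
            events = case_events(case, level, dictionary, unknown_policy)
            pairs += len(events)
            for ev in events:
                counts[ev] = counts.get(ev, 0) + 1
        return counts, pairs

    drug_counts, drug_pairs = tally(cohort.drug_cases)
    bg_counts, bg_pairs = tally(cohort.background_cases)
    drug_margin = len(cohort.drug_cases) if counting_unit == "reports" else drug_pairs
    bg_margin = len(cohort.background_cases) if counting_unit == "reports" else bg_pairs

    tables = []
    for label in sorted(set(drug_counts) | set(bg_counts)):
        a = drug_counts.get(label, 0)
        c = bg_counts.get(label, 0)
        tables.append(
            ContingencyTable(
                event_label=label, level=level,
                a=a, b=drug_margin - a, c=c, d=bg_margin - c,
            )
        )
    return tables


def filter_min_count(tables: Iterable[ContingencyTable],
                     min_a: int = 3) -> list[ContingencyTable]:
    """Keep tables with strictly more than ``min_a`` target-drug reports.

    The conventional inclusion rule N > 3 corresponds to the default, i.e.
    only events with at least 4 target-drug reports are analysed.
    """
    tables = list(tables)
    kept = [t for t in tables if t.a > min_a]
    logger.info("minimum-count filter (a > %d): kept %d of %d table(s)",
                min_a, len(kept), len(tables))
    return kept


def tables_frame(tables: Iterable[ContingencyTable]) -> pd.DataFrame:
    """Tidy audit frame (event_label, level, a, b, c, d, n_total)."""
    return pd.DataFrame(
        [
            {"event_label": t.event_label, "level": t.level,
             "a": t.a, "b": t.b, "c": t.c, "d": t.d, "n_total": t.n_total}
            for t in tables
        ],
        columns=["event_label", "level", "a", "b", "c", "d", "n_total"],
    )
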