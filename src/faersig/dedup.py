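"""Case deduplication, target-drug cohort construction and
indication-based PT exclusion.

A FAERS safety report (CASEID) accumulates versions over time, each with
its own PRIMARYID and FDA receipt date.  Standard practice keeps the most
recent version per case: latest FDA_DT, ties broken by the numerically
highest PRIMARYID.  The analysis cohort is then the deduplicated reports
in which the target drug appears as primary suspect (PS); everything else
is the comparator background.  PTs that merely restate the drug's
indication (confounding by indication) are harvested from the target
drug's own INDI rows and removed from the cohort's reaction sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

from .io import FaersCase

logger = logging.getLogger(__name__)


class DedupError(Exception):
    """Corrupt input detected during deduplication."""


@dataclass(frozen=True)
class DedupResult:
    retained: tuple[FaersCase, ...]
    n_input: int
    n_duplicates_removed: int

    def __post_init__(self):
        if self.n_input != self.n_duplicates_removed + len(self.retained):
            raise ValueError("dedup accounting does not balance")


@dataclass(frozen=True)
class DrugQuery:
    """Name-matching rule identifying the target drug in free-text fields.

    FAERS drug names are uncurated free text, so matching is
    case-insensitive after trimming and whitespace-collapsing, applied to
    both the verbatim name and the active-ingredient field, in
    ``substring`` (default) or ``exact`` mode, optionally extended with
    synonyms.
    """

    name: str
    match: str = "substring"  # "substring" | "exact"
    synonyms: tuple[str, ...] = ()

    def __post_init__(self):
        if self.match not in ("substring", "exact"):
            raise ValueError(f"unknown match mode: {self.match!r}")

    def _terms(self) -> list[str]:
        return [_normalize(t) for t in (self.name, *self.synonyms) if t.strip()]

    def matches(self, *fields: str) -> bool:
        terms = self._terms()
        for raw in fields:
            text = _normalize(raw)
            if not text:
                continue
            for term in terms:
                if term == text if self.match == "exact" else term in text:
                    return True
        return False


@dataclass(frozen=True)
class Cohort:
    drug_cases: tuple[FaersCase, ...]
    background_cases: tuple[FaersCase, ...]
    excluded_pts: frozenset[str] = frozenset()
    query: DrugQuery | None = None


def _normalize(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).casefold()


def _version_key(case: FaersCase) -> tuple[date, int]:
    try:
        pid = int(case.primaryid)
    except (TypeError, ValueError):
        raise DedupError(f"PRIMARYID not an integer: {case.primaryid!r} (caseid {case.caseid})")
    return (case.fda_dt or date.min, pid)


def deduplicate(cases: Sequence[FaersCase]) -> DedupResult:
    """Keep one version per CASEID: max FDA_DT, then max numeric PRIMARYID.

    Order-independent and idempotent; the number removed plus the number
    retained equals the input count.
    """
    best: dict[str, FaersCase] = {}
    for case in cases:
        incumbent = best.get(case.caseid)
        if incumbent is None or _version_key(case) > _version_key(incumbent):
            best[case.caseid] = case
    retained = tuple(sorted(best.values(), key=_version_key))
    result = DedupResult(
        retained=retained,
        n_input=len(cases),
        n_duplicates_removed=len(cases) - len(retained),
    )
    logger.info(
        "deduplication: %d input -> %d unique (%d duplicate version(s) removed)",
        result.n_input, len(retained), result.n_duplicates_removed,
    )
    return result


def _target_entries(case: FaersCase, query: DrugQuery, role: str | None = "PS"):
    for entry in case.drugs:
        if role is not None and entry.role != role:
            continue
        if query.matches(entry.name, entry.active_ingredient):
            yield entry


def build_cohort(dedup: DedupResult, query: DrugQuery,
                 extra_excluded_pts: Iterable[str] = (),
                 disable_exclusion: bool = False) -> Cohort:
    """Split deduplicated cases into target-drug (PS) cohort and background.

    A case enters ``drug_cases`` when at least one of its drug rows matches
    the query with role PS.  The indication-PT exclusion set is the union
    of INDI PTs attached to the matching PS drug rows across the cohort
    (not indications of concomitant drugs), optionally extended or disabled
    via configuration.
    """
    drug_cases: list[FaersCase] = []
    background: list[FaersCase] = []
    excluded: set[str] = set()
    for case in dedup.retained:
        entries = list(_target_entries(case, query))
        if entries:
            drug_cases.append(case)
            for entry in entries:
                excluded.update(entry.indications)
        else:
            background.append(case)
    if not drug_cases:
        logger.warning("drug query %r matched no primary-suspect reports", query.name)
    if disable_exclusion:
        excluded = set()
    else:
        excluded.update(extra_excluded_pts)
    logger.info(
        "cohort: %d target-drug report(s), %d background report(s), "
        "%d indication PT(s) marked for exclusion",
        len(drug_cases), len(background), len(excluded),
    )
    return Cohort(
        drug_cases=tuple(drug_cases),
        background_cases=tuple(background),
        excluded_pts=frozenset(excluded),
        query=query,
    )


def apply_pt_exclusion(cohort: Cohort) -> Cohort:
    """Remove indication-linked PTs from the cohort's reaction sets.

    Only the PT strings are removed, never the reports: a case whose every
    reaction is excluded stays in the cohort and keeps contributing to the
    drug margin of each contingency table.  Background cases are untouched.
    """
    if not cohort.excluded_pts:
        return cohort
    removed: dict[str, int] = {}
    new_cases = []
    for case in cohort.drug_cases:
        hit = case.reactions & cohort.excluded_pts
        if hit:
            for pt in hit:
                removed[pt] = removed.get(pt, 0) + 1
            new_cases.append(case.with_reactions(case.reactions - hit))
        else:
            new_cases.append(case)
    for pt, n in sorted(removed.items()):
        logger.info("indication exclusion: removed PT %r from %d report(s)", pt, n)
    return Cohort(
        drug_cases=tuple(new_cases),
        background_cases=cohort.background_cases,
        excluded_pts=cohort.excluded_pts,
        query=cohort.query,
    )
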