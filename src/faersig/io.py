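"""Reading and writing FAERS-style quarterly ASCII extracts.

The FDA distributes FAERS as one dollar-delimited text file per table per
quarter (DEMO, DRUG, REAC, OUTC, INDI, THER), each with a single header
line and no quoting or escape mechanism.  This module parses those files
into a :class:`RawRecordSet` of plain row dictionaries, assembles joined
:class:`FaersCase` records (one per report version, keyed by PRIMARYID),
and writes record sets back out in the same dialect so that synthetic
quarters round-trip exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: Canonical column order per table.  Real extracts carry more columns; the
#: parser is header-driven and keeps whatever columns a file declares, but
#: these are the fields the pipeline consumes and the writer emits.
TABLE_COLUMNS: dict[str, list[str]] = {
    "DEMO": [
        "primaryid", "caseid", "fda_dt", "age", "age_cod", "sex",
        "wt", "wt_cod", "occp_cod", "reporter_country",
    ],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
}

MANDATORY_TABLES = ("DEMO", "DRUG", "REAC")
OPTIONAL_TABLES = ("OUTC", "INDI", "THER")

DEFAULT_FILE_PATTERN = "{table}{yy}Q{q}.txt"

ROLE_CODES = frozenset({"PS", "SS", "C", "I", ""})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: AGE_COD → factor converting the coded value to years.
AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: WT_COD → factor converting the coded value to kilograms.
WEIGHT_FACTORS = {"KG": 1.0, "LBS": 0.453592, "GMS": 1.0 / 1000.0}

#: Occupation code → the three reporter buckets used in FAERS summaries.
REPORTER_MAP = {
    "MD": "physician",
    "PH": "other_health_professional",
    "OT": "other_health_professional",
    "HP": "other_health_professional",
    "RN": "other_health_professional",
    "CN": "consumer",
    "LW": "consumer",
}


class FaersIOError(Exception):
    """Unrecoverable problem with a quarterly extract."""


@dataclass
class RawRecordSet:
    """All rows of one quarter, one list of row-dicts per table."""

    demo_rows: list[dict] = field(default_factory=list)
    drug_rows: list[dict] = field(default_factory=list)
    reac_rows: list[dict] = field(default_factory=list)
    outc_rows: list[dict] = field(default_factory=list)
    indi_rows: list[dict] = field(default_factory=list)
    ther_rows: list[dict] = field(default_factory=list)
    source_quarter: str = ""
    #: per-table column order as declared by the file headers
    columns: dict[str, list[str]] = field(
        default_factory=lambda: {t: list(c) for t, c in TABLE_COLUMNS.items()}
    )

    _ATTR_FOR_TABLE = {
        "DEMO": "demo_rows", "DRUG": "drug_rows", "REAC": "reac_rows",
        "OUTC": "outc_rows", "INDI": "indi_rows", "THER": "ther_rows",
    }

    def rows_for(self, table: str) -> list[dict]:
        return getattr(self, self._ATTR_FOR_TABLE[table])


@dataclass(frozen=True)
class DrugEntry:
    """One DRUG row joined with its indication PTs from INDI."""

    seq: str
    name: str
    active_ingredient: str
    role: str
    indications: frozenset[str] = frozenset()


@dataclass(frozen=True)
class FaersCase:
    """One report version: demographics joined with drugs, reactions,
    outcomes and indications.

    ``caseid`` identifies the safety report; ``primaryid`` identifies this
    particular submitted version of it.  Age and weight are unit-converted
    to years / kilograms at assembly time or absent.
    """

    caseid: str
    primaryid: str
    fda_dt: date | None
    age_years: float | None
    sex: str  # male | female | unknown
    weight_kg: float | None
    reporter: str  # physician | other_health_professional | consumer | unknown
    country: str  # verbatim country string or "unknown"
    drugs: tuple[DrugEntry, ...]
    reactions: frozenset[str]
    outcomes: frozenset[str]
    indications: frozenset[str]

    def with_reactions(self, reactions: Iterable[str]) -> "FaersCase":
        return replace(self, reactions=frozenset(reactions))


def quarter_tokens(quarter: str) -> tuple[str, str]:
    """Split a quarter label like ``2014Q1`` into (two-digit year, quarter digit)."""
    q = quarter.strip().upper()
    if len(q) != 6 or q[4] != "Q" or not q[:4].isdigit() or q[5] not in "1234":
        raise FaersIOError(f"malformed quarter label: {quarter!r} (expected e.g. 2014Q1)")
    return q[2:4], q[5]


def _table_path(directory: Path, table: str, quarter: str, pattern: str) -> Path:
    yy, q = quarter_tokens(quarter)
    return directory / pattern.format(table=table, yy=yy, q=q)


def _read_table(path: Path, table: str) -> tuple[list[dict], list[str]]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline().rstrip("\r\n")
        if not header_line:
            raise FaersIOError(f"{path}: empty file (no header line)")
        columns = [c.strip().lower() for c in header_line.split(DELIMITER)]
        rows: list[dict] = []
        skipped = 0
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split(DELIMITER)
            if len(fields) != len(columns):
                skipped += 1
                continue
            rows.append(dict(zip(columns, fields)))
    if skipped:
        logger.warning("%s: skipped %d malformed row(s) (wrong field count)", path.name, skipped)
    return rows, columns


def read_quarter(directory: str | Path, quarter: str,
                 pattern: str = DEFAULT_FILE_PATTERN) -> RawRecordSet:
    """Parse one quarter's table files from ``directory``.

    DEMO, DRUG and REAC are mandatory; a missing file is a hard error.
    OUTC, INDI and THER are optional and yield empty row lists with a
    warning.  Rows whose field count disagrees with the header are skipped
    and counted in the log — never silently truncated or padded.
    """
    directory = Path(directory)
    out = RawRecordSet(source_quarter=quarter)
    for table in MANDATORY_TABLES + OPTIONAL_TABLES:
        path = _table_path(directory, table, quarter, pattern)
        if not path.exists():
            if table in MANDATORY_TABLES:
                raise FaersIOError(f"mandatory table file missing: {path}")
            logger.warning("optional table file missing: %s (treated as empty)", path)
            out.columns[table] = list(TABLE_COLUMNS[table])
            continue
        rows, columns = _read_table(path, table)
        out.rows_for(table).extend(rows)
        out.columns[table] = columns
    return out


def write_quarter(raw: RawRecordSet, directory: str | Path,
                  pattern: str = DEFAULT_FILE_PATTERN) -> list[Path]:
    """Write a record set as dollar-delimited quarter files.

    The dialect has no quoting, so a field value containing the delimiter
    cannot be represented and is rejected with an error naming the field.
    Returns the list of files written.  ``read_quarter`` of the output
    reproduces ``raw`` field for field.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FaersIOError(f"cannot create output directory {directory}: {exc}") from exc
    written: list[Path] = []
    for table in MANDATORY_TABLES + OPTIONAL_TABLES:
        columns = raw.columns.get(table, TABLE_COLUMNS[table])
        path = _table_path(directory, table, raw.source_quarter, pattern)
        lines = [DELIMITER.join(columns)]
        for row in raw.rows_for(table):
            values = []
            for col in columns:
                value = str(row.get(col, ""))
                if DELIMITER in value:
                    raise FaersIOError(
                        f"field {col!r} in table {table} contains the delimiter "
                        f"{DELIMITER!r} and cannot be written: {value!r}"
                    )
                values.append(value)
            lines.append(DELIMITER.join(values))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(path)
    return written


def _parse_date(text: str) -> date | None:
    text = text.strip()
    if len(text) != 8 or not text.isdigit():
        return None
    try:
        return date(int(text[:4]), int(text[4:6]), int(text[6:8]))
    except ValueError:
        return None


def convert_age(age: str, age_cod: str) -> float | None:
    """Convert a coded AGE/AGE_COD pair to years; None when unparseable."""
    try:
        value = float(age)
    except (TypeError, ValueError):
        return None
    factor = AGE_FACTORS.get(age_cod.strip().upper())
    if factor is None or value < 0:
        return None
    return value * factor


def convert_weight(wt: str, wt_cod: str) -> float | None:
    """Convert a coded WT/WT_COD pair to kilograms; None when unparseable."""
    try:
        value = float(wt)
    except (TypeError, ValueError):
        return None
    factor = WEIGHT_FACTORS.get(wt_cod.strip().upper())
    if factor is None or value <= 0:
        return None
    return value * factor


def _map_sex(code: str) -> str:
    return {"M": "male", "F": "female"}.get(code.strip().upper(), "unknown")


def _map_reporter(code: str) -> str:
    return REPORTER_MAP.get(code.strip().upper(), "unknown")


def _group_by(rows: Iterable[Mapping], key: str) -> dict[str, list[Mapping]]:
    grouped: dict[str, list[Mapping]] = {}
    for row in rows:
        grouped.setdefault(row.get(key, ""), []).append(row)
    return grouped


def assemble_cases(raw: RawRecordSet) -> list[FaersCase]:
    """Join the six tables into one :class:`FaersCase` per PRIMARYID in DEMO.

    Rows in DRUG/REAC/OUTC/INDI referencing a PRIMARYID absent from DEMO
    are dropped with a logged orphan count; blank reaction and indication
    PTs are dropped with a logged count.  Reactions are a set, so a PT
    coded twice on one report counts once.
    """
    demo_ids = {row.get("primaryid", "") for row in raw.demo_rows}
    drug_by_id = _group_by(raw.drug_rows, "primaryid")
    reac_by_id = _group_by(raw.reac_rows, "primaryid")
    outc_by_id = _group_by(raw.outc_rows, "primaryid")
    indi_by_id = _group_by(raw.indi_rows, "primaryid")

    orphans = sum(
        len(rows)
        for by_id in (drug_by_id, reac_by_id, outc_by_id, indi_by_id)
        for pid, rows in by_id.items()
        if pid not in demo_ids
    )
    if orphans:
        logger.warning("dropped %d row(s) referencing a PRIMARYID absent from DEMO", orphans)

    blank_pts = 0
    cases: list[FaersCase] = []
    seen: set[str] = set()
    for row in raw.demo_rows:
        pid = row.get("primaryid", "")
        if pid in seen:
            logger.warning("duplicate DEMO row for primaryid %s ignored", pid)
            continue
        seen.add(pid)

        indi_for_seq: dict[str, set[str]] = {}
        for indi in indi_by_id.get(pid, ()):
            pt = indi.get("indi_pt", "").strip()
            if not pt:
                blank_pts += 1
                continue
            indi_for_seq.setdefault(indi.get("indi_drug_seq", ""), set()).add(pt)

        drugs = tuple(
            DrugEntry(
                seq=d.get("drug_seq", ""),
                name=d.get("drugname", "").strip(),
                active_ingredient=d.get("prod_ai", "").strip(),
                role=d.get("role_cod", "").strip().upper(),
                indications=frozenset(indi_for_seq.get(d.get("drug_seq", ""), ())),
            )
            for d in drug_by_id.get(pid, ())
        )

        reactions = set()
        for reac in reac_by_id.get(pid, ()):
            pt = reac.get("pt", "").strip()
            if pt:
                reactions.add(pt)
            else:
                blank_pts += 1

        outcomes = {
            o.get("outc_cod", "").strip().upper()
            for o in outc_by_id.get(pid, ())
            if o.get("outc_cod", "").strip().upper() in OUTCOME_CODES
        }

        country = row.get("reporter_country", "").strip()
        cases.append(
            FaersCase(
                caseid=row.get("caseid", ""),
                primaryid=pid,
                fda_dt=_parse_date(row.get("fda_dt", "")),
                age_years=convert_age(row.get("age", ""), row.get("age_cod", "")),
                sex=_map_sex(row.get("sex", "")),
                weight_kg=convert_weight(row.get("wt", ""), row.get("wt_cod", "")),
                reporter=_map_reporter(row.get("occp_cod", "")),
                country=country if country else "unknown",
                drugs=drugs,
                reactions=frozenset(reactions),
                outcomes=frozenset(outcomes),
                indications=frozenset().union(*indi_for_seq.values()) if indi_for_seq else frozenset(),
            )
        )
    if blank_pts:
        logger.warning("dropped %d blank PT string(s) from REAC/INDI", blank_pts)
    return cases
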