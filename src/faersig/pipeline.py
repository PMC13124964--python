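"""End-to-end pipeline: ingestion -> deduplication -> cohort ->
contingency -> disproportionality -> descriptives, with run accounting.

Configuration is a single YAML file; every behavioural toggle of the
library surfaces as a key with its library default.  Outputs are tidy TSV
files plus a JSON run ledger echoing each stage's counts, so that no
report is dropped silently anywhere in the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import contingency as ct
from . import descriptives as dsc
from . import io as fio
from . import stats as st
from .dedup import DrugQuery, apply_pt_exclusion, build_cohort, deduplicate
from .meddra import load_dictionary, load_toy_dictionary
from .synthetic import generate, ground_truth_frame, scenario_from_dict

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    """A stage failed; the message names the stage."""


@dataclass
class RunLedger:
    """Flow accounting for one pipeline run."""

    n_retrieved: int = 0
    n_duplicates_removed: int = 0
    n_unique: int = 0
    n_drug_reports: int = 0
    n_event_entries: int = 0  # reaction PT entries across drug reports, post-exclusion
    n_excluded_pts: int = 0
    n_pt_tables: int = 0
    n_soc_tables: int = 0
    n_pt_signals: int = 0
    n_soc_signals: int = 0
    timestamps: dict[str, float] = field(default_factory=dict)

    def stamp(self, stage: str) -> None:
        self.timestamps[stage] = time.time()

    def validate(self) -> None:
        if self.n_unique != self.n_retrieved - self.n_duplicates_removed:
            raise PipelineError(
                "ledger arithmetic violated: "
                f"{self.n_retrieved} - {self.n_duplicates_removed} != {self.n_unique}"
            )
        if self.n_drug_reports > self.n_unique:
            raise PipelineError("ledger: more drug reports than unique cases")


@dataclass
class PipelineResult:
    ledger: RunLedger
    soc_decisions: list[st.SignalDecision]
    pt_decisions: list[st.SignalDecision]
    summary: dsc.DescriptiveSummary
    output_files: list[Path]


DEFAULT_CONFIG: dict = {
    "input": {
        "mode": "quarters",        # "quarters" | "synthetic"
        "directory": None,
        "quarters": [],
        "pattern": fio.DEFAULT_FILE_PATTERN,
        "scenario": {},            # synthetic-mode scenario overrides
    },
    "drug_query": {"name": "POTASSIUM CITRATE", "match": "substring", "synonyms": []},
    "exclusion": {"extra_pts": [], "disable": False},
    "meddra": {"dictionary_path": None, "unknown_policy": "unmapped-bucket"},
    "analysis": {
        "min_count": 3,
        "zero_cell_policy": "haldane",
        "counting_unit": "reports",
        "top_k_countries": 5,
    },
    "output": {"directory": "faersig_out"},
    "seed": 0,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _stage(name: str):
    """Wrap stage exceptions with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: dict | str | Path) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    On any stage failure, files already written for this run are removed
    and a :class:`PipelineError` naming the stage propagates.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge(DEFAULT_CONFIG, config)

    outdir = Path(config["output"]["directory"])
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    ledger = RunLedger()

    def emit(name: str, frame) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)

    try:
        ledger.stamp("start")
        with _stage("ingest"):
            cases = []
            truth = None
            mode = config["input"]["mode"]
            if mode == "synthetic":
                scenario_cfg = dict(config["input"]["scenario"] or {})
                scenario_cfg.setdefault("seed", config["seed"])
                scenario = scenario_from_dict(scenario_cfg)
                raw, truth = generate(scenario)
                cases = fio.assemble_cases(raw)
            elif mode == "quarters":
                directory = config["input"]["directory"]
                if not directory:
                    raise ValueError("input.directory is required in quarters mode")
                for quarter in config["input"]["quarters"]:
                    raw = fio.read_quarter(directory, quarter, config["input"]["pattern"])
                    cases.extend(fio.assemble_cases(raw))
            else:
                raise ValueError(f"unknown input mode: {mode!r}")
            ledger.n_retrieved = len(cases)
        ledger.stamp("ingest")

        with _stage("deduplicate"):
            dedup = deduplicate(cases)
            ledger.n_duplicates_removed = dedup.n_duplicates_removed
            ledger.n_unique = len(dedup.retained)
        ledger.stamp("deduplicate")

        with _stage("cohort"):
            query_cfg = config["drug_query"]
            query = DrugQuery(
                name=query_cfg["name"],
                match=query_cfg.get("match", "substring"),
                synonyms=tuple(query_cfg.get("synonyms", ())),
            )
            cohort = build_cohort(
                dedup, query,
                extra_excluded_pts=config["exclusion"].get("extra_pts", ()),
                disable_exclusion=config["exclusion"].get("disable", False),
            )
            cohort = apply_pt_exclusion(cohort)
            ledger.n_drug_reports = len(cohort.drug_cases)
            ledger.n_excluded_pts = len(cohort.excluded_pts)
            ledger.n_event_entries = sum(len(c.reactions) for c in cohort.drug_cases)
        ledger.stamp("cohort")

        with _stage("meddra"):
            dict_path = config["meddra"]["dictionary_path"]
            dictionary = load_dictionary(dict_path) if dict_path else load_toy_dictionary()
            unknown_policy = config["meddra"]["unknown_policy"]
        ledger.stamp("meddra")

        analysis = config["analysis"]
        decisions: dict[str, list[st.SignalDecision]] = {}
        for level in (ct.PT_LEVEL, ct.SOC_LEVEL):
            with _stage(f"analysis-{level}"):
                tables = ct.count_tables(
                    cohort, dictionary, level,
                    unknown_policy=unknown_policy,
                    counting_unit=analysis["counting_unit"],
                )
                emit(f"tables_{level.lower()}.tsv", ct.tables_frame(tables))
                tables = ct.filter_min_count(tables, analysis["min_count"])
                decisions[level] = st.run_level(tables, analysis["zero_cell_policy"])
                emit(f"signals_{level.lower()}.tsv", st.decisions_frame(decisions[level]))
            ledger.stamp(f"analysis-{level}")
        ledger.n_pt_tables = len(decisions[ct.PT_LEVEL])
        ledger.n_soc_tables = len(decisions[ct.SOC_LEVEL])
        ledger.n_pt_signals = sum(d.is_signal for d in decisions[ct.PT_LEVEL])
        ledger.n_soc_signals = sum(d.is_signal for d in decisions[ct.SOC_LEVEL])

        with _stage("descriptives"):
            summary = dsc.summarize(cohort.drug_cases, analysis["top_k_countries"])
            emit("descriptives.tsv", dsc.summary_frame(summary))
            (outdir / "descriptives.txt").write_text(
                dsc.format_text(summary) + "\n", encoding="utf-8")
            written.append(outdir / "descriptives.txt")
        ledger.stamp("descriptives")

        if truth is not None:
            emit("ground_truth.tsv", ground_truth_frame(truth))

        ledger.validate()
        ledger_path = outdir / "ledger.json"
        ledger_path.write_text(json.dumps(asdict(ledger), indent=2) + "\n", encoding="utf-8")
        written.append(ledger_path)
    except Exception:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise

    logger.info(
        "run complete: %d retrieved, %d duplicates removed, %d unique, "
        "%d drug reports; %d PT signal(s), %d SOC signal(s)",
        ledger.n_retrieved, ledger.n_duplicates_removed, ledger.n_unique,
        ledger.n_drug_reports, ledger.n_pt_signals, ledger.n_soc_signals,
    )
    return PipelineResult(
        ledger=ledger,
        soc_decisions=decisions[ct.SOC_LEVEL],
        pt_decisions=decisions[ct.PT_LEVEL],
        summary=summary,
        output_files=written,
    )
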