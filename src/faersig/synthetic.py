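"""Synthetic FAERS-shaped quarterly data with known ground truth.

The generator emulates the structure of the quarterly extracts — per-case
demographics with realistic missingness, drug rows with role codes,
MedDRA-PT reaction rows, outcome codes, indication rows, and deliberate
duplicate case versions — under a reporting model simple enough to admit
closed-form expectations:

* each case is a target-drug (primary suspect) case with probability
  ``target_drug_fraction``, otherwise a background case;
* the case draws ``k`` distinct reaction PTs (zero-truncated Poisson,
  stated mean) from the PT catalog, with sampling weight
  ``background_probability x injected relative rate`` for target cases
  and ``background_probability`` for background cases;
* with probability ``duplicate_rate`` the case additionally emits an
  earlier report version: identical content, distinct PRIMARYID, strictly
  earlier FDA_DT — so deduplication can be verified exactly.

Defaults mirror a small-cohort pharmacovigilance setting: ~400 target
reports among 5000, ~1.86 reaction entries per report, a ~13.9% duplicate
ratio, and FAERS-typical field missingness (age ~25%, weight ~90%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import yaml

from .io import RawRecordSet

TARGET_DRUG = "POTASSIUM CITRATE"

#: (PT, primary SOC, background sampling weight) — matches the bundled toy
#: PT->SOC dictionary.  Weights are relative reporting frequencies of each
#: term among all reports, loosely graded from very common complaints to
#: rare product-quality terms.
DEFAULT_PT_CATALOG: tuple[tuple[str, str, float], ...] = (
    ("Drug ineffective", "General disorders and administration site conditions", 0.100),
    ("Nausea", "Gastrointestinal disorders", 0.070),
    ("Fatigue", "General disorders and administration site conditions", 0.060),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.050),
    ("Vomiting", "Gastrointestinal disorders", 0.050),
    ("Abdominal pain", "Gastrointestinal disorders", 0.045),
    ("Pyrexia", "General disorders and administration site conditions", 0.040),
    ("Pruritus", "Skin and subcutaneous tissue disorders", 0.035),
    ("Abdominal discomfort", "Gastrointestinal disorders", 0.030),
    ("Weight decreased", "Investigations", 0.025),
    ("Palpitations", "Cardiac disorders", 0.020),
    ("Drug dose omission", "Injury, poisoning and procedural complications", 0.020),
    ("Blood creatinine increased", "Investigations", 0.015),
    ("Dysphagia", "Gastrointestinal disorders", 0.012),
    ("Nephrolithiasis", "Renal and urinary disorders", 0.012),
    ("Oropharyngeal pain", "Respiratory, thoracic and mediastinal disorders", 0.012),
    ("Maternal exposure during pregnancy", "Injury, poisoning and procedural complications", 0.010),
    ("Flank pain", "Musculoskeletal and connective tissue disorders", 0.010),
    ("Proteinuria", "Renal and urinary disorders", 0.009),
    ("Pollakiuria", "Renal and urinary disorders", 0.008),
    ("Renal colic", "Renal and urinary disorders", 0.008),
    ("Throat irritation", "Respiratory, thoracic and mediastinal disorders", 0.008),
    ("Hyperkalaemia", "Metabolism and nutrition disorders", 0.008),
    ("Product dispensing error", "Injury, poisoning and procedural complications", 0.008),
    ("Blood potassium increased", "Investigations", 0.006),
    ("Retching", "Gastrointestinal disorders", 0.006),
    ("Drug ineffective for unapproved indication",
     "General disorders and administration site conditions", 0.006),
    ("Product substitution issue", "Product issues", 0.005),
    ("Product use complaint", "Product issues", 0.004),
    ("Malabsorption", "Gastrointestinal disorders", 0.003),
    ("Product physical issue", "Product issues", 0.003),
    ("Foreign body", "Injury, poisoning and procedural complications", 0.003),
    ("Product residue present", "Product issues", 0.002),
    ("Poor quality product administered", "Product issues", 0.002),
    ("Foreign body in respiratory tract",
     "Injury, poisoning and procedural complications", 0.002),
    ("Medication residue present", "Product issues", 0.0015),
    ("Product solubility abnormal", "Product issues", 0.001),
)

OTHER_DRUGS = (
    "LISINOPRIL", "METFORMIN", "ATORVASTATIN", "OMEPRAZOLE", "AMLODIPINE",
    "LEVOTHYROXINE", "IBUPROFEN", "HYDROCHLOROTHIAZIDE", "ASPIRIN", "GABAPENTIN",
)

OUTCOME_WEIGHTS = (("OT", 0.40), ("HO", 0.35), ("DE", 0.15),
                   ("LT", 0.04), ("DS", 0.03), ("CA", 0.02), ("RI", 0.01))

COUNTRY_WEIGHTS = (("US", 0.92), ("CA", 0.03), ("JP", 0.02), ("IN", 0.02), ("GB", 0.01))


class ScenarioError(ValueError):
    """A scenario field failed validation."""


@dataclass(frozen=True)
class Missingness:
    age: float = 0.255
    sex: float = 0.118
    weight: float = 0.897
    country: float = 0.054


@dataclass(frozen=True)
class SyntheticScenario:
    """Generator parameters; defaults describe the reference study setting."""

    n_cases: int = 5000
    target_drug_fraction: float = 0.08
    pt_catalog: tuple[tuple[str, str, float], ...] = DEFAULT_PT_CATALOG
    injected_signals: tuple[tuple[str, float], ...] = ()
    events_per_case_mean: float = 1.86  # mean of the zero-truncated Poisson
    duplicate_rate: float = 0.139
    missingness: Missingness = field(default_factory=Missingness)
    indication_pts: tuple[str, ...] = ("Nephrolithiasis",)
    indication_rate: float = 0.5
    outcome_rate: float = 0.25
    concomitant_rate: float = 0.79
    quarter: str = "2014Q1"
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1:
            raise ScenarioError("n_cases must be >= 1")
        for name in ("target_drug_fraction", "duplicate_rate", "indication_rate",
                     "outcome_rate", "concomitant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{name} must be a probability in [0, 1], got {v}")
        for name in ("age", "sex", "weight", "country"):
            v = getattr(self.missingness, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"missingness.{name} must be in [0, 1], got {v}")
        if self.events_per_case_mean <= 1.0:
            raise ScenarioError("events_per_case_mean must exceed 1 (minimum one event per case)")
        pts = [pt for pt, _, _ in self.pt_catalog]
        if len(pts) != len(set(pts)):
            raise ScenarioError("pt_catalog PTs must be unique")
        for pt, _, p in self.pt_catalog:
            if p < 0:
                raise ScenarioError(f"pt_catalog background probability for {pt!r} must be >= 0")
        catalog = set(pts)
        for pt, rate in self.injected_signals:
            if pt not in catalog:
                raise ScenarioError(f"injected_signals PT {pt!r} not in pt_catalog")
            if rate < 0:
                raise ScenarioError(f"injected relative rate for {pt!r} must be >= 0")

    @property
    def rate_for(self) -> dict[str, float]:
        rates = {pt: 1.0 for pt, _, _ in self.pt_catalog}
        rates.update(dict(self.injected_signals))
        return rates


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    scenario: SyntheticScenario
    target_caseids: frozenset[str]
    #: CASEID -> all emitted PRIMARYIDs, latest version last
    versions: dict[str, tuple[str, ...]]
    #: PT -> injected relative reporting rate (1.0 when not injected)
    relative_rates: dict[str, float]

    @property
    def n_extra_versions(self) -> int:
        return sum(len(v) - 1 for v in self.versions.values())


def _truncated_poisson_lambda(mean: float) -> float:
    """Poisson parameter whose zero-truncated mean equals ``mean`` (Newton)."""
    lam = mean
    for _ in range(50):
        em = math.exp(-lam)
        f = lam / (1.0 - em) - mean
        df = (1.0 - em - lam * em) / (1.0 - em) ** 2
        step = f / df
        lam -= step
        if abs(step) < 1e-12:
            break
    return lam


def _sample_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    k = rng.poisson(lam, size=size)
    while True:
        zero = k == 0
        if not zero.any():
            return k
        k[zero] = rng.poisson(lam, size=int(zero.sum()))


def _weights(scenario: SyntheticScenario, target: bool) -> np.ndarray:
    rates = scenario.rate_for
    w = np.array(
        [p * (rates[pt] if target else 1.0) for pt, _, p in scenario.pt_catalog],
        dtype=float,
    )
    total = w.sum()
    if total <= 0:
        raise ScenarioError("pt_catalog weights sum to zero")
    return w / total


def _date_str(d: date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def generate(scenario: SyntheticScenario) -> tuple[RawRecordSet, GroundTruth]:
    """Generate one quarter of FAERS-shaped rows plus its ground truth.

    Deterministic under ``scenario.seed``; duplicate versions share the
    CASEID with a distinct PRIMARYID and a strictly earlier FDA_DT and are
    otherwise byte-identical in content.
    """
    rng = np.random.default_rng(scenario.seed)
    lam = _truncated_poisson_lambda(scenario.events_per_case_mean)
    n = scenario.n_cases
    catalog_pts = [pt for pt, _, _ in scenario.pt_catalog]
    w_target = _weights(scenario, target=True)
    w_background = _weights(scenario, target=False)

    is_target = rng.random(n) < scenario.target_drug_fraction
    k_events = np.minimum(_sample_truncated_poisson(rng, lam, n), len(catalog_pts))
    ages = np.clip(rng.normal(55.0, 18.0, n), 1.0, 95.0)
    age_missing = rng.random(n) < scenario.missingness.age
    sexes = np.where(rng.random(n) < 0.5, "M", "F")
    sex_missing = rng.random(n) < scenario.missingness.sex
    weights_kg = np.clip(rng.normal(80.0, 18.0, n), 35.0, 180.0)
    weight_missing = rng.random(n) < scenario.missingness.weight
    country_missing = rng.random(n) < scenario.missingness.country
    country_draw = rng.choice(
        [c for c, _ in COUNTRY_WEIGHTS], size=n,
        p=np.array([p for _, p in COUNTRY_WEIGHTS]) / sum(p for _, p in COUNTRY_WEIGHTS),
    )
    occp_draw = rng.choice(["MD", "OT", "CN"], size=n, p=[0.73, 0.206, 0.064])
    has_outcome = rng.random(n) < scenario.outcome_rate
    duplicated = rng.random(n) < scenario.duplicate_rate

    base = date(int(scenario.quarter[:4]), 1, 1)
    latest_offsets = rng.integers(120, 420, size=n)
    dup_back = rng.integers(30, 110, size=n)

    raw = RawRecordSet(source_quarter=scenario.quarter)
    versions: dict[str, tuple[str, ...]] = {}
    target_caseids: set[str] = set()

    for i in range(n):
        caseid = str(10000000 + i)
        latest_dt = base + timedelta(days=int(latest_offsets[i]))
        pids = [f"{caseid}2"]
        dts = [latest_dt]
        if duplicated[i]:
            pids.insert(0, f"{caseid}1")
            dts.insert(0, latest_dt - timedelta(days=int(dup_back[i])))
        versions[caseid] = tuple(pids)
        if is_target[i]:
            target_caseids.add(caseid)

        # case content, shared verbatim by every version
        weights = w_target if is_target[i] else w_background
        events = [catalog_pts[j] for j in
                  rng.choice(len(catalog_pts), size=int(k_events[i]), replace=False, p=weights)]

        drug_rows = []
        indi_rows = []
        if is_target[i]:
            drug_rows.append(("1", "PS", TARGET_DRUG, TARGET_DRUG))
            for pt in scenario.indication_pts:
                if rng.random() < scenario.indication_rate:
                    indi_rows.append(("1", pt))
            if rng.random() < scenario.concomitant_rate:
                for j, name in enumerate(
                        rng.choice(OTHER_DRUGS, size=int(rng.integers(1, 4)), replace=False)):
                    drug_rows.append((str(2 + j), "C", name, name))
        else:
            names = rng.choice(OTHER_DRUGS, size=int(rng.integers(1, 4)), replace=False)
            for j, name in enumerate(names):
                drug_rows.append((str(1 + j), "PS" if j == 0 else ("SS" if j == 1 else "C"),
                                  name, name))
            if rng.random() < 0.3:
                indi_rows.append(("1", "Hypertension"))

        outcome_codes: list[str] = []
        if has_outcome[i]:
            n_codes = int(rng.integers(1, 3))
            outcome_codes = list(rng.choice(
                [c for c, _ in OUTCOME_WEIGHTS], size=n_codes, replace=False,
                p=[p for _, p in OUTCOME_WEIGHTS]))

        demo_common = {
            "caseid": caseid,
            "age": "" if age_missing[i] else str(int(round(ages[i]))),
            "age_cod": "" if age_missing[i] else "YR",
            "sex": "" if sex_missing[i] else str(sexes[i]),
            "wt": "" if weight_missing[i] else str(int(round(weights_kg[i]))),
            "wt_cod": "" if weight_missing[i] else "KG",
            "occp_cod": str(occp_draw[i]),
            "reporter_country": "" if country_missing[i] else str(country_draw[i]),
        }
        for pid, dt in zip(pids, dts):
            raw.demo_rows.append({"primaryid": pid, "fda_dt": _date_str(dt), **demo_common})
            for seq, role, name, ai in drug_rows:
                raw.drug_rows.append({
                    "primaryid": pid, "caseid": caseid, "drug_seq": seq,
                    "role_cod": role, "drugname": name, "prod_ai": ai,
                })
                raw.ther_rows.append({
                    "primaryid": pid, "caseid": caseid, "dsg_drug_seq": seq,
                    "start_dt": _date_str(dt - timedelta(days=90)), "end_dt": "",
                })
            for pt in events:
                raw.reac_rows.append({"primaryid": pid, "caseid": caseid, "pt": pt})
            for code in outcome_codes:
                raw.outc_rows.append({"primaryid": pid, "caseid": caseid, "outc_cod": code})
            for seq, pt in indi_rows:
                raw.indi_rows.append({
                    "primaryid": pid, "caseid": caseid,
                    "indi_drug_seq": seq, "indi_pt": pt,
                })

    truth = GroundTruth(
        scenario=scenario,
        target_caseids=frozenset(target_caseids),
        versions=versions,
        relative_rates=scenario.rate_for,
    )
    return raw, truth


@dataclass(frozen=True)
class ExpectedTable:
    """Real-valued expectation of a 2x2 table under the generator model."""

    pt: str
    a: float
    b: float
    c: float
    d: float

    @property
    def ror(self) -> float:
        return (self.a * self.d) / (self.b * self.c)


def _event_probability(q: float, lam: float) -> float:
    # P(PT drawn at least once) for k ~ zero-truncated Poisson(lam) draws
    # with per-draw inclusion weight q, using the with-replacement closed
    # form E[1 - (1-q)^k]; a mild approximation to without-replacement
    # sampling, accurate for small q.
    return 1.0 - (math.exp(lam * (1.0 - q)) - 1.0) / (math.exp(lam) - 1.0)


def expected_table(scenario: SyntheticScenario, pt: str) -> ExpectedTable:
    """Analytic expectation of (a, b, c, d) for one catalog PT."""
    pts = [p for p, _, _ in scenario.pt_catalog]
    if pt not in pts:
        raise ScenarioError(f"PT {pt!r} not in pt_catalog")
    idx = pts.index(pt)
    lam = _truncated_poisson_lambda(scenario.events_per_case_mean)
    q_target = float(_weights(scenario, target=True)[idx])
    q_background = float(_weights(scenario, target=False)[idx])
    n_target = scenario.n_cases * scenario.target_drug_fraction
    n_background = scenario.n_cases * (1.0 - scenario.target_drug_fraction)
    a = n_target * _event_probability(q_target, lam)
    c = n_background * _event_probability(q_background, lam)
    return ExpectedTable(pt=pt, a=a, b=n_target - a, c=c, d=n_background - c)


def scenario_from_yaml(path: str | Path) -> SyntheticScenario:
    """Load a scenario from a YAML file (missing keys take the defaults)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return scenario_from_dict(data)


def scenario_from_dict(data: dict) -> SyntheticScenario:
    kwargs = dict(data)
    if "pt_catalog" in kwargs:
        kwargs["pt_catalog"] = tuple(tuple(row) for row in kwargs["pt_catalog"])
    if "injected_signals" in kwargs:
        kwargs["injected_signals"] = tuple(
            (pt, float(rate)) for pt, rate in kwargs["injected_signals"])
    if "indication_pts" in kwargs:
        kwargs["indication_pts"] = tuple(kwargs["indication_pts"])
    if "missingness" in kwargs:
        kwargs["missingness"] = Missingness(**kwargs["missingness"])
    try:
        return SyntheticScenario(**kwargs)
    except TypeError as exc:
        raise ScenarioError(str(exc)) from exc


def ground_truth_frame(truth: GroundTruth):
    """Tidy per-PT ground-truth table (pt, soc, background_p, relative_rate)."""
    import pandas as pd

    rows = [
        {"pt": pt, "soc": soc, "background_p": p,
         "relative_rate": truth.relative_rates[pt]}
        for pt, soc, p in truth.scenario.pt_catalog
    ]
    return pd.DataFrame(rows, columns=["pt", "soc", "background_p", "relative_rate"])
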