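from __future__ import annotations

from datetime import date

import pytest

from faersig.io import DrugEntry, FaersCase
from faersig.meddra import load_toy_dictionary


@pytest.fixture(scope="session")
def toy_dict():
    return load_toy_dictionary()


def make_case(
    caseid: str = "1000",
    primaryid: str = "10002",
    fda_dt: date = date(2024, 3, 1),
    reactions=("Rash",),
    drugs=(("POTASSIUM CITRATE", "PS"),),
    indications=(),
    outcomes=(),
    age_years=None,
    sex="unknown",
    weight_kg=None,
    reporter="unknown",
    country="US",
) -> FaersCase:
    """Hand-built FaersCase with sensible defaults for unit tests."""
    entries = tuple(
        DrugEntry(
            seq=str(i + 1), name=name, active_ingredient=name, role=role,
            indications=frozenset(indications) if role == "PS" else frozenset(),
        )
        for i, (name, role) in enumerate(drugs)
    )
    return FaersCase(
        caseid=caseid, primaryid=primaryid, fda_dt=fda_dt,
        age_years=age_years, sex=sex, weight_kg=weight_kg,
        reporter=reporter, country=country,
        drugs=entries, reactions=frozenset(reactions),
        outcomes=frozenset(outcomes), indications=frozenset(indications),
    )


@pytest.fixture
def case_factory():
    return make_case
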