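import logging
from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faersig.dedup import (DedupError, DrugQuery, apply_pt_exclusion, build_cohort,
                           deduplicate)
from tests.conftest import make_case


class TestDeduplicate:
    def test_most_recent_fda_dt_retained(self):
        older = make_case(caseid="555", primaryid="5551", fda_dt=date(2024, 1, 1))
        newer = make_case(caseid="555", primaryid="5550", fda_dt=date(2024, 3, 1))
        result = deduplicate([older, newer])
        assert result.retained == (newer,)
        assert result.n_duplicates_removed == 1

    def test_tie_broken_by_highest_primaryid(self):
        v1 = make_case(caseid="555", primaryid="5551", fda_dt=date(2024, 1, 1))
        v2 = make_case(caseid="555", primaryid="5552", fda_dt=date(2024, 1, 1))
        result = deduplicate([v2, v1])
        assert result.retained[0].primaryid == "5552"

    def test_primaryid_compared_numerically_not_lexically(self):
        v1 = make_case(caseid="7", primaryid="9", fda_dt=date(2024, 1, 1))
        v2 = make_case(caseid="7", primaryid="10", fda_dt=date(2024, 1, 1))
        assert deduplicate([v1, v2]).retained[0].primaryid == "10"

    def test_distinct_caseids_all_retained(self):
        cases = [make_case(caseid=str(i), primaryid=f"{i}1") for i in range(10)]
        result = deduplicate(cases)
        assert len(result.retained) == 10
        assert result.n_duplicates_removed == 0

    def test_unparseable_primaryid_is_hard_error(self):
        with pytest.raises(DedupError, match="PRIMARYID"):
            deduplicate([make_case(primaryid="12x4")])

    def test_idempotent(self):
        cases = [
            make_case(caseid=str(i // 2), primaryid=f"{i}0",
                      fda_dt=date(2024, 1, 1 + i % 2))
            for i in range(12)
        ]
        once = deduplicate(cases)
        twice = deduplicate(list(once.retained))
        assert twice.retained == once.retained
        assert twice.n_duplicates_removed == 0

    @settings(derandomize=True, max_examples=30)
    @given(perm=st.permutations(list(range(9))))
    def test_order_independent(self, perm):
        cases = [
            make_case(caseid=str(i % 3), primaryid=f"{100 + i}",
                      fda_dt=date(2024, 1, 1 + i % 4))
            for i in range(9)
        ]
        baseline = deduplicate(cases)
        shuffled = deduplicate([cases[i] for i in perm])
        assert set(shuffled.retained) == set(baseline.retained)

    def test_accounting_balances(self):
        cases = [make_case(caseid=str(i % 4), primaryid=f"{10 + i}") for i in range(10)]
        result = deduplicate(cases)
        assert result.n_input == result.n_duplicates_removed + len(result.retained)


class TestBuildCohort:
    def test_primary_suspect_match_enters_cohort(self):
        ps = make_case(caseid="1", primaryid="11", drugs=(("POTASSIUM CITRATE", "PS"),))
        concomitant = make_case(caseid="2", primaryid="21",
                                drugs=(("POTASSIUM CITRATE", "C"), ("METFORMIN", "PS")))
        other = make_case(caseid="3", primaryid="31", drugs=(("METFORMIN", "PS"),))
        cohort = build_cohort(deduplicate([ps, concomitant, other]),
                              DrugQuery("potassium citrate"))
        assert cohort.drug_cases == (ps,)
        assert set(cohort.background_cases) == {concomitant, other}

    def test_partition_is_complete(self):
        cases = [make_case(caseid=str(i), primaryid=f"{i}9",
                           drugs=(("POTASSIUM CITRATE" if i % 3 == 0 else "ASPIRIN", "PS"),))
                 for i in range(12)]
        dedup = deduplicate(cases)
        cohort = build_cohort(dedup, DrugQuery("POTASSIUM CITRATE"))
        assert len(cohort.drug_cases) + len(cohort.background_cases) == len(dedup.retained)
        assert not set(cohort.drug_cases) & set(cohort.background_cases)

    def test_substring_and_exact_matching(self):
        case = make_case(drugs=(("UROCIT-K (POTASSIUM CITRATE)", "PS"),))
        dedup = deduplicate([case])
        assert build_cohort(dedup, DrugQuery("potassium  citrate")).drug_cases
        assert not build_cohort(dedup, DrugQuery("potassium citrate", match="exact")).drug_cases
        assert build_cohort(
            dedup, DrugQuery("nope", match="exact", synonyms=("UROCIT-K (POTASSIUM CITRATE)",))
        ).drug_cases

    def test_indication_pts_harvested_from_target_drug_only(self):
        target = make_case(caseid="1", primaryid="11", indications=("Nephrolithiasis",))
        bystander = make_case(caseid="2", primaryid="21", drugs=(("METFORMIN", "PS"),),
                              indications=("Diabetes mellitus",))
        cohort = build_cohort(deduplicate([target, bystander]), DrugQuery("POTASSIUM CITRATE"))
        assert cohort.excluded_pts == {"Nephrolithiasis"}

    def test_empty_cohort_warns_not_fatal(self, caplog):
        dedup = deduplicate([make_case(drugs=(("ASPIRIN", "PS"),))])
        with caplog.at_level(logging.WARNING):
            cohort = build_cohort(dedup, DrugQuery("POTASSIUM CITRATE"))
        assert cohort.drug_cases == ()
        assert "matched no" in caplog.text


class TestPtExclusion:
    def test_excluded_pts_removed_from_drug_cases_only(self):
        drug_case = make_case(caseid="1", primaryid="11",
                              reactions=("Nephrolithiasis", "Rash"),
                              indications=("Nephrolithiasis",))
        bg = make_case(caseid="2", primaryid="21", drugs=(("ASPIRIN", "PS"),),
                       reactions=("Nephrolithiasis",))
        cohort = build_cohort(deduplicate([drug_case, bg]), DrugQuery("POTASSIUM CITRATE"))
        cohort = apply_pt_exclusion(cohort)
        assert cohort.drug_cases[0].reactions == {"Rash"}
        assert cohort.background_cases[0].reactions == {"Nephrolithiasis"}

    def test_empty_exclusion_set_is_identity(self):
        case = make_case(reactions=("Rash",))
        cohort = build_cohort(deduplicate([case]), DrugQuery("POTASSIUM CITRATE"))
        assert apply_pt_exclusion(cohort) is cohort

    def test_fully_excluded_case_stays_in_denominator(self):
        only_indication = make_case(caseid="1", primaryid="11",
                                    reactions=("Nephrolithiasis",),
                                    indications=("Nephrolithiasis",))
        cohort = apply_pt_exclusion(
            build_cohort(deduplicate([only_indication]), DrugQuery("POTASSIUM CITRATE")))
        assert len(cohort.drug_cases) == 1
        assert cohort.drug_cases[0].reactions == frozenset()

    def test_extra_pts_from_config_are_excluded(self):
        case = make_case(reactions=("Rash", "Pruritus"))
        cohort = build_cohort(deduplicate([case]), DrugQuery("POTASSIUM CITRATE"),
                              extra_excluded_pts=("Pruritus",))
        assert apply_pt_exclusion(cohort).drug_cases[0].reactions == {"Rash"}
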