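import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faersig.contingency import ContingencyTable, PT_LEVEL
from faersig.stats import (compute_bcpnn, compute_ebgm, compute_prr_chi2, compute_ror,
                           compute_statistics, decide_signal, decisions_frame,
                           round_half_up, run_level, SignalStatistics)
from tests.published_rows import PT_ROWS, SOC_ROWS, as_statistics


def table(a, b, c, d):
    return ContingencyTable("x", PT_LEVEL, a=a, b=b, c=c, d=d)


WORKED = table(20, 80, 100, 9800)


class TestPointEstimates:
    def test_ror_worked_example(self):
        ror, low, high = compute_ror(WORKED)
        assert ror == pytest.approx(24.5)
        assert low == pytest.approx(14.448, abs=1e-3)
        assert high == pytest.approx(41.546, abs=1e-3)

    def test_prr_chi2_worked_example(self):
        prr, chi2 = compute_prr_chi2(WORKED)
        assert prr == pytest.approx(19.8)
        assert chi2 == pytest.approx(301.12, abs=0.01)

    def test_bcpnn_worked_example(self):
        ic, ic025, var = compute_bcpnn(WORKED)
        assert ic == pytest.approx(math.log2(16.6667), abs=1e-4)
        assert math.sqrt(var) == pytest.approx(0.2571, abs=1e-4)
        assert ic025 == pytest.approx(ic - 2 * 0.2571, abs=1e-3)

    def test_ebgm_worked_example(self):
        ebgm, ebgm05 = compute_ebgm(WORKED)
        assert ebgm == pytest.approx(16.6667, abs=1e-4)
        assert ebgm05 == pytest.approx(9.83, abs=0.01)

    @pytest.mark.parametrize("t", [table(1, 1, 1, 1), table(25, 25, 25, 25),
                                   table(2, 2, 2, 2), table(10, 90, 20, 180)])
    def test_independence_tables(self, t):
        """a*d = b*c and a*N = (a+b)(a+c): every estimate is 1, chi2 and IC are 0."""
        s = compute_statistics(t)
        assert s.ror == pytest.approx(1.0)
        assert s.prr == pytest.approx(1.0)
        assert s.ebgm == pytest.approx(1.0)
        assert s.ic == pytest.approx(0.0, abs=1e-12)
        assert s.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_ic_equals_log2_ebgm(self):
        for t in [WORKED, table(4, 404, 96, 13000), table(67, 341, 800, 14000000)]:
            s = compute_statistics(t)
            assert s.ic == pytest.approx(math.log2(s.ebgm), rel=1e-14)

    def test_monotonicity_in_a(self):
        rors, ebgms = [], []
        for a in range(1, 30):
            s = compute_statistics(table(a, 80, 100, 9800))
            rors.append(s.ror)
            ebgms.append(s.ebgm)
        assert all(x < y for x, y in zip(rors, rors[1:]))
        assert all(x < y for x, y in zip(ebgms, ebgms[1:]))


class TestZeroCells:
    def test_haldane_correction_applied_and_flagged(self):
        s = compute_statistics(table(0, 100, 50, 9850))
        expected = (0.5 * 9850.5) / (100.5 * 50.5)
        assert s.corrected
        assert s.ror == pytest.approx(expected)

    def test_undefined_policy_yields_nan_and_no_signal(self):
        s = compute_statistics(table(0, 100, 50, 9850), zero_cell_policy="undefined")
        assert math.isnan(s.ror) and math.isnan(s.ic) and math.isnan(s.ebgm05)
        decision = decide_signal(s)
        assert decision.n_methods_met == 0 and not decision.is_signal

    def test_nonzero_table_is_never_corrected(self):
        assert not compute_statistics(WORKED).corrected

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            compute_statistics(WORKED, zero_cell_policy="wish")


class TestDecideSignal:
    def test_two_of_four_rule_on_borderline_published_row(self):
        # ROR lower bound 1.01 and IC025 0.23 met; PRR 1.76 and EBGM05 0.99 not
        cardiac = as_statistics(SOC_ROWS[-1], "SOC")
        decision = decide_signal(cardiac)
        assert (decision.ror_met, decision.prr_met,
                decision.bcpnn_met, decision.mgps_met) == (True, False, True, False)
        assert decision.n_methods_met == 2 and decision.is_signal

    def test_all_four_methods_on_strong_published_row(self):
        product_issues = as_statistics(SOC_ROWS[0], "SOC")
        decision = decide_signal(product_issues)
        assert decision.n_methods_met == 4 and decision.is_signal

    def test_independence_table_is_no_signal(self):
        decision = decide_signal(compute_statistics(table(25, 25, 25, 25)))
        assert decision.n_methods_met == 0 and not decision.is_signal

    def test_prr_requires_both_prr_and_chi2(self):
        stats = SignalStatistics(prr=2.5, chi2=3.9)
        assert not decide_signal(stats).prr_met
        stats = SignalStatistics(prr=2.5, chi2=4.0)
        assert decide_signal(stats).prr_met


class TestRunLevel:
    def test_ranked_by_descending_ror_then_a_then_label(self):
        tables = [
            ContingencyTable("B", PT_LEVEL, 10, 90, 10, 890),   # ror 9.89
            ContingencyTable("A", PT_LEVEL, 20, 80, 40, 860),   # ror 5.375
            ContingencyTable("C", PT_LEVEL, 20, 180, 10, 490),  # ror 5.44
        ]
        order = [d.stats.event_label for d in run_level(tables)]
        assert order == ["B", "C", "A"]

    def test_empty_input(self):
        assert run_level([]) == []

    def test_frame_mirrors_decisions(self):
        decisions = run_level([WORKED, table(5, 95, 500, 9500)])
        frame = decisions_frame(decisions)
        assert list(frame["event_label"]) == [d.stats.event_label for d in decisions]
        assert frame["is_signal"].tolist() == [d.is_signal for d in decisions]


class TestRounding:
    @pytest.mark.parametrize("value,decimals,expected", [
        (2.675, 2, 2.68),     # half-up, not banker's
        (1.005, 2, 1.01),
        (41.666, 1, 41.7),
        (9.1418, 2, 9.14),
    ])
    def test_half_up(self, value, decimals, expected):
        assert round_half_up(value, decimals) == expected


@settings(derandomize=True, max_examples=200)
@given(
    a=st.integers(1, 500), b=st.integers(1, 100000),
    c=st.integers(1, 100000), d=st.integers(1, 10000000),
)
def test_interval_ordering_invariants(a, b, c, d):
    s = compute_statistics(table(a, b, c, d))
    assert s.ror_low <= s.ror <= s.ror_high
    assert s.ebgm05 <= s.ebgm or math.isclose(s.ebgm05, s.ebgm)
    assert s.ic025 <= s.ic
    assert s.chi2 >= 0
    assert s.ebgm == pytest.approx(2 ** s.ic, rel=1e-12)


def test_published_rows_satisfy_interval_ordering():
    for rows, level in ((SOC_ROWS, "SOC"), (PT_ROWS, "PT")):
        for row in rows:
            s = as_statistics(row, level)
            assert s.ror_low <= s.ror <= s.ror_high
            assert s.ebgm05 <= s.ebgm
            assert s.ic025 <= s.ic
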