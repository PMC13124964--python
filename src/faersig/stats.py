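"""The four disproportionality statistics and the >=2-method signal rule.

For a 2x2 table (a, b, c, d) with N = a+b+c+d:

* ROR  = (a*d)/(b*c), 95% CI = exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d))
* PRR  = [a/(a+b)] / [c/(c+d)], with the uncorrected chi-squared
  chi2 = (a*d - b*c)^2 * N / ((a+b)(c+d)(a+c)(b+d))
* BCPNN information component IC = log2(a*N / ((a+c)(a+b))), interval
  IC +/- 2*sqrt(V(IC)) with a delta-method variance
  V(IC) = (1/ln 2)^2 * (1/a - 1/(a+b) - 1/(a+c) + 1/N)
* EBGM = a*N / ((a+c)(a+b)) — the same observed/expected ratio, so
  IC = log2(EBGM) identically — with the approximate interval
  exp(ln EBGM +/- 1.96*sqrt(1/a+1/b+1/c+1/d)).

Thresholds: ROR lower bound > 1; PRR >= 2 with chi2 >= 4; IC025 > 0;
EBGM05 > 2.  An event meeting at least two of the four is a signal — a
reporting-disproportionality hypothesis, not a causal claim.

Zero cells make the ratio statistics degenerate.  The default policy
applies the Haldane–Anscombe correction (add 0.5 to every cell) for
statistic and interval computation only, flagged in the output; the
``undefined`` policy leaves every statistic NaN instead, which no
threshold treats as met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .contingency import ContingencyTable

NAN = float("nan")

LOG2_SQ_INV = (1.0 / math.log(2.0)) ** 2

#: default per-method thresholds
ROR_LOW_THRESHOLD = 1.0
PRR_THRESHOLD = 2.0
CHI2_THRESHOLD = 4.0
IC025_THRESHOLD = 0.0
EBGM05_THRESHOLD = 2.0
MIN_METHODS = 2


@dataclass(frozen=True)
class SignalStatistics:
    """Point estimates and interval bounds for one contingency table.

    Constructible directly from published statistics (table=None) so that
    threshold logic can be exercised on printed rows.
    """

    event_label: str = ""
    level: str = ""
    a: int = 0
    ror: float = NAN
    ror_low: float = NAN
    ror_high: float = NAN
    prr: float = NAN
    chi2: float = NAN
    ic: float = NAN
    ic025: float = NAN
    ic_variance: float = NAN
    ebgm: float = NAN
    ebgm05: float = NAN
    corrected: bool = False  # Haldane correction was applied
    table: ContingencyTable | None = None


@dataclass(frozen=True)
class SignalDecision:
    stats: SignalStatistics
    ror_met: bool
    prr_met: bool
    bcpnn_met: bool
    mgps_met: bool

    @property
    def n_methods_met(self) -> int:
        return sum((self.ror_met, self.prr_met, self.bcpnn_met, self.mgps_met))

    @property
    def is_signal(self) -> bool:
        return self.n_methods_met >= MIN_METHODS


def _cells(table: ContingencyTable, zero_cell_policy: str) -> tuple[float, float, float, float, bool] | None:
    """Effective cells for ratio statistics, or None when undefined."""
    if zero_cell_policy not in ("haldane", "undefined"):
        raise ValueError(f"unknown zero-cell policy: {zero_cell_policy!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) > 0:
        return float(a), float(b), float(c), float(d), False
    if zero_cell_policy == "haldane":
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return None


def _se_log(a: float, b: float, c: float, d: float) -> float:
    return math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def compute_ror(table: ContingencyTable,
                zero_cell_policy: str = "haldane") -> tuple[float, float, float]:
    """Reporting odds ratio with Wald log-scale 95% CI."""
    eff = _cells(table, zero_cell_policy)
    if eff is None:
        return NAN, NAN, NAN
    a, b, c, d, _ = eff
    ror = (a * d) / (b * c)
    half = 1.96 * _se_log(a, b, c, d)
    return ror, ror * math.exp(-half), ror * math.exp(half)


def compute_prr_chi2(table: ContingencyTable,
                     zero_cell_policy: str = "haldane") -> tuple[float, float]:
    """Proportional reporting ratio and its uncorrected chi-squared."""
    eff = _cells(table, zero_cell_policy)
    if eff is None:
        return NAN, NAN
    a, b, c, d, _ = eff
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    chi2 = ((a * d - b * c) ** 2 * n) / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, chi2


def compute_bcpnn(table: ContingencyTable,
                  zero_cell_policy: str = "haldane") -> tuple[float, float, float]:
    """Information component, its lower 95% bound, and the variance used.

    IC025 = IC - 2*sqrt(V(IC)) with the delta-method variance; the point
    IC itself is the plug-in log2 observed/expected ratio.
    """
    eff = _cells(table, zero_cell_policy)
    if eff is None:
        return NAN, NAN, NAN
    a, b, c, d, _ = eff
    n = a + b + c + d
    ic = math.log2(a * n / ((a + c) * (a + b)))
    variance = LOG2_SQ_INV * (1.0 / a - 1.0 / (a + b) - 1.0 / (a + c) + 1.0 / n)
    variance = max(variance, 0.0)
    return ic, ic - 2.0 * math.sqrt(variance), variance


def compute_ebgm(table: ContingencyTable,
                 zero_cell_policy: str = "haldane") -> tuple[float, float]:
    """Observed/expected ratio (closed-form EBGM, no shrinkage) and EBGM05."""
    eff = _cells(table, zero_cell_policy)
    if eff is None:
        return NAN, NAN
    a, b, c, d, _ = eff
    n = a + b + c + d
    ebgm = a * n / ((a + c) * (a + b))
    ebgm05 = math.exp(math.log(ebgm) - 1.96 * _se_log(a, b, c, d))
    return ebgm, ebgm05


def compute_statistics(table: ContingencyTable,
                       zero_cell_policy: str = "haldane") -> SignalStatistics:
    """All four statistics for one table under a shared zero-cell policy."""
    eff = _cells(table, zero_cell_policy)
    corrected = eff is not None and eff[4]
    ror, ror_low, ror_high = compute_ror(table, zero_cell_policy)
    prr, chi2 = compute_prr_chi2(table, zero_cell_policy)
    ic, ic025, ic_var = compute_bcpnn(table, zero_cell_policy)
    ebgm, ebgm05 = compute_ebgm(table, zero_cell_policy)
    return SignalStatistics(
        event_label=table.event_label, level=table.level, a=table.a,
        ror=ror, ror_low=ror_low, ror_high=ror_high,
        prr=prr, chi2=chi2,
        ic=ic, ic025=ic025, ic_variance=ic_var,
        ebgm=ebgm, ebgm05=ebgm05,
        corrected=corrected, table=table,
    )


def decide_signal(stats: SignalStatistics) -> SignalDecision:
    """Apply the four thresholds and the >=2-method rule.

    NaN statistics (undefined under the ``undefined`` zero-cell policy)
    never meet a threshold.
    """
    return SignalDecision(
        stats=stats,
        ror_met=stats.ror_low > ROR_LOW_THRESHOLD,
        prr_met=stats.prr >= PRR_THRESHOLD and stats.chi2 >= CHI2_THRESHOLD,
        bcpnn_met=stats.ic025 > IC025_THRESHOLD,
        mgps_met=stats.ebgm05 > EBGM05_THRESHOLD,
    )


def _rank_key(decision: SignalDecision):
    s = decision.stats
    ror = s.ror if not math.isnan(s.ror) else -math.inf
    return (-ror, -s.a, s.event_label)


def run_level(tables: Sequence[ContingencyTable],
              zero_cell_policy: str = "haldane") -> list[SignalDecision]:
    """Statistics and signal decisions for every table, ranked by ROR.

    Descending ROR, ties broken by descending a then label; undefined
    statistics sort last.
    """
    decisions = [decide_signal(compute_statistics(t, zero_cell_policy)) for t in tables]
    return sorted(decisions, key=_rank_key)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero, as used in report output."""
    if math.isnan(value):
        return value
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def decisions_frame(decisions: Iterable[SignalDecision]) -> pd.DataFrame:
    """Report-style frame mirroring a published signal table (2-dp, half-up)."""
    rows = []
    for dec in decisions:
        s = dec.stats
        rows.append({
            "level": s.level,
            "event_label": s.event_label,
            "a": s.a,
            "ror": round_half_up(s.ror),
            "ror_low": round_half_up(s.ror_low),
            "ror_high": round_half_up(s.ror_high),
            "prr": round_half_up(s.prr),
            "chi2": round_half_up(s.chi2),
            "ic": round_half_up(s.ic),
            "ic025": round_half_up(s.ic025),
            "ebgm": round_half_up(s.ebgm),
            "ebgm05": round_half_up(s.ebgm05),
            "corrected": s.corrected,
            "methods_met": dec.n_methods_met,
            "is_signal": dec.is_signal,
        })
    return pd.DataFrame(rows, columns=[
        "level", "event_label", "a", "ror", "ror_low", "ror_high", "prr",
        "chi2", "ic", "ic025", "ebgm", "ebgm05", "corrected",
        "methods_met", "is_signal",
    ])
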