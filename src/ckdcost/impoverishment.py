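"""Impoverishing health expenditure (IHE): poverty headcount, gap, Pen's Parade.

Living standards are expressed as plain per-capita daily consumption in PPP
dollars; the extreme poverty line is 2.15 PPP$/day. Post-OOP values deduct
the household's net annual OOP (per capita) from consumption before
conversion. The poverty headcount counts households strictly below the line;
the poverty gap is the population-mean shortfall below the line (equivalently
headcount x mean shortfall among the poor); the normalised gap divides the
gap by the line. Post-OOP consumption is not floored at zero, so the gap can
reflect shortfalls deeper than the line itself.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .expenditure import AnnualCost
from .records import HouseholdRecord, VisitType

STRATA = ("total", "outpatient", "inpatient", "dialysis")


@dataclasses.dataclass(frozen=True)
class PovertyResult:
    """Pre/post-OOP poverty metrics for one stratum (gaps in PPP$/day)."""

    stratum: str
    n: int
    headcount_pre: float
    headcount_post: float
    gap_pre: float
    gap_post: float
    ngap_pre: float
    ngap_post: float


def poverty_line_annual(daily_ppp: float, ppp_rate: float, days: int) -> float:
    """Annual poverty line in local currency: daily PPP$ x days x PPP rate."""
    if daily_ppp <= 0 or ppp_rate <= 0 or days <= 0:
        raise ValueError("poverty line inputs must be > 0")
    return daily_ppp * days * ppp_rate


def daily_ppp_consumption(
    percap_consumption_plain: float,
    oop_percap: float,
    ppp_rate: float,
    days: int,
) -> float:
    """Per-capita daily consumption in PPP$ after deducting per-capita OOP.

    May be negative when OOP exceeds consumption; the sign is carried through
    so the poverty gap reflects the full shortfall.
    """
    if days <= 0 or ppp_rate <= 0:
        raise ValueError("days and ppp_rate must be > 0")
    return (percap_consumption_plain - oop_percap) / days / ppp_rate


def poverty_headcount(daily_values: Sequence[float], line_daily: float) -> float:
    """Fraction strictly below the line."""
    x = np.asarray(daily_values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    return float(np.mean(x < line_daily))


def poverty_gap(daily_values: Sequence[float], line_daily: float) -> float:
    """Population-mean shortfall below the line (same units as the values)."""
    x = np.asarray(daily_values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    return float(np.mean(np.maximum(0.0, line_daily - x)))


def normalized_gap(gap: float, line_daily: float) -> float:
    """Poverty gap as a fraction of the line (comparable across lines)."""
    if line_daily <= 0:
        raise ValueError("poverty line must be > 0")
    return gap / line_daily


@dataclasses.dataclass(frozen=True)
class PenParade:
    """Paired pre/post-OOP series ordered by pre-OOP living standards."""

    table: pd.DataFrame  # columns: rank, pre, post, line
    n_already_poor: int
    n_newly_poor: int
    n_never_poor: int


def pens_parade(
    daily_values_pre: Sequence[float],
    daily_values_post: Sequence[float],
    line_daily: float,
) -> PenParade:
    """Order households by pre-OOP consumption and pair with post-OOP values.

    Counts: already poor (pre below the line), newly impoverished (pre at or
    above, post below), never poor (both at or above).
    """
    pre = np.asarray(daily_values_pre, dtype=float)
    post = np.asarray(daily_values_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post series must have the same length")
    order = np.argsort(pre, kind="stable")
    n = pre.size
    table = pd.DataFrame(
        {
            "rank": (np.arange(1, n + 1) - 0.5) / n,
            "pre": pre[order],
            "post": post[order],
            "line": line_daily,
        }
    )
    already = int(np.sum(pre < line_daily))
    newly = int(np.sum((pre >= line_daily) & (post < line_daily)))
    never = int(np.sum((pre >= line_daily) & (post >= line_daily)))
    return PenParade(table, already, newly, never)


def daily_values(
    records: Sequence[HouseholdRecord],
    costs: Sequence[AnnualCost],
    config: AnalysisConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-capita daily PPP consumption before and after net OOP deduction."""
    pre, post = [], []
    for r, c in zip(records, costs):
        size = r.household_size
        percap = r.annual_consumption / size
        oop_percap = c.oop_net_annual / size
        pre.append(
            daily_ppp_consumption(percap, 0.0, config.ppp_rate, config.days_per_year)
        )
        post.append(
            daily_ppp_consumption(
                percap, oop_percap, config.ppp_rate, config.days_per_year
            )
        )
    return np.array(pre), np.array(post)


def poverty_table(
    records: Sequence[HouseholdRecord],
    costs: Sequence[AnnualCost],
    config: AnalysisConfig,
) -> list[PovertyResult]:
    """Pre/post-OOP poverty metrics overall and by visit-type stratum."""
    pre, post = daily_values(records, costs, config)
    line = config.poverty_line_daily_ppp
    results = []
    for stratum in STRATA:
        if stratum == "total":
            mask = np.ones(len(records), dtype=bool)
        else:
            mask = np.array([r.visit_type == VisitType(stratum) for r in records])
        if not mask.any():
            continue
        g_pre = poverty_gap(pre[mask], line)
        g_post = poverty_gap(post[mask], line)
        results.append(
            PovertyResult(
                stratum=stratum,
                n=int(mask.sum()),
                headcount_pre=poverty_headcount(pre[mask], line),
                headcount_post=poverty_headcount(post[mask], line),
                gap_pre=g_pre,
                gap_post=g_post,
                ngap_pre=normalized_gap(g_pre, line),
                ngap_post=normalized_gap(g_post, line),
            )
        )
    return results


def poverty_frame(results: Sequence[PovertyResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
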