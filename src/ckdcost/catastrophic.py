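"""Catastrophic health expenditure (CHE): incidence, intensity, distribution.

A household's OOP share is its net annual OOP spending divided by either its
total annual consumption (thresholds 10%/5%) or its capacity-to-pay — non-food
expenditure — (thresholds 40%/25%). The headcount H is the fraction of
households whose share strictly exceeds the threshold z; the overshoot O is
the population-mean excess above z; the mean positive overshoot O/H is the
average excess among catastrophic households only. Distribution across the
wealth gradient is summarised by the concentration index
``C = 2 cov(y, r) / mean(y)`` with r the fractional living-standards rank,
and by the rank-weighted measures ``H (1 - C)`` and ``O (1 - C)``
(the Wagstaff–van Doorslaer construction: weights ``2 (1 - r)`` up-weight
poorer households).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .expenditure import AnnualCost
from .living_standards import LivingStandards
from .records import HouseholdRecord, VisitType

STRATA = ("total", "outpatient", "inpatient", "dialysis")


@dataclasses.dataclass(frozen=True)
class CheResult:
    """CHE metrics for one (threshold, denominator, stratum) cell.

    Concentration indices (and hence weighted measures) are computed on the
    total cohort's wealth ranks; within a stratum they use the stratum's own
    ranks and are secondary descriptive quantities.
    """

    threshold: float
    denominator: str  # "consumption" or "capacity_to_pay"
    stratum: str
    n: int
    headcount: float
    overshoot: float
    mpo: float | None  # None when headcount is 0 (undefined, not 0)
    ci_headcount: float | None
    ci_overshoot: float | None
    weighted_headcount: float | None
    weighted_overshoot: float | None


def oop_share(oop_net_annual: float, denominator_value: float, record_id: str = "?") -> float:
    """Share s = net OOP / denominator; may exceed 1."""
    if denominator_value <= 0:
        raise ValueError(
            f"record {record_id}: non-positive denominator ({denominator_value})"
        )
    return oop_net_annual / denominator_value


def headcount(shares: Sequence[float], z: float) -> float:
    """Fraction of households with share strictly above z."""
    shares = np.asarray(shares, dtype=float)
    if shares.size == 0:
        raise ValueError("need at least one share")
    return float(np.mean(shares > z))


def overshoot(shares: Sequence[float], z: float) -> float:
    """Population-mean excess of the share above z (zero for non-catastrophic)."""
    shares = np.asarray(shares, dtype=float)
    if shares.size == 0:
        raise ValueError("need at least one share")
    return float(np.mean(np.maximum(0.0, shares - z)))


def mean_positive_overshoot(o: float, h: float) -> float:
    """O/H: average excess among catastrophic households; undefined at H=0."""
    if h <= 0:
        raise ValueError("mean positive overshoot undefined when headcount is 0")
    return o / h


def concentration_index(y: Sequence[float], ranks: Sequence[float]) -> float:
    """Concentration index ``C = 2 cov(y, r) / mean(y)`` (population covariance).

    Negative C: y concentrated among the poor; positive: among the rich.
    For non-negative y, C lies in [-1, 1].
    """
    y = np.asarray(y, dtype=float)
    r = np.asarray(ranks, dtype=float)
    if y.shape != r.shape:
        raise ValueError("y and ranks must have the same length")
    mu = y.mean()
    if mu == 0:
        raise ValueError("concentration index undefined: mean(y) is 0")
    cov = np.mean(y * r) - y.mean() * r.mean()
    return float(2.0 * cov / mu)


def rank_weighted(measure: float, c: float) -> float:
    """Rank-weighted measure ``measure * (1 - C)``."""
    if measure < 0:
        raise ValueError("measure must be >= 0")
    return measure * (1.0 - c)


def compute_shares(
    records: Sequence[HouseholdRecord],
    living: Sequence[LivingStandards],
    costs: Sequence[AnnualCost],
    denominator: str,
) -> np.ndarray:
    """OOP shares for every record against the chosen denominator."""
    if denominator == "consumption":
        denoms = [r.annual_consumption for r in records]
    elif denominator == "capacity_to_pay":
        denoms = [ls.capacity_to_pay for ls in living]
    else:
        raise ValueError(f"unknown denominator: {denominator}")
    return np.array(
        [
            oop_share(c.oop_net_annual, d, r.record_id)
            for r, c, d in zip(records, costs, denoms)
        ]
    )


def _cell(
    shares: np.ndarray,
    ranks: np.ndarray,
    z: float,
    denominator: str,
    stratum: str,
) -> CheResult:
    h = headcount(shares, z)
    o = overshoot(shares, z)
    mpo = mean_positive_overshoot(o, h) if h > 0 else None
    flags = (shares > z).astype(float)
    excess = np.maximum(0.0, shares - z)
    c_h = concentration_index(flags, ranks) if flags.mean() > 0 else None
    c_o = concentration_index(excess, ranks) if excess.mean() > 0 else None
    return CheResult(
        threshold=z,
        denominator=denominator,
        stratum=stratum,
        n=shares.size,
        headcount=h,
        overshoot=o,
        mpo=mpo,
        ci_headcount=c_h,
        ci_overshoot=c_o,
        weighted_headcount=rank_weighted(h, c_h) if c_h is not None else None,
        weighted_overshoot=rank_weighted(o, c_o) if c_o is not None else None,
    )


def che_table(
    records: Sequence[HouseholdRecord],
    living: Sequence[LivingStandards],
    costs: Sequence[AnnualCost],
    config: AnalysisConfig,
) -> list[CheResult]:
    """One CheResult per (threshold x denominator x stratum).

    Thresholds come from the config (primary and sensitivity levels for each
    denominator); strata are the total cohort and the three visit types.
    Empty strata are omitted with a warning. Ranks for the concentration
    index always come from AE-adjusted per-capita consumption.
    """
    ranks = np.array([ls.fractional_rank for ls in living])
    results: list[CheResult] = []
    plans = [("consumption", config.che_thresholds_consumption),
             ("capacity_to_pay", config.che_thresholds_ctp)]
    for denominator, thresholds in plans:
        shares = compute_shares(records, living, costs, denominator)
        for z in thresholds:
            for stratum in STRATA:
                if stratum == "total":
                    mask = np.ones(len(records), dtype=bool)
                else:
                    mask = np.array(
                        [r.visit_type == VisitType(stratum) for r in records]
                    )
                if not mask.any():
                    warnings.warn(f"empty stratum omitted: {stratum}", stacklevel=2)
                    continue
                results.append(
                    _cell(shares[mask], ranks[mask], z, denominator, stratum)
                )
    return results


def che_frame(results: Iterable[CheResult]) -> pd.DataFrame:
    """Long-form machine-readable table (threshold, denominator, stratum, metric, value)."""
    rows = []
    for r in results:
        for metric in (
            "n",
            "headcount",
            "overshoot",
            "mpo",
            "ci_headcount",
            "ci_overshoot",
            "weighted_headcount",
            "weighted_overshoot",
        ):
            rows.append(
                {
                    "threshold": r.threshold,
                    "denominator": r.denominator,
                    "stratum": r.stratum,
                    "metric": metric,
                    "value": getattr(r, metric),
                }
            )
    return pd.DataFrame(rows)
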