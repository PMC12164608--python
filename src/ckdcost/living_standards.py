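"""Living standards: adult-equivalence, per-capita consumption, quintiles, ranks.

Household consumption is deflated by an adult-equivalent (AE) score
``AE = (A + alpha*C)**theta`` where ``A`` counts adults, ``C`` children,
``alpha`` is the cost of children and ``theta`` captures economies of scale.
Wealth quintiles and fractional ranks — the inputs of the concentration
index — are built on AE-adjusted per-capita consumption; plain per-capita
consumption is kept alongside for the poverty analysis.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import AnalysisConfig
from .records import HouseholdRecord

QUINTILE_LABELS = ("Q1", "Q2", "Q3", "Q4", "Q5")


@dataclasses.dataclass(frozen=True)
class LivingStandards:
    """Per-record living-standards summary (money in local currency/year)."""

    record_id: str
    ae_score: float
    percap_consumption_ae: float
    percap_consumption_plain: float
    quintile: str
    fractional_rank: float
    capacity_to_pay: float


def adult_equivalents(adults: int, children: int, alpha: float, theta: float) -> float:
    """AE score ``(A + alpha*C)**theta``; requires at least one adult."""
    if adults < 1:
        raise ValueError("adults must be >= 1")
    if children < 0:
        raise ValueError("children must be >= 0")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must be in (0, 1]")
    return float((adults + alpha * children) ** theta)


def per_capita(consumption: float, divisor: float) -> float:
    """Consumption per AE (or per head); the divisor must be positive."""
    if divisor <= 0:
        raise ValueError("divisor must be > 0")
    return consumption / divisor


def assign_quintiles(values: Sequence[float]) -> list[str]:
    """Assign Q1 (poorest) .. Q5 (richest) by ascending value.

    Records are sorted ascending with a stable sort, so ties keep their input
    order, and split into contiguous blocks whose sizes differ by at most one
    (the larger blocks come first, e.g. n=433 -> 87,87,87,86,86).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 5:
        raise ValueError("need at least 5 records to form quintiles")
    order = np.argsort(values, kind="stable")
    block_sizes = [len(b) for b in np.array_split(np.arange(n), 5)]
    labels = np.empty(n, dtype=object)
    start = 0
    for label, size in zip(QUINTILE_LABELS, block_sizes):
        labels[order[start : start + size]] = label
        start += size
    return list(labels)


def fractional_rank(values: Sequence[float]) -> np.ndarray:
    """Midpoint fractional ranks ``(i - 0.5)/n`` in ascending order of value.

    Ties receive the mean of the positions they span (the convention of the
    health-equity concentration-index literature). Ranks always average to
    exactly 0.5.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    avg_rank = rankdata(values, method="average")
    return (avg_rank - 0.5) / values.size


def compute_living_standards(
    records: Iterable[HouseholdRecord], config: AnalysisConfig
) -> list[LivingStandards]:
    """AE scores, per-capita consumption, quintiles and fractional ranks.

    Quintiles and ranks are both taken over AE-adjusted per-capita
    consumption; capacity-to-pay is household consumption minus food
    expenditure (a household-level aggregate, not per-AE).
    """
    records = list(records)
    ae = [
        adult_equivalents(r.adults, r.children, config.ae_alpha, config.ae_theta)
        for r in records
    ]
    percap_ae = [per_capita(r.annual_consumption, a) for r, a in zip(records, ae)]
    percap_plain = [
        per_capita(r.annual_consumption, r.household_size) for r in records
    ]
    quintiles = assign_quintiles(percap_ae)
    ranks = fractional_rank(percap_ae)
    return [
        LivingStandards(
            record_id=r.record_id,
            ae_score=a,
            percap_consumption_ae=pae,
            percap_consumption_plain=pp,
            quintile=q,
            fractional_rank=float(rk),
            capacity_to_pay=r.annual_consumption - r.annual_food_expenditure,
        )
        for r, a, pae, pp, q, rk in zip(
            records, ae, percap_ae, percap_plain, quintiles, ranks
        )
    ]


def living_standards_frame(living: Iterable[LivingStandards]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(ls) for ls in living])


def quintile_summary(
    records: Iterable[HouseholdRecord],
    living: Iterable[LivingStandards],
    oop_annual: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-quintile means of consumption, food share and (optionally) OOP.

    Returns a 5-row table indexed Q1..Q5 with an attached
    ``richest_poorest_ratio`` attribute (mean consumption Q5 / Q1).
    """
    records = list(records)
    living = list(living)
    df = pd.DataFrame(
        {
            "quintile": [ls.quintile for ls in living],
            "consumption": [r.annual_consumption for r in records],
            "food_share": [
                (r.annual_food_expenditure / r.annual_consumption)
                if r.annual_consumption > 0
                else np.nan
                for r in records
            ],
        }
    )
    if oop_annual is not None:
        df["oop_annual"] = list(oop_annual)
    out = df.groupby("quintile").mean()
    missing = [q for q in QUINTILE_LABELS if q not in out.index]
    if missing:
        raise ValueError(f"empty quintile(s): {', '.join(missing)}")
    out = out.loc[list(QUINTILE_LABELS)]
    ratio = out.loc["Q5", "consumption"] / out.loc["Q1", "consumption"]
    out.attrs["richest_poorest_ratio"] = float(ratio)
    return out
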