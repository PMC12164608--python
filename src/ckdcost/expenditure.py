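"""OOP cost aggregation: DME/DNME sums, annualisation, currency conversion,
productivity losses and coping-strategy tabulation.

Six-month itemised expenditures are summed into direct medical (DME) and
direct non-medical (DNME) components and annualised by doubling (the cohort
was followed for six months; spending is assumed stationary over the year).
Reimbursement is annualised by the same doubling rule and netted at the
period level, floored at zero.
"""

from __future__ import annotations

import dataclasses
import enum
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .records import DME_FIELDS, DNME_FIELDS, CopingSource, ExpenditureBreakdown, HouseholdRecord


class Currency(str, enum.Enum):
    LOCAL = "local"
    USD = "USD"
    PPP = "PPP"


@dataclasses.dataclass(frozen=True)
class AnnualCost:
    """Annualised cost profile for one record.

    ``oop_annual = dme_annual + dnme_annual`` exactly; ``oop_net_annual`` is
    OOP minus annualised reimbursement, floored at zero.
    """

    record_id: str
    dme_annual: float
    dnme_annual: float
    oop_annual: float
    oop_net_annual: float
    productivity_loss_annual: float
    currency: Currency = Currency.LOCAL


def sum_dme(breakdown: ExpenditureBreakdown) -> float:
    """Six-month direct medical expenditure: consultation, diagnostics,
    procedures, medications/supplies, hospital stay and dialysis fees."""
    return float(sum(getattr(breakdown, f) for f in DME_FIELDS))


def sum_dnme(breakdown: ExpenditureBreakdown) -> float:
    """Six-month direct non-medical expenditure: transport, food, lodging."""
    return float(sum(getattr(breakdown, f) for f in DNME_FIELDS))


def annualize(six_month_amount: float) -> float:
    """Scale a six-month amount to a 12-month reference period (doubling)."""
    if six_month_amount < 0:
        raise ValueError("six-month amount must be >= 0")
    return 2.0 * six_month_amount


def convert(amount: float, target: Currency | str, config: AnalysisConfig) -> float:
    """Convert a local-currency amount to USD or PPP$ (identity for local)."""
    target = Currency(target)
    if target is Currency.LOCAL:
        return amount
    if target is Currency.USD:
        return amount / config.usd_rate
    if target is Currency.PPP:
        return amount / config.ppp_rate
    raise ValueError(f"unknown currency target: {target}")


def productivity_loss(
    patient_loss_6m: float,
    caregiver_losses_6m: Sequence[float],
    cap: int,
) -> float:
    """Annualised income loss of the patient plus at most ``cap`` caregivers.

    When more than ``cap`` caregiver losses are reported, the ``cap`` largest
    are counted (deterministic and conservative-stable; the data-collection
    protocol already limited reports to the cap, so this only matters for
    out-of-protocol inputs).
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    kept = sorted(caregiver_losses_6m, reverse=True)[:cap]
    return annualize(patient_loss_6m + sum(kept))


def dme_share(cost: AnnualCost) -> float:
    """DME as a fraction of total annual OOP; undefined when OOP is zero."""
    if cost.oop_annual <= 0:
        raise ValueError(f"record {cost.record_id}: zero OOP, DME share undefined")
    return cost.dme_annual / cost.oop_annual


def compute_annual_costs(
    records: Iterable[HouseholdRecord], config: AnalysisConfig
) -> list[AnnualCost]:
    """Annualised DME/DNME/total/net OOP and productivity loss per record."""
    costs = []
    for r in records:
        dme = annualize(sum_dme(r.oop))
        dnme = annualize(sum_dnme(r.oop))
        oop = dme + dnme
        net = max(0.0, oop - annualize(r.reimbursement_6m))
        loss = productivity_loss(
            r.income_loss_patient_6m,
            r.income_loss_caregivers_6m,
            config.caregiver_cap,
        )
        costs.append(
            AnnualCost(
                record_id=r.record_id,
                dme_annual=dme,
                dnme_annual=dnme,
                oop_annual=oop,
                oop_net_annual=net,
                productivity_loss_annual=loss,
            )
        )
    return costs


def costs_frame(costs: Iterable[AnnualCost]) -> pd.DataFrame:
    rows = []
    for c in costs:
        d = dataclasses.asdict(c)
        d["currency"] = c.currency.value
        rows.append(d)
    return pd.DataFrame(rows)


def coping_tabulation(records: Iterable[HouseholdRecord]) -> pd.DataFrame:
    """Frequency table of coping sources (count, percent of households).

    Multi-select: a household may appear under several sources, so the
    percentages need not sum to 100.
    """
    records = list(records)
    n = len(records)
    counter: Counter[CopingSource] = Counter()
    for r in records:
        counter.update(r.coping_sources)
    rows = [
        {
            "source": src.value,
            "count": counter.get(src, 0),
            "percent": 100.0 * counter.get(src, 0) / n if n else np.nan,
        }
        for src in CopingSource
    ]
    df = pd.DataFrame(rows)
    return df[df["count"] > 0].reset_index(drop=True) if n else pd.DataFrame(
        columns=["source", "count", "percent"]
    )


def _bootstrap_ci(
    values: np.ndarray, reps: int, rng: np.random.Generator, level: float = 0.95
) -> tuple[float, float]:
    n = values.size
    idx = rng.integers(0, n, size=(reps, n))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def cost_summary(
    records: Iterable[HouseholdRecord],
    costs: Iterable[AnnualCost],
    config: AnalysisConfig,
    quintiles: Sequence[str] | None = None,
    currency: Currency = Currency.USD,
) -> pd.DataFrame:
    """Mean annual OOP by covariate group with percentile-bootstrap 95% CIs.

    Groups mirror the cost-association table of the analysis: facility type,
    visit type, insurance, residence, disease stage and (when quintile labels
    are supplied) wealth quintile, plus the overall mean.
    """
    records = list(records)
    costs = list(costs)
    rng = np.random.default_rng(config.seed)
    oop = np.array([convert(c.oop_annual, currency, config) for c in costs])

    groups: list[tuple[str, str, np.ndarray]] = [("total", "all", np.ones(len(records), bool))]
    def add(category: str, key) -> None:
        for level in sorted({key(r) for r in records}):
            mask = np.array([key(r) == level for r in records])
            groups.append((category, str(level), mask))

    add("facility_type", lambda r: r.facility_type.value)
    add("visit_type", lambda r: r.visit_type.value)
    add("insured", lambda r: r.insured)
    add("residence", lambda r: r.residence.value)
    add("disease_stage", lambda r: r.disease_stage)
    if quintiles is not None:
        q = list(quintiles)
        for level in sorted(set(q)):
            groups.append(("wealth_quintile", level, np.array([x == level for x in q])))

    rows = []
    for category, level, mask in groups:
        vals = oop[mask]
        if vals.size == 0:
            continue
        lo, hi = _bootstrap_ci(vals, config.bootstrap_reps, rng)
        rows.append(
            {
                "category": category,
                "level": level,
                "n": int(mask.sum()),
                "mean_oop_annual": float(vals.mean()),
                "ci_low": lo,
                "ci_high": hi,
                "currency": currency.value,
            }
        )
    return pd.DataFrame(rows)
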