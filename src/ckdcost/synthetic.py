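"""Synthetic household cohort generator.

Emulates the statistical structure of a facility-based chronic-kidney-disease
costing cohort: ~433 patients split across outpatient (260), inpatient (30)
and haemodialysis (143) strata; wealth-graded log-normal household
consumption with a richest:poorest mean ratio near 6.6 and food shares
falling from 72% (poorest) to 32% (richest); visit-type-graded log-normal
annual OOP costs with means of 677 / 2759 / 5312 US$ for outpatient /
inpatient / dialysis care; 66% insurance membership; 8% six-month mortality;
and a disease-stage mix dominated by stage V.

Annual OOP is drawn first and halved into the six-month itemised fields, so
the downstream doubling rule recovers the annual draw exactly. Wealth
stratum is assigned uniformly first and consumption drawn conditional on it,
which guarantees a well-defined monotone wealth gradient for oracle tests.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .records import (
    CopingSource,
    ExpenditureBreakdown,
    FacilityType,
    HouseholdRecord,
    Residence,
    Sex,
    VisitType,
)

#: per-quintile mean annual consumption in US$; endpoints are the study's
#: poorest/richest quintile means (ratio 6.6), interior points geometric
QUINTILE_MEAN_CONSUMPTION_USD = (1865.0, 2990.4, 4794.7, 7687.7, 12312.0)

_DEFAULT_CONSUMPTION_SDLOG = 0.45
_DEFAULT_USD_RATE = 54.2


def _default_consumption_meanlog() -> tuple[float, ...]:
    # log-normal mean exp(mu + s^2/2) hits the target quintile mean (local currency)
    s2 = _DEFAULT_CONSUMPTION_SDLOG**2
    return tuple(
        math.log(m * _DEFAULT_USD_RATE) - s2 / 2.0
        for m in QUINTILE_MEAN_CONSUMPTION_USD
    )


class SyntheticConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_outpatient: int = Field(default=260, ge=0)
    n_inpatient: int = Field(default=30, ge=0)
    n_dialysis: int = Field(default=143, ge=0)
    usd_rate: float = Field(default=_DEFAULT_USD_RATE, gt=0)
    consumption_meanlog_by_quintile: tuple[float, float, float, float, float] = Field(
        default_factory=_default_consumption_meanlog
    )
    consumption_sdlog: float = Field(default=_DEFAULT_CONSUMPTION_SDLOG, gt=0)
    food_share_poorest: float = Field(default=0.72, gt=0, lt=1)
    food_share_richest: float = Field(default=0.32, gt=0, lt=1)
    #: mean annual OOP in US$ by visit type
    oop_mean_by_visit: dict[str, float] = Field(
        default_factory=lambda: {
            "outpatient": 677.0,
            "inpatient": 2759.0,
            "dialysis": 5312.0,
        }
    )
    oop_sdlog: float = Field(default=0.8, gt=0)
    dme_share_range: tuple[float, float] = (0.76, 0.85)
    transport_share_of_dnme: float = Field(default=0.64, gt=0, lt=1)
    p_insured: float = Field(default=0.66, ge=0, le=1)
    p_death_6m: float = Field(default=0.08, ge=0, le=1)
    p_urban: float = Field(default=0.88, ge=0, le=1)
    p_government: float = Field(default=0.70, ge=0, le=1)
    p_male: float = Field(default=0.64, ge=0, le=1)
    stage_distribution: tuple[float, float, float, float, float] = Field(
        default=(0.016, 0.037, 0.192, 0.206, 0.547), validate_default=True
    )
    household_size_mean: float = Field(default=6.4, gt=1)
    #: fraction of patients (paid employment) reporting any income loss
    p_income_loss: float = Field(default=0.30, ge=0, le=1)
    caregiver_cap: int = Field(default=3, ge=0)
    #: probability an insured record gets partial reimbursement
    p_reimbursed: float = Field(default=0.05, ge=0, le=1)
    coping_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "family_friends": 0.41,
            "current_income": 0.37,
            "savings": 0.12,
            "asset_sale": 0.03,
            "borrowing": 0.02,
            "other": 0.05,
        }
    )
    seed: int = 0

    @field_validator("stage_distribution", mode="after")
    @classmethod
    def _normalise_stages(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        total = sum(v)
        # printed percentage mixes can be off by rounding; renormalise quietly
        if abs(total - 1.0) > 0.01:
            raise ValueError("stage_distribution must sum to 1")
        return tuple(x / total for x in v)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        lo, hi = self.dme_share_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("dme_share_range must satisfy 0 < lo <= hi < 1")
        return self

    @property
    def n_total(self) -> int:
        return self.n_outpatient + self.n_inpatient + self.n_dialysis


# DME component shares given the visit type (excluding the dme_share split).
# Dialysis: dialysis fees 63% of DME, medications/supplies 23%, remainder even.
_DME_SUBSHARES = {
    VisitType.DIALYSIS: {
        "dialysis_fees_6m": 0.63,
        "medications_supplies_6m": 0.23,
        "consultation_6m": 0.035,
        "diagnostics_6m": 0.035,
        "procedures_6m": 0.035,
        "hospital_stay_6m": 0.035,
    },
    VisitType.OUTPATIENT: {
        "dialysis_fees_6m": 0.0,
        "medications_supplies_6m": 0.45,
        "consultation_6m": 0.15,
        "diagnostics_6m": 0.25,
        "procedures_6m": 0.05,
        "hospital_stay_6m": 0.10,
    },
    VisitType.INPATIENT: {
        "dialysis_fees_6m": 0.0,
        "medications_supplies_6m": 0.30,
        "consultation_6m": 0.10,
        "diagnostics_6m": 0.15,
        "procedures_6m": 0.10,
        "hospital_stay_6m": 0.35,
    },
}

_REGION_PROBS = {
    "Addis Ababa": 0.641,
    "Amhara": 0.162,
    "Sidama": 0.162,
    "Oromia": 0.035,
}


def _food_share(config: SyntheticConfig, stratum: int) -> float:
    """Linear interpolation across wealth strata 0..4 (poorest to richest)."""
    t = stratum / 4.0
    return config.food_share_poorest + t * (
        config.food_share_richest - config.food_share_poorest
    )


def generate_cohort(config: SyntheticConfig) -> list[HouseholdRecord]:
    """Draw a full cohort; bit-reproducible for a given config (incl. seed)."""
    if config.n_total == 0:
        raise ValueError("cohort must contain at least one record")
    rng = np.random.default_rng(config.seed)

    visit_types = (
        [VisitType.OUTPATIENT] * config.n_outpatient
        + [VisitType.INPATIENT] * config.n_inpatient
        + [VisitType.DIALYSIS] * config.n_dialysis
    )

    # dialysis records are end-stage (stage V) by definition; non-dialysis
    # records draw from the conditional distribution that keeps the cohort
    # marginal equal to stage_distribution in expectation
    f_dial = config.n_dialysis / config.n_total
    if f_dial < 1.0:
        cond = np.array(config.stage_distribution, dtype=float)
        cond[4] = max(0.0, cond[4] - f_dial)
        cond /= cond.sum()
    else:
        cond = np.zeros(5)
        cond[4] = 1.0
    records: list[HouseholdRecord] = []
    for i, vt in enumerate(visit_types):
        # household composition: size = 1 + Poisson(mean-1) so mean is exact
        size = 1 + int(rng.poisson(config.household_size_mean - 1.0))
        children = int(rng.binomial(size - 1, 0.45)) if size > 1 else 0
        adults = size - children

        # wealth stratum first, consumption conditional on it
        stratum = int(rng.integers(0, 5))
        consumption = float(
            rng.lognormal(
                config.consumption_meanlog_by_quintile[stratum],
                config.consumption_sdlog,
            )
        )
        food = consumption * _food_share(config, stratum)

        # annual OOP on the local-currency scale, halved into 6-month items
        mean_local = config.oop_mean_by_visit[vt.value] * config.usd_rate
        mu = math.log(mean_local) - config.oop_sdlog**2 / 2.0
        oop_annual = float(rng.lognormal(mu, config.oop_sdlog))
        oop_6m = oop_annual / 2.0
        dme_share = float(rng.uniform(*config.dme_share_range))
        dme_6m = oop_6m * dme_share
        dnme_6m = oop_6m - dme_6m
        components = {
            k: dme_6m * share for k, share in _DME_SUBSHARES[vt].items()
        }
        transport = dnme_6m * config.transport_share_of_dnme
        rest = dnme_6m - transport
        components.update(
            {"transport_6m": transport, "food_6m": rest / 2.0, "lodging_6m": rest / 2.0}
        )
        breakdown = ExpenditureBreakdown(**components)

        insured = bool(rng.random() < config.p_insured)
        reimbursement = 0.0
        if insured and rng.random() < config.p_reimbursed:
            reimbursement = float(rng.uniform(0.02, 0.20)) * breakdown.total_6m

        patient_loss = 0.0
        caregiver_losses: tuple[float, ...] = ()
        if rng.random() < config.p_income_loss:
            # annual productivity losses average a few hundred US$; draw the
            # 6-month patient loss log-normally around 100 US$-equivalent
            patient_loss = float(rng.lognormal(math.log(100.0 * config.usd_rate), 0.6))
            n_cg = int(rng.integers(0, config.caregiver_cap + 1))
            caregiver_losses = tuple(
                float(rng.lognormal(math.log(30.0 * config.usd_rate), 0.6))
                for _ in range(n_cg)
            )

        coping = frozenset(
            CopingSource(code)
            for code, p in config.coping_probs.items()
            if rng.random() < p
        )

        stage = 5 if vt is VisitType.DIALYSIS else 1 + int(rng.choice(5, p=cond))
        records.append(
            HouseholdRecord(
                record_id=f"S{i:04d}",
                adults=adults,
                children=children,
                annual_consumption=consumption,
                annual_food_expenditure=food,
                visit_type=vt,
                facility_type=(
                    FacilityType.GOVERNMENT
                    if rng.random() < config.p_government
                    else FacilityType.PRIVATE
                ),
                disease_stage=stage,
                insured=insured,
                residence=(
                    Residence.URBAN if rng.random() < config.p_urban else Residence.RURAL
                ),
                region=str(
                    rng.choice(
                        list(_REGION_PROBS), p=list(_REGION_PROBS.values())
                    )
                ),
                age_years=float(np.clip(rng.normal(49.6, 14.0), 18.0, 95.0)),
                sex=Sex.MALE if rng.random() < config.p_male else Sex.FEMALE,
                died_during_followup=bool(rng.random() < config.p_death_6m),
                oop=breakdown,
                reimbursement_6m=reimbursement,
                income_loss_patient_6m=patient_loss,
                income_loss_caregivers_6m=caregiver_losses,
                coping_sources=coping,
                extra={"wealth_stratum": stratum},
            )
        )
    return records


def generate_known_metrics_cohort(
    n: int,
    target_headcount: float,
    threshold: float,
    seed: int = 0,
) -> list[HouseholdRecord]:
    """Cohort whose true CHE headcount at ``threshold`` is exact by construction.

    ``n * target_headcount`` must be an integer k; the first k records get an
    OOP/consumption share of 1.5x the threshold and the rest 0.5x, with no
    reimbursement, so the downstream headcount equals ``target_headcount``
    to machine precision. Consumption varies slightly across records so
    quintiles and ranks remain well defined.
    """
    if not 0.0 <= target_headcount <= 1.0:
        raise ValueError("target_headcount must be in [0, 1]")
    k_float = n * target_headcount
    k = round(k_float)
    if abs(k_float - k) > 1e-9:
        raise ValueError(
            f"n * target_headcount = {k_float} is not an integer"
        )
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        consumption = 100_000.0 * (1.0 + 0.001 * i)
        share = threshold * (1.5 if i < k else 0.5)
        oop_annual = share * consumption
        records.append(
            HouseholdRecord(
                record_id=f"K{i:04d}",
                adults=2,
                children=2,
                annual_consumption=consumption,
                annual_food_expenditure=0.4 * consumption,
                visit_type=VisitType.OUTPATIENT,
                facility_type=FacilityType.GOVERNMENT,
                disease_stage=3,
                insured=bool(rng.random() < 0.5),
                residence=Residence.URBAN,
                region="Addis Ababa",
                age_years=50.0,
                sex=Sex.MALE,
                died_during_followup=False,
                oop=ExpenditureBreakdown(consultation_6m=oop_annual / 2.0),
                reimbursement_6m=0.0,
            )
        )
    return records


def cohort_oop_annual(records: Sequence[HouseholdRecord]) -> np.ndarray:
    """Annualised gross OOP per record (doubling rule), local currency."""
    return np.array([2.0 * r.oop.total_6m for r in records])
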