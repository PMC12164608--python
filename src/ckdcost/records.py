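"""Cohort data model: one household/patient record per row.

A record carries household composition (adults/children), annual household
consumption expenditure (HCE) split into food and non-food, the itemised
six-month out-of-pocket (OOP) expenditures split into direct medical (DME)
and direct non-medical (DNME) components, third-party reimbursement, reported
income losses for the patient and their caregivers, and the covariates used
by the driver analysis (visit type, facility type, disease stage, insurance,
residence, region, age, sex).

All monetary fields are in local currency (birr-like) unless a function says
otherwise; currency conversion happens downstream in :mod:`ckdcost.expenditure`.
"""

from __future__ import annotations

import enum
from typing import Any

from pydantic import BaseModel, ConfigDict, Field, NonNegativeFloat, model_validator


class VisitType(str, enum.Enum):
    OUTPATIENT = "outpatient"
    INPATIENT = "inpatient"
    DIALYSIS = "dialysis"


class FacilityType(str, enum.Enum):
    GOVERNMENT = "government"
    PRIVATE = "private"


class Residence(str, enum.Enum):
    URBAN = "urban"
    RURAL = "rural"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class CopingSource(str, enum.Enum):
    FAMILY_FRIENDS = "family_friends"
    CURRENT_INCOME = "current_income"
    SAVINGS = "savings"
    ASSET_SALE = "asset_sale"
    BORROWING = "borrowing"
    OTHER = "other"


#: DME components: payments made to (or at) the facility for medical care.
DME_FIELDS = (
    "consultation_6m",
    "diagnostics_6m",
    "procedures_6m",
    "medications_supplies_6m",
    "hospital_stay_6m",
    "dialysis_fees_6m",
)

#: DNME components: costs of getting to and staying near care.
DNME_FIELDS = ("transport_6m", "food_6m", "lodging_6m")


class ExpenditureBreakdown(BaseModel):
    """Itemised six-month OOP spending, all components >= 0."""

    model_config = ConfigDict(frozen=True)

    consultation_6m: NonNegativeFloat = 0.0
    diagnostics_6m: NonNegativeFloat = 0.0
    procedures_6m: NonNegativeFloat = 0.0
    medications_supplies_6m: NonNegativeFloat = 0.0
    hospital_stay_6m: NonNegativeFloat = 0.0
    dialysis_fees_6m: NonNegativeFloat = 0.0
    transport_6m: NonNegativeFloat = 0.0
    food_6m: NonNegativeFloat = 0.0
    lodging_6m: NonNegativeFloat = 0.0

    @property
    def dme_6m(self) -> float:
        return sum(getattr(self, f) for f in DME_FIELDS)

    @property
    def dnme_6m(self) -> float:
        return sum(getattr(self, f) for f in DNME_FIELDS)

    @property
    def total_6m(self) -> float:
        return self.dme_6m + self.dnme_6m


class HouseholdRecord(BaseModel):
    """One patient/household observation.

    Invariants enforced at construction:

    * ``adults >= 1``, ``children >= 0``
    * ``0 <= annual_food_expenditure <= annual_consumption``
    * all money fields >= 0; ``reimbursement_6m`` never exceeds total
      six-month OOP
    * ``disease_stage`` in 1..5
    """

    model_config = ConfigDict(frozen=True)

    record_id: str
    adults: int = Field(ge=1)
    children: int = Field(ge=0)
    annual_consumption: NonNegativeFloat
    annual_food_expenditure: NonNegativeFloat
    visit_type: VisitType
    facility_type: FacilityType
    disease_stage: int = Field(ge=1, le=5)
    insured: bool
    residence: Residence
    region: str = ""
    age_years: float = Field(ge=0)
    sex: Sex
    died_during_followup: bool = False
    oop: ExpenditureBreakdown
    reimbursement_6m: NonNegativeFloat = 0.0
    income_loss_patient_6m: NonNegativeFloat = 0.0
    income_loss_caregivers_6m: tuple[float, ...] = ()
    coping_sources: frozenset[CopingSource] = frozenset()
    extra: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_cross_field(self) -> "HouseholdRecord":
        if self.annual_food_expenditure > self.annual_consumption + 1e-9:
            raise ValueError(
                f"record {self.record_id}: annual_food_expenditure "
                f"({self.annual_food_expenditure}) exceeds annual_consumption "
                f"({self.annual_consumption})"
            )
        if self.reimbursement_6m > self.oop.total_6m + 1e-9:
            raise ValueError(
                f"record {self.record_id}: reimbursement_6m "
                f"({self.reimbursement_6m}) exceeds total 6-month OOP "
                f"({self.oop.total_6m})"
            )
        if any(x < 0 for x in self.income_loss_caregivers_6m):
            raise ValueError(
                f"record {self.record_id}: negative caregiver income loss"
            )
        return self

    @property
    def household_size(self) -> int:
        return self.adults + self.children
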