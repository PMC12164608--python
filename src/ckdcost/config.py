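"""Analysis configuration.

Every tunable constant of the pipeline lives here: the adult-equivalence
scale parameters (alpha = cost of children, theta = economies of scale),
currency conversion rates, catastrophic-expenditure thresholds, the
international poverty line, the caregiver cap for productivity losses, and
the p-value cut-offs of the driver analysis. All randomness in the package
flows from ``seed``; there is no hidden global state.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    #: cost-of-children weight in AE = (A + alpha*C)^theta
    ae_alpha: float = Field(default=0.3, ge=0.0, le=1.0)
    #: economies-of-scale exponent in the AE formula
    ae_theta: float = Field(default=0.9, gt=0.0, le=1.0)
    #: local currency units per US$
    usd_rate: float = Field(default=54.2, gt=0)
    #: local currency units per PPP US$
    ppp_rate: float = Field(default=22.2, gt=0)
    #: CHE thresholds applied to total household consumption (primary, sensitivity)
    che_thresholds_consumption: tuple[float, ...] = (0.10, 0.05)
    #: CHE thresholds applied to capacity-to-pay (non-food expenditure)
    che_thresholds_ctp: tuple[float, ...] = (0.40, 0.25)
    #: extreme poverty line, PPP US$ per person per day
    poverty_line_daily_ppp: float = Field(default=2.15, gt=0)
    days_per_year: int = Field(default=365, gt=0)
    #: maximum number of caregivers whose income losses count per patient
    caregiver_cap: int = Field(default=3, ge=0)
    #: bivariate screening p-value cut-off for the driver analysis
    screen_p: float = Field(default=0.2, gt=0, lt=1)
    #: significance level for the adjusted model
    sig_p: float = Field(default=0.05, gt=0, lt=1)
    #: bootstrap replicates for cost-summary confidence intervals
    bootstrap_reps: int = Field(default=1000, gt=0)
    seed: int = 0

    @field_validator("che_thresholds_consumption", "che_thresholds_ctp")
    @classmethod
    def _thresholds_in_unit_interval(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(not (0.0 < z < 1.0) for z in v):
            raise ValueError("CHE thresholds must lie in (0, 1)")
        return v


def load_config(path: str | Path) -> AnalysisConfig:
    """Read a flat YAML/JSON key-value document into an AnalysisConfig."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return AnalysisConfig(**data)


def save_config(config: AnalysisConfig, path: str | Path) -> Path:
    path = Path(path)
    payload = json.loads(config.model_dump_json())
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
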