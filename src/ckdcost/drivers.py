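"""Drivers of catastrophic expenditure: covariate screening + logistic model.

Each candidate covariate is first fit alone against the binary CHE outcome;
multi-level (categorical) covariates are screened with a likelihood-ratio
test of the whole factor against the intercept-only model. Covariates whose
bivariate p-value is at or below ``screen_p`` (default 0.2) enter a joint
multivariable logistic regression. Odds ratios are exponentiated maximum-
likelihood coefficients with Wald 95% confidence intervals
``exp(beta +/- 1.96 SE)``; no multiple-testing correction is applied.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

Z_95 = 1.96  # Wald multiplier, conventional epidemiology reporting

#: coefficient / SE magnitudes beyond which a fit is treated as separated
_SEPARATION_COEF = 15.0
_SEPARATION_SE = 200.0


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


@dataclasses.dataclass(frozen=True)
class Covariate:
    """One candidate driver.

    ``kind`` is "categorical" or "continuous"; categorical covariates declare
    the reference level against which odds ratios are reported.
    """

    name: str
    kind: str = "categorical"
    reference: str | None = None

    def term(self) -> str:
        if self.kind == "continuous":
            return self.name
        if self.reference is not None:
            return f"C({self.name}, Treatment(reference={self.reference!r}))"
        return f"C({self.name})"


@dataclasses.dataclass(frozen=True)
class ScreenDecision:
    covariate: str
    p_value: float | None
    kept: bool
    reason: str  # "p <= screen_p", "p > screen_p", "degenerate", "separation"


@dataclasses.dataclass(frozen=True)
class OddsRatioRow:
    covariate: str
    level: str  # "" for continuous covariates
    is_reference: bool
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None


def _fit_glm(formula: str, data: pd.DataFrame):
    model = smf.glm(formula, data=data, family=sm.families.Binomial())
    return model.fit(maxiter=200)


def _prepare(data: pd.DataFrame, covariates: Sequence[Covariate]) -> pd.DataFrame:
    """Coerce categorical covariates to strings so declared reference levels
    match regardless of the column's storage dtype."""
    data = data.copy()
    for cov in covariates:
        if cov.kind == "categorical" and cov.name in data.columns:
            data[cov.name] = data[cov.name].astype(str)
    return data


def _is_separated(result) -> bool:
    return bool(
        np.any(np.abs(result.params.to_numpy()) > _SEPARATION_COEF)
        or np.any(result.bse.to_numpy() > _SEPARATION_SE)
    )


def bivariate_screen(
    data: pd.DataFrame,
    outcome: str,
    candidates: Sequence[Covariate],
    screen_p: float = 0.2,
) -> tuple[list[Covariate], list[ScreenDecision]]:
    """Screen candidates one at a time against the outcome.

    Returns the kept covariates (in input order) and the per-covariate
    decisions. A covariate with a single observed level is excluded as
    degenerate; a separated fit is kept (p reported as 0) and flagged.
    """
    y = data[outcome]
    if y.nunique() != 2:
        raise ValueError("outcome must be binary with both classes present")
    data = _prepare(data, candidates)
    null_llf = _fit_glm(f"{outcome} ~ 1", data).llf

    kept: list[Covariate] = []
    decisions: list[ScreenDecision] = []
    for cov in candidates:
        if data[cov.name].nunique() <= 1:
            decisions.append(ScreenDecision(cov.name, None, False, "degenerate"))
            continue
        try:
            res = _fit_glm(f"{outcome} ~ {cov.term()}", data)
        except Exception:
            decisions.append(ScreenDecision(cov.name, 0.0, True, "separation"))
            kept.append(cov)
            continue
        if _is_separated(res):
            decisions.append(ScreenDecision(cov.name, 0.0, True, "separation"))
            kept.append(cov)
            continue
        lr = 2.0 * (res.llf - null_llf)
        df = res.df_model
        p = float(stats.chi2.sf(max(lr, 0.0), df)) if df > 0 else 1.0
        keep = p <= screen_p
        decisions.append(
            ScreenDecision(cov.name, p, keep, "p <= screen_p" if keep else "p > screen_p")
        )
        if keep:
            kept.append(cov)
    return kept, decisions


def _rows_from_fit(result, covariates: Sequence[Covariate], data: pd.DataFrame) -> list[OddsRatioRow]:
    params = result.params
    bse = result.bse
    pvals = result.pvalues
    rows: list[OddsRatioRow] = []
    for cov in covariates:
        if cov.kind == "continuous":
            b, se, p = params[cov.name], bse[cov.name], pvals[cov.name]
            rows.append(
                OddsRatioRow(
                    cov.name, "", False,
                    float(np.exp(b)),
                    float(np.exp(b - Z_95 * se)),
                    float(np.exp(b + Z_95 * se)),
                    float(p),
                )
            )
            continue
        levels = sorted(data[cov.name].astype(str).unique())
        ref = str(cov.reference) if cov.reference is not None else levels[0]
        rows.append(OddsRatioRow(cov.name, ref, True, 1.0, None, None, None))
        prefix = cov.term()
        for level in levels:
            if level == ref:
                continue
            key = f"{prefix}[T.{level}]"
            if key not in params.index:
                continue
            b, se, p = params[key], bse[key], pvals[key]
            rows.append(
                OddsRatioRow(
                    cov.name, level, False,
                    float(np.exp(b)),
                    float(np.exp(b - Z_95 * se)),
                    float(np.exp(b + Z_95 * se)),
                    float(p),
                )
            )
    return rows


def fit_logistic(
    data: pd.DataFrame, outcome: str, covariates: Sequence[Covariate]
) -> list[OddsRatioRow]:
    """Joint maximum-likelihood logistic fit; odds ratios with Wald 95% CIs.

    Raises :class:`SeparationError` on complete or quasi-complete separation
    rather than reporting unbounded odds ratios.
    """
    if not covariates:
        raise ValueError("no covariates to fit")
    data = _prepare(data, covariates)
    formula = f"{outcome} ~ " + " + ".join(c.term() for c in covariates)
    res = _fit_glm(formula, data)
    if _is_separated(res):
        raise SeparationError(
            "separation detected: at least one coefficient or standard error "
            "diverged; the odds ratio is not identified"
        )
    return _rows_from_fit(res, covariates, data)


def driver_table(
    data: pd.DataFrame,
    outcome: str,
    candidates: Sequence[Covariate],
    screen_p: float = 0.2,
    sig_p: float = 0.05,
) -> pd.DataFrame:
    """Unadjusted and adjusted odds-ratio report.

    Unadjusted columns come from one-covariate fits of every candidate;
    adjusted columns from the joint fit of the screened-in covariates.
    Reference levels print OR = 1 with empty CI; adjusted p-values at or
    below ``sig_p`` are starred.
    """
    kept, decisions = bivariate_screen(data, outcome, candidates, screen_p)
    kept_names = {c.name for c in kept}

    unadj: dict[tuple[str, str], OddsRatioRow] = {}
    for cov in candidates:
        if data[cov.name].nunique() <= 1:
            continue
        try:
            rows = fit_logistic(data, outcome, [cov])
        except SeparationError:
            continue
        for row in rows:
            unadj[(row.covariate, row.level)] = row

    adj: dict[tuple[str, str], OddsRatioRow] = {}
    if kept:
        for row in fit_logistic(data, outcome, kept):
            adj[(row.covariate, row.level)] = row

    screen_ps = {d.covariate: d.p_value for d in decisions}
    records = []
    for key, u in unadj.items():
        a = adj.get(key)
        records.append(
            {
                "covariate": key[0],
                "level": key[1],
                "screen_p": screen_ps.get(key[0]),
                "screened_in": key[0] in kept_names,
                "unadjusted_OR": u.odds_ratio,
                "unadj_CI_low": u.ci_low,
                "unadj_CI_high": u.ci_high,
                "adjusted_OR": a.odds_ratio if a else None,
                "adj_CI_low": a.ci_low if a else None,
                "adj_CI_high": a.ci_high if a else None,
                "p": a.p_value if a else None,
                "significant": bool(
                    a is not None and a.p_value is not None and a.p_value <= sig_p
                ),
            }
        )
    df = pd.DataFrame(records)
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "covariate", "level", "screen_p", "screened_in",
                "unadjusted_OR", "unadj_CI_low", "unadj_CI_high",
                "adjusted_OR", "adj_CI_low", "adj_CI_high", "p", "significant",
            ]
        )
        df.attrs["note"] = "no usable covariates (all degenerate or separated)"
    return df


def default_candidates() -> list[Covariate]:
    """The candidate set of the CHE driver analysis with its reference levels:
    outpatient visits, government facilities, stage 1 disease, the poorest
    quintile, urban residence and insurance membership."""
    return [
        Covariate("visit_type", "categorical", "outpatient"),
        Covariate("quintile", "categorical", "Q1"),
        Covariate("disease_stage", "categorical", "1"),
        Covariate("facility_type", "categorical", "government"),
        Covariate("household_size", "continuous"),
        Covariate("residence", "categorical", "urban"),
        Covariate("age_years", "continuous"),
        Covariate("insured", "categorical", "True"),
    ]
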