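"""Covariate screening and logistic odds-ratio reporting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ckdcost.drivers import (
    Covariate,
    SeparationError,
    bivariate_screen,
    driver_table,
    fit_logistic,
)


def two_by_two(n11, n10, n01, n00) -> pd.DataFrame:
    """exposed: n11 events / n10 non-events; unexposed: n01 / n00."""
    rows = (
        [(1, 1)] * n11 + [(1, 0)] * n10 + [(0, 1)] * n01 + [(0, 0)] * n00
    )
    return pd.DataFrame(rows, columns=["exposed", "y"])


class TestFitLogistic:
    def test_two_by_two_cross_product(self):
        data = two_by_two(8, 2, 2, 8)
        rows = fit_logistic(data, "y", [Covariate("exposed", "categorical", "0")])
        orow = next(r for r in rows if not r.is_reference)
        assert orow.odds_ratio == pytest.approx(16.0, abs=1e-6)

    def test_null_covariate_or_near_one(self, rng):
        n = 4000
        data = pd.DataFrame(
            {"x": rng.integers(0, 2, n), "y": rng.integers(0, 2, n)}
        )
        rows = fit_logistic(data, "y", [Covariate("x", "categorical", "0")])
        orow = next(r for r in rows if not r.is_reference)
        assert orow.ci_low < 1.0 < orow.ci_high

    def test_wald_ci_endpoints(self):
        data = two_by_two(30, 20, 15, 35)
        data["exposed"] = data["exposed"].astype(str)
        res = smf.glm(
            "y ~ C(exposed, Treatment(reference='0'))",
            data=data,
            family=sm.families.Binomial(),
        ).fit()
        b = res.params.iloc[1]
        se = res.bse.iloc[1]
        rows = fit_logistic(data, "y", [Covariate("exposed", "categorical", "0")])
        orow = next(r for r in rows if not r.is_reference)
        assert orow.ci_low == pytest.approx(np.exp(b - 1.96 * se), abs=1e-9)
        assert orow.ci_high == pytest.approx(np.exp(b + 1.96 * se), abs=1e-9)

    def test_separation_raises(self):
        data = pd.DataFrame({"x": [0] * 20 + [1] * 20, "y": [0] * 20 + [1] * 20})
        with pytest.raises(SeparationError):
            fit_logistic(data, "y", [Covariate("x", "categorical", "0")])

    def test_continuous_covariate_row(self, rng):
        n = 500
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.5 * x)))
        data = pd.DataFrame({"x": x, "y": rng.binomial(1, p)})
        rows = fit_logistic(data, "y", [Covariate("x", "continuous")])
        assert len(rows) == 1 and rows[0].level == ""
        assert rows[0].odds_ratio > 1


class TestScreen:
    def test_constant_covariate_excluded(self, rng):
        data = pd.DataFrame({"c": [1] * 50, "y": rng.integers(0, 2, 50)})
        kept, decisions = bivariate_screen(data, "y", [Covariate("c", "categorical")])
        assert kept == []
        assert decisions[0].reason == "degenerate"

    def test_outcome_copy_kept_and_flagged(self):
        y = [0] * 25 + [1] * 25
        data = pd.DataFrame({"x": y, "y": y})
        kept, decisions = bivariate_screen(data, "y", [Covariate("x", "categorical")])
        assert [c.name for c in kept] == ["x"]
        assert decisions[0].reason == "separation"
        assert decisions[0].p_value == 0.0

    def test_strong_predictor_kept(self, rng):
        n = 400
        x = rng.integers(0, 2, n)
        p = 1 / (1 + np.exp(-(-0.5 + 1.5 * x)))
        data = pd.DataFrame({"x": x, "y": rng.binomial(1, p)})
        kept, _ = bivariate_screen(data, "y", [Covariate("x", "categorical")])
        assert [c.name for c in kept] == ["x"]

    def test_non_binary_outcome_rejected(self):
        data = pd.DataFrame({"x": [0, 1, 0], "y": [0, 1, 2]})
        with pytest.raises(ValueError):
            bivariate_screen(data, "y", [Covariate("x", "categorical")])


class TestDriverTable:
    @pytest.fixture(scope="class")
    def simulated(self):
        rng = np.random.default_rng(7)
        n = 600
        visit = rng.choice(["outpatient", "inpatient", "dialysis"], n, p=[0.6, 0.1, 0.3])
        noise = rng.choice(["a", "b"], n)
        logit = -1.0 + 2.0 * (visit == "dialysis") + 0.8 * (visit == "inpatient")
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        return pd.DataFrame({"visit_type": visit, "noise": noise, "che": y})

    def test_strong_effect_flagged_significant(self, simulated):
        tab = driver_table(
            simulated,
            "che",
            [Covariate("visit_type", "categorical", "outpatient"),
             Covariate("noise", "categorical", "a")],
        )
        dial = tab[(tab["covariate"] == "visit_type") & (tab["level"] == "dialysis")]
        assert bool(dial["significant"].iloc[0])
        assert dial["adjusted_OR"].iloc[0] > 1

    def test_reference_rows_print_unit_or(self, simulated):
        tab = driver_table(
            simulated, "che", [Covariate("visit_type", "categorical", "outpatient")]
        )
        ref = tab[(tab["level"] == "outpatient")]
        assert (ref["unadjusted_OR"] == 1.0).all()
        assert ref["unadj_CI_low"].isna().all()

    def test_adjusted_model_contains_exactly_screened(self, simulated):
        tab = driver_table(
            simulated,
            "che",
            [Covariate("visit_type", "categorical", "outpatient"),
             Covariate("noise", "categorical", "a")],
            screen_p=1e-6,  # only the strong factor survives
        )
        noise_rows = tab[tab["covariate"] == "noise"]
        assert not noise_rows["screened_in"].any()
        assert noise_rows["adjusted_OR"].isna().all()
        visit_rows = tab[(tab["covariate"] == "visit_type") & (tab["level"] != "outpatient")]
        assert visit_rows["adjusted_OR"].notna().all()

    def test_all_constant_candidates_yield_empty_report(self):
        data = pd.DataFrame({"c": [1] * 40, "y": [0, 1] * 20})
        tab = driver_table(data, "y", [Covariate("c", "categorical")])
        assert tab.empty


def test_log_or_recovery_single_large_sim(rng):
    """With a true dialysis-vs-outpatient log-OR of 1, a large single
    simulation recovers the coefficient closely."""
    n = 20000
    x = rng.integers(0, 2, n)
    p = 1 / (1 + np.exp(-(-0.8 + 1.0 * x)))
    data = pd.DataFrame({"x": x, "y": rng.binomial(1, p)})
    rows = fit_logistic(data, "y", [Covariate("x", "categorical", "0")])
    orow = next(r for r in rows if not r.is_reference)
    assert np.log(orow.odds_ratio) == pytest.approx(1.0, abs=0.1)
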