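"""CHE metrics against brute-force oracles and worked examples."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ckdcost.catastrophic import (
    che_table,
    compute_shares,
    concentration_index,
    headcount,
    mean_positive_overshoot,
    oop_share,
    overshoot,
    rank_weighted,
)
from ckdcost.config import AnalysisConfig
from ckdcost.expenditure import compute_annual_costs
from ckdcost.living_standards import compute_living_standards, fractional_rank
from ckdcost.synthetic import generate_known_metrics_cohort


def brute_headcount(shares, z):
    return sum(1 for s in shares if s > z) / len(shares)


def brute_overshoot(shares, z):
    return sum(max(0.0, s - z) for s in shares) / len(shares)


def brute_concentration(y, r):
    n = len(y)
    mu = sum(y) / n
    rbar = sum(r) / n
    cov = sum(yi * ri for yi, ri in zip(y, r)) / n - mu * rbar
    return 2 * cov / mu


class TestShares:
    def test_values(self):
        assert oop_share(0, 1000) == 0
        assert oop_share(250, 1000) == 0.25
        assert oop_share(1200, 1000) == pytest.approx(1.2)  # may exceed 1

    def test_bad_denominator_names_record(self):
        with pytest.raises(ValueError, match="R7"):
            oop_share(100, 0, record_id="R7")


class TestHeadcountOvershoot:
    def test_headcount_example(self):
        assert headcount([0.05, 0.12, 0.50], 0.10) == pytest.approx(2 / 3)

    def test_headcount_zero(self):
        assert headcount([0.0, 0.0], 0.10) == 0

    def test_headcount_is_strict(self):
        assert headcount([0.10, 0.10], 0.10) == 0

    def test_overshoot_example(self):
        assert overshoot([0.05, 0.12, 0.50], 0.10) == pytest.approx(0.14)

    def test_overshoot_boundary(self):
        assert overshoot([0.10, 0.10], 0.10) == 0
        assert overshoot([0.01, 0.02], 0.10) == 0

    def test_printed_headcount_fraction(self):
        # 242 catastrophic households of 433 print as 55.9%
        shares = [0.2] * 242 + [0.01] * 191
        assert round(100 * headcount(shares, 0.10), 1) == 55.9


class TestMeanPositiveOvershoot:
    def test_example(self):
        assert mean_positive_overshoot(0.14, 2 / 3) == pytest.approx(0.21)

    def test_inpatient_worked_example(self):
        # overshoot 45.4% with headcount 20/30 prints as 68.1%
        assert round(100 * mean_positive_overshoot(0.454, 20 / 30), 1) == 68.1

    def test_zero_overshoot(self):
        assert mean_positive_overshoot(0.0, 0.5) == 0

    def test_undefined_at_zero_headcount(self):
        with pytest.raises(ValueError):
            mean_positive_overshoot(0.1, 0.0)


class TestConcentrationIndex:
    def test_poor_concentrated_binary(self):
        c = concentration_index([1, 0, 1, 0], [0.125, 0.375, 0.625, 0.875])
        assert c == pytest.approx(-0.25)

    def test_constant_y_is_zero(self):
        assert concentration_index([3, 3, 3], [0.1, 0.5, 0.9]) == pytest.approx(0.0)

    def test_pro_rich_positive(self):
        r = fractional_rank([1, 2, 3, 4, 5])
        assert concentration_index([1, 2, 3, 4, 5], r) > 0

    def test_zero_mean_undefined(self):
        with pytest.raises(ValueError):
            concentration_index([0, 0], [0.25, 0.75])

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=100).filter(lambda v: sum(v) > 1e-6))
    def test_matches_convenient_regression(self, y):
        """C equals the slope of the WHO 'convenient regression'
        2*var(r)*(y_i/mu) on r_i (population moments)."""
        r = fractional_rank(np.arange(len(y), dtype=float))
        c = concentration_index(y, r)
        mu = np.mean(y)
        lhs = 2 * np.var(r) * (np.array(y) / mu)
        slope = np.cov(lhs, r, bias=True)[0, 1] / np.var(r)
        assert c == pytest.approx(slope, abs=1e-9)

    @given(st.lists(st.integers(0, 1), min_size=3, max_size=200).filter(
        lambda v: 0 < sum(v)))
    def test_binary_bound(self, y):
        r = fractional_rank(np.arange(len(y), dtype=float))
        c = concentration_index(y, r)
        assert abs(c) <= 1 - np.mean(y) + 1e-12


class TestRankWeighted:
    def test_examples(self):
        assert rank_weighted(0.5, 0) == 0.5
        assert rank_weighted(0.5, -0.25) == pytest.approx(0.625)
        assert rank_weighted(0.5, 1) == 0


@given(st.integers(0, 2**31 - 1))
def test_oracle_equivalence_on_random_cohorts(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 500))
    shares = rng.gamma(1.0, 0.3, size=n)
    ranks = fractional_rank(rng.normal(size=n))
    z = float(rng.uniform(0.02, 0.6))
    assert headcount(shares, z) == pytest.approx(brute_headcount(shares, z), abs=1e-12)
    assert overshoot(shares, z) == pytest.approx(brute_overshoot(shares, z), abs=1e-12)
    if shares.mean() > 0:
        assert concentration_index(shares, ranks) == pytest.approx(
            brute_concentration(list(shares), list(ranks)), abs=1e-9
        )


def test_headcount_and_overshoot_nonincreasing_in_z(rng):
    shares = rng.gamma(1.0, 0.4, size=300)
    grid = np.linspace(0.01, 1.5, 40)
    h = [headcount(shares, z) for z in grid]
    o = [overshoot(shares, z) for z in grid]
    assert all(a >= b for a, b in zip(h, h[1:]))
    assert all(a >= b - 1e-12 for a, b in zip(o, o[1:]))


class TestCheTable:
    @pytest.fixture(scope="class")
    def table_433(self):
        cfg = AnalysisConfig()
        records = generate_known_metrics_cohort(433, 242 / 433, 0.10, seed=3)
        living = compute_living_standards(records, cfg)
        costs = compute_annual_costs(records, cfg)
        return che_table(records, living, costs, cfg)

    def test_total_headcount_prints_55_9(self, table_433):
        cell = next(
            r for r in table_433
            if r.stratum == "total" and r.denominator == "consumption"
            and r.threshold == 0.10
        )
        assert round(100 * cell.headcount, 1) == 55.9
        assert cell.n == 433

    def test_sensitivity_rows_dominate(self, table_433):
        by = {(r.denominator, r.threshold, r.stratum): r for r in table_433}
        assert by[("consumption", 0.05, "total")].headcount >= by[
            ("consumption", 0.10, "total")
        ].headcount
        assert by[("capacity_to_pay", 0.25, "total")].headcount >= by[
            ("capacity_to_pay", 0.40, "total")
        ].headcount

    def test_all_catastrophic_cohort(self):
        cfg = AnalysisConfig()
        records = generate_known_metrics_cohort(20, 1.0, 0.9, seed=0)
        living = compute_living_standards(records, cfg)
        costs = compute_annual_costs(records, cfg)
        results = che_table(records, living, costs, cfg)
        for r in results:
            if r.denominator == "consumption":
                assert r.headcount == 1.0

    def test_empty_stratum_warns(self, table_433):
        # known-metrics cohorts are all-outpatient: dialysis/inpatient omitted
        strata = {r.stratum for r in table_433}
        assert strata == {"total", "outpatient"}

    def test_mpo_exceeds_nothing_when_h_zero(self):
        cfg = AnalysisConfig()
        records = generate_known_metrics_cohort(20, 0.0, 0.10, seed=0)
        living = compute_living_standards(records, cfg)
        costs = compute_annual_costs(records, cfg)
        results = che_table(records, living, costs, cfg)
        cell = next(
            r for r in results
            if r.denominator == "consumption" and r.threshold == 0.10
            and r.stratum == "total"
        )
        assert cell.headcount == 0.0 and cell.mpo is None


def test_compute_shares_matches_manual(cohort433, acfg):
    living = compute_living_standards(cohort433, acfg)
    costs = compute_annual_costs(cohort433, acfg)
    shares = compute_shares(cohort433, living, costs, "consumption")
    i = 7
    assert shares[i] == pytest.approx(
        costs[i].oop_net_annual / cohort433[i].annual_consumption, rel=1e-12
    )
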