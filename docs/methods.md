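# Methods

## Problem and scope

`ckdcost` measures the household financial burden of chronic kidney disease
(CKD) care from patient-level expenditure records: how much households pay
out of pocket (OOP), how often that spending is *catastrophic* relative to
their living standards, how often it pushes them below the extreme poverty
line (*impoverishing* health expenditure), how the burden is distributed
across the wealth gradient, and which covariates drive the odds of
catastrophe. The reference setting is a facility-based Ethiopian cohort of
433 patients followed for six months across outpatient, inpatient and
haemodialysis strata; the package ships a synthetic generator that emulates
that cohort so every stage is testable without any external data.

## Cost aggregation

Itemised six-month OOP spending is split into direct medical expenditures
(DME: consultation, diagnostics, procedures, medications/supplies, hospital
stay, dialysis fees) and direct non-medical expenditures (DNME: transport,
food, lodging). Annual figures are obtained by doubling the six-month sums
(stationarity over the year is assumed; the same doubling is applied
uniformly to patients who died during follow-up, since their six-month
spending is all that was observed). Reimbursement is annualised by the same
rule and netted at the period level, floored at zero — netting per period
rather than per visit is an assumption; visit-level reimbursement timing is
not recorded in the data model. Productivity losses add the patient's
reported six-month income loss to the losses of at most `caregiver_cap = 3`
caregivers; if more entries arrive, the largest `cap` are kept
(deterministic; the collection protocol already caps reports, so this branch
only handles out-of-protocol inputs).

Currency: amounts are stored in local currency and converted on demand at
54.2 birr/US$ and 22.2 birr per PPP US$ (2023 medians). Conversion is linear
and exactly invertible.

## Living standards

Household consumption is deflated by an adult-equivalent score
`AE = (A + αC)^θ` with defaults α = 0.3 (cost of children) and θ = 0.9
(limited economies of scale, appropriate where food dominates consumption).
Wealth quintiles and fractional ranks are built on AE-adjusted per-capita
consumption; the poverty analysis uses plain per-capita consumption
(household total ÷ household size), matching the international
poverty-line convention. Capacity-to-pay is household consumption minus food
expenditure at the household level; because CHE shares against it are
unit-free, the per-household (rather than per-AE) scale cancels.

Quintile assignment sorts ascending with a stable sort (ties keep input
order) and cuts contiguous blocks whose sizes differ by at most one, larger
blocks first (n = 433 → 87, 87, 87, 86, 86). Fractional ranks use the
midpoint convention `(i − 0.5)/n` with mean-rank ties — the standard choice
in the health-equity concentration-index literature; ranks always average to
exactly 0.5.

## Catastrophic health expenditure

For threshold z and share `s_i = net OOP_i / denominator_i`:

* headcount `H = (1/n)·#{s_i > z}` — strictly greater than; a household
  spending exactly the threshold is not counted (the convention is
  configurable in spirit but fixed here and documented);
* overshoot `O = (1/n)·Σ max(0, s_i − z)`;
* mean positive overshoot `MPO = O/H`, reported as undefined (not zero) when
  H = 0;
* concentration index `C = 2·cov(y, r)/mean(y)` with the population (1/n)
  covariance and r the fractional wealth rank — always the AE-consumption
  rank, regardless of the CHE denominator, because inequality is measured
  with respect to living standards;
* rank-weighted measures `H·(1 − C)` and `O·(1 − C)` (weights `2(1 − r)`,
  the Wagstaff–van Doorslaer construction).

Thresholds default to 10% and 5% of total consumption and 40% and 25% of
capacity-to-pay. Strata are the total cohort plus the three visit types;
concentration indices within a stratum use the stratum's own ranks and are
secondary descriptive output — the primary indices are the total-cohort
ones.

## Impoverishment

The extreme poverty line is 2.15 PPP$/day; annually in local currency that
is `2.15 × 365 × 22.2 = 17 421.45`. Per-capita daily PPP consumption is
computed before and after deducting per-capita net annual OOP; post-OOP
values are *not* floored at zero, so the poverty gap (population-mean
shortfall below the line) reflects the full depth of impoverishment. The
headcount uses strictly-below. Pen's Parade orders households by pre-OOP
consumption and pairs each with its post-OOP value, returning counts of
already-poor, newly-impoverished and never-poor households; because OOP
deduction only lowers consumption, newly-impoverished equals the post-minus-
pre headcount difference.

## Driver analysis

The CHE indicator (default: 10% of consumption) is regressed on candidate
covariates: visit type, wealth quintile, disease stage, facility type,
household size, residence, age and insurance, with reference levels
outpatient / Q1 / stage 1 / government / urban / insured. Each candidate is
first fit alone; categorical factors are screened with a likelihood-ratio
test of the whole factor against the intercept-only model (per-level Wald
tests would make the screen depend on the reference coding). Candidates with
p ≤ 0.2 enter the joint logistic fit. Odds ratios are exponentiated ML
coefficients with Wald 95% CIs `exp(β ± 1.96·SE)`; no multiple-testing
correction is applied. Separation is detected by a post-fit magnitude check
(|β| > 15 or SE > 200) and raised as an explicit error in the joint fit; in
the screen a separated covariate is retained with p = 0 and flagged. The
same machinery can be pointed at the post-OOP poverty flag to analyse IHE
drivers.

## Synthetic cohort generator

The generator is calibrated to the study conditions, not fitted to data:

* strata 260 outpatient / 30 inpatient / 143 dialysis (total 433);
* wealth stratum drawn uniformly over five levels first, then annual
  consumption log-normally conditional on the stratum. Stratum means are
  1865 US$ (poorest) and 12 312 US$ (richest) — ratio 6.6 — with geometric
  interpolation between (implied overall mean ≈ 5 929 US$); `sdlog = 0.45`
  is a free dispersion parameter (the study reports only CIs of means).
  Drawing consumption conditional on an assigned stratum guarantees a
  well-defined monotone wealth gradient for oracle tests;
* food share falls linearly from 72% (poorest stratum) to 32% (richest);
* annual OOP is log-normal per visit type with means 677 / 2 759 / 5 312
  US$ (outpatient / inpatient / dialysis), `sdlog = 0.8` (free parameter),
  drawn on the annual scale and halved into the six-month fields so the
  doubling rule recovers the draw exactly. The DME share of OOP is uniform
  on [0.76, 0.85]; within DME, dialysis records put 63% into dialysis fees
  and 23% into medications (remainder even across the other components);
  non-dialysis sub-shares are not pinned down by the study, so outpatient
  records are medication-dominant (45%) and inpatient records
  hospital-stay-dominant (35%) as a design choice. Transport takes 64% of
  DNME, food and lodging split the rest evenly;
* insurance membership Bernoulli(0.66); six-month mortality
  Bernoulli(0.08); urban residence 0.88; government facility 0.70; male
  0.64; age normal(49.6, 14) clipped to [18, 95]; household size
  1 + Poisson(5.4) (mean exactly 6.4);
* disease stage: dialysis records are stage V by definition; non-dialysis
  records draw from the conditional distribution that keeps the cohort
  marginal at (1.6, 3.7, 19.2, 20.6, 54.7)% in expectation;
* reimbursement is zero for most records; a small fraction (5%) of insured
  records receives 2–20% of six-month OOP back (full reimbursement was
  essentially absent in the study);
* coping sources are independent Bernoulli draws with marginals 41%
  (family/friends), 37% (current income), 12% (savings), 3% (asset sale),
  2% (borrowing), 5% (other).

What the generator does **not** emulate: correlation between wealth and
visit type or facility type (in reality richer households use private
facilities and dialysis more), visit-level longitudinal structure, clinical
stage progression, and any dependence of mortality on stage or dialysis
frequency. Tests passing on synthetic cohorts therefore validate the
*metrics pipeline*, not claims about real Ethiopian households; in
particular the driver analysis on generated data finds the mechanical
wealth–share gradient (poorer households have higher OOP shares by
construction), not the study's adjusted covariate structure.

`generate_known_metrics_cohort` builds deterministic cohorts whose CHE
headcount at a given threshold is exact by construction (shares placed at
1.5× and 0.5× the threshold), providing ground truth for end-to-end tests.

## Numerical choices

* Strict inequalities at both the CHE threshold and the poverty line.
* Population (1/n) covariance in the concentration index; cross-checked in
  tests against the "convenient regression" formulation.
* Invariant tolerances: brute-force oracle agreement to 1e-12 (1e-9 for the
  concentration index); rank mean 0.5 to 1e-12; Wald CI endpoints use the
  literal 1.96 multiplier.
* Cross-field record invariants (food ≤ consumption, reimbursement ≤ OOP)
  allow 1e-9 absolute slack so serialisation round-trips cannot create
  spurious violations.
* Bootstrap CIs for cost summaries: percentile method, 1000 replicates,
  seeded from the analysis config.

## Problem sizes in tests and scripts

The acceptance script averages generator calibration targets over 20
replicate seeds (~8 700 records) and runs the worked examples at the
study's printed counts. The test suite's parameter-recovery checks use 30
seeds for the insured/mortality fractions, 100 replicates at n = 400 for
logistic coefficient recovery, and 200 simulations for the screening
type-I retention rate; the oracle-equivalence sweep uses 1 000 random
cohorts of n ≤ 500. These sizes give Monte-Carlo error comfortably inside
the asserted bounds while keeping the default run fast.

## Known limitations

* The study's printed rank-weighted headcount/overshoot cells are not
  consistent with its own printed H, O and C values under any standard
  weighting convention; the package implements the standard `H·(1 − C)`
  construction and does not attempt to reverse-engineer the printed cells.
* The printed annual poverty line (17 398 birr) differs slightly from the
  arithmetic product of its stated components (17 421.45); the computed
  value is used.
* Adjusted odds ratios of the study's driver table cannot be recomputed
  without the underlying microdata and are out of scope.
* No survey weights or facility clustering: the cohort is an unweighted
  facility sample and is analysed as such.
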