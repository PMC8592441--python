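# Methods

This note documents the model implemented by `sclc_cea`, the conventions
chosen where the source analysis is under-specified, and what the test
suite does and does not establish.

## Cohort model

Three states (progression-free, progressed, dead); everyone enters
progression-free. Horizon 10 years at 21-day cycles → `ceil(10·365.25/21)`
= 174 cycles. Discounting is continuous-time compounding at 3%/year
evaluated at cycle boundaries, `(1.03)^(−k·21/365.25)`.

**Transitions.** Death is evaluated first each cycle, for both alive
states, from the arm's overall-survival law: `tp_die(t) = 1 −
S_os(t)/S_os(t−1)` with `t` in cycles. Among survivors, the probability of
remaining progression-free is the conditional ratio
`[S_pfs(t)/S_pfs(t−1)]/(1 − tp_die)`, so the unconditional stay probability
is the plain PFS ratio and progression takes the remainder
`1 − tp_die − S_pfs(t)/S_pfs(t−1)`, floored at zero. The floor matters in
the first one or two cycles, where the fitted PFS law can decay more slowly
than the OS law; the warning-free clip keeps every transition row a
probability vector. Two consequences used heavily by the tests: alive
occupancy equals `S_os(t)` exactly (telescoping), and progression-free
occupancy equals `S_pfs(t)` wherever the floor is inactive.

**Accrual convention.** All per-cycle accruals (life-years, QALYs,
per-cycle cost streams) use the *standard half-cycle correction*: cycle `k`
credits the mean of its start- and end-of-cycle discounted occupancy.
One-off bundles are charged at model entry; the terminal-care cost is
charged per new death at the death cycle's half-cycle discount weight. The
source publication does not state its convention; we chose the half-cycle
correction because it reproduces the published incremental cost almost
exactly (81,281 vs 81,472 USD) and keeps every published base-case
outcome within its stated tolerance, whereas start-of-cycle accrual
overshoots the ICER band. `half_cycle: none` (start-of-cycle occupancy)
remains available in the configuration.

## Survival laws and fitting

The log-logistic law is `S(t) = 1/(1+θ·t^γ)`. The published transition
equations print `exp(θ)` where the rate appears; substituting θ directly
reproduces the trial's reported arm medians (≈9.7 and ≈11.0 months with
21-day cycles), while `exp(θ) ≈ 1` would put both medians below one cycle.
We therefore treat the printed `exp` as a typographical artifact and
default to `rate_transform: identity`, with `exp` available as a switch.
The time unit is model cycles: no other unit makes the printed (θ, γ) pairs
consistent with the trial medians.

Fitting offers two routes, mirroring the two things one can extract from a
published figure:

- `fit_ipd` — maximum likelihood with right censoring (via `lifelines`)
  for (pseudo) individual patient data; AIC = 2k − 2ℓ and
  BIC = k·ln n − 2ℓ with n the number of observations.
- `fit_km_points` — unweighted nonlinear least squares on the survival
  scale for digitized curve points. The publication names only software,
  not an objective; least squares on S(t) is the natural reading for
  digitized points. AIC/BIC use the Gaussian-equivalent log-likelihood of
  the residual sum of squares with a pseudo-n equal to the number of
  points (overridable), which makes criteria comparable across families
  fitted to the same points but not across data sets.

`select_distribution` minimizes AIC, breaking ties by BIC and then the
fixed order exponential → Weibull → log-normal → log-logistic.

## Utilities

Time-to-death utilities (0.834 / 0.765 / 0.709 / 0.563 with band edges at
1, 6 and 12 months; one month = 365.25/12 days) apply identically in both
alive states; the state-wise QALY split emerges from occupancy alone.

The cohort-level application of time-to-death bands is not specified in the
source. Two weightings are implemented:

- **`baseline` (default).** Band weights at cycle `t` are read off the
  arm's fitted OS curve at fixed offsets, e.g. weight(>12 m) = `S(t+12m)`,
  weight(≤1 m) = `1 − S(t+1m)`; the weights sum to one, with the mass of
  deaths accrued *before* `t` folded into the nearest-to-death band. This
  reproduces the published per-arm QALYs and the published incremental
  QALY gain (0.225 vs 0.22) and is what a curve-lookup reward table in a
  decision-tree package computes.
- **`conditional`.** Proper conditional probabilities
  `[S(t+a)−S(t+b)]/S(t)` given survival to `t` (the partition returned by
  `band_probabilities`). This is the probabilistically self-consistent
  reading — it equals assigning each patient utilities along their own
  time-to-death trajectory — but yields per-arm QALYs ≈0.08 higher and an
  incremental gain of 0.296, irreconcilable with the published 0.22±0.04
  because the incremental *life-year* gain implied by the published OS
  parameters is already 0.352 and no utility profile in [0.563, 0.834] can
  compress it below ≈0.26 under conditional weighting.

Both weightings coincide at model entry and under degenerate (immortal)
laws, satisfy QALY ≤ LY, and are monotone in each band value.

## Costs

Eight categories mirror the published base-case table.

- **First-line acquisition.** Pembrolizumab 200 mg q3w; etoposide
  100 mg/m² days 1–3 and platinum (carboplatin AUC 5 by Calvert, share
  0.711 / cisplatin 75 mg/m², share 0.289) for 4 cycles — the trial's
  regimen, all overridable in the configuration. Costs accrue over
  progression-free occupancy; pembrolizumab while progression-free up to
  its 35-dose cap (default policy `pfs_occupancy_max35`, which reconciles
  with the published 94,384 USD first-line acquisition). `fixed_median7`
  caps pembrolizumab at the trial's 7 median cycles instead.
- **Second-line acquisition.** Default mode `calibrated`: a per-cycle rate
  applied to treated progressed occupancy (uptake 0.529 / 0.655), with the
  rates (174.30 / 80.76 USD per treated cycle) calibrated once so the
  discounted base-case totals equal the published 1,439 / 614 USD; they
  scale with occupancy and uptake in sensitivity analyses. A bottom-up
  `nccn` mode prices a configurable subsequent-therapy mix
  (nivolumab+ipilimumab, topotecan, irinotecan, etoposide) with infusion
  fees; its dose schedule and shares are package assumptions, since the
  source's regimen appendix is not reproduced here.
- **Administration / AE bundles.** The published per-arm first-line AE
  management bundles (8,680.05 / 8,110.70) feed the "drug administration"
  row; the second-line AE rows (13,572 / 23,180) are encoded as the
  subsequent-therapy bundles (5,429.48 / 6,129.80) times fixed per-arm
  multipliers (2.4997 / 3.7815 — the first is exactly 2.5), so sampling
  the bundles propagates proportionally. First-line AE rows
  (1,250 / 978) are direct inputs.
- **Visits, supportive care, death.** Outpatient visits 52.33 USD per
  alive cycle; supportive care 637 USD/month for progressed patients
  without subsequent therapy; 9,433 USD once per death. The published
  table's values for these three rows (e.g. follow-up visits of 3,482 vs
  4,612 with the *shorter-lived* arm costing more) cannot be derived from
  these stated unit costs under any occupancy accounting we found; the
  formulas are implemented as stated and the discrepancy (≈+3–6% on arm
  totals) is absorbed by the published ±10% tolerance on totals.

Prices are linear per mg (average sales price); no vial rounding.

## Sensitivity analyses

**DSA.** Every parameter moves one at a time to its published range
(mostly ±20%); the full model is re-evaluated at each bound and rows are
sorted by ICER spread. Pembrolizumab price dominates; the utility within
one month of death is second — matching the published narrative — and all
one-way ICERs fall in ≈[283k, 439k] $/QALY.

**PSA.** 1,000 joint independent draws. Gamma distributions are
parameterized (shape, rate) with mean shape/rate; beta as (a, b) with mean
a/(a+b). The published table prints (shape, second) pairs whose second
entry is redundant given the base value; the sampler therefore derives
rate = shape/mean and b = a(1−μ)/μ, which reproduces the printed pairs to
rounding and corrects three entries whose printed second parameter implies
a mean far from its own base value (irinotecan, the additional infusion
hour, and the 1–6-month utility). Survival parameters are held fixed (no
distributions are published for them) — a documented limitation that makes
the CEAC steeper than one sampling survival uncertainty would be. Because
the traces are therefore draw-invariant, each iteration reduces to
re-weighting precomputed occupancy aggregates, and a point-mass PSA
reproduces the base case exactly (tested).

**Internal inconsistency of the published PSA summaries.** The published
PSA reports a 1.55% probability of cost-effectiveness at $100,000/QALY and
a CEAC 50% crossing at $210,000/QALY. Jointly these imply a median
incremental cost near $46,000 — not the published $81,472 — and a crossing
at $210,000 with ΔC = $81,472 would require ΔQALY ≈ 0.39, exceeding the
incremental life-years (0.30 published, 0.352 implied by the OS
parameters), which QALY ≤ LY forbids. Our PSA, centred on the base case as
the published distributions dictate, yields a crossing near the base-case
ICER (≈$360,000) and a PSA price threshold of ≈$16/mg rather than the
published <$10/mg; note the published deterministic "65% reduction"
figure itself implies ≈$17.3/mg, consistent with ours. The two acceptance
tests asserting the published crossing and price threshold therefore fail,
deliberately: they record the published values as published.

**Price analyses.** Deterministic threshold by bisection on the unit price
until the ICER is within $100/QALY of the target ($16.31/mg, a 67%
reduction, for $100,000/QALY); probabilistic sweep over a price grid with
the sampling mean rescaled to each grid price and common random numbers
across grid points.

## Synthetic data

The generator emulates the two inputs the fitting pipeline needs: IPD by
inverse-CDF sampling with administrative censoring (default n = 1000,
censoring at 45 cycles ≈ the trial's OS follow-up), and digitized curve
points (30 points over the published follow-up windows — 33 months OS, 21
months PFS — with additive Gaussian noise, sd 0.01, clipped and
isotonically corrected). It does not model trial accrual, dropout
mechanisms, arm imbalance, digitization serial correlation, or
between-reader variability, so passing recovery tests show the estimators
work on clean curve-shaped data, not that digitization of real figures is
unbiased.

## Numerical choices and problem sizes

- Trace propagation is an exact 174-step recursion; no stochastic error.
- The microsimulation oracle in the tests uses 100,000 patients and agrees
  with the cohort trace within 3 binomial standard errors at cycles 1, 17,
  87 and 173.
- Distribution-selection replication uses 50 seeded cohorts of n = 1000;
  parameter-recovery checks use n ∈ {200, 1000, 5000}.
- PSA uses 1,000 iterations (as published); the PSA price sweep in the
  acceptance script uses a $0.50 grid at 1,000 iterations per point.
- Least-squares fits start from a crude median-based initial guess with
  positivity bounds; non-convergence is reported, not raised.

## Known limitations

- Single reference patient; no covariate or subgroup structure.
- No adverse-event disutilities (none are modelled in the source).
- Survival uncertainty is excluded from the PSA (see above).
- The three under-derivable cost rows (visits, supportive care, terminal
  care) follow their stated unit-cost formulas, not the published row
  values; arm totals remain within ±10% of the published table.
- Extrapolation rests entirely on the log-logistic tails beyond ~3 years
  of follow-up; the heavy pembrolizumab tail (γ ≈ 1.72) drives most of the
  incremental life-years.
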