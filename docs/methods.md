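# Methods

This note documents the model, its assumptions and parameters, the
numerical choices, and what the synthetic-data generator does and does not
emulate. It describes what the package computes; every number cited here
is produced by the test suite or the acceptance script.

## The decision model

Two strategies are compared for female entertainment workers in Cambodia:
the Mobile Link messaging-plus-outreach intervention and usual care. The
trial that motivates the model found no statistically significant
differences on its primary outcomes; the evaluation therefore treats the
arm-level endline risks as uncertain quantities and asks a probabilistic
question — how likely is the intervention to be cost-effective given the
evidence — rather than a hypothesis-testing one.

### Health effects

Five binary outcomes enter the model: HIV testing, STI testing, modern
contraceptive use, no forced drinking at work, and low/no gender-based
violence. All are coded so that a *higher* endline risk is the healthier
state. Each outcome maps to a disability weight (the severity, in [0, 1],
of the health state it protects against); over the model's 1-year horizon
no years of life lost accrue, so the DALYs attached to an outcome equal
its disability weight times time. The per-person effect is

    total DALYs averted = Σ_i (ARD_i / 100) · DW_i

with `ARD_i` the absolute risk difference (intervention minus usual care)
in percentage points. Risks are carried on the percent scale everywhere
upstream; the ÷100 conversion happens exactly once, in `daly_model`.

The bundled disability weights (means/SDs: HIV 0.147/0.085, STI
0.006/0.002, contraception 0.014/0.008, forced drinking 0.123/0.063, GBV
0.211/0.109) are treated as already adjusted for disease prevalence and
treatment-after-testing probabilities; the exact adjustment formulas
behind them were not published. `adjust_dw` offers a generic
multiplicative adjustment (`dw × prevalence × p_treated_after_positive`)
for users starting from raw burden-of-disease weights; it defaults to the
identity rather than guessing the original formulas.

### Uncertainty propagation

Each arm's endline risk is drawn from a distribution moment-matched to
its reported mean/SD: normal in the base case, beta or uniform as
sensitivity analyses. Disability weights are always beta, with shapes
from the method of moments (`ν = μ(1−μ)/σ² − 1`, `α = μν`, `β = (1−μ)ν`);
infeasible moment pairs (σ² ≥ μ(1−μ)) raise a named error. Uniform bounds
are `μ ± √3·σ` by default, with an explicit-bounds mode per outcome for
users who have interval endpoints instead of moments.

Numerical choices:

- **No truncation of normal risk draws to [0, 100].** Truncation would
  bias the mean/SD away from the reported moments the family is matched
  to; out-of-range draws are counted and logged at debug level. At the
  bundled parameters they are vanishingly rare.
- **Independence everywhere** — across outcomes, between arms, and
  between risks and weights. The distributions are fitted separately per
  arm and outcome and no correlation structure is specified; this also
  makes the expected total equal the sum of products of means, which the
  tests exploit as an analytic oracle (0.0174647 from the bundled point
  estimates).
- **Draw order is fixed and outcome-major**: per outcome, control risks,
  then intervention risks, then weights, all from one seeded
  `numpy.random.Generator`. A zero-SD input produces a constant column
  and consumes no draws. Runs are bit-reproducible at a fixed numpy
  version given seed and config.
- **Predicted intervals** are the 5th–95th empirical percentiles of the
  simulated results (linear interpolation between order statistics) —
  the percentile pair is configurable, and the defaults follow the
  source evaluation's stated definition of its "95% predicted interval",
  which is a 90% interval by the usual naming convention.

A known reproduction limit: the source evaluation's printed predicted
intervals are several times wider than what moment-matched sampling from
the printed arm-level SDs can generate (its distributions were evidently
parameterized from confidence-interval bounds in unpublished appendices).
The per-outcome and total *means* reproduce; the intervals do not, and
are reported as this model's own. Similarly the printed uniform-family
means imply asymmetric bounds that cannot be recovered from printed
moments, so the uniform family here is a moment-matched sensitivity
analysis, not a replication of that column.

### Costs

The payer cost ledger classifies trial expenditure by funder, activity
and input type, with an arm-scope flag: usual-care services funded for
both arms, and intervention-specific costs. Shared costs are divided
evenly over all participants; intervention-only costs over
intervention-arm participants — this conserves money (per-person cost
times denominator, summed over arms, returns the ledger total). Because
the denominators behind the published per-person figures (US $429
intervention, US $230 usual care) were never printed, per-person
overrides are first-class config and the bundled config pins them; the
allocation path is exercised with synthetic ledgers in the tests.

One reconciliation choice: the printed Global Fund IEC input lines sum to
one dollar more than the printed IEC subtotal. The bundled ledger lowers
the IEC personnel line by $1 (254,432) so that every printed subtotal and
funder total (163,180; 396,357) reproduces exactly.

The payer+patient perspective credits each arm with the value of time
saved by outreach contact: 2.2 h to reach services unaided vs 0.6 h after
contacting an outreach worker (net 1.6 h/contact), two contacts, valued
at US $6.75/h (US $270 weekly earnings over a 40-hour week) — US $21.60
per fully-engaged person. Arm-specific contact proportions were not
published; the bundled pair (0.585 vs 0.400) is **reconstructed** so that
its difference (0.185) reproduces the published combined-perspective
incremental of US $195, and only the difference is identified. Out-of-
pocket and transportation costs are excluded, as in the source analysis.
All amounts are 2019 US $ floats; no discounting on a 1-year horizon.

### Decision analysis

The ICER is the ratio of expected values, `ΔC / E[ΔE]`, not the mean of
per-simulation ratios: the simulated effect crosses zero, where per-sim
ratios are undefined and their mean unstable. The acceptability frontier
computes, per threshold λ on a default grid of US $0–50,000 in $250
steps, the probability that each strategy has the higher net monetary
benefit, and reports the strategy with the higher *expected* NMB (usual
care on ties); the frontier's switch point coincides with the ICER of the
draws by construction. Break-even analyses invert the ICER: required cost
reduction `1 − λ·E[ΔE]/ΔC` (floored at 0) and required effect `ΔC/λ`.
The effect multiplier is reported under both conventions — the plain
ratio and ratio − 1 ("times higher") — because the two phrasings are
routinely conflated; the package does not privilege either.

### Budget impact

Coverage grows by 6,958 newly enrolled people per year for 5 years
(34,790 of an estimated 50,000; the often-quoted "additional 14% per
year" would be 7,000 — the enrollee count is taken as primary because
5 × 6,958 matches the reported final coverage). Messaging (US $2.66) and
outreach (US $9.54) costs accrue per person per year on *cumulative*
coverage — enrollees keep receiving services — which is what makes
outreach dominate the horizon budget. Outreach headcount
(⌈cumulative/280⌉) is informational; costs use the per-person rate. The
startup (capital) cost lands in year 1 only; its published line-item
basis was not printed, so the bundled value (US $316,686) is
**back-derived** to reconcile the reported ~US $1.59 million horizon
total, and is plain config. (The source's abstract prints US $1.64
million against US $1.59 million in its results text; the tests assert
internal arithmetic consistency, not either headline.) No discounting:
the projection is a financial budget.

## The synthetic trial generator

`synthetic_trial` emulates the statistical structure the model assumes:
an individually randomized two-arm trial, binary endline outcomes drawn
independently per participant and outcome at configurable true risks, and
dropout that is missing completely at random (consistent with the source
trial's report of no significant differences between dropouts and
stayers). Arm-level estimation returns the complete-case risk on the
percent scale with its binomial standard error, which slots directly into
an `OutcomeSpec`. Default CLI dimensions (559 per arm, 65% dropout)
mirror the source trial's scale.

What it does **not** emulate: baseline/midline longitudinal structure,
covariate adjustment (the source's multilevel logistic models are out of
scope), informative dropout, or between-outcome correlation within a
participant. Passing tests therefore demonstrate that the pipeline is
correct under its own assumptions — unbiased risk recovery, correct
propagation — not that those assumptions hold in any real trial.

## Problem sizes and tolerances

The default PSA runs 10,000 simulations (seconds on one CPU); moment-
recovery property tests use 100,000 draws and a 4-standard-error band;
synthetic-trial parameter recovery uses 10,000 per arm and a 3-binomial-SE
band. Stochastic end-to-end checks compare Monte Carlo means to analytic
expectations within 3–4 MC standard errors plus printed-precision
rounding; the total-effect check uses a ±0.002 band around the published
0.018 because the published components themselves sum to 0.0174647. The
published ICERs (US $10,955 and $10,755) imply an unrounded mean effect
(≈0.0182) that printed inputs cannot reproduce exactly; the fixture ICER
lands within ~4% and is asserted within 10%.
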