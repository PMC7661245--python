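# Methods

## Measurement model

Items follow Samejima's graded response model (GRM). Each item has one
discrimination `a > 0` and ordered thresholds `b_1 < … < b_{K-1}` for `K`
response categories. Cumulative curves are logistic,
`P*_k(θ) = 1 / (1 + exp(−a(θ − b_k)))`, category probabilities are adjacent
differences with boundaries `P*_0 = 1`, `P*_K = 0`, and item Fisher
information is `I(θ) = Σ_k (P*'_k − P*'_{k+1})² / P_k` with
`P*'_k = a P*_k (1 − P*_k)`. Information is additive across items under
local independence. For `K = 2` every quantity reduces to the
two-parameter-logistic closed forms (`I = a² P (1 − P)`), which the tests
use as anchors.

The logistic metric is `D = 1`, the dominant convention in CAT engines.
Parameter tables calibrated on the normal metric (`D = 1.7`) must have
their `a` values multiplied by 1.7 before loading; the package does not
guess the metric from the data.

## Ability estimation

Scoring is expected a posteriori (EAP): the posterior mean of θ under a
standard-normal prior, computed on a fixed equally spaced 61-point grid
over [−4.5, 4.5]. The reported SEM is the posterior SD on the same grid —
it is finite after a single response (where maximum likelihood diverges on
all-minimum or all-maximum patterns) and equals the prior SD exactly for
the empty pattern, which keeps the downstream percentile step (a N(0, 1)
reference) coherent with the estimator. EAP was preferred over ML/MAP/WLE
because it is deterministic, defined for every response pattern, and its
prior matches the reference population of the percentile score; other
estimators are out of scope for this release.

Numerical choices:

- The likelihood is accumulated in log space and normalized by a single
  max-subtraction before exponentiating, so 50+ item patterns cannot
  underflow. Category probabilities are floored at 1e−300 inside logs and
  at 1e−10 inside information sums (tail guard; no effect at reported
  precision).
- Grid endpoints carry half weight (trapezoid rule). With raw density
  weights the quadrature error decays only linearly in the grid spacing
  when the posterior has visible mass near ±4.5; with the endpoint
  correction the 61-point estimate agrees with a 10,001-point direct
  integration to better than 1e−4 in both θ and SEM, which the test suite
  verifies on 200 random patterns.
- The empty-pattern estimate returns the prior's closed-form moments
  (0, 1) exactly rather than their quadrature approximations; the grid
  records those moments.
- Per-item log-probability tables on the grid are cached on the grid
  object: an item's curves are fixed, so the repeated re-estimations of a
  session (and all simulees sharing a grid) reuse them.

## Adaptive loop

The engine selects the unadministered item with maximum information at the
current θ estimate; ties break by bank (file) order, first wins, so runs
are fully deterministic. With no responses yet the estimate is the prior
mean, so the first item is the most informative one at θ = 0 — the
deterministic, prior-consistent choice.

Stopping rules (at least one required): minimum SEM, maximum item count,
maximum elapsed seconds, plus implicit bank exhaustion. The SEM rule uses
`sem ≤ threshold` (reaching the threshold exactly stops the test) and is
checked only after at least one response, so a prior SD already below
threshold cannot produce a zero-item test. When several rules are met at
once the reported reason follows the fixed precedence
min_sem → max_items → max_seconds → bank_exhausted, keeping reason labels
reproducible. The time limit is supported as configuration but is not
exercised by the simulation designs (simulated respondents answer
instantly). There is no exposure control or content balancing: selection
is literally maximum-information.

## Scoring, feedback, persistence

The flow mirrors a three-node assessment: the adaptive session yields
(θ, SEM); a scoring node maps θ to `percent = 100 Φ((θ − mean)/sd)` with a
configurable normal reference (default mean 0, SD 1); a feedback node
substitutes `{{theta}}`, `{{sem}}`, `{{percent}}` into a template validated
at load time (unknown placeholder names are rejected). Display formatting
is 2 decimals for θ and SEM and 1 for percent, configurable; stored values
keep full precision and are formatted only at render time, so nothing is
double-rounded and percent is never clamped away from 0/100.

Sessions persist to an append-mode CSV, one row per administered item plus
a summary row carrying the final estimate, percentile, stop reason and
rendered feedback. Numeric fields are written with `repr` round-trip
precision, so persist-then-load reproduces the record exactly. The
timestamp column holds the session start time on step rows and the end
time on the summary row. Duplicate session ids are rejected as conflicts.

## Synthetic data

The generator emulates a calibrated PROM bank, not any specific published
instrument. Defaults: 100 items, 4 categories; discriminations log-normal
with location log 1.7 and scale 0.3 (mean a ≈ 1.78 — the magnitude of
well-calibrated PROM banks, where discriminations are positive and
right-skewed); item threshold centers N(0, 1.2²), spreading difficulty
over the population range; within-item thresholds equally spaced 1.0 apart
around the center, making them strictly increasing by construction.
Simulees draw θ from N(0, 1), matching the estimator's prior; a
prior-mismatch stress design is available by passing a different
`theta_mean`/`theta_sd` to the experiment, but is not a default. All
randomness descends from one seed through spawned `SeedSequence` streams,
one per simulee, so experiments are bit-reproducible and per-simulee
streams are independent.

What the generator does **not** emulate: local dependence between items,
multidimensionality, differential item functioning, careless or missing
responses, and calibration error in the item parameters (parameters are
treated as known truth). Passing simulations therefore demonstrate the
engine's correctness and the internal consistency of the adaptive
machinery, not the field performance of any real instrument.

## Validation experiments and problem sizes

The headline experiment administers each of 500 simulees twice — adaptively
to the SEM ≤ 0.5 rule and with the complete 100-item bank (the adaptive
session consumes responses pre-drawn for the full bank, so the two scores
differ only through item selection) — and summarizes mean administered
items, the reduction fraction, Pearson r between adaptive and full-bank
scores, and trait recovery (bias, RMSE). These sizes run in seconds to a
couple of minutes on one CPU and give Monte-Carlo standard errors of
roughly 0.005 on the recovery bias, small against the tested bounds.

Frozen regression bounds for full-bank recovery (|bias| < 0.05,
RMSE < 0.25) were set from an independent large-n run (5,000 simulees,
separate seed), which observed bias ≈ −0.001, RMSE ≈ 0.124 and calibration
slope 0.986 — comfortably inside the bounds, which mainly guard against
estimator regressions rather than sampling noise.

A caveat on the adaptive-vs-full agreement statistic: because the adaptive
pattern is a subset of the full pattern, the correlation between the two
EAP scores equals sd(cat)/sd(full) ≈ sqrt(rel_cat/rel_full), and stopping
at SEM ≤ 0.5 pins the adaptive reliability near 1 − 0.5² ≈ 0.75–0.80. The
default experiment therefore centers r almost exactly on 0.90 and
individual seeds land on either side of it (observed 0.885–0.911 across
seeds); r is a property of the stopping threshold, not of engine quality.
Tightening the rule to SEM ≤ 0.4 moves r decisively above 0.9 at the cost
of more items.

## Known limitations

- GRM only; no partial-credit, nominal or multidimensional models.
- EAP only; the estimator interface is internal, not pluggable.
- No item exposure control, content balancing, or enemy-item constraints.
- The response store is a flat CSV intended for desk-scale use, not a
  concurrent multi-user backend.
- Time-limit stopping exists in configuration but is untested against
  real human pacing.
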