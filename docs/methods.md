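# Methods

## The statistical problem

Daily time use is a zero-sum budget: the D behaviours of a 24-hour day
(here D = 4: sleep, sedentary time, light-intensity activities and games,
energetic play; or D = 5 with sedentary time split into screen time and
quiet play) sum to 1440 min. Raw minutes therefore live on a simplex and
carry only relative information; treating them as unconstrained regressors
produces exactly collinear designs and uninterpretable coefficients.
`coda24` follows the standard compositional approach: map the composition
to D−1 isometric log-ratio (ilr) coordinates, model the outcome linearly in
those coordinates, and express results either as per-rotation first pivot
coefficients or as predicted changes under time reallocations.

## Pivot coordinates

With the dominant behaviour moved to position 1 and the remaining parts in
declared order, the j-th pivot coordinate is

ilr_j = √((D−j)/(D−j+1)) · ln( x_(j) / (∏_{k>j} x_(k))^{1/(D−j)} ),  j = 1…D−1.

The corresponding D×(D−1) contrast matrix V has orthonormal, zero-sum
columns, so coordinates are computed as Vᵀ ln x and are invariant to any
rescaling of x (closure is cosmetic for the transform; it matters for
reporting minutes). The sign convention makes a positive ilr₁ mean
relatively more of the dominant behaviour. The ordering of the
non-dominant parts is arbitrary; it changes ilr₂…ilr_{D−1} but provably
not ilr₁, nor any fitted value, R² or substitution delta of a linear model
using the full coordinate set (the bases differ by an orthogonal rotation).
Property tests assert this invariance to 1e−10…1e−12.

## Preprocessing rules

- Non-wear: maximal runs of per-minute signal SD strictly below 13 mg
  lasting ≥ 30 min (half-open minute intervals).
- Valid day: ≥ 480 min wear. Included child: ≥ 3 valid weekdays and
  ≥ 1 valid weekend day, with complete survey and outcome data.
- Energetic play = walking + running + moderate-to-vigorous activities and
  games, summed per day before averaging.
- Valid days are averaged arithmetically and unweighted (no
  weekday/weekend weighting).
- Sleep is the parent-reported night + day total; the accelerometer covers
  waking hours only.
- Non-wear reallocation: wake parts are scaled by
  (1440 − sleep)/Σ(wake parts). This preserves wake-behaviour ratios
  exactly and handles both under- and over-coverage of the waking window
  with the same formula.
- Sedentary disaggregation (5-part mode): parent-reported weekly screen
  and quiet-play minutes are divided by 7, zeros replaced with 1 min, and
  the resulting proportions applied to the device-measured sedentary part,
  so screen + quiet play reproduce it exactly. Children without these
  reports are excluded only in this mode.
- Wake behaviours averaging exactly zero across valid days are set to
  1 min before closure (same convention as the survey zeros) and logged.
- SDQ total difficulties is recomputed as the sum of the emotional,
  conduct, hyperactivity and peer subscales; prosocial behaviour is
  reported separately.

## Regression and substitution

For each outcome and each dominant behaviour, ordinary least squares of the
outcome on [1, ilr coordinates, age (years), male indicator, parent
education dummies with secondary school as reference]. The overall
significance (F-test of the ilr block) and its R² come from the companion
fit without covariates; the covariate-adjusted R² and the ilr₁ coefficient
with its CI come from the full fit. Confidence intervals use Student-t
quantiles with the residual degrees of freedom (at n ≈ 1000 the difference
from normal quantiles is negligible; t is what standard linear-model output
reports). Outcomes are modelled as continuous despite being integer scores,
and no multiple-testing correction is applied — both deliberate mirrors of
common practice in this literature. Degenerate designs raise: rank
deficiency (e.g. an education dummy that is all zeros) is reported with the
design columns, and a constant outcome yields a zero-R² fit rather than a
division-by-zero artefact.

Substitution estimates use the cohort's closed geometric-mean composition
as the base day. For a reallocation of m minutes from A to B,
d = ilr(base_{A→B,m}) − ilr(base), Δ = β_ilrᵀ d, Var(Δ) = dᵀ Cov(β_ilr) d,
CI = Δ ± t_{0.975,df} √Var. This equals the difference of two full-model
predictions with covariates held fixed (asserted to 1e−10 in tests), and is
invariant to the dominant-behaviour rotation of the fitted model.
Reallocations that would drive a part to zero or below are infeasible:
tables mark the cell, curves truncate at the first infeasible grid point.
Ordered pairs are reported (A→B and B→A), and at small m the two are
near-antisymmetric; the package tests this between the large behaviours,
where m is a genuinely small perturbation — for the ~40-min energetic-play
part a 10-min move is a 25% change and the log-ratio curvature makes exact
antisymmetry impossible.

## Synthetic cohort generator

The generator exists because no raw cohort of this kind is publicly
available; it encodes the study conditions the analysis assumes and records
its ground truth so that recovery is checkable end to end.

- **Latent composition.** Sleep ~ Normal(687.9, 75.5) min truncated to
  (300, 900). Wake behaviours are logistic-normal around means
  (sedentary 291.3, LIAG 334.2, energetic 39.4) min with log-scale SDs
  (0.21, 0.14, 0.36) chosen to match the observed minute-scale SDs
  (62.4, 46.6, 14.2) at those means; the wake vector is scaled into the
  waking window 1440 − sleep and the 4-part day is closed to 1440.
  Sleep and wake composition are generated independently (their true joint
  dependence is unknown; the assumption is recorded here rather than
  hidden). Because renormalisation biases the expected share of
  high-variance small parts upward by ~2%, a deterministic, config-driven
  fixed point (fixed internal seed, cached) centres the log-means so that
  realised mean wake fractions match the configured means.
- **Day records.** Seven days per child (5 weekday + 2 weekend). Day-level
  compositional jitter is lognormal with SD 0.12 on each wake part
  (renormalised). Non-wear ~ Gamma(4, mean 87 min) — 87 = waking window
  752.1 minus the wake-minute total 664.9, so mean valid-day wear lands on
  the observed total — capped so regular days keep ≥ 8 h wear; invalid days
  are injected explicitly with probability 0.05 (wear ~ U(60, 470)).
  Energetic play is split into walking/running/MV games as 0.5/0.2/0.3.
- **Survey.** Naps occur with probability 0.6 (Normal(75, 25) min,
  clipped); night sleep is the remainder of the latent total. The
  screen share of reported sedentary time is Beta(5, 5) — centred, matching
  the near-even observed split (geometric means 141.3 vs 137.0 min) —
  with weekly totals zero-inflated at 0.009 (screen) and 0.039 (quiet
  play) and reports missing entirely with probability 0.009. Age
  ~ U(2, 5) years, male with probability 0.511, parent education
  trinomial (0.138, 0.280, 0.582).
- **Outcomes.** Each SDQ subscale is linear in the ilr coordinates of the
  latent 4-part composition (sleep-dominant basis) plus covariate effects
  and Gaussian noise; intercepts are calibrated so population means hit the
  observed subscale means. The default first-coordinate effects are the
  reported per-subscale magnitudes, and total difficulties is always the
  *sum* of the four difficulty subscales — their first coefficients sum to
  −2.65, the recovery truth. A shared residual component (SD 0.72) across
  the difficulty subscales, representing a parent-rating halo, lifts the
  total's residual SD to the observed 4.5 (independent subscale residuals
  alone would give √12 ≈ 3.5). Covariate effects are small plausible
  values (e.g. hyperactivity higher in boys, declining with age); nothing
  in the source material pins them down, and recovery tests do not depend
  on them. Discretisation (round + clip to 0–10) is off by default for
  clean recovery experiments and on wherever survey CSVs are emitted.

What the generator does **not** emulate: raw 30 Hz accelerations and
classifier error, within-week structure (weekend days differ only by
label), sleep–wake-composition dependence, non-leisure sedentary time, and
item-level SDQ scoring. Passing recovery tests therefore show that the
estimation chain is unbiased and calibrated *under its own assumptions*,
not that those assumptions hold in any real cohort.

## Problem sizes and numerical choices

- Exactness suites run 1000 seeded random cases (round-trip 1e−10,
  orthonormality 1e−10, ilr₁ order-invariance 1e−12, delta-oracle 1e−10).
- Recovery: 500 replicates at n = 1073 via the record-level generation
  path; mean ilr₁(sleep) within 10% of −2.65 and 95% CI coverage in
  [92%, 98%].
- Null calibration: 2000 replicates at n = 500; overall-p rejection rate
  in [3.5%, 6.5%] at nominal 5%.
- CSV serialisation uses 6 significant digits; the day-record consistency
  check (class minutes ≤ wear) allows 0.01 min slack so serialised cohorts
  re-validate.
- Seeds: every stochastic routine takes a NumPy `Generator` or integer
  seed; replicate seeds are drawn below 2³¹ from a parent generator.

## Known limitations

- The proportional non-wear reallocation is one reading of "proportionally
  reallocated"; alternatives (e.g. behaviour-specific reallocation
  probabilities) are not implemented.
- Arithmetic (not compositional) averaging of valid days is used before
  closure; a sensitivity comparison would be straightforward but is out of
  scope.
- Substitution CIs use the delta-method coefficient-covariance form, not a
  bootstrap.
- The CLI exposes only CSV artefacts; band plots (reallocation curves) are
  left to the user's plotting tool of choice via `curves.csv`.
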