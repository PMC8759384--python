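# Methods

## Growth model and eigenvalues

Per-stem accumulation is modelled as `W(T) = W_max/(1 + a·e^(−k·T))`
with `W_max > 0` (asymptote, g stem⁻¹ for dry matter, mg stem⁻¹ for
nitrogen), `a > 0` (dimensionless shape) and `k > 0` (d⁻¹). Time is
counted in days after sowing; an emergence offset can be added by
shifting the input times, but the default origin is sowing because the
reference trial's inflection times (~135–156 d of a ~200 d season) are
only consistent with sowing-based counting.

The fast-phase summary follows from the curve's derivatives. The second
derivative vanishes where the shape factor `u = a·e^(−kT)` equals 1,
giving `Tm = ln(a)/k`; the third derivative vanishes at `u = 2 ± √3`,
giving `T1 = ln(a/(2+√3))/k` and `T2 = ln(a/(2−√3))/k`. Note the
argument of the logarithm is `a/(2±√3)`: with `a ≫ 1` the reciprocal
form would place both boundaries at negative times. Derived identities
used as invariants: `T2 − T1 = 2·ln(2+√3)/k` (depends on `k` only),
`W2 − W1 = W_max/√3`, `Vm = k·W_max/4`, `Vt = W_max/(√3·(T2−T1))` and
`Vm/Vt = (√3/2)·ln(2+√3) ≈ 1.1405` for every parameter triple. The
derivation is cross-checked in the tests against bisection roots of
symbolically differentiated curves (sympy + brentq), which agree to
~1e-13 d; plain finite differences were too cancellation-prone at the
1e-6 d tolerance and were rejected as the oracle.

The phase is undefined for `a ≤ 2−√3` (the boundary would precede the
curve's support ordering); this raises a dedicated error rather than
returning unordered times.

## Fitting

`fit_logistic` minimises the unweighted SSE over `(W_max, a, k)` with
positivity bounds using `scipy.optimize.least_squares` (trust-region
reflective, `x_scale` set from the initial point because `a` spans
10⁴–10⁹ while `k` is ~0.1). Replicates are averaged per time point
before fitting — the reference fits used six stage means — and at least
four distinct times are required for three free parameters. The
initial guess is deterministic: `W_max⁰ = 1.05·max(w)`, then OLS of
`ln(W_max⁰/w − 1)` on `t` over points strictly inside `(0, W_max⁰)`
yields `a⁰ = e^intercept`, `k⁰ = −slope`. The 5 % asymptote inflation
biases the linearisation (on noiseless test curves `k⁰` lands within
~20 % and the implied inflection within ~10 % of truth), which is
sufficient: the subsequent bounded fit recovers noiseless parameters to
optimizer tolerance (~1e-14 relative in practice). There are no random
restarts by default, so a fit is a pure function of the data and
options. Non-convergence sets `converged=False` and logs a warning
instead of raising, so one bad treatment does not abort a batch run.
`R²` is `1 − SSE/SST` on the per-time means and is undefined (error)
for zero-variance data.

## Thermal time and phenology

Accumulated temperature is `Σ max(t_mean − base, 0)` over an interval
inclusive of both endpoint days; the base defaults to 0 °C, which
reproduces the magnitudes of the reference season table, and is
configurable. Wintering onset is the first day of the first run of at
least `run` (default 3) consecutive days with mean temperature below
`threshold` (default 10 °C); the pre-wintering thermal time sums from
sowing to the day *before* onset, since the onset day already belongs
to the cold spell. Cross-sowing-date contrasts (flowering advance,
growth-duration shortening, percent thermal-time reduction) are
computed per season first and then averaged across seasons — the only
convention that reproduces the reference trial's printed 4.0/7.5/11.5 d
flowering advances and 18 d duration shortening exactly. Percent
reductions are reported both raw and half-up-rounded; on the reference
data the 8-day-delay case averages 20.4 %, which prints as 21 % in the
original report's convention — a one-unit discrepancy inherent to the
printed table, not resolvable from the data.

## Yield statistics

Yield loss is `(Y_ns − Y)/Y_ns × 100` against the normal sowing date
(scale-invariant; negative for gains). Treatment advantages are
per-season ratios minus one, averaged across seasons. Pearson
correlations use `scipy.stats.pearsonr` on treatment means pooled
across seasons (n = 8) for yield-component traits, and within-season
means (n = 4) for the filling-days vs filling-temperature relation —
the conventions under which the reference correlations (0.73, −0.94)
reproduce. The loss-per-day slope is reported under three explicit
conventions (pooled OLS, mean of per-season OLS slopes, pooled
through-origin) because the published figure-level fit is not
recoverable from treatment means: the three give 1.18, 1.18 and 1.18
(0.98 through-origin on the first season alone) against a published
0.97 ± 0.22. No variant is claimed to equal the published value.

Ratio regressions fit grain yield on the mature/jointing accumulation
ratio per season (OLS via `scipy.stats.linregress`), solve
`slope·x + intercept = target` per season and average the thresholds —
this per-season-then-average convention reproduces the published 4.06
(DMA) and 2.49 (NA) thresholds at a 6000 kg ha⁻¹ target. A
coefficients-only path (`threshold_from_lines`) accepts already-fitted
lines so the solving step can run without raw points.

## Synthetic experiments

The generator emulates the *structure* of a two-season sowing-date
trial, not any particular year's weather:

- **Weather**: daily means are a sinusoid (annual mean 16 °C, amplitude
  10 °C, trough 15 Jan, so winter bottoms at 6 °C and a wintering onset
  always exists) plus AR(1) anomalies (sd 1.5 °C, ρ = 0.6);
  t_min/t_max sit ∓4 °C around the mean; precipitation is an
  exponential wet-day process. One realisation per season is shared by
  all sowing dates, as in the field design.
- **Phenology**: stages fall where each treatment's own thermal-time
  clock (base 0 °C) crosses thresholds of 350 (wintering), 1000
  (jointing), 1250 (booting), 1450 (flowering) and 2150 °C·d
  (maturity), so delayed sowing propagates into compressed phenology
  qualitatively as in the reference trial (the simulated compression,
  ~2–8 d, is milder than the observed one, which also reflects
  photoperiod and vernalisation responses the generator does not
  model).
- **Growth**: per treatment and variable, truth parameters are drawn
  uniformly inside envelopes taken from the reference fits (DMA:
  W_max 3.0–3.9 g, k 0.070–0.100, Tm 134–156 d; NA: W_max 44–54 mg,
  k 0.072–0.111, Tm 123–143 d), parameterised by `(W_max, k, Tm)` with
  `a = e^(k·Tm)` to keep curves in-window. Observations are sampled at
  one early-tillering point (day 15) plus the five stages — six points,
  matching the reference fits' n = 6; which sixth point the original
  analysis used is not stated, so the early point is this package's
  choice — with multiplicative log-normal noise (default sd 0.05),
  appropriate because accumulation is positive and spans orders of
  magnitude early on.
- **Yields**: plot yields are linear in the noise-free DMA
  mature/jointing ratio with per-season slopes/intercepts defaulting to
  the reference regression lines, Gaussian noise (sd 150 kg ha⁻¹) and
  three replicates; yield components are plausible correlates only.

Everything is driven by `numpy.random.default_rng` seeded from the
mandatory config seed with fixed per-component stream tags, so a given
config is byte-reproducible. A `zero_noise()` config variant switches
every stochastic term off; on it the full pipeline returns the
generating parameters, thermal sums and yield-line coefficients to
numerical tolerance (the principal integration test). Monte-Carlo
calibration at the defaults (200 seeds, 5 % noise, six stage points)
recovers the rate constant `k` with a median relative error of ~8 %.

Passing tests on synthetic data therefore demonstrate correctness of
the estimators under the generator's assumptions (logistic truth,
log-normal noise, linear yield-ratio link); they do not validate those
assumptions against field data — that evidence comes from the bundled
published summary tables, which the pipeline reproduces cell by cell.

## Numerical conventions

- Printed-precision comparisons round half-up (times to 1 decimal,
  rates to 2) before asserting, with tolerances 0.15 d / 0.015
  accumulation units justified by the 4-decimal rounding of the printed
  `k` values.
- Eigenvalue tables are reproduced from printed coefficients to worst
  deviations of 0.149 d (times) and 0.0052 (rates) across all 96 cells.
- Treatment labels are day–month strings (`28-Oct`) derived from sowing
  dates, which identifies a treatment across seasons.
- Degenerate inputs raise typed errors: non-positive parameters,
  `a ≤ 2−√3`, < 4 distinct fit times, all-equal observations (no
  linearisation), zero-variance R², out-of-range weather dates, zero
  reference thermal time, zero regression slope.

## Problem sizes

Default test and acceptance runs use two seasons × four sowing dates ×
two variables (16 curves), 200-replicate Monte-Carlo recovery checks and
1000 random parameter triples for the derivative-oracle equivalence;
these sizes give stable medians while keeping the whole suite in a few
seconds on one core.

## Known limitations

- No photoperiod/vernalisation phenology, no process-based crop
  physiology, and no area-based (population) accumulation curves;
  per-stem only.
- Alternative growth laws (Gompertz, Richards) and Bayesian fitting are
  out of scope; the logistic form is assumed, not selected.
- ANOVA/LSD multiple-comparison letters of the original report are not
  computed; significance is reported as raw p-values with the two-tier
  star convention.
- The published per-day yield-loss slope is reported descriptively only
  (see above).
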