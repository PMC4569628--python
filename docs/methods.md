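# Methods

## Model

Batch-culture biomass is modelled by the logistic law
`dx/dt = k·x·(1 − x/xs)`: growth is first-order in biomass with
self-inhibition proportional to x², which reproduces the lag →
exponential → stationary shape of autotrophic microalgal batch runs
without modelling substrate explicitly. Its closed form is

    x(t) = x0·e^{kt} / (1 − (x0/xs)·(1 − e^{kt})).

Lipid (product) formation follows the two-parameter Luedeking–Piret
law `dp/dt = α·dx/dt + β·x`. Integrating along the logistic trajectory
gives

    P(t) = p0 + α·(x(t) − x0) + β·(xs/k)·ln[1 − (x0/xs)·(1 − e^{kt})].

Both closed forms are implemented in numerically stable variants
(`x0 / (e^{-kt}(1−r) + r)` with `r = x0/xs`, and
`ln D(t) = kt + ln(e^{-kt}(1−r) + r)`), so no intermediate `e^{kt}`
overflows at large `kt`. A coupled numeric simulation (`simulate`) uses
an adaptive Runge–Kutta 2(3) pair — the low-order family conventional
in bioprocess work — at rtol 1e-8 / atol 1e-10, tight enough that
closed-form/ODE agreement to 1e-6 relative is a meaningful test. The
tests additionally arbitrate both closed forms against an independent
high-order integrator (DOP853 at rtol 1e-12), which is what justifies
the exact parenthesization of the logistic denominator and the
logarithmic non-growth term in P(t): each is the unique expression that
solves its differential equation.

Assumptions: a closed, well-mixed batch; no substrate or light
dynamics (nitrogen status enters only as separate fitted conditions);
α, β ≥ 0 and constant over the run; time units are whatever the user's
`k` is expressed in (labelled hours by default) and are never
converted.

## Estimation

Two-step pipeline, mirroring standard practice:

1. **Growth.** `LogisticGrowthModel` fits (x0, k, xs) jointly by
   nonlinear least squares (scipy `curve_fit`, positivity bounds).
   Initial guesses are deterministic and data-driven — x0 from the
   first observation, xs from the maximum, k from the slope of
   ln(biomass) over the first half of the series (zero readings, which
   the truncated noise model can produce at a small inoculum, are
   excluded from the log slope) — so refits of the same data are
   bit-identical. Constant or strictly decreasing biomass raises a
   non-identifiability error rather than returning garbage, as does a
   fit landing at x0 ≥ xs.

2. **Product.** With growth fixed, P(t) − P(t₀) is linear in (α, β)
   with regressors `x(t) − x(t₀)` and `(xs/k)·[ln D(t) − ln D(t₀)]`;
   `LuedekingPiretModel` solves the no-intercept ordinary least squares
   and clips the estimates at zero to respect the model's sign
   convention. A rank check rejects degenerate grids on which the two
   regressors are collinear. Estimating through the *integrated* form
   uses every observation and avoids differentiating noisy data.

A second, independent route to β — `beta_stationary` — divides the mean
finite-difference product slope over the stationary window by xs, since
dp/dt → β·xs once growth stops. The stationary window is the trailing
run of points whose biomass is within 2% (configurable) of the observed
maximum, requiring at least 3 points. This route is deliberately
simple and exposed for cross-checking the joint fit; on long noiseless
runs the two agree within a few percent, the residual gap being the
growth-associated contribution that has not fully decayed at the
window's leading edge (tightening the window tolerance shrinks it).

Diagnostics: R² is 1 − SS_res/SS_tot about the observed mean; the
percent error is the mean over timepoints of |(obs − pred)/obs| × 100,
with zero-valued observations excluded (the relative error is undefined
there) and logged. The Gaden class is assigned from the fitted (α, β)
with a zero-tolerance of 1e-6 in the coefficients' own units: α and β
both effectively zero is an error (no product formation), otherwise
β ≈ 0 → Class I, α ≈ 0 → Class III, both nonzero → Class II. All four
published culture regimes carry strictly positive α and β and classify
as Class II; the α/β ratio is available from the result for readers who
want to argue about how dominant the growth-associated term is.

## Synthetic data

`generate_dataset` evaluates the closed forms on the sampling grid and
adds independent zero-mean Gaussian noise per channel, truncating
negative readings to zero (concentrations cannot be negative). Defaults
emulate the published study conditions: 30 equally spaced samples over
[0, 20] time units; presets carry the published (k, α, β) per condition
(k 0.3786–0.447, α 0.125–0.211, β 0.0006–0.002); x0 = 0.05 g/L,
xs = 2.0 g/L and p0 = 0 are package conventions, chosen to give a full
sigmoid over the grid, because no initial conditions were published.
The default noise scale for robustness tests is 2% of xs, which puts
refit percent errors in the 3–5% range typical of this kind of data.
For the *C. salina* N⁻ condition the published β is typographically
ambiguous (0.002 vs 0.0024); the preset defaults to 0.002 and takes an
override.

What the generator does *not* emulate: heteroscedastic or
multiplicative error, autocorrelated sensor drift, missing samples,
batch-to-batch variability, or any feedback of lipid accumulation on
growth. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated error model, not robustness to every
artefact of real cultivation data.

A statistical subtlety the tests make explicit: truncation at the
p = 0 boundary biases early product observations upward (E[max(ε, 0)] > 0
when the true value is 0), so strict unbiasedness of α̂ is asserted
with the initial product offset away from the boundary; and refitting
the growth parameters from noisy biomass propagates parameter noise
into the product regressors, a plug-in effect that leaves a small
(< 5% here) bias in α̂ for the full pipeline. Both effects are
properties of the error model and the two-step design, not estimator
defects, and both are covered by dedicated tests.

## Numerical choices

- Solver: RK23, rtol 1e-8, atol 1e-10; failures raise with the time
  reached. The grid may start after t = 0; the initial condition is
  always anchored at t = 0.
- Logistic fit: `curve_fit` bounds keep all parameters positive;
  `max_nfev` defaults to 10⁴.
- Product OLS: `numpy.linalg.lstsq` with a rank-tolerance scaled to the
  design's magnitude; α̂, β̂ clipped at 0 after the solve.
- Degenerate inputs: x0 = xs simulates as the constant trajectory
  (product p0 + β·xs·t) but is rejected by fitting; an all-zero product
  series fits α̂ = β̂ = 0 with R² defined as 1 by convention (the
  zero-variance case).
- Serialization: CSV with 17-significant-digit floats and pandas'
  round-trip parser, JSON results with a stable key order, so repeated
  runs are byte-identical.

## Problem sizes

Round-trip and recovery checks use the 30-point default grid; Monte
Carlo bias checks use 200 seeded replicates; closed-form/ODE agreement
is checked over 200 random parameter sets; the stationary-phase β
cross-check uses 90–120 points over 45–60 time units so the culture is
deep into stationary phase. These sizes make the whole suite run in
well under a minute while leaving Monte-Carlo standard errors small
enough for 2-SE bias assertions to bite.

## Known limitations

- Only the logistic growth law is offered; no model selection against
  Gompertz, Baranyi, Monod-type or light-limited alternatives.
- No uncertainty quantification on the estimates (no profile
  likelihood or bootstrap intervals).
- The published rate constants are printed in h⁻¹ while the underlying
  cultivations ran for days; the package treats the time unit as a
  user declaration and does not arbitrate that inconsistency.
- The stationary-window heuristic needs the run to actually reach
  stationary phase; it refuses (with a pointer to the joint fit)
  otherwise.
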