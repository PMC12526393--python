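# Methods

## Tree-level biomass models

Component dry mass (foliage or aboveground woody parts, g) of a young
beech tree is modelled as a power law of stem basal diameter `d0` (mm),
tree height `h` (m), or both:

    BC = b0·d0^b1,    BC = b0·h^b1,    BC = b0·d0^b1·h^b2,

with an additive residual on the original mass scale. Basal diameter is
used rather than breast-height diameter because young trees may be
shorter than 1.3 m; the height-only form exists because height is the
easiest measurement in the youngest stands and connects these models to
mature-stand models.

### Heteroscedasticity weighting

Mass residuals fan out with tree size. The variance is modelled as a
power function of the predictor,

    Var(r_i) = α · x_i^λ,

and fitted from the residual profile: residuals are ordered by the
predictor, grouped in sets of 25, and the ln of each group's sample
variance is regressed on the ln of its mean predictor. The slope is `λ`,
the exponentiated intercept `α`. Weights `w_i = x_i^−λ` then make the
weighted residuals homoscedastic.

The full procedure is two passes. Pass 1: unweighted nonlinear
least-squares fit → residual profile → (α, λ) → weights. Pass 2: weighted
fit with the pass-1 weights → new residual profile → final (α, λ) → final
weights → final weighted fit. The second pass is run exactly once, not
iterated to convergence: one re-estimation already stabilises `λ`, and a
fixed pipeline keeps results reproducible and auditable.

The weighting variable is the model's own size predictor: `d0` for the
diameter and combined forms (the variance law is naturally expressed in
diameter), `h` for the height-only form.

Residual grouping when n is not a multiple of 25: a short final group
with fewer than 13 members is merged into the preceding group, otherwise
kept. A 111-tree sample therefore yields 4 groups (25, 25, 25, 36); tiny
tail groups would otherwise contribute the noisiest variance estimate at
the largest diameters, exactly where the weights matter most.

### Diagnostics

* **Breusch–Pagan.** Squared weight-standardised residuals
  `(r_i·√w_i)²` are regressed on the mean-model predictor(s); the LM
  statistic `n·R²` is referred to a χ² with one degree of freedom per
  predictor (via `statsmodels`). Standardising by the weights makes the
  test answer the question actually at stake: *did the weighting remove
  the heteroscedasticity?* p > 0.05 means no remaining dependence of the
  residual variance on tree size. Constant residuals are handled before
  the auxiliary regression (R² = 0, p = 1).
* **Fit metrics**, all on the weighted scale: `MSE = Σw_i r_i²/n`,
  `RSE = √(Σw_i r_i²/(n−p))` (so `MSE = RSE²·(n−p)/n` identically), and
  AIC from the weighted Gaussian log-likelihood with σ² profiled out
  (`−2ℓ + 2(p+1)`, with the `½Σln w_i` Jacobian term included). Because
  the weights enter the likelihood, AICs are comparable across forms
  fitted to the same trees, as a ranking; their absolute level depends on
  the weighting.
* **Outlier rule.** If a fit fails to converge, response values above the
  99th percentile are removed and the procedure restarts (at most three
  rounds); removals are counted in the results. The rule is applied per
  component being fitted.
* **Degenerate inputs.** Noise-free data give zero group variances; the
  ln-ln variance fit is then impossible and the procedure falls back to
  the unweighted fit with a warning (`λ = 0`, unit weights). An exactly
  collinear `d0`–`h` pair makes the combined form unidentifiable; the
  near-singular normal matrix is flagged with a warning rather than an
  error, since near-collinearity is common in even-aged stands.

### Numerical choices

Nonlinear fits use Levenberg–Marquardt with start values from ln-ln OLS
(always available because masses and predictors are positive), relative
tolerance 1e−8 and a 200-iteration cap. The coefficient covariance is
`(JᵀWJ)⁻¹·s²` with `s²` the weighted residual variance. Confidence bands
for predictions are Monte-Carlo: coefficient vectors drawn from the
multivariate normal with the fitted mean and covariance, the power form
evaluated per draw, and the 2.5th/97.5th percentiles reported. This
captures the curvature of the power form that a first-order delta method
misses; a second-order Taylor expansion would serve the same purpose and
is subsumed by the simulation.

## Stand-level accounting

Per-hectare stock of a plot-year is mean single-tree biomass times the
nominal planting density:

    ws = w_avg · 10⁴/(a·b)   [Mg ha⁻¹],   w_avg = w/N   [Mg],

with spacing `a×b` in metres (1.6 m × 1.6 m ⇒ 3906.25 trees ha⁻¹). The
measured plot area and tree count enter only through `w_avg`; the stock
is therefore invariant to plot size for a fixed tree-size distribution.
This density-normalisation reading is an interpretation: the source
formulation mixes area and spacing symbols ambiguously, but only this
reading reproduces the stated "nearly 4000 trees per hectare"
arithmetic.

NPP accounting assumes complete annual foliage turnover (foliage NPP =
foliage stock = annual leaf litter) and no mortality (woody NPP = plain
difference of consecutive woody stocks over living trees). A negative
woody increment is flagged with a warning, not an error — it indicates a
data problem, not a modelling one.

Annual diameter and height increments are pooled into the age classes
≤5, 6–10 and 11–15 years (interval assigned by its end age; age-16
intervals excluded), averaged per plot, and compared across classes with
a one-way ANOVA on the plot-level values. Classes with fewer than two
plots are excluded from the ANOVA with a warning.

## Stand-age models

Stocks and NPP versus stand age `t` are fitted with `y = b0·t^b1` by
unweighted nonlinear least squares (start values from ln-ln OLS on the
positive values), reporting `R² = 1 − SSE/SST` and `MSE = SSE/n`. Fits
use plot-level points — each subplot contributes one point per year at
its own age — because stocks are computed per subplot. The
natural-regeneration models are packaged constants (published parameter
sets; the underlying raw data are not available for refitting), and the
planted parameter sets are likewise available as reference constants.
The origin comparison tabulates both predictions and their ratio over
ages 5–16 and locates ratio crossovers by bisection on the log-ratio.
Models should not be extrapolated beyond age 16 or outside
moderately fertile Western-Carpathian sites.

## Synthetic data

The generator emulates the two field datasets the analysis consumes.

*Destructive sample*: `d0` uniform on 4–70 mm (the observed range; the
true sampling distribution is unknown, so uniform is a deliberate
choice, giving even leverage across the range), heights
`h = 0.062·d0^0.98` with lognormal noise (σ_ln = 0.1), masses
`b0·d0^b1 + ε` with `ε ~ N(0, α·d0^λ)` and negative draws redrawn.
Default allometric coefficients are the published estimates (foliage
0.00878/2.63892, woody 0.01762/2.93664) and λ = 1.85, matching the
fitted variance exponents (1.76–1.98). The additive-Gaussian noise with
power-law variance is chosen deliberately — it is exactly the structure
the weighting procedure assumes, so parameter-recovery tests are
meaningful. The noise scale α = 0.001 g²·mm⁻λ is bounded by the smallest
trees: foliage mass at 4 mm is ~0.34 g, and α must keep the noise sd
well below that or the redraw truncation distorts the very variance law
being estimated; the default keeps redraws below ~0.2% of draws at the
minimum diameter.

*Remeasurement series*: 15 sites × 3 plots × 5 consecutive annual
campaigns (default start ages 2–12, so stand ages span 2–16), ~30 trees
per plot, no mortality. Plot-mean diameter follows `1.5·age^1.377` mm;
each tree keeps a persistent lognormal deviation (σ_ln = 0.15) from the
plot mean, so individual series are monotone. The growth exponent is
chosen so that (a) plot-mean `d0` at age 15 falls in the observed
40–70 mm band and (b) the implied woody-stock age exponent
`b1_wood · 1.377 = 4.044` equals the published planted woody-stock
exponent, making end-to-end exponent recovery a meaningful check.

What the generator does **not** emulate: mortality, browsing,
competition, spatial structure, measurement error on `d0`/`h`, site or
year effects, and the real (unknown) diameter distribution of the
destructive sample. Passing recovery tests therefore demonstrates the
estimation machinery is correct under the assumed error structure, not
that the published models are correct for real stands. The synthetic
stands' absolute stock levels are also lower than the published ones
(~14 vs ~48 Mg ha⁻¹ woody at age 15): the published tree models
evaluated at a 40–70 mm age-15 mean diameter cannot reach the published
stand stocks at 3906 trees ha⁻¹, so the generator reproduces the growth
*exponents* and realistic diameters rather than the absolute stock
levels, which depend on the real data.

## Problem sizes

Default simulations mirror the study design: 111 sample trees, 45 plot
series over 5 years. Recovery experiments use 100 replicates of 500
trees for coefficient/exponent recovery and Breusch–Pagan calibration,
60 replicates of 200 trees for interval coverage, and a single
full-pipeline run (500 trees, 45 plots) for end-to-end exponent
recovery; these sizes give stable medians and proportions while keeping
the suite fast.

## Units

`d0` mm, `h` m, masses g, stocks Mg ha⁻¹, NPP Mg ha⁻¹ yr⁻¹, age yr.
Conversions (g → Mg, spacing → density) live in the stand-accounting
layer, never in the fitting core.
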