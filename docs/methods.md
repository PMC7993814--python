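# Methods

## The model

Anchoring-vignette surveys collect, for each respondent *i*, one ordinal
self-assessment *y<sub>i</sub>* ∈ {1..K} and ratings
*V<sub>ij</sub>* ∈ {1..K} of *J* hypothetical vignettes, together with
covariates. The hierarchical ordered probit (HOPIT) family models

- a latent condition *y\*<sub>i</sub> = β′x<sub>i</sub> + ε<sub>i</sub>*,
  ε<sub>i</sub> ~ N(0,1) (outcome intercept fixed at 0 and error sd at 1
  for identification);
- respondent-specific cut-points
  τ<sub>i</sub><sup>1</sup> = γ₁′z<sub>i</sub> + σ<sub>u</sub>u<sub>i</sub>,
  τ<sub>i</sub><sup>k</sup> = τ<sub>i</sub><sup>k−1</sup> + exp(γ<sub>k</sub>′z<sub>i</sub>),
  u<sub>i</sub> ~ N(0,1), so that reporting scales may shift with the same
  traits that drive the outcome (differential item functioning);
- self-reports and vignette ratings both classified through the
  respondent's own cut-points (response consistency), with the half-open
  convention *y = k ⇔ τ<sup>k−1</sup> ≤ y\* < τ<sup>k</sup>*;
- vignette perceptions *V\*<sub>ij</sub> = θ<sub>j</sub> + s<sub>ij</sub>v<sub>ij</sub>*,
  v<sub>ij</sub> ~ N(0,1).

The standard HOPIT assumes *s<sub>ij</sub> = σ<sub>v</sub>* (vignette
equivalence). The extended model replaces this with

  s<sub>ij</sub> = σ<sub>v</sub> · exp(α (y\*<sub>i</sub> − θ<sub>j</sub>)²),

so a respondent perceives vignettes far from their own latent condition
less precisely (the psychological-distance mechanism). α = 0 recovers
the standard model, which makes a one-degree-of-freedom likelihood-ratio
test of vignette equivalence available:
LR = −2(L<sub>standard</sub> − L<sub>extended</sub>) ~ χ²(1).

A per-pair noise summary integrates the unobserved ε out in closed form:

  E<sub>ε</sub>[σ<sub>v</sub> exp(α(β′x + ε − θ<sub>j</sub>)²)]
  = σ<sub>v</sub> (1 − 2α)<sup>−1/2</sup> exp(α c²/(1 − 2α)),  c = β′x − θ<sub>j</sub>,

finite only for α < 1/2 (the α upper bound of 0.49 in the optimizer
keeps it finite). The closed form is validated against adaptive
quadrature in the test suite.

## Likelihood and integration

The individual likelihood is a double integral over (ε, u) of the
self-report indicator times the product of conditional vignette cell
probabilities. It is simulated with a 2-D Halton sequence: dimension 1
(base 2) is mapped through Φ⁻¹ to the cut-point shift u; dimension 2
(base 3) drives an importance sampler for ε. Given u, ε is drawn by
inverse-CDF from the normal truncated to the interval where the
self-report indicator equals 1, and the interval's normal mass enters
as the weight. The integrand is then smooth (no indicator
discontinuity), and the estimator is unbiased for the inner integral —
verified against dense Gauss–Hermite × Gauss–Legendre tensor
integration and against total-probability conservation over all
K^(J+1) response patterns.

Numerical choices:

- **Halton skip/leap.** The first 1000 points are discarded and the
  sequence is thinned. A thinning interval must be coprime with every
  Halton base: an even leap collides with base 2 and collapses
  dimension 1 into a sub-interval of (0,1) (we measured a mean of
  Φ⁻¹(u) ≈ 1.27 rather than 0 with leap 100, which biased σ̂_u upward
  about two-fold before the default was corrected). The default leap
  is therefore 101; both skip and leap are configurable.
- **Draw count.** R = 200 by default for one-off fits; the Monte Carlo
  harness and the acceptance script use R = 32–48, validated against
  R = 256 reference fits on the reference design (coefficient drift
  well below one tenth of the sampling error) and keeping a full
  standard+extended fit pair at N = 1000 within a couple of minutes on
  one core.
- **Tail stability.** Normal-interval masses are computed by the
  survival-function form whenever the interval lies mostly above zero,
  avoiding the catastrophic cancellation of Φ(b) − Φ(a) near 1; the
  per-respondent likelihood is floored at 1e−300 so optimizer
  excursions never produce −∞.
- **Two code paths.** A readable vectorised numpy implementation is the
  reference; a numba kernel (with an Acklam-plus-Halley inverse normal
  CDF, accurate to near machine precision) is used inside optimization.
  The two agree to ~1e−12 relative and are tested against each other.

## Estimation

Maximum simulated likelihood with `scipy.optimize.minimize`
(L-BFGS-B, numeric gradients) on an unconstrained re-parameterisation:
σ<sub>u</sub>, σ<sub>v</sub> on the log scale, α box-bounded in
(−0.25, 0.49]. Tolerances: relative function tolerance 3e−8 for harness
runs (1e−9 for one-off fits), gradient tolerance 1e−5, at most 400–500
iterations. The same `QmcDraws` object must be shared by both fits of an
LR comparison so integration noise cancels from the statistic; the fit
results carry a data fingerprint and the draw spec, and `lr_test`
refuses mismatched pairs.

Initialization is deterministic: an ordered probit with constant
cut-points seeds β and the threshold intercepts; a pooled ordered
probit of vignette ratings on the cut-point covariates (with vignette
dummies) supplies the sign and rough scale of the threshold slopes —
necessary because when cut-point shifts track the outcome index the
self-report alone carries no information about β; vignette locations
start at the pooled category barycentre on the threshold scale;
σ<sub>u</sub> = σ<sub>v</sub> = 0.5, α = 0. The extended fit warm-starts
from the standard optimum.

Standard errors are observed-information: central-difference Hessian of
−L at the optimum on the transformed scale, inverted (eigenvalue-clipped
if not positive definite, with a warning) and delta-mapped to the
natural scale; t-statistics are estimate/SE with 0.1/0.05/0.01
significance stars. AIC = 2k − 2L with k counting every free parameter
of the variant (β: p; γ: (K−1)·q; θ: J; σ<sub>u</sub>, σ<sub>v</sub>;
plus α for the extended model).

## The synthetic-data generator

The generator emulates a cross-country vignette survey with a 3-point
scale:

| quantity | default | basis |
|---|---|---|
| K | 3 | stated design |
| covariates | 5 × U(0,1), 5 × Bernoulli(½) | stated design (success probability not stated; ½ is the symmetric choice for sex-like dummies) |
| β | (+1, −1, …, −1) | stated design |
| cut-point equations | same slopes as β, intercepts 0 | literal reading of "cut-point parameters equal to the outcome equation's"; makes reporting heterogeneity track the outcome index |
| J | 1, 3 or 5 | stated design |
| α | 0, 0.02, 0.05 | stated design |
| N | 1000 or 2000 | stated design |
| σ<sub>u</sub>, σ<sub>v</sub> | 0.3, 0.9 | calibrated to the empirical estimates (≈0.31, ≈0.93) |
| θ | equally spaced on [1, 5] | see below |

**Vignette locations.** The design leaves θ unstated. Two facts pin the
choice down. First, under the shared-slope cut-point design the
self-report is marginally independent of x (τ¹ − β′x has no covariate
signal), so *all* information about β flows through the vignette
ratings. Second, severity-vignette batteries in real surveys describe
conditions mostly worse than the average respondent's, i.e. they sit to
one side of the latent-index distribution (here mean 0, sd ≈ 1.29) and
span several sd. A one-sided battery is also what makes the
homoskedastic model genuinely misspecified: perception noise then grows
monotonically as the respondent's condition improves, the standard fit
absorbs the average inflation into σ̂<sub>v</sub> (we observe
σ̂<sub>v</sub> ≈ 2.5 at α = 0.05 against a true 0.9), the vignette
signal is correspondingly down-weighted, and β̂ shrinks and grows noisy
— reproducing the reference misfit pattern (order-of-magnitude MSE
inflation, degraded predicted-outcome correlation). A symmetric,
centrally-placed battery was tried first and does *not* produce that
pattern: the distortion averages out and the standard model stays
nearly unbiased. Locations equally spaced on [1, 5] (single vignette:
3) were fixed once on this reasoning and not revisited per run.

**Latent-index correlations.** The fit measures correlate the fitted
latent index β̂′x with the simulated latent outcome y\* = β′x + ε
(Pearson, and tie-free Kendall; for categorical predictions the
package's `dependence` uses tau-b). Under the reference design
sd(β′x) = √(5/12 + 5/4) ≈ 1.291 and sd(y\*) ≈ 1.633, so a perfectly
estimated model attains ρ = √0.625 ≈ 0.791 and Kendall
τ ≈ (2/π)arcsin(0.791) ≈ 0.581; the observed values under the correct
model match these ceilings, and shortfalls below them measure
estimation error. A modal-category predictor is deliberately *not* used
for these measures: under the shared-slope design every respondent's
marginal category distribution is identical (category 1 has probability
½ for everyone), so the modal prediction is constant and its
correlation undefined. Modal-category prediction remains available (and
sensible) for real data via the estimators' `predict`.

**Per-replication seeds** are spawned from the master seed via
`numpy.random.SeedSequence` and logged in the report for replay.

## What the generator does and does not emulate

It reproduces the probabilistic structure of the reference design —
ordinal scales, cut-point shifts driven by the same traits as the
outcome, one-sided severity vignettes, distance-dependent perception
noise. It does not emulate missing data, survey weights, panel
structure, K = 5 scales, vignette-specific baseline variances, or
non-normal disturbances. Passing tests therefore demonstrate correct
recovery of the model's own generating process and the documented
misfit of the homoskedastic model under heteroskedastic perceptions —
not robustness to the further complications of real survey data.

## Problem sizes

The Monte Carlo harness defaults to 100 replications per grid cell; the
test suite and the acceptance script run reduced-scale versions (2–6
replications per cell, R = 32–48, N = 1000 except where a recovery
check names N = 2000) chosen so a full run completes in tens of minutes on one
core. Reduced scale widens Monte Carlo error on the aggregated
measures; the correlation and rejection-rate measures are stable at
these scales (per-replication spreads of ~0.01 and 0 respectively),
while per-parameter MSEs of the *misspecified* model are the noisiest
quantities and are interpreted as order-of-magnitude signatures, which
is also how the reference tables present them.

## Known limitations

- The misspecified standard fit's MSE depends strongly on the unstated
  θ, σ calibration; we reproduce its direction and order of magnitude,
  not digit-level values.
- Numeric (finite-difference) gradients make fits O(40×) the cost of a
  likelihood evaluation per iteration; analytic scores are out of
  scope.
- Observed-information SEs assume an interior optimum; α̂ estimated at
  its bound would invalidate them (not observed in practice at the
  calibrated α values).
- The importance sampler conditions on the self-report interval; for
  respondents whose interval mass is below ~1e−300 the likelihood floor
  binds and the fit logs a warning.
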