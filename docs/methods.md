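# Methods

This note documents the statistical models in `pyrograss`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## Fire return intervals from window-censored burn histories

A location's burn history is a point pattern inside a fixed observation
window (default April 2000 – January 2020, i.e. 19.83 yr, expressed in
fractional years with day-of-year/365.25). Successive fires give complete
intervals; the window ends give two open tails per burnt pixel. We model
intervals as i.i.d. Weibull(b, c) with density
f(t) = (c/b)(t/b)^(c−1) exp(−(t/b)^c) and survival S(t) = exp(−(t/b)^c),
and summarize frequency by the median, FRI = b(ln 2)^(1/c).

The two open tails are not the same object:

- the **trailing tail** (last fire → window end) is a genuine right-censored
  draw from the interval distribution and contributes log S(t);
- the **leading tail** (window start → first fire) is the *forward
  recurrence time* of the renewal process. Its density under stationarity is
  S(t)/μ with μ = bΓ(1+1/c), so it contributes log S(t) − log μ;
- pooling only pixels that burnt at least once inside the window selects
  pixels with shorter-than-typical intervals, so the likelihood further
  conditions on that event, whose probability has the closed form
  P(≥1 fire) = γ̃(1/c, (L/b)^c) (regularized lower incomplete gamma) for a
  window of length L.

Treating both tails as ordinary right-censored observations — the simpler
survival-analysis treatment, available via
`CensoredWeibull(stationary_tails=False)` — overestimates the median FRI by
25–90% in our renewal simulations once the true FRI approaches the window
length, because the interval straddling the window start is length-biased.
With the full stationary-renewal likelihood the estimator recovers the true
median within ~5% across b ∈ {3, 8, 20} yr and c ∈ {0.8, 1.2, 2.0} at a few
thousand pooled intervals; this corrected likelihood is therefore the
default.

Numerics: the likelihood is maximized in (log b, log c) with L-BFGS-B,
analytic gradients (the conditioning term differentiated by central
differences), three starts (a moment-based start plus seeded perturbations),
and exponents clipped at e^200 so the surface stays finite and sloped far
from the optimum. Convergence is judged by the score norm at the best
solution. Zero-variance interval sets drive c to its upper bound (the MLE is
c → ∞); the bounded maximum is reported with `shape_at_bound_` set, since
the median is then effectively the scale. Fits with no complete interval are
flagged non-converged rather than extrapolated. Fitted medians outside
[1, 100] yr are treated as unresolved by a 20-yr window and dropped from
frequency analyses.

## Fire-prone classification

The proportion of a species' records falling in burnt pixels is thresholded
to decide whether fire is a recurrent selective pressure. The threshold can
be estimated by a continuous two-segment (break-point) regression on the
species-count curve (counts per proportion bin, default width 0.02): the
hinge is located by exhaustive search over interior x values plus bounded
local refinement of the RSS, with collinear data flagged as degenerate. The
pipeline default is a fixed threshold of 0.26 (the value this procedure
yields on global grass occurrence data); passing
`fire_prone_threshold=None` re-estimates it from the data at hand.

## Fire intensity

Fire radiative power detections below 50% confidence are discarded; each
species is summarized by the 0.95 quantile (linear interpolation between
order statistics at 1+(n−1)q) of the FRP values joined to its records by
shared location. The upper quantile damps the low bias from night-time and
partial detections; r² diagnostics of q95 against the species mean and
median are reported.

## Foley's drought index

FDI(m) = (Σ rainfall over the 36 months ending at and including m − 3·MAP)
/ MAP, with MAP the mean annual precipitation over a fixed baseline
(1901–2003). The window is rolling, not calendar-blocked; the alternative
(calendar 3-yr blocks) would coarsen but not re-scale the index. The index
is dimensionless, 0 at climatology, −1 after a completely rainless year at
an otherwise-average site, and invariant to rescaling the whole series.
Months whose trailing window crosses a data gap are undefined. A species'
drought exposure is the flat average of FDI over its record × month pool
(each record contributes its location's full series, so duplicated locations
count once per record).

## Phylogenetic logistic regression

Strategy y ∈ {0, 1} (0 = seeder, 1 = resprouter) is modelled marginally as
logit P(y_i = 1) = x_i'β, with residual dependence between tips i and j
decaying with their divergence time t_ij as corr = exp(−2α t_ij / T)
(T = tree height, α ≥ 0). β solves Firth-type bias-reduced generalized
estimating equations, U(β) = D'V⁻¹(y − μ) + a(β), where V = A^{1/2}RA^{1/2},
A = diag(μ(1−μ)), and a(β) generalizes Firth's hat-value adjustment using
the working information D'V⁻¹D; with R = I this reduces *algebraically* to
Firth-penalized logistic regression, so finite estimates survive complete
separation. α is estimated by least-squares matching of Pearson-residual
cross-products to the correlation curve, alternating with the β solve; full
independence competes as a candidate. Two guards matter in practice:

- the working correlation is capped at 0.95 off-diagonal, keeping V
  invertible when tips are nearly twins;
- on a star phylogeny all divergence times are equal, the decay rate is
  unidentifiable and there is no shared history to model, so the estimator
  collapses structurally to the independence (Firth) fit.

A Gaussian pseudo-likelihood profile for α was rejected: its −½log|R| term
diverges as R approaches singularity and selected degenerate fits.

Confidence intervals come from a parametric bootstrap: strategy vectors are
re-simulated from the fitted means through a Gaussian copula with the fitted
correlation, β is re-estimated per replicate with α held at its point
estimate (a tractability choice; α re-estimation roughly doubles cost and
moved the intervals negligibly in our checks), and percentile intervals are
taken over converged replicates (default 1000; 10,000 is configurable).
Failed replicates are counted and >20% triggers a warning. On null-effect
simulations the 95% intervals cover zero at the nominal rate within
Monte-Carlo error.

The binary-trait generator uses the same structure: y_i = 1{Φ(z_i) < μ_i}
with z ~ MVN(0, R(α)), which has *exactly* the logistic marginal means and
α-decaying dependence, and α → ∞ gives independent tips. Note that at very
small α this mechanism makes near-twin tips deterministic copies regardless
of their predictor contrast — information the fitting model then correctly
discounts; the benchmark default α = 3 ("moderate" signal: sister-pair
latent correlation ≈ 0.7, deep pairs ≈ 0) avoids that degenerate regime.

Interactions between the two fire/drought predictors are tested on the
centred product (near-orthogonal to the main effects) and retained at
p < 0.05, matching the analysis convention of including only significant
interactions.

## PGLS and leaf-trait PCA

PGLS assumes Brownian residual covariance proportional to shared
root-to-tip branch length (λ = 1, no transformation — estimating λ is a
known alternative we did not take, as the downstream use is diagnostic).
Estimation whitens by the Cholesky factor of the covariance; F, r² and p
are computed in the whitened space against the GLS intercept-only model. On
a star phylogeny this is ordinary least squares.

The leaf-trait PCA standardizes SLA, leaf N and C:N (population SD) and
fixes orientation: leaf N loads positively on dimension 1, SLA positively
on dimension 2. Variance fractions are reported for all axes and sum to 1.

## Synthetic benchmark

`make_benchmark_bundle` generates, per seed: a pure-birth phylogeny (tips
extended by the expected time to the next speciation, so near-twin tips are
distinct and the Brownian covariance is invertible); species fire regimes
with median FRI lognormal around 7 yr (log-SD 0.8, spanning roughly 1–50 yr
as in real fire-prone floras) and shape c around 1.3; 60 renewal-process
pixels per species inside the 2000–2020 window with a burn-in of five mean
intervals for near-stationarity; 50 climate cells with seasonal rainfall
from 1901, lognormal noise, and two 18-month drought episodes of
cell-specific depth; FRP detections lognormal per species with median
85·(FRI/7)^0.4 MW, reproducing the negative frequency–intensity
association; occurrence tables with injected QC noise (duplicates,
low-precision coordinates, pre-1980 dates, high-HII records, each at rate
0.05); and strategies drawn from the logistic trait model with
β = (0.37, 0.84, 1.3) on (intercept, log FRI, FDI) — the coefficient scale
field estimates of this model take on real grass data — and α = 3.

What the benchmark does *not* emulate: spatially autocorrelated fire
regimes across neighbouring pixels, measurement error in burn dates (MODIS
dates are approximate), taxonomic noise, within-species trait variation,
and climate–fire feedbacks. Passing tests therefore demonstrate that the
estimators recover the generating process under the stated model
assumptions at realistic sizes — not that those assumptions hold for any
particular satellite product.

Problem sizes used in the shipped checks (chosen to exercise each method at
study-relevant scale): 80 species × 60 pixels per pipeline run, 100 seeded
runs for sign recovery; ≥2,000 pooled intervals per fire-regime cell for
FRI recovery; 150-tip trees × 60 replicates for slope recovery; 400
null-effect replicates × 100 bootstrap draws for CI coverage.

## Degenerate inputs and tie-breaks

Empty occurrence tables warn and pass through; unparseable dates are
dropped and counted. Spatial thinning uses a local equal-area grid
(longitude scaled by cos latitude) with cell area 10 km², seeded uniform
subsampling, and is idempotent. Constant predictors, constant traits,
missing values in model matrices, singular designs, and out-of-tree species
raise informative errors rather than silently degrading. All generators and
model fits are deterministic given their seeds.
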