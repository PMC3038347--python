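# Methods

This note documents the statistical models implemented in `occurange`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Grid conventions

All stages share one planar grid of square cells (default 2 × 2 km, the
scale of a large-ungulate home range and a practical survey unit). Cells
are half-open squares `[x0, x0+s) × [y0, y0+s)` and rows index south to
north; every point-in-cell test uses this convention, which removes any
ambiguity for points on cell edges. ESRI ASCII grids (which store rows
north-first) are flipped on read/write. A cell with nodata in any raster
layer is masked in every analysis. Incidental records with stated
location precision of 1 km or worse are dropped, because they cannot be
placed in a single 2-km cell.

Covariate screening removes one member of every pair with Pearson
|r| > 0.7 over unmasked cells. The member dropped is the one with the
larger mean absolute correlation to the remaining covariates, ties
keeping the alphabetically first name — the rule is a repository
convention chosen to make the filter deterministic; any single-member
removal satisfies the pairwise bound. Standardization uses the sample
(n−1) standard deviation, and the constants are stored so prediction
grids are transformed with the training means and sds (never
re-centered).

## Presence-only model

The maximum-entropy model places a Gibbs distribution
`q(x) ∝ exp(λ·f(x))` over an evaluation set consisting of a uniform
background sample (default 10 000 cells, drawn without replacement;
presence cells may also be drawn) together with the presence cells.
Features are linear and quadratic transforms of the standardized
covariates — no hinge, product or threshold features. The weights
maximize

    J(λ) = mean_p[λ·f(x_p)] − ln Z(λ) − Σ_j reg_j |λ_j|,

with per-feature penalty `reg_j = m^(−1/2) · sd_j(background)` scaled by
a user multiplier. The problem is concave; it is solved by L-BFGS-B on
the positive/negative split λ = u − v (u, v ≥ 0), which makes the
penalty smooth and keeps the iterate objective monotone. Correctness is
defined against a brute-force grid maximization of the identical
objective (tested to 1e-3 on small instances), not against any specific
optimizer trajectory.

The habitat suitability index is the logistic output
`h = e^H q / (1 + e^H q)` with `H` the entropy of the fitted
distribution over the evaluation set, so the uniform model scores
exactly 0.5 everywhere. The training gain is

    gain = mean_p[ln q(x_p)] + ln N_eval − Σ_j reg_j|λ_j|,

zero for the uniform model; `exp(gain)` (before penalty) is the ratio of
the geometric-mean presence likelihood to that of a random cell.
Normalization uses the full evaluation set rather than the background
alone so that both identities hold exactly.

Variable contributions are permutation importances: the mean drop in
gain over 10 permutations of a covariate's values (its linear and
quadratic features moving together), clipped at zero and normalized to
sum to 100. This is a documented approximation to path-based
contribution accounting, which depends on a particular optimizer
trajectory and is not reproducible from the model definition. The
jackknife refits the model 2K + 1 times (each covariate alone, each
omitted, plus the full model).

AUC uses the Mann–Whitney rank formulation with ties counted one half;
it is exact (1.0) under perfect separation and invariant to strictly
monotone transforms of the scores.

## Survey design

The weighted stratum implements the literal "retained with probability
equal to the suitability index": propose a uniformly random unselected
cell, accept with probability HSI, repeat until 60 cells are retained
(a proposal cap of 10^6 guards against degenerate maps). The marginal
inclusion probability is therefore proportional to HSI. The 20
simple-random cells are drawn without replacement from the cells not
already selected, so no cell is surveyed twice. Every cell receives 3
pellet transects and 1 sign survey; a simple random 40 of the 80 cells
receive 2 cameras. All counts are configurable.

## Occupancy model

State-space formulation: `z_i ~ Bernoulli(ψ_i)` with
`logit ψ_i = α + x_i'β`, and replicate j of method m at site i observed
as `Y ~ Bernoulli(z_i p_m)`. An unoccupied site yields Y = 0 with
probability one; sites lacking a method (no cameras) simply contribute
no replicates for it. Detection probabilities are method-level constants
(no detection covariates), and sites are conditionally independent given
covariates — no spatial autocorrelation or multi-season dynamics.

Priors: Normal(0, variance 100) on α and each β — read as a vague prior
on logit-scale coefficients (the precision-100 reading would be
absurdly informative) — and Beta(1, 1) on each `p_m`.

The sampler composes conjugate Gibbs draws with Metropolis steps:

- `z_i`: pinned at 1 where any detection occurred; otherwise drawn from
  `ψ q / (ψ q + 1 − ψ)` with `q = Π_m (1 − p_m)^{k_mi}`.
- `p_m`: `Beta(1 + detections, 1 + misses)` counted over occupied sites
  only.
- `(α, β)`: one random-walk Metropolis update per coefficient against
  the conditional posterior `Π ψ^z (1−ψ)^{1−z} ×` prior.

Proposal scales start at 0.5 and are multiplicatively adapted every 50
iterations toward a 20–50% acceptance rate **during burn-in only**, so
the retained chain is a time-homogeneous Markov chain. Chains start
overdispersed (coefficients ~ Normal(0, 1.5²), p ~ Uniform(0.1, 0.9)).
Defaults are 3 chains × (1000 burn-in + 20 000 retained) = 60 000
combined draws. Convergence is monitored by the split-chain potential
scale reduction factor with a warning (not an error) above 1.1. The
sampler is validated two ways: against dense-grid quadrature of the
exact posterior on 2-site instances (KS < 0.05 per margin) and by
parameter recovery and interval coverage on simulated data.

Posterior prediction maps each draw's `invlogit(α + x'β)` over the grid
and averages over draws (evenly thinned to at most 2000 for the
cell-wise mean and sd; thinning error is far below posterior sd at that
count).

## Model selection and averaging

The deviance entering DIC marginalizes the latent states:
`D(θ) = −2 Σ_i ln[ψ_i Π p^Y(1−p)^{1−Y} + (1−ψ_i) I(all Y=0)]`, with
model focus (α, β, p). `pD = D̄ − D(θ̄)` evaluates `D` at posterior
means (coefficients on the identity scale, p on the probability scale).
Samplers that condition on z (classic BUGS-style DIC) report different
absolute values; rankings, not absolute DICs, are this module's
contract, because the marginal deviance is well-defined and exactly
reproducible from the draws.

The candidate search runs all singletons and pairs, ranks covariates by
their best stage-one DIC, and takes all 3- and 4-subsets of the top 7 —
with 12 covariates, 78 + 70 = 148 candidates. Weights are
`exp(−Δ/2)` normalized; the averaging set is the smallest weight-sorted
prefix reaching cumulative weight 0.9 (ties broken by fewer covariates,
then input order). Averaged estimates use renormalized weights with
absent coefficients contributing 0 (the shrinkage convention), the
unconditional SD `Σ w √(var + (θ̂ − θ̄)²)`, and importance as the summed
weight of models containing the coefficient. The candidate sweep
defaults to reduced single-chain settings (500 + 2000 iterations per
model) because it only needs DIC rankings; the full 3 × 20 000 settings
for 148 models are a cluster-scale computation, and the reduction is
configurable and recorded in the run manifest.

Maps from the presence-only and occupancy models live on different
scales, so they are compared by ranks: Spearman correlation over
unmasked cells (average ranks for ties) and a decile-difference grid
(deciles 1–10 assigned by rank).

## Range delineation

The threshold on the occupancy surface is the largest value of a
1001-point grid whose false-negative rate over presence cells is at most
0.05 — i.e. maximal specificity subject to the sensitivity constraint;
since FNR is a non-decreasing step function of the threshold the
admissible set is a prefix and the rule is well-defined. Presence
"truth" at this stage is the pooled presence cells (incidental sightings
plus surveyed cells with any detection); non-presence cells are
pseudo-absences, so the reported FPR is a commission-error analogue, not
a true false-positive rate.

Kernel smoothing uses a bivariate Gaussian product kernel with a
diagonal bandwidth matrix, each axis bandwidth from the Sheather–Jones
solve-the-equation plug-in: two pilot bandwidths (1.24 and 1.23 ×
min(sd, IQR/1.349) × n^(−1/7), n^(−1/9)) estimate the curvature
functionals through binned pairwise sums (1000 distance bins, the same
approximation the classic reference implementation uses), and the fixed
point `h = [R(K)/(n S_D(α₂(h)))]^{1/5}` is solved by bracketed root
finding with the bracket widened up to ten times; if no root is found
Silverman's rule is the documented fallback. The implementation agrees
with the reference R implementation within 3% and with the asymptotic
Gaussian-reference bandwidth within 15% at n = 10 000.

The current-range contour is a density super-level set through point
densities: each pooled presence takes its cell's density, and the level
is the `ceil(0.995 n)`-th largest, so at least 99.5% of points fall
inside (ties fall inside). Current range = suitable ∧ density ≥ level;
potential range = suitable ∧ density < level; areas are exact integer
multiples of the cell area. The published workflow additionally
moderated the contour with historical range information — a subjective,
unreproducible step deliberately excluded here.

## Synthetic landscapes

The generator produces what the analysis assumes and nothing more:
covariates are independent Gaussian random fields (white noise convolved
with an isotropic Gaussian kernel, scale 5 cells by default, then
standardized); occupancy truth is `ψ = invlogit(α + Xβ)` with an
independent Bernoulli state per cell; incidental sightings are drawn
with replacement from occupied cells with weight
`exp(bias_strength × covariate)` (an explicit stand-in for
observer-effort bias; zero strength is exactly uniform), uniform
positions within the cell and sub-km stated precision; survey outcomes
are independent Bernoulli(z·p_m) per replicate.

Default scenario: 100 × 100 grid of 2-km cells, 3 covariates, α = 1.0,
β = (2.0, −1.5, 0.0) — one strong positive, one moderate negative and
one null effect — and detection probabilities (0.362, 0.746, 0.302) for
pellet transects, sign surveys and cameras, realistic field values for
a large cryptic ungulate surveyed by these methods. Deliberately **not**
emulated: animal movement and home-range structure (occupancy is
cell-level i.i.d. given covariates), pellet decay and plot-level detail
within transects (transect-level Bernoulli only), spatial correlation in
detection, and temporal dynamics. Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to the violations real data exhibit (except where the
effort-bias knob is turned deliberately).

## Problem sizes and seeds

Tests and the acceptance script run at desk scale by choice: parameter
recovery uses 800 survey sites at the full 3 × 20 000 chain settings;
the tiny-instance quadrature check uses 2 sites on a 241 × 241 × 200
grid; the 148-model sweep runs on an 80-cell survey with reduced
per-model chains; coverage checks use 60 replicate datasets of 200
sites. Every random quantity flows from an explicit seed through
`numpy.random.SeedSequence` fan-out (the pipeline derives one child per
stage from the master seed), so reruns are byte-identical.

## Known limitations

- Absolute DIC values differ from latent-state-conditioned samplers (see
  above); only rankings and weights are comparable across
  implementations.
- The maxent module matches the stated objective, not any specific
  legacy software's numeric output (no feature clamping, no cumulative
  output format).
- Rasters must share one planar grid; there is no CRS handling or
  reprojection.
- The rejection-sampling survey design can be slow when suitability is
  near zero almost everywhere (it is guarded, not optimized, for that
  regime).
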