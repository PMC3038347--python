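# occurange

Estimating the **current** and **potential** distributions of an
established invasive species, for ecologists and invasive-species
managers who have incidental sightings (presence-only records), the
capacity to run designed field surveys, or both.

The workflow chains six stages on one planar grid of square cells:

1. **Presence-only habitat suitability (maxent).** Incidental sightings
   binned to cells plus gridded biophysical covariates fit a
   maximum-entropy model: a Gibbs distribution
   `q(x) ∝ exp(λ·f(x))` over a background sample, with linear and
   quadratic features of the standardized covariates and an
   L1-regularized likelihood. The habitat suitability index (HSI) uses
   the logistic output `h = e^H q / (1 + e^H q)`, with `H` the entropy of
   the fitted distribution. Performance is summarized by the training
   gain, AUC, and fractional predicted area over a threshold sweep.
2. **Suitability-stratified survey design.** Survey cells are proposed
   uniformly at random and retained with probability equal to their HSI
   (60 cells by default), plus a simple-random stratum (20 cells); every
   cell receives 3 faecal-pellet transects and a sign survey, and a
   random half receive 2 camera traps.
3. **Bayesian multi-method occupancy model.** A state-space model
   separates the latent occupancy state `z_i ~ Bernoulli(ψ_i)`,
   `logit(ψ_i) = α + x_i'β`, from imperfect observation
   `Y_ijm ~ Bernoulli(z_i · p_m)` with method-specific detection
   probabilities `p_m`. Priors are Normal(0, 100) on coefficients and
   Beta(1, 1) on each `p_m`; fitting is by Gibbs-within-Metropolis MCMC
   (3 chains × 20 000 post-burn-in draws by default). The composite
   detection probability over k replicates is `p* = 1 − Π(1 − p_j)`.
4. **DIC model selection and averaging.** Candidates are every covariate
   alone and in pairs, then all 3- and 4-way combinations of the
   best-performing shortlist; DIC weights `w_i ∝ exp(−Δ_i/2)` are summed
   largest-first and the prefix reaching cumulative weight 0.9 is
   averaged (absent coefficients enter as 0; the reported SD is the
   unconditional estimator; importance is the summed weight of models
   containing a coefficient).
5. **Suitable habitat.** The model-averaged occupancy surface is
   thresholded at the largest value whose false-negative (omission) rate
   over presence cells is at most 0.05.
6. **Current vs potential range.** A bivariate Gaussian kernel density
   of the pooled presences (incidental + survey detections), with
   Sheather–Jones solve-the-equation bandwidths per axis, is cut at the
   level that keeps 99.5% of the presence points; suitable cells inside
   that contour are the current (occupied) range, the rest the potential
   (unoccupied) range — the priority area for incursion surveillance.

No field data ship with the package: a first-class synthetic-landscape
module generates smooth covariate fields, a known occupancy truth,
effort-biased sightings and multi-method survey outcomes, so the whole
pipeline is testable end to end against known truth.

## Worked example

```python
import numpy as np
from occurange import (generate_covariates, generate_truth,
                       simulate_incidental, bin_to_cells, fit_maxent,
                       predict_hsi, training_gain, select_cells,
                       assign_methods, simulate_surveys,
                       OccupancyModelSpec, run_mcmc, composite_detection)
from occurange.maxent import roc_summary
from occurange.synthetic import DEFAULT_SCENARIO

# a 100x100 landscape of 2-km cells with three smooth covariates
grid = generate_covariates(100, 100, 3, smoothness=5, seed=1)
truth = generate_truth(grid, {"cov1": 2.0, "cov2": -1.5, "cov3": 0.0},
                       DEFAULT_SCENARIO["p_true"], alpha=1.0, seed=2)
sightings = simulate_incidental(truth, 391, seed=3)

mask, _ = bin_to_cells(sightings, grid)
cells = np.flatnonzero(mask.ravel())
model = fit_maxent(cells, grid, n_background=10000, seed=4)
hsi = predict_hsi(model, grid)
roc = roc_summary(hsi, cells, grid.nodata_mask)
print(f"maxent: gain={training_gain(model, grid=grid):.3f}  AUC={roc.auc:.3f}")

design = select_cells(hsi, n_weighted=60, n_random=20, seed=5)
design = assign_methods(design, n_camera_cells=40, seed=6)
history = simulate_surveys(design, truth, seed=7)
posterior = run_mcmc(OccupancyModelSpec(("cov1", "cov2", "cov3")),
                     history, seed=8)
print(posterior.summary().round(3).to_string(index=False))

p = posterior.p.mean(axis=0)
print(f"site-level detection, full protocol: "
      f"{composite_detection([p[0]]*3 + [p[1]] + [p[2]]*2):.3f}")
```

prints

```
maxent: gain=0.100  AUC=0.649
 parameter   mean    sd   q2.5  q97.5  rhat
     alpha  1.423 0.676  0.338  2.979 1.001
beta[cov1]  3.512 1.031  1.917  5.947 1.001
beta[cov2] -3.326 1.102 -5.872 -1.602 1.001
beta[cov3] -0.119 0.525 -1.160  0.926 1.000
 p[pellet]  0.390 0.040  0.314  0.469 1.000
   p[sign]  0.749 0.060  0.623  0.858 1.000
 p[camera]  0.371 0.066  0.247  0.505 1.000
site-level detection, full protocol: 0.978
```

The 80-cell survey recovers the simulation's detection probabilities
(truth 0.362 / 0.746 / 0.302) within their posterior uncertainty, the
occupancy coefficients carry the correct signs (`cov3`, whose true effect
is 0, straddles zero), every R-hat is at 1.00, and combining all methods
at a site makes a false negative rare (`p* ≈ 0.98`). The maxent AUC is
modest here because occupancy is widespread in this scenario, so
presences discriminate weakly — the HSI still ranks cells well, which is
what the survey design and the comparison stage use.

The same analysis runs from the shell via the `occurange` CLI
(`simulate`, `maxent`, `design`, `occupancy`, `delineate`, `run-all`),
with all stage parameters in a YAML config and a JSON run manifest
recording seeds, parameters and outputs.

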