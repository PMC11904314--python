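# Methods

## Model

The latent state is an inhomogeneous Poisson point process with intensity
λ(s) = exp(η(s)), η(s) = α + Σ_u β_u X_u(s) + c·ζ(s), on a planar study
region Ω in km units. ζ is a zero-mean Gaussian random field with Matérn
covariance of smoothness ν = 1 (the standard 2-D default of the SPDE
family), range ρ (km) and marginal sd σ, using the convention κ = √(8ν)/ρ
so that the correlation at distance ρ is (√8)K₁(√8) ≈ 0.14 ("approximately
0.1"), which is the convention under which a prior statement like
"P(range < 200 km) = 20%" is meaningful. The inter-likelihood sharing
constant c is fixed (default 1): all datasets see the same latent surface
at full strength.

Observation models per dataset type:

* Presence-only data are a thinned Poisson process with observed intensity
  λ(s)q(s). log q(s) = Σ_v γ_v W_v(s) + b(s) is a linear bias predictor —
  observational covariates W_v and/or a second Matérn field b — entering
  presence-only likelihoods only, because thinning acts on collection, not
  on the species' latent state. The point-process log-likelihood
  Σ_i η*(s_i) − ∫_Ω e^{η*(s)} ds uses the quadrature scheme below.
* Presence-absence records are Bernoulli with the cloglog link
  p = 1 − exp(−E e^η), the exact probability of at least one point in a
  site of measure E. The exposure convention is per dataset, default
  E = 1; the synthetic surveys use E = 15 (below).
* Counts are Poisson with mean E e^η per sampling site. Modelling counts
  per site with an exposure offset, rather than one integral per dataset,
  matches how count surveys enter joint models in practice; a dataset-level
  integral is the special case E = cell area.

The joint posterior multiplies all dataset likelihoods with the Gaussian
field priors, the PC hyperpriors, and (by default) a Normal(0, 10²) prior
on the fixed effects (a flat-prior mode exists for MLE-style fits; 10 is
wide relative to standardized covariates, so it acts only as mild
regularization).

## Geometry and quadrature

Ω is a shapely polygon; a regular nx × ny grid tiles its bounding box and
each cell is clipped to Ω by exact polygon intersection, so clipped areas
sum to |Ω| at any resolution. The quadrature rule takes one node per
intersecting cell with weight equal to the clipped area. Nodes sit at the
centroid of the clipped region (falling back to a representative interior
point in degenerate cases): for interior cells this is the midpoint, and
for boundary cells it keeps every node inside Ω. Cells with clipped area
below 1e-12 km² are dropped. All geometry is planar; geographic
coordinates are first projected with an equirectangular projection about a
reference point (R = 6371 km). That projection is deliberately simple and
dependency-free; its distortion is negligible at regional extents but it
is not a substitute for a proper projected CRS at continental scale.

## Fields on knots

Random fields are represented exactly on a regular knot lattice: the knot
coefficients have a dense Matérn covariance (plus a jitter nugget, default
1e-8 σ²) and are projected to arbitrary locations by bilinear
interpolation. This replaces the finite-element SPDE construction with
something directly checkable against brute-force covariance evaluation; it
is adequate for lattices up to a few thousand knots. The bias field uses
its own (ρ, σ) with the same PC prior as the shared field, and one bias
field is shared by all presence-only datasets (configurable in principle
by fitting datasets separately; the default follows the common design).

PC priors: ρ has density λ_ρ ρ⁻² exp(−λ_ρ/ρ) with λ_ρ = −log(α_ρ)·ρ0, and
σ is exponential with rate λ_σ = −log(α_σ)/σ0. These make the calibration
statements P(ρ < ρ0) = α_ρ, P(σ > σ0) = α_σ hold exactly; the test suite
verifies them by adaptive quadrature rather than the closed forms.

## Inference

Everything in the latent state (α, β, γ, z, b) enters linearly in η, and
all three observation log-likelihoods are concave in η, so the inner
problem is solved by a damped Newton iteration (Cholesky solves with a
ridge fallback, backtracking line search, convergence on relative
objective change, default 1e-8). Gradients and Hessians are analytic in
design-matrix form Aᵀ g′ / Aᵀ diag(g″) A. Initialization puts α at the
homogeneous-process solution log(total presences/|Ω|) and everything else
at zero.

Hyperparameters θ = (log ρ, log σ) per field are optimized in an outer
loop (Powell with bounds) against the Laplace-approximated marginal
posterior: the inner objective at its mode plus ½ log det H. The raw
profile objective is not used because the Gaussian-prior normalizer makes
it unbounded as σ → 0; the log-determinant term supplies the missing
volume correction. Bounds: ρ ∈ [median cell size, 10 × domain diameter],
σ ∈ [1e-3, 10]. A "fixed" mode holds θ at its initial values.

Posterior uncertainty is the inverse Hessian at the mode (symmetrized;
an indefinite Hessian raises a "saddle-point" error). Prediction maps
propagate seeded Gaussian draws from N(mode, H⁻¹) through the linear
predictor per grid cell, reporting per-cell mean and sd on the log,
intensity (exp) or probability (cloglog) scale; the bias map uses the same
draws for the full and plain predictors so their difference is exactly
the bias contribution. Conditioning on θ̂ understates total uncertainty
slightly — the known price of the empirical-Bayes shortcut.

## Data handling

Occurrence CSVs use Darwin-Core column names by default with a column-map
override. Cleaning rules: records with stated coordinate uncertainty above
a threshold (100 m in the emulated workflow) are dropped; records with
*missing* uncertainty are retained by default (aggregated data frequently
omit the field) with a strict mode that drops them. Absences are inferred
from cross-list surveys: the site set is the union of distinct sampling
locations (snapped to a 1 m lattice by default — "the same location" needs
a numerical tolerance), and each (site, species) pair without a presence
record becomes an absence. In count datasets a record marked present with
a missing count is treated as count 1. Covariates are z-standardized over
in-domain cells, storing (mean, sd) for back-transformation. Every dataset
and covariate is entered into a provenance ledger along with the filters
applied. Rasters are ESRI ASCII grids — a deliberately plain-text raster
dialect; anything else should be converted upstream.

## Synthetic scenarios

The generator produces exactly the structure the model assumes: a Matérn
field drawn by dense Cholesky on grid cell centers, per-cell Poisson
counts with uniform in-cell placement (points in boundary cells are
re-drawn until inside Ω), Bernoulli thinning, and cloglog/Poisson surveys
evaluated at the cell values of the latent surface.

The `standard` scenario fixes the study conditions used throughout the
tests: a 100 × 100 km square; a 40 × 40 simulation grid; one smooth
standardized covariate (diagonal gradient plus a gentle north–south
oscillation, so it is not a pure monotone ramp); true α = −4.0 per km²
and β = 1.5; field ρ = 40 km, σ = 0.6 — strong but realistic residual
structure at sub-domain range; south-heavy thinning q(y) = exp(−1.5 y/L)
(retention 1.0 in the far south to 0.22 in the far north), emulating
effort concentrated near population centres; two cross-list
presence-absence surveys of 80 random sites with exposure 15 (baseline
detection probability ≈ 0.2–0.3, typical of moderately intensive
surveys); the `rich` scenario adds a 40-site count survey with the same
exposure. Under these conditions a seed produces on the order of 200–300
retained presence-only points. What the generator does *not* emulate:
taxonomic misidentification, imperfect detection beyond thinning,
clustered (non-Poisson) recording behaviour, temporal structure, and
covariate measurement error — passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to real-data violations of them.

## Reference fit resolution

`simulate.fit_scenario` fixes the package's reference protocol for the
100 km scenarios: 40 × 40 quadrature, a 9 × 9 knot lattice per field,
hyperparameter optimization with Powell budget 150 evaluations, initial
(ρ, σ) = (35 km, 0.5). Resolution matters: with a much coarser lattice
(7 × 7) the unrepresented fine-scale field variation acts like unmodelled
heterogeneity and attenuates covariate coefficients — the classic
omitted-heterogeneity bias of log-link models. The 9 × 9 / 40 × 40
configuration removes that attenuation for fields with ρ ≈ 40 km while
keeping a full fit well under a second.

## Cross-validation

Spatial-block CV tiles the bounding box into k_x × k_y blocks dealt to
folds by a seeded balanced permutation; each fold's fit restricts the
presence-only quadrature to the training blocks' nodes (weights are
untouched, so restricted weights still sum to the training area whenever
block edges align with the quadrature grid). Scores are plug-in
predictive log-likelihoods at the training MAP state: the point-process
log-density over held-out blocks for presence-only data, observation-model
log-likelihoods for survey records. The aggregate is the
held-out-size-weighted mean over folds; folds with no held-out data are
skipped with a note. Leave-one-dataset-out refits without each dataset in
turn and scores it the same way. No buffered folds and no variable
selection — predictive log-score is the single reported criterion.

## Numerical choices and degenerate inputs

* Bernoulli probabilities are clamped to [1e-12, 1 − 1e-12] against
  cloglog overflow; the count and presence-absence derivative formulas use
  expm1 forms for small-μ stability.
* Duplicate knots, non-positive-definite covariances (with advice to raise
  the nugget), empty domains, grids coarser than 2 × 2, quadrature schemes
  with no positive-area cell, locations outside the knot extent or raster
  coverage, negative counts, and out-of-range coordinates all raise typed
  errors with stable short codes.
* Ties in block-to-fold allocation are resolved by the seeded permutation
  itself; all simulation randomness flows from a single seed through
  independently drawn sub-seeds.
* Fitting is deterministic given data and options; prediction-map draws
  are deterministic given the seed.

## Limitations

Dense knot covariances limit lattices to a few thousand knots; the
midpoint quadrature has no boundary-layer refinement; the equirectangular
projection is regional-scale only; hyperparameter uncertainty is not
propagated into maps; multi-species shared-field ("richness") modelling
and temporal dynamics are out of scope, and the workflow refuses richness
configurations explicitly rather than approximating them.
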