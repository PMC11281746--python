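# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `spatialenroll`.

## Problem setting

The unit of analysis is a *small area* (emulating commercial micro-areas of
roughly 300 households). Each area carries counts of insurants, diabetics
and unenrolled diabetics, plus socioeconomic covariates. The quantity of
interest is *enrollment potential*: the fraction of diabetics not enrolled
in the disease management program, mapped, cluster-tested and regressed on
individual and area covariates.

## Spatial structure

Contiguity follows the shared-boundary rule: two areas are neighbours iff
their polygon boundaries intersect in a set of positive length. Corner
touching does **not** create an edge (an "edge" has length); this is the
rook rule on square lattices. The ICAR structure matrix is the graph
Laplacian `Q = D − W`; it is positive semidefinite with one null vector
(the constant) per connected component, so every ICAR-distributed field is
constrained to sum to zero per component. Isolated areas are retained and
receive only unstructured effects, the standard disease-mapping treatment.

All geometry lives in a planar projection with kilometre units. The
synthetic generator emits coordinates with a large false-easting-style
offset (origin ≈ (3300, 5800) km) as real projected data would have; a
heuristic warns when coordinates look like raw longitude/latitude.

## Synthetic data-generating process

`SimulationConfig` fixes the ground truth; every stage derives an
independent seeded stream from the master seed, so datasets are exactly
reproducible and carry their generating parameters for recovery tests.

* **Region**: an `n_rows × n_cols` lattice of square cells (default 10×10,
  1 km cells). Insurant counts are Poisson (mean 300 per area, truncated at
  ≥ 1) — the scale of the micro-areas being emulated.
* **Area covariates** (unemployment, employed-at-residence, purchasing
  power, education shares, household size, commuter share, physician
  density, foreign share): each is an affine transform of
  `√0.6 · ICAR-draw + √0.4 · white noise`, clipped to its natural range, so
  covariates are spatially autocorrelated but not collinear.
* **Individuals**: age ~ truncated Normal(55, 20²) on [18, 100]; sex
  balanced; unemployment log-odds linear in the area deprivation index;
  foreign citizenship Bernoulli with the area's foreign share; diabetes
  log-odds linear in age (slope 0.05/year) with the intercept calibrated by
  root-finding so the expected diabetic share hits a target, default 17.3%
  — the prevalence scale of the insurance population this emulates.
* **Outcome**: for each diabetic,
  `P(not enrolled) = logistic(β₀ + β·x_ind + γ·x_area + u_a + v_a + Σ_k δ_k,a x_k)`.
  Default coefficients are the odds ratios a large regional DMP-unenrollment
  analysis reported (male 0.938, age 0.997/yr, foreign 1.058, unemployed
  1.100, deprivation 1.000, household size 0.801, commuter % 0.996,
  physician density 0.998), so "literature-like" scenarios are the default.
  The intercept is calibrated so the marginal unenrollment fraction hits
  36.8% unless set explicitly. Structured/unstructured area-effect sds
  default to 0.3 / 0.1 on the log-odds scale — visible but subdominant
  spatial heterogeneity, a typical magnitude for areal health outcomes.
* **ICAR field draws** use the eigendecomposition of `Q` restricted to its
  non-null space, rescaled to a requested marginal sd: exact and seed-stable
  at desk scale (≤ a few thousand areas).

What the generator does **not** emulate: realistic polygon shapes and sizes
(all methods used here depend only on adjacency, centroids and counts),
household structure, insurance-switching dynamics, and the empirical
age/sex composition of real diabetics beyond the calibated prevalence.
Passing recovery tests therefore show that the estimators recover the
*assumed* model's parameters, not that the model is right for any real
region.

## Deprivation index

The five indicators are oriented so higher = more deprived, converted to
mid-rank percentiles `(rank − 0.5)/n`, averaged within the domains
employment (2 indicators), income (1) and education (2), the three domain
scores averaged with equal weight, and the result rescaled linearly over
areas to [1, 100]. Rank aggregation makes the index invariant to affine
transforms of any indicator and deterministic under ties (mid-rank). When
all areas tie, every area gets the midpoint 50.5 with a warning. The
rank-percentile recipe is one defensible member of the family of
multiple-deprivation indices; it is isolated behind `compute_deprivation`
so a weighted or factor-analytic variant can be swapped in.

## BYM disease mapping

`O_i ~ Poisson(E_i θ_i)`, `log θ_i = β₀ + u_i + v_i`, with expected counts
`E_i = n_diab,i · (ΣO/Σn_diab)` (internal standardization, `ΣE = ΣO`
exactly). Hyperpriors: `τ_u, τ_v ~ Gamma(1, 5·10⁻⁴)` — the conventional
diffuse disease-mapping default, config-overridable; `β₀ ~ N(0, 10²)`.

Inference is Metropolis-within-Gibbs MCMC:

* single-site random-walk updates of `u`, vectorised over a greedy graph
  colouring (areas of one colour share no edge, so their full conditionals
  are independent and update simultaneously);
* sum-to-zero recentering of `u` per component each sweep, folding the
  removed grand mean into `β₀` (exact for a connected graph);
* independent Metropolis updates of all `v_i`, a scalar update of `β₀`,
  conjugate Gamma draws for `τ_u` (shape uses the ICAR rank `n − #comp`)
  and `τ_v`;
* proposal scales adapt toward 44% acceptance during burn-in only.

Defaults: 4 chains × 5,000 draws after 2,000 burn-in. Convergence is
summarised by split-R̂; the `converged` flag keys on the quantities used
downstream (intercept, deviance, representative `log θ_i`) with threshold
1.1, while the precision R̂s are reported but not gated — a precision whose
variance component is ≈ 0 is weakly identified and its R̂ is uninformative
about the risk surface. Non-convergence produces a flagged result plus a
warning, never a silent success.

### Continuous surface

The smoothed rates are interpolated from area centroids with a Gaussian
process with Matérn covariance, smoothness fixed at 1 (the planar
Whittle–Matérn case, matching the SPDE-type smoothers used for this
purpose). Range and sill are fitted by maximum likelihood via
`sklearn.gaussian_process` unless supplied; the nugget defaults to 1e-8 so
the surface interpolates the inputs, and predictions revert to the fitted
constant mean far from all centroids. Grid default: bounding box / 200 per
axis. Duplicate centroids are rejected (singular covariance).

## Spatial scan statistic

Windows grow around every centroid by adding the next-nearest centroid
while the radius stays within the cap (default 30 km — the setting for
sparsely populated regions where a 50%-population cap yields impractically
large clusters; a population cap is not imposed). Distance ties break by
area order. The Poisson LLR is computed only for high-rate windows (the
scan targets unusually *high* unenrollment); `0·log 0 = 0`.

Significance is conditional Monte-Carlo: the observed total is
redistributed multinomially with probabilities `E_i/ΣE` (9,999 replications
by default; the test suite uses 999), and
`p = (1 + #{null max-LLR ≥ LLR}) / (1 + n_sim)`. The primary cluster is the
max-LLR window (ties → fewer members, then lower center index); secondary
clusters follow in LLR order subject to sharing no member area with any
better-ranked cluster — the strictest standard overlap rule. All reported
clusters are judged against the same null max-LLR distribution.

## Global regression

Logistic regression of unenrollment with fixed effects
`N(0, 10²)`-priored and an area random effect of type none / iid / Besag /
BYM. Continuous covariates enter unstandardized (standardization is an
SVC-only device for comparability of local coefficients). Reference
categories: female, German citizenship, not unemployed.

Inference is empirical-Bayes Laplace: the latent field is found by
penalised Newton (IRLS) iterations; random-effect precisions follow the
EM-type fixed point `τ ← m / (b'Kb + tr(Σ K))`, where `K` is the block's
penalty (identity for iid; `Q` plus a per-component centering term
`11'/m_c` for ICAR, which pins the component means softly at zero and makes
the penalty proper); the posterior is approximated by a Gaussian at the
mode and seeded draws are taken from it. EM stops when precisions move less
than 0.1% or when the implied field scales `1/√τ` move less than 5·10⁻³
log-odds — precisions of null fields diverge along a flat ridge and only
their field scale is statistically meaningful. This Laplace strategy is the
same family of approximations used by the standard applied tooling for
these models, and is what makes hundred-fold replicate fits at n = 50,000
feasible; exact MCMC remains in use for the Poisson mapping model, and the
Laplace fits are validated against a maximum-likelihood oracle and coverage
simulations in the test suite.

Quasi-separation is detected as a fixed-effect mode beyond one prior sd
(|β̂| > 10 log-odds) and produces a warning, not an error: under the
diffuse-but-proper prior the fit remains finite and is returned flagged.

DIC uses classical `p_D = D̄ − D(ẑ)` with the deviance evaluated at the
posterior mode of the latent field, and `D̄` averaged over the Gaussian
posterior draws (1,000 by default).

## SVC regression

`logit P = Σ_k (β_k + δ_k,j(i)) x_ik`, one ICAR field and one precision per
selected covariate, plus a spatially varying intercept (default on). The
model runs on a *coarsened* graph: fine areas are mapped onto
municipality-like units (edge iff any fine pair across two units is
adjacent), cutting the latent dimension by roughly an order of magnitude —
the same device that makes these models tractable in practice. Age,
deprivation and commuter share are standardized (population sd) so local
coefficient magnitudes compare directly; binary covariates, household size
and physician density stay on their native scale.

Exceedance probabilities use the *total* coefficient `β_k + δ_kj`:
`P(exp(total) > 1)` per unit, or `P(< 1)` for household size, whose
ubiquitous protective direction makes the below-one probability the
informative map. Bands: `[0, 0.6)`, `[0.6, 0.8]`, `(0.8, 1]` — the band
edges at 0.6 and 0.8 are a mapping convention; both boundary values close
into the middle band.

## Pipeline

One JSON config with per-stage blocks drives
`simulate → deprivation → map → scan → global_fit → svc`. Stage seeds
derive deterministically from the master seed (`seed·10007 + stage index`,
reduced mod 2³¹). Each stage writes text artifacts (GeoJSON / CSV at 6
significant digits / JSON) and a manifest entry (parameter hash, outputs,
wall time, version); re-running an unchanged stage is a no-op, and changing
any upstream parameter invalidates all downstream hashes.
`validate_inputs` checks GeoJSON validity, schemas, the count invariant
`n_unenrolled ≤ n_diabetics ≤ n_insurants` and referential integrity of
area ids.

## Problem sizes used by the test and acceptance suites

Simulation studies run at desk scale, chosen to keep each operating
characteristic measurable with comfortable margins: scan type-I error on a
10×10 lattice with `E_i = 50` at 999 Monte-Carlo replications × 200
replicates; scan power against a threefold-risk 5-area block × 100 seeds;
global-model coverage with 100 replicate fits at ≈ 50,000 diabetics;
DIC model selection (iid vs Besag, structured sd 1.0) × 100 replicates;
BYM recovery on a 15×15 lattice (structured sd 0.5, `E_i = 50`); SVC
recovery with 100 coarse units at ≈ 50,000 diabetics, and an 11-replicate
DIC comparison against the global model. The exhaustive scan oracle runs on
100 random maps of ≤ 12 areas.

## Known limitations

* The logistic fits use a Gaussian approximation to the posterior;
  credible intervals for very rare covariate patterns or tiny samples will
  be less accurate than MCMC would give.
* Empirical-Bayes precisions ignore hyperparameter uncertainty; interval
  widths for the random-effect fields are accordingly slightly optimistic.
* ICAR centering is soft (precision-level), not a hard constraint; with
  very weak data the component mean of a field can drift at the `1/√τ`
  scale.
* The scan considers circular windows only; elongated clusters are found
  as unions of circles or missed.
* BYM is parameterized with two free precisions; no BYM2/penalised-
  complexity reparameterization is provided yet.
* The surface interpolator fits a single global Matérn range;
  nonstationary smoothing (urban vs rural) is out of scope.
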