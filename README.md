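# spatialenroll

Small-area Bayesian spatial analysis of **disease-management-program (DMP)
unenrollment**. Structured treatment programs for type 2 diabetes only help
the diabetics who are enrolled in them; health insurers therefore want to
know *where* unenrolled diabetics cluster and *which* population groups in
which places stay unenrolled. This package implements the full
spatial-epidemiological workflow for that question at the scale of
micro-areas (a few hundred households each), exercised end-to-end on
synthetic regions with known ground truth, because the individual insurance
records such analyses run on are legally non-shareable.

It is aimed at spatial epidemiologists and health-services researchers who
work with areal count data and individual-level binary outcomes.

## What it computes

With `O_i` unenrolled diabetics and `E_i` internally standardized expected
counts per area `i` (so `ΣE = ΣO`):

* **Disease mapping (BYM).** `O_i ~ Poisson(E_i·θ_i)`,
  `log θ_i = β₀ + u_i + v_i`, with `u ~ ICAR(τ_u)` (graph-Laplacian
  precision, sum-to-zero per connected component) and `v_i ~ N(0, 1/τ_v)`.
  Smoothed rates `θ̂_i ×` global rate are interpolated from centroids to a
  continuous surface with a Matérn Gaussian process (smoothness 1).
  Inference is Metropolis-within-Gibbs MCMC with split-R̂ diagnostics.
* **Local cluster detection.** Kulldorff's purely spatial Poisson scan over
  circular windows up to a 30 km radius, ranked by
  `LLR = O_in log(O_in/E_in) + O_out log(O_out/E_out)` (high-rate windows
  only), with conditional Monte-Carlo p-values (9,999 replications by
  default) and non-overlapping secondary clusters.
* **Global regression.** Bayesian logistic regression of
  `P(not enrolled)` on sex, age, unemployment, foreign citizenship,
  deprivation, household size, commuter share and physician density, with
  area random effects of type none / iid / Besag / BYM, VIF screening,
  DIC comparison (`DIC = D̄ + p_D`, `p_D = D̄ − D(θ̄)`) and odds-ratio /
  percent-change reporting.
* **Spatially varying coefficients (SVC).**
  `logit P = Σ_k (β_k + δ_k,j(i))·x_ik` with one ICAR field `δ_k` per
  covariate on a coarsened (municipality-like) graph, per-unit exceedance
  probabilities `P(exp(β_k + δ_kj) > 1)` (or `< 1` for protective effects)
  banded at 0.6 / 0.8 for mapping.
* **Deprivation index.** Rank-based composite of five indicators in three
  equally weighted domains (employment, income, education), scaled to
  1 (least deprived) … 100 (most deprived).
* **Synthetic regions.** A seeded generator producing lattice regions,
  spatially correlated area covariates, insurant rosters (≈17.3% diabetic)
  and enrollment outcomes (≈36.8% unenrolled) from a configurable logistic
  ground truth, so every estimator can be tested for parameter recovery.

## Worked example

```python
import numpy as np
from spatialenroll import (SimulationConfig, simulate_dataset, expected_counts,
                           fit_bym, detect_clusters, build_design, fit_global)
from spatialenroll.disease_mapping import MappingInputs, InferenceConfig
from spatialenroll.spatial_structure import centroid_distance_matrix

ds = simulate_dataset(SimulationConfig(n_rows=10, n_cols=10, seed=1))
O = np.array([a.n_unenrolled for a in ds.areas], float)
nd = np.array([a.n_diabetics for a in ds.areas], float)
E = expected_counts(nd, O)

post = fit_bym(MappingInputs(O, E, ds.graph),
               inference=InferenceConfig(chains=2, draws=2000, burn=1000, seed=2))
```

This prints (via `examples/03_disease_mapping.py`):

```
global unenrollment rate: 36.4%
smoothed area rates:      29.7% .. 47.2%
crude area rates:         15.4% .. 68.2%
chains converged:         True
```

The crude area rates range from 15% to 68% purely through small-count
noise; BYM smoothing shrinks them to 30–47%, the range supported by the
data. The scan statistic then localises true excesses: in
`examples/04_cluster_scan.py` a threefold-risk block injected into five
areas is recovered as the primary cluster with relative risk 2.2 and
p = 0.001, while all noise windows stay non-significant.

The `examples/` directory holds one short script per capability
(simulation, deprivation, mapping, scanning, global regression, SVC,
pipeline); each prints its numbers with a line on what they mean. The same
workflow is scriptable from the shell:

```bash
spatialenroll run --config cfg.json --seed 1
spatialenroll validate outdir/
```

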