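"""BYM-smooth area unenrollment rates and interpolate a continuous surface.

The Besag-York-Mollié model shrinks noisy small-area rates toward their
neighbours (ICAR effect) and the global mean (iid effect); the smoothed
relative risks are then interpolated from centroids with a Matérn Gaussian
process, giving a continuous 'enrollment potential' surface without
artificial area boundaries.
"""

import numpy as np

from spatialenroll import (
    SimulationConfig,
    expected_counts,
    fit_bym,
    interpolate_surface,
    simulate_dataset,
    smoothed_rates,
)
from spatialenroll.disease_mapping import InferenceConfig, MappingInputs

ds = simulate_dataset(SimulationConfig(n_rows=10, n_cols=10, seed=1))
O = np.array([a.n_unenrolled for a in ds.areas], float)
n_diab = np.array([a.n_diabetics for a in ds.areas], float)
E = expected_counts(n_diab, O)

post = fit_bym(
    MappingInputs(O, E, ds.graph),
    inference=InferenceConfig(chains=2, draws=2000, burn=1000, seed=2),
)
global_rate = O.sum() / n_diab.sum()
rates = smoothed_rates(post, global_rate)

print(f"global unenrollment rate: {global_rate:.1%}")
print(f"smoothed area rates:      {rates['rate'].min():.1%} .. {rates['rate'].max():.1%}")
print(f"crude area rates:         {(O / n_diab).min():.1%} .. {(O / n_diab).max():.1%}")
print(f"chains converged:         {post.diagnostics['converged']}")

centroids = np.array([a.centroid for a in ds.areas])
surface = interpolate_surface(centroids, rates["rate"].to_numpy())
print(f"surface grid:             {surface.values.shape}, "
      f"range {surface.values.min():.1%} .. {surface.values.max():.1%}")

# The smoothed range is narrower than the crude range: extreme rates in
# small areas are shrunk toward their neighbourhood and the global mean.
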