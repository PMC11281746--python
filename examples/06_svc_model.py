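"""Fit the spatially varying coefficient model and map exceedance bands.

Each selected covariate's coefficient becomes a global value plus an
ICAR-distributed deviation over a coarsened (municipality-like) graph.
Per-unit exceedance probabilities — P(exponentiated coefficient > 1), or
< 1 for household size — say how reliably the local effect points one way,
banded at 0.6 and 0.8 for mapping.
"""

from collections import Counter

from spatialenroll import SimulationConfig, build_design, fit_svc, simulate_dataset
from spatialenroll.global_regression import FitConfig
from spatialenroll.svc_regression import block_mapping, coarsen

# simulate a region where the male effect genuinely varies over space
ds = simulate_dataset(
    SimulationConfig(n_rows=10, n_cols=10, svc_fields={"male": 0.5}, seed=9)
)
design = build_design(ds.insurants, ds.covariates)
coarse = coarsen(ds.graph, block_mapping(10, 10, 2, design.area_ids))
print(f"fine areas: {ds.graph.n_areas}  ->  coarse units: {len(coarse.unit_ids)}")

fit = fit_svc(
    design, coarse, ["male", "household_size"], FitConfig(n_draws=500, seed=10)
)
print(f"SVC DIC: {fit.dic['DIC']:.1f} (pD {fit.dic['pD']:.1f})")

for name in ("male", "household_size"):
    fld = fit.fields[name]
    bands = Counter(fld.bands)
    print(
        f"\n{name} (direction: OR {fld.direction} than 1):\n"
        f"  local coefficient range: {fld.coef_mean.min():+.3f} .. {fld.coef_mean.max():+.3f}\n"
        f"  exceedance bands: {dict(bands)}"
    )

# Units in the '>0.8' band have a >80% posterior probability that the local
# effect points in the stated direction — the map-ready reliability measure.
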