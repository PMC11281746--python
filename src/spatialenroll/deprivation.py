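"""Multi-domain small-area deprivation index on a 1-100 scale.

The index aggregates five area indicators into three equally weighted
domains — employment (unemployment rate, employed-at-residence share),
income (purchasing power) and education (high-school-degree share, share
without formal education) — in the spirit of German multiple-deprivation
indices.  Aggregation is rank-based: each indicator is oriented so that
higher = more deprived, converted to a mid-rank percentile, averaged within
domain, averaged across domains, and linearly rescaled over areas so the
least deprived area scores 1 and the most deprived 100.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: indicator -> (domain, orientation); +1 means higher raw value = more deprived
INDICATORS = {
    "unemployment_rate": ("employment", +1),
    "employed_at_residence": ("employment", -1),
    "purchasing_power": ("income", -1),
    "highschool_degree": ("education", -1),
    "no_formal_education": ("education", +1),
}

DOMAINS = ("employment", "income", "education")


def compute_deprivation(covariates: pd.DataFrame) -> pd.DataFrame:
    """Compute the deprivation index for every area.

    Parameters
    ----------
    covariates : DataFrame
        Must contain ``area_id`` and the five indicator columns listed in
        :data:`INDICATORS`; missing values are rejected with the offending
        area named.

    Returns
    -------
    DataFrame with columns ``area_id``, one score in [0, 1] per domain, and
    ``index`` in [1, 100] (1 = least deprived, 100 = most deprived).  If all
    areas tie on the raw score every index is set to the midpoint 50.5 with a
    warning.
    """
    required = ["area_id", *INDICATORS]
    missing_cols = [c for c in required if c not in covariates.columns]
    if missing_cols:
        raise ValueError(f"missing indicator columns: {missing_cols}")
    if len(covariates) < 2:
        raise ValueError("need at least 2 areas to scale the index")

    sub = covariates[required].copy()
    for col in INDICATORS:
        bad = sub.loc[sub[col].isna(), "area_id"].tolist()
        if bad:
            raise ValueError(f"missing {col} for areas {bad}")

    n = len(sub)
    percentiles = {}
    for col, (_, orient) in INDICATORS.items():
        values = orient * sub[col].to_numpy(dtype=float)
        # mid-rank percentile in [0, 1]: (rank - 0.5) / n
        percentiles[col] = (rankdata(values, method="average") - 0.5) / n

    out = pd.DataFrame({"area_id": sub["area_id"]})
    for dom in DOMAINS:
        cols = [c for c, (d, _) in INDICATORS.items() if d == dom]
        out[dom] = np.mean([percentiles[c] for c in cols], axis=0)
    raw = out[list(DOMAINS)].mean(axis=1).to_numpy()

    span = raw.max() - raw.min()
    if span == 0:
        warnings.warn(
            "all areas have identical deprivation scores; assigning 50.5",
            UserWarning,
            stacklevel=2,
        )
        out["index"] = 50.5
    else:
        out["index"] = 1.0 + 99.0 * (raw - raw.min()) / span
    return out
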