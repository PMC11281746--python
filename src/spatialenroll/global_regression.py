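"""Global Bayesian logistic regression of DMP unenrollment.

The outcome is a diabetic insurant *not* being enrolled (1 = unenrolled).
Individual covariates: male sex (ref. female), age in years, foreign
citizenship (ref. German), currently unemployed (ref. not).  Area covariates
joined by area id: deprivation index, average household size, commuter share
and physician density per 100,000.  Covariates enter unstandardized.

Four variants differ only in the area random effect: none, iid (unstructured
exchangeable heterogeneity), Besag (ICAR spatial autocorrelation: close areas
are more similar than distant ones), or BYM (both).  Fixed effects carry
Normal(0, 10^2) priors.  Models are screened for multicollinearity with the
variance inflation factor (VIF > 5 flags a covariate) and compared by the
deviance information criterion DIC = mean deviance + pD, with
pD = mean deviance - deviance at the posterior mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

from spatialenroll._laplace import (
    LaplaceFit,
    RandomBlock,
    bernoulli_deviance,
    deviance_samples_from_draws,
    fit_logistic_laplace,
    icar_penalty,
)
from spatialenroll.posterior import PosteriorSummary
from spatialenroll.spatial_structure import AdjacencyGraph, icar_structure

#: canonical covariate order (reference categories: female, German
#: citizenship, not unemployed)
COVARIATE_ORDER = [
    "male",
    "age",
    "foreign_citizenship",
    "unemployed",
    "deprivation",
    "household_size",
    "commuter_pct",
    "physician_density",
]

EFFECT_TYPES = ("none", "iid", "besag", "bym")


@dataclass
class RegressionDesign:
    """Per-diabetic design: outcome, covariate matrix and area index."""

    y: np.ndarray  # 1 = NOT enrolled
    X: pd.DataFrame  # columns = COVARIATE_ORDER
    area_ids: list[str]  # unit order used by area_index
    area_index: np.ndarray  # row -> position in area_ids

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.X.isna().any().any():
            raise ValueError("design contains missing cells")
        if len(self.y) != len(self.X) or len(self.y) != len(self.area_index):
            raise ValueError("design length mismatch")

    @property
    def n(self) -> int:
        return len(self.y)


def build_design(
    insurants: pd.DataFrame,
    covariates: pd.DataFrame,
    area_ids: list[str] | None = None,
) -> RegressionDesign:
    """Assemble the regression design from the insurant roster (diabetics
    only) and the area covariate table (must carry a ``deprivation`` column,
    e.g. from :func:`spatialenroll.deprivation.compute_deprivation`)."""
    diab = insurants[insurants["diabetic"] == 1].copy()
    if diab["enrolled"].isna().any():
        raise ValueError("diabetics with undefined enrollment in design")
    if area_ids is None:
        area_ids = covariates["area_id"].tolist()
    pos = {a: i for i, a in enumerate(area_ids)}
    unknown = set(diab["area_id"]) - set(pos)
    if unknown:
        raise ValueError(f"insurants reference unknown areas {sorted(unknown)[:5]}")

    cov = covariates.set_index("area_id")
    X = pd.DataFrame(
        {
            "male": diab["male"].to_numpy(dtype=float),
            "age": diab["age"].to_numpy(dtype=float),
            "foreign_citizenship": diab["foreign_citizenship"].to_numpy(dtype=float),
            "unemployed": diab["unemployed"].to_numpy(dtype=float),
            "deprivation": cov["deprivation"].reindex(diab["area_id"]).to_numpy(dtype=float),
            "household_size": cov["household_size"].reindex(diab["area_id"]).to_numpy(dtype=float),
            "commuter_pct": cov["commuter_pct"].reindex(diab["area_id"]).to_numpy(dtype=float),
            "physician_density": cov["physician_density"].reindex(diab["area_id"]).to_numpy(dtype=float),
        }
    )
    y = (diab["enrolled"] == 0).to_numpy(dtype=float)
    area_index = np.array([pos[a] for a in diab["area_id"]])
    return RegressionDesign(y=y, X=X, area_ids=list(area_ids), area_index=area_index)


def compute_vif(design: RegressionDesign | pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors: VIF_k = 1/(1 - R^2_k) from regressing
    covariate k on all others plus an intercept.  Perfectly collinear
    covariates get an infinite VIF and are flagged."""
    X = design.X if isinstance(design, RegressionDesign) else design
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 covariates for VIF")
    if len(X) <= len(cols) + 1:
        raise ValueError("need more rows than covariates")
    M = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    vifs = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for j in range(1, M.shape[1]):
            v = variance_inflation_factor(M, j)
            vifs.append(np.inf if (not np.isfinite(v) or v > 1e12) else float(v))
    out = pd.DataFrame({"covariate": cols, "vif": vifs})
    out["flagged"] = out["vif"] > threshold
    return out


@dataclass
class FitConfig:
    """Settings of the Laplace fit and its posterior sampling."""

    n_draws: int = 1000
    seed: int = 0
    prior_sd: float = 10.0
    em_iters: int = 50
    em_tol: float = 1e-3


@dataclass
class GlobalFit:
    """Posterior of a global model plus its DIC bookkeeping."""

    effect_type: str
    posterior: PosteriorSummary  # intercept + fixed effects (log-odds scale)
    dic: dict  # {"DIC", "pD", "mean_deviance"}
    taus: dict
    laplace: LaplaceFit
    diagnostics: dict = field(default_factory=dict)

    def odds_ratios(self) -> pd.DataFrame:
        return odds_ratio_table(self.posterior)


def fit_global(
    design: RegressionDesign,
    graph: AdjacencyGraph | None = None,
    effect_type: str = "bym",
    config: FitConfig | None = None,
) -> GlobalFit:
    """Fit the global unenrollment model with the requested area effect.

    ``graph`` is required for any spatial effect type; Besag/BYM require
    connected components of at least two areas for the structured effect.
    """
    if effect_type not in EFFECT_TYPES:
        raise ValueError(f"effect_type must be one of {EFFECT_TYPES}")
    cfg = config or FitConfig()
    if effect_type != "none" and graph is None:
        raise ValueError("spatial effect types need an adjacency graph")

    Xmat = np.column_stack(
        [np.ones(design.n), design.X[COVARIATE_ORDER].to_numpy(dtype=float)]
    )
    names = ["intercept", *COVARIATE_ORDER]

    blocks: list[RandomBlock] = []
    if effect_type in ("iid", "bym"):
        blocks.append(RandomBlock(name="v_iid", K=np.eye(len(design.area_ids))))
    if effect_type in ("besag", "bym"):
        icar = icar_structure(graph)
        if all(len(c) < 2 for c in graph.components):
            raise ValueError("Besag effect needs a component with >= 2 areas")
        blocks.append(
            RandomBlock(
                name="u_besag",
                K=icar_penalty(icar.Q.toarray(), icar.component_indicator),
            )
        )

    fit = fit_logistic_laplace(
        design.y,
        Xmat,
        names,
        groups=design.area_index if blocks else None,
        n_units=len(design.area_ids) if blocks else 0,
        blocks=blocks,
        prior_sd=cfg.prior_sd,
        em_iters=cfg.em_iters,
        em_tol=cfg.em_tol,
    )

    rng = np.random.default_rng(cfg.seed)
    draws = fit.draw(cfg.n_draws, rng)
    mults = [None for _ in blocks]
    dev = deviance_samples_from_draws(
        design.y, Xmat, design.area_index if blocks else None, mults,
        draws, fit.p_fixed, fit.m,
    )
    eta_mode = Xmat @ fit.mode[: fit.p_fixed]
    for k in range(len(blocks)):
        eta_mode = eta_mode + fit.mode[fit.block_slice(k)][design.area_index]
    dev_at_mean = bernoulli_deviance(design.y, eta_mode)

    posterior = PosteriorSummary(
        names=names,
        samples=draws[:, : fit.p_fixed],
        deviance_samples=dev,
        deviance_at_mean=dev_at_mean,
        diagnostics=fit.diagnostics,
    )
    return GlobalFit(
        effect_type=effect_type,
        posterior=posterior,
        dic=compute_dic(dev, dev_at_mean),
        taus=fit.taus,
        laplace=fit,
        diagnostics=fit.diagnostics,
    )


def compute_dic(deviance_samples: np.ndarray, deviance_at_posterior_mean: float) -> dict:
    """Spiegelhalter DIC: mean deviance plus the effective parameter count
    pD = mean deviance - deviance at the posterior mean."""
    deviance_samples = np.asarray(deviance_samples, dtype=float)
    if deviance_samples.size < 2:
        raise ValueError("need at least 2 deviance samples")
    dbar = float(deviance_samples.mean())
    pd_ = dbar - float(deviance_at_posterior_mean)
    return {"DIC": dbar + pd_, "pD": pd_, "mean_deviance": dbar}


def model_comparison_table(fits: list[GlobalFit]) -> pd.DataFrame:
    """Goodness-of-fit comparison across effect types (lower DIC is better)."""
    return pd.DataFrame(
        [
            {
                "effect": f.effect_type,
                "prior": {"none": "-", "iid": "Iid", "besag": "Besag",
                          "bym": "Besag-York-Mollie (BYM)"}[f.effect_type],
                "DIC": f.dic["DIC"],
                "pD": f.dic["pD"],
            }
            for f in fits
        ]
    )


def odds_ratio_table(posterior: PosteriorSummary) -> pd.DataFrame:
    """Exponentiated posterior summaries, one row per coefficient, in the
    canonical covariate order (intercept first)."""
    rows = []
    for name in posterior.names:
        ors = np.exp(posterior.column(name))
        rows.append(
            {
                "covariate": name,
                "or_mean": float(ors.mean()),
                "or_median": float(np.quantile(ors, 0.5)),
                "ci_2.5": float(np.quantile(ors, 0.025)),
                "ci_97.5": float(np.quantile(ors, 0.975)),
            }
        )
    return pd.DataFrame(rows)


def percent_change(or_value: float) -> float:
    """Convert an odds ratio to a signed percent change in risk phrasing,
    rounded half-up to one decimal: 0.938 -> -6.2 ("6.2% lower risk")."""
    if or_value <= 0:
        raise ValueError("odds ratio must be > 0")
    pct = (Decimal(repr(or_value)) - 1) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
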