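"""Composite variables: coefficient-weighted sums of operational variables.

A composite collapses several observed "operational" variables into a single
model node: the weights are the coefficients of a multiple regression of the
response on the (z-scored) indicators, the composite score is the weighted
sum, and scores are re-standardized to unit variance so downstream
standardized path coefficients are well defined.  Three composites are used
in the pipeline: contemporary climate (temperature + precipitation), climate
instability (temperature + precipitation anomalies), and community-wide
traits (body size, size variance, trophic structure).  Composite scores are
treated as fixed regressors downstream (two-step estimation).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CompositeSpec", "CompositeFit", "fit_composite", "score_composite", "STANDARD_COMPOSITES"]

#: Canonical composite layouts (name -> indicator variable ids).
STANDARD_COMPOSITES: dict[str, tuple[str, ...]] = {
    "contemporary_climate": ("temp_current", "precip_current"),
    "climate_instability": ("temp_anomaly", "precip_anomaly"),
    "community_traits": ("body_size", "size_variance", "trophic_structure"),
}


@dataclasses.dataclass(frozen=True)
class CompositeSpec:
    """Name, indicator variables, and the weighting response of a composite."""

    name: str
    indicators: tuple[str, ...]
    response: str

    def __post_init__(self) -> None:
        if len(self.indicators) == 0:
            raise ValueError("a composite needs at least one indicator")
        if len(set(self.indicators)) != len(self.indicators):
            raise ValueError("indicators must be distinct")


@dataclasses.dataclass(frozen=True)
class CompositeFit:
    """Fitted composite: indicator weights plus the stored standardization.

    ``scores`` are the per-cell standardized composite values on the training
    data; ``weights`` apply to z-scored indicators (z-scoring parameters in
    ``indicator_means`` / ``indicator_sds``); ``raw_mean`` / ``raw_sd``
    standardize the weighted sum.
    """

    spec: CompositeSpec
    weights: pd.Series
    indicator_means: pd.Series
    indicator_sds: pd.Series
    raw_mean: float
    raw_sd: float
    scores: pd.Series


def fit_composite(spec: CompositeSpec, data: pd.DataFrame) -> CompositeFit:
    """Estimate composite weights by OLS of the response on the indicators.

    Indicators are z-scored before the weighting regression (the response
    keeps its scale; weights are only defined up to a common factor since
    the score is re-standardized).  The composite score is the weighted sum
    of z-scored indicators, re-standardized to zero mean and unit variance.
    Perfectly collinear indicators raise, pointing the user at the
    collinearity prefilter.
    """
    cols = list(spec.indicators)
    missing = [c for c in cols + [spec.response] if c not in data.columns]
    if missing:
        raise KeyError(f"missing columns for composite {spec.name!r}: {missing}")
    x = data[cols].to_numpy(dtype=float)
    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("composite inputs must not contain missing values")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [c for c, s in zip(cols, sds) if s == 0]
        raise ValueError(f"constant indicators: {bad}")
    xz = (x - means) / sds
    if np.linalg.matrix_rank(xz) < xz.shape[1]:
        raise ValueError(
            f"indicators of composite {spec.name!r} are perfectly collinear; "
            "run the collinearity prefilter first"
        )
    if y.std(ddof=1) == 0:
        raise ValueError("response is constant")
    design = np.column_stack([np.ones(len(y)), xz])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    weights = pd.Series(beta[1:], index=cols, name=spec.name)
    raw = xz @ weights.to_numpy()
    raw_mean = float(raw.mean())
    raw_sd = float(raw.std(ddof=1))
    if raw_sd == 0:
        raise ValueError("composite scores are constant (all weights zero?)")
    scores = pd.Series((raw - raw_mean) / raw_sd, index=data.index, name=spec.name)
    return CompositeFit(
        spec=spec,
        weights=weights,
        indicator_means=pd.Series(means, index=cols),
        indicator_sds=pd.Series(sds, index=cols),
        raw_mean=raw_mean,
        raw_sd=raw_sd,
        scores=scores,
    )


def score_composite(fit: CompositeFit, new_data: pd.DataFrame) -> pd.Series:
    """Apply stored weights and standardization to new data.

    Uses the training-time z-scoring and score standardization, so scores
    are comparable across calls; scoring the training data reproduces the
    stored scores exactly.
    """
    cols = list(fit.spec.indicators)
    missing = [c for c in cols if c not in new_data.columns]
    if missing:
        raise KeyError(f"missing indicators: {missing}")
    xz = (new_data[cols].to_numpy(dtype=float) - fit.indicator_means.to_numpy()) / fit.indicator_sds.to_numpy()
    raw = xz @ fit.weights.to_numpy()
    return pd.Series((raw - fit.raw_mean) / fit.raw_sd, index=new_data.index, name=fit.spec.name)


def standardized_weights(fit: CompositeFit) -> pd.Series:
    """Weights expressed per unit of the *standardized composite score*.

    The effective standardized edge from indicator ``t`` into any model that
    uses the standardized composite is ``weight_t / raw_sd`` times the
    composite's own coefficient; exposed for effect decomposition.
    """
    return fit.weights / fit.raw_sd
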