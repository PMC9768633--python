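"""Principal-component weighting and factor scoring per subdimension.

Each of the three subdimensions (education, employment, income) pools its
three harmonized indicators over all regions and the years 2001-2019 —
early years are excluded from the fit because they contain imputed values
— z-standardizes them on the pooled sample, and extracts the first
principal component of their 3x3 correlation matrix.  The component's
loadings (correlations of the indicators with the component) become the
indicator weights; squared loadings normalized to 100 give the share of
each indicator within its dimension, and a third of that its share in the
total index.  Scores use the regression method, ``w_i = lambda_i / eta``
applied to the pooled z-scores; the standardization constants are frozen
from the fit so the years 1998-2000 are scored on the same scale.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .regions import DIMENSIONS, IndicatorSpec

__all__ = [
    "DimensionPCA",
    "shares_from_loadings",
    "loading_table",
    "WeightingError",
]

POOL_YEARS = (2001, 2019)


class WeightingError(ValueError):
    pass


class DimensionPCA(BaseEstimator, TransformerMixin):
    """First-principal-component weights for one subdimension.

    Parameters
    ----------
    indicators : sequence of str
        The indicator (column) names of the dimension, typically three.
    signs : mapping indicator -> {+1, -1}
        Deprivation polarity; +1 for deprivation-increasing indicators.
        Used to orient the component so that higher scores mean more
        deprivation.
    min_explained : float
        Warn when the first component explains less than this fraction
        of the dimension's variance (weak one-dimensionality).

    Attributes
    ----------
    loadings_ : pd.Series
        Signed loadings of the indicators on the first component.
    eigenvalue_ : float
        Variance of the first component (= sum of squared loadings).
    eigenvalues_ : np.ndarray
        All eigenvalues, descending; the second and third are the
        one-dimensionality diagnostics.
    mean_, scale_ : pd.Series
        Pooled standardization constants, frozen at fit time.
    """

    def __init__(self, indicators: Sequence[str],
                 signs: Mapping[str, int] | None = None,
                 min_explained: float = 0.5) -> None:
        self.indicators = list(indicators)
        self.signs = signs
        self.min_explained = min_explained

    def fit(self, X: pd.DataFrame, y=None) -> "DimensionPCA":
        Z = X[self.indicators].astype(float)
        if Z.isna().any().any():
            raise WeightingError("missing cells in the PCA pool")
        self.mean_ = Z.mean()
        self.scale_ = Z.std(ddof=1)
        if (self.scale_ == 0).any():
            flat = self.scale_.index[self.scale_ == 0].tolist()
            raise WeightingError(f"zero pooled variance for {flat}")
        Zs = (Z - self.mean_) / self.scale_
        corr = np.corrcoef(Zs.to_numpy().T)
        w, v = np.linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        load = v[:, 0] * np.sqrt(w[0])
        if self.signs is not None:
            sgn = np.array([self.signs[c] for c in self.indicators], float)
            if load @ sgn < 0:
                load = -load
        elif load.sum() < 0:
            load = -load
        self.loadings_ = pd.Series(load, index=self.indicators)
        self.eigenvalue_ = float(w[0])
        self.eigenvalues_ = w
        self.explained_ = float(w[0] / w.sum())
        if self.explained_ < self.min_explained:
            warnings.warn(
                f"first component explains only {self.explained_:.1%} of "
                f"the variance of {self.indicators}; the dimension may not "
                "be one-dimensional", stacklevel=2)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Regression-method factor scores on the frozen pooled scale."""
        Zs = (X[self.indicators] - self.mean_) / self.scale_
        w = self.loadings_ / self.eigenvalue_
        return Zs.to_numpy() @ w.to_numpy()


def shares_from_loadings(loadings: Sequence[float] | pd.Series
                         ) -> pd.DataFrame:
    """Indicator weight shares from first-component loadings.

    ``share_dimension = 100 * lambda_i^2 / sum_j lambda_j^2`` and
    ``share_gisd = share_dimension / 3`` (each dimension enters the total
    index with weight one third).  Values are returned at full precision;
    rounding is a display concern.
    """
    lam = pd.Series(loadings, dtype=float)
    ss = float((lam ** 2).sum())
    if ss == 0:
        raise WeightingError("all-zero loadings")
    share = 100.0 * lam ** 2 / ss
    return pd.DataFrame({"loading": lam, "share_dimension": share,
                         "share_gisd": share / 3.0})


def loading_table(fitted: Mapping[str, DimensionPCA],
                  specs: Mapping[str, IndicatorSpec] | None = None
                  ) -> pd.DataFrame:
    """Assemble the per-dimension loading/share table.

    One row per indicator: dimension, loading, eigenvalue of the first
    component, within-dimension share (percent) and share of the total
    index (percent); plus the second/third eigenvalues as diagnostics.
    """
    frames = []
    for dim in DIMENSIONS:
        if dim not in fitted:
            continue
        pca = fitted[dim]
        tab = shares_from_loadings(pca.loadings_)
        tab.insert(0, "dimension", dim)
        tab["eigenvalue"] = pca.eigenvalue_
        tab["eigenvalue_2"] = pca.eigenvalues_[1]
        tab["eigenvalue_3"] = pca.eigenvalues_[2]
        frames.append(tab)
    out = pd.concat(frames)
    out.index.name = "indicator"
    return out.reset_index()
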