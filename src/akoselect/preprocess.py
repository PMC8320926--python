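"""Missingness filtering, KNN imputation and standardization.

The preprocessing chain applied before knockoff filtering is

1. the *t% rule*: keep a metabolite only if it has an observed, nonzero
   intensity in at least ``t`%` of samples (``t = 0`` keeps everything;
   ``t = 100`` keeps only complete metabolites);
2. K-nearest-neighbour imputation of the remaining missing entries, over
   nearest *samples*, with distances computed on co-observed metabolites;
3. per-metabolite standardization to zero mean and unit variance
   (denominator ``n - 1``).

Each step is exposed both as a scikit-learn transformer (composable in a
:class:`sklearn.pipeline.Pipeline`) and as a DataFrame-in/DataFrame-out
function.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.impute import KNNImputer
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "MissingnessThresholdFilter",
    "SampleKNNImputer",
    "UnitVarianceScaler",
    "PreprocessReport",
    "t_percent_filter",
    "knn_impute",
    "standardize",
]


@dataclass
class PreprocessReport:
    """Provenance of one preprocessing pass."""

    t: float
    kept_metabolites: list[str]
    dropped_metabolites: list[str]
    imputation_k: int | None = None
    standardization: dict[str, dict[str, float]] = field(default_factory=dict)


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


class MissingnessThresholdFilter(SelectorMixin, BaseEstimator):
    """Drop metabolites observed (nonzero) in fewer than ``t``% of samples.

    Parameters
    ----------
    t : float
        Threshold in percent, in ``[0, 100]``.  A metabolite is kept iff its
        count of observed nonzero entries is at least ``ceil(t/100 * n)``.
        ``t = 0`` disables filtering entirely; ``t = 100`` keeps exactly the
        complete metabolites.
    """

    def __init__(self, t: float = 0.0):
        self.t = t

    def fit(self, X, y=None):
        if not 0 <= self.t <= 100:
            raise ValueError(f"t must lie in [0, 100], got {self.t}")
        arr = _as_array(X)
        n = arr.shape[0]
        self.n_features_in_ = arr.shape[1]
        observed = (~np.isnan(arr)) & (arr != 0)
        counts = observed.sum(axis=0)
        if self.t == 0:
            mask = np.ones(arr.shape[1], dtype=bool)
        else:
            mask = counts >= math.ceil(self.t / 100.0 * n)
        if not mask.any():
            raise ValueError(
                f"t={self.t}% removes every metabolite; the pipeline cannot proceed"
            )
        self.observed_counts_ = counts
        self.support_mask_ = mask
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def __sklearn_tags__(self):  # pragma: no cover - sklearn plumbing
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        return tags


class SampleKNNImputer(TransformerMixin, BaseEstimator):
    """KNN imputation over nearest *samples*.

    A missing entry ``(i, j)`` is filled with the average of metabolite
    ``j``'s values among the ``k`` nearest samples that observed ``j``;
    distances between samples are Euclidean over their co-observed
    metabolites, rescaled by the number of co-observed coordinates.  When no
    candidate donor observes ``j`` the metabolite's observed mean is used.
    Delegates to :class:`sklearn.impute.KNNImputer`, which implements exactly
    these semantics.
    """

    def __init__(self, k: int = 10):
        self.k = k

    def fit(self, X, y=None):
        arr = _as_array(X)
        n = arr.shape[0]
        if self.k < 1 or self.k >= n:
            raise ValueError(f"k must satisfy 1 <= k < n_samples={n}, got {self.k}")
        if np.isnan(arr).all(axis=0).any():
            bad = np.nonzero(np.isnan(arr).all(axis=0))[0].tolist()
            raise ValueError(
                f"metabolite columns {bad} have no observed values; drop them "
                "(t% filtering with t > 0 guarantees this cannot happen)"
            )
        self.n_features_in_ = arr.shape[1]
        self._imputer = KNNImputer(n_neighbors=self.k, weights="uniform")
        self._imputer.fit(arr)
        return self

    def transform(self, X):
        check_is_fitted(self, "_imputer")
        arr = _as_array(X)
        out = self._imputer.transform(arr)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    def __sklearn_tags__(self):  # pragma: no cover - sklearn plumbing
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        return tags


class UnitVarianceScaler(TransformerMixin, BaseEstimator):
    """Standardize each metabolite to mean 0, SD 1 (denominator ``n - 1``).

    Constant metabolites cannot be scaled and are dropped with a logged
    warning.  Missing entries are an error: imputation must come first.
    """

    def fit(self, X, y=None):
        arr = _as_array(X)
        if np.isnan(arr).any():
            raise ValueError("standardization requires a complete table; impute first")
        self.n_features_in_ = arr.shape[1]
        self.means_ = arr.mean(axis=0)
        self.sds_ = arr.std(axis=0, ddof=1)
        self.support_mask_ = self.sds_ > 0
        if not self.support_mask_.all():
            n_const = int((~self.support_mask_).sum())
            logger.warning("dropping %d constant metabolite column(s)", n_const)
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        arr = _as_array(X)
        if np.isnan(arr).any():
            raise ValueError("standardization requires a complete table; impute first")
        keep = self.support_mask_
        out = (arr[:, keep] - self.means_[keep]) / self.sds_[keep]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns[keep])
        return out


# ---------------------------------------------------------------------------
# DataFrame-level functional API


def t_percent_filter(
    table: pd.DataFrame, t: float
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Apply the t% rule to a feature table (NaN = missing)."""
    f = MissingnessThresholdFilter(t=t).fit(table)
    keep = f.support_mask_
    report = PreprocessReport(
        t=t,
        kept_metabolites=list(table.columns[keep]),
        dropped_metabolites=list(table.columns[~keep]),
    )
    return table.loc[:, keep], report


def knn_impute(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill every missing entry by sample-space KNN averaging."""
    if not table.isna().to_numpy().any():
        return table.copy()
    return SampleKNNImputer(k=k).fit(table).transform(table)


def standardize(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """Z-score each metabolite; returns the applied means and SDs."""
    sc = UnitVarianceScaler().fit(table)
    out = sc.transform(table)
    means = pd.Series(sc.means_[sc.support_mask_], index=out.columns)
    sds = pd.Series(sc.sds_[sc.support_mask_], index=out.columns)
    return out, (means, sds)
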