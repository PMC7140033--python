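"""Filtering, normalization and elementary fold-change transforms.

The inference steps downstream assume complete, log2-scale, quantile-
normalized matrices; this module provides the row filters (zero-variance
removal, SD-quantile selection), quantile normalization, the log2 transform
and the qPCR delta-delta-Ct fold change.

Each step is exposed both as a domain-level function operating on
:class:`~integromics.model.ExpressionMatrix` and as a scikit-learn style
transformer operating on ``(n_samples, n_features)`` arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .model import ExpressionMatrix, FilterReport

_ZERO_VAR_TOL = 1e-12


# ---------------------------------------------------------------------------
# core numerics (feature-major arrays: rows are features, columns samples)
# ---------------------------------------------------------------------------

def _zero_variance_mask(values: np.ndarray) -> np.ndarray:
    """True for rows whose sample variance is exactly 0 (within 1e-12)."""
    return np.var(values, axis=1, ddof=0) <= _ZERO_VAR_TOL


def _sd_cutoff(values: np.ndarray, q: float) -> tuple[np.ndarray, float]:
    sds = np.std(values, axis=1, ddof=1)
    sds[sds <= _ZERO_VAR_TOL] = 0.0  # constant rows: don't rank float dust
    # linear-interpolation ("type 7") quantile convention, pinned for
    # bit-exact reproducibility; ties at the cutoff are retained (>=).
    cutoff = float(np.quantile(sds, q))
    return sds >= cutoff, cutoff


def _quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    """Replace each column's value at rank r by the mean across columns of
    rank-r values, so every column ends with the identical distribution."""
    order = np.argsort(values, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n_rows, n_cols = values.shape
    row_idx = np.arange(n_rows)[:, None]
    ranks[order, np.arange(n_cols)[None, :]] = row_idx
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    return reference[ranks]


# ---------------------------------------------------------------------------
# domain-level operations
# ---------------------------------------------------------------------------

def remove_zero_variance(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop features expressed at the same level in every sample (variance 0).

    Such features are uninformative for any stage contrast; the study design
    that motivates this package removed them before all downstream analysis.
    """
    if matrix.shape[1] < 1:
        raise ValueError("need at least one sample")
    matrix.require_complete("zero-variance filtering")
    mask = _zero_variance_mask(matrix.values)
    kept = matrix.data.loc[~mask]
    report = FilterReport(
        n_input=len(matrix.data),
        n_removed=int(mask.sum()),
        n_retained=len(kept),
        rule="zero_variance",
        threshold=0.0,
    )
    return ExpressionMatrix(kept, matrix.kind, raw=matrix.raw), report


def sd_quantile_filter(
    matrix: ExpressionMatrix, q: float = 0.25
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep features whose across-sample SD is at least the q-quantile of all
    row SDs (default: drop the lowest-variation quartile as expression noise)."""
    if not (0.0 <= q < 1.0):
        raise ValueError(f"q must be in [0, 1), got {q}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples to compute row SDs")
    matrix.require_complete("SD-quantile filtering")
    mask, cutoff = _sd_cutoff(matrix.values, q)
    kept = matrix.data.loc[mask]
    report = FilterReport(
        n_input=len(matrix.data),
        n_removed=int((~mask).sum()),
        n_retained=len(kept),
        rule=f"sd_quantile(q={q})",
        threshold=cutoff,
    )
    return ExpressionMatrix(kept, matrix.kind, raw=matrix.raw), report


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns so all samples share one empirical distribution."""
    matrix.require_complete("quantile normalization")
    values = _quantile_normalize_values(matrix.values)
    data = pd.DataFrame(values, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(data, matrix.kind, raw=matrix.raw)


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); input values must be non-negative."""
    matrix.require_complete("log transform")
    values = matrix.values
    if (values < 0).any():
        raise ValueError("log transform requires non-negative values")
    data = pd.DataFrame(
        np.log2(values + pseudocount),
        index=matrix.data.index,
        columns=matrix.data.columns,
    )
    return ExpressionMatrix(data, matrix.kind, raw=False)


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """qPCR fold change by the delta-delta-Ct method: 2**-ddCt with
    ddCt = (Ct_target,sample - Ct_ref,sample) - (Ct_target,cal - Ct_ref,cal)."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_cal, ct_ref_cal):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# scikit-learn style transformers (X is samples x features)
# ---------------------------------------------------------------------------

class _FeatureMaskFilter(BaseEstimator, TransformerMixin):
    """Base for feature-selecting transformers; fit learns support_."""

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X)
        if X.shape[1] != self.support_.size:
            raise ValueError("X has a different number of features than at fit")
        return X[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


class ZeroVarianceFilter(_FeatureMaskFilter):
    """Drop features constant across all samples (variance exactly 0)."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.support_ = ~_zero_variance_mask(X.T)
        self.n_features_in_ = X.shape[1]
        self.report_ = FilterReport(
            n_input=X.shape[1],
            n_removed=int((~self.support_).sum()),
            n_retained=int(self.support_.sum()),
            rule="zero_variance",
            threshold=0.0,
        )
        return self


class SDQuantileFilter(_FeatureMaskFilter):
    """Keep features with across-sample SD >= the q-quantile of all SDs."""

    def __init__(self, q: float = 0.25):
        self.q = q

    def fit(self, X, y=None):
        if not (0.0 <= self.q < 1.0):
            raise ValueError(f"q must be in [0, 1), got {self.q}")
        X = check_array(X)
        self.support_, self.cutoff_ = _sd_cutoff(X.T, self.q)
        self.n_features_in_ = X.shape[1]
        self.report_ = FilterReport(
            n_input=X.shape[1],
            n_removed=int((~self.support_).sum()),
            n_retained=int(self.support_.sum()),
            rule=f"sd_quantile(q={self.q})",
            threshold=self.cutoff_,
        )
        return self


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Map every sample (row of X) onto the mean empirical distribution.

    ``fit`` stores the reference distribution (mean of the sorted sample
    vectors); ``transform`` replaces each sample's value of rank r by the
    reference value of rank r.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X)
        if X.shape[1] != self.reference_.size:
            raise ValueError("X has a different number of features than at fit")
        order = np.argsort(X, axis=1, kind="stable")
        ranks = np.empty_like(order)
        ranks[np.arange(X.shape[0])[:, None], order] = np.arange(X.shape[1])[None, :]
        return self.reference_[ranks]
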