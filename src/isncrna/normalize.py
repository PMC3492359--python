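"""Microarray normalization: quantile and global-rank-invariant-set (GRSN).

Both methods are exposed twice: as scikit-learn compatible transformers
operating on ``(n_arrays, n_probes)`` matrices (so they compose with
sklearn pipelines), and as module functions operating on
:class:`~isncrna.expression.ExpressionMatrix` (probes x samples, the
orientation expression tables are stored in).

Quantile normalization forces every array onto the common distribution
obtained by averaging sorted intensities across arrays; ties are resolved
by average rank.  GRSN anchors an intensity-dependent correction on a
*global rank-invariant set*: probes whose rank across arrays is most
stable, after trimming intensity extremes.  Each array's deviation from
the per-probe reference profile is smoothed against intensity (lowess) on
that set and subtracted genome-wide, which removes array-level distortions
without assuming most probes are unchanged in magnitude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.nonparametric.smoothers_lowess import lowess

from .expression import STATE_GRSN, STATE_QUANTILE, STATE_RAW, ExpressionMatrix


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization across arrays.

    Parameters
    ----------
    log2 : bool, default False
        Apply a log2 transform first (input must then be positive).

    Attributes
    ----------
    reference_ : ndarray of shape (n_probes,)
        Mean of sorted per-array values; the shared target distribution.
    """

    def __init__(self, log2: bool = False):
        self.log2 = log2

    def _prepare(self, X):
        X = check_array(X, dtype=np.float64, ensure_min_samples=1)
        if self.log2:
            if (X <= 0).any():
                raise ValueError("log2 quantile normalization requires positive intensities")
            X = np.log2(X)
        return X

    def fit(self, X, y=None):
        X = self._prepare(X)
        self.n_features_in_ = X.shape[1]
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = self._prepare(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        n = X.shape[1]
        grid = np.arange(1, n + 1, dtype=np.float64)
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            ranks = rankdata(X[i], method="average")
            # average ranks land between grid points; interpolation yields
            # the mean of the tied reference values
            out[i] = np.interp(ranks, grid, self.reference_)
        return out


class GRSNNormalizer(TransformerMixin, BaseEstimator):
    """Global rank-invariant set normalization.

    Parameters
    ----------
    invariant_fraction : float, default 0.1
        Fraction of probes (after intensity trimming) with the smallest
        cross-array rank spread used as the invariant anchor set.
    trim_fraction : float, default 0.05
        Fraction of probes discarded at each intensity extreme before the
        invariant set is chosen (rank spread is trivially small there).
    lowess_frac : float, default 0.4
        Lowess smoother span for the deviation-vs-intensity fit.
    log2 : bool, default False
        Apply log2 first.

    Attributes
    ----------
    reference_profile_ : ndarray of shape (n_probes,)
        Per-probe mean across the fitted arrays (log scale).
    invariant_idx_ : ndarray
        Indices of the rank-invariant probe set.
    """

    def __init__(
        self,
        invariant_fraction: float = 0.1,
        trim_fraction: float = 0.05,
        lowess_frac: float = 0.4,
        log2: bool = False,
    ):
        self.invariant_fraction = invariant_fraction
        self.trim_fraction = trim_fraction
        self.lowess_frac = lowess_frac
        self.log2 = log2

    def _prepare(self, X):
        X = check_array(X, dtype=np.float64)
        if self.log2:
            if (X <= 0).any():
                raise ValueError("GRSN on log2 scale requires positive intensities")
            X = np.log2(X)
        return X

    def fit(self, X, y=None):
        X = self._prepare(X)
        n_arrays, n_probes = X.shape
        if n_probes < 20:
            raise ValueError(f"GRSN needs at least 20 probes, got {n_probes}")
        self.n_features_in_ = n_probes
        ref = X.mean(axis=0)
        ranks = np.vstack([rankdata(row, method="average") for row in X])
        spread = ranks.max(axis=0) - ranks.min(axis=0)
        order = np.argsort(ref, kind="stable")
        n_trim = int(np.floor(self.trim_fraction * n_probes))
        eligible = order[n_trim : n_probes - n_trim] if n_trim else order
        n_inv = int(np.floor(self.invariant_fraction * n_probes))
        if n_inv < 10:
            raise ValueError(f"invariant set would hold {n_inv} probes (< 10)")
        inv = eligible[np.argsort(spread[eligible], kind="stable")[:n_inv]]
        self.reference_profile_ = ref
        self.invariant_idx_ = np.sort(inv)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_profile_")
        X = self._prepare(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        ref = self.reference_profile_
        inv = self.invariant_idx_
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            dev = X[i] - ref
            fit = lowess(dev[inv], ref[inv], frac=self.lowess_frac, it=2, return_sorted=True)
            # constant extrapolation beyond the invariant-set intensity range
            correction = np.interp(ref, fit[:, 0], fit[:, 1])
            out[i] = X[i] - correction
        return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2 then quantile-normalize a raw expression matrix."""
    if matrix.normalization_state != STATE_RAW:
        raise ValueError("quantile_normalize expects a raw matrix")
    norm = QuantileNormalizer(log2=True).fit_transform(matrix.data.to_numpy().T).T
    return ExpressionMatrix(
        pd.DataFrame(norm, index=matrix.data.index, columns=matrix.data.columns),
        normalization_state=STATE_QUANTILE,
    )


def grsn_normalize(matrix: ExpressionMatrix, invariant_fraction: float = 0.1) -> ExpressionMatrix:
    """log2 then GRSN-normalize a raw expression matrix."""
    if matrix.normalization_state != STATE_RAW:
        raise ValueError("grsn_normalize expects a raw matrix")
    est = GRSNNormalizer(invariant_fraction=invariant_fraction, log2=True)
    norm = est.fit_transform(matrix.data.to_numpy().T).T
    return ExpressionMatrix(
        pd.DataFrame(norm, index=matrix.data.index, columns=matrix.data.columns),
        normalization_state=STATE_GRSN,
    )
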