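"""Equal-width quantization between real feature vectors and bus levels.

`LevelQuantizer` is a scikit-learn transformer: `fit` learns per-feature
(lo, hi) ranges from a training table, `transform` maps real vectors to
m-bit integer levels, `inverse_transform` maps levels back to bin
midpoints. Missing values (NaN) pass through as unassigned arguments.

Uniform bins keep the digital/real conversion affine and order-preserving;
out-of-range values are clipped rather than rejected so that corrupted or
occluded cues still quantize.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .ric import DiscreteFunction

__all__ = ["LevelQuantizer", "fit_quantizer", "quantize", "dequantize"]


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("expected a vector or a 2-D table of feature vectors")
    return X


class LevelQuantizer(TransformerMixin, BaseEstimator):
    """Map n real features to 2**m_bits equal-width levels and back.

    Parameters
    ----------
    m_bits : int, default=5
        Bit depth; the number of levels per feature is ``2**m_bits``.

    Attributes
    ----------
    lo_, hi_ : ndarray of shape (n_features_in_,)
        Observed per-feature minimum / maximum over non-missing training
        entries. ``hi_ >= lo_``; a constant feature has ``lo_ == hi_`` and
        always quantizes to level 0.
    n_features_in_ : int

    Notes
    -----
    Level of value v: ``floor((v - lo) / (hi - lo) * 2**m)`` clipped to
    ``[0, 2**m - 1]``. Level ℓ dequantizes to the bin midpoint
    ``lo + (ℓ + 0.5) (hi - lo) / 2**m``, so quantize∘dequantize is the
    identity on levels and the round trip error is at most one bin width.
    """

    def __init__(self, m_bits: int = 5):
        self.m_bits = m_bits

    @property
    def n_levels(self) -> int:
        return 2 ** int(self.m_bits)

    def fit(self, X, y=None):
        if self.m_bits < 0:
            raise ValueError("m_bits must be non-negative")
        X = _as_2d(X)
        if X.shape[0] == 0:
            raise ValueError("cannot fit a quantizer on an empty table")
        observed = ~np.isnan(X)
        if not observed.any(axis=0).all():
            bad = int(np.nonzero(~observed.any(axis=0))[0][0])
            raise ValueError(f"feature {bad} has no observed values")
        self.n_features_in_ = X.shape[1]
        self.lo_ = np.nanmin(X, axis=0)
        self.hi_ = np.nanmax(X, axis=0)
        return self

    def _check_width(self, X) -> np.ndarray:
        check_is_fitted(self, "lo_")
        X = _as_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X

    def transform(self, X) -> np.ndarray:
        """Real values to integer levels; NaN maps to -1 (unassigned)."""
        X = self._check_width(X)
        span = self.hi_ - self.lo_
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(span > 0, (X - self.lo_) / np.where(span > 0, span, 1.0), 0.0)
        levels = np.floor(frac * self.n_levels)
        levels = np.clip(levels, 0, self.n_levels - 1)
        levels = np.where(np.isnan(X), -1, levels)
        return levels.astype(np.int64)

    def inverse_transform(self, L) -> np.ndarray:
        """Integer levels to bin midpoints; level -1 maps to NaN."""
        check_is_fitted(self, "lo_")
        L = np.asarray(L)
        squeeze = L.ndim == 1
        if squeeze:
            L = L[None, :]
        if L.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {L.shape[1]}"
            )
        span = self.hi_ - self.lo_
        vals = self.lo_ + (L + 0.5) * span / self.n_levels
        vals = np.where(L < 0, np.nan, vals)
        return vals[0] if squeeze else vals

    # --- DiscreteFunction bridge -------------------------------------------------

    def to_function(self, v) -> DiscreteFunction:
        """Quantize one real vector into a DiscreteFunction on the bus."""
        levels = self.transform(np.asarray(v, dtype=float)[None, :])[0]
        return DiscreteFunction.from_arrays(
            np.maximum(levels, 0), levels >= 0, self.n_levels
        )

    def from_function(self, f: DiscreteFunction) -> np.ndarray:
        """Dequantize a DiscreteFunction back to a real vector (NaN = unassigned)."""
        check_is_fitted(self, "lo_")
        if f.n_args != self.n_features_in_ or f.n_levels != self.n_levels:
            raise ValueError("function geometry does not match quantizer")
        L = np.where(f.assigned, f.levels, -1)
        return self.inverse_transform(L[None, :])[0]


def fit_quantizer(feature_table, m_bits: int) -> LevelQuantizer:
    """Fit per-feature ranges on a table of real vectors (NaN = missing)."""
    return LevelQuantizer(m_bits=m_bits).fit(feature_table)


def quantize(v, q: LevelQuantizer) -> DiscreteFunction:
    return q.to_function(v)


def dequantize(f: DiscreteFunction, q: LevelQuantizer) -> np.ndarray:
    return q.from_function(f)
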