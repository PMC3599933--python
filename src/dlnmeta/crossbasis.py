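"""Lagged-exposure matrices and cross-basis design construction.

The cross-basis combines a predictor-space basis ``Z`` and a lag-space basis
``C`` into the design matrix ``W`` whose coefficients describe a
simultaneously non-linear and lagged exposure-response surface.

Column ordering convention (important!): the predictor-basis index ``j``
varies fastest within the lag-basis index ``k``, i.e. the coefficient vector
is stacked as ``eta_11, ..., eta_{v_x,1}, eta_12, ...``.  This is the
ordering under which the dimension-reduction matrices are literal Kronecker
products (``I ⊗ z``, ``c ⊗ I``); note that some other implementations use
the transposed ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisMatrix, BasisSpec, make_basis

__all__ = ["LaggedExposureMatrix", "CrossBasis", "lag_matrix", "build_crossbasis"]


@dataclass
class LaggedExposureMatrix:
    """N x (L+1) matrix of lagged copies of the exposure series.

    ``values[t, l] == x[t - l]`` where defined; the first ``L`` rows contain
    NaN for lags reaching before the start of the series.
    """

    values: np.ndarray
    lags: np.ndarray


@dataclass
class CrossBasis:
    """Cross-basis design matrix with the metadata needed downstream."""

    W: np.ndarray
    var_spec: BasisSpec
    lag_spec: BasisSpec
    L: int
    x: np.ndarray

    @property
    def v_x(self) -> int:
        return self.var_spec.dimension()

    @property
    def v_lag(self) -> int:
        return self.lag_spec.dimension()

    @property
    def missing_rows(self) -> np.ndarray:
        return ~np.all(np.isfinite(self.W), axis=1)


def lag_matrix(x, L: int) -> LaggedExposureMatrix:
    """Shifted copies of ``x`` for lags ``0..L``, NaN-padded at the head."""
    xv = np.asarray(x, dtype=float).ravel()
    if L < 0:
        raise ValueError("L must be >= 0")
    if L >= xv.size:
        raise ValueError(f"L ({L}) must be < length of x ({xv.size})")
    n = xv.size
    q = np.full((n, L + 1), np.nan)
    for lag in range(L + 1):
        q[lag:, lag] = xv[: n - lag]
    return LaggedExposureMatrix(values=q, lags=np.arange(L + 1))


def build_crossbasis(x, var_spec: BasisSpec, lag_spec: BasisSpec, L: int) -> CrossBasis:
    """Assemble the N x (v_x * v_lag) cross-basis design matrix.

    ``W[t, (k-1)*v_x + j] = sum_l Z(x_{t-l})_j * C(l)_k`` — accumulated
    lag-by-lag so the full N x v_x x (L+1) intermediate array is never
    materialized.  Rows touching a missing lagged exposure come out NaN.
    """
    xv = np.asarray(x, dtype=float).ravel()
    q = lag_matrix(xv, L)
    c = make_basis(np.arange(L + 1), lag_spec).values  # (L+1) x v_lag
    v_x = var_spec.dimension()
    v_lag = lag_spec.dimension()
    w = np.zeros((xv.size, v_x * v_lag))
    for lag in range(L + 1):
        z_l = make_basis(q.values[:, lag], var_spec).values  # N x v_x
        for k in range(v_lag):
            w[:, k * v_x : (k + 1) * v_x] += z_l * c[lag, k]
    return CrossBasis(W=w, var_spec=var_spec, lag_spec=lag_spec, L=L, x=xv)
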