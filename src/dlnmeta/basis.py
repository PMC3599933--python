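"""Uni-dimensional basis functions for the predictor and lag spaces.

A :class:`BasisSpec` describes one basis (B-spline, natural cubic B-spline,
polynomial, linear, strata, threshold or constant) together with its knots;
:func:`make_basis` evaluates it at arbitrary points, producing the matrix
``Z`` (predictor space) or ``C`` (lag space) used to assemble cross-basis
designs and reduction matrices.

Centering is deliberately *not* applied here: the reference subtraction
``z(x) - z(cen)`` happens at prediction/reduction time, so the fitted design
stays in its plain uncentered parameterization and the reference value can be
changed after fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisSpec",
    "BasisMatrix",
    "make_basis",
    "place_lag_knots",
    "place_var_knots",
]

_KINDS = {
    "bspline",
    "natural_cubic",
    "poly",
    "linear",
    "strata",
    "threshold",
    "constant",
}


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a uni-dimensional basis.

    Parameters
    ----------
    kind
        One of ``bspline``, ``natural_cubic``, ``poly``, ``linear``,
        ``strata``, ``threshold``, ``constant``.
    degree
        Spline/polynomial degree (B-splines only; natural cubic is always
        cubic).
    internal_knots
        Strictly increasing knots strictly inside the boundary.
    boundary_knots
        Pair ``(lower, upper)``; required for spline kinds.
    intercept
        Whether the basis spans the constant function.
    center
        Optional reference value (predictor-space bases only); stored here
        for convenience but never applied by :func:`make_basis`.
    """

    kind: str
    degree: int = 3
    internal_knots: tuple[float, ...] = ()
    boundary_knots: Optional[tuple[float, float]] = None
    intercept: bool = False
    center: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown basis kind {self.kind!r}")
        object.__setattr__(self, "internal_knots", tuple(float(k) for k in self.internal_knots))
        if self.boundary_knots is not None:
            lo, hi = self.boundary_knots
            if not lo < hi:
                raise ValueError("boundary_knots must satisfy lower < upper")
            object.__setattr__(self, "boundary_knots", (float(lo), float(hi)))
        ik = np.asarray(self.internal_knots, dtype=float)
        if ik.size:
            if np.any(np.diff(ik) <= 0):
                raise ValueError("internal_knots must be strictly increasing")
            if self.boundary_knots is not None:
                lo, hi = self.boundary_knots
                if ik[0] <= lo or ik[-1] >= hi:
                    raise ValueError("internal_knots must lie strictly inside boundary_knots")
        if self.kind in ("bspline", "natural_cubic") and self.boundary_knots is None:
            raise ValueError(f"{self.kind} basis requires boundary_knots")
        if self.kind == "bspline" and self.degree < 1:
            raise ValueError("bspline degree must be >= 1")

    def dimension(self) -> int:
        """Number of basis functions (columns of the evaluated matrix)."""
        n = len(self.internal_knots)
        icpt = int(self.intercept)
        if self.kind == "bspline":
            return n + self.degree + icpt
        if self.kind == "natural_cubic":
            return n + 1 + icpt
        if self.kind == "poly":
            return self.degree + icpt
        if self.kind == "linear":
            return 1 + icpt
        if self.kind == "strata":
            return n + icpt
        if self.kind == "threshold":
            return max(n, 1) + icpt
        if self.kind == "constant":
            return 1
        raise AssertionError(self.kind)

    def with_center(self, center: Optional[float]) -> "BasisSpec":
        return replace(self, center=center)

    # -- plain-mapping round trip used by the YAML/JSON pipeline config -----
    def to_config(self) -> dict:
        cfg: dict = {"kind": self.kind, "intercept": self.intercept}
        if self.kind in ("bspline", "poly"):
            cfg["degree"] = self.degree
        if self.internal_knots:
            cfg["knots"] = list(self.internal_knots)
        if self.boundary_knots is not None:
            cfg["boundary"] = list(self.boundary_knots)
        if self.center is not None:
            cfg["center"] = self.center
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "BasisSpec":
        boundary = cfg.get("boundary")
        return cls(
            kind=cfg["kind"],
            degree=int(cfg.get("degree", 3)),
            internal_knots=tuple(cfg.get("knots", ())),
            boundary_knots=tuple(boundary) if boundary is not None else None,
            intercept=bool(cfg.get("intercept", False)),
            center=cfg.get("center"),
        )


@dataclass
class BasisMatrix:
    """An evaluated basis: rows are evaluation points, columns basis functions."""

    values: np.ndarray
    spec: BasisSpec
    eval_points: np.ndarray


def _padded_knots(spec: BasisSpec, degree: int) -> np.ndarray:
    lo, hi = spec.boundary_knots
    return np.concatenate(
        [np.full(degree + 1, lo), np.asarray(spec.internal_knots), np.full(degree + 1, hi)]
    )


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int, deriv: int = 0) -> np.ndarray:
    """Full B-spline design matrix, polynomial extrapolation outside boundary."""
    n_basis = len(knots) - degree - 1
    b = BSpline(knots, np.eye(n_basis), degree, extrapolate=True)
    if deriv:
        b = b.derivative(deriv)
    return b(x)


def _natural_cubic(x: np.ndarray, spec: BasisSpec) -> np.ndarray:
    # Cubic B-spline basis constrained to zero curvature at the boundary
    # knots, extended linearly beyond them (the classic restricted-cubic
    # construction).
    knots = _padded_knots(spec, 3)
    lo, hi = spec.boundary_knots
    n_basis = len(knots) - 4

    inside = np.clip(x, lo, hi)
    base = _bspline_design(inside, knots, 3)
    below, above = x < lo, x > hi
    if np.any(below):
        d = _bspline_design(np.array([lo]), knots, 3, deriv=1)
        base[below] += (x[below] - lo)[:, None] * d
    if np.any(above):
        d = _bspline_design(np.array([hi]), knots, 3, deriv=1)
        base[above] += (x[above] - hi)[:, None] * d

    const = _bspline_design(np.array([lo, hi]), knots, 3, deriv=2)
    if not spec.intercept:
        base = base[:, 1:]
        const = const[:, 1:]
    # Project onto the null space of the two curvature constraints.
    q, _ = np.linalg.qr(const.T, mode="complete")
    return base @ q[:, 2:]


def make_basis(eval_points: Sequence[float], spec: BasisSpec) -> BasisMatrix:
    """Evaluate ``spec`` at ``eval_points``.

    Missing (NaN) evaluation points yield all-NaN rows, which lets lagged
    designs propagate missingness naturally.
    """
    x = np.asarray(eval_points, dtype=float).ravel()
    ok = np.isfinite(x)
    out = np.full((x.size, spec.dimension()), np.nan)
    xv = x[ok]
    if xv.size:
        out[ok] = _eval_finite(xv, spec)
    return BasisMatrix(values=out, spec=spec, eval_points=x)


def _eval_finite(x: np.ndarray, spec: BasisSpec) -> np.ndarray:
    kind = spec.kind
    if kind == "constant":
        return np.ones((x.size, 1))
    if kind == "linear":
        cols = [x]
        if spec.intercept:
            cols.insert(0, np.ones_like(x))
        return np.column_stack(cols)
    if kind == "poly":
        powers = np.arange(0 if spec.intercept else 1, spec.degree + 1)
        return x[:, None] ** powers[None, :]
    if kind == "strata":
        # indicator per stratum above the reference (lowest) interval
        breaks = np.asarray(spec.internal_knots)
        idx = np.searchsorted(breaks, x, side="right")
        n_strata = breaks.size + 1
        full = np.equal(idx[:, None], np.arange(n_strata)[None, :]).astype(float)
        return full if spec.intercept else full[:, 1:]
    if kind == "threshold":
        knots = np.asarray(spec.internal_knots)
        cols = [np.maximum(x - k, 0.0) for k in knots]
        if spec.intercept:
            cols.insert(0, np.ones_like(x))
        return np.column_stack(cols)
    if kind == "bspline":
        knots = _padded_knots(spec, spec.degree)
        base = _bspline_design(x, knots, spec.degree)
        return base if spec.intercept else base[:, 1:]
    if kind == "natural_cubic":
        return _natural_cubic(x, spec)
    raise AssertionError(kind)


def place_lag_knots(L: int, nk: int) -> np.ndarray:
    """Knots equally spaced on the log-lag scale.

    ``knots_j = exp(j * log(L) / nk)`` for ``j = 0..nk-1``; for ``L=21,
    nk=3`` this gives (1.0, 2.76, 7.61).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if nk < 1:
        raise ValueError("nk must be >= 1")
    if nk >= L:
        raise ValueError("nk must be < L")
    j = np.arange(nk)
    return np.exp(j * np.log(L) / nk)


def place_var_knots(x: Sequence[float], nk: int, mode: str = "equal_values") -> np.ndarray:
    """Internal knots along the predictor range.

    ``equal_values`` splits ``[min(x), max(x)]`` into ``nk + 1`` equal
    intervals; ``quantiles`` uses equally spaced sample quantiles.
    """
    xv = np.asarray(x, dtype=float).ravel()
    xv = xv[np.isfinite(xv)]
    if xv.size == 0:
        raise ValueError("x has no finite values")
    if nk < 1:
        raise ValueError("nk must be >= 1")
    lo, hi = xv.min(), xv.max()
    if lo == hi:
        raise ValueError("x is constant; cannot place knots")
    probs = np.arange(1, nk + 1) / (nk + 1)
    if mode == "equal_values":
        return lo + (hi - lo) * probs
    if mode == "quantiles":
        return np.quantile(xv, probs)
    raise ValueError(f"unknown mode {mode!r}")
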