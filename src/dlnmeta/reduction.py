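"""Dimension reduction of cross-basis fits to one-dimensional summaries.

A fitted cross-basis surface carries ``v_x * v_lag`` coefficients.  Three
uni-dimensional summaries — the lag curve at a fixed exposure value
(*predictor-specific*), the exposure-response curve at a fixed lag
(*lag-specific*) and the *overall cumulative* exposure-response curve — are
exact linear transformations of those coefficients.  The reduction matrices
are Kronecker products:

    predictor-specific at x0:  M = I_(v_lag) ⊗ z(x0)^T      (v_lag rows)
    lag-specific at l0:        M = c(l0)^T ⊗ I_(v_x)        (v_x rows)
    overall cumulative:        M = (1^T C) ⊗ I_(v_x)        (v_x rows)

mapping (eta, V) to (theta, M V M^T).  The reduction is irreversible: M has
full row rank but fewer rows than columns.

For the predictor-specific summary the reference subtraction
``z(x0) - z(cen)`` is embedded in M, so the reduced lag curve is directly
relative to the reference; the other two summaries stay uncentered and are
centered at prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
from scipy import stats

from .basis import BasisSpec, make_basis

if TYPE_CHECKING:  # pragma: no cover
    from .twostage import FirstStageFit

__all__ = [
    "ReductionMatrix",
    "ReducedFit",
    "SummaryCurve",
    "reduction_matrix",
    "reduce_fit",
    "predict_reduced",
]

KINDS = ("predictor_specific", "lag_specific", "overall")

_Z95 = stats.norm.ppf(0.975)  # 1.959964...


@dataclass
class ReductionMatrix:
    M: np.ndarray
    kind: str
    at_value: Optional[float]
    var_spec: BasisSpec
    lag_spec: BasisSpec
    L: int


@dataclass
class ReducedFit:
    """Reduced coefficients and covariance for one summary type.

    This is the hand-off artifact between the first and second stage.
    """

    theta: np.ndarray
    vcov: np.ndarray
    kind: str
    at_value: Optional[float]
    basis_for_prediction: BasisSpec
    center: Optional[float] = None
    L: Optional[int] = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        self.vcov = np.asarray(self.vcov, dtype=float)
        if self.theta.size != self.basis_for_prediction.dimension():
            raise ValueError("theta length does not match prediction basis dimension")
        if self.vcov.shape != (self.theta.size, self.theta.size):
            raise ValueError("vcov shape does not match theta")

    def to_json(self) -> str:
        return json.dumps(
            {
                "theta": self.theta.tolist(),
                "vcov": self.vcov.tolist(),
                "kind": self.kind,
                "at_value": self.at_value,
                "spec": self.basis_for_prediction.to_config(),
                "center": self.center,
                "L": self.L,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "ReducedFit":
        d = json.loads(s)
        return cls(
            theta=np.asarray(d["theta"]),
            vcov=np.asarray(d["vcov"]),
            kind=d["kind"],
            at_value=d["at_value"],
            basis_for_prediction=BasisSpec.from_config(d["spec"]),
            center=d.get("center"),
            L=d.get("L"),
        )


@dataclass
class SummaryCurve:
    """A one-dimensional summary evaluated on a grid, with inference."""

    grid: np.ndarray
    fit: np.ndarray
    se: np.ndarray

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.fit)

    @property
    def rr_low(self) -> np.ndarray:
        return np.exp(self.fit - _Z95 * self.se)

    @property
    def rr_high(self) -> np.ndarray:
        return np.exp(self.fit + _Z95 * self.se)


def reduction_matrix(
    kind: str,
    at_value: Optional[float],
    var_spec: BasisSpec,
    lag_spec: BasisSpec,
    L: int,
    center: Optional[float] = None,
) -> ReductionMatrix:
    """Assemble the dimension-reducing matrix for one summary type.

    ``center`` only affects the predictor-specific kind, where the
    row ``z(x0) - z(center)`` replaces the raw basis row.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown reduction kind {kind!r}")
    v_x = var_spec.dimension()
    v_lag = lag_spec.dimension()
    if kind == "overall":
        if at_value is not None:
            raise ValueError("overall reduction takes no at_value")
        c = make_basis(np.arange(L + 1), lag_spec).values
        row = np.ones(L + 1) @ c  # 1^T C
        m = np.kron(row, np.eye(v_x))
    elif kind == "lag_specific":
        if at_value is None:
            raise ValueError("lag_specific reduction requires at_value")
        c0 = make_basis([at_value], lag_spec).values[0]
        m = np.kron(c0, np.eye(v_x))
    else:  # predictor_specific
        if at_value is None:
            raise ValueError("predictor_specific reduction requires at_value")
        z0 = make_basis([at_value], var_spec).values[0]
        if center is not None:
            z0 = z0 - make_basis([center], var_spec).values[0]
        m = np.kron(np.eye(v_lag), z0)
    return ReductionMatrix(M=m, kind=kind, at_value=at_value, var_spec=var_spec, lag_spec=lag_spec, L=L)


def reduce_fit(
    fit: "FirstStageFit",
    kind: str,
    at_value: Optional[float] = None,
    center: Optional[float] = None,
) -> ReducedFit:
    """Map a full cross-basis fit to a reduced summary: theta = M eta,
    V(theta) = M V(eta) M^T."""
    var_spec, lag_spec, L = fit.crossbasis_specs
    rm = reduction_matrix(kind, at_value, var_spec, lag_spec, L, center=center)
    eta = np.asarray(fit.eta, dtype=float).ravel()
    vcov = np.asarray(fit.vcov, dtype=float)
    if rm.M.shape[1] != eta.size:
        raise ValueError(
            f"reduction matrix expects {rm.M.shape[1]} coefficients, fit has {eta.size}"
        )
    theta = rm.M @ eta
    v = rm.M @ vcov @ rm.M.T
    basis = lag_spec if kind == "predictor_specific" else var_spec
    return ReducedFit(
        theta=theta,
        vcov=v,
        kind=kind,
        at_value=at_value,
        basis_for_prediction=basis,
        center=center,
        L=L,
    )


def predict_reduced(rf: ReducedFit, grid, cen: Optional[float] = None) -> SummaryCurve:
    """Evaluate a reduced summary on a grid with delta-method standard errors.

    For overall/lag-specific summaries the basis rows are centered at
    ``cen`` (defaulting to the center recorded on the fit); the
    predictor-specific summary is already relative to its reference and the
    lag-basis rows are used as-is.
    """
    g = np.asarray(grid, dtype=float).ravel()
    b = make_basis(g, rf.basis_for_prediction).values
    if rf.kind != "predictor_specific":
        c = cen if cen is not None else rf.center
        if c is None:
            raise ValueError("a centering value is required for this summary")
        b = b - make_basis([c], rf.basis_for_prediction).values
    fit = b @ rf.theta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", b, rf.vcov, b), 0.0))
    return SummaryCurve(grid=g, fit=fit, se=se)
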