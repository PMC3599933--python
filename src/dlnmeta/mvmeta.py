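"""Multivariate meta-analysis and meta-regression of vector-valued estimates.

Pools m location-specific coefficient vectors theta_i (length k, with known
within-location covariances S_i) under the model

    theta_i ~ N(U_i beta, S_i + Psi),      U_i = I_(k) ⊗ u_i^T,

where u_i holds the p meta-variables (first entry 1) and Psi is the
between-location covariance.  Estimation: fixed-effects GLS, or ML/REML with
beta profiled out by GLS and Psi parameterized through its log-Cholesky
factor (log diagonal, free off-diagonal), optimized by quasi-Newton with
numeric gradients.

beta is stacked outcome-major: the p meta-regression coefficients of the
first outcome come first, then those of the second, and so on — the layout
implied by U_i = I ⊗ u_i^T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MVMetaInput",
    "MVMetaModel",
    "HeterogeneityStats",
    "fit_mvmeta",
    "cochran_q",
    "wald_test",
    "mvmeta_predict",
]


@dataclass
class MVMetaInput:
    """Estimates to pool: m vectors of length k, their covariances, and the
    m x p meta-variable design (first column all ones)."""

    thetas: list[np.ndarray]
    S_list: list[np.ndarray]
    u: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.thetas = [np.asarray(t, dtype=float).ravel() for t in self.thetas]
        self.S_list = [np.asarray(s, dtype=float) for s in self.S_list]
        m = len(self.thetas)
        if m == 0:
            raise ValueError("no studies supplied")
        if len(self.S_list) != m:
            raise ValueError("thetas and S_list length mismatch")
        k = self.thetas[0].size
        for i, (t, s) in enumerate(zip(self.thetas, self.S_list)):
            if t.size != k:
                raise ValueError(f"study {i}: theta length {t.size} != {k}")
            if s.shape != (k, k):
                raise ValueError(f"study {i}: S shape {s.shape} != ({k},{k})")
        if self.u is None:
            self.u = np.ones((m, 1))
        else:
            self.u = np.asarray(self.u, dtype=float)
            if self.u.ndim == 1:
                self.u = self.u[:, None]
            if self.u.shape[0] != m:
                raise ValueError("u row count != number of studies")
        if m < self.u.shape[1]:
            raise ValueError("more meta-variables than studies")

    @property
    def m(self) -> int:
        return len(self.thetas)

    @property
    def k(self) -> int:
        return self.thetas[0].size

    @property
    def p(self) -> int:
        return self.u.shape[1]


@dataclass
class MVMetaModel:
    beta: np.ndarray
    vcov_beta: np.ndarray
    Psi: np.ndarray
    xi: Optional[np.ndarray]
    method: str
    loglik: float
    converged: bool
    k: int
    p: int
    m: int


@dataclass
class HeterogeneityStats:
    Q: float
    df: int
    p_value: float
    I2: float


def _u_kron(u_row: np.ndarray, k: int) -> np.ndarray:
    return np.kron(np.eye(k), u_row[None, :])  # k x kp


def _gls(inp: MVMetaInput, Psi: np.ndarray):
    """GLS of theta on the Kronecker-expanded design with weights
    (S_i + Psi)^-1; returns beta, its covariance, and the residual/logdet
    pieces needed by the likelihoods.

    Vectorized over studies: U_i^T W U_i collapses to W ⊗ u_i u_i^T, so the
    normal equations are assembled with batched small-matrix algebra.
    """
    k, p, m = inp.k, inp.p, inp.m
    kp = k * p
    sarr = np.stack(inp.S_list)  # m x k x k
    T = np.vstack(inp.thetas)  # m x k
    u = inp.u
    sigma = sarr + Psi[None, :, :]
    try:
        cf = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        for i in range(m):
            try:
                np.linalg.cholesky(sigma[i])
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"singular marginal covariance for study {i}"
                ) from err
        raise
    sum_logdet = 2.0 * float(np.sum(np.log(np.diagonal(cf, axis1=1, axis2=2))))
    eye = np.broadcast_to(np.eye(k), (m, k, k))
    invs = np.linalg.solve(sigma, eye)
    A = np.einsum("ijk,ip,iq->jpkq", invs, u, u).reshape(kp, kp)
    sol = np.einsum("ijk,ik->ij", invs, T)
    b = np.einsum("ij,ip->jp", sol, u).ravel()
    vcov = np.linalg.inv(A)
    beta = vcov @ b
    resid = T - u @ beta.reshape(k, p).T
    rss = float(np.einsum("ij,ijk,ik->", resid, invs, resid))
    _, logdet_A = np.linalg.slogdet(A)
    return beta, vcov, rss, sum_logdet, logdet_A


def _loglik(inp: MVMetaInput, Psi: np.ndarray, restricted: bool) -> float:
    m, k, p = inp.m, inp.k, inp.p
    _, _, rss, sum_logdet, logdet_A = _gls(inp, Psi)
    n = m * k
    ll = -0.5 * (sum_logdet + rss)
    if restricted:
        ll -= 0.5 * logdet_A
        ll -= 0.5 * (n - k * p) * np.log(2.0 * np.pi)
    else:
        ll -= 0.5 * n * np.log(2.0 * np.pi)
    return ll


def _xi_to_psi(xi: np.ndarray, k: int) -> np.ndarray:
    """Log-Cholesky: xi holds the lower triangle row-wise, diagonal on the
    log scale."""
    chol = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(i + 1):
            if i == j:
                chol[i, j] = np.exp(xi[idx])
            else:
                chol[i, j] = xi[idx]
            idx += 1
    return chol @ chol.T


def _psi_to_xi(Psi: np.ndarray) -> np.ndarray:
    k = Psi.shape[0]
    chol = np.linalg.cholesky(Psi + 1e-12 * np.eye(k))
    xi = []
    for i in range(k):
        for j in range(i + 1):
            xi.append(np.log(max(chol[i, j], 1e-8)) if i == j else chol[i, j])
    return np.asarray(xi)


def fit_mvmeta(inp: MVMetaInput, method: str = "reml") -> MVMetaModel:
    """Fit the multivariate meta-analysis / meta-regression model.

    method: ``fixed`` (Psi = 0, GLS), ``ml`` or ``reml``.
    """
    if method not in ("fixed", "ml", "reml"):
        raise ValueError(f"unknown method {method!r}")
    k, p, m = inp.k, inp.p, inp.m
    if method == "fixed":
        Psi = np.zeros((k, k))
        beta, vcov, rss, sum_logdet, _ = _gls(inp, Psi)
        ll = -0.5 * (sum_logdet + rss + m * k * np.log(2 * np.pi))
        return MVMetaModel(beta, vcov, Psi, None, method, ll, True, k, p, m)
    if m < 2:
        raise ValueError("random-effects estimation requires at least 2 studies")

    restricted = method == "reml"

    # start: Psi = 0.1 * diag of the weighted variance of the thetas
    T = np.vstack(inp.thetas)
    w = np.array([1.0 / max(np.trace(S) / k, 1e-12) for S in inp.S_list])
    w = w / w.sum()
    mu = w @ T
    var = np.maximum(w @ (T - mu) ** 2, 1e-8)
    xi0 = _psi_to_xi(np.diag(0.1 * var))

    def negll(xi: np.ndarray) -> float:
        Psi = _xi_to_psi(xi, k)
        try:
            return -_loglik(inp, Psi, restricted)
        except np.linalg.LinAlgError:
            return 1e12

    res = optimize.minimize(
        negll,
        xi0,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    Psi = _xi_to_psi(res.x, k)
    beta, vcov, _, _, _ = _gls(inp, Psi)
    return MVMetaModel(
        beta=beta,
        vcov_beta=vcov,
        Psi=Psi,
        xi=res.x,
        method=method,
        loglik=-res.fun,
        converged=bool(res.success or res.fun < negll(xi0)),
        k=k,
        p=p,
        m=m,
    )


def cochran_q(inp: MVMetaInput) -> HeterogeneityStats:
    """Multivariate Cochran Q on fixed-effects GLS residuals, with the
    associated I^2 = max(0, (Q - df)/Q) * 100."""
    k, p, m = inp.k, inp.p, inp.m
    Psi = np.zeros((k, k))
    beta, _, rss, _, _ = _gls(inp, Psi)
    q = float(rss)
    df = m * k - k * p
    pval = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityStats(Q=q, df=df, p_value=pval, I2=i2)


def wald_test(model: MVMetaModel, block: Sequence[int]) -> dict:
    """Wald chi-square test that a block of beta coefficients is zero."""
    idx = np.asarray(block, dtype=int)
    b = model.beta[idx]
    v = model.vcov_beta[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(v, b))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular covariance block in Wald test") from err
    df = idx.size
    return {"stat": stat, "df": df, "p": float(stats.chi2.sf(stat, df))}


def covariate_block(model: MVMetaModel, covariate: int) -> np.ndarray:
    """Indices of the k beta entries belonging to one meta-variable."""
    return covariate + model.p * np.arange(model.k)


def mvmeta_predict(model: MVMetaModel, u_new: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled coefficient vector (and covariance) at meta-variable values
    ``u_new``; composable with ``reduction.predict_reduced``."""
    u = np.asarray(u_new, dtype=float).ravel()
    if u.size != model.p:
        raise ValueError(f"u_new must have length {model.p}")
    uk = _u_kron(u, model.k)
    theta = uk @ model.beta
    vcov = uk @ model.vcov_beta @ uk.T
    return theta, vcov
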