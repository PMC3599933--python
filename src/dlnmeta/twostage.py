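"""End-to-end two-stage pipeline.

Stage one fits, per location, an overdispersed Poisson time-series
regression of daily counts on a cross-basis of the exposure plus a long-term
trend spline and day-of-week indicators, and reduces the fitted surface to
one-dimensional summaries.  Stage two pools the reduced coefficients across
locations by multivariate meta-analysis (optionally meta-regression on
location-level variables) and derives pooled curves, heterogeneity
statistics and the exposure value of minimum risk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .basis import BasisSpec, make_basis, place_lag_knots, place_var_knots
from .crossbasis import CrossBasis, build_crossbasis
from .mvmeta import (
    HeterogeneityStats,
    MVMetaInput,
    MVMetaModel,
    cochran_q,
    covariate_block,
    fit_mvmeta,
    mvmeta_predict,
    wald_test,
)
from .reduction import ReducedFit, SummaryCurve, predict_reduced, reduce_fit

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSeries",
    "FirstStageFit",
    "CrossPred",
    "PipelineConfig",
    "TwoStageResult",
    "fit_first_stage",
    "crosspred",
    "run_two_stage",
    "pooled_reduced_fit",
    "min_mortality_temperature",
    "fit_moving_average_model",
]


@dataclass
class RegionSeries:
    """Daily series for one location."""

    region_id: str
    dates: pd.DatetimeIndex
    deaths: np.ndarray
    temperature: np.ndarray
    latitude: Optional[float] = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.deaths = np.asarray(self.deaths)
        self.temperature = np.asarray(self.temperature, dtype=float)
        n = len(self.dates)
        if len(self.deaths) != n or len(self.temperature) != n:
            raise ValueError(f"region {self.region_id}: vectors must share the date length")
        if n > 1:
            step = np.diff(self.dates.view("int64"))
            if np.any(step <= 0):
                raise ValueError(f"region {self.region_id}: dates must be strictly increasing")
            if np.any(step != 86_400_000_000_000):
                raise ValueError(f"region {self.region_id}: dates must be consecutive days")
        d = self.deaths[~pd.isna(self.deaths)]
        if np.any(d < 0) or np.any(d != np.floor(d)):
            raise ValueError(f"region {self.region_id}: deaths must be non-negative integers")

    @property
    def n_days(self) -> int:
        return len(self.dates)


@dataclass
class FirstStageFit:
    """Cross-basis coefficient block of one location's regression."""

    eta: np.ndarray
    vcov: np.ndarray
    dispersion: float
    n_used: int
    crossbasis_specs: tuple[BasisSpec, BasisSpec, int]
    region_id: str = ""


@dataclass
class CrossPred:
    """Full bi-dimensional surface prediction on a predictor x lag grid."""

    grid_x: np.ndarray
    grid_lag: np.ndarray
    matfit: np.ndarray
    matse: np.ndarray
    cumfit: np.ndarray
    cumse: np.ndarray
    center: float


@dataclass
class PipelineConfig:
    """Modelling choices shared by every location.

    The defaults reproduce the reference temperature-mortality setup:
    quadratic B-spline for the predictor (2 internal knots at equally spaced
    values, boundary at the pooled range), natural cubic B-spline with
    intercept for lags 0..21 (3 internal knots equally spaced on the log
    scale), trend spline with 10 df/year, day-of-week indicators, summaries
    relative to a fixed reference.
    """

    L: int = 21
    var_degree: int = 2
    var_nknots: int = 2
    var_knots: Optional[Sequence[float]] = None
    var_boundary: Optional[Sequence[float]] = None
    lag_nknots: int = 3
    lag_knots: Optional[Sequence[float]] = None
    center: float = 17.0
    df_per_year: float = 10.0
    day_of_week: bool = True
    summary_values: Sequence[float] = (0.0, 22.0)
    meta_method: str = "reml"
    meta_variables: Sequence[str] = ()
    grid_step: float = 0.1

    @classmethod
    def from_mapping(cls, cfg: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(cfg) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**cfg)


def build_specs(config: PipelineConfig, pooled_exposure) -> tuple[BasisSpec, BasisSpec]:
    """Common predictor/lag basis specs from the pooled exposure distribution."""
    x = np.asarray(pooled_exposure, dtype=float)
    x = x[np.isfinite(x)]
    if config.var_boundary is not None:
        boundary = tuple(config.var_boundary)
    else:
        boundary = (float(x.min()), float(x.max()))
    if config.var_knots is not None:
        knots = tuple(config.var_knots)
    else:
        lo, hi = boundary
        probs = np.arange(1, config.var_nknots + 1) / (config.var_nknots + 1)
        knots = tuple(lo + (hi - lo) * probs)
    var_spec = BasisSpec(
        "bspline",
        degree=config.var_degree,
        internal_knots=knots,
        boundary_knots=boundary,
        intercept=False,
        center=config.center,
    )
    if config.lag_knots is not None:
        lag_knots = tuple(config.lag_knots)
    else:
        lag_knots = tuple(place_lag_knots(config.L, config.lag_nknots))
    lag_spec = BasisSpec(
        "natural_cubic",
        internal_knots=lag_knots,
        boundary_knots=(0.0, float(config.L)),
        intercept=True,
    )
    return var_spec, lag_spec


def _time_spline(n: int, df: int) -> np.ndarray:
    """Natural cubic spline of the day index with `df` columns, internal
    knots at equally spaced quantiles (== equally spaced values for a
    regular daily index)."""
    t = np.arange(n, dtype=float)
    probs = np.arange(1, df) / df
    knots = tuple(np.quantile(t, probs))
    spec = BasisSpec(
        "natural_cubic", internal_knots=knots, boundary_knots=(0.0, float(n - 1)), intercept=False
    )
    return make_basis(t, spec).values


def _confounder_design(series: RegionSeries, config: PipelineConfig) -> tuple[np.ndarray, list[str]]:
    n = series.n_days
    cols = [np.ones(n)]
    names = ["intercept"]
    if config.df_per_year > 0:
        df = int(round(config.df_per_year * n / 365.25))
        df = max(df, 2)
        ts = _time_spline(n, df)
        cols.append(ts)
        names += [f"time_s{i+1}" for i in range(ts.shape[1])]
    if config.day_of_week:
        dow = series.dates.dayofweek.to_numpy()  # Monday=0 baseline
        for d in range(1, 7):
            cols.append((dow == d).astype(float))
            names.append(f"dow_{d}")
    x = np.column_stack(cols)
    return x, names


def fit_first_stage(
    series: RegionSeries,
    config: PipelineConfig,
    var_spec: Optional[BasisSpec] = None,
    lag_spec: Optional[BasisSpec] = None,
) -> FirstStageFit:
    """Quasi-Poisson regression of counts on the cross-basis plus
    confounders; returns the cross-basis coefficient block with its
    Pearson-dispersion-scaled covariance."""
    if not np.any(np.isfinite(series.temperature)):
        raise ValueError(f"region {series.region_id}: exposure is all missing")
    if var_spec is None or lag_spec is None:
        var_spec, lag_spec = build_specs(config, series.temperature)
    cb = build_crossbasis(series.temperature, var_spec, lag_spec, config.L)
    conf, _ = _confounder_design(series, config)
    y = np.asarray(series.deaths, dtype=float)
    design = np.column_stack([cb.W, conf])
    ok = np.all(np.isfinite(design), axis=1) & np.isfinite(y)
    n_cb = cb.W.shape[1]
    x_fit, y_fit = design[ok], y[ok]
    if x_fit.shape[0] <= x_fit.shape[1]:
        raise ValueError(f"region {series.region_id}: not enough complete rows to fit")
    if np.linalg.matrix_rank(x_fit) < x_fit.shape[1]:
        raise ValueError(f"region {series.region_id}: rank-deficient design")
    model = sm.GLM(y_fit, x_fit, family=sm.families.Poisson())
    try:
        res = model.fit(scale="X2")
    except Exception as err:  # pragma: no cover
        raise RuntimeError(f"region {series.region_id}: first-stage fit failed: {err}") from err
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(f"region {series.region_id}: first-stage fit did not converge")
    eta = res.params[:n_cb]
    vcov = np.asarray(res.cov_params())[:n_cb, :n_cb]
    return FirstStageFit(
        eta=eta,
        vcov=vcov,
        dispersion=float(res.scale),
        n_used=int(ok.sum()),
        crossbasis_specs=(var_spec, lag_spec, config.L),
        region_id=series.region_id,
    )


def crosspred(fit: FirstStageFit, grid_x, grid_lag, cen: float) -> CrossPred:
    """Predict the full log-RR surface relative to the reference ``cen``,
    with delta-method standard errors, plus the lag-cumulated curve."""
    var_spec, lag_spec, L = fit.crossbasis_specs
    gx = np.asarray(grid_x, dtype=float).ravel()
    gl = np.asarray(grid_lag, dtype=float).ravel()
    zc = make_basis([cen], var_spec).values
    a = make_basis(gx, var_spec).values - zc  # |x| x v_x, centered
    cp = make_basis(gl, lag_spec).values  # |lag| x v_lag
    v_x, v_lag = var_spec.dimension(), lag_spec.dimension()
    h = fit.eta.reshape(v_lag, v_x).T  # eta_{jk}, j fastest in storage
    matfit = a @ h @ cp.T
    vcov = fit.vcov
    matse = np.empty_like(matfit)
    for li in range(gl.size):
        w = np.kron(cp[li : li + 1, :], a)  # |x| x (v_x v_lag)
        matse[:, li] = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", w, vcov, w), 0.0))
    csum = np.ones(gl.size) @ cp
    wc = np.kron(csum[None, :], a)
    cumfit = matfit.sum(axis=1)
    cumse = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", wc, vcov, wc), 0.0))
    return CrossPred(
        grid_x=gx, grid_lag=gl, matfit=matfit, matse=matse, cumfit=cumfit, cumse=cumse, center=cen
    )


@dataclass
class TwoStageResult:
    config: PipelineConfig
    var_spec: BasisSpec
    lag_spec: BasisSpec
    first_stage: dict[str, FirstStageFit]
    reduced: dict[str, dict[str, ReducedFit]]  # summary -> region -> fit
    meta: dict[str, MVMetaModel]
    heterogeneity: dict[str, HeterogeneityStats]
    wald: dict[str, dict]
    pooled: dict[str, SummaryCurve]
    grid_x: np.ndarray
    grid_lag: np.ndarray
    mmt: Optional[float] = None
    u: Optional[np.ndarray] = None  # second-stage design (m x p)
    region_ids: Optional[list[str]] = None

    def summary_labels(self) -> list[str]:
        return list(self.reduced)


def _summary_label(value: float) -> str:
    return f"pred_{value:g}"


def pooled_reduced_fit(
    result: "TwoStageResult", summary: str, u_new: Optional[Sequence[float]] = None
) -> ReducedFit:
    """Pooled-coefficient ReducedFit for one summary, optionally at given
    meta-variable values (defaults to intercept-only pooling)."""
    model = result.meta[summary]
    if u_new is None:
        if model.p > 1:
            raise ValueError("u_new required for a meta-regression model")
        u_new = [1.0]
    theta, vcov = mvmeta_predict(model, u_new)
    template = next(iter(result.reduced[summary].values()))
    return ReducedFit(
        theta=theta,
        vcov=vcov,
        kind=template.kind,
        at_value=template.at_value,
        basis_for_prediction=template.basis_for_prediction,
        center=template.center,
        L=template.L,
    )


def min_mortality_temperature(
    curve: SummaryCurve, reference: Optional[float] = None
) -> float:
    """Argmin of the pooled cumulative log-RR curve; ties broken toward the
    reference, boundary minima flagged with a warning."""
    fit = curve.fit
    grid = curve.grid
    best = np.flatnonzero(fit == fit.min())
    if best.size > 1 and reference is not None:
        best = best[np.argsort(np.abs(grid[best] - reference))]
    idx = int(best[0])
    if idx in (0, grid.size - 1):
        warnings.warn("minimum of the pooled curve lies on the grid boundary")
    return float(grid[idx])


def run_two_stage(dataset: Sequence[RegionSeries], config: PipelineConfig) -> TwoStageResult:
    """Full pipeline: per-region fit + reduction, second-stage pooling,
    heterogeneity, pooled curves and minimum-risk exposure."""
    if len(dataset) < 2:
        raise ValueError("two-stage analysis requires at least 2 regions")
    pooled_x = np.concatenate([s.temperature for s in dataset])
    var_spec, lag_spec = build_specs(config, pooled_x)
    cen = config.center

    first_stage: dict[str, FirstStageFit] = {}
    for s in dataset:
        logger.info("fitting first-stage model for region %s", s.region_id)
        first_stage[s.region_id] = fit_first_stage(s, config, var_spec, lag_spec)

    summaries = ["overall"] + [_summary_label(v) for v in config.summary_values]
    reduced: dict[str, dict[str, ReducedFit]] = {lab: {} for lab in summaries}
    for rid, fit in first_stage.items():
        reduced["overall"][rid] = reduce_fit(fit, "overall", center=cen)
        for v in config.summary_values:
            reduced[_summary_label(v)][rid] = reduce_fit(
                fit, "predictor_specific", at_value=v, center=cen
            )

    # second-stage design
    u = None
    if config.meta_variables:
        cols = [np.ones(len(dataset))]
        for name in config.meta_variables:
            if name != "latitude":
                raise ValueError(f"unknown meta-variable {name!r}")
            vals = [s.latitude for s in dataset]
            if any(v is None for v in vals):
                raise ValueError("latitude missing for some regions")
            cols.append(np.asarray(vals, dtype=float))
        u = np.column_stack(cols)

    meta: dict[str, MVMetaModel] = {}
    het: dict[str, HeterogeneityStats] = {}
    wald: dict[str, dict] = {}
    region_ids = [s.region_id for s in dataset]
    for lab in summaries:
        thetas = [reduced[lab][rid].theta for rid in region_ids]
        s_list = [reduced[lab][rid].vcov for rid in region_ids]
        inp = MVMetaInput(thetas=thetas, S_list=s_list, u=u)
        logger.info("pooling summary %s across %d regions", lab, len(dataset))
        meta[lab] = fit_mvmeta(inp, method=config.meta_method)
        het[lab] = cochran_q(inp)
        if u is not None and u.shape[1] > 1:
            for c in range(1, u.shape[1]):
                wald[lab] = wald_test(meta[lab], covariate_block(meta[lab], c))

    lo, hi = var_spec.boundary_knots
    grid_x = np.round(np.arange(np.ceil(lo / config.grid_step), np.floor(hi / config.grid_step) + 1) * config.grid_step, 10)
    grid_lag = np.arange(config.L + 1, dtype=float)

    # pooled curves at the average meta-variable profile (intercept-only when
    # no meta-variables are configured)
    u_mean = None if u is None else u.mean(axis=0)
    result = TwoStageResult(
        config=config,
        var_spec=var_spec,
        lag_spec=lag_spec,
        first_stage=first_stage,
        reduced=reduced,
        meta=meta,
        heterogeneity=het,
        wald=wald,
        pooled={},
        grid_x=grid_x,
        grid_lag=grid_lag,
        u=u,
        region_ids=region_ids,
    )
    for lab in summaries:
        rf = pooled_reduced_fit(result, lab, u_new=u_mean)
        grid = grid_x if rf.kind != "predictor_specific" else grid_lag
        result.pooled[lab] = predict_reduced(rf, grid, cen=cen)
    result.mmt = min_mortality_temperature(result.pooled["overall"], reference=cen)
    return result


def fit_moving_average_model(
    series: RegionSeries,
    window: int,
    config: PipelineConfig,
    var_spec: Optional[BasisSpec] = None,
) -> FirstStageFit:
    """Comparison model: spline of the 0..window moving-average exposure,
    expressed as a cross-basis with a constant lag basis (so the standard
    reduction machinery applies; its overall reduction matrix is
    (window+1) * I)."""
    if var_spec is None:
        var_spec, _ = build_specs(config, series.temperature)
    lag_spec = BasisSpec("constant")
    cfg = PipelineConfig(**{**config.__dict__, "L": window})
    return fit_first_stage(series, cfg, var_spec, lag_spec)
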