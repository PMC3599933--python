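"""Synthetic multi-region daily series with a known exposure-lag-response
surface, plus the CSV reader/writer for the pipeline's input dialect.

Regions share a common true coefficient vector ``eta_true`` on a cross-basis
surface; region-specific deviations are drawn from a known between-region
covariance, so both pipeline stages can be validated jointly.  Counts are
negative-binomial (NB1 / gamma-Poisson mixture) so that the variance is a
constant multiple of the mean, the generative analogue of quasi-Poisson
overdispersion; ``dispersion = 1`` gives exact Poisson counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .basis import BasisSpec
from .crossbasis import build_crossbasis
from .reduction import reduction_matrix
from .twostage import RegionSeries

__all__ = ["SimConfig", "SimTruth", "simulate_regions", "read_regions_csv", "write_regions_csv"]


@dataclass
class SimConfig:
    m: int = 10
    N: int = 2000
    var_spec: Optional[BasisSpec] = None
    lag_spec: Optional[BasisSpec] = None
    eta_true: Optional[np.ndarray] = None
    L: int = 21
    Psi_true: Optional[np.ndarray] = None  # between-region covariance of eta
    baseline_log_mean: float = np.log(50.0)
    season_amplitude: float = 0.2
    trend_slope: float = 0.0  # per day, on the log scale
    dispersion: float = 1.0
    exposure_mean: float = 11.0
    exposure_amplitude: float = 7.0
    exposure_sd: float = 2.5
    exposure_ar: float = 0.8
    start_date: str = "2000-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.N <= self.L:
            raise ValueError("need m >= 1 and N > L")
        if self.dispersion < 1:
            raise ValueError("dispersion must be >= 1")
        if self.exposure_sd < 0 or self.season_amplitude < 0:
            raise ValueError("variances/amplitudes must be >= 0")
        if self.var_spec is None:
            object.__setattr__(
                self,
                "var_spec",
                BasisSpec(
                    "bspline",
                    degree=2,
                    internal_knots=(8.0, 15.0),
                    boundary_knots=(-6.0, 28.0),
                    intercept=False,
                    center=17.0,
                ),
            )
        if self.lag_spec is None:
            from .basis import place_lag_knots

            nk = min(3, self.L - 1)
            object.__setattr__(
                self,
                "lag_spec",
                BasisSpec(
                    "natural_cubic",
                    internal_knots=tuple(place_lag_knots(self.L, nk)),
                    boundary_knots=(0.0, float(self.L)),
                    intercept=True,
                ),
            )
        dim = self.var_spec.dimension() * self.lag_spec.dimension()
        if self.eta_true is None:
            object.__setattr__(self, "eta_true", np.zeros(dim))
        else:
            eta = np.asarray(self.eta_true, dtype=float).ravel()
            if eta.size != dim:
                raise ValueError(f"eta_true must have length {dim}")
            object.__setattr__(self, "eta_true", eta)
        if self.Psi_true is not None:
            psi = np.asarray(self.Psi_true, dtype=float)
            if psi.shape != (dim, dim):
                raise ValueError(f"Psi_true must be {dim}x{dim}")
            object.__setattr__(self, "Psi_true", psi)


@dataclass
class SimTruth:
    """What was actually used to generate the data."""

    eta_true: np.ndarray
    eta_regions: dict[str, np.ndarray]
    theta_overall_regions: dict[str, np.ndarray]
    var_spec: BasisSpec
    lag_spec: BasisSpec
    L: int

    def overall_log_rr(self, grid, cen: float, region: Optional[str] = None) -> np.ndarray:
        """Analytic overall cumulative log-RR curve (truth) at grid values."""
        from .basis import make_basis

        eta = self.eta_true if region is None else self.eta_regions[region]
        m = reduction_matrix("overall", None, self.var_spec, self.lag_spec, self.L)
        theta = m.M @ eta
        b = make_basis(grid, self.var_spec).values - make_basis([cen], self.var_spec).values
        return b @ theta


def _simulate_exposure(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    t = np.arange(n)
    season = cfg.exposure_amplitude * np.sin(2 * np.pi * t / 365.25)
    noise = np.empty(n)
    eps = rng.normal(0.0, cfg.exposure_sd * np.sqrt(1 - cfg.exposure_ar**2), size=n)
    noise[0] = rng.normal(0.0, cfg.exposure_sd)
    for i in range(1, n):
        noise[i] = cfg.exposure_ar * noise[i - 1] + eps[i]
    return cfg.exposure_mean + season + noise


def simulate_regions(cfg: SimConfig) -> tuple[list[RegionSeries], SimTruth]:
    """Generate ``m`` region series of length ``N`` plus the truth record.

    An extra burn-in of ``L`` days of exposure is simulated per region so
    every returned day has a full lag history.
    """
    rng = np.random.default_rng(cfg.seed)
    dim = cfg.eta_true.size
    regions: list[RegionSeries] = []
    eta_regions: dict[str, np.ndarray] = {}
    theta_regions: dict[str, np.ndarray] = {}
    m_overall = reduction_matrix("overall", None, cfg.var_spec, cfg.lag_spec, cfg.L)
    dates = pd.date_range(cfg.start_date, periods=cfg.N, freq="D")
    t = np.arange(cfg.N)
    season = cfg.season_amplitude * np.cos(2 * np.pi * t / 365.25)
    baseline = cfg.baseline_log_mean + season + cfg.trend_slope * t
    for i in range(cfg.m):
        rid = f"region{i+1:02d}"
        eta_i = cfg.eta_true.copy()
        if cfg.Psi_true is not None:
            eta_i = eta_i + rng.multivariate_normal(np.zeros(dim), cfg.Psi_true, method="cholesky")
        x_full = _simulate_exposure(rng, cfg, cfg.N + cfg.L)
        cb = build_crossbasis(x_full, cfg.var_spec, cfg.lag_spec, cfg.L)
        s = (cb.W @ eta_i)[cfg.L :]  # fully-lagged rows only
        # center the surface term so the baseline keeps its interpretation
        mu = np.exp(baseline + s - s.mean())
        if cfg.dispersion == 1.0:
            y = rng.poisson(mu)
        else:
            delta = cfg.dispersion - 1.0
            lam = rng.gamma(shape=mu / delta, scale=delta)
            y = rng.poisson(lam)
        regions.append(
            RegionSeries(
                region_id=rid,
                dates=dates,
                deaths=y,
                temperature=x_full[cfg.L :],
                latitude=50.0 + 1.0 * i,
            )
        )
        eta_regions[rid] = eta_i
        theta_regions[rid] = m_overall.M @ eta_i
    truth = SimTruth(
        eta_true=cfg.eta_true,
        eta_regions=eta_regions,
        theta_overall_regions=theta_regions,
        var_spec=cfg.var_spec,
        lag_spec=cfg.lag_spec,
        L=cfg.L,
    )
    return regions, truth


# ---------------------------------------------------------------------------
# CSV dialect: columns region, date (ISO-8601), deaths, temperature
# (+ optional latitude, constant within region)
# ---------------------------------------------------------------------------

def write_regions_csv(regions: Sequence[RegionSeries], path) -> None:
    frames = []
    for s in regions:
        df = pd.DataFrame(
            {
                "region": s.region_id,
                "date": s.dates.strftime("%Y-%m-%d"),
                "deaths": s.deaths,
                "temperature": s.temperature,
            }
        )
        if s.latitude is not None:
            df["latitude"] = s.latitude
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_regions_csv(path, metadata: Optional[pd.DataFrame] = None) -> list[RegionSeries]:
    """Read the pipeline's CSV dialect into validated RegionSeries.

    ``metadata`` may supply a (region, latitude) table when the main file
    lacks a latitude column.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: file is empty")
    required = {"region", "date", "deaths", "temperature"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    lat_by_region: dict[str, float] = {}
    if metadata is not None:
        lat_by_region = dict(zip(metadata["region"].astype(str), metadata["latitude"]))
    out = []
    for rid, grp in df.groupby("region", sort=False):
        rid = str(rid)
        dates = pd.to_datetime(grp["date"], format="%Y-%m-%d", errors="raise")
        lat = None
        if "latitude" in grp.columns:
            lat = float(grp["latitude"].iloc[0])
        lat = lat_by_region.get(rid, lat)
        try:
            out.append(
                RegionSeries(
                    region_id=rid,
                    dates=pd.DatetimeIndex(dates),
                    deaths=grp["deaths"].to_numpy(),
                    temperature=grp["temperature"].to_numpy(dtype=float),
                    latitude=lat,
                )
            )
        except ValueError as err:
            raise ValueError(f"{path}: {err}") from err
    return out
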