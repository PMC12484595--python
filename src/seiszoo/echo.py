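"""Vertical-distribution indicators from gridded volume backscatter.

Works on echo-integration grids of volume backscattering strength
Sv (dB re 1 m⁻¹) on a regular depth × time lattice (default 2 m × 2 s).
All moments are computed on the linear-domain coefficient sv = 10^(Sv/10)
(m⁻¹), the standard echo-integration convention:

    CM  = Σ z·sv·Δz / Σ sv·Δz                    (center of mass, m)
    I   = Σ (z − CM)²·sv·Δz / Σ sv·Δz            (inertia, m²)
    s_A = 4π·1852² · Σ sv·Δz                     (area scattering, m² nmi⁻²)

Depth is positive downward with zero at the surface.  A distance-vs-indicator
regression is exposed as :class:`IndicatorDistanceModel`, an OLS model
(`response ~ distance`, a Gaussian identity-link GLM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "SvGrid",
    "db_to_linear",
    "linear_to_db",
    "apply_exclusions",
    "center_of_mass",
    "inertia",
    "area_scattering",
    "indicators_by_time",
    "join_track",
    "bin_by_distance",
    "IndicatorDistanceModel",
    "IndicatorFitResults",
    "fit_indicator_glm",
]

#: 4π times one nautical mile squared — scales depth-integrated sv to s_A
SA_COEFF = 4.0 * np.pi * 1852.0 ** 2


def db_to_linear(sv_db):
    """Sv (dB re 1 m⁻¹) → sv (m⁻¹)."""
    return 10.0 ** (np.asarray(sv_db, dtype=float) / 10.0)


def linear_to_db(sv):
    """sv (m⁻¹) → Sv (dB re 1 m⁻¹)."""
    return 10.0 * np.log10(np.asarray(sv, dtype=float))


def _check_uniform(x, name):
    x = np.asarray(x, dtype=float)
    if x.size > 1:
        d = np.diff(x)
        if np.any(d <= 0):
            raise ValueError(f"{name} must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError(f"{name} must be uniformly spaced")
    return x


@dataclass
class SvGrid:
    """Depth × time grid of volume backscattering strength.

    ``sv_db[i, j]`` is Sv in dB re 1 m⁻¹ at depth ``depth_centers[i]`` (m,
    positive downward) and time ``time_centers[j]`` (s).  ``mask`` is True
    where a cell is excluded from analysis; masked values are retained.
    """

    sv_db: np.ndarray
    depth_centers: np.ndarray
    time_centers: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.sv_db = np.asarray(self.sv_db, dtype=float)
        self.depth_centers = _check_uniform(self.depth_centers, "depth_centers")
        self.time_centers = _check_uniform(self.time_centers, "time_centers")
        if self.sv_db.shape != (self.depth_centers.size, self.time_centers.size):
            raise ValueError("sv_db shape must be (n_depth, n_time)")
        if self.mask is None:
            self.mask = np.zeros(self.sv_db.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.sv_db.shape:
                raise ValueError("mask shape must match sv_db")

    @property
    def dz(self) -> float:
        return float(self.depth_centers[1] - self.depth_centers[0]) \
            if self.depth_centers.size > 1 else float("nan")

    @property
    def dt(self) -> float:
        return float(self.time_centers[1] - self.time_centers[0]) \
            if self.time_centers.size > 1 else float("nan")

    def to_csv(self, path) -> None:
        """First column depth-bin center (m), header row time-bin centers (s)."""
        df = pd.DataFrame(self.sv_db, index=self.depth_centers,
                          columns=self.time_centers)
        df.index.name = "depth_m"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SvGrid":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float),
                   df.index.to_numpy(dtype=float),
                   np.array([float(c) for c in df.columns]))


def apply_exclusions(grid: SvGrid, surface_depth: float,
                     bottom_clearance: float = 5.0) -> SvGrid:
    """Mask the surface layer and the near-transducer bottom layer.

    Cells with centers shallower than ``surface_depth`` (surface turbulence,
    bubbles) and within ``bottom_clearance`` of the deepest grid edge are
    excluded; values underneath the mask are kept.
    """
    z = grid.depth_centers
    if not 0 <= surface_depth:
        raise ValueError("surface_depth must be non-negative")
    bottom_edge = z[-1] + grid.dz / 2.0 if z.size > 1 else z[-1]
    excl = (z < surface_depth) | (z > bottom_edge - bottom_clearance)
    mask = grid.mask | excl[:, None]
    if mask.all():
        raise ValueError("exclusions mask every cell")
    return replace(grid, mask=mask)


def _moments(sv_lin, depths, dz, mask=None):
    """(total weight, CM, inertia) of one linear-domain profile."""
    sv = np.asarray(sv_lin, dtype=float)
    z = np.asarray(depths, dtype=float)
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        sv, z = sv[keep], z[keep]
    w = sv * dz
    tot = w.sum()
    if tot <= 0 or not np.isfinite(tot):
        return tot, np.nan, np.nan
    cm = float((z * w).sum() / tot)
    iner = float((((z - cm) ** 2) * w).sum() / tot)
    return tot, cm, iner


def center_of_mass(sv_lin, depths, dz, mask=None) -> float:
    """Backscatter-weighted mean depth (m); NaN for an all-zero profile."""
    return _moments(sv_lin, depths, dz, mask)[1]


def inertia(sv_lin, depths, dz, mask=None) -> float:
    """Backscatter-weighted variance of depth about the CM (m²)."""
    return _moments(sv_lin, depths, dz, mask)[2]


def area_scattering(sv_lin, dz, mask=None) -> float:
    """Nautical area scattering coefficient s_A = 4π·1852²·Σ sv·Δz."""
    sv = np.asarray(sv_lin, dtype=float)
    if mask is not None:
        sv = sv[~np.asarray(mask, dtype=bool)]
    return float(SA_COEFF * sv.sum() * dz)


def indicators_by_time(grid: SvGrid) -> pd.DataFrame:
    """One indicator record per time bin (CM, inertia, s_A, cells used).

    Moments are taken in the linear domain over unmasked cells.  Time bins
    whose unmasked energy is zero (or fully masked) get NaN indicators and
    are logged; downstream fits drop them rather than imputing.
    """
    sv_lin = db_to_linear(grid.sv_db)
    w = np.where(grid.mask, 0.0, sv_lin) * grid.dz
    z = grid.depth_centers[:, None]
    tot = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = np.where(tot > 0, (z * w).sum(axis=0) / tot, np.nan)
        iner = np.where(tot > 0,
                        ((z - cm[None, :]) ** 2 * w).sum(axis=0) / tot, np.nan)
    sa = SA_COEFF * tot
    n_dropped = int(np.sum(~(tot > 0)))
    if n_dropped:
        logger.info("%d time bins with no unmasked energy: indicators dropped",
                    n_dropped)
    return pd.DataFrame({"time_s": grid.time_centers.astype(float),
                         "cm_m": cm, "inertia_m2": iner, "sa": sa,
                         "n_cells": (~grid.mask).sum(axis=0).astype(int)})


def join_track(indicators: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Attach source distance (m) interpolated from the vessel track."""
    t = indicators["time_s"].to_numpy()
    t_lo, t_hi = track["time_s"].min(), track["time_s"].max()
    if t.min() < t_lo or t.max() > t_hi:
        raise ValueError("track does not cover indicator time span")
    out = indicators.copy()
    out["distance_m"] = np.interp(t, track["time_s"].to_numpy(),
                                  track["distance_m"].to_numpy())
    return out


def bin_by_distance(indicators: pd.DataFrame, bin_width: float = 1000.0,
                    max_distance: float = 9000.0) -> pd.DataFrame:
    """Mean CM/I per half-open distance interval [k·w, (k+1)·w), up to
    ``max_distance``.  Empty bins are omitted (and logged)."""
    df = indicators.dropna(subset=["cm_m", "inertia_m2", "distance_m"])
    df = df[df["distance_m"] < max_distance]
    idx = np.floor(df["distance_m"] / bin_width).astype(int)
    g = df.groupby(idx)
    out = g.agg(cm_m=("cm_m", "mean"), inertia_m2=("inertia_m2", "mean"),
                sa=("sa", "mean"), n=("cm_m", "size"))
    out.insert(0, "distance_m", (out.index.to_numpy() + 0.5) * bin_width)
    n_expected = int(np.ceil(max_distance / bin_width))
    if len(out) < n_expected:
        logger.info("%d of %d distance bins empty", n_expected - len(out), n_expected)
    return out.reset_index(drop=True)


class IndicatorDistanceModel:
    """OLS of a vertical-distribution indicator on distance to the source.

    ``response ~ distance`` with a Gaussian identity link — a general linear
    model with one continuous covariate.  Rows with NaN response or distance
    (sentinel time bins) are dropped before fitting.

    Parameters
    ----------
    indicators : DataFrame
        Must carry ``distance_m`` and the response column.
    response : {"cm", "inertia"}
        Which indicator to regress.
    """

    _COLS = {"cm": "cm_m", "inertia": "inertia_m2"}

    def __init__(self, indicators: pd.DataFrame, response: str = "cm"):
        if response not in self._COLS:
            raise ValueError(f"response must be one of {sorted(self._COLS)}")
        col = self._COLS[response]
        df = indicators[["distance_m", col]].dropna()
        if len(df) < 3:
            raise ValueError("need at least 3 records with finite response and distance")
        if np.ptp(df["distance_m"].to_numpy()) == 0:
            raise ValueError("distance is constant: design matrix rank-deficient")
        self.response = response
        self.data = df.rename(columns={col: "y"})

    def fit(self) -> "IndicatorFitResults":
        X = sm.add_constant(self.data["distance_m"].to_numpy())
        res = sm.OLS(self.data["y"].to_numpy(), X).fit()
        return IndicatorFitResults(self, res)


@dataclass
class IndicatorFitResults:
    """Slope/intercept/p of an indicator-vs-distance fit."""

    model: IndicatorDistanceModel
    _res: object

    @property
    def slope(self) -> float:
        return float(self._res.params[1])

    @property
    def intercept(self) -> float:
        return float(self._res.params[0])

    @property
    def slope_se(self) -> float:
        return float(self._res.bse[1])

    @property
    def p_value(self) -> float:
        return float(self._res.pvalues[1])

    @property
    def n(self) -> int:
        return int(self._res.nobs)

    def summary(self):
        return self._res.summary()

    def to_dict(self) -> dict:
        return {"response": self.model.response, "slope": self.slope,
                "se": self.slope_se, "intercept": self.intercept,
                "p": self.p_value, "n": self.n}


def fit_indicator_glm(indicators: pd.DataFrame, response: str = "cm") -> IndicatorFitResults:
    """Convenience wrapper: build and fit :class:`IndicatorDistanceModel`."""
    return IndicatorDistanceModel(indicators, response).fit()
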