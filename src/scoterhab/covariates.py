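"""Covariate construction: shore distance, buoy interpolation, standardization,
and assembly of the 14-column design matrix.

Seven linear covariates enter the model: yearly North Atlantic Oscillation
index (NAO), bathymetry (m, negative below sea level), sea-floor slope
(degrees), distance to shore (km), latitude (degrees), and survey-window
averages of wind speed (m/s) and time between waves (s) interpolated from
buoy networks by inverse distance weighting. All are standardized to mean 0,
sd 1 before quadratics and interactions are formed inside the linear
predictor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union

LINEAR_COVARIATES = ["nao", "bathy", "slope", "dist", "wind", "wave", "latitude"]

#: fixed design-matrix column order: intercept + 13 predictor terms
DESIGN_COLUMNS = [
    "intercept",
    "nao",
    "bathy",
    "bathy2",
    "slope",
    "dist",
    "dist2",
    "wind",
    "wind2",
    "wave",
    "wave2",
    "latitude",
    "nao_x_bathy",
    "nao_x_dist",
]


@dataclass
class BuoyObservation:
    buoy_id: str
    lon: float
    lat: float
    date: str  # ISO calendar date
    value: float  # wind speed (m/s) or wave period (s); NaN if missing


@dataclass
class CovariateTable:
    """Per cell-year covariates, raw and standardized.

    ``data`` has one row per cell-year with raw columns named as in
    LINEAR_COVARIATES plus `cell_id`, `year`, `count`; standardized columns
    carry a ``_z`` suffix. Standardization constants are stored so new data
    (prediction grids) can be placed on the fitted scale.
    """

    data: pd.DataFrame
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def constants_json(self) -> str:
        return json.dumps({"means": self.means, "sds": self.sds}, sort_keys=True)


def distance_to_shore(points_xy, shoreline_geoms) -> np.ndarray:
    """Minimum Euclidean distance (km) from planar points to a shoreline.

    ``points_xy``: (n, 2) array of projected meters; ``shoreline_geoms``:
    shapely LineString(s) in the same plane.
    """
    if shoreline_geoms is None:
        raise ValueError("shoreline is empty")
    if isinstance(shoreline_geoms, (list, tuple)):
        if len(shoreline_geoms) == 0:
            raise ValueError("shoreline is empty")
        shore = unary_union(list(shoreline_geoms))
    else:
        shore = shoreline_geoms
    if shore.is_empty:
        raise ValueError("shoreline is empty")
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    return np.array([shore.distance(Point(x, y)) for x, y in pts]) / 1000.0


def idw_surface(
    obs_xy: np.ndarray,
    obs_values: np.ndarray,
    targets_xy: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation on the plane.

    value(t) = sum_b d(t,b)^-power * z_b / sum_b d(t,b)^-power. A target
    coincident with an observation site returns that observation exactly.
    Missing (NaN) observations are excluded; all-missing is an error.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    obs_xy = np.atleast_2d(np.asarray(obs_xy, dtype=float))
    z = np.asarray(obs_values, dtype=float)
    ok = np.isfinite(z)
    if not ok.any():
        raise ValueError("all observations missing for this date/variable")
    obs_xy, z = obs_xy[ok], z[ok]
    t = np.atleast_2d(np.asarray(targets_xy, dtype=float))
    d = np.sqrt(((t[:, None, :] - obs_xy[None, :, :]) ** 2).sum(axis=2))
    out = np.empty(len(t))
    coincident = d < 1e-9
    any_coin = coincident.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[coincident] = np.nan  # handled separately
    out = np.where(
        any_coin,
        z[np.argmax(coincident, axis=1)],
        np.nansum(w * z[None, :], axis=1) / np.nansum(w, axis=1),
    )
    return out


def average_survey_window(daily_surfaces: dict, survey_dates) -> np.ndarray:
    """Arithmetic mean of per-date cell surfaces over the survey dates."""
    missing = [d for d in survey_dates if d not in daily_surfaces]
    if missing:
        raise ValueError(f"no interpolated surface for survey date(s) {missing}")
    stack = np.stack([np.asarray(daily_surfaces[d], dtype=float) for d in survey_dates])
    return stack.mean(axis=0)


def standardize(
    table: CovariateTable,
    columns=LINEAR_COVARIATES,
    ddof: int = 1,
) -> CovariateTable:
    """z = (x - mean)/sd per column; constants stored for reuse.

    If the table already carries constants for a column they are reused
    (idempotence on refresh and the contract for scoring new data).
    """
    df = table.data
    for col in columns:
        x = df[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"column {col!r} has missing values among modeled rows")
        m = table.means.get(col, float(np.mean(x)))
        s = table.sds.get(col, float(np.std(x, ddof=ddof)))
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"column {col!r} has zero variance")
        df[col + "_z"] = (x - m) / s
        table.means[col] = m
        table.sds[col] = s
    return table


def destandardize(table: CovariateTable, column: str, z) -> np.ndarray:
    return np.asarray(z, dtype=float) * table.sds[column] + table.means[column]


def pairwise_collinearity(
    table: CovariateTable, columns=LINEAR_COVARIATES, threshold: float = 0.6
) -> pd.DataFrame:
    """|Pearson r| among the linear covariates; warns above ``threshold``."""
    df = table.data[list(columns)]
    if df.shape[0] < 3 or df.shape[1] < 2:
        raise ValueError("need at least 3 rows and 2 columns")
    if (df.std(ddof=1) == 0).any():
        bad = df.columns[(df.std(ddof=1) == 0)].tolist()
        raise ValueError(f"constant column(s): {bad}")
    r = df.corr(method="pearson").abs()
    off = r.to_numpy()[~np.eye(len(columns), dtype=bool)]
    if (off >= threshold).any():
        warnings.warn(
            f"pairwise collinearity >= {threshold} among covariates", stacklevel=2
        )
    return r


@dataclass
class DesignMatrix:
    """Response y plus the 14 fixed-order predictor columns."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str] = field(default_factory=lambda: list(DESIGN_COLUMNS))
    constants_checksum: str = ""

    def __post_init__(self):
        self.y = np.asarray(self.y)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column count mismatch")
        if self.X.shape[0] != len(self.y):
            raise ValueError("row count mismatch between X and y")

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "y", self.y)
        return df


def design_rows_from_z(z: dict) -> np.ndarray:
    """Assemble design rows from standardized linear covariate arrays.

    ``z`` maps the seven linear covariate names to equal-length arrays on
    the standardized scale; quadratics and interactions are products of
    these, never re-standardized.
    """
    n = len(np.atleast_1d(z["nao"]))
    cols = {
        "intercept": np.ones(n),
        "nao": z["nao"],
        "bathy": z["bathy"],
        "bathy2": np.asarray(z["bathy"]) ** 2,
        "slope": z["slope"],
        "dist": z["dist"],
        "dist2": np.asarray(z["dist"]) ** 2,
        "wind": z["wind"],
        "wind2": np.asarray(z["wind"]) ** 2,
        "wave": z["wave"],
        "wave2": np.asarray(z["wave"]) ** 2,
        "latitude": z["latitude"],
        "nao_x_bathy": np.asarray(z["nao"]) * np.asarray(z["bathy"]),
        "nao_x_dist": np.asarray(z["nao"]) * np.asarray(z["dist"]),
    }
    return np.column_stack([np.broadcast_to(cols[c], (n,)) for c in DESIGN_COLUMNS])


def build_design_matrix(table: CovariateTable, counts=None) -> DesignMatrix:
    """Build the 14-column design matrix from a standardized covariate table.

    ``counts`` defaults to the table's own `count` column; rows must align.
    """
    df = table.data
    for col in LINEAR_COVARIATES:
        if col + "_z" not in df:
            raise ValueError("table must be standardized first (call standardize)")
    if counts is None:
        counts = df["count"].to_numpy()
    counts = np.asarray(counts)
    if len(counts) != len(df):
        raise ValueError(
            f"row-count mismatch: {len(counts)} counts vs {len(df)} covariate rows"
        )
    z = {c: df[c + "_z"].to_numpy() for c in LINEAR_COVARIATES}
    X = design_rows_from_z(z)
    return DesignMatrix(y=counts, X=X, constants_checksum=table.constants_json())
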