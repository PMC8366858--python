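"""Posterior prediction of relative abundance and interaction-response curves.

"Relative abundance" is the posterior expected count per 1,000 m x 550 m
survey cell — the model's native unit; no density rescaling is applied.
Summaries are the posterior mean and the equal-tailed 95% credible interval
(2.5/97.5 percentiles over draws) of mu = exp(beta0 + X beta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import CovariateTable, design_rows_from_z, LINEAR_COVARIATES
from .model import PosteriorDraws

#: NAO conditioning levels spanning the observed range of the index
DEFAULT_NAO_LEVELS = (-3.9, -1.4, 2.8)


@dataclass
class PredictionSurface:
    data: pd.DataFrame  # columns: mean, lower, upper, sd (one row per input row)


@dataclass
class ResponseCurve:
    data: pd.DataFrame  # columns: nao_level, bathymetry_m, mean, lower, upper


def _mu_draws(draws: PosteriorDraws, X_new: np.ndarray, chunk: int = 512):
    b0 = draws.flat("beta0")
    beta = draws.flat_beta()
    Xp = np.asarray(X_new, dtype=float)[:, 1:]
    for i in range(0, Xp.shape[0], chunk):
        eta = b0[None, :] + Xp[i : i + chunk] @ beta.T  # (rows, draws)
        yield np.exp(eta)


def predict_mu(
    draws: PosteriorDraws,
    X_new: np.ndarray,
    constants_checksum: str | None = None,
    expected_checksum: str | None = None,
) -> PredictionSurface:
    """Posterior mean / 95% CI / sd of mu for each design row.

    New rows must be standardized with the SAME constants as the fitted
    design matrix; pass both checksums to enforce this.
    """
    if (
        constants_checksum is not None
        and expected_checksum is not None
        and constants_checksum != expected_checksum
    ):
        raise ValueError(
            "standardization constants of the prediction rows do not match the fit"
        )
    rows = []
    for mu in _mu_draws(draws, X_new):
        lo, hi = np.percentile(mu, [2.5, 97.5], axis=1)
        rows.append(
            np.column_stack([mu.mean(axis=1), lo, hi, mu.std(axis=1, ddof=1)])
        )
    out = pd.DataFrame(
        np.vstack(rows), columns=["mean", "lower", "upper", "sd"]
    )
    return PredictionSurface(data=out)


def interaction_curve(
    draws: PosteriorDraws,
    table: CovariateTable,
    bathy_grid_m,
    nao_levels=DEFAULT_NAO_LEVELS,
) -> ResponseCurve:
    """Predicted abundance vs bathymetry (raw meters) at fixed NAO levels.

    Bathymetry and NAO are standardized with the fitted constants; every
    other covariate is held at its mean (standardized 0), so only the
    intercept, nao, bathy, bathy^2 and nao x bathy columns act. Requests
    outside the fitted covariate range warn (extrapolation) but proceed.
    """
    bathy_grid_m = np.asarray(bathy_grid_m, dtype=float)
    if not np.all(np.diff(bathy_grid_m) > 0):
        raise ValueError("bathymetry grid must be strictly increasing")
    bz = (bathy_grid_m - table.means["bathy"]) / table.sds["bathy"]
    fitted_b = table.data["bathy"]
    if bathy_grid_m.min() < fitted_b.min() or bathy_grid_m.max() > fitted_b.max():
        warnings.warn("bathymetry grid extrapolates beyond the fitted range")
    fitted_nao = table.data["nao"]
    frames = []
    for nao in nao_levels:
        if not (fitted_nao.min() <= nao <= fitted_nao.max()):
            warnings.warn(f"NAO level {nao} extrapolates beyond the fitted range")
        nz = (nao - table.means["nao"]) / table.sds["nao"]
        z = {c: np.zeros_like(bz) for c in LINEAR_COVARIATES}
        z["bathy"] = bz
        z["nao"] = np.full_like(bz, nz)
        X = design_rows_from_z(z)
        surf = predict_mu(draws, X)
        df = surf.data[["mean", "lower", "upper"]].copy()
        df.insert(0, "bathymetry_m", bathy_grid_m)
        df.insert(0, "nao_level", nao)
        frames.append(df)
    return ResponseCurve(data=pd.concat(frames, ignore_index=True))


def aggregate_surface(
    surface: PredictionSurface, lon, lat, degree: float = 0.3
) -> pd.DataFrame:
    """Mean of cell-level posterior means within coarse lon/lat blocks
    (presentation-scale aggregation)."""
    df = surface.data.copy()
    df["lon_bin"] = (np.floor(np.asarray(lon) / degree) + 0.5) * degree
    df["lat_bin"] = (np.floor(np.asarray(lat) / degree) + 0.5) * degree
    return (
        df.groupby(["lon_bin", "lat_bin"], as_index=False)["mean"]
        .mean()
        .rename(columns={"mean": "mean_abundance"})
    )
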