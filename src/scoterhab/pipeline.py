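"""End-to-end orchestration: seascape -> grid -> covariates -> design ->
simulated counts -> fit -> check -> predict, from one scenario and one seed.

Also reads/writes the exchange formats the stages ingest (transect GeoJSON,
sightings CSV, ESRI ASCII bathymetry, shoreline GeoJSON, buoy CSV, NAO CSV,
truth JSON), so a synthetic study round-trips through the same files a real
survey would arrive in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from . import covariates as cov
from .covariates import BuoyObservation, CovariateTable, DesignMatrix
from .geometry import (
    LocalProjection,
    read_geojson_features,
    write_geojson_features,
)
from .model import MCMCConfig, PosteriorDraws, PriorSpec, sample_posterior
from .checking import PPCResult, posterior_predictive_pvalue
from .raster import RasterGrid, compute_slope, read_ascii_grid, write_ascii_grid
from .simulate import SyntheticScenario, generate_buoy_series, generate_seascape, simulate_counts
from .survey_grid import (
    GridCell,
    SightingRecord,
    TransectLine,
    assign_sightings,
    cells_to_frame,
    segment_transect,
    summarize_counts,
    BLACK_SCOTER,
)


# ---------------------------------------------------------------------------
# covariate assembly


def build_covariate_table(
    cells: list[GridCell],
    bathy: RasterGrid,
    slope: RasterGrid,
    shoreline: LineString,
    wind_obs: list[BuoyObservation],
    wave_obs: list[BuoyObservation],
    nao_by_year: dict,
    transects: list[TransectLine],
    projection: LocalProjection,
    idw_power: float = 2.0,
) -> CovariateTable:
    """Assemble raw covariates per cell-year, then standardize.

    Bathymetry and slope are sampled at cell centers; distance to shore is
    the planar minimum from the center (km); wind and wave are IDW surfaces
    per survey date averaged over the year's survey window; NAO is the
    yearly index value.
    """
    centers = np.array([c.center_xy for c in cells])
    years = np.array([c.year for c in cells])
    tr_by_key = {(t.transect_id, t.year): t for t in transects}

    bathy_v = bathy.sample(centers[:, 0], centers[:, 1])
    slope_v = slope.sample(centers[:, 0], centers[:, 1])
    dist_v = cov.distance_to_shore(centers, shoreline)
    lat_v = np.array(
        [
            c.center_lonlat[1]
            if c.center_lonlat
            else projection.inverse(*c.center_xy)[1]
            for c in cells
        ],
        dtype=float,
    )

    def buoy_frame(obs):
        return pd.DataFrame(
            [
                dict(buoy_id=o.buoy_id, lon=o.lon, lat=o.lat, date=o.date, value=o.value)
                for o in obs
            ]
        )

    wind_df, wave_df = buoy_frame(wind_obs), buoy_frame(wave_obs)
    wind_v = np.empty(len(cells))
    wave_v = np.empty(len(cells))
    for year in np.unique(years):
        sel = years == year
        tgt = centers[sel]
        # survey dates of this year's transects
        dates = sorted(
            {d for (tid, yr), t in tr_by_key.items() if yr == year for d in t.survey_dates}
        )
        for arr, df in ((wind_v, wind_df), (wave_v, wave_df)):
            daily = {}
            for d in dates:
                day = df[df.date == d]
                if day.empty:
                    raise ValueError(f"no buoy observations for survey date {d}")
                ox, oy = projection.forward(day.lon.to_numpy(), day.lat.to_numpy())
                daily[d] = cov.idw_surface(
                    np.column_stack([ox, oy]), day.value.to_numpy(), tgt, power=idw_power
                )
            arr[sel] = cov.average_survey_window(daily, dates)

    nao_v = np.array([nao_by_year[y] for y in years], dtype=float)
    df = pd.DataFrame(
        dict(
            cell_id=[c.cell_id for c in cells],
            year=years,
            count=[c.count for c in cells],
            nao=nao_v,
            bathy=bathy_v,
            slope=slope_v,
            dist=dist_v,
            wind=wind_v,
            wave=wave_v,
            latitude=lat_v,
        )
    )
    table = CovariateTable(data=df)
    return cov.standardize(table)


# ---------------------------------------------------------------------------
# sightings scattering (inverse of gridding, for pipeline closure)


def scatter_sightings(
    cells: list[GridCell],
    counts: np.ndarray,
    transects: list[TransectLine],
    seed: int,
) -> list[SightingRecord]:
    """Turn per-cell counts into point sightings inside each cell's strip.

    Each occupied cell yields one flock at a random along-track position in
    [a, b) with a random perpendicular offset within the half-width, so that
    re-gridding recovers the counts exactly (conservation closure).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    tr = {(t.transect_id, t.year): t for t in transects}
    out = []
    for c, n in zip(cells, counts):
        if n <= 0:
            continue
        t = tr[(c.transect_id, c.year)]
        along = rng.uniform(c.along_start_m, c.along_end_m - 1e-6)
        offset = rng.uniform(-c.half_width_m + 1.0, c.half_width_m - 1.0)
        base: Point = t.path.interpolate(along)
        ahead: Point = t.path.interpolate(min(along + 1.0, t.path.length))
        dx, dy = ahead.x - base.x, ahead.y - base.y
        norm = max(np.hypot(dx, dy), 1e-12)
        px, py = base.x - dy / norm * offset, base.y + dx / norm * offset
        out.append(
            SightingRecord(
                transect_id=c.transect_id,
                year=c.year,
                position=(px, py),
                species=BLACK_SCOTER,
                group_size=int(n),
            )
        )
    return out


# ---------------------------------------------------------------------------
# end-to-end


@dataclass
class PipelineResult:
    scenario: SyntheticScenario
    projection: LocalProjection
    bathy: RasterGrid
    slope: RasterGrid
    shoreline: LineString
    transects: list
    cells: list
    n_dropped: int
    table: CovariateTable
    design: DesignMatrix
    draws: PosteriorDraws | None = None
    ppc: PPCResult | None = None
    extras: dict = field(default_factory=dict)

    def count_summary(self):
        return summarize_counts(self.cells)

    def cells_frame(self) -> pd.DataFrame:
        return cells_to_frame(self.cells)


def run_pipeline(
    scenario: SyntheticScenario,
    seed: int | None = None,
    fit: bool = False,
    family: str = "nb",
    config: MCMCConfig | None = None,
    priors: PriorSpec | None = None,
    check: bool = False,
) -> PipelineResult:
    """Generate a synthetic study and push it through every stage.

    Counts are simulated from the scenario truth on the real design matrix,
    scattered into point sightings, then re-gridded with the survey module —
    so the count response the model sees has passed through the same
    geometry code a real survey would.
    """
    seed = scenario.seed if seed is None else seed
    bathy, shoreline, transects, proj = generate_seascape(scenario)
    slope = compute_slope(bathy)
    cells = []
    for t in transects:
        cells.extend(
            segment_transect(
                t,
                cell_length_m=scenario.cell_length_m,
                half_width_m=scenario.half_width_m,
                projection=proj,
            )
        )
    wind_obs, wave_obs = generate_buoy_series(scenario)
    table = build_covariate_table(
        cells, bathy, slope, shoreline, wind_obs, wave_obs,
        scenario.nao_values(), transects, proj,
    )
    design0 = cov.build_design_matrix(table, counts=np.zeros(len(cells), dtype=int))
    y = simulate_counts(design0.X, scenario, seed)
    sightings = scatter_sightings(cells, y, transects, seed)
    cells, n_dropped = assign_sightings(sightings, cells, transects)
    table.data["count"] = [c.count for c in cells]
    design = cov.build_design_matrix(table)

    result = PipelineResult(
        scenario=scenario,
        projection=proj,
        bathy=bathy,
        slope=slope,
        shoreline=shoreline,
        transects=transects,
        cells=cells,
        n_dropped=n_dropped,
        table=table,
        design=design,
    )
    if fit:
        cfg = config or MCMCConfig(seed=seed)
        result.draws = sample_posterior(
            design.y, design.X, priors=priors, config=cfg, family=family
        )
        if check:
            result.ppc = posterior_predictive_pvalue(
                result.draws, design.y, design.X, seed=seed + 1
            )
    return result


# ---------------------------------------------------------------------------
# exchange-format I/O


def write_scenario_files(result: PipelineResult, out_dir) -> dict:
    """Emit the pipeline's input files for a generated study."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proj = result.projection

    feats = []
    for t in result.transects:
        xs, ys = np.array(t.path.coords).T
        lon, lat = proj.inverse(xs, ys)
        feats.append(
            (
                LineString(np.column_stack([lon, lat])),
                {"transect_id": t.transect_id, "year": t.year, "dates": t.survey_dates},
            )
        )
    write_geojson_features(out / "transects.geojson", feats)

    xs, ys = np.array(result.shoreline.coords).T
    lon, lat = proj.inverse(xs, ys)
    write_geojson_features(
        out / "shoreline.geojson", [(LineString(np.column_stack([lon, lat])), {})]
    )
    write_ascii_grid(out / "bathymetry.asc", result.bathy)

    scn = result.scenario
    sightings = scatter_sightings(
        result.cells,
        np.array([c.count for c in result.cells]),
        result.transects,
        scn.seed,
    )
    rows = []
    for s in sightings:
        lon, lat = proj.inverse(*s.position)
        rows.append(
            dict(
                transect_id=s.transect_id, year=s.year, lat=float(lat),
                lon=float(lon), species=s.species, count=s.group_size,
            )
        )
    pd.DataFrame(
        rows, columns=["transect_id", "year", "lat", "lon", "species", "count"]
    ).to_csv(out / "sightings.csv", index=False)

    wind_obs, wave_obs = generate_buoy_series(scn)
    brows = [
        dict(buoy_id=o.buoy_id, lat=o.lat, lon=o.lon, date=o.date,
             wind_speed_ms=o.value, wave_period_s=np.nan)
        for o in wind_obs
    ] + [
        dict(buoy_id=o.buoy_id, lat=o.lat, lon=o.lon, date=o.date,
             wind_speed_ms=np.nan, wave_period_s=o.value)
        for o in wave_obs
    ]
    pd.DataFrame(brows).to_csv(out / "buoys.csv", index=False)

    nao = scn.nao_values()
    pd.DataFrame(
        [dict(year=y, month=2, value=v) for y, v in nao.items()]
    ).to_csv(out / "nao.csv", index=False)

    with open(out / "truth.json", "w") as fh:
        fh.write(scn.to_json())
    result.cells_frame().to_csv(out / "cells.csv", index=False)
    return {p.name: str(p) for p in out.iterdir()}


def load_transects(path, projection: LocalProjection) -> list[TransectLine]:
    out = []
    for geom, props in read_geojson_features(path):
        lon, lat = np.array(geom.coords).T
        x, y = projection.forward(lon, lat)
        out.append(
            TransectLine(
                transect_id=str(props["transect_id"]),
                year=int(props["year"]),
                path=LineString(np.column_stack([x, y])),
                survey_dates=list(props["dates"]),
            )
        )
    return out


def load_sightings(path, projection: LocalProjection) -> list[SightingRecord]:
    df = pd.read_csv(path)
    x, y = projection.forward(df.lon.to_numpy(), df.lat.to_numpy())
    return [
        SightingRecord(
            transect_id=str(r.transect_id), year=int(r.year),
            position=(float(xi), float(yi)), species=str(r.species),
            group_size=int(r["count"]),
        )
        for (_, r), xi, yi in zip(df.iterrows(), x, y)
    ]


def load_shoreline(path, projection: LocalProjection) -> LineString:
    geoms = read_geojson_features(path)
    lines = []
    for geom, _ in geoms:
        lon, lat = np.array(geom.coords).T
        x, y = projection.forward(lon, lat)
        lines.append(np.column_stack([x, y]))
    return LineString(np.vstack(lines))


def load_buoys(path) -> tuple[list[BuoyObservation], list[BuoyObservation]]:
    df = pd.read_csv(path)
    wind, wave = [], []
    for _, r in df.iterrows():
        if np.isfinite(r.wind_speed_ms):
            wind.append(
                BuoyObservation(str(r.buoy_id), float(r.lon), float(r.lat),
                                str(r.date), float(r.wind_speed_ms))
            )
        if np.isfinite(r.wave_period_s):
            wave.append(
                BuoyObservation(str(r.buoy_id), float(r.lon), float(r.lat),
                                str(r.date), float(r.wave_period_s))
            )
    return wind, wave


def load_nao(path, month: int = 2) -> dict:
    """Yearly NAO from a monthly CSV; February (survey month) by default."""
    df = pd.read_csv(path)
    sel = df[df.month == month]
    return {int(r.year): float(r.value) for _, r in sel.iterrows()}


def rebuild_from_files(in_dir, scenario: SyntheticScenario) -> PipelineResult:
    """Ingest a directory written by write_scenario_files and re-run the
    gridding + covariate stages from the files alone."""
    d = Path(in_dir)
    proj = scenario.projection()
    transects = load_transects(d / "transects.geojson", proj)
    sightings = load_sightings(d / "sightings.csv", proj)
    shoreline = load_shoreline(d / "shoreline.geojson", proj)
    bathy = read_ascii_grid(d / "bathymetry.asc")
    slope = compute_slope(bathy)
    wind_obs, wave_obs = load_buoys(d / "buoys.csv")
    nao = load_nao(d / "nao.csv")
    cells = []
    for t in transects:
        cells.extend(
            segment_transect(
                t,
                cell_length_m=scenario.cell_length_m,
                half_width_m=scenario.half_width_m,
                projection=proj,
            )
        )
    cells, n_dropped = assign_sightings(sightings, cells, transects)
    table = build_covariate_table(
        cells, bathy, slope, shoreline, wind_obs, wave_obs, nao, transects, proj
    )
    table.data["count"] = [c.count for c in cells]
    design = cov.build_design_matrix(table)
    return PipelineResult(
        scenario=scenario, projection=proj, bathy=bathy, slope=slope,
        shoreline=shoreline, transects=transects, cells=cells,
        n_dropped=n_dropped, table=table, design=design,
    )
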