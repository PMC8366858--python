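"""Strip-transect gridding and per-cell count aggregation.

Aerial strip-transect surveys record flocks along east-west flight lines.
The analysis unit is a grid cell 1,000 m long (along-track) and 550 m wide
(275 m either side of the line, the surveyed 250 m strip plus a 25 m GPS
buffer). Each transect is segmented into consecutive half-open along-track
intervals, sightings are projected onto the line and summed per cell and
year, and the per-cell-year totals form the count response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .geometry import LocalProjection

logger = logging.getLogger(__name__)

CELL_LENGTH_M = 1000.0
HALF_WIDTH_M = 275.0
BLACK_SCOTER = "BLSC"


@dataclass
class TransectLine:
    """One flown transect: an ordered planar path (meters) plus survey dates."""

    transect_id: str
    year: int
    path: LineString
    survey_dates: list = field(default_factory=list)

    def __post_init__(self):
        if not isinstance(self.path, LineString):
            self.path = LineString(self.path)
        if len(self.path.coords) < 2 or self.path.length <= 0:
            raise ValueError(
                f"transect {self.transect_id!r}: path must have >=2 vertices "
                "and positive length"
            )
        if not self.survey_dates:
            raise ValueError(f"transect {self.transect_id!r}: survey_dates empty")


@dataclass
class SightingRecord:
    transect_id: str
    year: int
    position: tuple  # planar (x, y) meters
    species: str
    group_size: int

    def __post_init__(self):
        if self.group_size < 0:
            raise ValueError("group_size must be >= 0")


@dataclass
class GridCell:
    """One cell-year: a half-open along-track interval [along_start_m, along_end_m)."""

    cell_id: str
    transect_id: str
    year: int
    along_start_m: float
    along_end_m: float
    center_xy: tuple
    center_lonlat: tuple | None
    length_m: float
    half_width_m: float
    partial: bool = False
    count: int = 0

    def __post_init__(self):
        if self.along_end_m <= self.along_start_m:
            raise ValueError("along_end_m must exceed along_start_m")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass
class CountSummary:
    n_cells: int
    n_occupied: int
    mean: float
    median: float
    q025: float
    q50: float
    q975: float
    max: int


def segment_transect(
    transect: TransectLine,
    cell_length_m: float = CELL_LENGTH_M,
    half_width_m: float = HALF_WIDTH_M,
    remainder: str = "keep",
    projection: LocalProjection | None = None,
) -> list[GridCell]:
    """Tile a transect into consecutive grid cells along its arc length.

    ``remainder`` controls the trailing partial cell when the transect length
    is not a multiple of ``cell_length_m``: "keep" (default) retains it
    flagged partial, "drop" discards it, "merge" extends the last full cell.
    """
    if cell_length_m <= 0 or half_width_m <= 0:
        raise ValueError("cell_length_m and half_width_m must be positive")
    if remainder not in ("keep", "drop", "merge"):
        raise ValueError(f"unknown remainder policy {remainder!r}")
    L = transect.path.length
    n_full = int(np.floor(L / cell_length_m))
    # guard against float L being an exact multiple
    rem = L - n_full * cell_length_m
    edges = [i * cell_length_m for i in range(n_full + 1)]
    if rem > 1e-9:
        if remainder == "keep":
            edges.append(L)
        elif remainder == "merge" and n_full >= 1:
            edges[-1] = L
        elif remainder == "merge":
            edges.append(L)  # transect shorter than one cell: keep as one
    cells = []
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        mid = transect.path.interpolate((a + b) / 2.0)
        lonlat = None
        if projection is not None:
            lon, lat = projection.inverse(mid.x, mid.y)
            lonlat = (float(lon), float(lat))
        cells.append(
            GridCell(
                cell_id=f"{transect.transect_id}:{i:04d}",
                transect_id=transect.transect_id,
                year=transect.year,
                along_start_m=a,
                along_end_m=b,
                center_xy=(mid.x, mid.y),
                center_lonlat=lonlat,
                length_m=b - a,
                half_width_m=half_width_m,
                partial=(b - a) < cell_length_m - 1e-9,
            )
        )
    return cells


def cell_polygon(cell: GridCell, transect: TransectLine) -> Polygon:
    """Planar strip rectangle of a cell (buffered along-track segment)."""
    a = transect.path.interpolate(cell.along_start_m)
    b = transect.path.interpolate(min(cell.along_end_m, transect.path.length))
    seg = LineString([a, b])
    return seg.buffer(cell.half_width_m, cap_style="flat")


def assign_sightings(
    sightings: list[SightingRecord],
    cells: list[GridCell],
    transects: dict[str, TransectLine] | list[TransectLine],
    species: str = BLACK_SCOTER,
) -> tuple[list[GridCell], int]:
    """Project sightings onto their transect and sum group sizes per cell.

    A sighting lands in the cell whose half-open interval [a, b) contains its
    along-track projection, provided its perpendicular offset is within the
    strip half-width. Off-strip or past-the-end sightings are logged and
    dropped; the dropped count is returned. Only the target species is
    counted; other species are ignored silently (not "dropped").
    """
    if isinstance(transects, list):
        transects = {(t.transect_id, t.year): t for t in transects}
    else:
        transects = dict(transects)

    index: dict[tuple, list[GridCell]] = {}
    for c in cells:
        c.count = 0
        index.setdefault((c.transect_id, c.year), []).append(c)
    for group in index.values():
        group.sort(key=lambda c: c.along_start_m)

    n_dropped = 0
    for s in sightings:
        if s.species != species:
            continue
        key = (s.transect_id, s.year)
        tr = transects.get(key)
        group = index.get(key)
        if tr is None or not group:
            logger.warning("sighting on unknown transect %s dropped", key)
            n_dropped += 1
            continue
        p = Point(s.position)
        along = tr.path.project(p)
        offset = tr.path.distance(p)
        if offset > group[0].half_width_m + 1e-9:
            logger.info("sighting %.0f m off-strip on %s dropped", offset, key)
            n_dropped += 1
            continue
        # half-open intervals: at an interior boundary the later cell wins
        hit = None
        for c in group:
            if c.along_start_m <= along < c.along_end_m:
                hit = c
                break
        if hit is None:
            # shapely clamps projections to [0, L]; along == L only at the very end
            if along >= group[-1].along_end_m - 1e-9 and along <= tr.path.length + 1e-9:
                hit = group[-1] if abs(along - tr.path.length) < 1e-9 else None
        if hit is None:
            n_dropped += 1
            continue
        hit.count += s.group_size
    if n_dropped:
        logger.warning("%d sightings dropped during assignment", n_dropped)
    return cells, n_dropped


def summarize_counts(cells: list[GridCell]) -> CountSummary:
    """Count summary over all cell-years; quantiles are lower-nearest order
    statistics (type 1), matching integer count reporting."""
    if not cells:
        raise ValueError("cannot summarize an empty cell list")
    y = np.array([c.count for c in cells])
    q = np.quantile(y, [0.025, 0.5, 0.975], method="inverted_cdf")
    return CountSummary(
        n_cells=len(y),
        n_occupied=int((y > 0).sum()),
        mean=float(y.mean()),
        median=float(np.quantile(y, 0.5, method="inverted_cdf")),
        q025=float(q[0]),
        q50=float(q[1]),
        q975=float(q[2]),
        max=int(y.max()),
    )


def cells_to_frame(cells: list[GridCell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        lon, lat = c.center_lonlat if c.center_lonlat else (np.nan, np.nan)
        rows.append(
            dict(
                cell_id=c.cell_id,
                transect_id=c.transect_id,
                year=c.year,
                center_x=c.center_xy[0],
                center_y=c.center_xy[1],
                center_lon=lon,
                center_lat=lat,
                length_m=c.length_m,
                partial_flag=c.partial,
                count=c.count,
            )
        )
    return pd.DataFrame(rows)
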