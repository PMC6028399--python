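"""Nested equal-area analysis grids and route-to-cell aggregation.

Analysis proceeds on square grids of side 50, 100, 200, 400, 800 and 1600 km
in an equal-area projection, plus two sentinel scales: ``continental`` (one
cell covering the whole extent) and ``global`` (a symbolic single cell where
every non-extinct species is considered present).  All grids share one origin
so that each cell of side 2L is exactly the union of four cells of side L.

Routes are assigned to the cell containing their median point; a cell enters
the analysis in a given year only if every route initially assigned to it was
surveyed that year, which keeps survey effort per cell constant through time.
Cell-level occupancy is the maximum of member-route occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.spatial.distance import cdist

GRID_SCALES_KM = (50, 100, 200, 400, 800, 1600)
SENTINEL_SCALES = ("continental", "global")
ALL_SCALES = tuple(list(GRID_SCALES_KM) + list(SENTINEL_SCALES))


def subsample_routes_by_bcr(routes: pd.DataFrame, max_per_bcr: int = 30) -> pd.DataFrame:
    """Cap the number of routes per region by thinning the most crowded first.

    Regions (BCRs) with more than ``max_per_bcr`` routes are reduced to the
    cap by repeatedly removing the route with the smallest nearest-neighbour
    distance among those still retained (ties broken by route_id).  Regions
    at or under the cap are untouched.
    """
    if max_per_bcr < 1:
        raise ValueError("max_per_bcr must be >= 1")
    keep_idx = []
    for _, grp in routes.groupby("bcr_id", sort=False):
        idx = list(grp.index)
        if len(idx) <= max_per_bcr:
            keep_idx.extend(idx)
            continue
        pts = grp[["x_km", "y_km"]].to_numpy(dtype=float)
        alive = list(range(len(idx)))
        while len(alive) > max_per_bcr:
            sub = pts[alive]
            d = cdist(sub, sub)
            np.fill_diagonal(d, np.inf)
            nn = d.min(axis=1)
            order = sorted(
                range(len(alive)), key=lambda a: (nn[a], str(routes.loc[idx[alive[a]], "route_id"]))
            )
            alive.pop(order[0])
        keep_idx.extend(idx[a] for a in alive)
    return routes.loc[sorted(keep_idx, key=list(routes.index).index)].copy()


def filter_constant_effort(routes: pd.DataFrame, first_year: int, last_year: int) -> pd.DataFrame:
    """Retain only routes surveyed in both endpoint years."""
    mask = routes["surveyed_years"].map(lambda s: first_year in s and last_year in s)
    return routes.loc[mask].copy()


@dataclass
class Grid:
    """A square equal-area grid at one scale, or a sentinel single cell."""

    scale: object  # int km or 'continental'/'global'
    cells: pd.DataFrame  # cell_id, ix, iy, x_min, y_min, x_max, y_max, area_km2
    origin: tuple = (0.0, 0.0)

    @property
    def is_sentinel(self) -> bool:
        return self.scale in SENTINEL_SCALES


def build_grid(scale_km, extent, origin=(0.0, 0.0)) -> Grid:
    """Tile a projected extent with square cells of side ``scale_km``.

    ``extent`` is (x_min, y_min, x_max, y_max) in projected km.  The grid is
    anchored at ``origin`` (shared across scales) so successive doublings
    nest.  Sentinel scales produce a single cell: ``continental`` covers the
    extent; ``global`` is symbolic (infinite bounds, NaN area).
    """
    if scale_km in SENTINEL_SCALES:
        x0, y0, x1, y1 = (extent if scale_km == "continental" else (-np.inf, -np.inf, np.inf, np.inf))
        area = (x1 - x0) * (y1 - y0) if scale_km == "continental" else np.nan
        cells = pd.DataFrame(
            [{"cell_id": f"{scale_km}:0:0", "ix": 0, "iy": 0, "x_min": x0, "y_min": y0,
              "x_max": x1, "y_max": y1, "area_km2": area}]
        )
        return Grid(scale=scale_km, cells=cells, origin=origin)
    if scale_km not in GRID_SCALES_KM:
        raise ValueError(f"unknown scale {scale_km!r}; use one of {ALL_SCALES}")
    x0, y0, x1, y1 = extent
    s = float(scale_km)
    ix0 = int(np.floor((x0 - origin[0]) / s))
    iy0 = int(np.floor((y0 - origin[1]) / s))
    ix1 = int(np.ceil((x1 - origin[0]) / s))
    iy1 = int(np.ceil((y1 - origin[1]) / s))
    rows = []
    for ix in range(ix0, max(ix1, ix0 + 1)):
        for iy in range(iy0, max(iy1, iy0 + 1)):
            rows.append(
                {
                    "cell_id": f"{scale_km}:{ix}:{iy}",
                    "ix": ix,
                    "iy": iy,
                    "x_min": origin[0] + ix * s,
                    "y_min": origin[1] + iy * s,
                    "x_max": origin[0] + (ix + 1) * s,
                    "y_max": origin[1] + (iy + 1) * s,
                    "area_km2": s * s,
                }
            )
    return Grid(scale=scale_km, cells=pd.DataFrame(rows), origin=origin)


@dataclass
class CellAssignment:
    """Route-to-cell map at one scale, with per-year retention masks."""

    scale: object
    route_to_cell: pd.Series  # index route_id -> cell_id
    cell_routes: dict = field(default_factory=dict)  # cell_id -> [route_id]
    retained: pd.DataFrame | None = None  # cells x years boolean mask

    def routes_in(self, cell_id) -> list:
        return self.cell_routes[cell_id]


def _cell_index(coord, origin, s):
    """Grid index with the lower-indexed cell winning exact-boundary ties."""
    u = (np.asarray(coord, dtype=float) - origin) / s
    idx = np.floor(u).astype(int)
    on_edge = (u == idx) & (idx > 0)
    # floor puts a boundary point into the upper cell; shift it down
    return np.where(on_edge, idx - 1, idx)


def assign_routes_to_cells(routes: pd.DataFrame, grid: Grid) -> CellAssignment:
    """Assign each route to the cell containing its median point."""
    if grid.is_sentinel:
        cell = grid.cells["cell_id"].iloc[0]
        mapping = pd.Series(cell, index=routes["route_id"].to_numpy())
    else:
        s = float(grid.scale)
        ix = _cell_index(routes["x_km"].to_numpy(), grid.origin[0], s)
        iy = _cell_index(routes["y_km"].to_numpy(), grid.origin[1], s)
        known = set(grid.cells["cell_id"])
        ids = [f"{grid.scale}:{a}:{b}" for a, b in zip(ix, iy)]
        bad = [r for r, cid in zip(routes["route_id"], ids) if cid not in known]
        if bad:
            raise ValueError(f"routes outside grid extent: {bad[:5]}")
        mapping = pd.Series(ids, index=routes["route_id"].to_numpy())
    cell_routes: dict[str, list] = {}
    for rid, cid in mapping.items():
        cell_routes.setdefault(cid, []).append(rid)
    return CellAssignment(scale=grid.scale, route_to_cell=mapping, cell_routes=cell_routes)


def retain_constant_cells(assignment: CellAssignment, surveyed_years_by_route, years) -> CellAssignment:
    """Per-year retention mask: a cell is kept only with its full route set.

    For each year, a cell is retained only if every route initially assigned
    to it was surveyed that year; this keeps effort per retained cell constant
    across the years in which it appears.
    """
    surveyed = dict(surveyed_years_by_route)
    cells = sorted(assignment.cell_routes)
    mask = pd.DataFrame(False, index=cells, columns=list(years))
    for cid in cells:
        rts = assignment.cell_routes[cid]
        for yr in years:
            mask.loc[cid, yr] = all(yr in surveyed[r] for r in rts)
    return CellAssignment(
        scale=assignment.scale,
        route_to_cell=assignment.route_to_cell,
        cell_routes=assignment.cell_routes,
        retained=mask,
    )


def aggregate_psi(psi_routes: pd.DataFrame, assignment: CellAssignment, year=None) -> pd.DataFrame:
    """Cell-level occupancy: max over member routes, retained cells only.

    ``psi_routes`` is species x route.  If the assignment carries a retention
    mask and ``year`` is given, only cells retained that year are emitted;
    otherwise all cells with complete route occupancy data are used.
    """
    if assignment.retained is not None and year is not None:
        cells = [c for c in assignment.retained.index if assignment.retained.loc[c, year]]
    else:
        cells = sorted(assignment.cell_routes)
    cols = {}
    for cid in cells:
        rts = assignment.cell_routes[cid]
        missing = [r for r in rts if r not in psi_routes.columns]
        if missing:
            raise ValueError(f"retained cell {cid} lacks psi for routes {missing[:5]}")
        cols[cid] = psi_routes[rts].max(axis=1)
    return pd.DataFrame(cols, index=psi_routes.index)
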