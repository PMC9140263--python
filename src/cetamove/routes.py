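"""Geodesic distances and least-cost paths through water.

The observed migration route is compared against the shortest possible route
through water: a Dijkstra shortest path over the graph of water cells of a
bathymetry grid (cells with depth above a minimum, default 10 m), with
16-neighbour connectivity (the 8 adjacent cells plus knight moves, which
reduces grid-direction bias) and WGS84 geodesic edge lengths.  Endpoints are
snapped to the nearest admissible water cell within a few cells, which is
common for coastal endpoints such as fjords.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .geodesy import cumulative_distance, geodesic_inverse
from .geodesy import geodesic_distance as geodesic_distance  # re-export

#: 16-neighbourhood offsets: 8 adjacent plus knight moves.
NEIGHBORS_16 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1),
                (-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1)]
NEIGHBORS_8 = NEIGHBORS_16[:8]


class UnreachableError(RuntimeError):
    pass


@dataclass
class DepthGrid:
    """Bathymetry raster: depth in metres, positive down; <= 0 or NaN is land."""

    lats: np.ndarray
    lons: np.ndarray
    depth: np.ndarray   # (lat, lon)

    def __post_init__(self):
        if self.depth.shape != (len(self.lats), len(self.lons)):
            raise ValueError("depth shape inconsistent with axes")
        if np.any(np.diff(self.lats) <= 0) or np.any(np.diff(self.lons) <= 0):
            raise ValueError("lat/lon axes must be strictly ascending")

    def water_mask(self, min_depth: float = 10.0) -> np.ndarray:
        d = np.where(np.isfinite(self.depth), self.depth, -1.0)
        return d > min_depth


@dataclass
class RoutePath:
    """An ordered path of lon/lat vertices with its geodesic length."""

    lons: np.ndarray
    lats: np.ndarray
    cells: list[tuple[int, int]]

    @property
    def length_km(self) -> float:
        if len(self.lons) < 2:
            return 0.0
        return float(cumulative_distance(self.lons, self.lats)[-1] / 1000.0)


def _snap(grid: DepthGrid, lon, lat, water, max_cells: int = 5):
    """Nearest admissible cell within ``max_cells`` of the naive nearest cell."""
    la = int(np.argmin(np.abs(grid.lats - lat)))
    lo = int(np.argmin(np.abs(grid.lons - lon)))
    if water[la, lo]:
        return la, lo
    best = None
    for r in range(1, max_cells + 1):
        for dla in range(-r, r + 1):
            for dlo in range(-r, r + 1):
                if max(abs(dla), abs(dlo)) != r:
                    continue
                a, b = la + dla, lo + dlo
                if 0 <= a < len(grid.lats) and 0 <= b < len(grid.lons) and water[a, b]:
                    key = (abs(dla) + abs(dlo), a, b)
                    if best is None or key < best[0]:
                        best = (key, a, b)
        if best is not None:
            return best[1], best[2]
    raise UnreachableError(
        f"no admissible water cell within {max_cells} cells of ({lon}, {lat})"
    )


def build_water_graph(grid: DepthGrid, min_depth: float = 10.0,
                      connectivity: int = 16):
    """Sparse geodesic-weighted adjacency over water cells.

    Returns ``(adjacency, node_of_cell, cells)`` where ``node_of_cell`` maps
    (lat_idx, lon_idx) -> node id.
    """
    water = grid.water_mask(min_depth)
    cells = [(i, j) for i in range(len(grid.lats)) for j in range(len(grid.lons))
             if water[i, j]]
    node_of = {c: k for k, c in enumerate(cells)}
    offsets = NEIGHBORS_16 if connectivity == 16 else NEIGHBORS_8
    rows, colns, w = [], [], []
    for (i, j) in cells:
        a = node_of[(i, j)]
        for di, dj in offsets:
            ni, nj = i + di, j + dj
            if (ni, nj) in node_of:
                # knight moves must pass a water corridor: at least one of the
                # two cells adjacent to both endpoints has to be water
                if abs(di) + abs(dj) == 3:
                    mid1 = (i + di // 2, j + dj) if abs(di) == 2 else (i + di, j + dj // 2)
                    mid2 = (i + di // 2, j) if abs(di) == 2 else (i, j + dj // 2)
                    if mid1 not in node_of and mid2 not in node_of:
                        continue
                b = node_of[(ni, nj)]
                if a < b:
                    d, _ = geodesic_inverse(grid.lons[j], grid.lats[i],
                                            grid.lons[nj], grid.lats[ni])
                    rows.append(a)
                    colns.append(b)
                    w.append(d)
    n = len(cells)
    adj = coo_matrix((w + w, (rows + colns, colns + rows)), shape=(n, n)).tocsr()
    return adj, node_of, cells


def least_cost_path(start, end, grid: DepthGrid, min_depth: float = 10.0,
                    connectivity: int = 16, snap_cells: int = 5) -> RoutePath:
    """Shortest water path between two lon/lat points on the cell graph.

    Exact optimum on the graph (Dijkstra); raises ``UnreachableError`` when
    the endpoints lie in disconnected basins or cannot be snapped to water.
    """
    water = grid.water_mask(min_depth)
    a = _snap(grid, start[0], start[1], water, snap_cells)
    b = _snap(grid, end[0], end[1], water, snap_cells)
    adj, node_of, cells = build_water_graph(grid, min_depth, connectivity)
    src, dst = node_of[a], node_of[b]
    if src == dst:
        lon, lat = grid.lons[a[1]], grid.lats[a[0]]
        return RoutePath(np.array([lon]), np.array([lat]), [a])
    dist, pred = _csgraph_dijkstra(adj, indices=src, return_predecessors=True)
    if not np.isfinite(dist[dst]):
        raise UnreachableError("end point not reachable through water")
    path_nodes = [dst]
    while path_nodes[-1] != src:
        path_nodes.append(int(pred[path_nodes[-1]]))
    path_nodes.reverse()
    pcells = [cells[k] for k in path_nodes]
    return RoutePath(
        lons=np.array([grid.lons[j] for _, j in pcells]),
        lats=np.array([grid.lats[i] for i, _ in pcells]),
        cells=pcells,
    )


@dataclass
class RouteComparison:
    observed_km: float
    direct_km: float
    via_stopovers_km: float

    @property
    def stopover_increase_pct(self) -> float:
        """Percent increase of the via-stopover route over the direct route."""
        return 100.0 * (self.via_stopovers_km - self.direct_km) / self.direct_km

    @property
    def observed_excess_over_direct_pct(self) -> float:
        return 100.0 * (self.observed_km - self.direct_km) / self.direct_km

    @property
    def observed_excess_over_stopovers_pct(self) -> float:
        return 100.0 * (self.observed_km - self.via_stopovers_km) / self.via_stopovers_km


def route_comparison(observed_lons, observed_lats, direct: RoutePath,
                     via_stopovers: RoutePath) -> RouteComparison:
    """Compare observed cumulative distance with direct/via-stopover routes."""
    if len(observed_lons) == 0:
        raise ValueError("observed track is empty")
    obs_km = float(cumulative_distance(observed_lons, observed_lats)[-1] / 1000.0)
    return RouteComparison(
        observed_km=obs_km,
        direct_km=direct.length_km,
        via_stopovers_km=via_stopovers.length_km,
    )


def mean_position(lons, lats) -> tuple[float, float]:
    """Arithmetic mean lon/lat of a set of locations (segment centroid)."""
    return float(np.mean(lons)), float(np.mean(lats))
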