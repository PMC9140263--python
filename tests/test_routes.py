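import heapq
import itertools

import numpy as np
import pytest

from cetamove.geodesy import geodesic_distance
from cetamove.routes import (NEIGHBORS_16, DepthGrid, RoutePath,
                             UnreachableError, build_water_graph,
                             least_cost_path, mean_position, route_comparison)


def make_grid(depth):
    depth = np.asarray(depth, dtype=float)
    nlat, nlon = depth.shape
    return DepthGrid(lats=np.linspace(45.0, 45.0 + 0.5 * (nlat - 1), nlat),
                     lons=np.linspace(-20.0, -20.0 + 0.5 * (nlon - 1), nlon),
                     depth=depth)


def enumerate_shortest(grid, src_cell, dst_cell, min_depth=10.0):
    """Pruned exhaustive path search over the water-cell graph (oracle)."""
    water = grid.water_mask(min_depth)
    best = [np.inf]

    def edge(a, b):
        return geodesic_distance((grid.lons[a[1]], grid.lats[a[0]]),
                                 (grid.lons[b[1]], grid.lats[b[0]]))

    def is_water(c):
        return (0 <= c[0] < water.shape[0] and 0 <= c[1] < water.shape[1]
                and water[c])

    def passable(cell, di, dj):
        """Knight moves need a water corridor through an adjacent cell."""
        if abs(di) + abs(dj) != 3:
            return True
        i, j = cell
        if abs(di) == 2:
            mids = [(i + di // 2, j + dj), (i + di // 2, j)]
        else:
            mids = [(i + di, j + dj // 2), (i, j + dj // 2)]
        return any(is_water(m) for m in mids)

    def lower_bound(cell):
        # straight geodesic to the target never overestimates the path length
        return edge(cell, dst_cell)

    labels = {}   # cell -> best accumulated length seen (dominance pruning)

    def dfs(cell, visited, acc):
        if acc + lower_bound(cell) >= best[0]:
            return
        if acc >= labels.get(cell, np.inf):
            return   # a cheaper way to reach this cell was already explored
        labels[cell] = acc
        if cell == dst_cell:
            best[0] = acc
            return
        nbrs = []
        for di, dj in NEIGHBORS_16:
            nxt = (cell[0] + di, cell[1] + dj)
            if (is_water(nxt) and nxt not in visited
                    and passable(cell, di, dj)):
                nbrs.append((lower_bound(nxt), nxt, edge(cell, nxt)))
        for _, nxt, w in sorted(nbrs):
            visited.add(nxt)
            dfs(nxt, visited, acc + w)
            visited.remove(nxt)

    dfs(src_cell, {src_cell}, 0.0)
    return best[0]


class TestGeodesicDistance:
    def test_equatorial_degree(self):
        assert geodesic_distance((0.0, 0.0), (1.0, 0.0)) / 1000.0 == pytest.approx(
            111.32, abs=0.01)

    def test_zero_and_symmetry(self):
        assert geodesic_distance((3.0, 50.0), (3.0, 50.0)) == 0.0
        assert geodesic_distance((0.0, 10.0), (5.0, 12.0)) == pytest.approx(
            geodesic_distance((5.0, 12.0), (0.0, 10.0)))


class TestLeastCostPath:
    def test_open_water_path_close_to_straight_line(self):
        grid = make_grid(np.full((8, 8), 3000.0))
        p = least_cost_path((-20.0, 45.0), (-16.5, 48.5), grid)
        straight = geodesic_distance((-20.0, 45.0), (-16.5, 48.5)) / 1000.0
        cell_diag = geodesic_distance((-20.0, 45.0), (-19.5, 45.5)) / 1000.0
        assert p.length_km <= straight + cell_diag

    def test_wall_with_gap_matches_enumeration_oracle(self):
        depth = np.full((7, 7), 3000.0)
        depth[:, 3] = 0.0       # meridional wall...
        depth[5, 3] = 3000.0    # ...with one gap
        grid = make_grid(depth)
        p = least_cost_path((-20.0, 45.0), (-17.0, 45.0), grid)
        assert (5, 3) in p.cells  # goes through the gap
        ref = enumerate_shortest(grid, (0, 0), (0, 6)) / 1000.0
        assert p.length_km == pytest.approx(ref, rel=1e-9)

    def test_start_equals_end_is_zero_length(self):
        grid = make_grid(np.full((5, 5), 100.0))
        p = least_cost_path((-19.0, 46.0), (-19.0, 46.0), grid)
        assert p.length_km == 0.0

    def test_enclosed_start_is_unreachable(self):
        depth = np.full((7, 7), 3000.0)
        depth[2:5, 2:5] = 0.0
        depth[3, 3] = 3000.0    # pond fully ringed by land
        grid = make_grid(depth)
        with pytest.raises(UnreachableError):
            least_cost_path((grid.lons[3], grid.lats[3]),
                            (grid.lons[6], grid.lats[6]), grid, snap_cells=0)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_grids_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        depth = np.where(rng.random((6, 6)) < 0.35, 0.0, 2000.0)
        depth[0, 0] = depth[5, 5] = 2000.0
        grid = make_grid(depth)
        try:
            p = least_cost_path((grid.lons[0], grid.lats[0]),
                                (grid.lons[5], grid.lats[5]), grid, snap_cells=0)
        except UnreachableError:
            assert enumerate_shortest(grid, (0, 0), (5, 5)) == np.inf
            return
        ref = enumerate_shortest(grid, (0, 0), (5, 5))
        assert p.length_km * 1000.0 == pytest.approx(ref, rel=1e-9)

    def test_raising_min_depth_never_shortens_path(self):
        rng = np.random.default_rng(10)
        depth = rng.uniform(5.0, 60.0, (8, 8))
        depth[0, 0] = depth[7, 7] = 60.0
        grid = make_grid(depth)
        lengths = []
        for md in (10.0, 20.0, 40.0):
            try:
                lengths.append(least_cost_path(
                    (grid.lons[0], grid.lats[0]), (grid.lons[7], grid.lats[7]),
                    grid, min_depth=md, snap_cells=0).length_km)
            except UnreachableError:
                lengths.append(np.inf)
        assert lengths == sorted(lengths)

    def test_triangle_inequality_on_graph_metric(self):
        grid = make_grid(np.full((6, 6), 500.0))
        adj, node_of, cells = build_water_graph(grid)
        from scipy.sparse.csgraph import dijkstra
        D = dijkstra(adj)
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c = rng.integers(0, len(cells), 3)
            assert D[a, c] <= D[a, b] + D[b, c] + 1e-6

    def test_snapping_moves_coastal_endpoint_to_water(self):
        depth = np.full((5, 5), 2000.0)
        depth[0, 0] = 0.0
        grid = make_grid(depth)
        p = least_cost_path((grid.lons[0], grid.lats[0]),
                            (grid.lons[4], grid.lats[4]), grid)
        assert p.cells[0] != (0, 0)


class TestRouteComparison:
    def _path(self, lons, lats):
        return RoutePath(np.asarray(lons, float), np.asarray(lats, float), [])

    def test_identical_routes_zero_increase(self):
        d = self._path([-20, -19, -18], [45, 45.5, 46])
        cmp = route_comparison([-20, -19, -18], [45, 45.5, 46], d, d)
        assert cmp.stopover_increase_pct == pytest.approx(0.0)
        assert cmp.observed_excess_over_stopovers_pct == pytest.approx(0.0)

    def test_ten_percent_detour(self):
        # direct: equatorial arc of 2 degrees (222.64 km); a detour via
        # (1 deg E, 0.4613 deg N) makes each leg ~1.1x half the arc
        direct = self._path([0, 2], [0, 0])
        via = self._path([0, 1, 2], [0, 0.4613, 0])
        cmp = route_comparison([0, 2], [0, 0], direct, via)
        assert cmp.stopover_increase_pct == pytest.approx(10.0, abs=0.2)

    def test_mean_position(self):
        lon, lat = mean_position([10.0, 20.0], [60.0, 70.0])
        assert (lon, lat) == (15.0, 65.0)
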