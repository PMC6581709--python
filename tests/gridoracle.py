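"""Brute-force geodesic oracle: shortest path on a fine 8-connected grid
graph restricted to the polygon.

The grid path length converges to the true geodesic from above; on an
8-connected grid the overestimate is bounded by the octile factor
(2*sqrt(2) - 2) / sqrt(2)  ->  length <= true * 1.0824, plus a snapping
error of at most 2 * spacing * sqrt(2) for the two endpoints.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import LineString, Point
from shapely.prepared import prep

OCTILE_FACTOR = 2.0 * np.sqrt(2.0) - 2.0 + 1.0  # ~1.0824, 8-connectivity bound


class GridOracle:
    def __init__(self, polygon, spacing: float):
        self.polygon = polygon
        self.spacing = spacing
        cover = prep(polygon.buffer(1e-9))
        minx, miny, maxx, maxy = polygon.bounds
        xs = np.arange(minx, maxx + spacing, spacing)
        ys = np.arange(miny, maxy + spacing, spacing)
        nodes = []
        index = {}
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                if cover.covers(Point(x, y)):
                    index[(i, j)] = len(nodes)
                    nodes.append((x, y))
        self.nodes = np.asarray(nodes)
        rows, cols, weights = [], [], []
        steps = [(1, 0), (0, 1), (1, 1), (1, -1)]
        for (i, j), a in index.items():
            for di, dj in steps:
                b = index.get((i + di, j + dj))
                if b is None:
                    continue
                seg = LineString([self.nodes[a], self.nodes[b]])
                if cover.covers(seg):
                    rows.append(a)
                    cols.append(b)
                    weights.append(seg.length)
        n = len(nodes)
        self.graph = coo_matrix((weights, (rows, cols)), shape=(n, n)).tocsr()

    def snap(self, p) -> int:
        return int(np.argmin(np.linalg.norm(self.nodes - np.asarray(p), axis=1)))

    def distances_from(self, p) -> np.ndarray:
        return dijkstra(self.graph, directed=False, indices=self.snap(p))

    def distance(self, p, q) -> float:
        return float(self.distances_from(p)[self.snap(q)])

    def bound_ok(self, exact: float, grid: float) -> bool:
        """Is a claimed exact geodesic consistent with the grid estimate?"""
        snap_err = 2.0 * self.spacing * np.sqrt(2.0)
        return (exact <= grid + snap_err + 1e-9) and (
            grid <= exact * OCTILE_FACTOR + 2.0 * snap_err
        )
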