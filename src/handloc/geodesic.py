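"""Shortest paths constrained to the interior of the hand polygon.

All error metrics are geodesic: the length of the locally length-minimizing
curve between two points that never leaves the closed hand outline.  In a
simple polygon that curve is a polyline whose interior vertices are reflex
vertices of the polygon, so the exact distance is obtained from a
visibility graph over {start, end, polygon vertices} followed by Dijkstra.

Segments that graze the boundary (collinear with an edge or touching a
vertex) count as visible; robustness against floating-point orientation
noise comes from testing visibility on the polygon dilated by ``_TOL``
(1e-9 template units).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import LineString, Point
from shapely.prepared import prep

from .hand_template import HandTemplate

_TOL = 1e-9  # boundary-grazing tolerance, template units


@dataclass(frozen=True)
class GeodesicPath:
    """A realizing shortest path: start, any polygon corner waypoints, end."""

    waypoints: tuple[tuple[float, float], ...]
    length: float

    def reversed(self) -> "GeodesicPath":
        return GeodesicPath(tuple(reversed(self.waypoints)), self.length)


class GeodesicEngine:
    """Per-template geodesic solver with cached vertex-to-vertex paths.

    Caching only reuses exact intermediate results (the vertex visibility
    graph and all-pairs vertex distances); query answers are identical with
    or without it.
    """

    def __init__(self, template: HandTemplate):
        self.template = template
        self._poly = template.polygon
        # covers() on the slightly dilated polygon = closed-polygon
        # visibility with boundary grazing allowed
        self._cover = prep(self._poly.buffer(_TOL, join_style="mitre"))
        self._vertices = np.asarray(template.outline, dtype=float)
        n = len(self._vertices)
        vis = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                vis[i, j] = vis[j, i] = self._segment_inside(
                    self._vertices[i], self._vertices[j]
                )
        diff = self._vertices[:, None, :] - self._vertices[None, :, :]
        w = np.linalg.norm(diff, axis=-1)
        w[~vis] = np.inf
        np.fill_diagonal(w, 0.0)
        self._vertex_vis = vis
        graph = csr_matrix(np.where(np.isfinite(w), w, 0.0))
        self._vv_dist, self._vv_pred = dijkstra(
            graph, directed=False, return_predecessors=True
        )
        self._site_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    # -- primitives -------------------------------------------------------

    def _segment_inside(self, p: np.ndarray, q: np.ndarray) -> bool:
        if np.allclose(p, q):
            return True
        return bool(self._cover.covers(LineString([p, q])))

    def _require_inside(self, p: Sequence[float], name: str) -> np.ndarray:
        pt = np.asarray(p, dtype=float)
        shp = Point(pt)
        if not self._poly.covers(shp) and self._poly.distance(shp) > _TOL:
            raise ValueError(f"point {name}={tuple(pt)} lies outside the hand outline")
        return pt

    def _visible_vertices(self, p: np.ndarray) -> np.ndarray:
        return np.array(
            [self._segment_inside(p, v) for v in self._vertices], dtype=bool
        )

    # -- queries ----------------------------------------------------------

    def distance(self, p: Sequence[float], q: Sequence[float]) -> float:
        return self.path(p, q).length

    def path(self, p: Sequence[float], q: Sequence[float]) -> GeodesicPath:
        """Shortest in-polygon path from ``p`` to ``q``."""
        p = self._require_inside(p, "p")
        q = self._require_inside(q, "q")
        if np.allclose(p, q):
            return GeodesicPath((tuple(p), tuple(q)), 0.0)
        if self._segment_inside(p, q):
            return GeodesicPath(
                (tuple(p), tuple(q)), float(np.linalg.norm(q - p))
            )
        vis_p = self._visible_vertices(p)
        vis_q = self._visible_vertices(q)
        dp = np.where(vis_p, np.linalg.norm(self._vertices - p, axis=1), np.inf)
        dq = np.where(vis_q, np.linalg.norm(self._vertices - q, axis=1), np.inf)
        # best route: p -> vertex i -> ... -> vertex j -> q
        total = dp[:, None] + self._vv_dist + dq[None, :]
        i, j = np.unravel_index(np.argmin(total), total.shape)
        length = float(total[i, j])
        if not np.isfinite(length):
            raise ValueError("polygon interior is disconnected at query points")
        chain = self._vertex_chain(int(i), int(j))
        waypoints = (tuple(p), *[tuple(self._vertices[k]) for k in chain], tuple(q))
        return GeodesicPath(waypoints, length)

    def _vertex_chain(self, i: int, j: int) -> list[int]:
        chain = [j]
        while chain[-1] != i:
            prev = self._vv_pred[i, chain[-1]]
            if prev < 0:
                raise ValueError("no vertex path found")
            chain.append(int(prev))
        return list(reversed(chain))

    def distances_to_sites(self, p: Sequence[float]) -> dict[int, float]:
        """Geodesic distance from ``p`` to every stimulation site.

        Used by the confusion-matrix discretization; one visibility scan of
        ``p`` serves all 24 sites via the cached vertex/site distances.
        """
        p = self._require_inside(p, "p")
        vis_p = self._visible_vertices(p)
        dp = np.where(vis_p, np.linalg.norm(self._vertices - p, axis=1), np.inf)
        out: dict[int, float] = {}
        for site in self.template.sites:
            s_pos, s_dist = self._site_vertex_distances(site.site_id)
            if self._segment_inside(p, s_pos):
                out[site.site_id] = float(np.linalg.norm(s_pos - p))
            else:
                out[site.site_id] = float(np.min(dp + s_dist))
        return out

    def _site_vertex_distances(self, site_id: int) -> tuple[np.ndarray, np.ndarray]:
        cached = self._site_cache.get(site_id)
        if cached is None:
            s = np.asarray(self.template.site(site_id).position, dtype=float)
            vis = self._visible_vertices(s)
            ds = np.where(vis, np.linalg.norm(self._vertices - s, axis=1), np.inf)
            # shortest distance from each vertex to the site through the graph
            best = np.min(self._vv_dist + ds[None, :], axis=1)
            cached = (s, best)
            self._site_cache[site_id] = cached
        return cached


_ENGINES: dict[int, GeodesicEngine] = {}


def engine_for(template: HandTemplate) -> GeodesicEngine:
    """Memoized engine per template instance."""
    key = id(template)
    eng = _ENGINES.get(key)
    if eng is None or eng.template is not template:
        eng = GeodesicEngine(template)
        _ENGINES[key] = eng
    return eng


def geodesic_distance(
    template: HandTemplate, p: Sequence[float], q: Sequence[float]
) -> float:
    """Length of the shortest in-polygon path between two interior points,
    in template units."""
    return engine_for(template).distance(p, q)


def geodesic_path(
    template: HandTemplate, p: Sequence[float], q: Sequence[float]
) -> GeodesicPath:
    return engine_for(template).path(p, q)
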