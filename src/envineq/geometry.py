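"""Areal support of the analysis: a polygonal tessellation of an abstract city.

Coordinates live on the unit square with no CRS; the analysis only ever uses
relative distances.  Physical areas are reported in km**2 by scaling the unit
square to ``DOMAIN_KM2`` (roughly the footprint of a compact European city).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import voronoi_diagram

from ._rng import substream
from .errors import GraphError, InvalidArgumentError

__all__ = ["CityGeometry", "generate_geometry", "DOMAIN_KM2"]

DOMAIN_KM2 = 101.3  # physical area assigned to the unit square
_UNIT_SQUARE = box(0.0, 0.0, 1.0, 1.0)


@dataclass
class CityGeometry:
    """Polygonal tessellation of the unit square plus its adjacency graph.

    Attributes
    ----------
    area_ids
        Integer labels, 1-based, in a fixed order shared by all arrays.
    polygons
        One shapely polygon per area; pairwise interior-disjoint and jointly
        covering the unit square.
    centroids
        (n, 2) array of polygon centroids.
    neighbors
        area_id -> set of adjacent area_ids (shared positive-length boundary).
    area_km2
        Physical area of each polygon.
    """

    area_ids: list[int]
    polygons: list[Polygon]
    centroids: np.ndarray
    neighbors: dict[int, set[int]] = field(repr=False)
    area_km2: np.ndarray = field(repr=False)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def index_of(self, area_id: int) -> int:
        return self.area_ids.index(area_id)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.area_ids)
        for a, nbrs in self.neighbors.items():
            g.add_edges_from((a, b) for b in nbrs if b > a)
        return g

    def adjacency_matrix(self) -> np.ndarray:
        """Dense 0/1 adjacency in area order."""
        pos = {a: k for k, a in enumerate(self.area_ids)}
        m = np.zeros((self.n_areas, self.n_areas))
        for a, nbrs in self.neighbors.items():
            for b in nbrs:
                m[pos[a], pos[b]] = 1.0
        return m

    def containing_area(self, points: np.ndarray) -> np.ndarray:
        """Row index of the polygon containing each (x, y) point.

        Points on shared boundaries resolve to the nearest centroid, so the
        mapping is total on the unit square.
        """
        pts = shapely.points(np.asarray(points, dtype=float))
        tree = shapely.STRtree(self.polygons)
        out = np.full(len(pts), -1, dtype=int)
        q = tree.query(pts, predicate="intersects")
        # first match wins; overlaps only occur on shared boundaries
        for pi, gi in zip(*q):
            if out[pi] == -1:
                out[pi] = gi
        missing = np.flatnonzero(out == -1)
        if missing.size:
            d = np.linalg.norm(
                np.asarray(points)[missing, None, :] - self.centroids[None, :, :], axis=2
            )
            out[missing] = np.argmin(d, axis=1)
        return out

    def validate(self) -> None:
        total = sum(p.area for p in self.polygons)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise GraphError(f"polygons do not tessellate the unit square (area {total})")
        for a, nbrs in self.neighbors.items():
            if a in nbrs:
                raise GraphError(f"adjacency is reflexive at area {a}")
            for b in nbrs:
                if a not in self.neighbors[b]:
                    raise GraphError(f"adjacency not symmetric for ({a}, {b})")
        if not nx.is_connected(self.graph()):
            raise GraphError("adjacency graph is disconnected")


def _quasi_uniform_points(n: int, rng: np.random.Generator) -> np.ndarray:
    """n jittered-grid points in the unit square (quasi-uniform, seeded)."""
    g = math.ceil(math.sqrt(n))
    spacing = 1.0 / g
    xs, ys = np.meshgrid(np.arange(g), np.arange(g))
    centers = np.column_stack([(xs.ravel() + 0.5), (ys.ravel() + 0.5)]) * spacing
    jitter = rng.uniform(-0.35, 0.35, size=centers.shape) * spacing
    pts = centers + jitter
    keep = np.sort(rng.choice(len(pts), size=n, replace=False))
    return pts[keep]


def generate_geometry(n_areas: int, seed: int) -> CityGeometry:
    """Voronoi tessellation of the unit square from quasi-uniform seed points.

    Deterministic given ``seed``.  Adjacency is defined by shared
    positive-length boundary; the jittered-grid construction guarantees a
    connected adjacency graph.
    """
    if n_areas < 4:
        raise InvalidArgumentError("n_areas must be at least 4")
    rng = substream(seed, "geometry")
    points = _quasi_uniform_points(n_areas, rng)
    cells = voronoi_diagram(MultiPoint([tuple(p) for p in points]), envelope=_UNIT_SQUARE)
    clipped = [geom.intersection(_UNIT_SQUARE) for geom in cells.geoms]
    # map each Voronoi cell back to its seed point
    pts = shapely.points(points)
    order = np.full(n_areas, -1, dtype=int)
    for gi, poly in enumerate(clipped):
        hit = shapely.covers(poly, pts)
        j = int(np.argmax(hit))
        if hit[j]:
            order[j] = gi
    if np.any(order < 0):  # pragma: no cover - degenerate clipping
        raise GraphError("failed to match Voronoi cells to seed points")
    polygons = [clipped[k] for k in order]
    area_ids = list(range(1, n_areas + 1))
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polygons])
    area = np.array([p.area for p in polygons])
    neighbors: dict[int, set[int]] = {a: set() for a in area_ids}
    tree = shapely.STRtree(polygons)
    ii, jj = tree.query(polygons, predicate="intersects")
    for i, j in zip(ii, jj):
        if i < j and polygons[i].intersection(polygons[j]).length > 1e-9:
            neighbors[area_ids[i]].add(area_ids[j])
            neighbors[area_ids[j]].add(area_ids[i])
    geom = CityGeometry(
        area_ids=area_ids,
        polygons=polygons,
        centroids=centroids,
        neighbors=neighbors,
        area_km2=area * DOMAIN_KM2,
    )
    geom.validate()
    return geom
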