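"""Voronoi tessellation of read pairs in a viewport.

Every read pair is a 2D point (x, y) in base-pair coordinates; its Voronoi
cell — the locus of plane points nearer to it than to any other pair —
is clipped to the rectangular viewport, and the reciprocal clipped area is
an adaptive local density estimate.  Cells tile the viewport exactly, so
densities integrate back to the number of retained points.

The tessellation is computed with Qhull (scipy.spatial.Voronoi).  Cells of
hull points are unbounded; boundedness inside the viewport is obtained by
adding the mirror image of every seed across each of the four viewport
edges, which places the cell boundary of an edge-adjacent seed exactly on
the viewport edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi as _QhullVoronoi

_MAX_VIEWPORT_AREA = 2.0 ** 53  # beyond this, float64 bp^2 arithmetic degrades


class EmptyDiagramError(ValueError):
    """No points fall inside the requested viewport."""


@dataclass(frozen=True)
class Viewport:
    """Rectangular query region; intervals are 0-based half-open bp."""

    chrom_x: str
    start_x: int
    end_x: int
    chrom_y: str
    start_y: int
    end_y: int

    def __post_init__(self):
        if self.end_x <= self.start_x or self.end_y <= self.start_y:
            raise ValueError("viewport intervals must satisfy end > start")
        if self.area > _MAX_VIEWPORT_AREA:
            raise ValueError("viewport area exceeds 2^53 bp^2")

    @classmethod
    def square(cls, chrom: str, start: int, end: int) -> "Viewport":
        return cls(chrom, start, end, chrom, start, end)

    @property
    def width(self) -> float:
        return float(self.end_x - self.start_x)

    @property
    def height(self) -> float:
        return float(self.end_y - self.start_y)

    @property
    def area(self) -> float:
        return float(self.end_x - self.start_x) * float(self.end_y - self.start_y)

    @property
    def on_diagonal(self) -> bool:
        return (self.chrom_x == self.chrom_y and self.start_x == self.start_y
                and self.end_x == self.end_y)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Closed-boundary membership mask for an (n, 2) point array."""
        points = np.asarray(points, dtype=float)
        return ((points[:, 0] >= self.start_x) & (points[:, 0] <= self.end_x)
                & (points[:, 1] >= self.start_y) & (points[:, 1] <= self.end_y))


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a simple polygon given as an (k, 2) vertex array."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area centroid via the signed-area decomposition formula."""
    x, y = vertices[:, 0], vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    signed_area = 0.5 * cross.sum()
    if abs(signed_area) < 1e-300:
        return vertices.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * signed_area)
    cy = ((y + yn) * cross).sum() / (6.0 * signed_area)
    return np.array([cx, cy])


@dataclass(frozen=True)
class VoronoiCell:
    seed: tuple
    polygon: np.ndarray  # (k, 2) vertices, counter-clockwise
    area: float
    multiplicity: int = 1

    @property
    def density(self) -> float:
        return self.multiplicity / self.area

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.polygon)


@dataclass
class VoronoiDiagram:
    viewport: Viewport
    cells: list
    mode: str = "full"  # full | reflected | fallback_binned
    filter_distance: float = None

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def seeds(self) -> np.ndarray:
        return np.array([c.seed for c in self.cells], dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.cells], dtype=float)

    @property
    def multiplicities(self) -> np.ndarray:
        return np.array([c.multiplicity for c in self.cells], dtype=int)

    @property
    def densities(self) -> np.ndarray:
        return self.multiplicities / self.areas

    @property
    def total_multiplicity(self) -> int:
        return int(self.multiplicities.sum())

    def density_of_points(self, points: np.ndarray) -> np.ndarray:
        """Density of the cell owning each (possibly duplicated) input point.

        Points are matched to seeds through the same coincidence quantum
        used when the diagram was built.
        """
        quantum = _quantum(self.viewport)
        lookup = {tuple(k): c.density
                  for c, k in zip(self.cells,
                                  _quantize(self.seeds, quantum))}
        keys = _quantize(points, quantum)
        return np.array([lookup[tuple(k)] for k in keys])

    def to_geojson(self) -> dict:
        """GeoJSON-like polygon dump (debugging aid)."""
        return {"type": "FeatureCollection", "features": [
            {"type": "Feature",
             "geometry": {"type": "Polygon",
                          "coordinates": [c.polygon.tolist() + [c.polygon[0].tolist()]]},
             "properties": {"seed": list(c.seed), "area": c.area,
                            "multiplicity": c.multiplicity}}
            for c in self.cells]}


@dataclass
class BinnedGrid:
    """Fixed-grid fallback used above the Voronoi point-count threshold."""

    viewport: Viewport
    counts: np.ndarray  # (ny, nx), row = y bin
    mode: str = "fallback_binned"


def _quantum(viewport: Viewport) -> float:
    # points closer than ~1e-12 of the viewport span are numerically
    # indistinguishable to the tessellation; collapse them to one seed
    return 1e-12 * max(viewport.width, viewport.height)


def _quantize(points: np.ndarray, quantum: float) -> np.ndarray:
    return np.round(np.asarray(points, dtype=float) / quantum).astype(np.int64)


def _dedupe(points: np.ndarray, quantum: float):
    """Collapse (near-)coincident points; returns (seeds, multiplicities).

    Seeds keep the coordinates of the first occurrence; multiplicity counts
    every collapsed input point.
    """
    keys = _quantize(points, quantum)
    _, first, counts = np.unique(keys, axis=0, return_index=True,
                                 return_counts=True)
    return points[np.sort(first)], counts[np.argsort(first)]


def _clip_to_box(vertices: np.ndarray, viewport: Viewport) -> np.ndarray:
    """Clip a convex polygon to the viewport (Sutherland–Hodgman)."""
    import shapely
    from shapely.geometry import Polygon, box
    poly = Polygon(vertices)
    clipped = poly.intersection(box(viewport.start_x, viewport.start_y,
                                    viewport.end_x, viewport.end_y))
    if clipped.is_empty or clipped.geom_type != "Polygon":
        raise ValueError("cell degenerated under clipping")
    coords = np.asarray(clipped.exterior.coords)[:-1]
    return coords


def _cells_from_seeds(seeds: np.ndarray, multiplicities: np.ndarray,
                      viewport: Viewport) -> list:
    n = len(seeds)
    if n == 0:
        raise EmptyDiagramError(
            "no points inside the viewport; widen the region or relax filters")
    rect = np.array([[viewport.start_x, viewport.start_y],
                     [viewport.end_x, viewport.start_y],
                     [viewport.end_x, viewport.end_y],
                     [viewport.start_x, viewport.end_y]], dtype=float)
    if n == 1:
        return [VoronoiCell(tuple(seeds[0]), rect, viewport.area,
                            int(multiplicities[0]))]
    # Mirror every seed across planes slightly outside each viewport edge.
    # The seed/mirror bisector then lies outside the viewport, so the
    # partition inside the viewport is untouched, every region is bounded,
    # and a seed sitting exactly on an edge never collides with its mirror.
    span = max(viewport.width, viewport.height)
    delta = 1e-6 * span
    x, y = seeds[:, 0], seeds[:, 1]
    mirrors = np.vstack([
        np.column_stack([2.0 * (viewport.start_x - delta) - x, y]),
        np.column_stack([2.0 * (viewport.end_x + delta) - x, y]),
        np.column_stack([x, 2.0 * (viewport.start_y - delta) - y]),
        np.column_stack([x, 2.0 * (viewport.end_y + delta) - y]),
    ])
    vor = _QhullVoronoi(np.vstack([seeds, mirrors]))
    tol = 1e-12 * span
    cells = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:  # cannot happen with the offset mirrors; be safe
            raise RuntimeError("unbounded Voronoi region despite edge mirrors")
        verts = vor.vertices[region]
        center = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - center[1],
                                      verts[:, 0] - center[0]))
        verts = verts[order]
        out_x = (verts[:, 0] < viewport.start_x - tol) | (verts[:, 0] > viewport.end_x + tol)
        out_y = (verts[:, 1] < viewport.start_y - tol) | (verts[:, 1] > viewport.end_y + tol)
        if np.any(out_x | out_y):
            verts = _clip_to_box(verts, viewport)
        else:
            verts = np.column_stack([
                np.clip(verts[:, 0], viewport.start_x, viewport.end_x),
                np.clip(verts[:, 1], viewport.start_y, viewport.end_y)])
        cells.append(VoronoiCell(tuple(seeds[i]), verts, polygon_area(verts),
                                 int(multiplicities[i])))
    return cells


def build_voronoi(points: np.ndarray, viewport: Viewport) -> VoronoiDiagram:
    """Voronoi diagram of the points inside ``viewport``, clipped to it.

    Points outside the viewport are discarded (closed boundaries: points
    exactly on the edge are retained); coincident points collapse to a
    single seed carrying a multiplicity.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise EmptyDiagramError(
            "no points inside the viewport; widen the region or relax filters")
    points = points[viewport.contains(points)]
    if len(points) == 0:
        raise EmptyDiagramError(
            "no points inside the viewport; widen the region or relax filters")
    seeds, mult = _dedupe(points, _quantum(viewport))
    cells = _cells_from_seeds(seeds, mult, viewport)
    return VoronoiDiagram(viewport, cells, mode="full")


def cell_densities(diagram: VoronoiDiagram) -> dict:
    """Mapping seed -> reciprocal-area density (multiplicity / area)."""
    return {c.seed: c.density for c in diagram.cells}


def apply_filter_distance(points: np.ndarray, d: float) -> np.ndarray:
    """Drop points whose perpendicular distance to the x = y axis is < d.

    Perpendicular distance of (x, y) to the diagonal is |x - y| / sqrt(2),
    so the kept set is {p : |x - y| >= d * sqrt(2)}.  Only meaningful for
    intrachromosomal planes; interchromosomal points have no diagonal and
    should not be passed through this filter.
    """
    if d < 0:
        raise ValueError("filter distance must be >= 0")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if d == 0:
        return points
    keep = np.abs(points[:, 0] - points[:, 1]) >= d * math.sqrt(2.0)
    return points[keep]


def reflect_upper_triangle(points: np.ndarray, viewport: Viewport) -> VoronoiDiagram:
    """Diagram for an on-diagonal viewport from upper-triangle points.

    The contact process is symmetric under (x, y) -> (y, x); the diagram is
    built over the symmetrized seed set, which equals computing it on the
    upper triangle and mirroring across x = y.  Cells of a mirrored pair are
    exact reflections of each other.
    """
    if not viewport.on_diagonal:
        raise ValueError("reflection requires a square on-diagonal viewport")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise EmptyDiagramError("empty upper triangle; widen the region")
    points = points[viewport.contains(points)]
    if len(points) == 0:
        raise EmptyDiagramError("empty upper triangle; widen the region")
    swap = points[:, 0] > points[:, 1]
    points[swap] = points[swap][:, ::-1]
    seeds, mult = _dedupe(points, _quantum(viewport))
    off_diag = seeds[:, 0] != seeds[:, 1]
    all_seeds = np.vstack([seeds, seeds[off_diag][:, ::-1]])
    all_mult = np.concatenate([mult, mult[off_diag]])
    cells = _cells_from_seeds(all_seeds, all_mult, viewport)
    return VoronoiDiagram(viewport, cells, mode="reflected")


def fallback_bin(points: np.ndarray, viewport: Viewport,
                 max_points: int = 100_000, output_resolution=512) -> BinnedGrid:
    """Fixed-grid binning at the output resolution for oversize point sets.

    Triggered strictly above ``max_points`` (the default threshold is
    100,000 points); one bin per output pixel, so finer Voronoi detail
    would not be resolvable anyway.
    """
    nx, ny = (output_resolution if isinstance(output_resolution, (tuple, list))
              else (output_resolution, output_resolution))
    if nx <= 0 or ny <= 0:
        raise ValueError("output resolution must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    points = points[viewport.contains(points)]
    counts, _, _ = np.histogram2d(
        points[:, 1], points[:, 0], bins=(ny, nx),
        range=[[viewport.start_y, viewport.end_y],
               [viewport.start_x, viewport.end_x]])
    return BinnedGrid(viewport, counts)


def auto_density(points: np.ndarray, viewport: Viewport,
                 max_points: int = 100_000, output_resolution=512):
    """Voronoi diagram up to ``max_points`` points, binned grid beyond.

    Re-querying a smaller region that holds fewer points returns a true
    diagram again (auto-scaling resolution).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    inside = points[viewport.contains(points)]
    if len(inside) > max_points:
        return fallback_bin(inside, viewport, max_points, output_resolution)
    return build_voronoi(inside, viewport)
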