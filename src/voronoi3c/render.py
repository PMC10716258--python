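"""Static figure export: Voronoi view, fixed-bin heatmap, triangle view.

Display conventions follow common practice for contact maps: heatmap
counts are square-root transformed and saturated at a high quantile
(default 99.9%) of the nonzero transformed values, with the diagonal and
nearest-neighbour bins removed for on-diagonal views; Voronoi cells are
filled by a monotone colour map of log cell area (smaller area = hotter).
Rendering is a pure function of (data, spec): repeated SVG exports of the
same input are byte-identical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Polygon as _MplPolygon

from .voronoi import BinnedGrid, Viewport, VoronoiDiagram

_SVG_RC = {"svg.hashsalt": "voronoi3c", "svg.fonttype": "none"}


@dataclass
class RenderSpec:
    mode: str = "voronoi"  # voronoi | heatmap | triangle
    smooth_iterations: int = 1
    bin_size: int = 5_000
    saturation_quantile: float = 0.999
    diagonal_removal: int = 1  # band |i-j| <= this is zeroed (on-diagonal views)
    cmap: str = "viridis"
    figsize: tuple = (7.0, 7.0)
    annotations_x: tuple = ()  # (start, end) 0-based intervals, axis tracks
    annotations_y: tuple = ()

    def __post_init__(self):
        if not (0.0 < self.saturation_quantile <= 1.0):
            raise ValueError("saturation quantile must be in (0, 1]")
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")


def heatmap_counts(points: np.ndarray, viewport: Viewport,
                   bin_size: int) -> np.ndarray:
    """Fixed-bin counts of pairs per square bin, rows indexing the y axis.

    For on-diagonal viewports the upper-triangle points are symmetrically
    completed: a pair contributes to both (i, j) and (j, i) unless the two
    coincide, so the matrix sum counts each mirrored pair once per cell it
    lands in.
    """
    if bin_size > min(viewport.width, viewport.height):
        raise ValueError("bin size exceeds the viewport span")
    if 2 * bin_size > min(viewport.width, viewport.height):
        raise ValueError("bin size must divide the viewport into >= 2 bins per axis")
    nx = math.ceil(viewport.width / bin_size)
    ny = math.ceil(viewport.height / bin_size)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    points = points[viewport.contains(points)]
    x_edges = viewport.start_x + bin_size * np.arange(nx + 1, dtype=float)
    y_edges = viewport.start_y + bin_size * np.arange(ny + 1, dtype=float)
    counts, _, _ = np.histogram2d(points[:, 1], points[:, 0],
                                  bins=(y_edges, x_edges))
    if viewport.on_diagonal:
        counts = counts + counts.T - np.diag(np.diag(counts))
    return counts


def _deterministic_save(fig, out_path):
    out_path = str(out_path)
    with matplotlib.rc_context(_SVG_RC):
        if out_path.endswith(".svg"):
            fig.savefig(out_path, metadata={"Date": None})
        else:
            fig.savefig(out_path)
    plt.close(fig)
    return out_path


def _saturation(values: np.ndarray, quantile: float) -> float:
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return 1.0
    return float(np.quantile(nonzero, quantile))


def heatmap_render(counts: np.ndarray, spec: RenderSpec, out_path,
                   viewport: Viewport = None) -> str:
    """Render a count matrix with sqrt transform and quantile saturation."""
    counts = np.array(counts, dtype=float)
    on_diag = viewport is not None and viewport.on_diagonal
    if on_diag and counts.shape[0] == counts.shape[1]:
        i, j = np.indices(counts.shape)
        counts[np.abs(i - j) <= spec.diagonal_removal] = 0.0
    transformed = np.sqrt(counts)
    if not np.any(transformed > 0):
        warnings.warn("all-zero count matrix; rendering a blank image")
        vmax = 1.0
    else:
        vmax = _saturation(transformed, spec.saturation_quantile)
    fig, ax = plt.subplots(figsize=spec.figsize)
    extent = None
    if viewport is not None:
        extent = (viewport.start_x, viewport.end_x,
                  viewport.start_y, viewport.end_y)
    ax.imshow(transformed, origin="lower", vmin=0.0, vmax=vmax,
              cmap=spec.cmap, extent=extent, interpolation="nearest",
              aspect="auto")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("position (bp)")
    return _deterministic_save(fig, out_path)


def _area_colors(areas: np.ndarray, cmap_name: str):
    # smaller area = hotter: map -log(area) through the colour map
    score = -np.log(areas)
    lo, hi = score.min(), score.max()
    norm = np.zeros_like(score) if hi == lo else (score - lo) / (hi - lo)
    return plt.get_cmap(cmap_name)(norm)


def _draw_annotations(ax, spec: RenderSpec, viewport: Viewport):
    for start, end in spec.annotations_x:
        ax.axvspan(start, end, ymin=0.98, ymax=1.0, color="0.3", lw=0)
    for start, end in spec.annotations_y:
        ax.axhspan(start, end, xmin=0.98, xmax=1.0, color="0.3", lw=0)


def voronoi_render(diagram, spec: RenderSpec, out_path) -> str:
    """Render Voronoi cells coloured by log area (SVG or PNG).

    Each cell becomes one SVG path (gid ``cell-<i>``).  A fallback-binned
    grid delegates to :func:`heatmap_render`.
    """
    if isinstance(diagram, BinnedGrid) or getattr(diagram, "mode", None) == "fallback_binned":
        return heatmap_render(diagram.counts, spec, out_path, diagram.viewport)
    vp = diagram.viewport
    colors = _area_colors(diagram.areas, spec.cmap)
    fig, ax = plt.subplots(figsize=spec.figsize)
    for i, (cell, color) in enumerate(zip(diagram.cells, colors)):
        patch = _MplPolygon(cell.polygon, closed=True, facecolor=color,
                            edgecolor="none")
        patch.set_gid(f"cell-{i}")
        ax.add_patch(patch)
    ax.set_xlim(vp.start_x, vp.end_x)
    ax.set_ylim(vp.start_y, vp.end_y)
    ax.set_xlabel(f"{vp.chrom_x} position (bp)")
    ax.set_ylabel(f"{vp.chrom_y} position (bp)")
    _draw_annotations(ax, spec, vp)
    return _deterministic_save(fig, out_path)


def triangle_transform(points: np.ndarray) -> np.ndarray:
    """Rigid 45-degree rotation taking the x = y diagonal to the horizontal.

    (x, y) -> (u, v) with u = (x + y) / sqrt(2), v = (y - x) / sqrt(2);
    the upper triangle (y >= x) maps to v >= 0 and areas are preserved.
    """
    points = np.asarray(points, dtype=float)
    r = math.sqrt(2.0)
    return np.column_stack([(points[..., 0] + points[..., 1]) / r,
                            (points[..., 1] - points[..., 0]) / r])


def triangle_render(diagram: VoronoiDiagram, spec: RenderSpec, out_path) -> str:
    """Triangle view: the on-diagonal upper triangle rotated flat.

    Only cells whose seed lies on or above the diagonal are drawn; the
    diagonal becomes the horizontal baseline, and the figure spans
    sqrt(2) times the viewport side in plot units.
    """
    vp = diagram.viewport
    if not vp.on_diagonal:
        raise ValueError("triangle view requires an on-diagonal square viewport")
    cells = [c for c in diagram.cells if c.seed[1] >= c.seed[0]]
    areas = np.array([c.area for c in cells])
    colors = _area_colors(areas, spec.cmap)
    r = math.sqrt(2.0)
    fig, ax = plt.subplots(figsize=(spec.figsize[0], spec.figsize[0] / 2))
    for i, (cell, color) in enumerate(zip(cells, colors)):
        patch = _MplPolygon(triangle_transform(cell.polygon), closed=True,
                            facecolor=color, edgecolor="none")
        patch.set_gid(f"cell-{i}")
        ax.add_patch(patch)
    u0, u1 = triangle_transform(np.array([[vp.start_x, vp.start_x],
                                          [vp.end_x, vp.end_x]]))[:, 0]
    ax.set_xlim(u0, u1)
    ax.set_ylim(0.0, (vp.end_x - vp.start_x) / r)
    ax.axhline(0.0, color="0.2", lw=0.8)
    ax.set_xlabel(f"{vp.chrom_x} diagonal position (bp / sqrt(2))")
    return _deterministic_save(fig, out_path)
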