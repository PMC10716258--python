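"""Centroidal Voronoi smoothing by Lloyd iteration.

One Lloyd step replaces every seed by the area centroid of its clipped cell
and rebuilds the diagram from the centroids; iterating drives the
tessellation toward a centroidal one in which neighbouring cells have close
to equal areas, making focal contact clusters easier to spot.  Display
figures conventionally use a single iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .voronoi import (VoronoiDiagram, Viewport, _cells_from_seeds,
                      _dedupe, _quantum)

#: Relative movement threshold (fraction of the larger viewport side) below
#: which the tessellation is treated as converged.  Exact co-location of
#: centroids and seeds is unattainable in floating point.
CONVERGENCE_TOL = 1e-6


@dataclass
class LloydState:
    iteration: int
    diagram: VoronoiDiagram
    movement: float  # max seed displacement this iteration, bp


def _rebuild(seeds: np.ndarray, multiplicities: np.ndarray,
             viewport: Viewport, mode: str) -> VoronoiDiagram:
    # Coincident centroids (vanishingly rare) merge, pooling their mass.
    from .voronoi import _quantize
    keys = _quantize(seeds, _quantum(viewport))
    uniq_keys, first, inverse = np.unique(keys, axis=0, return_index=True,
                                          return_inverse=True)
    order = np.argsort(first)
    mult = np.zeros(len(uniq_keys), dtype=int)
    np.add.at(mult, inverse, multiplicities)
    cells = _cells_from_seeds(seeds[first[order]], mult[order], viewport)
    return VoronoiDiagram(viewport, cells, mode=mode)


def lloyd_step(diagram: VoronoiDiagram) -> LloydState:
    """One Lloyd iteration: seeds -> cell centroids -> new diagram.

    Multiplicity of a collapsed seed travels with its centroid; the total
    mass and the seed count are conserved.
    """
    if diagram.mode == "fallback_binned":
        raise ValueError("cannot smooth a fallback-binned grid")
    old = diagram.seeds
    centroids = np.array([c.centroid for c in diagram.cells])
    movement = float(np.max(np.hypot(*(centroids - old).T)))
    new = _rebuild(centroids, diagram.multiplicities, diagram.viewport,
                   diagram.mode)
    return LloydState(iteration=1, diagram=new, movement=movement)


def smooth(diagram: VoronoiDiagram, iterations: int = 1,
           tol: float = CONVERGENCE_TOL) -> VoronoiDiagram:
    """Apply up to ``iterations`` Lloyd steps, stopping early on convergence.

    ``iterations=0`` is the identity.  Convergence means the largest seed
    displacement fell below ``tol`` times the larger viewport side.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    vp = diagram.viewport
    threshold = tol * max(vp.width, vp.height)
    for _ in range(iterations):
        state = lloyd_step(diagram)
        diagram = state.diagram
        if state.movement < threshold:
            break
    return diagram


def quantization_energy(diagram: VoronoiDiagram, n_samples: int = 200_000,
                        rng=None) -> float:
    """Monte-Carlo estimate of sum over cells of the integral ||p - seed||^2.

    The energy is non-increasing under Lloyd steps; used as a numerical
    check of the smoothing dynamics.  Samples are drawn uniformly over the
    viewport and charged to the nearest seed, mirroring the tessellation's
    defining property.
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(rng)
    vp = diagram.viewport
    pts = np.column_stack([
        rng.uniform(vp.start_x, vp.end_x, n_samples),
        rng.uniform(vp.start_y, vp.end_y, n_samples)])
    tree = cKDTree(diagram.seeds)
    dist, _ = tree.query(pts, k=1)
    return float(np.mean(dist ** 2) * vp.area)
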