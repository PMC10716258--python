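import numpy as np
import pytest

import voronoi3c as v3c
from voronoi3c.voronoi import polygon_area, polygon_centroid


def brute_force_labels(seeds, probes):
    """Nearest-seed assignment with ties broken by lowest seed index."""
    d2 = ((probes[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def diagram_labels(diagram, probes):
    """Which cell polygon contains each probe (lowest cell index on ties)."""
    import shapely
    from shapely.geometry import Polygon

    pts = shapely.points(probes)
    labels = np.full(len(probes), -1)
    for i, cell in enumerate(diagram.cells):
        poly = Polygon(cell.polygon)
        inside = shapely.covers(poly, pts) & (labels == -1)
        labels[inside] = i
    return labels


class TestBuildVoronoi:
    def test_single_point_owns_viewport(self, unit_viewport):
        d = v3c.build_voronoi(np.array([[0.4, 0.7]]), unit_viewport)
        assert len(d) == 1
        assert d.cells[0].area == pytest.approx(unit_viewport.area)

    def test_four_corner_symmetry(self, unit_viewport):
        d = v3c.build_voronoi(np.array([[0, 0], [1, 0], [0, 1], [1, 1]]),
                              unit_viewport)
        assert np.allclose(d.areas, 0.25)
        assert np.allclose(d.densities, 4.0)

    def test_corners_plus_center(self, unit_viewport):
        # brute-force nearest-seed labelling of a fine grid converges to
        # center 0.5 and corners 0.125 each; Qhull gives them exactly
        seeds = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]])
        d = v3c.build_voronoi(seeds, unit_viewport)
        by_seed = {c.seed: c.area for c in d.cells}
        assert by_seed[(0.5, 0.5)] == pytest.approx(0.5, rel=1e-9)
        for corner in [(0., 0.), (1., 0.), (0., 1.), (1., 1.)]:
            assert by_seed[corner] == pytest.approx(0.125, rel=1e-9)
        g = np.linspace(0, 1, 201)
        grid = np.array(np.meshgrid(g, g)).reshape(2, -1).T
        labels = brute_force_labels(seeds, grid)
        approx = np.bincount(labels) / len(grid)
        assert np.allclose(approx, [0.125] * 4 + [0.5], atol=0.01)

    def test_membership_matches_brute_force_oracle(self, unit_viewport):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = rng.integers(2, 50)
            seeds = rng.random((n, 2))
            d = v3c.build_voronoi(seeds, unit_viewport)
            probes = rng.random((2000, 2))
            ordered_seeds = d.seeds
            expect = brute_force_labels(ordered_seeds, probes)
            got = diagram_labels(d, probes)
            assert np.array_equal(got, expect)

    def test_area_conservation_and_density_integral(self, unit_viewport):
        rng = np.random.default_rng(2)
        pts = rng.random((200, 2))
        d = v3c.build_voronoi(pts, unit_viewport)
        assert d.areas.sum() == pytest.approx(unit_viewport.area, rel=1e-9)
        assert (d.densities * d.areas).sum() == pytest.approx(200, abs=1e-6)

    def test_collinear_points_give_slabs(self, unit_viewport):
        pts = np.column_stack([np.linspace(0.1, 0.9, 5), np.full(5, 0.5)])
        d = v3c.build_voronoi(pts, unit_viewport)
        assert d.areas.sum() == pytest.approx(1.0, rel=1e-9)
        assert len(d) == 5

    def test_duplicates_collapse_with_multiplicity(self, unit_viewport):
        pts = np.array([[0.2, 0.2], [0.2, 0.2], [0.2, 0.2], [0.8, 0.8]])
        d = v3c.build_voronoi(pts, unit_viewport)
        assert len(d) == 2
        assert d.total_multiplicity == 4
        cell = next(c for c in d.cells if c.seed == (0.2, 0.2))
        assert cell.density == pytest.approx(3 / cell.area)

    def test_empty_viewport_raises_with_advice(self, unit_viewport):
        with pytest.raises(v3c.EmptyDiagramError, match="widen"):
            v3c.build_voronoi(np.array([[5.0, 5.0]]), unit_viewport)

    def test_deterministic_for_identical_input(self, unit_viewport):
        pts = np.random.default_rng(3).random((50, 2))
        d1 = v3c.build_voronoi(pts, unit_viewport)
        d2 = v3c.build_voronoi(pts, unit_viewport)
        assert [c.seed for c in d1.cells] == [c.seed for c in d2.cells]
        for a, b in zip(d1.cells, d2.cells):
            assert np.array_equal(a.polygon, b.polygon)

    def test_cell_densities_mapping(self, unit_viewport):
        d = v3c.build_voronoi(np.array([[0.25, 0.5]]),
                              v3c.Viewport.square("chr1", 0, 1000))
        dens = v3c.cell_densities(d)
        assert dens[(0.25, 0.5)] == pytest.approx(1e-6)


class TestReflection:
    def test_symmetric_points_equal_full_symmetrized_build(self):
        vp = v3c.Viewport.square("chr1", 0, 10)
        rng = np.random.default_rng(4)
        upper = rng.random((20, 2)) * 10
        upper = np.column_stack([np.minimum(upper[:, 0], upper[:, 1]),
                                 np.maximum(upper[:, 0], upper[:, 1])])
        refl = v3c.reflect_upper_triangle(upper, vp)
        full = v3c.build_voronoi(np.vstack([upper, upper[:, ::-1]]), vp)
        ra = {c.seed: c.area for c in refl.cells}
        fa = {c.seed: c.area for c in full.cells}
        assert set(ra) == set(fa)
        for seed in ra:
            assert ra[seed] == pytest.approx(fa[seed], rel=1e-9)
        assert refl.mode == "reflected"

    def test_single_off_diagonal_point_mirror_cells(self):
        vp = v3c.Viewport.square("chr1", 0, 10)
        d = v3c.reflect_upper_triangle(np.array([[2.0, 7.0]]), vp)
        assert len(d) == 2
        assert d.areas[0] == pytest.approx(d.areas[1], rel=1e-9)

    def test_empty_upper_triangle_raises(self):
        vp = v3c.Viewport.square("chr1", 0, 10)
        with pytest.raises(v3c.EmptyDiagramError):
            v3c.reflect_upper_triangle(np.empty((0, 2)), vp)

    def test_off_diagonal_viewport_rejected(self):
        vp = v3c.Viewport("chr1", 0, 10, "chr1", 5, 15)
        with pytest.raises(ValueError, match="on-diagonal"):
            v3c.reflect_upper_triangle(np.array([[1.0, 6.0]]), vp)


class TestFilterDistance:
    def test_zero_is_identity(self):
        pts = np.random.default_rng(5).random((30, 2))
        assert np.array_equal(v3c.apply_filter_distance(pts, 0.0), pts)

    def test_on_diagonal_point_removed(self):
        out = v3c.apply_filter_distance(np.array([[100.0, 100.0]]), 1.0)
        assert len(out) == 0

    def test_matches_direct_predicate(self):
        rng = np.random.default_rng(6)
        pts = rng.integers(0, 100_000, size=(500, 2)).astype(float)
        kept = v3c.apply_filter_distance(pts, 1000.0)
        expect = pts[np.abs(pts[:, 0] - pts[:, 1]) >= 1000.0 * np.sqrt(2)]
        assert np.array_equal(kept, expect)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            v3c.apply_filter_distance(np.array([[0.0, 1.0]]), -1.0)


class TestFallback:
    def test_grid_conserves_counts(self):
        vp = v3c.Viewport.square("chr1", 0, 1000)
        rng = np.random.default_rng(7)
        pts = rng.random((100_001, 2)) * 1000
        grid = v3c.fallback_bin(pts, vp, output_resolution=10)
        assert grid.counts.shape == (10, 10)
        assert grid.counts.sum() == 100_001
        assert grid.mode == "fallback_binned"

    def test_default_threshold_is_one_hundred_thousand(self):
        import inspect
        sig = inspect.signature(v3c.auto_density)
        assert sig.parameters["max_points"].default == 100_000

    def test_threshold_is_strictly_greater_than(self):
        vp = v3c.Viewport.square("chr1", 0, 1000)
        rng = np.random.default_rng(8)
        pts = rng.random((100, 2)) * 1000
        assert isinstance(v3c.auto_density(pts, vp, max_points=100),
                          v3c.VoronoiDiagram)
        assert isinstance(v3c.auto_density(np.vstack([pts, [[1.5, 2.5]]]), vp,
                                           max_points=100), v3c.BinnedGrid)

    def test_zoom_returns_true_diagram(self):
        vp = v3c.Viewport.square("chr1", 0, 1000)
        rng = np.random.default_rng(9)
        pts = rng.random((101, 2)) * 1000
        assert isinstance(v3c.auto_density(pts, vp, max_points=100), v3c.BinnedGrid)
        sub = v3c.Viewport.square("chr1", 0, 200)
        zoomed = v3c.auto_density(pts, sub, max_points=100)
        assert isinstance(zoomed, v3c.VoronoiDiagram)

    def test_bad_resolution_rejected(self):
        vp = v3c.Viewport.square("chr1", 0, 1000)
        with pytest.raises(ValueError):
            v3c.fallback_bin(np.array([[1.0, 1.0]]), vp, output_resolution=0)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, deadline=None, max_examples=25)
@given(st.lists(st.tuples(st.floats(0, 1, allow_nan=False),
                          st.floats(0, 1, allow_nan=False)),
                min_size=1, max_size=40))
def test_area_conservation_property(points):
    """Clipped cells tile the viewport for arbitrary point sets."""
    vp = v3c.Viewport.square("chr1", 0, 1)
    d = v3c.build_voronoi(np.array(points), vp)
    assert d.areas.sum() == pytest.approx(vp.area, rel=1e-9)
    assert (d.densities * d.areas).sum() == pytest.approx(len(points), rel=1e-9)


@settings(derandomize=True, deadline=None, max_examples=50)
@given(st.lists(st.tuples(st.integers(0, 10_000), st.integers(0, 10_000)),
                min_size=0, max_size=50),
       st.floats(0, 2_000, allow_nan=False))
def test_filter_distance_property(points, d):
    """The kept set is exactly the direct perpendicular-distance predicate."""
    pts = np.array(points, dtype=float).reshape(-1, 2)
    kept = v3c.apply_filter_distance(pts, d)
    if d == 0:
        assert np.array_equal(kept, pts)
    else:
        expect = pts[np.abs(pts[:, 0] - pts[:, 1]) >= d * np.sqrt(2.0)]
        assert np.array_equal(kept, expect)


def test_polygon_helpers_on_unit_square():
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    assert polygon_area(square) == pytest.approx(1.0)
    assert polygon_centroid(square) == pytest.approx([0.5, 0.5])


def test_viewport_validation():
    with pytest.raises(ValueError):
        v3c.Viewport.square("chr1", 10, 10)
    with pytest.raises(ValueError, match="2\\^53"):
        v3c.Viewport.square("chr1", 0, 200_000_000_000)
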