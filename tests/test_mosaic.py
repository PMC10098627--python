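"""Raster-to-mosaic pipeline: vectorization, adjacency, junctions, smoothing."""

import numpy as np
import pytest

from leafmosaic import LabelMap, ValueConfig, assemble_mosaic
from leafmosaic.mosaic import (
    MosaicError,
    build_adjacency,
    smooth_outline,
    vectorize_cells,
)
from tests.conftest import PAVE, STOMA, SUBS, WALL


def labelmap_from(grid, scale=None, extra_classes=None):
    classes = {"pavement": PAVE, "stomate": STOMA, "subsidiary": SUBS}
    if extra_classes:
        classes.update(extra_classes)
    cfg = ValueConfig(wall_value=WALL, class_values=classes, scale=scale)
    return LabelMap(np.asarray(grid, np.uint8), cfg)


def two_squares(scale=None):
    """Two 10x10 pavement squares separated by a 1-px vertical wall."""
    grid = np.full((10, 21), PAVE, np.uint8)
    grid[:, 10] = WALL
    return labelmap_from(grid, scale=scale)


class TestVectorize:
    def test_two_squares_give_two_unit_area_regions(self):
        cells, labels = vectorize_cells(two_squares())
        assert len(cells) == 2
        assert sorted(c.area for c in cells.values()) == [100.0, 100.0]

    def test_scale_multiplies_area(self):
        cells, _ = vectorize_cells(two_squares(scale=2.0))
        assert all(c.area == pytest.approx(400.0) for c in cells.values())

    def test_unscaled_areas_are_in_pixels(self):
        lm = two_squares()
        assert lm.units == "px"
        cells, _ = vectorize_cells(lm)
        assert all(c.area == 100.0 for c in cells.values())

    def test_small_regions_dropped(self):
        grid = np.full((10, 21), PAVE, np.uint8)
        grid[:, 10] = WALL
        grid[0, 12:] = WALL
        grid[1, 12:] = WALL  # shrink right cell
        grid[2:, 11] = WALL
        grid[0:2, 11] = STOMA  # 2-px region, below the 4-px minimum
        cells, _ = vectorize_cells(labelmap_from(grid))
        assert all(c.cell_class != "stomate" for c in cells.values())

    def test_pixel_bookkeeping_is_exact(self, square_grid_3x3):
        cells, labels = vectorize_cells(square_grid_3x3)
        cell_px = sum(c.pixel_count for c in cells.values())
        wall_px = int((square_grid_3x3.grid == WALL).sum())
        assert cell_px + wall_px == square_grid_3x3.grid.size


class TestAdjacency:
    def test_shared_wall_makes_neighbours(self):
        lm = two_squares()
        cells, labels = vectorize_cells(lm)
        g = build_adjacency(lm, cells, labels)
        assert g.number_of_edges() == 1

    def test_single_corner_contact_is_not_adjacency(self):
        # two squares touching only at one wall corner pixel
        grid = np.full((21, 21), WALL, np.uint8)
        grid[:10, :10] = PAVE
        grid[11:, 11:] = PAVE
        lm = labelmap_from(grid)
        cells, labels = vectorize_cells(lm)
        g = build_adjacency(lm, cells, labels)
        assert g.number_of_edges() == 0

    def test_interior_cell_of_grid_has_four_neighbours(self, square_grid_3x3):
        m = assemble_mosaic(square_grid_3x3)
        interior = [c for c in m.cells.values() if not c.is_edge]
        assert len(interior) == 1
        assert len(interior[0].neighbour_ids) == 4

    def test_adjacency_invariant_under_transposition(self, square_grid_3x3):
        lm = square_grid_3x3
        lm_t = LabelMap(lm.grid.T.copy(), lm.config)
        g = assemble_mosaic(lm).adjacency
        g_t = assemble_mosaic(lm_t).adjacency
        # cells enumerate in different order; compare degree multisets and edge count
        assert sorted(d for _, d in g.degree) == sorted(d for _, d in g_t.degree)
        assert g.number_of_edges() == g_t.number_of_edges()


class TestJunctions:
    def test_interior_brick_has_six_junctions(self, brick_mosaic):
        sm, lm, m = brick_mosaic
        interior = [
            c for c in m.cells.values() if not c.is_edge and len(c.neighbour_ids) == 6
        ]
        assert interior, "expected interior bricks"
        assert all(c.n_junctions == 6 for c in interior)

    def test_interior_square_has_four_junctions(self, square_grid_3x3):
        m = assemble_mosaic(square_grid_3x3)
        interior = [c for c in m.cells.values() if not c.is_edge]
        assert interior[0].n_junctions == 4

    def test_enclosed_cell_with_two_neighbours_is_unsimplifiable(self):
        # a frame cell enclosing two stacked cells: each inner cell meets
        # only 2 distinct neighbours, so it has < 3 junctions
        grid = np.full((31, 31), PAVE, np.uint8)
        grid[5, 5:26] = WALL
        grid[25, 5:26] = WALL
        grid[5:26, 5] = WALL
        grid[5:26, 25] = WALL
        grid[15, 6:25] = WALL  # divide the inner box into two cells
        lm = labelmap_from(grid)
        m = assemble_mosaic(lm)
        inner = [
            c for c in m.cells.values()
            if len(c.neighbour_ids) == 2 and not c.is_edge
        ]
        assert len(inner) == 2
        assert all(c.unsimplifiable for c in inner)

    def test_simplified_polygon_runs_through_junctions(self, brick_mosaic):
        sm, lm, m = brick_mosaic
        for c in m.cells.values():
            if c.unsimplifiable:
                continue
            np.testing.assert_allclose(c.simplified_outline, c.junctions)


class TestSmoothing:
    def test_zero_iterations_is_identity(self):
        ring = np.array([[0.0, 0], [10, 0], [10, 10], [0, 10]])
        out, _ = smooth_outline(ring, None, iterations=0)
        np.testing.assert_array_equal(out, ring)

    def test_corner_cutting_shrinks_perimeter_keeps_area(self):
        ring = np.array([[0.0, 0], [10, 0], [10, 10], [0, 10]])
        out, _ = smooth_outline(ring, np.arange(4), iterations=3)
        from shapely.geometry import Polygon

        assert Polygon(out).is_valid
        assert Polygon(out).length <= Polygon(ring).length
        assert abs(Polygon(out).area - 100) / 100 < 0.05

    def test_anchors_stay_fixed(self):
        ring = np.array([[0.0, 0], [10, 0], [10, 10], [0, 10]])
        out, idx = smooth_outline(ring, np.array([0, 2]), iterations=3)
        np.testing.assert_array_equal(out[idx], ring[[0, 2]])

    def test_staircase_smoothing_shortens_boundary(self):
        steps = [[0.0, 1.0]]
        for i in range(9):
            steps += [[i + 1, i + 1], [i + 1, i + 2]]
        ring = np.array(steps + [[10.0, 10.0], [10.0, 0.0], [0.0, 0.0]])
        out, _ = smooth_outline(ring, None, iterations=3)
        per = lambda r: np.hypot(*np.diff(np.vstack([r, r[:1]]), axis=0).T).sum()
        assert per(out) < per(ring)


class TestStomatalComplexes:
    def test_complex_groups_guard_with_touching_subsidiaries(self, stomatal_mosaic):
        sm, lm, m = stomatal_mosaic
        interior = [cx for cx in m.complexes if not cx.is_edge]
        assert interior
        for cx in interior:
            assert len(cx.subsidiary_ids) == 2
            for sid in cx.subsidiary_ids:
                assert m.cells[sid].cell_class == "subsidiary"

    def test_paired_guard_cells_merge_and_record_dividing_wall(self):
        # two guard cells side by side sharing a vertical wall
        grid = np.full((14, 40), PAVE, np.uint8)
        grid[2:12, 4:20] = STOMA
        grid[2:12, 20] = WALL
        grid[2:12, 21:37] = STOMA
        grid[1, 3:38] = WALL
        grid[12, 3:38] = WALL
        grid[2:12, 3] = WALL
        grid[2:12, 37] = WALL
        lm = labelmap_from(grid)
        m = assemble_mosaic(lm, paired_guard_cells=True)
        assert len(m.complexes) == 1
        cx = m.complexes[0]
        assert len(cx.guard_ids) == 2
        p0, p1 = cx.dividing_segment
        d = p1 - p0
        angle = np.degrees(np.arctan2(d[1], d[0])) % 180
        assert angle == pytest.approx(90.0, abs=2.0)
        # mirror-image guard cells: equal areas -> symmetry 1
        from leafmosaic.traits import stomatal_traits

        out = stomatal_traits(m, cx, north_deg=None)
        assert out["symmetry"] == pytest.approx(1.0, abs=0.05)

    def test_unpairable_guard_cell_raises(self):
        grid = np.full((14, 20), PAVE, np.uint8)
        grid[2:12, 4:16] = STOMA
        grid[1, 3:17] = WALL
        grid[12, 3:17] = WALL
        grid[2:12, 3] = WALL
        grid[2:12, 16] = WALL
        lm = labelmap_from(grid)
        with pytest.raises(MosaicError, match="guard"):
            assemble_mosaic(lm, paired_guard_cells=True)

    def test_border_clipped_stoma_flagged_edge(self):
        grid = np.full((20, 20), PAVE, np.uint8)
        grid[0:6, 0:8] = STOMA
        grid[6, 0:9] = WALL
        grid[0:6, 8] = WALL
        lm = labelmap_from(grid)
        m = assemble_mosaic(lm)
        assert len(m.complexes) == 1
        assert m.complexes[0].is_edge


class TestEdgeAndNA:
    def test_na_touching_cells_flagged_like_edge(self):
        grid = np.full((21, 21), PAVE, np.uint8)
        grid[:, 10] = WALL
        grid[10, :] = WALL
        grid[:10, :10] = 200  # NA over the top-left cell
        cfg = ValueConfig(
            wall_value=WALL, class_values={"pavement": PAVE}, na_value=200
        )
        m = assemble_mosaic(LabelMap(grid, cfg))
        na_adjacent = [c for c in m.cells.values() if c.touches_na]
        assert na_adjacent
        assert all(c.is_edge for c in na_adjacent)

    def test_cell_areas_plus_walls_cover_the_image(self, square_grid_3x3):
        m = assemble_mosaic(square_grid_3x3)
        cell_px = sum(c.pixel_count for c in m.cells.values())
        wall_px = int((square_grid_3x3.grid == WALL).sum())
        h, w = square_grid_3x3.shape
        assert cell_px + wall_px == h * w
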