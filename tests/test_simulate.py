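"""Synthetic-data generator: single cells, the factorial grid, mosaics
and the rasterization round trip."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from leafmosaic import assemble_mosaic
from leafmosaic.simulate import (
    MosaicSpec,
    SyntheticCellSpec,
    rasterize_mosaic,
    simulate_cell,
    simulate_cell_grid,
    simulate_mosaic,
)


class TestSimulateCell:
    @pytest.mark.parametrize("shape", ["rectangle", "ellipse", "crescent"])
    def test_zero_amplitude_gives_baseline_truth(self, shape):
        cell = simulate_cell(
            SyntheticCellSpec(gross_shape=shape, aspect_ratio=3.0, size=50.0)
        )
        gt = cell.ground_truth
        assert gt["complexity"] == pytest.approx(1.0, abs=1e-12)
        assert gt["undulation_amp"] == 0.0
        assert gt["undulation_freq"] == 0.0
        assert Polygon(cell.outline).is_valid

    def test_fixed_seed_reproduces_polygon(self):
        spec = SyntheticCellSpec(
            undulation_amplitude=4.0, undulation_periods_per_wall=2, rng_seed=9
        )
        a = simulate_cell(spec)
        b = simulate_cell(spec)
        np.testing.assert_array_equal(a.outline, b.outline)

    def test_phase_jitter_changes_outline_not_truth(self):
        base = dict(undulation_amplitude=4.0, undulation_periods_per_wall=2)
        cells = [
            simulate_cell(SyntheticCellSpec(phase=float(p), rng_seed=p, **base))
            for p in range(5)
        ]
        truths = [c.ground_truth for c in cells]
        for t in truths[1:]:
            assert t == truths[0]
        outlines = {tuple(np.round(c.outline[:8].ravel(), 6)) for c in cells}
        assert len(outlines) > 1

    def test_amplitude_bound_enforced(self):
        with pytest.raises(ValueError, match="bound"):
            simulate_cell(
                SyntheticCellSpec(
                    size=10.0, undulation_amplitude=5.0, undulation_periods_per_wall=1
                )
            )

    def test_quadrature_complexity_for_known_sine(self):
        """Arc length of a sine wall against direct numerical integration."""
        amp, periods, size = 5.0, 2, 100.0
        cell = simulate_cell(
            SyntheticCellSpec(
                gross_shape="rectangle",
                size=size,
                undulation_amplitude=amp,
                undulation_periods_per_wall=periods,
            )
        )
        t = np.linspace(0, 1, 200_001)
        # tapered sine: D(t) = a sin(2 pi p t) sin^2(pi t)
        dDdt = amp * (
            2 * np.pi * periods * np.cos(2 * np.pi * periods * t) * np.sin(np.pi * t) ** 2
            + np.sin(2 * np.pi * periods * t)
            * 2 * np.pi * np.sin(np.pi * t) * np.cos(np.pi * t)
        )
        arc = np.trapezoid(np.sqrt(size**2 + dDdt**2), t)
        assert cell.ground_truth["complexity"] == pytest.approx(
            arc * 4 / 400.0, rel=1e-5
        )


class TestCellGrid:
    def test_default_grid_has_1200_cells(self):
        cells, truth = simulate_cell_grid(replicates=5)
        assert len(cells) == 1200
        assert len(truth) == 1200

    def test_empty_factor_level_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_cell_grid(amplitudes=())

    def test_truth_table_matches_cells(self):
        cells, truth = simulate_cell_grid(
            shapes=("rectangle",), aspect_ratios=(1, 2), amplitudes=(0.0, 4.0),
            periods=(1,), replicates=2,
        )
        assert len(cells) == len(truth) == 8
        straight = truth[truth["amplitude"] == 0.0]
        assert (straight["true_complexity"] == pytest.approx(1.0)) if len(
            straight
        ) == 1 else (straight["true_complexity"] - 1.0).abs().max() < 1e-12

    def test_novel_metrics_ignore_gross_shape_legacy_does_not(self):
        """Straight cells: complexity is flat in aspect ratio; the legacy
        circle-based undulation index increases with it."""
        from scipy.stats import spearmanr

        from leafmosaic.traits import legacy_metrics
        from tests.test_traits import vector_cell

        cells, truth = simulate_cell_grid(
            aspect_ratios=(1, 2, 4, 7, 10), amplitudes=(0.0,), periods=(1,),
            replicates=4,
        )
        ar = truth["aspect_ratio"].to_numpy()
        cx = truth["true_complexity"].to_numpy()
        ui = np.array(
            [legacy_metrics(vector_cell(c.outline))["undulation_index"] for c in cells]
        )
        cx = np.round(cx, 9)  # straight walls: differences are fp dust
        rho_cx = spearmanr(ar, cx).statistic if np.unique(cx).size > 1 else 0.0
        assert abs(rho_cx) < 0.05
        # per gross shape: the circle-based index tracks elongation
        shapes = truth["gross_shape"].to_numpy()
        for shape in np.unique(shapes):
            sel = shapes == shape
            assert spearmanr(ar[sel], ui[sel]).statistic > 0.9


class TestSimulateMosaic:
    def test_fixed_seed_is_deterministic(self):
        spec = MosaicSpec(grid="voronoi", n_cols=5, n_rows=5, cell_size=24, rng_seed=3)
        a = simulate_mosaic(spec)
        b = simulate_mosaic(spec)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_two_rows_of_stomata_ground_truth(self):
        spec = MosaicSpec(
            grid="brick", n_cols=8, n_rows=8, cell_size=24,
            stomatal_row_indices=(2, 5), stoma_every=2, rng_seed=0,
        )
        sm = simulate_mosaic(spec)
        assert set(sm.stomata["row"]) == {0, 1}
        assert sm.north_deg == 0.0
        # jitter 0: all stomata of a row share the same y
        for _, grp in sm.stomata.groupby("row"):
            assert grp["cy"].nunique() == 1

    def test_no_stomata_means_empty_stomata_table(self):
        sm = simulate_mosaic(MosaicSpec(grid="voronoi", n_cols=4, n_rows=4))
        assert len(sm.stomata) == 0

    def test_overlapping_stoma_rejected_or_skipped(self):
        # oversized stomata cannot fit their host cells
        spec = MosaicSpec(
            grid="brick", n_cols=6, n_rows=6, cell_size=24,
            stomatal_row_indices=(2,), stoma_length_frac=0.89,
            stoma_width_frac=0.89, rng_seed=0,
        )
        sm = simulate_mosaic(spec)  # skipped with warnings, never invalid
        for cls, poly in sm.cells:
            assert poly.is_valid


class TestRasterizeRoundTrip:
    def test_wall_width_three_shrinks_areas_not_complexity(self):
        spec = MosaicSpec(grid="brick", n_cols=6, n_rows=6, cell_size=28, cell_aspect=1.4)
        sm = simulate_mosaic(spec)
        m1 = assemble_mosaic(rasterize_mosaic(sm, wall_width_px=1))
        m3 = assemble_mosaic(rasterize_mosaic(sm, wall_width_px=3))
        a1 = np.median([c.area for c in m1.cells.values() if not c.is_edge])
        a3 = np.median([c.area for c in m3.cells.values() if not c.is_edge])
        assert a3 < a1
        from leafmosaic.traits import cell_undulation_metrics

        for m in (m1, m3):
            cx = [
                cell_undulation_metrics(c.smoothed_outline, c.junctions)["complexity"]
                for c in m.cells.values()
                if not c.is_edge and not c.unsimplifiable
            ]
            assert np.median(cx) == pytest.approx(1.0, abs=0.01)

    def test_low_resolution_rejected(self):
        spec = MosaicSpec(grid="brick", n_cols=4, n_rows=4, cell_size=2.0)
        sm = simulate_mosaic(spec)
        with pytest.raises(ValueError):
            rasterize_mosaic(sm)

    def test_labelmap_loads_through_standard_pipeline(self, tmp_path):
        from leafmosaic import load_labelmap, save_labelmap

        spec = MosaicSpec(grid="hex", n_cols=5, n_rows=5, cell_size=24)
        lm = rasterize_mosaic(simulate_mosaic(spec), scale=0.5)
        p = tmp_path / "mosaic.png"
        save_labelmap(lm, p)
        again = load_labelmap(p, lm.config)
        np.testing.assert_array_equal(again.grid, lm.grid)
        m = assemble_mosaic(again)
        assert len(m.cells) > 10
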