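"""Shared fixtures: hand-built label grids and simulated mosaics."""

from __future__ import annotations

import numpy as np
import pytest

from leafmosaic import LabelMap, MosaicSpec, ValueConfig, assemble_mosaic
from leafmosaic.simulate import rasterize_mosaic, simulate_mosaic

WALL, PAVE, STOMA, SUBS = 0, 255, 85, 170


def grid_labelmap(n_rows: int, n_cols: int, cell: int = 10, scale=None) -> LabelMap:
    """Aligned square grid of ``cell``-px pavement cells, 1-px walls."""
    h = n_rows * cell + (n_rows - 1)
    w = n_cols * cell + (n_cols - 1)
    grid = np.full((h, w), PAVE, np.uint8)
    for k in range(1, n_rows):
        grid[k * cell + (k - 1), :] = WALL
    for k in range(1, n_cols):
        grid[:, k * cell + (k - 1)] = WALL
    cfg = ValueConfig(wall_value=WALL, class_values={"pavement": PAVE}, scale=scale)
    return LabelMap(grid, cfg)


@pytest.fixture(scope="session")
def square_grid_3x3() -> LabelMap:
    return grid_labelmap(3, 3)


@pytest.fixture(scope="session")
def brick_mosaic():
    """Straight-walled brick tessellation, no stomata (session-cached)."""
    spec = MosaicSpec(grid="brick", n_cols=6, n_rows=6, cell_size=24, cell_aspect=1.5)
    sm = simulate_mosaic(spec)
    lm = rasterize_mosaic(sm)
    return sm, lm, assemble_mosaic(lm)


@pytest.fixture(scope="session")
def stomatal_mosaic():
    """Brick mosaic with two stomatal rows and subsidiary cells."""
    spec = MosaicSpec(
        grid="brick",
        n_cols=8,
        n_rows=8,
        cell_size=28,
        cell_aspect=1.4,
        stomatal_row_indices=(2, 5),
        stoma_every=2,
        rng_seed=0,
    )
    sm = simulate_mosaic(spec)
    lm = rasterize_mosaic(sm)
    return sm, lm, assemble_mosaic(lm)
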