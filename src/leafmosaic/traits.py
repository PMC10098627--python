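"""Per-cell and per-image epidermal traits.

Pavement-cell shape is separated into *gross shape* (measured on the
simplified cell: aspect ratio, angle, endwall angles) and *wall
undulation*, measured against the simplified cell as baseline:

* ``complexity``  — smoothed perimeter / simplified perimeter (>= 1;
  1 = perfectly straight walls, independent of gross cell shape);
* ``undulation_amp`` — maximum offset of the wall from the simplified
  perimeter (same length units as the scale);
* ``undulation_freq`` — wall/baseline crossings per unit simplified
  perimeter (per px on unscaled images).

Stomatal dimensions are taken from the guard outline directly (extents
projected on the fitted ellipse axes), not from the fitted ellipse.
Orientation is reported relative to *stomatal north*, the axial mean
stomatal angle used as a proxy for the leaf axis.  The stomatal index
uses the unbiased counting rule: interior cells plus cells clipped by
the top or left image border count; cells clipped only by the
bottom/right border do not.

Legacy comparison metrics (undulation index, solidity, convexity) are
provided for benchmarking only; they confound gross shape with
undulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geometry import (
    DegenerateFitError,
    EllipseFit,
    axial_mean_angle,
    crossings_count,
    fit_ellipse_direct,
    max_normal_offset,
)
from .mosaic import GUARD_CLASS, CellMosaic, CellPolygon, StomatalComplex

logger = logging.getLogger(__name__)

__all__ = [
    "cell_undulation_metrics",
    "pavement_traits",
    "stomatal_traits",
    "stomatal_north",
    "stomatal_index",
    "densities",
    "legacy_metrics",
    "extract_image_traits",
    "ImageTraitRecord",
    "resample_ring",
]


# ---------------------------------------------------------------------------
# shared shape machinery
# ---------------------------------------------------------------------------


def _ring_perimeter(ring: np.ndarray) -> float:
    d = np.diff(np.vstack([ring, ring[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def resample_ring(ring: np.ndarray, n: int = 64) -> np.ndarray:
    """Resample a closed ring to ``n`` points uniform in arc length."""
    ring = np.asarray(ring, dtype=float)
    closed = np.vstack([ring, ring[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def _junction_indices(ring: np.ndarray, junctions: np.ndarray) -> np.ndarray:
    """Indices of the junction vertices within the ring, boundary order."""
    d2 = ((ring[None, :, :] - junctions[:, None, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    return np.sort(np.unique(idx))


def cell_undulation_metrics(
    ring: np.ndarray, junctions: np.ndarray, crossing_tol: float = 0.0
) -> dict[str, float]:
    """Undulation metrics of a cell outline against its simplified cell.

    Parameters
    ----------
    ring : (n, 2) array
        Smoothed cell outline (closed, first vertex not repeated).
    junctions : (k, 2) array, k >= 3
        Junction points in boundary order; each must coincide with a
        ring vertex.

    Returns a dict with ``perimeter``, ``simplified_perimeter``,
    ``complexity``, ``undulation_amp``, ``undulation_freq`` (crossings
    per unit simplified perimeter) and ``n_crossings``.
    """
    junctions = np.asarray(junctions, dtype=float)
    if len(junctions) < 3:
        raise ValueError("need >= 3 junctions to define the simplified cell")
    idx = _junction_indices(np.asarray(ring, float), junctions)
    ring = np.asarray(ring, dtype=float)
    perim = _ring_perimeter(ring)
    simp = ring[idx]
    simp_perim = _ring_perimeter(simp)
    n = len(ring)
    amp = 0.0
    total_crossings = 0
    for a, b in zip(idx, np.roll(idx, -1)):
        if b > a:
            arc = ring[a : b + 1]
        else:  # wraps around the ring start
            arc = np.vstack([ring[a:], ring[: b + 1]])
        baseline = (ring[a], ring[b % n])
        seg_len = float(np.hypot(*(baseline[1] - baseline[0])))
        if seg_len < 1e-12:
            continue
        amp = max(amp, max_normal_offset(arc, baseline))
        total_crossings += crossings_count(arc, baseline, tol_abs=crossing_tol)
    return {
        "perimeter": perim,
        "simplified_perimeter": simp_perim,
        "complexity": perim / simp_perim,
        "undulation_amp": amp,
        "undulation_freq": total_crossings / simp_perim,
        "n_crossings": total_crossings,
    }


def _fit_outline_ellipse(ring: np.ndarray, n_sample: int = 64) -> EllipseFit:
    """Ellipse fit of a (possibly < 6 vertex) outline, resampled densely."""
    return fit_ellipse_direct(resample_ring(ring, n_sample))


def _relative_angle(angle_deg: float, north_deg: float | None) -> float:
    if north_deg is None:
        return angle_deg % 180.0
    return (angle_deg - north_deg) % 180.0


def _endwall_angles(simplified: np.ndarray, fit: EllipseFit) -> float:
    """Mean acute angle between the two end walls and the major axis.

    The end walls are the two simplified edges whose midpoints lie
    furthest apart along the major axis.
    """
    simp = np.asarray(simplified, float)
    nxt = np.roll(simp, -1, axis=0)
    mids = 0.5 * (simp + nxt)
    axis = np.array(
        [np.cos(np.radians(fit.angle_deg)), np.sin(np.radians(fit.angle_deg))]
    )
    proj = (mids - np.array(fit.center)) @ axis
    lo, hi = int(np.argmin(proj)), int(np.argmax(proj))
    angles = []
    for e in (lo, hi):
        d = nxt[e] - simp[e]
        norm = np.hypot(*d)
        if norm < 1e-12:
            continue
        cosang = abs(float(d @ axis)) / norm
        angles.append(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    return float(np.mean(angles)) if angles else np.nan


# ---------------------------------------------------------------------------
# per-cell traits
# ---------------------------------------------------------------------------


def pavement_traits(
    cell: CellPolygon, north_deg: float | None, crossing_tol: float = 0.0
) -> dict:
    """Traits of one non-edge pavement cell.

    Undulation fields are NaN for unsimplifiable cells (< 3 junctions);
    size fields are always reported.  ``crossing_tol`` is the dead band
    for wall/baseline crossings (half a pixel for rasterized outlines).
    """
    ring = cell.smoothed_outline if cell.smoothed_outline is not None else cell.outline
    out: dict = {
        "cell_id": cell.cell_id,
        "area": cell.smoothed_polygon.area,
        "perimeter": _ring_perimeter(ring),
        "n_neighbours": len(cell.neighbour_ids),
        "n_junctions": cell.n_junctions,
    }
    for key in (
        "simplified_perimeter",
        "complexity",
        "undulation_amp",
        "undulation_freq",
        "aspect_ratio",
        "angle_deg",
        "endwall_angle_deg",
    ):
        out[key] = np.nan
    if not cell.unsimplifiable:
        und = cell_undulation_metrics(ring, cell.junctions, crossing_tol=crossing_tol)
        out.update(
            simplified_perimeter=und["simplified_perimeter"],
            complexity=und["complexity"],
            undulation_amp=und["undulation_amp"],
            undulation_freq=und["undulation_freq"],
        )
        try:
            fit = _fit_outline_ellipse(cell.simplified_outline)
            out["aspect_ratio"] = fit.aspect_ratio
            out["angle_deg"] = _relative_angle(fit.angle_deg, north_deg)
            out["endwall_angle_deg"] = _endwall_angles(cell.simplified_outline, fit)
        except DegenerateFitError:
            logger.warning("cell %d: degenerate ellipse fit", cell.cell_id)
    legacy = legacy_metrics(cell)
    out.update(
        undulation_index=legacy["undulation_index"],
        solidity=legacy["solidity"],
        convexity=legacy["convexity"],
    )
    return out


def legacy_metrics(cell: CellPolygon) -> dict[str, float]:
    """Classical single-polygon undulation metrics, on the smoothed outline.

    * undulation_index: perimeter / perimeter of the equal-area circle
      (>= 1; inflated by elongation alone);
    * solidity: area / convex hull area (<= 1);
    * convexity: perimeter / convex hull perimeter (>= 1).
    """
    poly = cell.smoothed_polygon
    area = poly.area
    perim = poly.exterior.length
    hull = poly.convex_hull
    return {
        "undulation_index": perim / (2.0 * np.sqrt(np.pi * area)),
        "solidity": area / hull.area,
        "convexity": perim / hull.exterior.length,
    }


def _complex_outline_points(mosaic: CellMosaic, cx: StomatalComplex) -> np.ndarray:
    pts = []
    for gid in cx.guard_ids:
        cell = mosaic.cells[gid]
        ring = cell.smoothed_outline if cell.smoothed_outline is not None else cell.outline
        pts.append(np.asarray(ring, float))
    return np.vstack(pts)


def _complex_angle(mosaic: CellMosaic, cx: StomatalComplex) -> float:
    """Absolute axial angle of one stomatal complex.

    Paired mode uses the dividing wall between the guard cells; single
    polygon mode the major axis of the direct ellipse fit.
    """
    if cx.dividing_segment is not None:
        p0, p1 = cx.dividing_segment
        d = p1 - p0
        return float(np.degrees(np.arctan2(d[1], d[0]))) % 180.0
    pts = _complex_outline_points(mosaic, cx)
    return fit_ellipse_direct(resample_ring(pts, max(len(pts), 64))).angle_deg


def stomatal_traits(
    mosaic: CellMosaic,
    cx: StomatalComplex,
    north_deg: float | None,
) -> dict:
    """Dimensions, angle and symmetry of one non-edge stomatal complex.

    Length and width are the extents of the guard outline(s) projected
    on the fitted major/minor axes — measured from the cells directly,
    not from the fitted ellipse.
    """
    out: dict = {
        "complex_id": cx.complex_id,
        "n_subsidiaries": len(cx.subsidiary_ids),
        "length": np.nan,
        "width": np.nan,
        "area": np.nan,
        "angle_deg": np.nan,
        "symmetry": np.nan,
    }
    pts = _complex_outline_points(mosaic, cx)
    try:
        angle = _complex_angle(mosaic, cx)
    except DegenerateFitError:
        logger.warning("complex %d: degenerate ellipse fit", cx.complex_id)
        return out
    rad = np.radians(angle)
    major = np.array([np.cos(rad), np.sin(rad)])
    minor = np.array([-np.sin(rad), np.cos(rad)])
    pmaj = pts @ major
    pmin = pts @ minor
    length = float(pmaj.max() - pmaj.min())
    width = float(pmin.max() - pmin.min())
    if width > length:  # dividing-wall axis can be the short axis of the union
        length, width = width, length
    out["length"] = length
    out["width"] = width
    out["area"] = float(sum(mosaic.cells[g].smoothed_polygon.area for g in cx.guard_ids))
    out["angle_deg"] = _relative_angle(angle, north_deg)
    if len(cx.guard_ids) == 2:
        a1, a2 = (mosaic.cells[g].smoothed_polygon.area for g in cx.guard_ids)
        out["symmetry"] = min(a1, a2) / max(a1, a2)
    return out


# ---------------------------------------------------------------------------
# image-level quantities
# ---------------------------------------------------------------------------


def stomatal_north(
    mosaic: CellMosaic, override_deg: float | None = None
) -> tuple[float | None, dict[int, float]]:
    """Axial mean stomatal angle, the proxy for the leaf axis.

    Returns ``(north_deg, per_complex_angles)``.  ``override_deg``
    short-circuits the estimate (for when the leaf axis is known).
    North is None (undefined) for isotropic stomatal angles; per-cell
    angles are then reported absolute.
    """
    angles: dict[int, float] = {}
    for cx in mosaic.complexes:
        if cx.is_edge:
            continue
        try:
            angles[cx.complex_id] = _complex_angle(mosaic, cx)
        except DegenerateFitError:
            continue
    if override_deg is not None:
        return float(override_deg) % 180.0, angles
    if not angles:
        raise ValueError(
            "no non-edge stomatal complexes to estimate stomatal north from; "
            "pass an orientation override"
        )
    mean, _r = axial_mean_angle(list(angles.values()))
    if mean is None:
        logger.warning("stomatal angles are isotropic; north undefined")
    return mean, angles


def _counts_for_index(mosaic: CellMosaic) -> tuple[int, int]:
    """(S, E): counted stomatal complexes and counted other cells.

    Counting rule: interior cells, plus cells clipped by the top or
    left image border; cells clipped only by the bottom/right border or
    by the NA mask are not counted.
    """
    def counted(cell: CellPolygon) -> bool:
        if not cell.is_edge:
            return True
        return cell.touches_top or cell.touches_left

    S = 0
    for cx in mosaic.complexes:
        guards = [mosaic.cells[g] for g in cx.guard_ids]
        if all(not g.is_edge for g in guards) or any(counted(g) and g.is_edge for g in guards):
            S += 1
    E = sum(
        1
        for c in mosaic.cells.values()
        if c.cell_class != GUARD_CLASS and counted(c)
    )
    return S, E


def stomatal_index(mosaic: CellMosaic) -> float:
    """Stomatal index, percent: 100 * S / (S + E) with the top/left rule."""
    S, E = _counts_for_index(mosaic)
    if S + E == 0:
        raise ValueError("no countable cells for the stomatal index")
    return 100.0 * S / (S + E)


_PER_AREA = {"um": 1e6, "mm": 1.0}  # conversion to mm^-2


def densities(mosaic: CellMosaic) -> tuple[float, float, str]:
    """(stomatal density, cell density, unit label).

    Whole (unclipped) complexes and cells per measured area.  Reported
    per mm^2 for micrometre/millimetre scales; otherwise per squared
    scale unit (per px^2 on unscaled images, with a warning).
    """
    if mosaic.measured_area <= 0:
        raise ValueError("measured area is zero")
    factor = _PER_AREA.get(mosaic.units)
    if factor is None:
        if mosaic.units == "px":
            logger.warning("no scale: densities reported per px^2")
        factor = 1.0
        unit = f"per {mosaic.units}^2"
    else:
        unit = "per mm^2"
    n_stomata = sum(1 for cx in mosaic.complexes if not cx.is_edge)
    n_cells = sum(
        1 for c in mosaic.cells.values() if not c.is_edge and c.cell_class != GUARD_CLASS
    )
    area = mosaic.measured_area / factor  # in mm^2 (or unit^2)
    return n_stomata / area, n_cells / area, unit


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

_MEDIAN_PAVEMENT = (
    "area",
    "perimeter",
    "simplified_perimeter",
    "complexity",
    "undulation_amp",
    "undulation_freq",
    "aspect_ratio",
    "endwall_angle_deg",
    "n_neighbours",
    "n_junctions",
)
_MEDIAN_STOMATAL = ("length", "width", "area", "symmetry", "n_subsidiaries")
_ANGLE_COLS = ("angle_deg",)


@dataclass
class ImageTraitRecord:
    """Aggregated trait vector for one image, plus the per-cell tables."""

    image_id: str
    plant_id: str | None
    north_deg: float | None
    traits: dict[str, float]
    pavement_cells: pd.DataFrame = field(repr=False, default=None)
    stomata: pd.DataFrame = field(repr=False, default=None)

    def to_series(self) -> pd.Series:
        s = pd.Series(self.traits, dtype=float)
        s["stomatal_north_deg"] = np.nan if self.north_deg is None else self.north_deg
        return s


def aggregate_cell_tables(
    pav: pd.DataFrame, sto: pd.DataFrame
) -> dict[str, float]:
    """Median/axial-mean aggregation of the per-cell tables."""
    out: dict[str, float] = {}
    for col in _MEDIAN_PAVEMENT:
        if col in pav and len(pav):
            out[f"pavement_{col}_median"] = float(np.nanmedian(pav[col]))
    for col in _ANGLE_COLS:
        if col in pav and len(pav) and pav[col].notna().any():
            mean, _ = axial_mean_angle(pav[col].dropna().to_numpy())
            out[f"pavement_{col}_mean"] = np.nan if mean is None else mean
    for col in _MEDIAN_STOMATAL:
        if col in sto and len(sto) and sto[col].notna().any():
            out[f"stomatal_{col}_median"] = float(np.nanmedian(sto[col]))
    for col in _ANGLE_COLS:
        if col in sto and len(sto) and sto[col].notna().any():
            mean, _ = axial_mean_angle(sto[col].dropna().to_numpy())
            out[f"stomatal_{col}_mean"] = np.nan if mean is None else mean
    return out


def extract_image_traits(
    mosaic: CellMosaic,
    image_id: str = "image",
    plant_id: str | None = None,
    north_override_deg: float | None = None,
    include: list[str] | None = None,
    exclude: list[str] | None = None,
) -> ImageTraitRecord:
    """Full per-image trait extraction.

    Per-cell traits are measured for all non-edge cells; shape traits
    aggregate by the median (robust to tracing errors), angles by the
    axial mean.  ``include``/``exclude`` restrict the aggregated trait
    vector (per-cell tables are unaffected).

    Raises if there are no non-edge pavement cells.
    """
    from . import arrangement  # local import to avoid a cycle

    try:
        north, _angles = stomatal_north(mosaic, north_override_deg)
    except ValueError:
        north = None

    pav_cells = [c for c in mosaic.pavement_cells if not c.is_edge]
    if not pav_cells:
        n_edge = sum(1 for c in mosaic.pavement_cells if c.is_edge)
        raise ValueError(
            f"no non-edge pavement cells to measure ({n_edge} pavement cells "
            "were excluded for touching the image border or NA mask)"
        )
    # rasterized outlines carry ~half-pixel residual noise: ignore
    # sub-pixel excursions when counting wall/baseline crossings
    crossing_tol = 0.5 * mosaic.scale
    pav = pd.DataFrame(
        [pavement_traits(c, north, crossing_tol=crossing_tol) for c in pav_cells]
    )
    zones = arrangement.classify_zones(mosaic)
    pav["zone"] = pav["cell_id"].map(zones)

    sto_rows = [
        stomatal_traits(mosaic, cx, north)
        for cx in mosaic.complexes
        if not cx.is_edge
    ]
    sto = pd.DataFrame(sto_rows) if sto_rows else pd.DataFrame(
        columns=["complex_id", *_MEDIAN_STOMATAL, "angle_deg"]
    )

    traits = aggregate_cell_tables(pav, sto)
    traits["stomatal_index_pct"] = stomatal_index(mosaic)
    sd, cd, unit = densities(mosaic)
    traits["stomatal_density"] = sd
    traits["cell_density"] = cd
    traits.update(arrangement.arrangement_traits(mosaic, north, zones))
    traits["n_cells"] = float(
        sum(1 for c in mosaic.cells.values() if c.cell_class != GUARD_CLASS)
    )
    traits["n_stomata"] = float(len(mosaic.complexes))
    traits["n_subsidiaries"] = float(
        sum(1 for c in mosaic.cells.values() if c.cell_class == "subsidiary")
    )

    if include is not None:
        traits = {k: v for k, v in traits.items() if k in set(include)}
    if exclude:
        traits = {k: v for k, v in traits.items() if k not in set(exclude)}
    return ImageTraitRecord(
        image_id=image_id,
        plant_id=plant_id,
        north_deg=north,
        traits=traits,
        pavement_cells=pav,
        stomata=sto,
    )
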