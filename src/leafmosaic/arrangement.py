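"""Spatial organisation of the cell mosaic.

Three families of arrangement measures:

* **zones** — pavement cells classified by their relation to the
  nearest stomatal complex: ``polar`` (abutting a complex, lying
  within a cone around its major axis), ``stomatal`` (abutting a
  complex laterally) or ``pavezone`` (everything else);
* **spacing** — mean number of cells between stomata (shortest paths
  on the adjacency graph with complexes contracted) and median
  nearest-neighbour distance between complex centroids;
* **rows** — stomatal row detection (single-linkage clustering of the
  across-leaf coordinate after rotating stomatal north onto +x) and
  the per-row metrics: spacing between adjacent row axes, consistency
  (continuity of stomata along the row) and wiggliness (deviation of
  centroids from a straight line, independent of cell size and
  spacing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .geometry import DegenerateFitError
from .mosaic import CellMosaic

logger = logging.getLogger(__name__)

__all__ = [
    "classify_zones",
    "mean_cells_between",
    "detect_rows",
    "row_metrics",
    "StomatalRowSet",
    "arrangement_traits",
]

ZONE_PAVEZONE = "pavezone"
ZONE_STOMATAL = "stomatal"
ZONE_POLAR = "polar"


def classify_zones(mosaic: CellMosaic, polar_cone_deg: float = 45.0) -> dict[int, str]:
    """Zone label for every pavement cell.

    Pavement cells adjacent (graph distance 1) to any member of a
    stomatal complex are ``polar`` when their centroid lies within
    ``polar_cone_deg`` of the complex's major axis as seen from the
    complex centroid, else ``stomatal``; all other pavement cells are
    ``pavezone``.  Cells abutting several complexes are classified
    against the nearest one.
    """
    from .traits import _complex_angle  # late import to avoid a cycle

    zones = {c.cell_id: ZONE_PAVEZONE for c in mosaic.pavement_cells}
    if not mosaic.complexes:
        return zones
    complex_info = []
    for cx in mosaic.complexes:
        try:
            angle = _complex_angle(mosaic, cx)
        except DegenerateFitError:
            angle = None
        members = cx.member_ids
        touching = set()
        for m in members:
            touching |= mosaic.cells[m].neighbour_ids
        complex_info.append((cx, angle, touching - members))
    for cell in mosaic.pavement_cells:
        candidates = [
            (np.hypot(*(cell.centroid - cx.centroid)), cx, angle)
            for cx, angle, touching in complex_info
            if cell.cell_id in touching
        ]
        if not candidates:
            continue
        _, cx, angle = min(candidates, key=lambda t: t[0])
        if angle is None:
            zones[cell.cell_id] = ZONE_STOMATAL
            continue
        v = cell.centroid - cx.centroid
        theta = np.degrees(np.arctan2(v[1], v[0]))
        diff = abs((theta - angle + 90.0) % 180.0 - 90.0)  # axial difference
        zones[cell.cell_id] = ZONE_POLAR if diff <= polar_cone_deg else ZONE_STOMATAL
    return zones


def mean_cells_between(mosaic: CellMosaic) -> float:
    """Mean number of cells between each stomatal complex and its nearest.

    Breadth-first search on the adjacency graph with each complex's
    members contracted to a single source; the path length is the
    number of intervening non-complex cells (0 for complexes sharing a
    wall).  NaN with fewer than two complexes or a disconnected graph.
    """
    if len(mosaic.complexes) < 2:
        return float("nan")
    owner = mosaic.complex_of_cell()
    dists = []
    for cx in mosaic.complexes:
        sources = set(cx.member_ids)
        visited = set(sources)
        frontier = sources
        depth = 0
        found = None
        while frontier and found is None:
            nxt = set()
            for cid in frontier:
                for nb in mosaic.adjacency.neighbors(cid):
                    if nb in visited:
                        continue
                    if owner.get(nb, cx.complex_id) != cx.complex_id:
                        found = depth  # `depth` cells lie strictly between
                        break
                    if nb not in owner:
                        nxt.add(nb)
                    visited.add(nb)
                if found is not None:
                    break
            frontier = nxt
            depth += 1
        if found is not None:
            dists.append(found)
    if not dists:
        logger.warning("no connected complex pairs; cells-between is undefined")
        return float("nan")
    return float(np.mean(dists))


@dataclass
class StomatalRowSet:
    """Detected stomatal rows, ordered by across-row position."""

    rows: list[list[int]]                 # complex ids, ordered along the row
    centroids: dict[int, np.ndarray]      # complex id -> centroid (original frame)
    north_deg: float
    low_confidence: bool = False          # cluster count unstable under cut +- 20%

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def _rotated(centroids: np.ndarray, north_deg: float) -> np.ndarray:
    """Rotate so stomatal north lies along +x."""
    rad = np.radians(north_deg)
    rot = np.array([[np.cos(rad), np.sin(rad)], [-np.sin(rad), np.cos(rad)]])
    return centroids @ rot.T


def detect_rows(
    mosaic: CellMosaic,
    north_deg: float | None,
    cut_factor: float = 1.5,
    median_width: float | None = None,
) -> StomatalRowSet:
    """Group non-edge stomatal complexes into rows.

    After rotating so north runs along +x, the across-row (y)
    coordinates are single-linkage clustered with the dendrogram cut at
    ``cut_factor`` x the median stomatal width.  The result is flagged
    low-confidence when the row count changes under a +-20% perturbed
    cut (e.g. for isotropically scattered stomata).
    """
    if north_deg is None:
        raise ValueError(
            "stomatal north is undefined; supply a leaf-axis override to detect rows"
        )
    complexes = [cx for cx in mosaic.complexes if not cx.is_edge]
    if len(complexes) < 2:
        raise ValueError("need at least two non-edge stomatal complexes")
    cents = {cx.complex_id: cx.centroid for cx in complexes}
    ids = sorted(cents)
    xy = _rotated(np.array([cents[i] for i in ids]), north_deg)
    if median_width is None:
        from .traits import stomatal_traits

        widths = [
            stomatal_traits(mosaic, cx, north_deg)["width"] for cx in complexes
        ]
        median_width = float(np.nanmedian(widths))
    cut = cut_factor * median_width

    def cluster(cut_at: float) -> np.ndarray:
        y = xy[:, 1:2]
        if len(y) == 1:
            return np.array([1])
        z = linkage(y, method="single")
        return fcluster(z, t=cut_at, criterion="distance")

    labels = cluster(cut)
    stable = all(
        len(np.unique(cluster(cut * f))) == len(np.unique(labels)) for f in (0.8, 1.2)
    )
    rows: dict[int, list[int]] = {}
    for cid, lab in zip(ids, labels):
        rows.setdefault(int(lab), []).append(cid)
    # order rows by across-axis position, stomata within rows by x
    def row_y(members):
        return float(np.mean([xy[ids.index(m), 1] for m in members]))

    ordered = sorted(rows.values(), key=row_y)
    ordered = [sorted(r, key=lambda m: xy[ids.index(m), 0]) for r in ordered]
    return StomatalRowSet(
        rows=ordered, centroids=cents, north_deg=north_deg, low_confidence=not stable
    )


def _tls_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through points: (center, unit direction)."""
    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center, full_matrices=False)
    return center, vt[0]


def row_metrics(rowset: StomatalRowSet) -> dict[str, float]:
    """Spacing, consistency and wiggliness of the detected rows.

    * ``row_wiggliness``: per row, RMS perpendicular residual about the
      total-least-squares line divided by the mean along-row gap
      (dimensionless, invariant to uniform scaling), averaged over rows
      with >= 3 stomata; NaN when no row qualifies.
    * ``row_spacing``: mean distance between adjacent rows' fitted
      lines.
    * ``row_consistency``: mean over rows of
      n_observed / (1 + row extent / median along-row gap), capped at 1
      — 1 for continuous evenly spaced rows, lower for gappy rows.
    """
    lines = []
    wigg = []
    consistency = []
    for members in rowset.rows:
        pts = np.array([rowset.centroids[m] for m in members])
        if len(pts) == 1:
            rad = np.radians(rowset.north_deg)
            lines.append((pts[0], np.array([np.cos(rad), np.sin(rad)])))
            consistency.append(1.0)
            continue
        center, direction = _tls_line(pts)
        lines.append((center, direction))
        t = np.sort((pts - center) @ direction)
        gaps = np.diff(t)
        mean_gap = float(gaps.mean())
        med_gap = float(np.median(gaps))
        extent = float(t[-1] - t[0])
        if med_gap > 0:
            consistency.append(min(1.0, len(pts) / (1.0 + extent / med_gap)))
        else:
            consistency.append(1.0)
        if len(pts) >= 3 and mean_gap > 0:
            normal = np.array([-direction[1], direction[0]])
            resid = (pts - center) @ normal
            wigg.append(float(np.sqrt(np.mean(resid**2))) / mean_gap)
    spacing = []
    for (c1, d1), (c2, _d2) in zip(lines[:-1], lines[1:]):
        n1 = np.array([-d1[1], d1[0]])
        spacing.append(abs(float((c2 - c1) @ n1)))
    return {
        "row_spacing": float(np.mean(spacing)) if spacing else float("nan"),
        "row_consistency": float(np.mean(consistency)) if consistency else float("nan"),
        "row_wiggliness": float(np.mean(wigg)) if wigg else float("nan"),
    }


def _nn_distance(mosaic: CellMosaic) -> float:
    cents = np.array([cx.centroid for cx in mosaic.complexes if not cx.is_edge])
    if len(cents) < 2:
        return float("nan")
    d2 = ((cents[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    return float(np.median(np.sqrt(d2.min(axis=1))))


def arrangement_traits(
    mosaic: CellMosaic,
    north_deg: float | None,
    zones: dict[int, str] | None = None,
) -> dict[str, float]:
    """All arrangement metrics as a flat dict (NaN where undefined)."""
    if zones is None:
        zones = classify_zones(mosaic)
    non_edge = [c for c in mosaic.pavement_cells if not c.is_edge]
    counts = {ZONE_PAVEZONE: 0, ZONE_STOMATAL: 0, ZONE_POLAR: 0}
    for c in non_edge:
        counts[zones[c.cell_id]] += 1
    out: dict[str, float] = {
        f"zone_{z}_count": float(n) for z, n in counts.items()
    }
    out["mean_cells_between_stomata"] = mean_cells_between(mosaic)
    out["nn_stomata_distance"] = _nn_distance(mosaic)
    out["n_rows"] = float("nan")
    out["row_spacing"] = float("nan")
    out["row_consistency"] = float("nan")
    out["row_wiggliness"] = float("nan")
    out["rows_low_confidence"] = float("nan")
    try:
        rowset = detect_rows(mosaic, north_deg)
    except ValueError:
        return out
    out["n_rows"] = float(rowset.n_rows)
    out["rows_low_confidence"] = float(rowset.low_confidence)
    out.update(row_metrics(rowset))
    return out
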