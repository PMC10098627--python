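"""From label raster to polygon cell mosaic.

The conversion pipeline:

1. ``vectorize_cells``: 4-connected components of each non-wall cell
   class become pixel-boundary polygons (half-open pixel model: pixel
   (r, c) owns [c, c+1) x [r, r+1); origin top-left, y down).
2. ``build_adjacency``: two cells are neighbours iff at least ``m``
   wall pixels see both in their 8-neighbourhood (walls are
   8-connected, interiors 4-connected, so a one-pixel wall always
   separates).
3. ``detect_junctions``: wall pixels seeing >= 3 cells (or >= 2 cells
   plus the image border / NA mask) are clustered into junction points
   — the corners where three or more cells meet.
4. ``smooth_outline``: Chaikin corner cutting of the pixelated
   outline, with junction-anchored vertices held fixed.
5. ``simplify_cell``: the polygon through a cell's junctions in
   boundary order — the hypothetical cell shape if all shared walls
   were straight.  This simplified cell is the baseline for every
   undulation metric.
6. ``assemble_mosaic``: ties it together and groups stomatal
   complexes (a guard polygon — or a pair of guard cells — plus the
   subsidiary cells touching it).

Cells clipped by the image border or by the NA mask are flagged
``is_edge`` and excluded from shape measurements downstream; their
membership of the top/left border is recorded for the stomatal-index
counting rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.measure import label as sk_label

from .labelmap import LabelMap

logger = logging.getLogger(__name__)

__all__ = [
    "CellPolygon",
    "StomatalComplex",
    "CellMosaic",
    "MosaicError",
    "vectorize_cells",
    "build_adjacency",
    "detect_junctions",
    "smooth_outline",
    "simplify_cell",
    "assemble_mosaic",
]

GUARD_CLASS = "stomate"
SUBSIDIARY_CLASS = "subsidiary"
PAVEMENT_CLASS = "pavement"


class MosaicError(ValueError):
    """Raised for structurally invalid mosaics."""


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class CellPolygon:
    """One epidermal cell recovered from the raster."""

    cell_id: int
    cell_class: str
    outline: np.ndarray               # (n, 2) pixel-boundary ring, scaled units
    pixel_count: int
    touches_top: bool = False
    touches_left: bool = False
    touches_border: bool = False
    touches_na: bool = False
    smoothed_outline: np.ndarray | None = None
    junctions: np.ndarray | None = None        # (k, 2) in boundary order
    simplified_outline: np.ndarray | None = None
    neighbour_ids: set[int] = field(default_factory=set)
    holes: list[np.ndarray] = field(default_factory=list)
    wall_share_px: float = 0.0   # this cell's share of adjacent wall pixels
    scale: float = 1.0

    @property
    def is_edge(self) -> bool:
        return self.touches_border or self.touches_na

    @property
    def n_junctions(self) -> int:
        return 0 if self.junctions is None else len(self.junctions)

    @property
    def unsimplifiable(self) -> bool:
        """True when the cell has < 3 junctions (no simplified shape)."""
        return self.simplified_outline is None

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.outline, [h for h in self.holes])

    @property
    def smoothed_polygon(self) -> Polygon:
        ring = self.smoothed_outline if self.smoothed_outline is not None else self.outline
        return Polygon(ring, [h for h in self.holes])

    @property
    def area(self) -> float:
        """Area of the traced interior (excludes the shared wall)."""
        return self.polygon.area

    @property
    def area_with_walls(self) -> float:
        """Interior area plus this cell's share of adjacent wall pixels.

        Cell interiors plus shared walls tile the image, so this is the
        unbiased estimate of the cell's footprint in the tissue.
        """
        return (self.pixel_count + self.wall_share_px) * self.scale**2

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])


@dataclass
class StomatalComplex:
    """Guard polygon(s) plus associated subsidiary cells."""

    complex_id: int
    guard_ids: tuple[int, ...]
    subsidiary_ids: frozenset[int]
    centroid: np.ndarray
    is_edge: bool
    dividing_segment: tuple[np.ndarray, np.ndarray] | None = None  # paired mode

    @property
    def member_ids(self) -> frozenset[int]:
        return frozenset(self.guard_ids) | self.subsidiary_ids


@dataclass
class CellMosaic:
    """All cell polygons, their adjacency graph and stomatal complexes."""

    cells: dict[int, CellPolygon]
    complexes: list[StomatalComplex]
    adjacency: nx.Graph
    scale: float
    units: str
    extent: tuple[float, float]       # (width, height) in scaled units
    measured_area: float
    paired_guard_cells: bool = False

    def cells_of_class(self, cls: str) -> list[CellPolygon]:
        return [c for c in self.cells.values() if c.cell_class == cls]

    @property
    def pavement_cells(self) -> list[CellPolygon]:
        return self.cells_of_class(PAVEMENT_CLASS)

    def complex_of_cell(self) -> dict[int, int]:
        """cell_id -> complex_id for every complex member."""
        out: dict[int, int] = {}
        for cx in self.complexes:
            for cid in cx.member_ids:
                out[cid] = cx.complex_id
        return out

    def to_geojson(self, path: str | Path | None = None) -> dict:
        """Export cells as a GeoJSON FeatureCollection (for inspection)."""
        feats = []
        for c in self.cells.values():
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [np.asarray(c.outline).tolist()
                                        + [np.asarray(c.outline)[0].tolist()]],
                    },
                    "properties": {
                        "cell_id": c.cell_id,
                        "cell_class": c.cell_class,
                        "is_edge": c.is_edge,
                        "neighbours": sorted(c.neighbour_ids),
                    },
                }
            )
        doc = {"type": "FeatureCollection", "features": feats}
        if path is not None:
            Path(path).write_text(json.dumps(doc))
        return doc


# ---------------------------------------------------------------------------
# pixel-boundary tracing
# ---------------------------------------------------------------------------

# directed boundary edges keep the region interior on the left in
# screen coordinates (y down): top edge runs +x, right edge +y, etc.
_SIDES = (
    ((-1, 0), (0, 0), (1, 0)),   # top neighbour absent: (c, r) -> (c+1, r)
    ((0, 1), (1, 0), (1, 1)),    # right: (c+1, r) -> (c+1, r+1)
    ((1, 0), (1, 1), (0, 1)),    # bottom: (c+1, r+1) -> (c, r+1)
    ((0, -1), (0, 1), (0, 0)),   # left: (c, r+1) -> (c, r)
)


def _trace_rings(pixels: set[tuple[int, int]]) -> list[np.ndarray]:
    """Chain the boundary edges of a pixel set into closed rings.

    Returns rings as (n, 2) arrays of (x, y) corner coordinates in
    pixel units.  The ring with the largest absolute area is the
    exterior; any others are hole rings.
    """
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for (r, c) in pixels:
        for (dr, dc), (ax, ay), (bx, by) in _SIDES:
            if (r + dr, c + dc) not in pixels:
                a = (c + ax, r + ay)
                b = (c + bx, r + by)
                edges.setdefault(a, []).append(b)
    rings: list[np.ndarray] = []
    while edges:
        start = min(edges)  # deterministic
        ring = [start]
        prev_dir = None
        cur = start
        while True:
            outs = edges[cur]
            if len(outs) == 1 or prev_dir is None:
                nxt = outs[0]
            else:
                # pinch vertex: prefer the sharpest left turn relative to
                # the incoming direction, keeping the interior consistent
                def turn(b):
                    d = (b[0] - cur[0], b[1] - cur[1])
                    cross = prev_dir[0] * d[1] - prev_dir[1] * d[0]
                    dot = prev_dir[0] * d[0] + prev_dir[1] * d[1]
                    return np.arctan2(cross, dot)
                nxt = min(outs, key=turn)
            outs.remove(nxt)
            if not outs:
                del edges[cur]
            prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
            cur = nxt
            if cur == start:
                break
            ring.append(cur)
        rings.append(np.asarray(ring, dtype=float))
    return rings


def _simplify_collinear(ring: np.ndarray) -> np.ndarray:
    """Drop vertices interior to straight runs of the ring."""
    n = len(ring)
    if n < 4:
        return ring
    prev = np.roll(ring, 1, axis=0)
    nxt = np.roll(ring, -1, axis=0)
    v1 = ring - prev
    v2 = nxt - ring
    keep = np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]) > 1e-12
    if keep.sum() < 3:
        return ring
    return ring[keep]


# ---------------------------------------------------------------------------
# pipeline operations
# ---------------------------------------------------------------------------


def vectorize_cells(
    labelmap: LabelMap, min_region_px: int = 4
) -> tuple[dict[int, CellPolygon], np.ndarray]:
    """Extract one region per 4-connected component of each cell class.

    Returns ``(cells, region_labels)`` where ``region_labels`` is an
    integer image assigning every cell-interior pixel its cell id
    (0 = wall or NA).  Regions smaller than ``min_region_px`` pixels
    are dropped with a logged warning.  Polygon coordinates are in
    scaled units.
    """
    grid = labelmap.grid
    scale = labelmap.scale
    region_labels = np.zeros(grid.shape, dtype=np.int32)
    cells: dict[int, CellPolygon] = {}
    next_id = 1
    na = labelmap.na_mask
    # NA-contact: within the 8-neighbourhood twice (crosses a 1-px wall)
    na_zone = ndimage.binary_dilation(na, structure=np.ones((3, 3), bool), iterations=2)
    h, w = grid.shape
    for cls in sorted(labelmap.config.class_values):
        code = labelmap.config.class_values[cls]
        mask = grid == code
        if not mask.any():
            continue
        lab, n = sk_label(mask, connectivity=1, return_num=True)
        for comp in range(1, n + 1):
            comp_mask = lab == comp
            count = int(comp_mask.sum())
            if count < min_region_px:
                logger.warning(
                    "dropping %s region of %d px (< %d px minimum)", cls, count, min_region_px
                )
                continue
            rows, cols = np.nonzero(comp_mask)
            pixels = set(zip(rows.tolist(), cols.tolist()))
            rings = _trace_rings(pixels)
            areas = [_ring_area(r) for r in rings]
            ext = int(np.argmax(np.abs(areas)))
            exterior = _simplify_collinear(rings[ext])
            holes = [_simplify_collinear(rings[i]) for i in range(len(rings)) if i != ext]
            cell = CellPolygon(
                cell_id=next_id,
                cell_class=cls,
                outline=exterior * scale,
                holes=[hh * scale for hh in holes],
                pixel_count=count,
                touches_top=bool((rows == 0).any()),
                touches_left=bool((cols == 0).any()),
                touches_border=bool(
                    (rows == 0).any() or (cols == 0).any()
                    or (rows == h - 1).any() or (cols == w - 1).any()
                ),
                touches_na=bool(na_zone[comp_mask].any()),
                scale=scale,
            )
            cells[next_id] = cell
            region_labels[comp_mask] = next_id
            next_id += 1
    return cells, region_labels


def _ring_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _wall_neighbour_sets(labelmap: LabelMap, region_labels: np.ndarray):
    """For every wall pixel, the set of distinct regions in its 8-hood.

    Returns ``(wall_rc, neigh)`` with ``wall_rc`` an (n, 2) array of
    wall pixel coordinates and ``neigh`` an (n, 8) array of region ids
    (0 where none), plus a boolean border/NA contact flag per pixel.
    """
    grid = labelmap.grid
    wall = grid == labelmap.config.wall_value
    h, w = grid.shape
    padded = np.zeros((h + 2, w + 2), dtype=np.int32)
    padded[1:-1, 1:-1] = region_labels
    na_pad = np.ones((h + 2, w + 2), dtype=bool)  # outside image counts as border
    na_pad[1:-1, 1:-1] = labelmap.na_mask
    rows, cols = np.nonzero(wall)
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    neigh = np.stack(
        [padded[rows + 1 + dr, cols + 1 + dc] for dr, dc in offs], axis=1
    )
    border = np.zeros(len(rows), dtype=bool)
    for dr, dc in offs:
        border |= na_pad[rows + 1 + dr, cols + 1 + dc]
    return np.column_stack([rows, cols]), neigh, border


def _wall_window_regions(
    labelmap: LabelMap, region_labels: np.ndarray, wall_rc: np.ndarray, radius: int
) -> np.ndarray:
    """Region ids within a (2r+1)^2 window of each wall pixel."""
    h, w = labelmap.grid.shape
    padded = np.zeros((h + 2 * radius, w + 2 * radius), dtype=np.int32)
    padded[radius:-radius, radius:-radius] = region_labels
    rows, cols = wall_rc[:, 0], wall_rc[:, 1]
    offs = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if (dr, dc) != (0, 0)
    ]
    return np.stack(
        [padded[rows + radius + dr, cols + radius + dc] for dr, dc in offs], axis=1
    )


def build_adjacency(
    labelmap: LabelMap,
    cells: dict[int, CellPolygon],
    region_labels: np.ndarray,
    min_shared_wall_px: int = 3,
    _walls=None,
) -> nx.Graph:
    """Neighbour graph: cells sharing >= m wall pixels' 8-neighbourhoods."""
    _, neigh, _ = _walls if _walls is not None else _wall_neighbour_sets(labelmap, region_labels)
    pair_counts: dict[tuple[int, int], int] = {}
    wall_share: dict[int, float] = {}
    for row in neigh:
        ids = np.unique(row)
        ids = ids[ids > 0]
        if len(ids) == 0:
            continue
        frac = 1.0 / len(ids)
        for i in ids:
            wall_share[int(i)] = wall_share.get(int(i), 0.0) + frac
        if len(ids) < 2:
            continue
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                key = (int(ids[i]), int(ids[j]))
                pair_counts[key] = pair_counts.get(key, 0) + 1
    g = nx.Graph()
    g.add_nodes_from(cells)
    for (a, b), n in pair_counts.items():
        if n >= min_shared_wall_px:
            g.add_edge(a, b, shared_wall_px=n)
    for cid, cell in cells.items():
        cell.neighbour_ids = set(g.neighbors(cid))
        cell.wall_share_px = wall_share.get(cid, 0.0)
    return g


def detect_junctions(
    labelmap: LabelMap,
    cells: dict[int, CellPolygon],
    region_labels: np.ndarray,
    _walls=None,
) -> dict[int, list[np.ndarray]]:
    """Junction points (where >= 3 cells, or 2 cells + border/NA, meet).

    Contiguous (8-connected) junction wall pixels are clustered and
    replaced by their centroid.  Returns, for every cell id, the list
    of junction points incident to that cell (unordered; ordering along
    the outline happens per cell later).  Coordinates are scaled.
    """
    wall_rc, neigh, border = _walls if _walls is not None else _wall_neighbour_sets(
        labelmap, region_labels
    )
    n_regions = np.array([len(np.unique(r[r > 0])) for r in neigh])
    strict = (n_regions >= 3) | ((n_regions >= 2) & border)
    # wide (5x5) fallback: at shallow wall angles the third cell's
    # interior can sit 2 px away from every wall pixel of the meeting.
    # Wide-only clusters count only when far from every strict junction,
    # otherwise undulating walls near a real junction would smear it.
    neigh_wide = _wall_window_regions(labelmap, region_labels, wall_rc, radius=2)
    n_wide = np.array([len(np.unique(r[r > 0])) for r in neigh_wide])
    wide_only = (n_wide >= 3) & ~strict
    is_junction = strict.copy()
    if wide_only.any():
        wmask = np.zeros(labelmap.grid.shape, dtype=bool)
        wmask[wall_rc[wide_only, 0], wall_rc[wide_only, 1]] = True
        wlab, n_w = sk_label(wmask, connectivity=2, return_num=True)
        strict_rc = wall_rc[strict]
        for k in range(1, n_w + 1):
            rs, cs = np.nonzero(wlab == k)
            if strict_rc.size:
                d2 = (
                    (strict_rc[:, 0][None, :] - rs[:, None]) ** 2
                    + (strict_rc[:, 1][None, :] - cs[:, None]) ** 2
                )
                if d2.min() <= 16:  # within 4 px of a strict junction
                    continue
            for r_, c_ in zip(rs, cs):
                pos = np.nonzero((wall_rc[:, 0] == r_) & (wall_rc[:, 1] == c_))[0]
                is_junction[pos] = True
    jmask = np.zeros(labelmap.grid.shape, dtype=bool)
    jmask[wall_rc[is_junction, 0], wall_rc[is_junction, 1]] = True
    clusters, n_clusters = sk_label(jmask, connectivity=2, return_num=True)

    scale = labelmap.scale
    per_cell: dict[int, list[np.ndarray]] = {cid: [] for cid in cells}
    # gather member pixels per cluster
    idx = clusters[wall_rc[is_junction, 0], wall_rc[is_junction, 1]]
    members: dict[int, list[int]] = {}
    for k, ci in enumerate(idx):
        members.setdefault(int(ci), []).append(k)
    jrows = wall_rc[is_junction]
    jneigh = np.concatenate([neigh, neigh_wide], axis=1)[is_junction]
    order = sorted(
        members,
        key=lambda ci: (jrows[members[ci]][:, 0].min(), jrows[members[ci]][:, 1].min()),
    )
    for ci in order:
        rows = jrows[members[ci]]
        # pixel centres; ties in clustering broken by lowest (row, col)
        cy = rows[:, 0].mean() + 0.5
        cx = rows[:, 1].mean() + 0.5
        point = np.array([cx, cy]) * scale
        incident = np.unique(jneigh[members[ci]])
        for cid in incident[incident > 0]:
            per_cell[int(cid)].append(point)
    return per_cell


def smooth_outline(
    ring: np.ndarray,
    anchor_idx: np.ndarray | None = None,
    iterations: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Chaikin corner cutting with anchored vertices held fixed.

    Parameters
    ----------
    ring : (n, 2) array
        Closed polygon (first vertex not repeated).
    anchor_idx : int array, optional
        Indices of vertices to keep fixed (cell junctions).
    iterations : int
        Number of corner-cutting passes (default 3); 0 is the identity.

    Returns
    -------
    smoothed : (m, 2) array
    new_anchor_idx : int array
        Indices of the anchors within the smoothed ring.

    Falls back to the unsmoothed ring (with a warning) if smoothing
    would produce a self-intersecting polygon.
    """
    pts = np.asarray(ring, dtype=float)
    anchors = set() if anchor_idx is None else set(int(i) for i in anchor_idx)
    if iterations <= 0 or len(pts) < 4:
        return pts, np.array(sorted(anchors), dtype=int)
    original = pts
    orig_anchors = anchors
    for _ in range(iterations):
        n = len(pts)
        out: list[np.ndarray] = []
        new_anchors: set[int] = set()
        for i in range(n):
            j = (i + 1) % n
            if i in anchors:
                new_anchors.add(len(out))
                out.append(pts[i])
            q = 0.75 * pts[i] + 0.25 * pts[j]
            r = 0.25 * pts[i] + 0.75 * pts[j]
            out.append(q)
            out.append(r)
        pts = np.asarray(out)
        anchors = new_anchors
    if not Polygon(pts).is_valid:
        logger.warning("Chaikin smoothing produced self-intersection; using raw outline")
        return original, np.array(sorted(orig_anchors), dtype=int)
    return pts, np.array(sorted(anchors), dtype=int)


def _densify_ring(
    ring: np.ndarray, anchors: np.ndarray, step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Insert vertices so no edge exceeds ``step``; anchors preserved."""
    n = len(ring)
    aset = set(int(a) for a in anchors)
    out: list[np.ndarray] = []
    new_anchors: list[int] = []
    for i in range(n):
        if i in aset:
            new_anchors.append(len(out))
        out.append(ring[i])
        a, b = ring[i], ring[(i + 1) % n]
        length = float(np.hypot(*(b - a)))
        k = int(np.ceil(length / step))
        for j in range(1, k):
            out.append(a + (j / k) * (b - a))
    return np.asarray(out), np.asarray(new_anchors, dtype=int)


def _anchored_moving_average(
    ring: np.ndarray, anchors: np.ndarray, window: int, passes: int
) -> np.ndarray:
    """Circular moving average of ring vertices; anchors held fixed.

    Requires roughly uniform vertex spacing (densify first).  Removes
    the +-half-pixel staircase of rasterized boundaries that corner
    cutting alone cannot, without disturbing straight walls.
    """
    n = len(ring)
    h = window // 2
    if n < window or h < 1 or passes < 1:
        return ring
    anch = np.zeros(n, dtype=bool)
    if len(anchors):
        anch[anchors] = True
    pts = ring.copy()
    idx = np.arange(n)
    for _ in range(passes):
        acc = np.zeros_like(pts)
        for d in range(-h, h + 1):
            acc += pts[(idx + d) % n]
        out = acc / (2 * h + 1)
        out[anch] = ring[anch]
        pts = out
    return pts


def simplify_cell(cell: CellPolygon) -> np.ndarray | None:
    """Polygon through the cell's junctions in boundary order.

    Returns None (and leaves the cell flagged unsimplifiable) when the
    cell has fewer than 3 junctions.
    """
    if cell.junctions is None or len(cell.junctions) < 3:
        return None
    return np.asarray(cell.junctions, dtype=float)


def _project_on_ring(ring: np.ndarray, p: np.ndarray) -> tuple[int, float, np.ndarray]:
    """Nearest point on the closed polyline: (segment index, t, point)."""
    a = ring
    b = np.roll(ring, -1, axis=0)
    d = b - a
    len2 = (d * d).sum(axis=1)
    len2[len2 == 0] = 1e-30
    t = np.clip(((p - a) * d).sum(axis=1) / len2, 0.0, 1.0)
    foot = a + t[:, None] * d
    dist2 = ((foot - p) ** 2).sum(axis=1)
    k = int(np.argmin(dist2))
    tk = float(t[k])
    if tk >= 1.0 - 1e-9:  # lands on the next vertex: canonicalise
        k = (k + 1) % len(ring)
        tk = 0.0
    return k, tk, ring[k] if tk == 0.0 else foot[k]


def _attach_junctions(
    cell: CellPolygon,
    points: list[np.ndarray],
    iterations: int,
    scale: float = 1.0,
    presmooth_window_px: int = 5,
    presmooth_passes: int = 2,
) -> None:
    """Anchor junctions onto the outline, smooth with anchors, simplify.

    Smoothing is a two-stage pass: an anchored moving average on the
    1-px-densified ring (removes rasterization staircase) followed by
    Chaikin corner cutting.
    """
    ring = cell.outline

    def _smooth(r: np.ndarray, anchors: np.ndarray):
        dring, danch = _densify_ring(r, anchors, step=max(scale, 1e-12))
        dring = _anchored_moving_average(
            dring, danch, presmooth_window_px, presmooth_passes
        )
        return smooth_outline(dring, danch, iterations)

    if not points:
        cell.smoothed_outline, _ = _smooth(ring, np.array([], dtype=int))
        cell.junctions = None
        cell.simplified_outline = None
        return
    # each junction is anchored at its nearest point on the outline;
    # a vertex is inserted there if none is close enough
    placements = []  # (segment index, t along segment) per junction
    for p in points:
        placements.append(_project_on_ring(ring, np.asarray(p, float))[:2])
    order = sorted(range(len(placements)), key=lambda i: placements[i])
    new_ring: list[np.ndarray] = []
    anchor_positions: list[int] = []
    last_key = None
    pi = 0
    for seg in range(len(ring)):
        new_ring.append(ring[seg])
        while pi < len(order) and placements[order[pi]][0] == seg:
            k, t = placements[order[pi]]
            a, b = ring[seg], ring[(seg + 1) % len(ring)]
            pt = a + t * (b - a)
            key = (round(pt[0], 9), round(pt[1], 9))
            if key != last_key:
                if np.allclose(pt, new_ring[-1]):
                    anchor_positions.append(len(new_ring) - 1)
                else:
                    anchor_positions.append(len(new_ring))
                    new_ring.append(pt)
                last_key = key
            pi += 1
    ring2 = np.asarray(new_ring)
    ordered_idx = np.array(sorted(set(anchor_positions)), dtype=int)
    smoothed, new_idx = _smooth(ring2, ordered_idx)
    cell.smoothed_outline = smoothed
    cell.junctions = smoothed[new_idx] if len(new_idx) else None
    if cell.junctions is not None and len(cell.junctions) >= 3:
        simp = simplify_cell(cell)
        if simp is not None and not Polygon(simp).is_valid:
            logger.warning("cell %d: simplified polygon self-intersects", cell.cell_id)
        cell.simplified_outline = simp
    else:
        cell.simplified_outline = None


def _dividing_segment(
    labelmap: LabelMap, walls, id_a: int, id_b: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Wall segment dividing two paired guard cells (PCA of wall pixels)."""
    wall_rc, neigh, _ = walls
    sees = (neigh == id_a).any(axis=1) & (neigh == id_b).any(axis=1)
    if sees.sum() < 2:
        return None
    rc = wall_rc[sees].astype(float)
    xy = np.column_stack([rc[:, 1] + 0.5, rc[:, 0] + 0.5]) * labelmap.scale
    center = xy.mean(axis=0)
    u, s, vt = np.linalg.svd(xy - center, full_matrices=False)
    direction = vt[0]
    t = (xy - center) @ direction
    return (center + t.min() * direction, center + t.max() * direction)


def assemble_mosaic(
    labelmap: LabelMap,
    paired_guard_cells: bool = False,
    min_region_px: int = 4,
    min_shared_wall_px: int = 3,
    smooth_iterations: int = 3,
) -> CellMosaic:
    """Run the full raster-to-mosaic pipeline."""
    cells, region_labels = vectorize_cells(labelmap, min_region_px)
    walls = _wall_neighbour_sets(labelmap, region_labels)
    adjacency = build_adjacency(labelmap, cells, region_labels, min_shared_wall_px, _walls=walls)
    per_cell_junctions = detect_junctions(labelmap, cells, region_labels, _walls=walls)
    for cid, cell in cells.items():
        _attach_junctions(
            cell, per_cell_junctions.get(cid, []), smooth_iterations, scale=labelmap.scale
        )

    complexes: list[StomatalComplex] = []
    guards = [c for c in cells.values() if c.cell_class == GUARD_CLASS]
    guard_groups: list[tuple[int, ...]] = []
    dividing: dict[tuple[int, ...], tuple[np.ndarray, np.ndarray] | None] = {}
    if paired_guard_cells:
        unpaired = {g.cell_id for g in guards}
        for g in sorted(guards, key=lambda c: c.cell_id):
            if g.cell_id not in unpaired:
                continue
            partners = [
                n for n in sorted(g.neighbour_ids)
                if n in unpaired and n != g.cell_id and cells[n].cell_class == GUARD_CLASS
            ]
            if not partners:
                raise MosaicError(
                    f"paired-guard-cell mode: guard cell {g.cell_id} has no "
                    "adjacent unpaired guard cell"
                )
            mate = partners[0]
            unpaired.discard(g.cell_id)
            unpaired.discard(mate)
            pair = (g.cell_id, mate)
            guard_groups.append(pair)
            dividing[pair] = _dividing_segment(labelmap, walls, *pair)
    else:
        guard_groups = [(g.cell_id,) for g in sorted(guards, key=lambda c: c.cell_id)]

    for k, group in enumerate(guard_groups):
        subs = set()
        for gid in group:
            subs |= {
                n for n in cells[gid].neighbour_ids
                if cells[n].cell_class == SUBSIDIARY_CLASS
            }
        areas = np.array([cells[g].area for g in group])
        cents = np.array([cells[g].centroid for g in group])
        centroid = (cents * areas[:, None]).sum(axis=0) / areas.sum()
        is_edge = any(cells[m].is_edge for m in (*group, *subs))
        complexes.append(
            StomatalComplex(
                complex_id=k,
                guard_ids=group,
                subsidiary_ids=frozenset(subs),
                centroid=centroid,
                is_edge=is_edge,
                dividing_segment=dividing.get(group),
            )
        )

    h, w = labelmap.shape
    return CellMosaic(
        cells=cells,
        complexes=complexes,
        adjacency=adjacency,
        scale=labelmap.scale,
        units=labelmap.units,
        extent=(w * labelmap.scale, h * labelmap.scale),
        measured_area=labelmap.measured_area,
        paired_guard_cells=paired_guard_cells,
    )
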