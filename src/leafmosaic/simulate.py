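"""Synthetic epidermis generator: ground-truth cells and mosaics.

Replaces micrographs for validation and testing.  Three layers:

* ``simulate_cell`` — single cells of controlled gross shape
  (rectangle / ellipse-polygon / non-convex crescent), aspect ratio
  and wall undulation.  Walls are perturbed by a normal sine that
  vanishes at the junctions, so junction positions are exact ground
  truth and amplitude, crossing counts and arc lengths are known
  analytically.
* ``simulate_cell_grid`` — a full factorial of shapes x aspect ratios
  x amplitudes x periods (default 1200 cells) used to show that the
  junction-based undulation metrics are independent of gross cell
  shape while legacy metrics are not.
* ``simulate_mosaic`` / ``rasterize_mosaic`` — whole tessellations
  (brick, hexagonal or Lloyd-relaxed Voronoi) with optional undulated
  shared walls and stomatal complexes placed on parallel rows
  (elliptical guard polygon carved into a host cell, flanked by two
  subsidiary cells), burned to a label raster that loads through the
  normal pipeline.  Ground truth (cell classes, adjacency, junction
  counts, undulation metrics, row assignments, zones, north) is
  recorded at the polygon level.

All geometry is built in pixel units; a scale is attached at
rasterization time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Polygon, box

from .labelmap import LabelMap, ValueConfig
from .geometry import crossings_count, max_normal_offset

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticCellSpec",
    "SyntheticCell",
    "MosaicSpec",
    "SyntheticMosaic",
    "simulate_cell",
    "simulate_cell_grid",
    "simulate_mosaic",
    "rasterize_mosaic",
    "DEFAULT_CODES",
]

GROSS_SHAPES = ("rectangle", "ellipse", "crescent")

DEFAULT_CODES = {"wall": 0, "pavement": 255, "stomate": 85, "subsidiary": 170}


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Parameters of one synthetic cell.

    ``size`` is the characteristic (short-axis) length; the long axis
    is ``size * aspect_ratio``.  ``undulation_amplitude`` is the sine
    amplitude normal to each wall; ``undulation_periods_per_wall`` the
    integer number of full sine periods per wall.  ``phase`` jitters
    the per-wall sign pattern of the sine without changing any
    ground-truth value.
    """

    gross_shape: str = "rectangle"
    aspect_ratio: float = 1.0
    size: float = 100.0
    undulation_amplitude: float = 0.0
    undulation_periods_per_wall: int = 0
    phase: float = 0.0
    rng_seed: int = 0
    points_per_wall: int = 96

    def __post_init__(self):
        if self.gross_shape not in GROSS_SHAPES:
            raise ValueError(f"gross_shape must be one of {GROSS_SHAPES}")
        if self.aspect_ratio < 1 or self.size <= 0:
            raise ValueError("aspect_ratio >= 1 and size > 0 required")
        if self.undulation_amplitude < 0 or self.undulation_periods_per_wall < 0:
            raise ValueError("undulation parameters must be non-negative")


@dataclass
class SyntheticCell:
    """Outline polygon with known junctions and ground-truth metrics."""

    spec: SyntheticCellSpec
    outline: np.ndarray        # (n, 2) dense polyline, closed implicitly
    junctions: np.ndarray      # (k, 2) base polygon vertices
    ground_truth: dict[str, float]


def _base_polygon(spec: SyntheticCellSpec) -> np.ndarray:
    L = spec.size * spec.aspect_ratio
    h = spec.size
    if spec.gross_shape == "rectangle":
        return np.array([[0, 0], [L, 0], [L, h], [0, h]], dtype=float)
    if spec.gross_shape == "ellipse":
        t = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        return np.column_stack([L / 2 * (1 + np.cos(t)), h / 2 * (1 + np.sin(t))])
    # crescent: non-convex "dart" quadrilateral
    return np.array([[0, 0], [L / 2, h], [L, 0], [L / 2, 0.5 * h]], dtype=float)


def _min_wall_spacing(base: np.ndarray) -> float:
    """Minimum distance between non-adjacent walls of the base polygon."""
    n = len(base)
    edges = [LineString([base[i], base[(i + 1) % n]]) for i in range(n)]
    dmin = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent walls share a junction
            dmin = min(dmin, edges[i].distance(edges[j]))
    return float(dmin)


def _sine_profile(t: np.ndarray, amp: float, periods: int) -> np.ndarray:
    """Normal displacement of an undulated wall at parameter t in [0, 1].

    A sine with ``periods`` full periods, tapered by a sin^2 envelope so
    both the displacement and its first derivative vanish at the
    junctions (sharp cell corners would otherwise self-intersect).  The
    interior zeros — and hence the baseline crossing count 2p - 1 — are
    those of the raw sine.
    """
    return amp * np.sin(2 * np.pi * periods * t) * np.sin(np.pi * t) ** 2


def _profile_peak(amp: float, periods: int) -> float:
    """max |displacement| of the tapered sine (dense numerical max)."""
    t = np.linspace(0.0, 1.0, 8193)
    return float(np.max(np.abs(_sine_profile(t, amp, periods))))


def _wall_polyline(
    a: np.ndarray, b: np.ndarray, amp: float, periods: int, sign: float, n: int
) -> np.ndarray:
    """Undulated wall from a to b, junction at t=0 included, t=1 not."""
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    base = a[None, :] + t[:, None] * (b - a)[None, :]
    if amp <= 0 or periods < 1:
        return base
    d = (b - a) / np.hypot(*(b - a))
    normal = np.array([-d[1], d[0]])
    return base + (sign * _sine_profile(t, amp, periods))[:, None] * normal


def simulate_cell(spec: SyntheticCellSpec) -> SyntheticCell:
    """Build one synthetic cell with exact ground truth.

    Ground truth: ``complexity`` by dense numerical quadrature of the
    wall arc length, ``undulation_amp`` as the peak of the tapered sine
    profile, crossing count 2p - 1 per undulated wall (p full periods
    anchored at both junctions cross the baseline at the interior zeros
    only).
    """
    base = _base_polygon(spec)
    amp = spec.undulation_amplitude
    periods = spec.undulation_periods_per_wall
    if amp > 0 and periods >= 1:
        bound = 0.45 * _min_wall_spacing(base)
        if amp >= bound:
            raise ValueError(
                f"amplitude {amp} exceeds the self-intersection bound {bound:.3g}"
            )
    rng = np.random.default_rng(
        (int(spec.rng_seed), int(abs(spec.phase) * 1e6) % (2**31))
    )
    n_walls = len(base)
    signs = rng.choice([-1.0, 1.0], size=n_walls)
    walls = []
    dense = []
    for i in range(n_walls):
        a, b = base[i], base[(i + 1) % n_walls]
        walls.append(_wall_polyline(a, b, amp, periods, signs[i], spec.points_per_wall))
        dense.append(_wall_polyline(a, b, amp, periods, signs[i], 4096))
    outline = np.vstack(walls)

    simp_perim = float(
        sum(np.hypot(*(base[(i + 1) % n_walls] - base[i])) for i in range(n_walls))
    )
    arc = 0.0
    for i, w in enumerate(dense):
        closed = np.vstack([w, base[(i + 1) % n_walls]])
        arc += float(np.hypot(*np.diff(closed, axis=0).T).sum())
    undulated = amp > 0 and periods >= 1
    crossings = n_walls * (2 * periods - 1) if undulated else 0
    truth = {
        "complexity": arc / simp_perim,
        "undulation_amp": _profile_peak(amp, periods) if undulated else 0.0,
        "undulation_freq": crossings / simp_perim,
        "n_crossings": float(crossings),
        "aspect_ratio": spec.aspect_ratio,
        "simplified_perimeter": simp_perim,
    }
    if not Polygon(outline).is_valid:
        raise ValueError("simulated outline self-intersects; reduce amplitude")
    return SyntheticCell(spec=spec, outline=outline, junctions=base, ground_truth=truth)


def simulate_cell_grid(
    shapes: tuple[str, ...] = GROSS_SHAPES,
    aspect_ratios: tuple[float, ...] = (1, 2, 4, 7, 10),
    amplitudes: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0),
    periods: tuple[int, ...] = (1, 2, 3, 4),
    replicates: int = 5,
    size: float = 100.0,
    rng_seed: int = 0,
) -> tuple[list[SyntheticCell], pd.DataFrame]:
    """Full factorial of synthetic cells plus their ground-truth table.

    The default grid (3 shapes x 5 aspect ratios x 4 amplitudes x 4
    period counts x 5 phase-jittered replicates) yields 1200 cells
    spanning straight-walled to strongly undulated, isodiametric to
    10:1 elongated, convex and crescent shapes.
    """
    for name, levels in (
        ("shapes", shapes),
        ("aspect_ratios", aspect_ratios),
        ("amplitudes", amplitudes),
        ("periods", periods),
    ):
        if not levels:
            raise ValueError(f"empty factor levels: {name}")
    cells = []
    rows = []
    k = 0
    for shape in shapes:
        for ar in aspect_ratios:
            for amp in amplitudes:
                for per in periods:
                    for rep in range(replicates):
                        spec = SyntheticCellSpec(
                            gross_shape=shape,
                            aspect_ratio=ar,
                            size=size,
                            undulation_amplitude=amp,
                            undulation_periods_per_wall=per,
                            phase=float(rep),
                            rng_seed=rng_seed + k,
                        )
                        cell = simulate_cell(spec)
                        cells.append(cell)
                        rows.append(
                            {
                                "cell_index": k,
                                "gross_shape": shape,
                                "aspect_ratio": ar,
                                "amplitude": amp,
                                "periods": per,
                                "replicate": rep,
                                **{f"true_{t}": v for t, v in cell.ground_truth.items()},
                            }
                        )
                        k += 1
    return cells, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole mosaics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MosaicSpec:
    """Parameters of a synthetic tessellated epidermis (pixel units)."""

    grid: str = "brick"                 # brick | hex | voronoi
    n_cols: int = 10
    n_rows: int = 10
    cell_size: float = 24.0             # short-axis cell dimension, px
    cell_aspect: float = 1.5            # brick elongation (brick grid only)
    undulation_amplitude: float = 0.0
    undulation_periods: int = 0
    stomatal_row_indices: tuple[int, ...] = ()
    stoma_every: int = 2                # a stoma in every k-th cell of a row
    row_jitter: float = 0.0             # SD of across-row centre jitter, px
    stoma_length_frac: float = 0.6      # of host cell long dimension
    stoma_width_frac: float = 0.4       # of host cell short dimension
    with_subsidiaries: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if self.grid not in ("brick", "hex", "voronoi"):
            raise ValueError("grid must be brick, hex or voronoi")
        if min(self.n_cols, self.n_rows) < 2 or self.cell_size <= 0:
            raise ValueError("grid dimensions must be >= 2 and cell_size > 0")
        if not (0 < self.stoma_length_frac < 0.9 and 0 < self.stoma_width_frac < 0.9):
            raise ValueError("stoma fractions must lie in (0, 0.9)")


@dataclass
class SyntheticMosaic:
    """Polygon mosaic plus ground truth, ready for rasterization."""

    spec: MosaicSpec
    cells: list[tuple[str, Polygon]]    # (class, polygon), index = truth cell_index
    truth: pd.DataFrame                 # per-cell ground truth
    adjacency: set[tuple[int, int]]     # index pairs, shared boundary >= 3 px
    stomata: pd.DataFrame               # per-stoma: centroid, row, host index
    north_deg: float = 0.0
    extent: tuple[float, float] = (0.0, 0.0)


def _brick_chains(spec: MosaicSpec) -> list[list[np.ndarray]]:
    """Vertex chains of a running-bond brick grid, T-points included."""
    W = spec.cell_size * spec.cell_aspect
    H = spec.cell_size
    total_w = spec.n_cols * W
    chains = []
    for r in range(spec.n_rows):
        y0, y1 = r * H, (r + 1) * H
        offset = (W / 2.0) if r % 2 else 0.0
        xs = [offset + i * W for i in range(-1, spec.n_cols + 1)]
        xs = [x for x in xs]
        for x0 in xs:
            x1 = x0 + W
            cx0, cx1 = max(x0, 0.0), min(x1, total_w)
            if cx1 - cx0 < 1e-9:
                continue
            # T-points: vertical walls of the rows above/below
            def tpoints(row):
                off = (W / 2.0) if row % 2 else 0.0
                pts = [off + i * W for i in range(-1, spec.n_cols + 2)]
                return sorted(p for p in pts if cx0 + 1e-9 < p < cx1 - 1e-9 and 0 <= p <= total_w)

            bottom_t = tpoints(r - 1) if r > 0 else []
            top_t = tpoints(r + 1) if r < spec.n_rows - 1 else []
            chain = [np.array([cx0, y0])]
            chain += [np.array([p, y0]) for p in bottom_t]
            chain.append(np.array([cx1, y0]))
            chain.append(np.array([cx1, y1]))
            chain += [np.array([p, y1]) for p in reversed(top_t)]
            chain.append(np.array([cx0, y1]))
            chains.append(chain)
    return chains


def _hex_chains(spec: MosaicSpec) -> list[list[np.ndarray]]:
    """Flat-top hexagon tiling clipped to its bounding box."""
    s = spec.cell_size / np.sqrt(3.0)  # side length from across-flats size
    width = 1.5 * s
    height = np.sqrt(3.0) * s
    total_w = spec.n_cols * width + s / 2.0
    total_h = (spec.n_rows + 0.5) * height
    clip = box(0, 0, total_w, total_h)
    chains = []
    for q in range(-1, spec.n_cols + 1):
        for r in range(-1, spec.n_rows + 1):
            cx = s + q * width
            cy = height / 2.0 + r * height + (height / 2.0 if q % 2 else 0.0)
            ang = np.radians(np.arange(0, 360, 60))
            verts = np.column_stack([cx + s * np.cos(ang), cy + s * np.sin(ang)])
            poly = Polygon(verts).intersection(clip)
            if poly.is_empty or poly.area < 1e-6:
                continue
            xy = np.asarray(poly.exterior.coords)[:-1]
            chains.append([v for v in xy])
    return chains


def _voronoi_chains(spec: MosaicSpec, rng: np.random.Generator) -> list[list[np.ndarray]]:
    """Lloyd-relaxed Voronoi tessellation of a jittered lattice."""
    W = spec.n_cols * spec.cell_size
    H = spec.n_rows * spec.cell_size
    gx, gy = np.meshgrid(
        (np.arange(spec.n_cols) + 0.5) * spec.cell_size,
        (np.arange(spec.n_rows) + 0.5) * spec.cell_size,
    )
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts + rng.uniform(-0.3, 0.3, pts.shape) * spec.cell_size
    clip = box(0, 0, W, H)
    for _ in range(2):  # Lloyd relaxation: kills most sliver edges
        polys = _bounded_voronoi(pts, clip)
        pts = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    polys = _bounded_voronoi(pts, clip)
    chains = [[v for v in np.asarray(p.exterior.coords)[:-1]] for p in polys]
    return _collapse_short_edges(chains, min_edge=0.25 * spec.cell_size)


def _collapse_short_edges(
    chains: list[list[np.ndarray]], min_edge: float
) -> list[list[np.ndarray]]:
    """Merge tessellation edges shorter than ``min_edge`` to a point.

    Sub-resolution edges cannot be recovered from a raster, so the
    ground truth itself must not contain them.  Endpoints of every
    short edge are union-found together and each group is replaced by
    its centroid, consistently across all cells.
    """
    parent: dict[tuple, tuple] = {}

    def find(v):
        while parent.get(v, v) != v:
            parent[v] = parent.get(parent[v], parent[v])
            v = parent[v]
        return v

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    keys = [[_round_pt(v) for v in chain] for chain in chains]
    for chain in keys:
        for i in range(len(chain)):
            a, b = chain[i], chain[(i + 1) % len(chain)]
            if np.hypot(b[0] - a[0], b[1] - a[1]) < min_edge:
                union(a, b)
    groups: dict[tuple, list[tuple]] = {}
    for chain in keys:
        for v in chain:
            groups.setdefault(find(v), []).append(v)
    rep = {
        root: np.array(members).mean(axis=0)
        for root, members in groups.items()
    }
    out = []
    for chain in keys:
        newc: list[np.ndarray] = []
        for v in chain:
            p = rep[find(v)]
            if newc and np.allclose(p, newc[-1]):
                continue
            newc.append(p)
        if len(newc) > 1 and np.allclose(newc[0], newc[-1]):
            newc.pop()
        out.append(newc)
    return out


def _bounded_voronoi(pts: np.ndarray, clip: Polygon) -> list[Polygon]:
    # mirror points across the four box edges so every interior region is finite
    minx, miny, maxx, maxy = clip.bounds
    mirrored = [pts]
    for ref in (
        np.column_stack([2 * minx - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * maxx - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * miny - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * maxy - pts[:, 1]]),
    ):
        mirrored.append(ref)
    vor = Voronoi(np.vstack(mirrored))
    out = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(clip)
        out.append(poly)
    return out


def _round_pt(p, nd=6):
    return (round(float(p[0]), nd), round(float(p[1]), nd))


def _undulate_chains(
    chains: list[list[np.ndarray]],
    spec: MosaicSpec,
    extent: tuple[float, float],
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Replace straight shared walls by sine polylines (shared exactly).

    Walls on the bounding box stay straight; walls too short for the
    requested amplitude stay straight too.  Both cells sharing a wall
    traverse the same polyline (one reversed), so the tessellation
    remains gap- and overlap-free.
    """
    amp = spec.undulation_amplitude
    periods = spec.undulation_periods
    W, H = extent
    wall_cache: dict[tuple, np.ndarray] = {}

    def on_border(a, b):
        for coord, lim in ((0, 0.0), (0, W)):
            if abs(a[0] - lim) < 1e-6 and abs(b[0] - lim) < 1e-6:
                return True
        for lim in (0.0, H):
            if abs(a[1] - lim) < 1e-6 and abs(b[1] - lim) < 1e-6:
                return True
        return False

    def wall(a, b) -> np.ndarray:
        ka, kb = _round_pt(a), _round_pt(b)
        key = (min(ka, kb), max(ka, kb))
        if key not in wall_cache:
            pa = np.array(key[0])
            pb = np.array(key[1])
            length = float(np.hypot(*(pb - pa)))
            n_pts = max(24, 12 * max(periods, 1))
            if (
                amp <= 0
                or periods < 1
                or on_border(pa, pb)
                or amp > 0.3 * length
            ):
                poly = _wall_polyline(pa, pb, 0.0, 0, 1.0, n_pts)
            else:
                sign = float(rng.choice([-1.0, 1.0]))
                poly = _wall_polyline(pa, pb, amp, periods, sign, n_pts)
            wall_cache[key] = poly
        poly = wall_cache[key]
        if _round_pt(a) == key[0]:
            return poly
        # reversed traversal: same polyline backwards, endpoint shifted
        rev = np.vstack([poly[1:][::-1], poly[:1]])
        return np.vstack([np.array(key[1])[None, :], rev[:-1]])

    outlines = []
    for chain in chains:
        parts = []
        n = len(chain)
        for i in range(n):
            parts.append(wall(chain[i], chain[(i + 1) % n]))
        outlines.append(np.vstack(parts))
    return outlines


def _carve_stoma(
    host: Polygon,
    center: np.ndarray,
    length: float,
    width: float,
    with_subs: bool,
) -> tuple[Polygon, list[Polygon]]:
    """Inscribe an elliptical guard polygon; split the rest laterally."""
    t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    ell = Polygon(
        np.column_stack(
            [center[0] + length / 2 * np.cos(t), center[1] + width / 2 * np.sin(t)]
        )
    )
    if not host.contains(ell):
        raise ValueError("stoma does not fit inside its host cell")
    rest = host.difference(ell)
    if not with_subs:
        return ell, [rest]
    minx, miny, maxx, maxy = host.bounds
    left = rest.intersection(box(minx - 1, miny - 1, center[0], maxy + 1))
    right = rest.intersection(box(center[0], miny - 1, maxx + 1, maxy + 1))
    subs = []
    for part in (left, right):
        if part.geom_type == "MultiPolygon":
            part = max(part.geoms, key=lambda g: g.area)
        # a 1-px erosion must leave one solid core, else the flanking
        # cell is too thin to survive rasterization
        core = part.buffer(-1.0)
        if core.is_empty or core.geom_type != "Polygon":
            raise ValueError("flanking subsidiary cell too thin for this host")
        subs.append(part)
    return ell, subs


def simulate_mosaic(spec: MosaicSpec) -> SyntheticMosaic:
    """Build a ground-truth polygon mosaic from a :class:`MosaicSpec`."""
    rng = np.random.default_rng(spec.rng_seed)
    if spec.grid == "brick":
        chains = _brick_chains(spec)
        extent = (
            spec.n_cols * spec.cell_size * spec.cell_aspect,
            spec.n_rows * spec.cell_size,
        )
    elif spec.grid == "hex":
        chains = _hex_chains(spec)
        s = spec.cell_size / np.sqrt(3.0)
        extent = (spec.n_cols * 1.5 * s + s / 2.0, (spec.n_rows + 0.5) * np.sqrt(3.0) * s)
    else:
        chains = _voronoi_chains(spec, rng)
        extent = (spec.n_cols * spec.cell_size, spec.n_rows * spec.cell_size)

    # junction ground truth from shared chain vertices
    vertex_cells: dict[tuple, set[int]] = {}
    for idx, chain in enumerate(chains):
        for v in chain:
            vertex_cells.setdefault(_round_pt(v), set()).add(idx)
    W, H = extent

    def is_border_pt(p):
        return (
            abs(p[0]) < 1e-6 or abs(p[0] - W) < 1e-6
            or abs(p[1]) < 1e-6 or abs(p[1] - H) < 1e-6
        )

    junction_count = []
    for idx, chain in enumerate(chains):
        n = 0
        for v in chain:
            owners = vertex_cells[_round_pt(v)]
            if len(owners) >= 3 or (len(owners) >= 2 and is_border_pt(v)):
                n += 1
        junction_count.append(n)

    outlines = _undulate_chains(chains, spec, extent, rng)
    for i, o in enumerate(outlines):
        if not Polygon(o).is_valid:
            raise ValueError(
                f"undulated cell {i} self-intersects; reduce the undulation "
                "amplitude or period count for this cell size"
            )

    # stomatal placement on designated tessellation rows (brick/hex grids)
    cells: list[tuple[str, Polygon]] = [("pavement", Polygon(o)) for o in outlines]
    chain_arr = [np.array([_round_pt(v) for v in c]) for c in chains]
    centroids = np.array([c.centroid.coords[0] for _, c in cells])
    sto_rows = []
    host_undulation_excluded: set[int] = set()
    n_base = len(cells)
    if spec.stomatal_row_indices:
        row_height = H / spec.n_rows
        for row_k, row_idx in enumerate(sorted(spec.stomatal_row_indices)):
            yc = (row_idx + 0.5) * row_height
            in_row = [
                i for i in range(n_base)
                if abs(centroids[i][1] - yc) < 0.45 * row_height
                and cells[i][0] == "pavement"
            ]
            in_row.sort(key=lambda i: centroids[i][0])
            for j, i in enumerate(in_row):
                if j % spec.stoma_every != spec.stoma_every // 2:
                    continue
                host = cells[i][1]
                minx, miny, maxx, maxy = host.bounds
                length = spec.stoma_length_frac * (maxx - minx)
                width = spec.stoma_width_frac * (maxy - miny)
                jit = float(rng.normal(0.0, spec.row_jitter)) if spec.row_jitter else 0.0
                max_jit = 0.5 * ((maxy - miny) - width) - 2.0
                jit = float(np.clip(jit, -max_jit, max_jit))
                center = np.array([(minx + maxx) / 2.0, (miny + maxy) / 2.0 + jit])
                try:
                    guard, subs = _carve_stoma(
                        host, center, length, width, spec.with_subsidiaries
                    )
                except ValueError:
                    logger.warning("stoma skipped: does not fit in host cell %d", i)
                    continue
                cells[i] = ("stomate", guard)
                host_undulation_excluded.add(i)
                sub_idx = []
                for sp in subs:
                    cells.append(("subsidiary", sp))
                    sub_idx.append(len(cells) - 1)
                sto_rows.append(
                    {
                        "guard_index": i,
                        "row": row_k,
                        "cx": center[0],
                        "cy": center[1],
                        "length": length,
                        "width": width,
                        "subsidiaries": tuple(sub_idx),
                    }
                )

    # ground-truth adjacency: shared boundary of >= 3 px
    tree = shapely.STRtree([c for _, c in cells])
    pairs = set()
    geoms = [c for _, c in cells]
    a_idx, b_idx = tree.query(geoms, predicate="intersects")
    for i, j in zip(a_idx, b_idx):
        if i >= j:
            continue
        inter = geoms[int(i)].intersection(geoms[int(j)])
        if inter.length >= 3.0:
            pairs.add((int(i), int(j)))

    truth_rows = []
    guard_hosts = {d["guard_index"] for d in sto_rows}
    for idx, (cls, poly) in enumerate(cells):
        row = {
            "cell_index": idx,
            "cell_class": cls,
            "area": poly.area,
            "centroid_x": poly.centroid.x,
            "centroid_y": poly.centroid.y,
            "is_edge": poly.exterior.distance(box(0, 0, W, H).exterior) < 1e-6
            or not box(0, 0, W, H).buffer(1e-6).contains(poly),
            "n_junctions": (
                junction_count[idx]
                if idx < len(chains) and idx not in guard_hosts
                else np.nan
            ),
            "true_complexity": np.nan,
            "true_undulation_amp": np.nan,
            "true_undulation_freq": np.nan,
        }
        if idx < len(chains) and idx not in guard_hosts and not row["is_edge"]:
            met = _vector_undulation(outlines[idx], chain_arr[idx])
            row.update(
                true_complexity=met["complexity"],
                true_undulation_amp=met["undulation_amp"],
                true_undulation_freq=met["undulation_freq"],
            )
        truth_rows.append(row)

    return SyntheticMosaic(
        spec=spec,
        cells=cells,
        truth=pd.DataFrame(truth_rows),
        adjacency=pairs,
        stomata=pd.DataFrame(sto_rows),
        north_deg=0.0,
        extent=extent,
    )


def _vector_undulation(outline: np.ndarray, junctions: np.ndarray) -> dict[str, float]:
    """Polygon-level undulation metrics of a constructed cell."""
    d2 = ((outline[None, :, :] - junctions[:, None, :]) ** 2).sum(axis=2)
    idx = np.sort(np.unique(d2.argmin(axis=1)))
    perim = float(
        np.hypot(*np.diff(np.vstack([outline, outline[:1]]), axis=0).T).sum()
    )
    simp = outline[idx]
    simp_perim = float(np.hypot(*np.diff(np.vstack([simp, simp[:1]]), axis=0).T).sum())
    amp = 0.0
    crossings = 0
    n = len(outline)
    for a, b in zip(idx, np.roll(idx, -1)):
        arc = outline[a : b + 1] if b > a else np.vstack([outline[a:], outline[: b + 1]])
        baseline = (outline[a], outline[b % n])
        if np.hypot(*(baseline[1] - baseline[0])) < 1e-9:
            continue
        amp = max(amp, max_normal_offset(arc, baseline))
        crossings += crossings_count(arc, baseline)
    return {
        "complexity": perim / simp_perim,
        "undulation_amp": amp,
        "undulation_freq": crossings / simp_perim,
    }


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize_mosaic(
    mosaic: SyntheticMosaic,
    wall_width_px: int = 1,
    scale: float | None = None,
    scale_units: str = "um",
    min_region_px: int = 4,
) -> LabelMap:
    """Burn the polygon mosaic to a label raster.

    Each pixel centre is assigned to the cell containing it; walls of
    the requested width are then drawn along every label boundary.  The
    output loads through the normal pipeline unchanged.  Raises when
    the resolution is too low for every cell to survive as a region of
    at least ``min_region_px`` pixels.
    """
    if wall_width_px < 1:
        raise ValueError("wall width must be >= 1 px")
    W, H = mosaic.extent
    w_px, h_px = int(round(W)), int(round(H))
    xs = (np.arange(w_px) + 0.5)[None, :].repeat(h_px, axis=0)
    ys = (np.arange(h_px) + 0.5)[:, None].repeat(w_px, axis=1)
    points = shapely.points(np.column_stack([xs.ravel(), ys.ravel()]))
    geoms = [g for _, g in mosaic.cells]
    tree = shapely.STRtree(geoms)
    pt_idx, cell_idx = tree.query(points, predicate="intersects")
    label = np.zeros(h_px * w_px, dtype=np.int32)
    # smallest cell index wins on shared boundaries (deterministic)
    order = np.argsort(cell_idx, kind="stable")[::-1]
    label[pt_idx[order]] = cell_idx[order] + 1
    label = label.reshape(h_px, w_px)

    wall = np.zeros_like(label, dtype=bool)
    wall[:, :-1] |= label[:, :-1] != label[:, 1:]
    wall[:-1, :] |= label[:-1, :] != label[1:, :]
    wall |= label == 0
    if wall_width_px > 1:
        from scipy.ndimage import binary_dilation

        wall = binary_dilation(
            wall, structure=np.ones((3, 3), bool), iterations=(wall_width_px - 1) // 2
        )

    codes = dict(DEFAULT_CODES)
    grid = np.zeros((h_px, w_px), dtype=np.uint8)
    class_of = np.array([codes[cls] for cls, _ in mosaic.cells], dtype=np.uint8)
    interior = ~wall & (label > 0)
    grid[interior] = class_of[label[interior] - 1]
    grid[wall] = codes["wall"]

    # sanity: every cell must survive rasterization as one region;
    # pixels pinched off at junction wedges (tiny fragments) become wall
    from skimage.measure import label as sk_label

    for idx in range(len(mosaic.cells)):
        mask = interior & (label == idx + 1)
        n_px = int(mask.sum())
        if n_px < min_region_px:
            raise ValueError(
                f"resolution too low: cell {idx} rasterized to {n_px} px"
            )
        comp, n_comp = sk_label(mask, connectivity=1, return_num=True)
        if n_comp > 1:
            sizes = np.bincount(comp.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1
            frag = mask & (comp != keep)
            if int(frag.sum()) > 4 or sizes.max() < min_region_px:
                raise ValueError(f"cell {idx} fragmented at this resolution")
            grid[frag] = codes["wall"]
            interior[frag] = False

    config = ValueConfig(
        wall_value=codes["wall"],
        class_values={k: v for k, v in codes.items() if k != "wall"},
        scale=scale,
        scale_units=scale_units,
    )
    return LabelMap(grid=grid, config=config)
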