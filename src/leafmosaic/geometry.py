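"""Reusable geometric primitives.

Three small families of operations used throughout the package:

* direct least-squares ellipse fitting with the ellipse-specific conic
  constraint (Fitzgibbon-Pilu-Fisher, in the numerically stable
  Halir-Flusser formulation);
* axial (orientation, 0-180 degree) circular statistics via the angle
  doubling method;
* signed-offset analysis of an undulating wall arc against its straight
  baseline segment: crossing counts and maximal normal offsets.

All angles are *axial*: theta and theta + 180 describe the same
orientation, because cells and stomata are unoriented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EllipseFit",
    "DegenerateFitError",
    "fit_ellipse_direct",
    "axial_mean_angle",
    "sample_arc_offsets",
    "crossings_count",
    "max_normal_offset",
]


class DegenerateFitError(ValueError):
    """Raised when a conic fit does not yield a proper ellipse."""


@dataclass(frozen=True)
class EllipseFit:
    """Geometric parameters of a fitted ellipse.

    Attributes
    ----------
    center : tuple of float
        (x, y) center.
    semi_major, semi_minor : float
        Semi-axis lengths, ``semi_major >= semi_minor > 0``.
    angle_deg : float
        Orientation of the major axis in [0, 180), measured from +x
        toward +y.
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle_deg: float

    @property
    def aspect_ratio(self) -> float:
        return self.semi_major / self.semi_minor


def fit_ellipse_direct(points: np.ndarray) -> EllipseFit:
    """Fit an ellipse to planar points by direct least squares.

    Solves the constrained conic fit ``min ||D a||`` subject to
    ``4AC - B^2 = 1``, which guarantees an elliptical solution.  Uses
    the block-decomposed generalized-eigenvalue formulation of Halir &
    Flusser, which is numerically stable for noiseless data.

    Parameters
    ----------
    points : (n, 2) array
        At least 6 non-collinear points.

    Raises
    ------
    DegenerateFitError
        If the points are (near-)collinear or the solution is not an
        ellipse.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise ValueError("need an (n, 2) array with n >= 6")
    # center and scale for conditioning; undone on the conic below
    mean = pts.mean(axis=0)
    x = pts[:, 0] - mean[0]
    y = pts[:, 1] - mean[1]
    scale = np.sqrt(np.mean(x * x + y * y))
    if scale < 1e-12:
        raise DegenerateFitError("degenerate point scatter (all points coincident)")
    x = x / scale
    y = y / scale

    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError("degenerate design matrix (collinear points?)") from exc
    M = S1 + S2 @ T
    # constraint matrix inverse applied analytically: C^-1 M
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    # the ellipse solution is the eigenvector with 4ac - b^2 > 0
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.where(np.isreal(eigval) & (cond > 0))[0]
    if ok.size == 0:
        raise DegenerateFitError("no elliptical solution (degenerate or hyperbolic fit)")
    a1 = np.real(eigvec[:, ok[0]])
    coeffs = np.concatenate([a1, T @ a1])  # A, B, C, D, E, F in scaled frame

    A, B, C, D, E, F = coeffs
    # undo the conditioning transform x_s = (x - mx)/s
    s = scale
    mx, my = mean
    A2 = A / s**2
    B2 = B / s**2
    C2 = C / s**2
    D2_ = D / s - 2 * A * mx / s**2 - B * my / s**2
    E2 = E / s - 2 * C * my / s**2 - B * mx / s**2
    F2 = (
        F
        + A * mx**2 / s**2
        + B * mx * my / s**2
        + C * my**2 / s**2
        - D * mx / s
        - E * my / s
    )
    return _conic_to_ellipse(A2, B2, C2, D2_, E2, F2)


def _conic_to_ellipse(A: float, B: float, C: float, D: float, E: float, F: float) -> EllipseFit:
    """Convert conic coefficients Ax^2+Bxy+Cy^2+Dx+Ey+F=0 to geometry."""
    den = 4 * A * C - B * B
    if den <= 0:
        raise DegenerateFitError("conic is not an ellipse")
    cx = (B * E - 2 * C * D) / den
    cy = (B * D - 2 * A * E) / den
    # value of the quadratic form at the center
    Fc = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    # eigenvalues of [[A, B/2], [B/2, C]]
    tr = A + C
    det = A * C - B * B / 4.0
    disc = np.sqrt(max(tr * tr / 4.0 - det, 0.0))
    lam1 = tr / 2.0 - disc  # smaller eigenvalue -> major axis
    lam2 = tr / 2.0 + disc
    if lam1 == 0 or lam2 == 0:
        raise DegenerateFitError("conic is degenerate (zero eigenvalue)")
    a2 = -Fc / lam1
    b2 = -Fc / lam2
    if a2 <= 0 or b2 <= 0:
        raise DegenerateFitError("conic has no real elliptical locus")
    if abs(B) < 1e-12 * (abs(A) + abs(C)):
        angle = 0.0 if A <= C else 90.0
    else:
        # axis of the eigenvector belonging to the smaller eigenvalue lam1
        angle = float(np.degrees(np.arctan2(lam1 - A, B / 2.0)))
    if a2 >= b2:
        semi_major, semi_minor = float(np.sqrt(a2)), float(np.sqrt(b2))
    else:
        # overall conic sign flipped the eigenvalue/axis pairing
        semi_major, semi_minor = float(np.sqrt(b2)), float(np.sqrt(a2))
        angle += 90.0
    angle = angle % 180.0
    return EllipseFit(
        center=(float(cx), float(cy)),
        semi_major=semi_major,
        semi_minor=semi_minor,
        angle_deg=angle,
    )


def axial_mean_angle(angles_deg, eps: float = 1e-9) -> tuple[float | None, float]:
    """Mean of axial angles (mod 180) by the doubling method.

    Unit vectors at ``2 * theta`` are averaged; the resultant angle is
    halved.  Returns ``(mean_deg, resultant_length)`` with the mean in
    [0, 180).  When the resultant length is below ``eps`` the
    orientation distribution is isotropic and the mean is ``None``.
    """
    a = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    rad2 = np.radians(2.0 * a)
    c = np.cos(rad2).mean()
    s = np.sin(rad2).mean()
    r = float(np.hypot(c, s))
    if r < eps:
        return None, r
    mean = float(np.degrees(0.5 * np.arctan2(s, c))) % 180.0
    return mean, r


def _offsets_along_baseline(arc: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Signed perpendicular offsets of arc vertices from segment p0->p1."""
    d = p1 - p0
    length = np.hypot(*d)
    if length < 1e-12:
        raise ValueError("zero-length baseline segment")
    n = np.array([-d[1], d[0]]) / length
    return (arc - p0) @ n


def sample_arc_offsets(
    wall_arc: np.ndarray,
    baseline: tuple[np.ndarray, np.ndarray],
    min_samples: int = 64,
) -> np.ndarray:
    """Signed offsets of a wall arc from its baseline, densely sampled.

    Samples at every arc vertex plus edge midpoints, subdividing until
    at least ``min_samples`` samples cover the arc, so that sign changes
    of the offset are not missed between sparse vertices.
    """
    arc = np.asarray(wall_arc, dtype=float)
    if arc.ndim != 2 or arc.shape[0] < 2:
        raise ValueError("wall arc needs at least 2 vertices")
    # subdivide edges until the sample count is met
    pts = arc
    while pts.shape[0] < min_samples:
        mids = 0.5 * (pts[:-1] + pts[1:])
        out = np.empty((pts.shape[0] + mids.shape[0], 2))
        out[0::2] = pts
        out[1::2] = mids
        pts = out
    p0 = np.asarray(baseline[0], dtype=float)
    p1 = np.asarray(baseline[1], dtype=float)
    return _offsets_along_baseline(pts, p0, p1)


def crossings_count(
    wall_arc: np.ndarray,
    baseline: tuple[np.ndarray, np.ndarray],
    min_samples: int = 64,
    tol_frac: float = 1e-9,
    tol_abs: float = 0.0,
) -> int:
    """Number of times a wall arc crosses its baseline segment.

    Counts sign changes of the signed perpendicular offset along the
    arc, endpoints excluded.  Tangency (touching the baseline without a
    sign change) is not counted.  ``tol_abs`` widens the dead band
    around zero; excursions smaller than it are ignored (used to reject
    residual rasterization noise, typically half a pixel).
    """
    off = sample_arc_offsets(wall_arc, baseline, min_samples=min_samples)
    scale = float(np.max(np.abs(off))) if off.size else 0.0
    tol = max(max(scale, 1.0) * tol_frac, tol_abs)
    signs = np.where(off > tol, 1, np.where(off < -tol, -1, 0))
    # drop zeros (on-baseline samples, incl. the anchored endpoints)
    nz = signs[signs != 0]
    if nz.size < 2:
        return 0
    return int(np.count_nonzero(nz[1:] != nz[:-1]))


def max_normal_offset(
    wall_arc: np.ndarray,
    baseline: tuple[np.ndarray, np.ndarray],
) -> float:
    """Maximum distance from wall-arc vertices to the baseline *segment*.

    Distance is to the segment (not the infinite line), so lobes beyond
    the segment ends are measured to the nearest endpoint.
    """
    arc = np.asarray(wall_arc, dtype=float)
    p0 = np.asarray(baseline[0], dtype=float)
    p1 = np.asarray(baseline[1], dtype=float)
    d = p1 - p0
    length2 = float(d @ d)
    if length2 < 1e-24:
        raise ValueError("zero-length baseline segment")
    t = np.clip((arc - p0) @ d / length2, 0.0, 1.0)
    foot = p0 + t[:, None] * d
    return float(np.max(np.hypot(*(arc - foot).T)))
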