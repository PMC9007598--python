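"""Polyline and polygon primitives shared by the isobole algorithms.

All geometric predicates operate in *normalized dose space*: each dose axis
is rescaled to [0, 1] by its maximum dose, so that curve-to-curve distances
(discrete Fréchet) and point-to-curve distances are scale-free even when the
two drugs have very different dose ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage import measure

__all__ = [
    "Polyline",
    "Polygon",
    "extract_contour",
    "discrete_frechet",
    "point_in_polygon",
    "distance_to_polyline",
]

_COORD_TOL = 1e-9


@dataclass(frozen=True)
class Polyline:
    """Ordered open polyline of (x, y) dose pairs.

    Consecutive duplicate vertices are dropped on construction; a non-empty
    polyline has at least two vertices.
    """

    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("polyline points must be an (n, 2) array")
        if len(pts) > 0:
            keep = np.ones(len(pts), dtype=bool)
            keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > _COORD_TOL, axis=1)
            pts = pts[keep]
            if len(pts) < 2:
                raise ValueError("non-empty polyline needs >= 2 distinct vertices")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def is_empty(self) -> bool:
        return len(self.points) == 0

    def length(self) -> float:
        """Total arc length."""
        if self.is_empty:
            return 0.0
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    def scaled(self, sx: float, sy: float) -> "Polyline":
        """Rescale coordinates axis-wise (e.g. normalized <-> dose units)."""
        return Polyline(self.points * np.array([sx, sy]))


@dataclass(frozen=True)
class Polygon:
    """Simple polygon given by its ordered vertices (implicitly closed)."""

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        object.__setattr__(self, "vertices", v)

    def area(self) -> float:
        """Unsigned area by the shoelace formula."""
        x, y = self.vertices.T
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


def extract_contour(grid_values, grid_axes, level: float) -> list[Polyline]:
    """Extract level-set polylines from a gridded surface.

    Marching squares with linear interpolation along cell edges (no
    smoothing): each returned vertex lies on a lattice edge where the two
    adjacent node values bracket ``level``.

    Parameters
    ----------
    grid_values : (n0, n1) array
        Surface values; axis 0 corresponds to ``grid_axes[0]`` (x), axis 1 to
        ``grid_axes[1]`` (y).
    grid_axes : pair of 1D arrays
        Strictly increasing coordinates for each lattice axis.
    level : float
        The threshold whose level set is traced.

    Returns
    -------
    list of Polyline, sorted by decreasing arc length (empty when all values
    lie strictly on one side of ``level``).
    """
    values = np.asarray(grid_values, dtype=float)
    if values.ndim != 2:
        raise ValueError("grid_values must be a 2D matrix")
    ax0 = np.asarray(grid_axes[0], dtype=float)
    ax1 = np.asarray(grid_axes[1], dtype=float)
    if values.shape != (len(ax0), len(ax1)):
        raise ValueError(
            f"grid shape {values.shape} inconsistent with axes "
            f"({len(ax0)}, {len(ax1)})"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("grid contains non-finite values; pass a fully evaluated lattice")
    for ax in (ax0, ax1):
        if len(ax) < 2 or np.any(np.diff(ax) <= 0):
            raise ValueError("lattice axes must be strictly increasing with >= 2 nodes")

    vmin, vmax = values.min(), values.max()
    if level < vmin or level > vmax:
        return []

    raw = measure.find_contours(values, level)
    polylines = []
    for comp in raw:
        # find_contours returns fractional (row, col) indices; map through axes
        x = np.interp(comp[:, 0], np.arange(len(ax0)), ax0)
        y = np.interp(comp[:, 1], np.arange(len(ax1)), ax1)
        pts = np.column_stack([x, y])
        # canonical orientation: first vertex lexicographically before the
        # last, so contours of the same curve are comparable by the
        # (orientation-sensitive) Fréchet distance
        if tuple(pts[-1]) < tuple(pts[0]):
            pts = pts[::-1]
        try:
            polylines.append(Polyline(pts))
        except ValueError:
            continue  # degenerate single-point component
    polylines.sort(key=lambda p: p.length(), reverse=True)
    return polylines


def discrete_frechet(a: Polyline, b: Polyline) -> float:
    """Discrete Fréchet distance between two polylines.

    The classic dynamic program over vertex pairs: the minimum over all
    order-preserving couplings of the maximum pointwise distance. Used as the
    convergence metric between successive isobole estimates.
    """
    if a.is_empty or b.is_empty:
        raise ValueError("discrete Fréchet distance undefined for empty polylines")
    pa, pb = a.points, b.points
    d = np.hypot(pa[:, None, 0] - pb[None, :, 0], pa[:, None, 1] - pb[None, :, 1])
    n, m = d.shape
    dp = np.empty_like(d)
    dp[0, 0] = d[0, 0]
    for j in range(1, m):
        dp[0, j] = max(dp[0, j - 1], d[0, j])
    for i in range(1, n):
        dp[i, 0] = max(dp[i - 1, 0], d[i, 0])
        row_prev = dp[i - 1]
        row = dp[i]
        for j in range(1, m):
            row[j] = max(d[i, j], min(row_prev[j], row_prev[j - 1], row[j - 1]))
    return float(dp[-1, -1])


def point_in_polygon(p, poly: Polygon) -> bool:
    """Even-odd containment test; points on the boundary count as inside."""
    sp = poly.to_shapely()
    return bool(sp.covers(_ShapelyPoint(p[0], p[1])))


def distance_to_polyline(p, a: Polyline) -> float:
    """Minimum Euclidean distance from a point to any segment of a polyline."""
    if a.is_empty:
        raise ValueError("distance to an empty polyline is undefined")
    return float(_segment_distances(np.asarray(p, float).reshape(1, 2), a.points)[0])


def distances_to_polyline(points, a: Polyline) -> np.ndarray:
    """Vectorized :func:`distance_to_polyline` for an (n, 2) point array."""
    if a.is_empty:
        raise ValueError("distance to an empty polyline is undefined")
    return _segment_distances(np.asarray(points, float), a.points)


def _segment_distances(points: np.ndarray, verts: np.ndarray) -> np.ndarray:
    if len(verts) == 1:
        return np.hypot(points[:, 0] - verts[0, 0], points[:, 1] - verts[0, 1])
    starts = verts[:-1]
    deltas = verts[1:] - starts  # (m, 2)
    seg_len2 = np.maximum(np.einsum("ij,ij->i", deltas, deltas), 1e-300)
    # projection parameter of each point onto each segment, clipped to [0, 1]
    w = points[:, None, :] - starts[None, :, :]  # (n, m, 2)
    t = np.clip(np.einsum("nmj,mj->nm", w, deltas) / seg_len2, 0.0, 1.0)
    closest = starts[None, :, :] + t[:, :, None] * deltas[None, :, :]
    diff = points[:, None, :] - closest
    return np.sqrt(np.einsum("nmj,nmj->nm", diff, diff).min(axis=1))
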