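"""Aggregate an ensemble of effective isoboles into a confidence surface.

Each population's effective isobole, closed through the origin of the
dosing space, bounds the polygon of dose combinations at which that
population misses the efficacy target. Classifying a fine reference grid
against each polygon gives one binary success field per population
(failure = 0, target achieved or exceeded = 1); averaging the fields over
populations yields the confidence-level response surface — the fraction of
parameter-uncertainty realizations reaching the target at each dose
combination. Contours of that surface at chosen probabilities are the
confidence-level isoboles (e.g. the doses with a 95% chance of reaching a
95% success rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .fastisoboles import EffectiveIsobole
from .geometry import (Polygon, Polyline, distances_to_polyline,
                       extract_contour)

__all__ = [
    "ConfidenceSurface",
    "isobole_to_polygon",
    "classify_binary",
    "aggregate_isoboles",
    "confidence_isobole",
]

_EDGE_TOL = 1e-9


@dataclass
class ConfidenceSurface:
    """Gridded confidence levels: fraction of populations meeting the target."""

    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray  # shape (len(axis1), len(axis2)), multiples of 1/n_pop
    target_rate: float
    n_pop: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.axis1), len(self.axis2)):
            raise ValueError("surface shape inconsistent with axes")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("confidence levels must lie in [0, 1]")
        self.values = v


def _edge_of(pt, bounds) -> str | None:
    """Which boundary edge a point lies on (None if strictly interior)."""
    x, y = pt
    tx = _EDGE_TOL * max(bounds)
    if abs(x) <= tx:
        return "left"
    if abs(y) <= tx:
        return "bottom"
    if abs(x - bounds[0]) <= tx:
        return "right"
    if abs(y - bounds[1]) <= tx:
        return "top"
    return None


def isobole_to_polygon(iso: EffectiveIsobole | Polyline, bounds=None) -> Polygon:
    """Close an effective isobole into the failure-region polygon.

    The isobole's vertex list is augmented with the origin (and, where an
    endpoint terminates on the far edge of the dosing space, the adjacent
    corner) so that the resulting polygon encloses exactly the region in
    which the efficacy target is not reached. Both isobole endpoints must
    lie on the dosing-space boundary; a strictly interior endpoint breaks
    the separation assumption and raises.
    """
    if isinstance(iso, EffectiveIsobole):
        polyline, bounds = iso.polyline, iso.bounds
    else:
        polyline = iso
        if bounds is None:
            raise ValueError("bounds required when passing a bare polyline")
    if polyline.is_empty:
        raise ValueError("cannot build a failure polygon from an empty isobole")
    pts = polyline.points
    e_start = _edge_of(pts[0], bounds)
    e_end = _edge_of(pts[-1], bounds)
    if e_start is None or e_end is None:
        raise ValueError(
            "isobole endpoints must terminate on the dosing-space boundary; "
            f"got {tuple(pts[0])} ({e_start}) and {tuple(pts[-1])} ({e_end})")
    # orient the curve from the drug-2 side (left/top) to the drug-1 side
    # (bottom/right) so the boundary closure below is uniform
    if (e_start in ("bottom", "right")) and (e_end in ("left", "top")):
        pts = pts[::-1]
        e_start, e_end = e_end, e_start
    closure = []
    if e_end == "right":
        closure.append((bounds[0], 0.0))
    closure.append((0.0, 0.0))
    if e_start == "top":
        closure.append((0.0, bounds[1]))
    verts = np.vstack([pts, np.array(closure)])
    # drop consecutive duplicates (isobole endpoint may be a closure vertex)
    keep = np.ones(len(verts), dtype=bool)
    keep[1:] = np.any(np.abs(np.diff(verts, axis=0)) >
                      _EDGE_TOL * max(bounds), axis=1)
    if np.all(np.abs(verts[0] - verts[-1]) <= _EDGE_TOL * max(bounds)):
        keep[-1] = False
    return Polygon(verts[keep])


def classify_binary(poly: Polygon, axis1, axis2,
                    isobole: Polyline | None = None) -> np.ndarray:
    """Binary success field on a lattice: 1 where the target is achieved or
    exceeded, 0 where it is missed.

    A node fails when the failure polygon covers it — except nodes lying on
    the isobole itself, which achieve the target exactly and are coded 1.
    (The polygon's remaining boundary runs along the dose axes through the
    origin, squarely inside the failure region, so plain strict-interior
    classification would miscode it.)
    """
    ax1 = np.asarray(axis1, dtype=float)
    ax2 = np.asarray(axis2, dtype=float)
    xx, yy = np.meshgrid(ax1, ax2, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    geom = poly.to_shapely()
    shapely.prepare(geom)
    failed = shapely.intersects_xy(geom, pts[:, 0], pts[:, 1])
    if isobole is not None and not isobole.is_empty:
        scale = max(np.abs(poly.vertices).max(), 1.0)
        on_iso = distances_to_polyline(pts, isobole) <= 1e-9 * scale
        failed &= ~on_iso
    return (~failed).astype(float).reshape(len(ax1), len(ax2))


def aggregate_isoboles(isoboles: list[EffectiveIsobole], bounds=None,
                       resolution: int | None = None,
                       target_rate: float | None = None) -> ConfidenceSurface:
    """Average per-population binary success fields into confidence levels.

    ``resolution`` is the number of nodes per axis of the fresh uniform
    sampling lattice (default 129, i.e. twice a level-6 isobole-search
    resolution). Degenerate isoboles contribute a constant field: an
    "entire space efficacious" population counts as success everywhere,
    "entire space non-efficacious" as failure everywhere.
    """
    if not isoboles:
        raise ValueError("need at least one effective isobole")
    bset = {iso.bounds for iso in isoboles}
    if bounds is not None:
        bset.add((float(bounds[0]), float(bounds[1])))
    if len(bset) > 1:
        raise ValueError(f"mixed dosing-space bounds among isoboles: {bset}")
    bounds = next(iter(bset))
    rates = {iso.target_rate for iso in isoboles}
    if target_rate is None:
        if len(rates) > 1:
            raise ValueError(f"mixed target rates among isoboles: {rates}")
        target_rate = next(iter(rates))
    n = 129 if resolution is None else int(resolution)
    ax1 = np.linspace(0.0, bounds[0], n)
    ax2 = np.linspace(0.0, bounds[1], n)
    acc = np.zeros((n, n))
    for iso in isoboles:
        if iso.degenerate:
            if iso.classification == "entire space efficacious":
                acc += 1.0
            elif iso.classification == "entire space non-efficacious":
                pass
            else:
                raise ValueError(
                    f"degenerate isobole for population {iso.population_id} "
                    f"lacks a classification")
            continue
        acc += classify_binary(isobole_to_polygon(iso), ax1, ax2,
                               isobole=iso.polyline)
    return ConfidenceSurface(ax1, ax2, acc / len(isoboles),
                             target_rate=target_rate, n_pop=len(isoboles))


def confidence_isobole(surface: ConfidenceSurface, level: float) -> Polyline:
    """Extract the confidence-level isobole at ``level`` in (0, 1).

    Linear interpolation on the (stepwise) confidence surface; when the
    level lies outside the surface's range an empty polyline is returned.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie strictly in (0, 1)")
    comps = extract_contour(surface.values, (surface.axis1, surface.axis2),
                            level)
    return comps[0] if comps else Polyline()
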