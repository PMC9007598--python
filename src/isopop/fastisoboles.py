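"""Adaptive dyadic-grid search for the effective isobole.

The effective isobole — the curve of minimum dose combinations reaching a
prespecified success rate — separates the dosing space into an efficacious
and a non-efficacious region, provided the success-rate surface is monotone
(one contour per level). This module generalizes 1D bisection to that
curve: starting from a coarse 3x3 lattice, the grid resolution is doubled
each iteration, but the (expensive) objective is evaluated only at new
lattice nodes lying within one pre-refinement grid spacing of the current
isobole estimate. Far-from-curve nodes keep bilinearly interpolated
surrogate values, which are safely on the correct side of the threshold for
monotone surfaces. Iteration stops once the discrete Fréchet distance
between successive isobole estimates falls below a tolerance, or after a
maximum number of iterations.

After iteration j the lattice holds (2^j + 1) doses per drug; six or seven
iterations (65 or 129 doses per axis) are the practical range, and the
evaluation count stays a small fraction of the full lattice.

All internal geometry lives in normalized dose units (each axis divided by
its maximum dose); results are reported back in dose units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .geometry import (Polyline, discrete_frechet, distances_to_polyline,
                       extract_contour)

__all__ = [
    "DoseGrid",
    "IterationRecord",
    "FastIsobolesResult",
    "EffectiveIsobole",
    "init_grid",
    "refine",
    "run_fastisoboles",
    "brute_force_surface",
]


@dataclass
class DoseGrid:
    """Dyadically refinable lattice over the dosing space with a value cache.

    The lattice at refinement level j has (2^j + 1) nodes per axis at
    normalized coordinates i / 2^j (exact binary fractions, so cache keys
    are stable across levels). ``surface`` carries a full matrix at the
    current level in which un-evaluated nodes hold bilinear surrogates.
    """

    bounds: tuple[float, float]
    level: int = 1
    cache: dict[tuple[float, float], float] = field(default_factory=dict)
    first_iteration: dict[tuple[float, float], int] = field(default_factory=dict)
    surface: np.ndarray | None = None

    def __post_init__(self):
        if self.bounds[0] <= 0 or self.bounds[1] <= 0:
            raise ValueError("dose bounds must be positive")

    @property
    def resolution(self) -> int:
        return 2 ** self.level + 1

    def axis(self) -> np.ndarray:
        """Normalized lattice coordinates at the current level."""
        return np.arange(self.resolution) / 2 ** self.level

    def nodes_dose_units(self):
        """Cached nodes as (amt1, amt2, value, iteration) rows."""
        rows = []
        for (fx, fy), v in self.cache.items():
            rows.append((fx * self.bounds[0], fy * self.bounds[1], v,
                         self.first_iteration[(fx, fy)]))
        return rows


@dataclass
class IterationRecord:
    """Per-iteration bookkeeping of one refinement run."""

    iteration: int
    resolution: int
    isobole: Polyline            # normalized units; may be empty
    n_new_evaluations: int
    n_total_evaluations: int
    frechet_step: float          # distance to previous estimate (nan at first)


@dataclass
class FastIsobolesResult:
    """Outcome of an isobole search.

    ``isobole`` is the final estimate in dose units (empty when the target
    level is never bracketed, in which case ``classification`` says whether
    the whole space is efficacious or non-efficacious).
    """

    isobole: Polyline
    iterations: list[IterationRecord]
    n_evaluations: int
    converged: bool
    classification: str | None
    grid: DoseGrid
    target_rate: float

    @property
    def final_level(self) -> int:
        return self.grid.level


@dataclass(frozen=True)
class EffectiveIsobole:
    """An effective isobole for one population, in dose units."""

    polyline: Polyline
    target_rate: float
    bounds: tuple[float, float]
    population_id: int = -1
    classification: str | None = None  # set for degenerate (no-curve) cases

    @property
    def degenerate(self) -> bool:
        return self.polyline.is_empty


def init_grid(bounds) -> DoseGrid:
    """Level-1 grid: the nine regularly interspaced nodes {0, max/2, max}^2."""
    return DoseGrid(bounds=(float(bounds[0]), float(bounds[1])))


def _evaluate(grid: DoseGrid, objective, nodes, iteration: int) -> int:
    """Evaluate the objective at normalized nodes not yet cached."""
    n_new = 0
    for fx, fy in nodes:
        key = (fx, fy)
        if key in grid.cache:
            continue
        grid.cache[key] = float(objective(fx * grid.bounds[0],
                                          fy * grid.bounds[1]))
        grid.first_iteration[key] = iteration
        n_new += 1
    return n_new


def _upsample(surface: np.ndarray) -> np.ndarray:
    """Bilinear 2x upsampling of a full lattice matrix (level j -> j+1)."""
    n = surface.shape[0]
    out = np.empty((2 * n - 1, 2 * n - 1))
    out[::2, ::2] = surface
    out[1::2, ::2] = (surface[:-1, :] + surface[1:, :]) / 2.0
    out[::2, 1::2] = (out[::2, :-1:2] + out[::2, 2::2]) / 2.0
    out[1::2, 1::2] = (out[1::2, :-1:2] + out[1::2, 2::2]) / 2.0
    return out


def _write_cache_into_surface(grid: DoseGrid) -> None:
    ax = grid.axis()
    step = 1.0 / 2 ** grid.level
    for (fx, fy), v in grid.cache.items():
        i = round(fx / step)
        j = round(fy / step)
        if 0 <= i < len(ax) and 0 <= j < len(ax) and \
                abs(ax[i] - fx) < 1e-12 and abs(ax[j] - fy) < 1e-12:
            grid.surface[i, j] = v


def refine(grid: DoseGrid, current_isoboles: list[Polyline],
           objective=None) -> list[tuple[float, float]]:
    """Double the grid resolution and select the new nodes to evaluate.

    A new node is selected iff its normalized Euclidean distance to the
    current isobole estimate (any component, measured to segments) is
    strictly smaller than the pre-refinement grid spacing 2^-level. When no
    estimate exists (empty list), all new nodes are selected for one full-
    lattice iteration — the 2D analogue of bisection's bracket check.

    Returns the selected nodes (normalized coordinates); if ``objective``
    is given they are evaluated into the cache at iteration level+1.
    """
    spacing = 1.0 / 2 ** grid.level
    grid.level += 1
    new_ax = grid.axis()
    ii, jj = np.meshgrid(np.arange(len(new_ax)), np.arange(len(new_ax)),
                         indexing="ij")
    fresh = (ii % 2 == 1) | (jj % 2 == 1)  # nodes absent from the old lattice
    pts = np.column_stack([new_ax[ii[fresh]], new_ax[jj[fresh]]])
    if current_isoboles:
        dmin = np.full(len(pts), np.inf)
        for comp in current_isoboles:
            dmin = np.minimum(dmin, distances_to_polyline(pts, comp))
        pts = pts[dmin < spacing]
    selected = [(float(x), float(y)) for x, y in pts]
    if grid.surface is not None:
        grid.surface = _upsample(grid.surface)
    if objective is not None:
        _evaluate(grid, objective, selected, grid.level)
        _write_cache_into_surface(grid)
    return selected


def run_fastisoboles(objective: Callable[[float, float], float],
                     target_rate: float, bounds,
                     max_iter: int = 6, tol: float = 2.0 ** -7
                     ) -> FastIsobolesResult:
    """Locate the isobole of ``objective`` at ``target_rate``.

    Parameters
    ----------
    objective : callable (amt1, amt2) -> value
        Deterministic success-rate objective in dose units (freeze the
        subject sample before calling).
    target_rate : float
        The efficacy level whose isobole is traced.
    bounds : (amt1_max, amt2_max)
        Upper dose limits; the search covers [0, max] per axis.
    max_iter : int
        Maximum refinement iterations; the final lattice has
        2**max_iter + 1 doses per axis.
    tol : float
        Convergence tolerance on the discrete Fréchet distance between
        successive estimates, in normalized dose units.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    grid = init_grid(bounds)
    ax = grid.axis()
    init_nodes = [(float(x), float(y)) for x in ax for y in ax]
    _evaluate(grid, objective, init_nodes, 1)
    grid.surface = np.array(
        [[grid.cache[(x, y)] for y in ax] for x in ax])

    records: list[IterationRecord] = []
    prev: Polyline | None = None
    converged = False
    classification = None
    did_fallback = False

    iteration = 1
    while True:
        ax = grid.axis()
        comps = extract_contour(grid.surface, (ax, ax), target_rate)
        isobole = comps[0] if comps else Polyline()
        step = float("nan")
        if not isobole.is_empty and prev is not None and not prev.is_empty:
            step = discrete_frechet(isobole, prev)
        records.append(IterationRecord(
            iteration=iteration, resolution=grid.resolution, isobole=isobole,
            n_new_evaluations=len(grid.cache) - (records[-1].n_total_evaluations
                                                 if records else 0),
            n_total_evaluations=len(grid.cache), frechet_step=step))

        if isobole.is_empty:
            if not did_fallback and iteration == 1:
                # full-lattice probe at level 2 before declaring non-bracketing:
                # a steep isobole can hide inside one coarse cell
                did_fallback = True
                refine(grid, [], objective)
                iteration += 1
                continue
            vals = np.array(list(grid.cache.values()))
            classification = ("entire space efficacious"
                              if vals.min() >= target_rate
                              else "entire space non-efficacious")
            break

        if not np.isnan(step) and step < tol:
            converged = True
            break
        if iteration >= max_iter:
            converged = not np.isnan(step) and step < tol
            break
        refine(grid, comps, objective)
        prev = isobole
        iteration += 1

    final = (Polyline() if isobole.is_empty
             else isobole.scaled(grid.bounds[0], grid.bounds[1]))
    return FastIsobolesResult(
        isobole=final, iterations=records, n_evaluations=len(grid.cache),
        converged=converged, classification=classification, grid=grid,
        target_rate=target_rate)


def brute_force_surface(objective, bounds, level: int):
    """Evaluate the objective on the full level-j lattice (reference mode).

    Returns (axis1_doses, axis2_doses, values) with values[i, j] =
    objective(axis1[i], axis2[j]); (2^level + 1)^2 evaluations.
    """
    n = 2 ** level + 1
    ax1 = np.linspace(0.0, bounds[0], n)
    ax2 = np.linspace(0.0, bounds[1], n)
    vals = np.array([[float(objective(a, b)) for b in ax2] for a in ax1])
    return ax1, ax2, vals
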