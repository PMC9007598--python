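"""Isobole aggregation into confidence-level response surfaces."""

import numpy as np
import pytest

from isopop.aggregate import (aggregate_isoboles, classify_binary,
                              confidence_isobole, isobole_to_polygon)
from isopop.fastisoboles import EffectiveIsobole
from isopop.geometry import Polyline, distance_to_polyline


def make_iso(points, bounds=(1.0, 1.0), target=0.95, pid=0, cls=None):
    pl = Polyline(points) if points is not None else Polyline()
    return EffectiveIsobole(pl, target, bounds, pid, cls)


def anti_diagonal(level, bounds=(1.0, 1.0), n=2, pid=0):
    # segment x + y = level in normalized units, clipped to the unit square
    x = np.linspace(max(0.0, level - 1.0), min(level, 1.0), n)
    y = level - x
    return make_iso(np.column_stack([x * bounds[0], y * bounds[1]]),
                    bounds, pid=pid)


# ---------------------------------------------------------------------------
# failure polygon construction
# ---------------------------------------------------------------------------


def test_straight_isobole_closes_into_triangle():
    poly = isobole_to_polygon(anti_diagonal(1.0))
    assert poly.area() == pytest.approx(0.5)
    assert len(poly.vertices) == 3


def test_axis_hugging_isobole_has_vanishing_area():
    eps = 1e-6
    iso = make_iso([[0.0, eps], [eps, eps], [eps, 0.0]])
    assert isobole_to_polygon(iso).area() < 1e-11


def test_l_shaped_isobole_matches_shoelace():
    iso = make_iso([[0.0, 0.8], [0.2, 0.2], [0.8, 0.0]])
    poly = isobole_to_polygon(iso)
    # shoelace on the explicit vertex list (isobole + origin)
    v = np.array([[0.0, 0.8], [0.2, 0.2], [0.8, 0.0], [0.0, 0.0]])
    x, y = v.T
    expected = abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2
    assert poly.area() == pytest.approx(expected)


def test_far_edge_endpoints_close_through_corners():
    # isobole from the top edge to the right edge: closure must walk the
    # boundary through (max1, 0), the origin and (0, max2)
    iso = make_iso([[0.3, 1.0], [0.5, 0.5], [1.0, 0.4]])
    poly = isobole_to_polygon(iso)
    verts = {tuple(v) for v in np.round(poly.vertices, 9)}
    assert {(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)} <= verts


def test_interior_endpoint_rejected():
    iso = make_iso([[0.0, 0.8], [0.5, 0.5]])
    with pytest.raises(ValueError, match="boundary"):
        isobole_to_polygon(iso)


def test_reversed_orientation_gives_same_polygon():
    a = isobole_to_polygon(make_iso([[0.0, 1.0], [1.0, 0.0]]))
    b = isobole_to_polygon(make_iso([[1.0, 0.0], [0.0, 1.0]]))
    assert a.area() == pytest.approx(b.area())


# ---------------------------------------------------------------------------
# binary classification
# ---------------------------------------------------------------------------


def test_classify_binary_matches_half_plane_rule():
    iso = anti_diagonal(1.0)
    poly = isobole_to_polygon(iso)
    ax = np.linspace(0.0, 1.0, 65)
    field = classify_binary(poly, ax, ax, isobole=iso.polyline)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    expected = (xx + yy >= 1.0 - 1e-12).astype(float)
    assert np.array_equal(field, expected)


def test_origin_fails_and_max_corner_succeeds():
    poly = isobole_to_polygon(anti_diagonal(0.6))
    field = classify_binary(poly, [0.0, 0.5, 1.0], [0.0, 0.5, 1.0])
    assert field[0, 0] == 0.0
    assert field[-1, -1] == 1.0


def test_nodes_on_isobole_count_as_success():
    iso = anti_diagonal(1.0)
    poly = isobole_to_polygon(iso)
    field = classify_binary(poly, [0.5], [0.5], isobole=iso.polyline)
    assert field[0, 0] == 1.0


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_identical_isoboles_give_binary_surface():
    isos = [anti_diagonal(0.8) for _ in range(7)]
    surf = aggregate_isoboles(isos, resolution=33)
    assert set(np.unique(surf.values)) <= {0.0, 1.0}
    assert surf.n_pop == 7


def test_nested_isoboles_count_in_bands():
    isos = [anti_diagonal(0.4, pid=0), anti_diagonal(0.8, pid=1)]
    surf = aggregate_isoboles(isos, resolution=41)
    assert set(np.unique(surf.values)) == {0.0, 0.5, 1.0}
    # inside both failure regions, between, and outside
    i = lambda v: int(round(v * 40))
    assert surf.values[i(0.1), i(0.1)] == 0.0
    assert surf.values[i(0.3), i(0.3)] == 0.5
    assert surf.values[i(0.9), i(0.9)] == 1.0


def test_degenerate_isoboles_contribute_constant_fields():
    isos = [anti_diagonal(0.6, pid=0),
            make_iso(None, pid=1, cls="entire space efficacious"),
            make_iso(None, pid=2, cls="entire space non-efficacious")]
    surf = aggregate_isoboles(isos, resolution=17)
    assert surf.values.max() == pytest.approx(2 / 3)
    assert surf.values.min() == pytest.approx(1 / 3)


def test_averaging_order_exchanges_exactly():
    rng = np.random.default_rng(3)
    isos = [anti_diagonal(lv) for lv in rng.uniform(0.3, 1.2, 9)]
    surf = aggregate_isoboles(isos, resolution=33)
    field_means = []
    for iso in isos:
        f = classify_binary(isobole_to_polygon(iso), surf.axis1, surf.axis2,
                            isobole=iso.polyline)
        field_means.append(f.mean())
    assert surf.values.mean() == pytest.approx(np.mean(field_means), rel=1e-12)


def test_mixed_bounds_rejected():
    isos = [anti_diagonal(0.5, bounds=(1.0, 1.0)),
            anti_diagonal(0.5, bounds=(2.0, 1.0))]
    with pytest.raises(ValueError, match="bounds"):
        aggregate_isoboles(isos)


def test_confidence_surface_monotone_for_monotone_isoboles():
    rng = np.random.default_rng(8)
    isos = [anti_diagonal(lv) for lv in rng.uniform(0.3, 1.3, 15)]
    surf = aggregate_isoboles(isos, resolution=33)
    assert np.all(np.diff(surf.values, axis=0) >= 0)
    assert np.all(np.diff(surf.values, axis=1) >= 0)


# ---------------------------------------------------------------------------
# confidence-level isoboles
# ---------------------------------------------------------------------------


def test_identical_ensemble_recovers_single_isobole():
    isos = [anti_diagonal(0.8) for _ in range(5)]
    surf = aggregate_isoboles(isos, resolution=65)
    cell = 1.0 / 64
    for level in (0.25, 0.5, 0.9):
        ci = confidence_isobole(surf, level)
        ref = Polyline([[0.0, 0.8], [0.8, 0.0]])
        for p in ci.points:
            assert distance_to_polyline(p, ref) <= cell + 1e-12


def test_three_quarters_level_sits_on_outer_step():
    isos = [anti_diagonal(0.4, pid=0), anti_diagonal(0.4, pid=1),
            anti_diagonal(0.4, pid=2), anti_diagonal(0.9, pid=3)]
    surf = aggregate_isoboles(isos, resolution=65)
    ci = confidence_isobole(surf, 0.75)
    outer = Polyline([[0.0, 0.9], [0.9, 0.0]])
    cell = 1.0 / 64
    for p in ci.points:
        assert distance_to_polyline(p, outer) <= cell + 1e-12


def test_level_ordering_along_rays():
    rng = np.random.default_rng(4)
    isos = [anti_diagonal(lv) for lv in rng.uniform(0.4, 1.2, 40)]
    surf = aggregate_isoboles(isos, resolution=65)
    lo = confidence_isobole(surf, 0.50)
    hi = confidence_isobole(surf, 0.95)
    # along rays from the origin the 95% curve is never closer than the 50%
    for theta in np.linspace(0.1, np.pi / 2 - 0.1, 9):
        u = np.array([np.cos(theta), np.sin(theta)])
        r_lo = _ray_crossing(lo, u)
        r_hi = _ray_crossing(hi, u)
        if r_lo is not None and r_hi is not None:
            assert r_hi >= r_lo - 1.0 / 64


def _ray_crossing(polyline, u):
    """Arc-length position where a ray from the origin crosses a polyline."""
    t = np.linspace(0, np.sqrt(2), 4000)
    pts = t[:, None] * u
    from isopop.geometry import distances_to_polyline
    d = distances_to_polyline(pts, polyline)
    i = int(np.argmin(d))
    return t[i] if d[i] < 5e-3 else None


def test_out_of_range_level_flagged_empty():
    isos = [anti_diagonal(0.8) for _ in range(3)]
    surf = aggregate_isoboles(isos, resolution=17)
    # all-or-nothing surface still brackets interior levels; shrink to a
    # one-population surface whose range is {0, 1} and ask for impossible n_pop
    with pytest.raises(ValueError):
        confidence_isobole(surf, 1.5)
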