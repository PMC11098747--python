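"""Geometric kernels: closed forms, conservation, invariance, MC oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histoshell import (
    CellRecord,
    GeometryError,
    Shell,
    Sphere,
    mc_prism_sphere_volume,
    polygon_disk_area,
    prism_sphere_volume,
    segment_sphere_fraction,
    shell_fraction,
    shell_volume,
)
from conftest import square_section, star_polygon

SQUARE = [(0.0, 0.0), (100.0, 0.0), (100.0, 100.0), (0.0, 100.0)]
ORIGIN_CELL = CellRecord("s0", 0.0, 0.0, "WT")


# -- segment–sphere closed form ---------------------------------------------

@pytest.mark.parametrize("cell_xy, radius, expected", [
    ((0.0, 0.0), 1000.0, 1.0),   # segment fully inside
    ((0.0, 0.0), 5.0, 0.5),      # overlap [-5, 5] over slab [-10, 10]
    ((30.0, 40.0), 49.0, 0.0),   # in-plane distance 50 > r
], ids=["fully-inside", "partial", "outside"])
def test_segment_sphere_fraction_closed_form(cell_xy, radius, expected):
    cell = CellRecord("s0", *cell_xy, population="WT")
    sec = square_section(origin=(-50.0, -50.0))  # slab [-10, 10]
    assert segment_sphere_fraction(cell, sec, Sphere((0, 0, 0), radius)) == \
        pytest.approx(expected, abs=1e-12)


def test_shell_fraction_matches_sphere_difference():
    sec = square_section(origin=(-50.0, -50.0))
    f = shell_fraction(ORIGIN_CELL, sec, Shell(0.0, 5.0, (0, 0, 0)))
    assert f == pytest.approx(0.5, abs=1e-12)
    rest = shell_fraction(ORIGIN_CELL, sec, Shell(5.0, 1000.0, (0, 0, 0)))
    assert f + rest == pytest.approx(1.0, abs=1e-12)


def test_zero_thickness_slab_rejected():
    sec = square_section(z_l=5.0, z_u=5.0)
    with pytest.raises(GeometryError, match="ZERO_THICKNESS"):
        segment_sphere_fraction(ORIGIN_CELL, sec, Sphere((0, 0, 0), 10.0))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 10**6))
def test_shell_fractions_partition_to_one(seed):
    """For any partition of [0, ∞) into shells, a cell's fractions sum to 1."""
    rng = np.random.default_rng(seed)
    z_l = float(rng.uniform(-50, 0))
    sec = square_section(z_l=z_l, z_u=z_l + float(rng.uniform(1.0, 40.0)),
                         origin=(-50, -50))
    cell = CellRecord("s0", *rng.uniform(-60, 60, 2), population="WT")
    center = tuple(rng.uniform(-100, 100, 3))
    edges = np.concatenate([[0.0], np.sort(rng.uniform(1.0, 500.0, 6)), [1e6]])
    total = sum(shell_fraction(cell, sec, Shell(a, b, center))
                for a, b in zip(edges[:-1], edges[1:]))
    assert total == pytest.approx(1.0, abs=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10**6))
def test_fraction_monotone_in_radius(seed):
    rng = np.random.default_rng(seed)
    sec = square_section(origin=(-50, -50))
    cell = CellRecord("s0", *rng.uniform(-80, 80, 2), population="WT")
    center = tuple(rng.uniform(-50, 50, 3))
    radii = np.sort(rng.uniform(0, 300, 8))
    fracs = [segment_sphere_fraction(cell, sec, Sphere(center, r)) for r in radii]
    assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))


# -- polygon ∩ disk exact area ----------------------------------------------

@pytest.mark.parametrize("center, radius, expected", [
    ((50, 50), 1000.0, 10000.0),          # polygon inside disk
    ((50, 50), 10.0, math.pi * 100.0),    # disk inside polygon
    ((0, 0), 10.0, 25.0 * math.pi),       # quarter disk at a corner
], ids=["poly-in-disk", "disk-in-poly", "quarter-disk"])
def test_polygon_disk_area_closed_forms(center, radius, expected):
    assert polygon_disk_area(SQUARE, center, radius) == \
        pytest.approx(expected, rel=1e-12)


def test_polygon_disk_area_orientation_independent():
    a = polygon_disk_area(SQUARE, (30, 70), 40.0)
    b = polygon_disk_area(SQUARE[::-1], (30, 70), 40.0)
    assert a == pytest.approx(b, rel=1e-12)


def test_polygon_disk_area_rejects_self_intersection():
    bowtie = [(0, 0), (100, 100), (100, 0), (0, 100)]
    with pytest.raises(GeometryError, match="POLYGON_NOT_SIMPLE"):
        polygon_disk_area(bowtie, (50, 50), 10.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10**6))
def test_polygon_disk_area_matches_shapely_buffer(seed):
    """Independent cross-check against a polygonal disk approximation."""
    from shapely.geometry import Point, Polygon
    rng = np.random.default_rng(seed)
    poly = star_polygon(rng, n_vertices=int(rng.integers(5, 14)), scale=100.0)
    center = tuple(rng.uniform(-80, 80, 2))
    radius = rng.uniform(10.0, 150.0)
    exact = polygon_disk_area(poly, center, radius)
    approx = Polygon(poly).intersection(
        Point(center).buffer(radius, quad_segs=512)).area
    assert exact == pytest.approx(approx, rel=5e-4, abs=1e-3)


# -- prism ∩ sphere volume ---------------------------------------------------

def test_prism_inside_sphere_is_exact_prism_volume():
    sec = square_section()
    est = prism_sphere_volume(sec, Sphere((50, 50, 0), 1000.0))
    assert est.value == pytest.approx(2.0e5, rel=1e-12)
    assert est.method == "analytic" and est.abs_err_bound == 0.0


def test_sphere_inside_prism_is_sphere_volume():
    sec = square_section(side=10_000.0, z_l=-10_000.0, z_u=10_000.0,
                         origin=(-5000.0, -5000.0))
    est = prism_sphere_volume(sec, Sphere((0, 0, 0), 5.0))
    assert est.value == pytest.approx(4.0 / 3.0 * math.pi * 125.0, rel=1e-6)


def test_half_space_gives_hemisphere():
    sec = square_section(side=10_000.0, z_l=0.0, z_u=10_000.0,
                         origin=(-5000.0, -5000.0))
    est = prism_sphere_volume(sec, Sphere((0, 0, 0), 100.0))
    assert est.value == pytest.approx(2.0 / 3.0 * math.pi * 1e6, rel=1e-6)


def test_volume_monotone_in_radius_and_bounded():
    rng = np.random.default_rng(5)
    poly = star_polygon(rng, n_vertices=9, scale=120.0)
    sec = square_section()
    sec.vertices = [(float(x), float(y)) for x, y in poly]
    prism = sec.area * sec.thickness
    prev = 0.0
    for r in np.linspace(0, 400, 12):
        v = prism_sphere_volume(sec, Sphere((20, -30, 5), r)).value
        assert v >= prev - 1e-6
        assert v <= min(prism, 4.0 / 3.0 * math.pi * r**3) + 1e-6 * prism + 1e-9
        prev = v


def test_rigid_translation_invariance():
    rng = np.random.default_rng(9)
    poly = star_polygon(rng, n_vertices=11, scale=100.0)
    sec = square_section()
    sec.vertices = poly
    sph = Sphere((10, 20, 3), 90.0)
    base = prism_sphere_volume(sec, sph).value
    shift = np.array([1234.5, -987.0, 55.5])
    sec2 = square_section(z_l=sec.z_l + shift[2], z_u=sec.z_u + shift[2])
    sec2.vertices = [(x + shift[0], y + shift[1]) for x, y in poly]
    moved = prism_sphere_volume(
        sec2, Sphere((10 + shift[0], 20 + shift[1], 3 + shift[2]), 90.0)).value
    assert moved == pytest.approx(base, rel=1e-9)


def test_bad_tolerance_rejected():
    with pytest.raises(GeometryError, match="BAD_TOLERANCE"):
        prism_sphere_volume(square_section(), Sphere((0, 0, 0), 10), rel_tol=0.5)


def test_shell_volumes_partition_to_prism_volume():
    sec = square_section()
    center = (20.0, 80.0, -3.0)
    edges = [0.0, 30.0, 60.0, 90.0, 1e5]
    total = sum(shell_volume(sec, Shell(a, b, center)).value
                for a, b in zip(edges[:-1], edges[1:]))
    assert total == pytest.approx(sec.area * sec.thickness, rel=1e-6)


def test_shell_beyond_prism_extent_is_zero():
    sec = square_section()
    est = shell_volume(sec, Shell(5000.0, 6000.0, (50.0, 50.0, 0.0)))
    assert est.value == 0.0


# -- Monte-Carlo oracle ------------------------------------------------------

def test_mc_estimate_is_deterministic_per_seed():
    sec = square_section()
    sph = Sphere((40, 60, 0), 55.0)
    a = mc_prism_sphere_volume(sec, sph, 50_000, seed=123)
    b = mc_prism_sphere_volume(sec, sph, 50_000, seed=123)
    assert a.value == b.value and a.abs_err_bound == b.abs_err_bound


def test_mc_prism_inside_sphere_is_exact():
    sec = square_section()
    est = mc_prism_sphere_volume(sec, Sphere((50, 50, 0), 1000.0), 10_000, seed=1)
    assert est.value == pytest.approx(2.0e5, rel=1e-12)
    assert est.abs_err_bound == 0.0


@pytest.mark.parametrize("seed", range(8))
def test_mc_agrees_with_quadrature(seed):
    """Analytic and MC routes agree within 4 SE on random non-convex cases."""
    rng = np.random.default_rng(1000 + seed)
    poly = star_polygon(rng, n_vertices=int(rng.integers(6, 14)), scale=100.0)
    sec = square_section(z_l=float(rng.uniform(-40, 0)),
                         z_u=float(rng.uniform(5, 45)))
    sec.vertices = poly
    sph = Sphere(tuple(rng.uniform(-60, 60, 3)), float(rng.uniform(40, 180)))
    analytic = prism_sphere_volume(sec, sph)
    mc = mc_prism_sphere_volume(sec, sph, 200_000, seed=seed)
    tol = 4 * mc.abs_err_bound + analytic.abs_err_bound + 1e-9
    assert abs(analytic.value - mc.value) <= tol
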