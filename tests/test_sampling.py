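"""Geometry sampling: lengths, LOI supercover tracing, polygon
rasterization, pixel statistics and wall-thickness grading."""

import math

import numpy as np
import pytest

from rvecv.sampling import (
    PolygonROI,
    PolylineLOI,
    grade_from_thickness,
    loi_stats,
    max_wall_thickness_px,
    polyline_length_mm,
    rasterize_polygon,
    roi_stats,
    trace_loi_pixels,
    validate_min_length,
)

from conftest import make_map


# ---------------------------------------------------------------------------
# lengths
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "vertices, spacing, expected",
    [
        ([(0, 0), (3, 4)], (1, 1), 5.0),            # 3-4-5 triangle
        ([(0, 0), (0, 10)], (1.9, 1.9), 19.0),
        ([(0, 0), (0, 2), (0, 5)], (2, 1), 5.0),    # column spacing applies
    ],
)
def test_polyline_length_anisotropic(vertices, spacing, expected):
    assert polyline_length_mm(PolylineLOI(np.array(vertices, float)), spacing) == pytest.approx(expected)


def test_min_length_rule():
    long_loi = PolylineLOI(np.array([(0.0, 0.0), (0.0, 10.0)]))
    short_loi = PolylineLOI(np.array([(0.0, 0.0), (3.0, 4.0)]))
    assert validate_min_length(long_loi, (1.9, 1.9)) == (True, pytest.approx(19.0))
    ok, length = validate_min_length(short_loi, (1, 1))
    assert not ok and length == pytest.approx(5.0)
    assert validate_min_length(short_loi, (1, 1), min_mm=0)[0]
    # ROI extent is judged by its longest vertex chord
    roi = PolygonROI(np.array([(0.0, 0.0), (0.0, 6.0), (8.0, 6.0)]))
    ok, chord = validate_min_length(roi, (1, 1))
    assert ok and chord == pytest.approx(10.0)


def test_degenerate_geometry_rejected():
    with pytest.raises(ValueError):
        PolylineLOI(np.array([(1.0, 1.0)]))
    with pytest.raises(ValueError):
        PolylineLOI(np.array([(1.0, 1.0), (1.0, 1.0)]))
    with pytest.raises(ValueError):
        PolygonROI(np.array([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)]))  # zero area


# ---------------------------------------------------------------------------
# LOI supercover tracing
# ---------------------------------------------------------------------------

def test_axis_aligned_interior_crossing():
    loi = PolylineLOI(np.array([(2.5, 0.2), (2.5, 2.8)]))
    assert trace_loi_pixels(loi, (8, 8)) == [(2, 0), (2, 1), (2, 2)]


def test_diagonal_corner_touches_excluded():
    """A diagonal through pixel corners crosses only the diagonal pixels."""
    loi = PolylineLOI(np.array([(0.5, 0.5), (2.5, 2.5)]))
    assert trace_loi_pixels(loi, (8, 8)) == [(0, 0), (1, 1), (2, 2)]


def test_gridline_riding_segment_crosses_nothing():
    """A segment lying exactly on a pixel edge touches no pixel interior."""
    loi = PolylineLOI(np.array([(2.0, 0.5), (2.0, 3.5), (2.5, 3.5)]))
    assert trace_loi_pixels(loi, (8, 8)) == [(2, 3)]


def test_loi_outside_grid_errors():
    loi = PolylineLOI(np.array([(20.5, 20.5), (22.5, 22.5)]))
    with pytest.raises(ValueError):
        trace_loi_pixels(loi, (8, 8))


def _clip_interval(p0, p1, r, c):
    """Liang-Barsky clip of segment p0->p1 against the open square of
    pixel (r, c); returns the parameter length of the interior chord."""
    t0, t1 = 0.0, 1.0
    for axis, lo, hi in ((0, r, r + 1), (1, c, c + 1)):
        d = p1[axis] - p0[axis]
        if d == 0:
            if not lo < p0[axis] < hi:
                return 0.0
            continue
        ta = (lo - p0[axis]) / d
        tb = (hi - p0[axis]) / d
        ta, tb = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, ta), min(t1, tb)
    return max(0.0, t1 - t0)


def _oracle_pixels(vertices, shape):
    """Independent supercover oracle: exact per-pixel segment clipping."""
    out = set()
    for p0, p1 in zip(vertices[:-1], vertices[1:]):
        lo_r = max(0, math.floor(min(p0[0], p1[0])))
        hi_r = min(shape[0] - 1, math.ceil(max(p0[0], p1[0])))
        lo_c = max(0, math.floor(min(p0[1], p1[1])))
        hi_c = min(shape[1] - 1, math.ceil(max(p0[1], p1[1])))
        for r in range(lo_r, hi_r + 1):
            for c in range(lo_c, hi_c + 1):
                if _clip_interval(p0, p1, r, c) > 1e-12:
                    out.add((r, c))
    return out


def test_trace_matches_clipping_oracle_on_random_polylines():
    """Supercover traversal equals an exact per-pixel clipping oracle, and
    every densely sampled interior point lands in a traced pixel."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = rng.integers(2, 6)
        verts = rng.uniform(2.0, 62.0, size=(n, 2))
        loi = PolylineLOI(verts)
        traced = trace_loi_pixels(loi, (64, 64))
        assert len(traced) == len(set(traced))  # each pixel listed once
        assert set(traced) == _oracle_pixels(verts, (64, 64))
        # dense point sampling: sampled pixels are a subset of the trace
        ts = np.linspace(0, 1, 500)[1:-1]
        for p0, p1 in zip(verts[:-1], verts[1:]):
            pts = p0 + ts[:, None] * (p1 - p0)
            on_grid = (pts == np.floor(pts)).any(axis=1)
            sampled = {
                (math.floor(r), math.floor(c))
                for (r, c), skip in zip(pts, on_grid) if not skip
            }
            assert sampled <= set(traced)


def test_trace_invariant_under_vertex_subdivision():
    rng = np.random.default_rng(7)
    verts = rng.uniform(2.0, 30.0, size=(4, 2))
    mids = (verts[:-1] + verts[1:]) / 2
    refined = np.empty((7, 2))
    refined[0::2] = verts
    refined[1::2] = mids
    assert trace_loi_pixels(PolylineLOI(verts), (32, 32)) == \
        trace_loi_pixels(PolylineLOI(refined), (32, 32))


# ---------------------------------------------------------------------------
# LOI statistics
# ---------------------------------------------------------------------------

def test_loi_stats_constant_map(constant_map):
    loi = PolylineLOI(np.array([(2.5, 0.2), (2.5, 12.8)]))
    st = loi_stats(constant_map, loi)
    assert st.mean_t1 == 1000.0 and st.sd_t1 == 0.0 and st.n_nan_excluded == 0


def test_loi_stats_population_sd():
    values = np.full((8, 8), 1000.0)
    values[2, 0], values[2, 1], values[2, 2] = 900.0, 1000.0, 1100.0
    m = make_map(values)
    st = loi_stats(m, PolylineLOI(np.array([(2.5, 0.2), (2.5, 2.8)])))
    assert st.n == 3
    assert st.mean_t1 == pytest.approx(1000.0)
    assert st.sd_t1 == pytest.approx(math.sqrt(20000.0 / 3.0))  # ~81.65


def test_loi_stats_nan_excluded_and_all_nan_error():
    values = np.full((8, 8), 1000.0)
    values[2, 1] = np.nan
    m = make_map(values)
    st = loi_stats(m, PolylineLOI(np.array([(2.5, 0.2), (2.5, 2.8)])))
    assert st.n == 2 and st.n_nan_excluded == 1
    values[:] = np.nan
    with pytest.raises(ValueError):
        loi_stats(make_map(values), PolylineLOI(np.array([(2.5, 0.2), (2.5, 2.8)])))


def test_length_weighted_mode_reweights_partial_chords():
    values = np.full((8, 8), 1000.0)
    values[2, 2] = 2000.0
    m = make_map(values)
    # chord in (2,2) is half as long as in (2,1)
    loi = PolylineLOI(np.array([(2.5, 1.0), (2.5, 2.5)]))
    uniform = loi_stats(m, loi, weights="uniform")
    weighted = loi_stats(m, loi, weights="length")
    assert uniform.mean_t1 == pytest.approx(1500.0)
    assert weighted.mean_t1 == pytest.approx(1000.0 * 2 / 3 + 2000.0 / 3)


# ---------------------------------------------------------------------------
# polygon rasterization
# ---------------------------------------------------------------------------

def test_square_rasterizes_to_interior_centers():
    roi = PolygonROI(np.array([(0.0, 0.0), (0.0, 3.0), (3.0, 3.0), (3.0, 0.0)]))
    assert sorted(rasterize_polygon(roi, (8, 8))) == \
        [(r, c) for r in range(3) for c in range(3)]


def test_subpixel_triangle_center_rule():
    contains = PolygonROI(np.array([(4.2, 4.2), (4.2, 4.9), (4.9, 4.55)]))
    assert rasterize_polygon(contains, (8, 8)) == [(4, 4)]
    misses = PolygonROI(np.array([(4.05, 4.05), (4.05, 4.4), (4.4, 4.2)]))
    with pytest.raises(ValueError):
        rasterize_polygon(misses, (8, 8))


def test_rasterize_matches_point_in_polygon_oracle():
    """Random star-shaped polygons against shapely's point-in-polygon."""
    from shapely.geometry import Point, Polygon

    rng = np.random.default_rng(3)
    for _ in range(100):
        n = rng.integers(3, 9)
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
        radii = rng.uniform(1.5, 12.0, n)
        center = rng.uniform(14.0, 18.0, 2)
        verts = np.stack(
            [center[0] + radii * np.sin(angles), center[1] + radii * np.cos(angles)], 1
        )
        try:
            roi = PolygonROI(verts)
            pixels = set(rasterize_polygon(roi, (32, 32)))
        except ValueError:
            continue  # degenerate draw encloses no center
        poly = Polygon([(c, r) for r, c in verts])
        expected = {
            (r, c)
            for r in range(32)
            for c in range(32)
            if poly.contains(Point(c + 0.5, r + 0.5))
        }
        assert pixels == expected


def test_rasterized_count_tracks_polygon_area():
    """Pixel count x pixel area approaches polygon area (perimeter-order error)."""
    th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    for radius in (5.0, 10.0, 20.0):
        verts = np.stack([32 + radius * np.sin(th), 32 + radius * np.cos(th)], 1)
        roi = PolygonROI(verts)
        count = len(rasterize_polygon(roi, (64, 64)))
        area = abs(roi.signed_area())
        perimeter = 2 * np.pi * radius
        assert abs(count - area) < perimeter


def test_roi_stats_checkerboard_and_loi_equivalence():
    values = np.where((np.add.outer(range(8), range(8)) % 2) == 0, 800.0, 1200.0)
    m = make_map(values)
    roi = PolygonROI(np.array([(2.0, 0.0), (2.0, 4.0), (3.0, 4.0), (3.0, 0.0)]))
    st_roi = roi_stats(m, roi)
    assert st_roi.mean_t1 == pytest.approx(1000.0)
    # an LOI crossing exactly the same pixels yields identical statistics
    loi = PolylineLOI(np.array([(2.5, 0.2), (2.5, 3.8)]))
    st_loi = loi_stats(m, loi)
    assert sorted(st_roi.pixel_set) == sorted(st_loi.pixel_set)
    assert st_roi.mean_t1 == st_loi.mean_t1
    assert st_roi.sd_t1 == st_loi.sd_t1


# ---------------------------------------------------------------------------
# wall thickness
# ---------------------------------------------------------------------------

def _band_mask(width_px, supersample, offset=0.0, shape=(16, 32)):
    """Horizontal band of the given width (map px) in a supersampled mask."""
    s = supersample
    sub_rows = shape[0] * s
    centers = (np.arange(sub_rows) + 0.5) / s
    rows = (centers >= 6.0 + offset) & (centers < 6.0 + offset + width_px)
    return np.repeat(rows[:, None], shape[1] * s, axis=1)


@pytest.mark.parametrize(
    "width, expected_grade",
    [(1.5, 2), (2.5, 1), (1.0, 2), (2.0, 2), (0.5, 3)],
)
def test_band_thickness_and_grade(width, expected_grade):
    s = 8
    mask = _band_mask(width, s)
    region = [(r, c) for r in range(16) for c in range(8, 24)]
    result = max_wall_thickness_px(mask, region, s)
    assert result.max_thickness_px == pytest.approx(width, abs=1.0 / s)
    assert result.grade == expected_grade


def test_subpixel_band_thickness_resolution():
    s = 8
    mask = _band_mask(0.6, s, offset=0.05)
    region = [(r, c) for r in range(16) for c in range(32)]
    result = max_wall_thickness_px(mask, region, s)
    assert result.max_thickness_px == pytest.approx(0.6, abs=1.0 / s)
    assert result.grade == 3


def test_grade_boundary_semantics():
    assert grade_from_thickness(1.0) == 2
    assert grade_from_thickness(2.0) == 2
    assert grade_from_thickness(2.0 + 1e-9) == 1
    assert grade_from_thickness(1.0 - 1e-9) == 3


def test_empty_region_gives_zero_thickness_grade3():
    mask = _band_mask(1.5, 4)
    result = max_wall_thickness_px(mask, [(0, 0), (0, 1)], 4)  # off the band
    assert result.max_thickness_px == 0.0 and result.grade == 3
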