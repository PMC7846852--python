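"""Turning operator geometry into pixel sets and T1 statistics.

Two sampling primitives are provided, matching the two measurement methods
this package compares:

* **Planimetric ROI** — a closed polygon; the pixels whose *centers* fall
  inside it (even-odd rule) are averaged.  This is the conventional
  standard for myocardial T1/ECV analysis.
* **Line of interest (LOI)** — an open polyline drawn along the mid-wall
  of a thin structure; the pixels whose interiors are *crossed* by the
  line are averaged, with no need to contour the wall.  This is the
  centerline method for thin-walled structures such as the RV free wall.

Pixel-crossing semantics ("supercover"): a pixel counts as crossed iff the
polyline intersects the *open* unit square of the pixel.  Touching only a
corner point or sliding exactly along an edge between two pixels does not
count — this makes the diagonal-through-corners case deterministic and
directly checkable against an exact per-pixel clipping oracle.

The module also measures maximum wall thickness (in map pixels) on a
supersampled binary mask via a medial-axis distance transform, and grades
it on the 1/2/3 scale used to judge whether a thin wall is measurable at
all (grade 1: > 2 px, grade 2: 1-2 px, grade 3: < 1 px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .maps_io import T1Map

__all__ = [
    "PolygonROI",
    "PolylineLOI",
    "SampleStats",
    "WallThicknessGrade",
    "polyline_length_mm",
    "roi_chord_length_mm",
    "validate_min_length",
    "trace_loi_pixels",
    "loi_stats",
    "rasterize_polygon",
    "roi_stats",
    "max_wall_thickness_px",
    "grade_from_thickness",
]

_TOL = 1e-12


@dataclass(frozen=True)
class PolylineLOI:
    """An open polyline in continuous (row, col) pixel coordinates."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 2:
            raise ValueError("LOI needs at least 2 (row, col) vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("LOI vertices must be finite")
        seg = np.diff(v, axis=0)
        if np.any(np.all(seg == 0, axis=1)):
            raise ValueError("LOI must not repeat consecutive vertices")


@dataclass(frozen=True)
class PolygonROI:
    """A closed polygon in continuous (row, col) pixel coordinates.

    The vertex list is implicitly closed (last connects back to first).
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("ROI needs at least 3 (row, col) vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("ROI vertices must be finite")
        if abs(self.signed_area()) <= 0:
            raise ValueError("ROI polygon must enclose a nonzero area")

    def signed_area(self) -> float:
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c))


@dataclass
class SampleStats:
    """Per-structure T1 statistics over a sampled pixel set.

    ``sd_t1`` is the *population* SD (divide by n), a descriptive measure
    of spread within the sample; NaN pixels are excluded from both moments
    and counted in ``n_nan_excluded``.
    """

    pixel_set: list[tuple[int, int]]
    n: int
    mean_t1: float
    sd_t1: float
    n_nan_excluded: int


@dataclass
class WallThicknessGrade:
    """Maximum wall thickness in map pixels with its 1/2/3 grade."""

    max_thickness_px: float
    grade: int


def grade_from_thickness(max_thickness_px: float) -> int:
    """Grade a maximum wall thickness: >2 px -> 1, 1-2 px -> 2, <1 px -> 3."""
    if max_thickness_px > 2:
        return 1
    if max_thickness_px >= 1:
        return 2
    return 3


# ---------------------------------------------------------------------------
# lengths
# ---------------------------------------------------------------------------

def polyline_length_mm(loi: PolylineLOI, spacing: tuple[float, float]) -> float:
    """Total path length in mm under anisotropic (row, col) spacing."""
    d = np.diff(loi.vertices, axis=0) * np.asarray(spacing, dtype=float)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def roi_chord_length_mm(roi: PolygonROI, spacing: tuple[float, float]) -> float:
    """Longest vertex-to-vertex chord of the polygon in mm."""
    v = roi.vertices * np.asarray(spacing, dtype=float)
    d = v[:, None, :] - v[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).max())


def validate_min_length(
    geometry: PolylineLOI | PolygonROI,
    spacing: tuple[float, float],
    min_mm: float = 10.0,
) -> tuple[bool, float]:
    """Check the minimum-extent rule for operator geometry.

    LOIs are measured by path length, ROIs by their longest vertex chord
    (an ROI is specified by its length, not its area).  Returns
    ``(passed, measured_mm)``.
    """
    if isinstance(geometry, PolylineLOI):
        length = polyline_length_mm(geometry, spacing)
    else:
        length = roi_chord_length_mm(geometry, spacing)
    return length >= min_mm, length


# ---------------------------------------------------------------------------
# LOI supercover traversal
# ---------------------------------------------------------------------------

def _segment_subintervals(p0: np.ndarray, p1: np.ndarray):
    """Split a segment at every integer-gridline crossing.

    Yields ``(t0, t1)`` parameter sub-intervals within which neither
    coordinate crosses an integer, so the open sub-segment lies inside a
    single pixel interior (or exactly on a gridline, which the caller
    screens out).
    """
    ts = [0.0, 1.0]
    for axis in (0, 1):
        a0, a1 = p0[axis], p1[axis]
        d = a1 - a0
        if d == 0:
            continue
        lo, hi = (a0, a1) if a0 < a1 else (a1, a0)
        for k in range(math.floor(lo) + 1, math.ceil(hi)):
            t = (k - a0) / d
            if 0.0 < t < 1.0:
                ts.append(t)
    ts.sort()
    prev = ts[0]
    for t in ts[1:]:
        if t - prev > _TOL:
            yield prev, t
            prev = t


def _iter_crossed(loi: PolylineLOI):
    """Yield (r, c, chord_vec) per crossed pixel, in first-crossing order.

    ``chord_vec`` is the (dr, dc) displacement of the traversed chord in
    pixel units; repeated crossings of the same pixel accumulate at its
    first occurrence.
    """
    order: list[tuple[int, int]] = []
    chords: dict[tuple[int, int], np.ndarray] = {}
    verts = loi.vertices
    for p0, p1 in zip(verts[:-1], verts[1:]):
        d = p1 - p0
        # A segment lying exactly on a gridline crosses no pixel interior.
        if d[0] == 0 and float(p0[0]).is_integer():
            continue
        if d[1] == 0 and float(p0[1]).is_integer():
            continue
        for t0, t1 in _segment_subintervals(p0, p1):
            tm = 0.5 * (t0 + t1)
            r = math.floor(p0[0] + tm * d[0])
            c = math.floor(p0[1] + tm * d[1])
            key = (r, c)
            if key not in chords:
                order.append(key)
                chords[key] = np.zeros(2)
            chords[key] += (t1 - t0) * d
    for key in order:
        yield key[0], key[1], chords[key]


def trace_loi_pixels(loi: PolylineLOI, shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Pixels whose open interior the polyline crosses, in first-crossing order.

    Each pixel appears once.  Pixels touched only at a corner point, or
    grazed exactly along an edge between two pixels, are excluded.  Pixels
    outside the ``shape`` grid are dropped; an LOI crossing no in-grid
    pixel interior is an error.
    """
    rows, cols = shape
    out = [
        (r, c)
        for r, c, _ in _iter_crossed(loi)
        if 0 <= r < rows and 0 <= c < cols
    ]
    if not out:
        raise ValueError("LOI does not cross the interior of any pixel in the grid")
    return out


def _stats_from_values(
    pixels: list[tuple[int, int]],
    values: np.ndarray,
    weights: np.ndarray | None,
) -> SampleStats:
    finite = np.isfinite(values)
    n_nan = int((~finite).sum())
    if not finite.any():
        raise ValueError("all sampled pixels are NaN; no T1 statistics available")
    vals = values[finite]
    if weights is None:
        mean = float(vals.mean())
        sd = float(vals.std())  # population SD
    else:
        w = weights[finite]
        w = w / w.sum()
        mean = float(np.sum(w * vals))
        sd = float(np.sqrt(np.sum(w * (vals - mean) ** 2)))
    return SampleStats(pixels, int(finite.sum()), mean, sd, n_nan)


def loi_stats(t1map: "T1Map", loi: PolylineLOI, weights: str = "uniform") -> SampleStats:
    """Mean and SD of T1 over the pixels crossed by an LOI.

    ``weights='uniform'`` (default) averages each crossed pixel once —
    the literal "pixels crossed by the line" rule.  ``weights='length'``
    weights each pixel by the chord length (in mm) the line traverses
    inside it, provided for sensitivity analysis.
    """
    pixels = trace_loi_pixels(loi, t1map.shape)
    values = np.array([t1map.values[r, c] for r, c in pixels])
    if weights == "uniform":
        w = None
    elif weights == "length":
        spacing = np.asarray(t1map.pixel_spacing)
        rows, cols = t1map.shape
        chords = {
            (r, c): float(np.hypot(*(vec * spacing)))
            for r, c, vec in _iter_crossed(loi)
            if 0 <= r < rows and 0 <= c < cols
        }
        w = np.array([chords[p] for p in pixels])
    else:
        raise ValueError("weights must be 'uniform' or 'length'")
    return _stats_from_values(pixels, values, w)


# ---------------------------------------------------------------------------
# Polygon rasterization (pixel-center, even-odd rule)
# ---------------------------------------------------------------------------

def rasterize_polygon(roi: PolygonROI, shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Pixels whose center lies inside the polygon (even-odd rule).

    A center exactly on the boundary is resolved deterministically: the
    scanline uses half-open edge spans in the row direction and half-open
    crossing intervals ``[x_enter, x_exit)`` in the column direction, so
    left/top boundary centers are in, right/bottom ones out.
    """
    rows, cols = shape
    v = roi.vertices
    vr = np.append(v[:, 0], v[0, 0])
    vc = np.append(v[:, 1], v[0, 1])
    r_lo = max(0, math.floor(v[:, 0].min() - 0.5))
    r_hi = min(rows - 1, math.ceil(v[:, 0].max()))
    pixels: list[tuple[int, int]] = []
    for r in range(r_lo, r_hi + 1):
        y = r + 0.5
        xs = []
        for (y1, x1, y2, x2) in zip(vr[:-1], vc[:-1], vr[1:], vc[1:]):
            if (y1 <= y < y2) or (y2 <= y < y1):
                xs.append(x1 + (y - y1) / (y2 - y1) * (x2 - x1))
        xs.sort()
        for x0, x1 in zip(xs[::2], xs[1::2]):
            c0 = max(0, math.ceil(x0 - 0.5))
            c1 = min(cols - 1, math.ceil(x1 - 0.5) - 1)
            pixels.extend((r, c) for c in range(c0, c1 + 1))
    if not pixels:
        raise ValueError("polygon encloses no pixel center")
    return pixels


def roi_stats(t1map: "T1Map", roi: PolygonROI) -> SampleStats:
    """Mean and (population) SD of T1 over the pixels enclosed by an ROI."""
    pixels = rasterize_polygon(roi, t1map.shape)
    values = np.array([t1map.values[r, c] for r, c in pixels])
    return _stats_from_values(pixels, values, None)


# ---------------------------------------------------------------------------
# Wall thickness on a supersampled mask
# ---------------------------------------------------------------------------

def max_wall_thickness_px(
    myocardium_mask: np.ndarray,
    region: Iterable[tuple[int, int]],
    supersample_factor: int,
) -> WallThicknessGrade:
    """Maximum wall thickness (map pixels) of a mask within a pixel region.

    ``myocardium_mask`` is a binary mask rendered at ``supersample_factor``
    subpixels per map pixel; ``region`` lists map-resolution (r, c) pixels
    (e.g. an ROI's pixel set).  Thickness is read off a Euclidean distance
    transform evaluated on the mask's medial-axis skeleton.  The mask is
    first upsampled x2 so a ribbon of w subpixels always has an even width
    and the center-to-background distance equals w exactly, removing the
    half-subpixel parity bias of the raw transform.

    An empty intersection of mask and region yields thickness 0, grade 3.
    """
    from scipy.ndimage import distance_transform_edt
    from skimage.morphology import skeletonize

    mask = np.asarray(myocardium_mask, dtype=bool)
    s = int(supersample_factor)
    if s < 1:
        raise ValueError("supersample_factor must be a positive integer")
    region = list(region)
    reg_map = np.zeros(
        (math.ceil(mask.shape[0] / s), math.ceil(mask.shape[1] / s)), dtype=bool
    )
    for r, c in region:
        if 0 <= r < reg_map.shape[0] and 0 <= c < reg_map.shape[1]:
            reg_map[r, c] = True
    reg_sup = np.repeat(np.repeat(reg_map, 2 * s, axis=0), 2 * s, axis=1)
    m2 = np.repeat(np.repeat(mask, 2, axis=0), 2, axis=1)
    reg_sup = reg_sup[: m2.shape[0], : m2.shape[1]]
    if not (m2 & reg_sup).any():
        return WallThicknessGrade(0.0, 3)
    # Crop to the mask bounding box (plus a background ring); the distance
    # transform is unchanged because everything outside the box is zero.
    rs, cs = np.nonzero(m2)
    r0 = max(0, rs.min() - 1)
    r1 = min(m2.shape[0], rs.max() + 2)
    c0 = max(0, cs.min() - 1)
    c1 = min(m2.shape[1], cs.max() + 2)
    m2 = m2[r0:r1, c0:c1]
    reg_sup = reg_sup[r0:r1, c0:c1]
    dt = distance_transform_edt(m2)
    sel = skeletonize(m2) & reg_sup
    if not sel.any():
        # Region clips the skeleton away entirely; fall back to the best
        # in-region bound (underestimates true thickness).
        sel = m2 & reg_sup
    thickness = float(dt[sel].max() / s)
    return WallThicknessGrade(thickness, grade_from_thickness(thickness))
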