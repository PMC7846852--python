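"""Reading and writing T1 parametric maps and operator geometry.

Two on-disk map dialects are supported:

* ``text_matrix`` — a diffable plain-text format.  The first line is
  ``rows cols spacing_r spacing_c phase orientation``; the remaining lines
  hold whitespace-separated T1 values in ms, with ``nan`` marking invalid
  pixels.
* ``dicom`` — a single-frame parametric map.  Pixel data are unsigned
  16-bit with ``RescaleSlope``/``RescaleIntercept``; the raw value 0xFFFF
  is reserved as the NaN sentinel.

Coordinate convention (used by every module in this package): pixel
``(r, c)`` occupies the half-open square ``[r, r+1) x [c, c+1)``;
continuous coordinates are ``(row, col)`` with the origin at the top-left
corner of pixel ``(0, 0)``, so the pixel center is ``(r + 0.5, c + 0.5)``.
Geometry sidecars (polygon ROIs and polyline LOIs with tissue tags) are
JSON files of vertex lists in these continuous coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sampling import PolygonROI, PolylineLOI

__all__ = [
    "T1Map",
    "GeometrySet",
    "TaggedShape",
    "SubjectRecord",
    "read_t1map",
    "write_t1map",
    "read_geometry",
    "write_geometry",
    "PLAUSIBLE_MAX_MS",
]

#: Upper plausibility bound for myocardial/blood T1 in ms.  Values outside
#: [0, PLAUSIBLE_MAX_MS] are replaced by NaN on load and counted.
PLAUSIBLE_MAX_MS = 5000.0

PHASES = ("native", "post")
ORIENTATIONS = ("SAX", "TRANS")
TISSUE_TAGS = ("RV_myocardium", "LV_myocardium", "blood_pool")

# DICOM storage parameters: ms = raw * slope + intercept.
_DICOM_SLOPE = 0.1
_DICOM_INTERCEPT = 0.0
_NAN_SENTINEL = 0xFFFF


@dataclass
class T1Map:
    """A 2D T1 parametric map in ms with pixel-spacing metadata.

    Parameters
    ----------
    values : ndarray
        2D grid of T1 values in ms.  NaN marks invalid pixels.
    pixel_spacing : (float, float)
        (row, col) spacing in mm; strictly positive.
    phase : {'native', 'post'}
        Pre- or post-contrast acquisition.
    orientation : {'SAX', 'TRANS'}
        Short-axis or transverse imaging plane.
    subject_id : str
        Free-text subject identifier.
    acquisition_delay_min : float, optional
        Minutes between contrast bolus and acquisition (post maps).
    n_implausible : int
        Number of pixels replaced by NaN on load because they fell outside
        the plausibility bound.
    """

    values: np.ndarray
    pixel_spacing: tuple[float, float]
    phase: str
    orientation: str = "SAX"
    subject_id: str = ""
    acquisition_delay_min: float | None = None
    n_implausible: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("T1Map values must be a 2D rectangular grid")
        if min(self.values.shape) < 8:
            warnings.warn(
                f"T1 map grid {self.values.shape} is smaller than 8x8; "
                "statistics on such maps are unreliable",
                stacklevel=2,
            )
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if not all(s > 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing must be strictly positive in both axes")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > PLAUSIBLE_MAX_MS):
            raise ValueError(
                "finite T1 values must lie in [0, "
                f"{PLAUSIBLE_MAX_MS}] ms; screen inputs with read_t1map"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _screen_plausibility(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace out-of-range pixels by NaN, returning the count replaced."""
    values = np.asarray(values, dtype=float)
    bad = np.isfinite(values) & ((values < 0) | (values > PLAUSIBLE_MAX_MS))
    n_bad = int(bad.sum())
    if n_bad:
        values = values.copy()
        values[bad] = np.nan
    return values, n_bad


# ---------------------------------------------------------------------------
# text_matrix dialect
# ---------------------------------------------------------------------------

def _read_text(path: Path) -> T1Map:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 6:
            raise ValueError(
                "text_matrix header must be 'rows cols spacing_r spacing_c "
                f"phase orientation', got {header!r}"
            )
        rows, cols = int(header[0]), int(header[1])
        spacing = (float(header[2]), float(header[3]))
        phase, orientation = header[4], header[5]
        data = [line.split() for line in fh if line.strip()]
    if len(data) != rows or any(len(row) != cols for row in data):
        raise ValueError(
            f"text matrix is not rectangular {rows}x{cols} as declared"
        )
    values = np.array([[float(v) for v in row] for row in data])
    values, n_bad = _screen_plausibility(values)
    return T1Map(values, spacing, phase, orientation, n_implausible=n_bad)


def _write_text(m: T1Map, path: Path) -> None:
    rows, cols = m.shape
    with open(path, "w") as fh:
        fh.write(
            f"{rows} {cols} {m.pixel_spacing[0]!r} {m.pixel_spacing[1]!r} "
            f"{m.phase} {m.orientation}\n"
        )
        for row in m.values:
            fh.write(" ".join("nan" if not np.isfinite(v) else repr(float(v)) for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# DICOM dialect (single-frame parametric map)
# ---------------------------------------------------------------------------

def _read_dicom(path: Path) -> T1Map:
    import pydicom

    ds = pydicom.dcmread(path)
    if "PixelSpacing" not in ds:
        raise ValueError(f"DICOM file {path} has no PixelSpacing; cannot load")
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    raw = ds.pixel_array.astype(np.int64)
    values = raw * slope + intercept
    values[raw == _NAN_SENTINEL] = np.nan
    phase, orientation, delay = "native", "SAX", None
    for item in str(getattr(ds, "ImageComments", "")).split(";"):
        if "=" not in item:
            continue
        key, val = item.split("=", 1)
        if key == "phase":
            phase = val
        elif key == "orientation":
            orientation = val
        elif key == "delay_min" and val != "None":
            delay = float(val)
    values, n_bad = _screen_plausibility(values)
    return T1Map(
        values,
        spacing,
        phase,
        orientation,
        subject_id=str(getattr(ds, "PatientID", "")),
        acquisition_delay_min=delay,
        n_implausible=n_bad,
    )


def _write_dicom(m: T1Map, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.PatientID = m.subject_id
    ds.SeriesDescription = f"T1MAP {m.phase} {m.orientation}"
    ds.ImageComments = (
        f"phase={m.phase};orientation={m.orientation};delay_min={m.acquisition_delay_min}"
    )
    ds.Rows, ds.Columns = m.shape
    ds.PixelSpacing = [m.pixel_spacing[0], m.pixel_spacing[1]]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = _DICOM_SLOPE
    ds.RescaleIntercept = _DICOM_INTERCEPT
    raw = np.round((m.values - _DICOM_INTERCEPT) / _DICOM_SLOPE)
    raw = np.where(np.isfinite(m.values), raw, _NAN_SENTINEL)
    if np.any((raw < 0) | (raw > _NAN_SENTINEL)):
        raise ValueError("T1 values do not fit the 16-bit DICOM encoding")
    ds.PixelData = raw.astype(np.uint16).tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)


def read_t1map(path: str | Path, dialect: str) -> T1Map:
    """Load a T1 map from ``path`` in the named dialect.

    Pixels outside the plausibility bound [0, 5000] ms are replaced by NaN
    and counted in the returned map's ``n_implausible`` field; plausible
    values are never altered (text round trips bit-exactly, DICOM to within
    the 0.1 ms/LSB quantization).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "text_matrix":
        return _read_text(path)
    if dialect == "dicom":
        return _read_dicom(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_t1map(m: T1Map, path: str | Path, dialect: str) -> None:
    """Write a T1 map; inverse of :func:`read_t1map` for finite pixels."""
    path = Path(path)
    if dialect == "text_matrix":
        _write_text(m, path)
    elif dialect == "dicom":
        _write_dicom(m, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Geometry sidecar (JSON)
# ---------------------------------------------------------------------------

@dataclass
class TaggedShape:
    """A named ROI or LOI carrying exactly one tissue tag."""

    name: str
    tissue: str
    shape: "PolygonROI | PolylineLOI"

    def __post_init__(self) -> None:
        if self.tissue not in TISSUE_TAGS:
            raise ValueError(f"tissue must be one of {TISSUE_TAGS}, got {self.tissue!r}")


@dataclass
class GeometrySet:
    """Operator geometry for one subject: polygon ROIs and polyline LOIs."""

    rois: list[TaggedShape] = field(default_factory=list)
    lois: list[TaggedShape] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.name for t in self.rois] + [t.name for t in self.lois]
        if len(names) != len(set(names)):
            raise ValueError("geometry names must be unique within a GeometrySet")

    def find_rois(self, tissue: str) -> list[TaggedShape]:
        return [t for t in self.rois if t.tissue == tissue]

    def find_lois(self, tissue: str) -> list[TaggedShape]:
        return [t for t in self.lois if t.tissue == tissue]


def _polygon_self_intersects(vertices: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return not Polygon([(float(c), float(r)) for r, c in vertices]).is_valid


def read_geometry(path: str | Path) -> GeometrySet:
    """Load a JSON geometry sidecar.

    Self-intersecting polygons load with a warning; ROIs with fewer than 3
    vertices or LOIs with fewer than 2 are hard errors.
    """
    with open(path) as fh:
        doc = json.load(fh)
    rois, lois = [], []
    for item in doc.get("rois", []):
        verts = np.asarray(item["vertices"], dtype=float)
        if verts.ndim != 2 or len(verts) < 3:
            raise ValueError(f"ROI {item.get('name')!r} needs at least 3 vertices")
        if _polygon_self_intersects(verts):
            warnings.warn(f"ROI {item['name']!r} is self-intersecting", stacklevel=2)
        rois.append(TaggedShape(item["name"], item["tissue"], PolygonROI(verts)))
    for item in doc.get("lois", []):
        verts = np.asarray(item["vertices"], dtype=float)
        if verts.ndim != 2 or len(verts) < 2:
            raise ValueError(f"LOI {item.get('name')!r} needs at least 2 vertices")
        lois.append(TaggedShape(item["name"], item["tissue"], PolylineLOI(verts)))
    return GeometrySet(rois, lois)


def write_geometry(geometry: GeometrySet, path: str | Path) -> None:
    """Write a geometry sidecar; lossless inverse of :func:`read_geometry`."""
    doc = {
        "rois": [
            {"name": t.name, "tissue": t.tissue,
             "vertices": [[float(r), float(c)] for r, c in t.shape.vertices]}
            for t in geometry.rois
        ],
        "lois": [
            {"name": t.name, "tissue": t.tissue,
             "vertices": [[float(r), float(c)] for r, c in t.shape.vertices]}
            for t in geometry.lois
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


@dataclass
class SubjectRecord:
    """Everything known about one subject prior to ECV computation.

    ``wall_grade`` may be supplied from visual grading or measured with
    :func:`rvecv.sampling.max_wall_thickness_px`; ``None`` means ungraded
    (treated as measurable for feasibility purposes).
    """

    subject_id: str
    hematocrit: float
    maps: list[T1Map] = field(default_factory=list)
    geometry: GeometrySet = field(default_factory=GeometrySet)
    quality_grade_native: int = 1
    quality_grade_post: int = 1
    wall_grade: int | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.hematocrit) and not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in the open interval (0, 1)")
        for g in (self.quality_grade_native, self.quality_grade_post):
            if g not in (1, 2, 3):
                raise ValueError("quality grades must be 1, 2 or 3")
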