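"""Extracellular volume fraction (ECV) from paired T1 maps and hematocrit.

The central quantity is the myocardial ECV,

    ECV = (1 - Hct) * [ (1/T1_myo_post - 1/T1_myo_pre)
                        / (1/T1_blood_post - 1/T1_blood_pre) ],

the ratio of contrast-induced relaxation-rate changes (Delta R1) in
myocardium and blood, scaled by the plasma fraction (1 - hematocrit).
Delta R1 is proportional to local gadolinium concentration, so the ratio
estimates the myocardial distribution volume of the extracellular contrast
agent — a marker of diffuse interstitial expansion (fibrosis).

T1 is in ms throughout; R1 is computed in 1/ms and the unit cancels in the
ratio, so ECV is invariant under a common rescaling of all four T1 values.

The module also enforces the feasibility rules for thin-walled structures:
a measurement is attempted only when image quality allows blood/myocardium
distinction (quality grade <= 2), the maximum wall thickness per ROI is at
least one pixel (wall grade <= 2), and both native and post-contrast maps
exist.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sampling
from .maps_io import SubjectRecord, T1Map

__all__ = [
    "SubjectMeasurement",
    "FeasibilityVerdict",
    "compute_ecv",
    "derive_post_t1_myo",
    "assess_feasibility",
    "subject_ecv_table",
    "cohort_summary",
]

log = logging.getLogger(__name__)


class InvalidBloodKineticsError(ValueError):
    """Blood Delta R1 is zero or negative: post T1 must be below native."""


@dataclass
class SubjectMeasurement:
    """The five scalars entering the ECV equation plus the result."""

    subject_id: str
    structure: str  # 'RV' | 'LV'
    method: str  # 'ROI' | 'LOI'
    orientation: str  # 'SAX' | 'TRANS'
    t1_myo_pre: float
    t1_myo_post: float
    t1_blood_pre: float
    t1_blood_post: float
    hematocrit: float
    ecv: float
    valid: bool = True


@dataclass
class FeasibilityVerdict:
    """Whether ECV can be measured, with machine-readable reasons if not."""

    measurable: bool
    reasons: list[str] = field(default_factory=list)


def compute_ecv(
    t1_myo_pre: float,
    t1_myo_post: float,
    t1_blood_pre: float,
    t1_blood_post: float,
    hematocrit: float,
) -> float:
    """Myocardial ECV from pre/post T1 of myocardium and blood and Hct.

    All T1 in ms (any common unit works — the rate ratio is unit-free).
    ``hematocrit`` must lie in (0, 1]; the degenerate value 1 gives ECV 0.
    A non-positive blood Delta R1 is a hard error ("invalid blood
    kinetics"); a negative myocardial Delta R1 yields a negative ECV with
    a warning, surfacing acquisition problems instead of clipping them.
    """
    for name, t1 in (
        ("t1_myo_pre", t1_myo_pre),
        ("t1_myo_post", t1_myo_post),
        ("t1_blood_pre", t1_blood_pre),
        ("t1_blood_post", t1_blood_post),
    ):
        if not t1 > 0:
            raise ValueError(f"{name} must be positive, got {t1}")
    if not 0 < hematocrit <= 1:
        raise ValueError(f"hematocrit must be in (0, 1], got {hematocrit}")
    dr1_blood = 1.0 / t1_blood_post - 1.0 / t1_blood_pre
    if dr1_blood <= 0:
        raise InvalidBloodKineticsError(
            "invalid blood kinetics: post-contrast blood T1 must be shorter "
            f"than native (Delta R1 = {dr1_blood:.3g} 1/ms)"
        )
    dr1_myo = 1.0 / t1_myo_post - 1.0 / t1_myo_pre
    if dr1_myo < 0:
        warnings.warn(
            "negative myocardial Delta R1: post T1 exceeds native; "
            "returning a negative (flagged) ECV",
            stacklevel=2,
        )
    return (1.0 - hematocrit) * (dr1_myo / dr1_blood)


def derive_post_t1_myo(
    target_ecv: float,
    hematocrit: float,
    t1_myo_pre: float,
    t1_blood_pre: float,
    t1_blood_post: float,
) -> float:
    """Analytic inverse of :func:`compute_ecv` in its myocardial-post slot.

    Returns the post-contrast myocardial T1 for which ``compute_ecv``
    round-trips to ``target_ecv`` exactly:

        1/T1_post = 1/T1_pre + ECV/(1-Hct) * Delta R1_blood.

    Used by the phantom generator to plant ground-truth ECV.
    """
    if not 0 < hematocrit < 1:
        raise ValueError("hematocrit must be in (0, 1)")
    if not 0 < target_ecv <= 1 - hematocrit:
        raise ValueError(
            f"target_ecv must lie in (0, 1 - hematocrit]; got {target_ecv} "
            f"with hematocrit {hematocrit}"
        )
    dr1_blood = 1.0 / t1_blood_post - 1.0 / t1_blood_pre
    if dr1_blood <= 0:
        raise InvalidBloodKineticsError("blood Delta R1 must be positive")
    r1_post = 1.0 / t1_myo_pre + target_ecv / (1.0 - hematocrit) * dr1_blood
    if r1_post <= 0:
        raise ValueError("parameters imply a non-positive post-contrast R1")
    return 1.0 / r1_post


def assess_feasibility(
    quality_grade: int,
    wall_grade: int | None,
    maps_present: bool = True,
) -> FeasibilityVerdict:
    """Apply the feasibility rules for a thin-wall ECV measurement.

    Measurable iff quality grade <= 2 (sufficient blood/myocardium
    contrast), wall grade <= 2 (maximum wall thickness per ROI >= 1 px)
    and both native and post maps are present.  ``wall_grade=None`` means
    ungraded and does not block measurement.
    """
    if quality_grade not in (1, 2, 3):
        raise ValueError("quality_grade must be 1, 2 or 3")
    if wall_grade not in (None, 1, 2, 3):
        raise ValueError("wall_grade must be 1, 2, 3 or None")
    reasons = []
    if quality_grade > 2:
        reasons.append("insufficient_contrast")
    if wall_grade is not None and wall_grade > 2:
        reasons.append("wall_below_1px")
    if not maps_present:
        reasons.append("missing_map")
    return FeasibilityVerdict(not reasons, reasons)


# ---------------------------------------------------------------------------
# Per-subject measurement pipeline
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "subject_id", "structure", "method", "orientation",
    "t1_myo_pre", "t1_myo_post", "t1_blood_pre", "t1_blood_post",
    "hct", "ecv", "n_pixels_pre", "n_pixels_post", "measurable", "reasons",
]


def _maps_by_orientation(maps: list[T1Map]) -> dict[str, dict[str, T1Map]]:
    out: dict[str, dict[str, T1Map]] = {}
    for m in maps:
        out.setdefault(m.orientation, {})[m.phase] = m
    return out


def _measure_structure(
    native: T1Map,
    post: T1Map,
    item: "sampling.PolygonROI | sampling.PolylineLOI",
    blood_roi: sampling.PolygonROI,
    hct: float,
) -> tuple[float, dict[str, float]]:
    """Sample one myocardial geometry on both phases and compute ECV."""
    if isinstance(item, sampling.PolylineLOI):
        myo_pre = sampling.loi_stats(native, item)
        myo_post = sampling.loi_stats(post, item)
    else:
        myo_pre = sampling.roi_stats(native, item)
        myo_post = sampling.roi_stats(post, item)
    blood_pre = sampling.roi_stats(native, blood_roi)
    blood_post = sampling.roi_stats(post, blood_roi)
    ecv = compute_ecv(
        myo_pre.mean_t1, myo_post.mean_t1, blood_pre.mean_t1, blood_post.mean_t1, hct
    )
    detail = {
        "t1_myo_pre": myo_pre.mean_t1,
        "t1_myo_post": myo_post.mean_t1,
        "t1_blood_pre": blood_pre.mean_t1,
        "t1_blood_post": blood_post.mean_t1,
        "n_pixels_pre": myo_pre.n,
        "n_pixels_post": myo_post.n,
    }
    return ecv, detail


def subject_ecv_table(
    records: list[SubjectRecord],
    min_length_mm: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject ECV table: one row per subject x structure x method x
    orientation, measurable rows only.

    Subjects with missing hematocrit are skipped; structures failing the
    feasibility rules or the minimum-length rule are excluded.  Returns
    ``(table, exclusions)`` where ``exclusions`` lists every skipped
    subject/structure with its reason — the exclusion accounting every run
    must be able to audit.
    """
    rows, excluded = [], []

    def exclude(subject_id, structure, method, orientation, reason):
        excluded.append(
            {"subject_id": subject_id, "structure": structure, "method": method,
             "orientation": orientation, "reason": reason}
        )
        log.info("excluded %s %s/%s/%s: %s", subject_id, structure, method,
                 orientation, reason)

    for rec in records:
        if not np.isfinite(rec.hematocrit):
            exclude(rec.subject_id, "*", "*", "*", "missing_hematocrit")
            continue
        quality = max(rec.quality_grade_native, rec.quality_grade_post)
        for orientation, phases in _maps_by_orientation(rec.maps).items():
            native, post = phases.get("native"), phases.get("post")
            if native is None or post is None:
                exclude(rec.subject_id, "*", "*", orientation, "missing_map")
                continue
            blood_rois = rec.geometry.find_rois("blood_pool")
            if not blood_rois:
                exclude(rec.subject_id, "*", "*", orientation, "missing_blood_roi")
                continue
            blood_roi = blood_rois[0].shape
            for structure in ("RV", "LV"):
                tissue = f"{structure}_myocardium"
                items = [("ROI", t.shape) for t in rec.geometry.find_rois(tissue)]
                items += [("LOI", t.shape) for t in rec.geometry.find_lois(tissue)]
                wall_grade = rec.wall_grade if structure == "RV" else None
                verdict = assess_feasibility(quality, wall_grade, True)
                for method, shape in items:
                    if not verdict.measurable:
                        exclude(rec.subject_id, structure, method, orientation,
                                ",".join(verdict.reasons))
                        continue
                    ok, length = sampling.validate_min_length(
                        shape, native.pixel_spacing, min_length_mm
                    )
                    if not ok:
                        exclude(rec.subject_id, structure, method, orientation,
                                f"below_min_length({length:.1f}mm)")
                        continue
                    try:
                        ecv, detail = _measure_structure(
                            native, post, shape, blood_roi, rec.hematocrit
                        )
                    except (ValueError, InvalidBloodKineticsError) as err:
                        exclude(rec.subject_id, structure, method, orientation,
                                f"measurement_error({err})")
                        continue
                    rows.append(
                        {"subject_id": rec.subject_id, "structure": structure,
                         "method": method, "orientation": orientation,
                         **detail, "hct": rec.hematocrit, "ecv": ecv,
                         "measurable": True, "reasons": ""}
                    )
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    exclusions = pd.DataFrame(
        excluded, columns=["subject_id", "structure", "method", "orientation", "reason"]
    )
    return table, exclusions


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean +/- SD per structure x method x orientation cell.

    Summaries are of per-subject ECVs (never the ECV of mean T1s — the
    two differ because a mean of ratios is not the ratio of means).
    """
    if table.empty:
        return pd.DataFrame()
    grouped = table.groupby(["structure", "method", "orientation"])
    out = grouped.agg(
        n=("ecv", "size"),
        ecv_mean=("ecv", "mean"),
        ecv_sd=("ecv", lambda s: s.std(ddof=1)),
        t1_myo_pre_mean=("t1_myo_pre", "mean"),
        t1_myo_pre_sd=("t1_myo_pre", lambda s: s.std(ddof=1)),
        t1_myo_post_mean=("t1_myo_post", "mean"),
        t1_myo_post_sd=("t1_myo_post", lambda s: s.std(ddof=1)),
    )
    return out.reset_index()
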