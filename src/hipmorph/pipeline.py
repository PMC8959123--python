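"""End-to-end measurement engine: detection gate → reference lines →
indices → grades, for one detection bundle or a whole cohort."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .detection import DetectionBundle, head_radius_from_roi, suppress_point_c
from .geometry import (
    HipMeasurements,
    LandmarkSet,
    Point2D,
    build_reference_frame,
    measure_hip,
)
from .grading import GradingResult, ShentonInputs, grade_hip
from .io import measurements_to_frame

__all__ = ["CaseResult", "measure_bundle", "measure_cohort", "cohort_report"]


@dataclass(frozen=True)
class CaseResult:
    """Per-hip measurements and grades of one radiograph."""

    image_id: Optional[str]
    landmarks: LandmarkSet  # post-gating
    measurements: Dict[str, HipMeasurements]
    grades: Dict[str, GradingResult]


def _shenton_from_contours(contours, side: str) -> Optional[ShentonInputs]:
    if not contours or side not in contours:
        return None
    c = contours[side]
    if "pubic_arc" not in c or "neck_arc" not in c:
        return None
    return ShentonInputs(
        pubic_arc=[Point2D.of(p) for p in c["pubic_arc"]],
        neck_arc=[Point2D.of(p) for p in c["neck_arc"]],
    )


def measure_bundle(
    bundle: DetectionBundle,
    shenton_tol: float = 5.0,
    confidence_threshold: float = 0.5,
    gate_mode: str = "per_side",
) -> CaseResult:
    """Run the full stage-3 engine on one detection bundle.

    The femoral-head-center gate runs first, then reference lines are
    drawn once and every index and grade is derived from them.  The head
    radius per hip comes from that hip's ROI (equivalent-circle radius of
    the mask area); without an ROI, AHI and the Tönnis grade are absent.
    """
    lms = suppress_point_c(
        bundle, confidence_threshold=confidence_threshold, mode=gate_mode
    )
    frame = build_reference_frame(lms)
    measurements: Dict[str, HipMeasurements] = {}
    grades: Dict[str, GradingResult] = {}
    for side in ("left", "right"):
        hip = lms.hip(side)
        roi = bundle.roi(side)
        radius = None
        if roi is not None and roi.confidence >= confidence_threshold:
            radius = head_radius_from_roi(roi)
        shenton = _shenton_from_contours(bundle.contours, side)
        measurements[side] = measure_hip(
            hip,
            frame,
            head_radius=radius,
            shenton_inputs=shenton,
            shenton_tol=shenton_tol,
            pixel_spacing_mm=lms.pixel_spacing_mm,
        )
        grades[side] = grade_hip(hip, frame, head_radius=radius)
    return CaseResult(
        image_id=lms.image_id, landmarks=lms, measurements=measurements, grades=grades
    )


def measure_cohort(bundles: List[DetectionBundle], **kwargs) -> List[CaseResult]:
    """Measure every bundle of a cohort with shared engine settings."""
    return [measure_bundle(b, **kwargs) for b in bundles]


def cohort_report(results: List[CaseResult]) -> pd.DataFrame:
    """Flatten case results into the one-row-per-hip measurement report."""
    triples: List[Tuple] = []
    for r in results:
        for side in ("left", "right"):
            triples.append((r.image_id, r.measurements[side], r.grades[side]))
    return measurements_to_frame(triples)
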