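"""Landmark-provider interface and the segmentation-gated suppression of
false femoral-head-center detections.

The learned stages of the original pipeline (instance segmentation of the
bony pelvis, heat-map landmark regression) are deliberately *not*
re-implemented here; instead a small provider protocol preserves the
pipeline topology so any detector can be plugged in.  Two providers ship
with the package: an oracle provider that reads synthetic ground truth
(with optional Gaussian jitter emulating detector error) and a file
provider that reads the landmark-JSON interchange format.

The gate itself encodes one coupling rule: the femoral-head ossific nucleus
may be invisible in young infants, so a detected "point C" is only trusted
when a femoral-head ROI exists for that hip; otherwise C is suppressed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Protocol

import numpy as np

from .geometry import HipLandmarks, LandmarkSet, Point2D

__all__ = [
    "FemoralHeadROI",
    "DetectionBundle",
    "suppress_point_c",
    "extract_patch",
    "head_radius_from_roi",
    "LandmarkProvider",
    "OracleProvider",
    "FileProvider",
]

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE_THRESHOLD = 0.5
DEFAULT_PATCH_SIZE = 256


@dataclass(frozen=True)
class FemoralHeadROI:
    """A femoral-head region of interest from segmentation."""

    side: str
    bbox: tuple  # (x_min, y_min, x_max, y_max) pixels
    mask_area: float = 0.0  # pixels²
    confidence: float = 1.0

    def __post_init__(self):
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate ROI box {self.bbox}")
        if self.mask_area < 0:
            raise ValueError("mask_area must be non-negative")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class DetectionBundle:
    """Raw detector output before gating: landmarks (possibly with spurious
    C points), femoral-head ROIs (possibly empty) and optional bone
    contours keyed by bone name per side."""

    landmarks: LandmarkSet
    head_rois: List[FemoralHeadROI] = field(default_factory=list)
    contours: Optional[dict] = None

    def __post_init__(self):
        sides = [r.side for r in self.head_rois]
        if len(sides) != len(set(sides)):
            raise ValueError("duplicate femoral-head ROI for one side")

    def roi(self, side: str) -> Optional[FemoralHeadROI]:
        for r in self.head_rois:
            if r.side == side:
                return r
        return None


def suppress_point_c(
    bundle: DetectionBundle,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    mode: str = "per_side",
) -> LandmarkSet:
    """Drop C landmarks not backed by a femoral-head ROI.

    ``per_side`` (default) suppresses C on a hip iff that hip has no ROI at
    or above the confidence threshold; ``global`` suppresses both C points
    whenever *no* ROI at all was detected.  E, Y and H always pass through
    untouched, and the operation is idempotent.
    """
    if mode not in ("per_side", "global"):
        raise ValueError(f"mode must be per_side or global, got {mode!r}")
    lms = bundle.landmarks

    def detected(side: str) -> bool:
        r = bundle.roi(side)
        return r is not None and r.confidence >= confidence_threshold

    any_detected = detected("left") or detected("right")

    def _gate(hip: HipLandmarks) -> HipLandmarks:
        keep = detected(hip.side) if mode == "per_side" else any_detected
        if hip.C is not None and not keep:
            logger.info(
                "suppressing point C on %s hip: no femoral-head ROI", hip.side
            )
            return replace(hip, C=None)
        return hip

    return replace(lms, left=_gate(lms.left), right=_gate(lms.right))


def extract_patch(
    image: np.ndarray, center: Point2D, patch_size: int = DEFAULT_PATCH_SIZE
):
    """Crop a square patch around ``center``, clipped to the image bounds.

    Returns ``(patch, offset)`` where ``offset`` is the (x, y) of the
    patch's top-left corner in image coordinates, so that
    ``patch_xy + offset = image_xy``.
    """
    h, w = image.shape[:2]
    cx, cy = center.x, center.y
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"patch center ({cx}, {cy}) outside image {w}x{h}")
    half = patch_size // 2
    x0 = max(0, int(math.floor(cx)) - half)
    y0 = max(0, int(math.floor(cy)) - half)
    x1 = min(w, x0 + patch_size)
    y1 = min(h, y0 + patch_size)
    x0 = max(0, x1 - patch_size)
    y0 = max(0, y1 - patch_size)
    return image[y0:y1, x0:x1], (float(x0), float(y0))


def head_radius_from_roi(roi: FemoralHeadROI) -> float:
    """Head radius in pixels: the equivalent-circle radius of the mask area
    when a mask exists, else a quarter of the mean box side."""
    if roi.mask_area > 0:
        return math.sqrt(roi.mask_area / math.pi)
    x0, y0, x1, y1 = roi.bbox
    return ((x1 - x0) + (y1 - y0)) / 2.0 / 4.0


class LandmarkProvider(Protocol):
    """Anything that can produce a :class:`DetectionBundle` for an image."""

    def provide(self, image=None) -> DetectionBundle: ...


class OracleProvider:
    """Reads synthetic ground truth and adds isotropic Gaussian jitter of
    standard deviation ``sigma_px`` per coordinate, emulating detector error.

    Ground truth landmarks stay clean inside the case; only the emitted
    bundle is jittered.  Deterministic for a fixed seed.
    """

    def __init__(self, case, sigma_px: float = 0.0, seed: Optional[int] = None):
        self.case = case
        self.sigma_px = float(sigma_px)
        self.seed = seed

    def provide(self, image=None) -> DetectionBundle:
        rng = np.random.default_rng(self.seed)
        lms = self.case.truth

        def _jit(p: Optional[Point2D]) -> Optional[Point2D]:
            if p is None:
                return None
            if self.sigma_px == 0.0:
                return p
            dx, dy = rng.normal(0.0, self.sigma_px, size=2)
            return Point2D(p.x + dx, p.y + dy)

        def _hip(h: HipLandmarks) -> HipLandmarks:
            return replace(h, E=_jit(h.E), Y=_jit(h.Y), C=_jit(h.C), H=_jit(h.H))

        jittered = replace(lms, left=_hip(lms.left), right=_hip(lms.right))
        base = self.case.bundle
        return DetectionBundle(
            landmarks=jittered, head_rois=list(base.head_rois), contours=base.contours
        )


class FileProvider:
    """Reads a landmark-JSON file (the package interchange dialect)."""

    def __init__(self, path):
        self.path = path

    def provide(self, image=None) -> DetectionBundle:
        from .io import read_bundle_json

        return read_bundle_json(self.path)
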