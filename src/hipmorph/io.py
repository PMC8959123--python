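"""Landmark-JSON interchange dialect, measurement-report CSV, and cohort
directory layout.

The canonical landmark file is::

    {
      "image_id": "case_0001",
      "pixel_spacing_mm": 0.2,            # optional
      "hips": {
        "left":  {"E": [x, y], "Y": [x, y], "C": [x, y] | null, "H": [x, y]},
        "right": {...}
      },
      "head_rois": [ {"side": "left", "bbox": [x0, y0, x1, y1],
                      "mask_area": 1256.6, "confidence": 0.98}, ... ],   # optional
      "contours": {"left": {"pubic_arc": [[x, y], ...],
                            "neck_arc": [[x, y], ...]}, ...},            # optional
      "canvas_transform": {...}                                          # optional
    }

Absent C is encoded as ``null``.  ``lateral_sign`` may be given per hip to
override the AP-view default (patient-left hip on image right).
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import List, Optional

import pandas as pd

from .detection import DetectionBundle, FemoralHeadROI
from .geometry import HipLandmarks, LandmarkSet, Point2D, default_lateral_sign

__all__ = [
    "read_landmark_json",
    "write_landmark_json",
    "read_bundle_json",
    "write_bundle_json",
    "measurements_to_frame",
    "write_cohort",
    "read_cohort_landmarks",
    "SchemaError",
]


class SchemaError(ValueError):
    """Malformed landmark JSON."""


def _parse_point(obj, name: str, side: str) -> Optional[Point2D]:
    if obj is None:
        return None
    try:
        return Point2D.of(obj)
    except Exception as exc:
        raise SchemaError(f"bad {side}.{name} coordinate {obj!r}: {exc}") from exc


def _parse_hip(d: dict, side: str) -> HipLandmarks:
    missing = [k for k in ("E", "Y", "H") if k not in d]
    if missing:
        raise SchemaError(f"{side} hip missing required landmarks {missing}")
    return HipLandmarks(
        side=side,
        E=_parse_point(d["E"], "E", side),
        Y=_parse_point(d["Y"], "Y", side),
        H=_parse_point(d["H"], "H", side),
        C=_parse_point(d.get("C"), "C", side),
        lateral_sign=int(d.get("lateral_sign", default_lateral_sign(side))),
    )


def _landmarks_from_dict(data: dict) -> LandmarkSet:
    if "hips" not in data or not isinstance(data["hips"], dict):
        raise SchemaError("landmark JSON must have a 'hips' object")
    hips = data["hips"]
    for side in ("left", "right"):
        if side not in hips:
            raise SchemaError(f"'hips' object missing side {side!r}")
    spacing = data.get("pixel_spacing_mm")
    return LandmarkSet(
        left=_parse_hip(hips["left"], "left"),
        right=_parse_hip(hips["right"], "right"),
        pixel_spacing_mm=None if spacing is None else float(spacing),
        image_id=data.get("image_id"),
    )


def read_landmark_json(path) -> LandmarkSet:
    """Read a landmark file (landmarks only; ROIs/contours ignored)."""
    return read_bundle_json(path).landmarks


def read_bundle_json(path) -> DetectionBundle:
    """Read a landmark file including optional head ROIs and contours."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid JSON in {path}: {exc}") from exc
    lms = _landmarks_from_dict(data)
    rois = []
    for r in data.get("head_rois", []) or []:
        try:
            rois.append(
                FemoralHeadROI(
                    side=r["side"],
                    bbox=tuple(float(v) for v in r["bbox"]),
                    mask_area=float(r.get("mask_area", 0.0)),
                    confidence=float(r.get("confidence", 1.0)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"bad head ROI entry {r!r}: {exc}") from exc
    return DetectionBundle(landmarks=lms, head_rois=rois, contours=data.get("contours"))


def _hip_to_dict(h: HipLandmarks) -> dict:
    d = {
        "E": [h.E.x, h.E.y],
        "Y": [h.Y.x, h.Y.y],
        "C": None if h.C is None else [h.C.x, h.C.y],
        "H": [h.H.x, h.H.y],
    }
    if h.lateral_sign != default_lateral_sign(h.side):
        d["lateral_sign"] = h.lateral_sign
    return d


def write_landmark_json(lms: LandmarkSet, path, canvas_transform=None) -> None:
    write_bundle_json(DetectionBundle(landmarks=lms), path, canvas_transform)


def write_bundle_json(bundle: DetectionBundle, path, canvas_transform=None) -> None:
    lms = bundle.landmarks
    data = {
        "image_id": lms.image_id,
        "pixel_spacing_mm": lms.pixel_spacing_mm,
        "hips": {"left": _hip_to_dict(lms.left), "right": _hip_to_dict(lms.right)},
    }
    if bundle.head_rois:
        data["head_rois"] = [
            {
                "side": r.side,
                "bbox": list(r.bbox),
                "mask_area": r.mask_area,
                "confidence": r.confidence,
            }
            for r in bundle.head_rois
        ]
    if bundle.contours:
        data["contours"] = bundle.contours
    if canvas_transform is not None:
        data["canvas_transform"] = canvas_transform.to_dict()
    Path(path).write_text(json.dumps(data, indent=1))


def measurements_to_frame(results) -> pd.DataFrame:
    """One row per hip from a list of (image_id, HipMeasurements,
    GradingResult) triples — the measurement-report layout."""
    rows = []
    for image_id, m, g in results:
        rows.append(
            {
                "image_id": image_id,
                "side": m.side,
                "acetabular_index_deg": m.acetabular_index_deg,
                "ce_angle_deg": m.ce_angle_deg,
                "ahi_percent": m.ahi_percent,
                "shenton": m.shenton,
                "head_radius_px": m.head_radius_px,
                "head_radius_mm": m.head_radius_mm,
                "tonnis": None if g is None or g.tonnis is None else int(g.tonnis),
                "ihdi": None if g is None else g.ihdi_roman,
                "boundary_flags": ""
                if g is None
                else ";".join(sorted(g.boundary_flags)),
            }
        )
    return pd.DataFrame(rows)


def write_cohort(cases, outdir, write_images: bool = False) -> pd.DataFrame:
    """Write a synthetic cohort as landmark JSON files plus a manifest CSV
    (and optionally rendered PNGs).  Returns the manifest."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, case in enumerate(cases):
        cid = case.params.image_id or f"case_{i:04d}"
        write_bundle_json(
            DetectionBundle(
                landmarks=replace(case.bundle.landmarks, image_id=cid),
                head_rois=case.bundle.head_rois,
                contours=case.bundle.contours,
            ),
            outdir / f"{cid}.json",
        )
        write_bundle_json(
            DetectionBundle(
                landmarks=replace(case.truth, image_id=cid),
                head_rois=case.bundle.head_rois,
                contours=case.bundle.contours,
            ),
            outdir / f"{cid}.truth.json",
        )
        if write_images:
            from .synthetic import render_image

            img = render_image(case)
            Image.fromarray(img).save(outdir / f"{cid}.png")
        p = case.params
        rows.append(
            {
                "case_id": cid,
                "ai_left": p.acetabular_index_deg.left,
                "ai_right": p.acetabular_index_deg.right,
                "ce_left": p.ce_angle_deg.left,
                "ce_right": p.ce_angle_deg.right,
                "disp_left_lat": p.displacement.left[0],
                "disp_left_sup": p.displacement.left[1],
                "disp_right_lat": p.displacement.right[0],
                "disp_right_sup": p.displacement.right[1],
                "rotation_deg": p.pelvic_rotation_deg,
                "noise_sigma_px": p.noise_sigma_px,
                "ihdi_left": case.truth_grades["left"].ihdi_roman,
                "ihdi_right": case.truth_grades["right"].ihdi_roman,
                "tonnis_left": case.truth_grades["left"].tonnis,
                "tonnis_right": case.truth_grades["right"].tonnis,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def read_cohort_landmarks(directory, truth: bool = False) -> List[LandmarkSet]:
    """Read all landmark files of a cohort directory, ordered by case id."""
    directory = Path(directory)
    suffix = ".truth.json" if truth else ".json"
    paths = sorted(
        p
        for p in directory.glob(f"*{suffix}")
        if truth or not p.name.endswith(".truth.json")
    )
    return [read_landmark_json(p) for p in paths]
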