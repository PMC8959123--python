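"""Core geometric types, reference lines, and radiographic hip indices.

All geometry lives in image (raster) coordinates: ``x`` increases rightward
along columns, ``y`` increases *downward* along rows, so "superior"
(toward the head) means smaller ``y``.  On a correctly displayed AP pelvis
radiograph the patient's left hip appears on the image-right half; each
:class:`HipLandmarks` therefore carries an explicit ``lateral_sign`` — the
sign of the image-x direction pointing away from the body midline for that
hip — so no function ever infers laterality from pixel position.

Angles are computed by projecting points into the *Hilgenreiner frame*: the
rotated coordinate system in which Hilgenreiner's line (through both
tri-radiate cartilage centers) is horizontal.  Signs are chosen so that a
normally formed hip yields a positive acetabular index and a positive
center-edge angle.  All angles are returned in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "Point2D",
    "Line2D",
    "HipLandmarks",
    "LandmarkSet",
    "ReferenceFrame",
    "HipMeasurements",
    "GeometryError",
    "hilgenreiner_line",
    "perkin_line",
    "ihdi_diagonal",
    "build_reference_frame",
    "acetabular_index",
    "center_edge_angle",
    "acetabular_head_index",
    "measure_hip",
]

_EPS = 1e-9


class GeometryError(ValueError):
    """Degenerate geometric input (coincident points, zero radius, ...)."""


class Point2D(NamedTuple):
    """A point in image coordinates (pixels); x = column, y = row."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    @staticmethod
    def of(obj) -> "Point2D":
        x, y = float(obj[0]), float(obj[1])
        if not (math.isfinite(x) and math.isfinite(y)):
            raise GeometryError(f"non-finite point coordinates: ({x}, {y})")
        return Point2D(x, y)


@dataclass(frozen=True)
class Line2D:
    """An infinite line given by an anchor point and a unit direction."""

    anchor: Point2D
    direction: Point2D  # unit vector

    def __post_init__(self):
        n = math.hypot(self.direction.x, self.direction.y)
        if abs(n - 1.0) > 1e-9:
            raise GeometryError(f"line direction must be unit length, got norm {n}")

    @property
    def normal(self) -> Point2D:
        """Unit normal obtained by rotating the direction +90° (x,y)→(−y,x)."""
        return Point2D(-self.direction.y, self.direction.x)

    def project_point(self, p: Point2D) -> Point2D:
        """Orthogonal projection of ``p`` onto the line."""
        d = self.direction
        t = (p.x - self.anchor.x) * d.x + (p.y - self.anchor.y) * d.y
        return Point2D(self.anchor.x + t * d.x, self.anchor.y + t * d.y)


@dataclass(frozen=True)
class HipLandmarks:
    """The four named landmarks of one hip.

    E: acetabulum superolateral (lateral bony rim) margin.
    Y: tri-radiate cartilage center.
    C: femoral head ossific-nucleus center; ``None`` when not ossified or
       suppressed by the detection gate.
    H: midpoint of the superior margin of the ossified femoral metaphysis.
    """

    side: str  # "left" | "right" (patient side)
    E: Point2D
    Y: Point2D
    H: Point2D
    C: Optional[Point2D] = None
    lateral_sign: int = 0  # +1 or -1; set explicitly or via default_lateral_sign

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        ls = self.lateral_sign if self.lateral_sign != 0 else default_lateral_sign(self.side)
        object.__setattr__(self, "lateral_sign", ls)
        if self.lateral_sign not in (+1, -1):
            raise ValueError("lateral_sign must be +1 or -1")
        if math.hypot(self.E.x - self.Y.x, self.E.y - self.Y.y) < _EPS:
            raise GeometryError("landmarks E and Y coincide")


def default_lateral_sign(side: str) -> int:
    """AP-view convention: patient-left hip sits on the image-right half,
    so 'lateral' (away from midline) is +x for the left hip, −x for the right."""
    return +1 if side == "left" else -1


@dataclass(frozen=True)
class LandmarkSet:
    """Bilateral landmarks of one radiograph, with optional pixel spacing."""

    left: HipLandmarks
    right: HipLandmarks
    pixel_spacing_mm: Optional[float] = None
    image_id: Optional[str] = None

    def __post_init__(self):
        d = math.hypot(self.left.Y.x - self.right.Y.x, self.left.Y.y - self.right.Y.y)
        if d < _EPS:
            raise GeometryError("left and right Y coincide; Hilgenreiner line undefined")

    def hip(self, side: str) -> HipLandmarks:
        return self.left if side == "left" else self.right


@dataclass(frozen=True)
class ReferenceFrame:
    """The stage-3 reference lines: Hilgenreiner's line, per-hip Perkin
    lines, and per-hip 45° IHDI diagonal (D) lines."""

    hilgenreiner: Line2D
    perkin_left: Line2D
    perkin_right: Line2D
    dline_left: Line2D
    dline_right: Line2D

    def perkin(self, side: str) -> Line2D:
        return self.perkin_left if side == "left" else self.perkin_right

    def dline(self, side: str) -> Line2D:
        return self.dline_left if side == "left" else self.dline_right


@dataclass(frozen=True)
class HipMeasurements:
    """Numeric indices plus the Shenton-line status of one hip.

    ``ce_angle_deg`` and ``ahi_percent`` are ``None`` when the femoral head
    center (or the head radius, for AHI) is unavailable.
    """

    side: str
    acetabular_index_deg: float
    ce_angle_deg: Optional[float] = None
    ahi_percent: Optional[float] = None
    shenton: str = "indeterminate"  # intact | disrupted | indeterminate
    head_radius_px: Optional[float] = None
    head_radius_mm: Optional[float] = None


# ---------------------------------------------------------------------------
# Hilgenreiner-frame helpers


def _frame_axes(hline: Line2D) -> tuple[Point2D, Point2D]:
    """Unit axes (u, v) of the Hilgenreiner frame in image coordinates.

    u points along the line with non-negative image-x (so image-right stays
    frame-right); v = rot90(u) points inferior (frame-y grows downward like
    image-y).
    """
    u = hline.direction
    if u.x < 0 or (u.x == 0 and u.y < 0):
        u = Point2D(-u.x, -u.y)
    v = Point2D(-u.y, u.x)
    return u, v


def to_hilgenreiner_frame(p: Point2D, hline: Line2D) -> Point2D:
    """Coordinates of ``p`` in the frame where ``hline`` is the x-axis.

    Returned y is signed distance from the line, positive on the inferior
    side (image convention: larger y = inferior).
    """
    u, v = _frame_axes(hline)
    dx, dy = p.x - hline.anchor.x, p.y - hline.anchor.y
    return Point2D(dx * u.x + dy * u.y, dx * v.x + dy * v.y)


# ---------------------------------------------------------------------------
# Reference-line construction


def hilgenreiner_line(Y_left: Point2D, Y_right: Point2D) -> Line2D:
    """Line through both tri-radiate cartilage centers, anchored at their
    midpoint."""
    dx, dy = Y_right.x - Y_left.x, Y_right.y - Y_left.y
    n = math.hypot(dx, dy)
    if n < _EPS:
        raise GeometryError("Y points coincide; cannot draw Hilgenreiner line")
    mid = Point2D((Y_left.x + Y_right.x) / 2.0, (Y_left.y + Y_right.y) / 2.0)
    return Line2D(mid, Point2D(dx / n, dy / n))


def perkin_line(E: Point2D, hline: Line2D) -> Line2D:
    """Perpendicular to Hilgenreiner's line through the lateral acetabular
    margin E."""
    return Line2D(E, hline.normal)


def ihdi_diagonal(E: Point2D, hline: Line2D, lateral_sign: int) -> Line2D:
    """45° inferolateral D-line from the Hilgenreiner–Perkin junction.

    The junction is the orthogonal projection of E onto Hilgenreiner's line;
    the ray runs at 45° toward lateral-inferior for the given hip.
    """
    junction = hline.project_point(E)
    u, v = _frame_axes(hline)
    s = 1.0 / math.sqrt(2.0)
    d = Point2D(s * (lateral_sign * u.x + v.x), s * (lateral_sign * u.y + v.y))
    return Line2D(junction, d)


def build_reference_frame(lms: LandmarkSet) -> ReferenceFrame:
    """Construct all stage-3 reference lines from a bilateral landmark set."""
    h = hilgenreiner_line(lms.left.Y, lms.right.Y)
    return ReferenceFrame(
        hilgenreiner=h,
        perkin_left=perkin_line(lms.left.E, h),
        perkin_right=perkin_line(lms.right.E, h),
        dline_left=ihdi_diagonal(lms.left.E, h, lms.left.lateral_sign),
        dline_right=ihdi_diagonal(lms.right.E, h, lms.right.lateral_sign),
    )


# ---------------------------------------------------------------------------
# Radiographic indices


def acetabular_index(E: Point2D, Y: Point2D, hline: Line2D) -> float:
    """Acetabular index: angle between the acetabular roof (Y→E) and
    Hilgenreiner's line, in degrees.

    Positive when E lies superior to the line through Y (the normal
    configuration); larger values mean a shallower, steeper acetabulum.
    """
    if math.hypot(E.x - Y.x, E.y - Y.y) < _EPS:
        raise GeometryError("E coincides with Y; acetabular roof degenerate")
    e = to_hilgenreiner_frame(E, hline)
    y = to_hilgenreiner_frame(Y, hline)
    run = abs(e.x - y.x)
    rise = abs(e.y - y.y)
    ang = math.degrees(math.atan2(rise, run))
    return ang if e.y <= y.y else -ang


def center_edge_angle(
    C: Point2D, E: Point2D, hline: Line2D, lateral_sign: int
) -> float:
    """Center-edge angle of Wiberg, in degrees.

    Measured at the femoral head center C between the superior perpendicular
    to Hilgenreiner's line and the ray C→E; positive when E is lateral to
    that perpendicular (normal coverage), negative when the rim falls medial
    of the head center (deficient coverage).
    """
    if math.hypot(E.x - C.x, E.y - C.y) < _EPS:
        raise GeometryError("E coincides with C; CE angle degenerate")
    c = to_hilgenreiner_frame(C, hline)
    e = to_hilgenreiner_frame(E, hline)
    lateral = lateral_sign * (e.x - c.x)
    superior = c.y - e.y
    return math.degrees(math.atan2(lateral, superior))


def acetabular_head_index(
    C: Point2D,
    head_radius: float,
    E: Point2D,
    hline: Line2D,
    lateral_sign: int,
) -> float:
    """Acetabular head index (AHI), percent of femoral head width covered
    by the bony roof.

    In the Hilgenreiner frame the head spans ``2·head_radius`` along the
    line; AHI = 100 × (distance from the medial head edge to E's projection,
    measured toward lateral) / head width.  100 means the rim reaches the
    lateral head edge (full cover); 50 means cover up to the head center;
    values are not clipped.
    """
    if head_radius <= 0:
        raise GeometryError(f"head radius must be positive, got {head_radius}")
    c = to_hilgenreiner_frame(C, hline)
    e = to_hilgenreiner_frame(E, hline)
    s_c = lateral_sign * c.x
    s_e = lateral_sign * e.x
    covered = s_e - (s_c - head_radius)
    return 100.0 * covered / (2.0 * head_radius)


def measure_hip(
    hip: HipLandmarks,
    frame: ReferenceFrame,
    head_radius: Optional[float] = None,
    shenton_inputs=None,
    shenton_tol: float = 5.0,
    pixel_spacing_mm: Optional[float] = None,
) -> HipMeasurements:
    """Assemble all stage-3 measurements of one hip.

    CE angle and AHI are reported absent when C is absent (AHI additionally
    requires a head radius); the Shenton status is ``indeterminate`` unless
    pubic/neck contour arcs are supplied.
    """
    hline = frame.hilgenreiner
    ai = acetabular_index(hip.E, hip.Y, hline)
    ce = ahi = None
    if hip.C is not None:
        ce = center_edge_angle(hip.C, hip.E, hline, hip.lateral_sign)
        if head_radius is not None:
            ahi = acetabular_head_index(
                hip.C, head_radius, hip.E, hline, hip.lateral_sign
            )
    shenton = "indeterminate"
    if shenton_inputs is not None:
        from .grading import shenton_check  # local import to avoid cycle

        shenton = shenton_check(shenton_inputs, tol=shenton_tol)
    r_mm = None
    if head_radius is not None and pixel_spacing_mm is not None:
        r_mm = head_radius * pixel_spacing_mm
    return HipMeasurements(
        side=hip.side,
        acetabular_index_deg=ai,
        ce_angle_deg=ce,
        ahi_percent=ahi,
        shenton=shenton,
        head_radius_px=head_radius,
        head_radius_mm=r_mm,
    )


# ---------------------------------------------------------------------------
# Transforms used by tests and the synthetic generator


def transform_point(p: Point2D, rotation_deg: float, center: Point2D, translation=(0.0, 0.0)) -> Point2D:
    """Rigid motion: rotate about ``center`` then translate."""
    a = math.radians(rotation_deg)
    ca, sa = math.cos(a), math.sin(a)
    dx, dy = p.x - center.x, p.y - center.y
    return Point2D(
        center.x + ca * dx - sa * dy + translation[0],
        center.y + sa * dx + ca * dy + translation[1],
    )


def transform_landmark_set(
    lms: LandmarkSet, rotation_deg: float, center: Point2D, translation=(0.0, 0.0)
) -> LandmarkSet:
    """Apply one rigid motion to every landmark of both hips."""

    def _hip(h: HipLandmarks) -> HipLandmarks:
        return replace(
            h,
            E=transform_point(h.E, rotation_deg, center, translation),
            Y=transform_point(h.Y, rotation_deg, center, translation),
            H=transform_point(h.H, rotation_deg, center, translation),
            C=None if h.C is None else transform_point(h.C, rotation_deg, center, translation),
        )

    return replace(lms, left=_hip(lms.left), right=_hip(lms.right))


def mirror_landmark_set(lms: LandmarkSet, axis_x: float) -> LandmarkSet:
    """Reflect the whole landmark set about the vertical line x = axis_x,
    swapping patient sides (a mirrored left hip becomes a right hip)."""

    def _pt(p: Optional[Point2D]) -> Optional[Point2D]:
        return None if p is None else Point2D(2.0 * axis_x - p.x, p.y)

    def _hip(h: HipLandmarks, new_side: str) -> HipLandmarks:
        return HipLandmarks(
            side=new_side,
            E=_pt(h.E),
            Y=_pt(h.Y),
            H=_pt(h.H),
            C=_pt(h.C),
            lateral_sign=default_lateral_sign(new_side),
        )

    return replace(lms, left=_hip(lms.right, "left"), right=_hip(lms.left, "right"))
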