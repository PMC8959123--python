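"""Rule-based Tönnis and IHDI dysplasia grading plus the geometric
Shenton-line continuity check.

Both graders work in the Hilgenreiner frame (Hilgenreiner's line
horizontal). The IHDI grade places the metaphysis midpoint H in one of the
four regions cut by Perkin's line, the 45° inferolateral D-line, and
Hilgenreiner's line, all through the Hilgenreiner–Perkin junction. The
Tönnis grade places the ossific-nucleus center C relative to Perkin's line
and a horizontal "rim band" of half-width equal to the head radius centered
at the level of the lateral rim E — a finite-size operationalisation of the
classical "at the level of the acetabular rim" wording.

Points lying exactly on a boundary resolve to the *lower* grade; every such
tie is recorded in ``boundary_flags`` for auditability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .geometry import (
    GeometryError,
    HipLandmarks,
    Point2D,
    ReferenceFrame,
    to_hilgenreiner_frame,
)

__all__ = [
    "GradingResult",
    "ShentonInputs",
    "ihdi_grade",
    "tonnis_grade",
    "shenton_check",
    "grade_hip",
    "IHDI_ROMAN",
]

IHDI_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV"}

_TIE_EPS = 1e-9  # boundary-flag detection only; comparisons themselves are exact


@dataclass(frozen=True)
class GradingResult:
    """Tönnis (1–4, absent without C) and IHDI (1–4, roman in reports)."""

    side: str
    ihdi: int
    tonnis: Optional[int] = None
    boundary_flags: frozenset = field(default_factory=frozenset)

    @property
    def ihdi_roman(self) -> str:
        return IHDI_ROMAN[self.ihdi]


@dataclass(frozen=True)
class ShentonInputs:
    """Contour arcs for the Shenton-line check: the inferior border of the
    superior pubic ramus and the medial femoral neck/metaphysis border."""

    pubic_arc: List[Point2D]
    neck_arc: List[Point2D]

    def __post_init__(self):
        if len(self.pubic_arc) < 3 or len(self.neck_arc) < 3:
            raise ValueError("each Shenton arc needs at least 3 points")


def _junction_coords(point: Point2D, E: Point2D, frame: ReferenceFrame, lateral_sign: int):
    """(lateral, inferior) coordinates of ``point`` relative to the
    Hilgenreiner–Perkin junction of this hip, in the Hilgenreiner frame."""
    h = frame.hilgenreiner
    p = to_hilgenreiner_frame(point, h)
    e = to_hilgenreiner_frame(E, h)
    lat = lateral_sign * (p.x - e.x)  # junction shares E's along-line coordinate
    inf = p.y  # Hilgenreiner line is y' = 0
    return lat, inf


def ihdi_grade(
    H: Point2D, frame: ReferenceFrame, side: str, lateral_sign: int, E: Point2D
) -> GradingResult:
    """IHDI grade of the H-point (metaphysis midpoint).

    I: at-or-medial to Perkin's line (and not above Hilgenreiner's line);
    II: lateral to Perkin's, at-or-medial to the 45° D-line;
    III: lateral to the D-line, at-or-inferior to Hilgenreiner's line;
    IV: strictly superior to Hilgenreiner's line.
    """
    lat, inf = _junction_coords(H, E, frame, lateral_sign)
    flags = set()
    if abs(inf) <= _TIE_EPS:
        flags.add("on_hline")
    if abs(lat) <= _TIE_EPS:
        flags.add("on_perkin")
    if abs(lat - inf) <= _TIE_EPS:
        flags.add("on_dline")
    if inf < 0:
        g = 4
    elif lat <= 0:
        g = 1
    elif lat <= inf:
        g = 2
    else:
        g = 3
    return GradingResult(side=side, ihdi=g, boundary_flags=frozenset(flags))


def tonnis_grade(
    C: Point2D,
    head_radius: float,
    frame: ReferenceFrame,
    E: Point2D,
    side: str,
    lateral_sign: int,
) -> int:
    """Tönnis grade of the ossific-nucleus center C.

    1: at-or-medial to Perkin's line; otherwise by superior-inferior level
    against the rim band (E's level ± head_radius): inferior to the band →
    2, within → 3, superior → 4.  Band edges tie toward the lower grade.
    """
    if head_radius <= 0:
        raise GeometryError(f"head radius must be positive, got {head_radius}")
    h = frame.hilgenreiner
    c = to_hilgenreiner_frame(C, h)
    e = to_hilgenreiner_frame(E, h)
    lat = lateral_sign * (c.x - e.x)
    if lat <= 0:
        return 1
    if c.y >= e.y + head_radius:
        return 2
    if c.y >= e.y - head_radius:
        return 3
    return 4


def _fit_circle(points: List[Point2D]):
    """Algebraic (Kåsa) least-squares circle fit; returns (cx, cy, r).

    Raises ``GeometryError`` when the points are collinear (singular system).
    """
    pts = np.asarray([[p.x, p.y] for p in points], dtype=float)
    A = np.column_stack([2.0 * pts[:, 0], 2.0 * pts[:, 1], np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise GeometryError("pubic arc points are collinear; circle fit singular")
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0 or not np.isfinite(r2):
        raise GeometryError("degenerate circle fit")
    return cx, cy, math.sqrt(r2)


def shenton_check(inputs: ShentonInputs, tol: float = 5.0) -> str:
    """Geometric Shenton-line continuity check.

    Fits a circle to the pubic arc and declares the line ``intact`` iff the
    maximum absolute radial residual of the neck-arc points from that circle
    is at most ``tol`` pixels; a step-off beyond ``tol`` → ``disrupted``.
    A collinear pubic arc yields ``indeterminate``.

    This is an explicit geometric proxy for a judgment that is made
    perceptually in clinical reading; reports flag it as such.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    try:
        cx, cy, r = _fit_circle(inputs.pubic_arc)
    except GeometryError:
        return "indeterminate"
    resid = max(
        abs(math.hypot(p.x - cx, p.y - cy) - r) for p in inputs.neck_arc
    )
    return "intact" if resid <= tol else "disrupted"


def grade_hip(
    hip: HipLandmarks,
    frame: ReferenceFrame,
    head_radius: Optional[float] = None,
) -> GradingResult:
    """Grade one hip: IHDI always (H present by construction), Tönnis only
    when the ossific nucleus center C and a head radius are available."""
    res = ihdi_grade(hip.H, frame, hip.side, hip.lateral_sign, hip.E)
    t = None
    if hip.C is not None and head_radius is not None:
        t = tonnis_grade(hip.C, head_radius, frame, hip.E, hip.side, hip.lateral_sign)
    return GradingResult(
        side=hip.side, ihdi=res.ihdi, tonnis=t, boundary_flags=res.boundary_flags
    )
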