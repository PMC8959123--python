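import math

import numpy as np
import pytest

from hipmorph.geometry import Line2D, Point2D
from hipmorph.synthetic import PelvisParams, generate_case


@pytest.fixture
def default_case():
    """Noise-free, undisplaced synthetic pelvis at default scene scale."""
    return generate_case(PelvisParams())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def horizontal_line(y: float = 0.0) -> Line2D:
    return Line2D(Point2D(0.0, y), Point2D(1.0, 0.0))


# ---------------------------------------------------------------------------
# Independent brute-force region classifiers for the graders.
#
# These recompute the Hilgenreiner frame with an explicit rotation matrix
# (rather than the package's dot-product projection) and re-state the
# region inequalities directly, so they share no code path with the
# implementations they check.


def _rotated(p: Point2D, hline: Line2D):
    ang = math.atan2(hline.direction.y, hline.direction.x)
    if math.cos(ang) < 0:
        ang += math.pi
    ca, sa = math.cos(ang), math.sin(ang)
    dx, dy = p.x - hline.anchor.x, p.y - hline.anchor.y
    return (ca * dx + sa * dy, -sa * dx + ca * dy)


def brute_force_ihdi(H: Point2D, E: Point2D, hline: Line2D, lateral_sign: int) -> int:
    hx, hy = _rotated(H, hline)
    ex, _ = _rotated(E, hline)
    lat = lateral_sign * (hx - ex)
    inferior = hy
    if inferior < 0:
        return 4
    if lat <= 0:
        return 1
    if lat <= inferior:
        return 2
    return 3


def brute_force_tonnis(
    C: Point2D, head_radius: float, E: Point2D, hline: Line2D, lateral_sign: int
) -> int:
    cx, cy = _rotated(C, hline)
    ex, ey = _rotated(E, hline)
    if lateral_sign * (cx - ex) <= 0:
        return 1
    if cy >= ey + head_radius:
        return 2
    if cy >= ey - head_radius:
        return 3
    return 4
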