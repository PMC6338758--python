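"""Genitalia angle-deviation measurement, classification and rotation arithmetic.

In *Myosin ID* mutant males the 360° rotation of the genitalia during pupal
development may stall, leaving the anus–penis axis deviated from the abdominal
midline.  This module measures that signed deviation from four landmark
coordinates, assigns it to one of eight circular classes, and converts a class
into the amount of developmental rotation that produced it.

Sign convention
---------------
Deviations are stored as signed degrees in ``(-180, 180]``; positive values are
deviations toward the fly's **right**, negative toward the **left**, as seen
from the posterior end.  Landmark coordinates live in the image frame (x right,
y increasing downward), the frame in which the photographs are annotated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "LandmarkSet",
    "AngleClass",
    "RotationDirection",
    "DegenerateGeometryError",
    "AmbiguousRotationError",
    "measure_deviation",
    "classify",
    "rotation_amounts",
    "rotation_difference",
    "wrap_angle_deg",
]


class DegenerateGeometryError(ValueError):
    """Raised when landmark points coincide and no axis is defined."""


class AmbiguousRotationError(ValueError):
    """Raised when a class maps to more than one candidate rotation amount."""


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle in degrees onto the signed interval ``(-180, 180]``."""
    wrapped = math.fmod(angle, 360.0)
    if wrapped <= -180.0:
        wrapped += 360.0
    elif wrapped > 180.0:
        wrapped -= 360.0
    return wrapped


@dataclass(frozen=True)
class LandmarkSet:
    """Four annotated points on a male genitalia photograph.

    ``midline_a`` is the anterior and ``midline_b`` the posterior of the two
    abdominal-midline points; the genitalia axis runs anus → penis (the penis
    taken as the middle of the claspers).  Coordinates are in pixels of the
    image frame.
    """

    anus: tuple[float, float]
    penis: tuple[float, float]
    midline_a: tuple[float, float]
    midline_b: tuple[float, float]

    def __post_init__(self) -> None:
        if _close(self.anus, self.penis):
            raise DegenerateGeometryError("anus and penis coincide: genitalia axis undefined")
        if _close(self.midline_a, self.midline_b):
            raise DegenerateGeometryError("midline points coincide: midline undefined")


def _close(p: tuple[float, float], q: tuple[float, float]) -> bool:
    return math.isclose(p[0], q[0], abs_tol=1e-12) and math.isclose(p[1], q[1], abs_tol=1e-12)


def measure_deviation(landmarks: LandmarkSet) -> float:
    """Signed deviation (degrees) of the genitalia axis from the abdominal midline.

    The deviation is the angle between the anterior→posterior midline direction
    and the anus→penis axis, wrapped to ``(-180, 180]`` with positive = Right.
    The measure is invariant under translation, rotation and uniform scaling of
    all four landmarks, because it only compares the two directions.
    """
    m = np.subtract(landmarks.midline_b, landmarks.midline_a, dtype=float)
    g = np.subtract(landmarks.penis, landmarks.anus, dtype=float)
    cross = m[0] * g[1] - m[1] * g[0]
    dot = m[0] * g[0] + m[1] * g[1]
    return wrap_angle_deg(math.degrees(math.atan2(cross, dot)))


class AngleClass(enum.Enum):
    """The eight circular classes of genitalia angle deviation.

    Bin boundaries follow the printed class endpoints: the 0° class spans
    Left 22°–Right 22° (exclusive), each lateral class is half-open with its
    boundary assigned to the class farther from 0°, and the 180° class absorbs
    both the +180 and −180 approaches (Right/Left 157° to 180°).  The eight
    bins partition the circle; widths are 44° (0°), 46° (180°) and 45°
    elsewhere.
    """

    DEG_0 = "0°"
    RIGHT_45 = "Right 45°"
    RIGHT_90 = "Right 90°"
    RIGHT_135 = "Right 135°"
    DEG_180 = "180°"
    LEFT_135 = "Left 135°"
    LEFT_90 = "Left 90°"
    LEFT_45 = "Left 45°"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# (lower, upper, class) on the signed scale; lower-inclusive/upper-exclusive
# except the 0° bin (both ends exclusive, handled by its neighbours' closures)
# and the wrap of the 180° bin.
_BINS: tuple[tuple[float, float, AngleClass], ...] = (
    (22.0, 67.0, AngleClass.RIGHT_45),
    (67.0, 112.0, AngleClass.RIGHT_90),
    (112.0, 157.0, AngleClass.RIGHT_135),
)

_CLASS_ORDER: tuple[AngleClass, ...] = (
    AngleClass.DEG_0,
    AngleClass.RIGHT_45,
    AngleClass.RIGHT_90,
    AngleClass.RIGHT_135,
    AngleClass.DEG_180,
    AngleClass.LEFT_135,
    AngleClass.LEFT_90,
    AngleClass.LEFT_45,
)


def class_order() -> tuple[AngleClass, ...]:
    """The eight classes in circular order starting from 0° going rightward."""
    return _CLASS_ORDER


def classify(deviation_deg: float) -> AngleClass:
    """Assign a signed deviation angle to its class.

    Every angle in ``(-180, 180]`` maps to exactly one class.  A shared printed
    endpoint (e.g. Right 22°) belongs to the class farther from 0°, so the bins
    are ``0° = (−22, 22)``, ``Right 45° = [22, 67)`` … ``180° = [157, 180] ∪
    (−180, −157]`` … ``Left 45° = (−67, −22]``.
    """
    a = wrap_angle_deg(float(deviation_deg))
    if -22.0 < a < 22.0:
        return AngleClass.DEG_0
    if a >= 157.0 or a <= -157.0:
        return AngleClass.DEG_180
    if a > 0:
        for lo, hi, cls in _BINS:
            if lo <= a < hi:
                return cls
    # left side mirrors the right with closures flipped: (-hi, -lo]
    for lo, hi, cls in _BINS:
        if -hi < a <= -lo:
            return _MIRROR[cls]
    raise AssertionError(f"unclassifiable angle {a!r}")  # pragma: no cover


_MIRROR = {
    AngleClass.RIGHT_45: AngleClass.LEFT_45,
    AngleClass.RIGHT_90: AngleClass.LEFT_90,
    AngleClass.RIGHT_135: AngleClass.LEFT_135,
}

# signed nominal class-centre deviation, degrees
_CLASS_CENTER_DEG = {
    AngleClass.DEG_0: 0.0,
    AngleClass.RIGHT_45: 45.0,
    AngleClass.RIGHT_90: 90.0,
    AngleClass.RIGHT_135: 135.0,
    AngleClass.DEG_180: 180.0,
    AngleClass.LEFT_135: -135.0,
    AngleClass.LEFT_90: -90.0,
    AngleClass.LEFT_45: -45.0,
}


class RotationDirection(enum.Enum):
    """Direction of the developmental genitalia rotation, viewed from the posterior.

    Wild-type genitalia rotate 360° clockwise; *Myosin ID* null mutants rotate
    counterclockwise.
    """

    COUNTERCLOCKWISE = "counterclockwise"
    CLOCKWISE = "clockwise"


def rotation_amounts(
    cls: AngleClass, direction: RotationDirection = RotationDirection.COUNTERCLOCKWISE
) -> frozenset[float]:
    """Rotation amounts (degrees) that end at the class-centre deviation.

    For a counterclockwise rotation a deviation of Left *d* is reached after
    rotating *d* degrees, and Right *d* after ``360 − d`` degrees (the rotation
    fell *d* short of completion); a clockwise rotation is the mirror image.
    The 0° class is two-valued ``{0, 360}``: a final deviation of zero cannot
    distinguish no rotation from full circumversion.
    """
    center = _CLASS_CENTER_DEG[cls]
    if cls is AngleClass.DEG_0:
        return frozenset({0.0, 360.0})
    if cls is AngleClass.DEG_180:
        return frozenset({180.0})
    if direction is RotationDirection.COUNTERCLOCKWISE:
        return frozenset({-center if center < 0 else 360.0 - center})
    return frozenset({center if center > 0 else 360.0 + center})


def rotation_difference(
    cls_a: AngleClass,
    cls_b: AngleClass,
    direction: RotationDirection = RotationDirection.COUNTERCLOCKWISE,
) -> float:
    """Absolute difference (degrees) between two classes' rotation amounts.

    Defined only for classes with a single-valued rotation amount; the 0°
    class is two-valued and raises :class:`AmbiguousRotationError`.
    """
    amounts = []
    for cls in (cls_a, cls_b):
        amt = rotation_amounts(cls, direction)
        if len(amt) != 1:
            raise AmbiguousRotationError(
                f"{cls.value} has candidate rotations {sorted(amt)}; difference undefined"
            )
        amounts.append(next(iter(amt)))
    return abs(amounts[0] - amounts[1])


def classify_many(deviations_deg: Iterable[float]) -> list[AngleClass]:
    """Classify a sequence of deviation angles."""
    return [classify(a) for a in deviations_deg]
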