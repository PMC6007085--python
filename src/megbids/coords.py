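"""Fiducial-defined head coordinate frames, unit conversion, rigid transforms.

MEG vendors use different head coordinate conventions, all right-handed and
defined from the three anatomical landmarks nasion (NAS), left and right
pre-auricular points (LPA, RPA):

* **ALS** (CTF / KIT style): origin at the midpoint of LPA and RPA; +x
  anterior through the nasion; +z superior, normal to the landmark plane;
  +y = z x x (leftward).
* **RAS** (Elekta/Neuromag style): +x from LPA to RPA (rightward); origin at
  the orthogonal projection of the nasion onto the LPA-RPA line; +y anterior
  through the nasion; +z = x x y (superior).

The canonical internal unit is metres; points are converted at ingest.  A
:class:`RigidTransform` is ``y = R (s x) + t`` with an orthonormal rotation
(det = +1 within 1e-9) and a positive scale used only for unit conversion, so
distances are preserved after unit normalisation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import GeometryError, MegBidsError

__all__ = [
    "FRAME_REGISTRY",
    "FrameConvention",
    "Fiducials",
    "RigidTransform",
    "frame_from_fiducials",
    "between_frames",
    "convert_units",
    "UNIT_FACTORS",
]

UNIT_FACTORS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3}

ORTHONORMALITY_TOL = 1e-9
COLLINEARITY_AREA_TOL = 1e-12  # m^2


@dataclass(frozen=True)
class FrameConvention:
    """A named head-frame axis convention."""

    name: str
    scheme: str  # ALS | RAS
    description: str


FRAME_REGISTRY: dict[str, FrameConvention] = {
    "CTF": FrameConvention(
        "CTF", "ALS", "+x anterior through nasion, +y left, +z superior; origin mid-ears"
    ),
    "KIT": FrameConvention(
        "KIT", "ALS", "+x anterior through nasion, +y left, +z superior; origin mid-ears"
    ),
    "ElektaNeuromag": FrameConvention(
        "ElektaNeuromag",
        "RAS",
        "+x right (LPA to RPA), +y anterior through nasion, +z superior",
    ),
}


def _convention(conv: "str | FrameConvention") -> FrameConvention:
    if isinstance(conv, FrameConvention):
        return conv
    try:
        return FRAME_REGISTRY[conv]
    except KeyError:
        raise MegBidsError(
            f"unknown coordinate convention {conv!r}; registry tokens are "
            f"{sorted(FRAME_REGISTRY)} (use an explicit FrameConvention for 'Other')"
        ) from None


@dataclass(frozen=True)
class Fiducials:
    """The three anatomical landmarks, in a common unit."""

    nas: np.ndarray
    lpa: np.ndarray
    rpa: np.ndarray
    units: str = "m"

    def __post_init__(self):
        if self.units not in UNIT_FACTORS:
            raise MegBidsError(f"unknown unit {self.units!r}")
        for name in ("nas", "lpa", "rpa"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (3,):
                raise MegBidsError(f"{name} must be a 3-vector")

    def in_meters(self) -> "Fiducials":
        f = UNIT_FACTORS[self.units]
        return Fiducials(self.nas * f, self.lpa * f, self.rpa * f, "m")

    def triangle_area(self) -> float:
        """Landmark triangle area in m^2 (degeneracy measure)."""
        m = self.in_meters()
        return 0.5 * float(np.linalg.norm(np.cross(m.lpa - m.nas, m.rpa - m.nas)))

    def check_noncollinear(self) -> None:
        if self.triangle_area() <= COLLINEARITY_AREA_TOL:
            raise GeometryError(
                f"fiducials are (near-)collinear: triangle area "
                f"{self.triangle_area():.3e} m^2 <= {COLLINEARITY_AREA_TOL:.0e}"
            )


@dataclass(frozen=True)
class RigidTransform:
    """y = rotation @ (scale * x) + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise MegBidsError("rotation must be 3x3 and translation a 3-vector")
        if self.scale_factor <= 0:
            raise MegBidsError("scale_factor must be positive")
        if np.max(np.abs(R.T @ R - np.eye(3))) > ORTHONORMALITY_TOL:
            raise MegBidsError("rotation is not orthonormal within 1e-9")
        if np.linalg.det(R) < 0:
            raise MegBidsError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: Iterable) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (self.scale_factor * pts) @ self.rotation.T + self.translation

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """self ∘ first: apply ``first``, then ``self``."""
        R = self.rotation @ first.rotation
        s = self.scale_factor * first.scale_factor
        t = self.scale_factor * (self.rotation @ first.translation) + self.translation
        return RigidTransform(R, t, s)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        s = 1.0 / self.scale_factor
        t = -s * (Rinv @ self.translation)
        return RigidTransform(Rinv, t, s)


def frame_from_fiducials(
    fid: Fiducials, convention: "str | FrameConvention" = "CTF"
) -> RigidTransform:
    """Transform from the fiducials' native space into the convention head frame.

    ALS: origin = midpoint(LPA, RPA); x = unit(NAS - origin);
    z = unit(x cross (LPA - RPA)); y = z cross x.

    RAS: x = unit(RPA - LPA); origin = LPA + ((NAS - LPA).x) x;
    y = unit(NAS - origin); z = x cross y.
    """
    conv = _convention(convention)
    fid.check_noncollinear()
    m = fid.in_meters()
    nas, lpa, rpa = m.nas, m.lpa, m.rpa
    if conv.scheme == "ALS":
        origin = (lpa + rpa) / 2.0
        x = _unit(nas - origin)
        z = _unit(np.cross(x, lpa - rpa))
        y = np.cross(z, x)
    elif conv.scheme == "RAS":
        x = _unit(rpa - lpa)
        origin = lpa + float(np.dot(nas - lpa, x)) * x
        y = _unit(nas - origin)
        z = np.cross(x, y)
    else:  # pragma: no cover - registry is closed
        raise MegBidsError(f"unknown axis scheme {conv.scheme!r}")
    R = np.vstack([x, y, z])  # rows are the frame axes => p_frame = R (p - origin)
    return RigidTransform(R, -R @ origin, UNIT_FACTORS[fid.units])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length axis vector (degenerate fiducials)")
    return v / n


def between_frames(
    fid: Fiducials,
    from_convention: "str | FrameConvention",
    to_convention: "str | FrameConvention",
) -> RigidTransform:
    """Mapping from one convention's head frame to another's (both in metres)."""
    fid_m = fid.in_meters()
    to_t = frame_from_fiducials(fid_m, to_convention)
    from_t = frame_from_fiducials(fid_m, from_convention)
    return to_t.compose(from_t.inverse())


_UNIT_EXP = {"m": 0, "cm": -2, "mm": -3}  # decimal exponent relative to metres


def convert_units(points: Iterable, from_unit: str, to_unit: str) -> np.ndarray:
    """Exact power-of-ten rescaling of coordinates between m, cm, and mm.

    Applied as repeated multiplication/division by 10 so that conversions in
    the same direction compose bit-exactly (m→cm→mm equals m→mm).
    """
    for u in (from_unit, to_unit):
        if u not in UNIT_FACTORS:
            raise MegBidsError(f"unknown unit {u!r}")
    pts = np.asarray(points, dtype=float)
    k = _UNIT_EXP[from_unit] - _UNIT_EXP[to_unit]
    for _ in range(abs(k)):
        pts = pts * 10.0 if k > 0 else pts / 10.0
    return pts
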