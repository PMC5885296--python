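"""Rigid alignment of arbitrarily oriented embryos to the canonical frame.

The canonical *C. elegans* frame used throughout this package ("anterior to
the left, dorsal up", in image coordinates where y grows downward):

* AP axis = ``(1, 0, 0)``, pointing anterior → posterior (anterior at low x);
* DV axis = ``(0, 1, 0)``, pointing dorsal → ventral (dorsal at low y);
* LR axis = ``(0, 0, 1)``, pointing left → right (under a compressed mount
  the LR axis of the 4-cell embryo aligns with the microscope's axial z).

``(AP, DV, LR)`` is right-handed, asserted at import.

Division-direction expectations are stored in this frame, so naming an
embryo mounted in any orientation requires a single proper rotation taking
the user-supplied image-space AP and LR vectors onto the canonical axes.
The rotation is built from two axis-angle rotations (AP alignment, then LR
alignment about the canonical AP axis) concatenated into one transform, with
explicit handling of the degenerate collinear cases (already canonical, and
flipped i.e. anti-parallel).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .model import LineageError, NucleusRecord

__all__ = [
    "CANONICAL_AP",
    "CANONICAL_DV",
    "CANONICAL_LR",
    "RigidTransform",
    "DegenerateAxesError",
    "axis_angle_rotation",
    "canonical_transform",
    "transform_direction",
    "isotropize",
]

logger = logging.getLogger(__name__)

CANONICAL_AP = np.array([1.0, 0.0, 0.0])
CANONICAL_DV = np.array([0.0, 1.0, 0.0])
CANONICAL_LR = np.array([0.0, 0.0, 1.0])

# right-handedness of (AP, DV, LR): AP x DV must equal LR
assert np.allclose(np.cross(CANONICAL_AP, CANONICAL_DV), CANONICAL_LR)

ORTHONORMAL_TOL = 1e-9


class DegenerateAxesError(LineageError):
    """The supplied AP/LR pair does not span a plane (collinear axes)."""


@dataclass
class RigidTransform:
    """A proper rotation plus translation mapping image space to canonical space.

    Directions transform with the rotation only; points additionally get the
    translation (zero unless a point transform is explicitly constructed).
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"rotation is not orthonormal (|R^T R - I| = {err:g})")
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-8:
            raise ValueError(f"rotation is improper (det = {det:g}); reflections are not allowed")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3))

    def apply_direction(self, v) -> np.ndarray:
        return self.rotation @ np.asarray(v, dtype=float)

    def apply_point(self, p) -> np.ndarray:
        return self.rotation @ np.asarray(p, dtype=float) + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


def _unit(v, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError(f"{what} must be nonzero")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{what} has non-finite components")
    return v / n


def axis_angle_rotation(from_dir, to_dir) -> RigidTransform:
    """Minimal proper rotation taking ``from_dir`` onto ``to_dir``.

    Rotation axis is ``from × to`` and the angle ``atan2(‖from × to‖, from·to)``
    on the normalized vectors.  Degenerate cases: parallel vectors give the
    identity; anti-parallel vectors give a 180° rotation about a deterministic
    perpendicular axis (the canonical basis vector least collinear with
    ``from_dir``, orthogonalized against it).
    """
    f = _unit(from_dir, "from_dir")
    t = _unit(to_dir, "to_dir")
    cross = np.cross(f, t)
    sin = np.linalg.norm(cross)
    cos = float(f @ t)
    if sin < 1e-12:
        if cos > 0.0:
            return RigidTransform.identity()
        # anti-parallel: pick the canonical basis vector least collinear with f
        basis = np.eye(3)
        k = int(np.argmin(np.abs(basis @ f)))
        perp = basis[k] - (basis[k] @ f) * f
        perp /= np.linalg.norm(perp)
        return RigidTransform(Rotation.from_rotvec(np.pi * perp).as_matrix())
    axis = cross / sin
    angle = np.arctan2(sin, cos)
    return RigidTransform(Rotation.from_rotvec(angle * axis).as_matrix())


def canonical_transform(
    ap,
    lr,
    *,
    warn_deg: float = 15.0,
    max_deg: float = 30.0,
) -> RigidTransform:
    """Rotation taking user-supplied image-space AP and LR axes to canonical.

    ``R = R_LR · R_AP``: first the minimal rotation aligning ``ap`` with the
    canonical AP axis, then a rotation about the canonical AP axis aligning
    the (orthogonalized) image of ``lr`` with the canonical LR axis.  The
    result maps both supplied axes onto their canonical counterparts and is
    always a proper rotation.

    ``lr`` need not be exactly perpendicular to ``ap``: it is orthogonalized
    against ``ap`` first.  A deviation from 90° beyond ``warn_deg`` logs a
    warning; beyond ``max_deg`` it is an error, as is a collinear pair.
    """
    a = _unit(ap, "AP vector")
    l = _unit(lr, "LR vector")

    dev = abs(90.0 - np.degrees(np.arccos(np.clip(a @ l, -1.0, 1.0))))
    if dev > max_deg:
        raise DegenerateAxesError(
            f"AP/LR axes deviate {dev:.1f} deg from perpendicular (max {max_deg} deg)"
        )
    if dev > warn_deg:
        msg = f"AP/LR axes deviate {dev:.1f} deg from perpendicular"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)

    r_ap = axis_angle_rotation(a, CANONICAL_AP)
    lr_img = r_ap.apply_direction(l)
    lr_perp = lr_img - (lr_img @ CANONICAL_AP) * CANONICAL_AP
    norm = np.linalg.norm(lr_perp)
    if norm < 1e-6:
        raise DegenerateAxesError("degenerate axis pair: LR is collinear with AP")
    lr_perp /= norm

    # signed in-plane angle from lr_perp to canonical LR about the AP axis
    angle = np.arctan2(
        float(np.cross(lr_perp, CANONICAL_LR) @ CANONICAL_AP),
        float(lr_perp @ CANONICAL_LR),
    )
    r_lr = RigidTransform(Rotation.from_rotvec(angle * CANONICAL_AP).as_matrix())
    return r_lr.compose(r_ap)


def transform_direction(t: RigidTransform, v) -> np.ndarray:
    """Apply the rotation (not the translation) to a direction vector."""
    return t.apply_direction(v)


def isotropize(record: NucleusRecord, meta) -> np.ndarray:
    """Record position in micrometers: (x·xy_res, y·xy_res, z·z_res).

    Pixel/plane coordinates are anisotropic whenever the plane spacing
    differs from the pixel pitch; angles between division axes are only
    geometrically meaningful after this scaling.
    """
    return np.array(
        [record.x * meta.xy_res, record.y * meta.xy_res, record.z * meta.z_res]
    )
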