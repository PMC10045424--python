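"""Denavit-Hartenberg parameterization and forward kinematics of the fingers.

Each finger is an open kinematic chain of hinge joints.  Consecutive joint
frames are related by the four classic DH parameters:

* ``theta`` -- rotation about the previous z axis (the joint angle, degrees),
* ``d``     -- translation along the previous z axis (mm),
* ``a``     -- translation along the new x axis (the link length, mm),
* ``alpha`` -- rotation about the new x axis (the link twist, degrees),

composed as ``Rz(theta) @ Tz(d) @ Tx(a) @ Rx(alpha)``.  The fingertip pose in
the hand frame is the base transform of the finger times the ordered product
of the per-joint DH matrices.

Because abduction/adduction is excluded from the simplified model, every
finger chain is planar in its own flexion plane (``d = 0``, ``alpha = 0``);
the placement of that plane within the hand is carried by a per-finger base
transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hand_model import Finger, HandModel, HandPose

ORTHONORMALITY_TOL = 1e-9


@dataclass(frozen=True)
class DHRow:
    """One joint's DH parameters: angles in degrees, lengths in mm."""

    theta: float
    d: float = 0.0
    a: float = 0.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        for name in ("theta", "d", "a", "alpha"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite DH parameter {name}")
        if self.a < 0:
            raise ValueError("link length a must be >= 0")


def _default_base() -> np.ndarray:
    return np.eye(4)


@dataclass(frozen=True)
class FingerGeometry:
    """Functional phalanx lengths of one finger and its base placement.

    ``link_lengths`` are proximal to distal (mm); ``base_transform`` places
    the finger's base frame in the global hand frame.
    """

    finger: Finger
    link_lengths: tuple[float, float, float]
    base_transform: np.ndarray = field(default_factory=_default_base)

    def __post_init__(self) -> None:
        if len(self.link_lengths) != 3:
            raise ValueError("a finger chain has exactly 3 links")
        if any(l <= 0 for l in self.link_lengths):
            raise ValueError("link lengths must be positive")
        base = np.asarray(self.base_transform, dtype=float)
        if base.shape != (4, 4):
            raise ValueError("base_transform must be a 4x4 matrix")
        _check_homogeneous(base)
        object.__setattr__(self, "base_transform", base)


def _check_homogeneous(matrix: np.ndarray, tol: float = ORTHONORMALITY_TOL) -> None:
    if not np.allclose(matrix[3], (0.0, 0.0, 0.0, 1.0), atol=tol):
        raise ValueError("bottom row of a homogeneous transform must be (0,0,0,1)")
    rot = matrix[:3, :3]
    if np.linalg.norm(rot.T @ rot - np.eye(3)) > 1e-6 or np.linalg.det(rot) < 0:
        raise ValueError("rotation block must be proper orthonormal")


def dh_matrix(row: DHRow) -> np.ndarray:
    """Homogeneous transform between consecutive DH frames.

    Closed form of ``Rz(theta) @ Tz(d) @ Tx(a) @ Rx(alpha)``.
    """
    th = math.radians(row.theta)
    al = math.radians(row.alpha)
    ct, st = math.cos(th), math.sin(th)
    ca, sa = math.cos(al), math.sin(al)
    return np.array(
        [
            [ct, -st * ca, st * sa, row.a * ct],
            [st, ct * ca, -ct * sa, row.a * st],
            [0.0, sa, ca, row.d],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def chain_transform(rows: list[DHRow] | tuple[DHRow, ...]) -> np.ndarray:
    """Ordered product of the DH matrices of a chain; empty chain -> identity."""
    transform = np.eye(4)
    for row in rows:
        transform = transform @ dh_matrix(row)
    return transform


def build_finger_chain(
    geometry: FingerGeometry, pose: HandPose, model: HandModel
) -> list[DHRow]:
    """DH rows of one finger for a given pose.

    One row per joint, proximal to distal: ``theta`` is the joint's flexion
    angle, ``a`` the functional phalanx length; ``d = alpha = 0`` (planar
    chain in the finger's flexion plane).
    """
    joints = model.finger_joints(geometry.finger)
    if len(joints) != len(geometry.link_lengths):
        raise ValueError(
            f"finger {geometry.finger.value}: {len(joints)} joints in the model "
            f"but {len(geometry.link_lengths)} links in the geometry"
        )
    rows = []
    for jid, link in zip(joints, geometry.link_lengths):
        if jid not in pose.angles:
            raise KeyError(f"pose is missing joint {jid}")
        rows.append(DHRow(theta=pose.angles[jid], d=0.0, a=link, alpha=0.0))
    return rows


def fingertip_transform(
    geometry: FingerGeometry, pose: HandPose, model: HandModel
) -> np.ndarray:
    """Pose of the fingertip frame in the global hand frame."""
    rows = build_finger_chain(geometry, pose, model)
    return geometry.base_transform @ chain_transform(rows)


def fingertip_position(
    geometry: FingerGeometry, pose: HandPose, model: HandModel
) -> np.ndarray:
    """Fingertip position (mm) in the global hand frame."""
    return fingertip_transform(geometry, pose, model)[:3, 3]


def translation(x: float = 0.0, y: float = 0.0, z: float = 0.0) -> np.ndarray:
    """Convenience 4x4 pure translation, for building base transforms."""
    base = np.eye(4)
    base[:3, 3] = (x, y, z)
    return base


def rotation_z(angle_deg: float) -> np.ndarray:
    """Convenience 4x4 rotation about z, for building base transforms."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    mat = np.eye(4)
    mat[:2, :2] = [[c, -s], [s, c]]
    return mat


# Default finger-base placements in the hand frame (mm): knuckle line of the
# long fingers offset along y (radial), thumb base rotated 45 degrees towards
# opposition.  Purely illustrative defaults; override per subject.
DEFAULT_FINGER_BASES: dict[Finger, np.ndarray] = {
    Finger.I: translation(20.0, 40.0, 0.0) @ rotation_z(45.0),
    Finger.II: translation(80.0, 20.0, 0.0),
    Finger.III: translation(85.0, 0.0, 0.0),
    Finger.IV: translation(80.0, -20.0, 0.0),
    Finger.V: translation(70.0, -40.0, 0.0),
}
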