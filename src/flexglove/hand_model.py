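"""Simplified 15-degree-of-freedom kinematic model of the human hand.

The anatomical hand has 23 degrees of freedom.  For wearable joint-angle
sensing this module reduces it to 15 by (a) dropping abduction/adduction at
every joint, (b) dropping the carpometacarpal (CMC) joints of fingers IV and
V, which move only minimally, and (c) modelling every remaining joint as a
1-DoF hinge.  The thumb (finger I) keeps CMC, MCP and IP; each long finger
(II-V) keeps MCP, PIP and DIP.

Flexion and extension of the DIP joint are mechanically coupled to the PIP
joint through the tendon apparatus; in free motion (no external forces)

    theta_DIP = (2/3) * theta_PIP.

The global hand frame sits at the centre of the wrist: x points distal,
y radial, z palmar.  All angles are degrees, flexion positive, extension
negative (neutral-zero convention: the anatomically neutral posture is 0).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

FRAME_CONVENTION = "x distal, y radial, z palmar; origin at the wrist centre"

#: Linear DIP-PIP coupling ratio in free motion.
DEFAULT_COUPLING_RATIO = 2.0 / 3.0


class Finger(str, enum.Enum):
    """Fingers numbered thumb (I) to pinkie (V)."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"


class Joint(str, enum.Enum):
    CMC = "CMC"
    MCP = "MCP"
    PIP = "PIP"
    DIP = "DIP"
    IP = "IP"


THUMB_JOINTS: tuple[Joint, ...] = (Joint.CMC, Joint.MCP, Joint.IP)
LONG_FINGER_JOINTS: tuple[Joint, ...] = (Joint.MCP, Joint.PIP, Joint.DIP)
LONG_FINGERS: tuple[Finger, ...] = (Finger.II, Finger.III, Finger.IV, Finger.V)


@dataclass(frozen=True)
class JointId:
    """One hinge joint of the simplified model, e.g. ``II.MCP``."""

    finger: Finger
    joint: Joint

    def __post_init__(self) -> None:
        allowed = THUMB_JOINTS if self.finger is Finger.I else LONG_FINGER_JOINTS
        if self.joint not in allowed:
            raise ValueError(
                f"joint {self.joint.value} does not exist on finger "
                f"{self.finger.value} in the simplified model"
            )

    def __str__(self) -> str:
        return f"{self.finger.value}.{self.joint.value}"

    @classmethod
    def parse(cls, text: str) -> "JointId":
        """Parse ``"II.MCP"``-style joint names (as used in JSON configs)."""
        try:
            finger_s, joint_s = text.split(".")
            return cls(Finger(finger_s), Joint(joint_s))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"unknown joint name {text!r}") from exc


def joints_of(finger: Finger) -> tuple[JointId, ...]:
    names = THUMB_JOINTS if finger is Finger.I else LONG_FINGER_JOINTS
    return tuple(JointId(finger, j) for j in names)


# Range-of-motion defaults, degrees.  MCP ranges follow the per-finger
# measurement ranges of the validation protocol (thumb 0-50, index 0-70,
# middle 0-80); fingers IV and V are treated like finger III.  PIP 0-90,
# DIP 0-60 via the 2/3 coupling, thumb IP 0-90.  All config-overridable.
DEFAULT_ROM: dict[str, tuple[float, float]] = {
    "I.CMC": (0.0, 50.0),
    "I.MCP": (0.0, 50.0),
    "I.IP": (0.0, 90.0),
    "II.MCP": (0.0, 70.0),
    "III.MCP": (0.0, 80.0),
    "IV.MCP": (0.0, 80.0),
    "V.MCP": (0.0, 80.0),
}
for _f in ("II", "III", "IV", "V"):
    DEFAULT_ROM[f"{_f}.PIP"] = (0.0, 90.0)
    DEFAULT_ROM[f"{_f}.DIP"] = (0.0, 60.0)


@dataclass(frozen=True)
class HandModel:
    """The simplified hand: joint inventory, ROM table and coupling rule."""

    joints: tuple[JointId, ...]
    rom: Mapping[JointId, tuple[float, float]]
    coupling_ratio: float = DEFAULT_COUPLING_RATIO
    thumb_cmc_fixed_deg: float = 0.0
    frame_convention: str = FRAME_CONVENTION

    def __post_init__(self) -> None:
        if not 0.0 < self.coupling_ratio <= 1.0:
            raise ValueError("coupling_ratio must lie in (0, 1]")
        for jid in self.joints:
            lo, hi = self.rom[jid]
            if lo > hi:
                raise ValueError(f"invalid ROM for {jid}: min {lo} > max {hi}")

    @property
    def fingers(self) -> tuple[Finger, ...]:
        seen: dict[Finger, None] = {}
        for jid in self.joints:
            seen.setdefault(jid.finger, None)
        return tuple(seen)

    def finger_joints(self, finger: Finger) -> tuple[JointId, ...]:
        return tuple(j for j in self.joints if j.finger is finger)


@dataclass(frozen=True)
class HandPose:
    """Flexion angles (degrees) for every joint of a model.

    ``out_of_range`` records joints whose decomposed angle violated the ROM
    and was clamped; it does not participate in equality.
    """

    angles: Mapping[JointId, float]
    out_of_range: frozenset = field(default_factory=frozenset, compare=False)

    def __post_init__(self) -> None:
        for jid, value in self.angles.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite angle for {jid}: {value}")

    def __getitem__(self, jid: JointId) -> float:
        return self.angles[jid]

    @classmethod
    def zero(cls, model: HandModel) -> "HandPose":
        return cls({jid: 0.0 for jid in model.joints})

    def replace_angles(self, updates: Mapping[JointId, float]) -> "HandPose":
        merged = dict(self.angles)
        merged.update(updates)
        return HandPose(merged, self.out_of_range)


@dataclass(frozen=True)
class SensorLayout:
    """Which fingers carry a (short, long) flex-sensor pair.

    The full glove carries a pair on every finger plus one fingertip pressure
    switch per sensorized finger and one IMU on the back of the hand.
    """

    fingers: tuple[Finger, ...] = tuple(Finger)

    def __post_init__(self) -> None:
        if len(set(self.fingers)) != len(self.fingers):
            raise ValueError("duplicate finger in sensor layout")

    @property
    def n_flex_sensors(self) -> int:
        return 2 * len(self.fingers)

    @property
    def n_pressure_sensors(self) -> int:
        return len(self.fingers)

    @property
    def n_imu(self) -> int:
        return 1


FULL_LAYOUT = SensorLayout()


def build_hand_model(config: Mapping | None = None) -> HandModel:
    """Build the simplified hand model, optionally overridden by a config dict.

    Recognised keys: ``coupling_ratio`` (float in (0,1]), ``rom`` (mapping
    ``"II.MCP" -> [min, max]`` degrees), ``thumb_cmc_fixed_deg`` (float) and
    ``fingers`` (subset of ``["I".."V"]`` to restrict the model to).
    """
    config = dict(config or {})
    fingers = tuple(Finger(f) for f in config.pop("fingers", [f.value for f in Finger]))
    ratio = float(config.pop("coupling_ratio", DEFAULT_COUPLING_RATIO))
    thumb_cmc = float(config.pop("thumb_cmc_fixed_deg", 0.0))

    rom: dict[JointId, tuple[float, float]] = {
        JointId.parse(k): (float(v[0]), float(v[1])) for k, v in DEFAULT_ROM.items()
    }
    for key, bounds in dict(config.pop("rom", {})).items():
        jid = JointId.parse(key)
        lo, hi = float(bounds[0]), float(bounds[1])
        if lo > hi:
            raise ValueError(f"invalid ROM for {jid}: min {lo} > max {hi}")
        rom[jid] = (lo, hi)
    if config:
        raise ValueError(f"unknown model config keys: {sorted(config)}")

    joints = tuple(jid for f in fingers for jid in joints_of(f))
    return HandModel(
        joints=joints,
        rom={jid: rom[jid] for jid in joints},
        coupling_ratio=ratio,
        thumb_cmc_fixed_deg=thumb_cmc,
    )


def dof_count(model: HandModel) -> int:
    """Degrees of freedom of the model: one per hinge joint."""
    return len(model.joints)


def couple_dip(theta_pip: float, ratio: float = DEFAULT_COUPLING_RATIO) -> float:
    """DIP flexion implied by PIP flexion under the linear tendon coupling."""
    if not math.isfinite(theta_pip):
        raise ValueError("theta_pip must be finite")
    return ratio * theta_pip


def clamp_pose(pose: HandPose, model: HandModel) -> HandPose:
    """Clip every angle to its joint's range of motion, flagging violations."""
    if set(pose.angles) != set(model.joints):
        raise ValueError("pose keys do not match the model's joints")
    clamped: dict[JointId, float] = {}
    flagged: set[JointId] = set(pose.out_of_range)
    for jid in model.joints:
        lo, hi = model.rom[jid]
        value = pose.angles[jid]
        clipped = min(max(value, lo), hi)
        if clipped != value:
            flagged.add(jid)
        clamped[jid] = clipped
    return HandPose(clamped, frozenset(flagged))


def count_measurable_angles(
    model: HandModel, layout: SensorLayout | Iterable[Finger]
) -> int:
    """Number of model joint angles determined by the flex-sensor layout.

    A (short, long) pair on a long finger determines MCP directly, PIP from
    the two readings and DIP through the coupling: 3 joints.  On the thumb it
    determines MCP and IP: 2 joints.  The thumb CMC is never sensed.
    """
    fingers = layout.fingers if isinstance(layout, SensorLayout) else tuple(layout)
    model_fingers = set(model.fingers)
    count = 0
    for finger in fingers:
        if not isinstance(finger, Finger):
            raise ValueError(f"unknown finger in layout: {finger!r}")
        if finger not in model_fingers:
            continue
        measurable = {Joint.MCP, Joint.IP} if finger is Finger.I else set(LONG_FINGER_JOINTS)
        count += sum(1 for jid in model.finger_joints(finger) if jid.joint in measurable)
    return count
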