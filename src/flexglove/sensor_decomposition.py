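"""Decompose raw glove readings into per-joint flexion angles.

Each finger carries two flex sensors: a short one over the MCP joint alone
and a long one whose angular meaning depends on the placement variant.
Writing ``s`` for the calibrated short reading and ``g`` for the long one
(both degrees), the long sensor reports

    SMALL   g = MCP + PIP + DIP      (thumb: MCP + IP)
    MEDIUM  g = MCP + PIP            (thumb: MCP + IP)
    LARGE   g = PIP                  (thumb: IP)

and the DIP-PIP coupling ``DIP = r * PIP`` closes the system:

    MCP = s
    SMALL   PIP = (g - s) / (1 + r),  DIP = r * PIP
    MEDIUM  PIP = g - s,              DIP = r * PIP
    LARGE   PIP = g,                  DIP = r * PIP

The thumb has no DIP: IP = g - s (SMALL/MEDIUM) or IP = g (LARGE).

Short channels arrive as ADC counts and require a linear calibration
(degrees = gain * counts + offset); long channels are digital and already
angle-valued.  Fingertip pressure switches toggle on an ADC threshold, and
the IMU quaternion is projected onto the hand frame (IMU frame assumed
congruent with the hand frame).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .anthropometry import PlacementVariant
from .hand_model import (
    DEFAULT_COUPLING_RATIO,
    Finger,
    HandModel,
    HandPose,
    Joint,
    JointId,
    clamp_pose,
)

ADC_MAX = 1023
DEFAULT_PRESSURE_THRESHOLD = 512

FINGER_ORDER: tuple[Finger, ...] = tuple(Finger)


@dataclass(frozen=True)
class SensorFrame:
    """One time-stamped glove packet.

    ``flex_short`` are raw ADC counts (or degrees once calibrated),
    ``flex_long`` degrees, ``pressure_raw`` ADC counts, ``quat`` a unit
    quaternion in (w, x, y, z) order, ``accel`` m/s^2, ``gyro`` deg/s.
    Channel order is finger I..V throughout.
    """

    timestamp_ms: int
    flex_short: tuple[float, float, float, float, float]
    flex_long: tuple[float, float, float, float, float]
    pressure_raw: tuple[int, int, int, int, int]
    quat: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    accel: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gyro: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name, arity in (
            ("flex_short", 5),
            ("flex_long", 5),
            ("pressure_raw", 5),
            ("quat", 4),
            ("accel", 3),
            ("gyro", 3),
        ):
            values = getattr(self, name)
            if len(values) != arity:
                raise ValueError(f"{name} must have {arity} entries")
            if not all(math.isfinite(v) for v in values):
                raise ValueError(f"non-finite value in {name}")
        if not all(0 <= p <= ADC_MAX for p in self.pressure_raw):
            raise ValueError(f"pressure counts must lie in [0, {ADC_MAX}]")
        if math.sqrt(sum(q * q for q in self.quat)) < 1e-12:
            raise ValueError("quaternion has zero norm")


@dataclass(frozen=True)
class CalibrationModel:
    """Per-channel linear count-to-degree maps for the five short sensors."""

    gain_deg_per_count: tuple[float, float, float, float, float]
    offset_deg: tuple[float, float, float, float, float]
    residual_rms_deg: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.gain_deg_per_count) != 5 or len(self.offset_deg) != 5:
            raise ValueError("calibration needs 5 gains and 5 offsets")
        if any(g == 0 for g in self.gain_deg_per_count):
            raise ValueError("calibration gain must be nonzero")

    def counts_to_degrees(self, counts: Sequence[float]) -> tuple[float, ...]:
        return tuple(
            g * c + o
            for g, o, c in zip(self.gain_deg_per_count, self.offset_deg, counts)
        )

    def degrees_to_counts(self, degrees: Sequence[float]) -> tuple[float, ...]:
        return tuple(
            (d - o) / g
            for g, o, d in zip(self.gain_deg_per_count, self.offset_deg, degrees)
        )

    @classmethod
    def identity(cls) -> "CalibrationModel":
        """Counts taken directly as degrees (gain 1, offset 0)."""
        return cls((1.0,) * 5, (0.0,) * 5)

    @classmethod
    def default(cls) -> "CalibrationModel":
        """0.125 deg/count, -20 deg offset: 10-bit span covers -20..+107.9 deg."""
        return cls((0.125,) * 5, (-20.0,) * 5)


@dataclass(frozen=True)
class ContactState:
    """Fingertip contact switches and the gestures derived from them."""

    contacts: tuple[bool, bool, bool, bool, bool]
    hand_closed: bool = field(init=False)
    thumb_opposed: bool = field(init=False)

    def __post_init__(self) -> None:
        if len(self.contacts) != 5:
            raise ValueError("contacts must have 5 entries")
        object.__setattr__(self, "hand_closed", all(self.contacts[1:]))
        object.__setattr__(self, "thumb_opposed", bool(self.contacts[0]))


def long_sensor_expected(
    pose: HandPose, finger: Finger, variant: PlacementVariant
) -> float:
    """Angle (degrees) the long flex sensor reports for a pose: the summed
    flexion of the joints it spans under the given placement variant."""
    if not isinstance(variant, PlacementVariant):
        raise ValueError(f"unknown placement variant: {variant!r}")
    if finger is Finger.I:
        mcp = pose[JointId(finger, Joint.MCP)]
        ip = pose[JointId(finger, Joint.IP)]
        return ip if variant is PlacementVariant.LARGE else mcp + ip
    mcp = pose[JointId(finger, Joint.MCP)]
    pip = pose[JointId(finger, Joint.PIP)]
    dip = pose[JointId(finger, Joint.DIP)]
    if variant is PlacementVariant.SMALL:
        return mcp + pip + dip
    if variant is PlacementVariant.MEDIUM:
        return mcp + pip
    return pip


def decompose_finger(
    short_deg: float,
    long_deg: float,
    finger: Finger,
    variant: PlacementVariant,
    ratio: float = DEFAULT_COUPLING_RATIO,
) -> tuple[float, ...]:
    """Per-joint flexion angles of one finger from its two calibrated readings.

    Returns ``(MCP, IP)`` for the thumb and ``(MCP, PIP, DIP)`` for fingers
    II-V, in degrees.
    """
    if not isinstance(variant, PlacementVariant):
        raise ValueError(f"unknown placement variant: {variant!r}")
    if not isinstance(finger, Finger):
        raise ValueError(f"unknown finger: {finger!r}")
    mcp = short_deg
    if finger is Finger.I:
        ip = long_deg if variant is PlacementVariant.LARGE else long_deg - short_deg
        return (mcp, ip)
    if variant is PlacementVariant.SMALL:
        pip = (long_deg - short_deg) / (1.0 + ratio)
    elif variant is PlacementVariant.MEDIUM:
        pip = long_deg - short_deg
    else:
        pip = long_deg
    return (mcp, pip, ratio * pip)


def decompose_frame(
    frame: SensorFrame,
    calib: CalibrationModel,
    variant: PlacementVariant,
    model: HandModel,
    clamp: bool = True,
) -> HandPose:
    """Full pose from one sensor frame.

    Short channels are calibrated to degrees, each finger decomposed, and the
    unmeasured thumb CMC set to the model's fixed value.  With ``clamp``
    (default) angles outside the ROM are clipped and flagged in the returned
    pose's ``out_of_range`` set.
    """
    short_deg = calib.counts_to_degrees(frame.flex_short)
    angles: dict[JointId, float] = {}
    for idx, finger in enumerate(FINGER_ORDER):
        if finger not in model.fingers:
            continue
        parts = decompose_finger(
            short_deg[idx], frame.flex_long[idx], finger, variant, model.coupling_ratio
        )
        if finger is Finger.I:
            angles[JointId(finger, Joint.CMC)] = model.thumb_cmc_fixed_deg
            angles[JointId(finger, Joint.MCP)] = parts[0]
            angles[JointId(finger, Joint.IP)] = parts[1]
        else:
            angles[JointId(finger, Joint.MCP)] = parts[0]
            angles[JointId(finger, Joint.PIP)] = parts[1]
            angles[JointId(finger, Joint.DIP)] = parts[2]
    missing = set(model.joints) - set(angles)
    if missing:
        raise ValueError(f"frame does not cover model joints: {sorted(map(str, missing))}")
    pose = HandPose(angles)
    return clamp_pose(pose, model) if clamp else pose


def calibrate(
    raw_counts: Sequence[Sequence[float]], reference_deg: Sequence[Sequence[float]]
) -> CalibrationModel:
    """Least-squares linear count-to-degree fit for the five short channels.

    ``raw_counts[ch]`` and ``reference_deg[ch]`` are paired observations for
    channel ``ch``; each channel needs at least two distinct count values.
    The per-channel RMS residual (degrees) is reported on the returned model.
    """
    if len(raw_counts) != 5 or len(reference_deg) != 5:
        raise ValueError("calibration requires data for all 5 short channels")
    gains, offsets, residuals = [], [], []
    for counts, degs in zip(raw_counts, reference_deg):
        counts = np.asarray(counts, dtype=float)
        degs = np.asarray(degs, dtype=float)
        if counts.shape != degs.shape or counts.size < 2:
            raise ValueError("each channel needs >= 2 paired reference points")
        if np.ptp(counts) == 0:
            raise ValueError("identical counts: singular calibration fit")
        gain, offset = np.polyfit(counts, degs, deg=1)
        gains.append(float(gain))
        offsets.append(float(offset))
        residuals.append(float(np.sqrt(np.mean((gain * counts + offset - degs) ** 2))))
    return CalibrationModel(tuple(gains), tuple(offsets), tuple(residuals))


def contact_states(
    pressure_raw: Sequence[int], threshold: int = DEFAULT_PRESSURE_THRESHOLD
) -> ContactState:
    """Fingertip contact switches: contact when the reading reaches the
    threshold (FSR conductance, hence ADC reading, rises with force)."""
    if len(pressure_raw) != 5:
        raise ValueError("pressure_raw must have 5 entries")
    return ContactState(tuple(p >= threshold for p in pressure_raw))


def hand_orientation(quat: Sequence[float]) -> np.ndarray:
    """Hand orientation as a 3x3 rotation matrix from the IMU quaternion.

    The quaternion is (w, x, y, z), normalized before conversion; the IMU
    frame is taken as congruent with the hand frame.
    """
    q = np.asarray(quat, dtype=float)
    if q.shape != (4,):
        raise ValueError("quaternion must have 4 components (w, x, y, z)")
    norm = np.linalg.norm(q)
    if norm < 1e-12:
        raise ValueError("quaternion has zero norm")
    return Rotation.from_quat(q / norm, scalar_first=True).as_matrix()
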