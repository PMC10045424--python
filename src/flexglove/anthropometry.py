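"""Hand-size examination: skin lengthening, phalanx ratios, sensor placement.

When a finger flexes, the dorsal skin over each joint lengthens.  Modelling
the joint as a disc of constant radius ``R`` turning by the flexion angle
``theta``, the lengthening is the arc length

    dL = (2 * pi * theta / 360) * R.

Adding the lengthening of the MCP, PIP and DIP joints to the extended
middle-finger length ``L`` (fingertip to MCP-joint midpoint) gives the skin
length that a sensor spanning the whole finger must accommodate at maximum
flexion.  Absolute phalanx lengths are scarce in the anthropometric
literature; instead the PIP-MCP joint-centre distance is estimated from the
DIP-MCP distance through the ratio 0.58 +/- 0.035 (sd), with the DIP-MCP
distance itself approximated upward by the total finger length.

These flexed lengths decide which placement variant of the long flex sensor
(active length 130 mm) a given hand needs: SMALL spans MCP+PIP+DIP, MEDIUM
spans MCP+PIP, LARGE spans PIP only (thumb: MCP+IP / MCP+IP / IP).  The
short sensor (active length 55 mm) always sits over the MCP joint alone.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .hand_model import Joint

SHORT_SENSOR_ACTIVE_MM = 55.0
LONG_SENSOR_ACTIVE_MM = 130.0


class PlacementVariant(str, enum.Enum):
    """Which joints the long flex sensor spans, by hand size."""

    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"

    @property
    def spanned_joints(self) -> Mapping[str, frozenset]:
        """Joints covered by the long sensor, for the thumb and long fingers."""
        table = {
            PlacementVariant.SMALL: (
                frozenset({Joint.MCP, Joint.IP}),
                frozenset({Joint.MCP, Joint.PIP, Joint.DIP}),
            ),
            PlacementVariant.MEDIUM: (
                frozenset({Joint.MCP, Joint.IP}),
                frozenset({Joint.MCP, Joint.PIP}),
            ),
            PlacementVariant.LARGE: (
                frozenset({Joint.IP}),
                frozenset({Joint.PIP}),
            ),
        }
        thumb, long_fingers = table[self]
        return {"I": thumb, "II-V": long_fingers}


@dataclass(frozen=True)
class PhalangeRatioModel:
    """PIP-MCP distance as a fraction of the DIP-MCP distance."""

    mean_ratio: float = 0.58
    sd_ratio: float = 0.035

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_ratio < 1.0:
            raise ValueError("mean_ratio must lie in (0, 1)")
        if self.sd_ratio < 0.0:
            raise ValueError("sd_ratio must be >= 0")


@dataclass(frozen=True)
class HandProfile:
    """Anthropometric parameters of one hand, middle finger as reference.

    ``middle_finger_length_mm`` is measured extended, fingertip to the
    midpoint of the MCP joint.  ``joint_radius_mm`` and ``max_flexion_deg``
    are per middle-finger joint (MCP, PIP, DIP).  An exact DIP-MCP distance
    may be supplied; otherwise the total finger length is used as an upward
    estimate.
    """

    sex: str
    percentile: float
    middle_finger_length_mm: float
    joint_radius_mm: Mapping[Joint, float]
    max_flexion_deg: Mapping[Joint, float]
    dip_mcp_distance_mm: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must lie in (0, 100)")
        if self.middle_finger_length_mm <= 0:
            raise ValueError("middle finger length must be positive")
        for joint in (Joint.MCP, Joint.PIP, Joint.DIP):
            if self.joint_radius_mm.get(joint, 0.0) <= 0:
                raise ValueError(f"joint radius for {joint.value} must be positive")
            theta = self.max_flexion_deg.get(joint)
            if theta is None or not 0.0 < theta < 180.0:
                raise ValueError(
                    f"max flexion for {joint.value} must lie in (0, 180) degrees"
                )
        if self.dip_mcp_distance_mm is not None and self.dip_mcp_distance_mm <= 0:
            raise ValueError("DIP-MCP distance must be positive")

    @property
    def effective_dip_mcp_mm(self) -> float:
        if self.dip_mcp_distance_mm is not None:
            return self.dip_mcp_distance_mm
        return self.middle_finger_length_mm

    @classmethod
    def from_dict(cls, data: Mapping) -> "HandProfile":
        return cls(
            sex=data["sex"],
            percentile=float(data["percentile"]),
            middle_finger_length_mm=float(data["middle_finger_length_mm"]),
            joint_radius_mm={
                Joint(k): float(v) for k, v in data["joint_radius_mm"].items()
            },
            max_flexion_deg={
                Joint(k): float(v) for k, v in data["max_flexion_deg"].items()
            },
            dip_mcp_distance_mm=(
                float(data["dip_mcp_distance_mm"])
                if data.get("dip_mcp_distance_mm") is not None
                else None
            ),
        )


# Illustrative default profiles (NOT a published anthropometric dataset):
# round numbers chosen to bracket small female and large male hands.
DEFAULT_PROFILES: dict[str, HandProfile] = {
    "female_p05": HandProfile(
        sex="female",
        percentile=5.0,
        middle_finger_length_mm=72.0,
        joint_radius_mm={Joint.MCP: 9.0, Joint.PIP: 7.5, Joint.DIP: 6.5},
        max_flexion_deg={Joint.MCP: 80.0, Joint.PIP: 90.0, Joint.DIP: 60.0},
    ),
    "male_p50": HandProfile(
        sex="male",
        percentile=50.0,
        middle_finger_length_mm=86.0,
        joint_radius_mm={Joint.MCP: 11.0, Joint.PIP: 9.0, Joint.DIP: 8.0},
        max_flexion_deg={Joint.MCP: 80.0, Joint.PIP: 90.0, Joint.DIP: 60.0},
    ),
    "male_p95": HandProfile(
        sex="male",
        percentile=95.0,
        middle_finger_length_mm=95.0,
        joint_radius_mm={Joint.MCP: 12.0, Joint.PIP: 10.0, Joint.DIP: 9.0},
        max_flexion_deg={Joint.MCP: 80.0, Joint.PIP: 90.0, Joint.DIP: 60.0},
    ),
}


class SensorFitWarning(UserWarning):
    """Short sensor does not fit the MCP region cleanly (code SHORT_SENSOR_FIT)."""


def skin_lengthening(theta_deg: float, radius_mm: float) -> float:
    """Arc-length increase (mm) of dorsal skin over a joint flexed by theta."""
    if theta_deg < 0:
        raise ValueError("flexion angle must be >= 0")
    if radius_mm <= 0:
        raise ValueError("joint radius must be positive")
    return 2.0 * math.pi * theta_deg / 360.0 * radius_mm


def flexed_finger_skin_length(profile: HandProfile) -> float:
    """Skin length (mm) spanning the middle finger at maximum active flexion.

    Extended length plus the arc-length lengthening over MCP, PIP and DIP.
    """
    added = sum(
        skin_lengthening(profile.max_flexion_deg[j], profile.joint_radius_mm[j])
        for j in (Joint.MCP, Joint.PIP, Joint.DIP)
    )
    return profile.middle_finger_length_mm + added


def pip_mcp_distance(
    total_length_mm: float, ratios: PhalangeRatioModel = PhalangeRatioModel()
) -> tuple[float, float]:
    """Extended PIP-MCP joint-centre distance (mean, sd) in mm.

    ``total_length_mm`` is the DIP-MCP distance, conventionally approximated
    upward by the total finger length.
    """
    if total_length_mm <= 0:
        raise ValueError("total length must be positive")
    return ratios.mean_ratio * total_length_mm, ratios.sd_ratio * total_length_mm


def flexed_pip_mcp_distance(
    profile: HandProfile, ratios: PhalangeRatioModel = PhalangeRatioModel()
) -> float:
    """Mean PIP-MCP skin distance (mm) with MCP and PIP at maximum flexion."""
    mean, _ = pip_mcp_distance(profile.effective_dip_mcp_mm, ratios)
    return (
        mean
        + skin_lengthening(profile.max_flexion_deg[Joint.MCP], profile.joint_radius_mm[Joint.MCP])
        + skin_lengthening(profile.max_flexion_deg[Joint.PIP], profile.joint_radius_mm[Joint.PIP])
    )


def select_placement_variant(
    profile: HandProfile,
    short_active_mm: float = SHORT_SENSOR_ACTIVE_MM,
    long_active_mm: float = LONG_SENSOR_ACTIVE_MM,
    ratios: PhalangeRatioModel = PhalangeRatioModel(),
) -> PlacementVariant:
    """Smallest placement variant whose flexed span fits the long sensor.

    SMALL requires the whole flexed finger (MCP+PIP+DIP) to fit within the
    long sensor's active length; MEDIUM requires only the flexed MCP+PIP
    span; LARGE (single joint) always fits.  A warning (not an error) is
    emitted when the short sensor, centred over the MCP joint, would either
    fail to cover the flexed MCP arc or reach past the extended PIP joint.
    """
    if short_active_mm <= 0 or long_active_mm <= 0:
        raise ValueError("sensor active lengths must be positive")

    mcp_arc = skin_lengthening(
        profile.max_flexion_deg[Joint.MCP], profile.joint_radius_mm[Joint.MCP]
    )
    extended_pip_mcp, _ = pip_mcp_distance(profile.effective_dip_mcp_mm, ratios)
    if short_active_mm < mcp_arc or short_active_mm / 2.0 >= extended_pip_mcp:
        warnings.warn(
            "SHORT_SENSOR_FIT: short flex sensor does not cleanly cover the "
            f"MCP region (arc {mcp_arc:.1f} mm, extended PIP-MCP "
            f"{extended_pip_mcp:.1f} mm, active length {short_active_mm:.1f} mm)",
            SensorFitWarning,
            stacklevel=2,
        )

    if flexed_finger_skin_length(profile) <= long_active_mm:
        return PlacementVariant.SMALL
    if flexed_pip_mcp_distance(profile, ratios) <= long_active_mm:
        return PlacementVariant.MEDIUM
    return PlacementVariant.LARGE


def phalanx_lengths_from_profile(
    profile: HandProfile,
    ratios: PhalangeRatioModel = PhalangeRatioModel(),
    middle_distal_split: tuple[float, float] = (0.55, 0.45),
) -> tuple[float, float, float]:
    """Functional phalanx lengths (mm) for forward kinematics.

    Proximal phalanx = mean PIP-MCP distance; the remainder of the finger
    length is split between middle and distal segments by the configurable
    ``middle_distal_split`` proportion (the literature gives only the
    proximal ratio).
    """
    if not math.isclose(sum(middle_distal_split), 1.0, abs_tol=1e-9):
        raise ValueError("middle_distal_split must sum to 1")
    length = profile.middle_finger_length_mm
    proximal, _ = pip_mcp_distance(profile.effective_dip_mcp_mm, ratios)
    remainder = length - proximal
    if remainder <= 0:
        raise ValueError("proximal phalanx estimate exceeds the finger length")
    return (
        proximal,
        remainder * middle_distal_split[0],
        remainder * middle_distal_split[1],
    )
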