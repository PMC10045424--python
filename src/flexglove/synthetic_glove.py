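"""Synthetic glove: generates the sensor stream a real glove would emit.

Ground-truth poses are pushed through the inverse of the sensor semantics:
the short channel encodes the MCP angle through the inverse calibration map
with additive Gaussian noise and ADC quantization; the long channel reports
the summed flexion of its spanned joints (placement variant) plus Gaussian
noise; pressure switches and the IMU track are attached from the trajectory.

This is the fixture generator for the whole test suite and for the accuracy
validation protocol: per finger, the MCP joint is swept over its measurement
grid and, at each MCP set point, the PIP (or thumb IP) joint over its own
grid, the DIP angle following from the 2/3 coupling; the glove records a
fixed number of repeats per set point at a fixed interval.

Real flex sensors drift, creep and respond nonlinearly near their mechanical
limits; none of that is modelled here -- noise is additive, zero-mean,
white and Gaussian, plus uniform quantization on the resistive channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np

from .anthropometry import PlacementVariant
from .hand_model import Finger, HandModel, HandPose, Joint, JointId, couple_dip
from .sensor_decomposition import (
    ADC_MAX,
    DEFAULT_PRESSURE_THRESHOLD,
    FINGER_ORDER,
    CalibrationModel,
    SensorFrame,
    long_sensor_expected,
)

PRESSURE_ON_COUNT = 900
PRESSURE_OFF_COUNT = 100

#: Device sampling rate (Hz); the reported hardware loop runs at 47-50 Hz.
DEFAULT_RATE_HZ = 50.0


@dataclass(frozen=True)
class NoiseModel:
    """Additive sensor noise and ADC quantization.

    ``sigma_short_deg``/``sigma_long_deg`` are standard deviations of
    zero-mean Gaussian noise on the angle carried by each channel, applied
    before the short channel is encoded to counts.  ``adc_bits`` sets the
    resistive channels' quantization (10-bit ADC by default).
    """

    sigma_short_deg: float = 0.5
    sigma_long_deg: float = 0.5
    adc_bits: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_short_deg < 0 or self.sigma_long_deg < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.adc_bits < 1:
            raise ValueError("adc_bits must be >= 1")

    @property
    def adc_max(self) -> int:
        return 2**self.adc_bits - 1

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


ZERO_NOISE = NoiseModel(0.0, 0.0)


@dataclass(frozen=True)
class ValidationProtocol:
    """Per-finger set-point grids of the accuracy validation sweep.

    ``grids[finger] = (mcp_grid, distal_grid)`` in degrees, where the distal
    grid drives the PIP joint (thumb: IP).  At each grid point the glove
    takes ``repeats`` measurements at ``interval_ms`` spacing.
    """

    grids: Mapping[Finger, tuple[tuple[float, ...], tuple[float, ...]]]
    repeats: int = 50
    interval_ms: int = 100

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.interval_ms <= 0:
            raise ValueError("interval_ms must be positive")

    @property
    def n_set_points(self) -> int:
        return sum(len(m) * len(d) for m, d in self.grids.values())

    @property
    def n_frames(self) -> int:
        return self.n_set_points * self.repeats


def default_protocol(
    fingers: Sequence[Finger] = (Finger.I, Finger.II, Finger.III),
    repeats: int = 50,
    interval_ms: int = 100,
) -> ValidationProtocol:
    """The neutral-zero accuracy protocol: MCP swept in 10-degree steps over
    its per-finger measurement range (thumb 0-50, index 0-70, middle 0-80)
    and the PIP/IP joint over 0-90, 50 repeats per set point."""
    mcp_max = {Finger.I: 50.0, Finger.II: 70.0, Finger.III: 80.0,
               Finger.IV: 80.0, Finger.V: 80.0}
    grids = {}
    for finger in fingers:
        mcp_grid = tuple(np.arange(0.0, mcp_max[finger] + 1e-9, 10.0))
        distal_grid = tuple(np.arange(0.0, 90.0 + 1e-9, 10.0))
        grids[finger] = (mcp_grid, distal_grid)
    return ValidationProtocol(grids, repeats=repeats, interval_ms=interval_ms)


def _quantize(counts: float, adc_bits: int) -> int:
    return int(min(max(round(counts), 0), 2**adc_bits - 1))


def _check_in_rom(pose: HandPose, model: HandModel) -> None:
    for jid in model.joints:
        lo, hi = model.rom[jid]
        if not lo <= pose[jid] <= hi:
            raise ValueError(f"pose out of ROM at {jid}: {pose[jid]} not in [{lo}, {hi}]")


def simulate_frame(
    pose: HandPose,
    variant: PlacementVariant,
    calib: CalibrationModel,
    noise: NoiseModel,
    rng: np.random.Generator,
    *,
    model: HandModel | None = None,
    timestamp_ms: int = 0,
    contacts: Sequence[bool] | None = None,
    closure_angle_deg: float | None = None,
    quat: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0),
    accel: tuple[float, float, float] = (0.0, 0.0, 0.0),
    gyro: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SensorFrame:
    """One sensor frame for a ground-truth pose.

    Fingers absent from the pose emit idle (zero-angle) channels.  Contacts
    come from explicit ``contacts`` flags; if none are given and
    ``closure_angle_deg`` is set, a fingertip touches when the finger's total
    flexion exceeds that angle (opt-in heuristic), otherwise no contact.
    """
    if model is not None:
        _check_in_rom(pose, model)
    short_counts: list[float] = []
    long_deg: list[float] = []
    pose_fingers = {jid.finger for jid in pose.angles}
    total_flexion: dict[Finger, float] = {}
    for channel, finger in enumerate(FINGER_ORDER):
        if finger not in pose_fingers:
            short_true, long_true, total = 0.0, 0.0, 0.0
        else:
            short_true = pose[JointId(finger, Joint.MCP)]
            long_true = long_sensor_expected(pose, finger, variant)
            joints = (Joint.MCP, Joint.IP) if finger is Finger.I else (
                Joint.MCP, Joint.PIP, Joint.DIP)
            total = sum(pose[JointId(finger, j)] for j in joints)
        total_flexion[finger] = total
        noisy_short = short_true + rng.normal(0.0, noise.sigma_short_deg)
        raw_count = (
            noisy_short - calib.offset_deg[channel]
        ) / calib.gain_deg_per_count[channel]
        short_counts.append(_quantize(raw_count, noise.adc_bits))
        long_deg.append(long_true + rng.normal(0.0, noise.sigma_long_deg))

    if contacts is None:
        if closure_angle_deg is not None:
            contacts = tuple(total_flexion[f] > closure_angle_deg for f in FINGER_ORDER)
        else:
            contacts = (False,) * 5
    pressure = tuple(
        PRESSURE_ON_COUNT if c else PRESSURE_OFF_COUNT for c in contacts
    )
    return SensorFrame(
        timestamp_ms=timestamp_ms,
        flex_short=tuple(short_counts),
        flex_long=tuple(long_deg),
        pressure_raw=pressure,
        quat=quat,
        accel=accel,
        gyro=gyro,
    )


@dataclass(frozen=True)
class SweepRecord:
    """One frame of the validation sweep with its ground truth."""

    finger: Finger
    set_pose: HandPose
    frame: SensorFrame
    rep: int


def set_pose_for(
    finger: Finger, mcp_deg: float, distal_deg: float, model: HandModel
) -> HandPose:
    """Protocol set pose: the target finger at (MCP, PIP-or-IP) with DIP from
    the coupling, every other joint at neutral zero."""
    angles = {jid: 0.0 for jid in model.joints}
    if Finger.I in model.fingers:
        angles[JointId(Finger.I, Joint.CMC)] = model.thumb_cmc_fixed_deg
    angles[JointId(finger, Joint.MCP)] = mcp_deg
    if finger is Finger.I:
        angles[JointId(finger, Joint.IP)] = distal_deg
    else:
        angles[JointId(finger, Joint.PIP)] = distal_deg
        angles[JointId(finger, Joint.DIP)] = couple_dip(distal_deg, model.coupling_ratio)
    return HandPose(angles)


def generate_validation_sweep(
    protocol: ValidationProtocol,
    variant: PlacementVariant,
    calib: CalibrationModel,
    noise: NoiseModel,
    model: HandModel,
    rng: np.random.Generator | None = None,
    grid_mask: "Callable[[Finger, float, float], bool] | None" = None,
    reference_sigma_deg: float = 0.0,
) -> Iterator[SweepRecord]:
    """Frames of the full accuracy sweep, finger by finger, grid-ordered.

    ``grid_mask(finger, mcp, distal) -> bool`` drops unreachable set points,
    emulating partial grid coverage on stiff hardware.  A nonzero
    ``reference_sigma_deg`` perturbs the actually-held pose around the
    nominal set point (goniometer reading uncertainty) while the record's
    ``set_pose`` keeps the nominal values, for sensitivity studies.
    """
    if rng is None:
        rng = noise.rng()
    if reference_sigma_deg < 0:
        raise ValueError("reference_sigma_deg must be >= 0")
    for finger, (mcp_grid, distal_grid) in protocol.grids.items():
        if finger not in model.fingers:
            raise ValueError(f"protocol references finger {finger.value} absent from model")
        timestamp = 0
        for mcp_deg in mcp_grid:
            for distal_deg in distal_grid:
                if grid_mask is not None and not grid_mask(finger, mcp_deg, distal_deg):
                    continue
                pose = set_pose_for(finger, mcp_deg, distal_deg, model)
                _check_in_rom(pose, model)
                for rep in range(protocol.repeats):
                    if reference_sigma_deg > 0.0:
                        held = set_pose_for(
                            finger,
                            mcp_deg + rng.normal(0.0, reference_sigma_deg),
                            distal_deg + rng.normal(0.0, reference_sigma_deg),
                            model,
                        )
                    else:
                        held = pose
                    frame = simulate_frame(
                        held, variant, calib, noise, rng,
                        timestamp_ms=timestamp,
                    )
                    timestamp += protocol.interval_ms
                    yield SweepRecord(finger, pose, frame, rep)


def generate_motion_trajectory(
    kind: str,
    duration_s: float,
    rate_hz: float = DEFAULT_RATE_HZ,
    model: HandModel | None = None,
    yaw_rate_deg_s: float = 20.0,
) -> tuple[list[HandPose], list[dict]]:
    """Smooth deterministic pose sequence plus a consistent IMU track.

    Kinds: ``grasp`` (all joints flex to ROM max at mid-trajectory and
    reopen), ``wave`` (per-finger phase-shifted flexion waves), ``sweep``
    (linear ramp from neutral to ROM max).  The hand yaws about the palmar
    axis at a constant rate, so the gyro track is the exact derivative of
    the orientation track.
    """
    from .hand_model import build_hand_model  # local: avoid import cycle at module load

    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if kind not in ("grasp", "wave", "sweep"):
        raise ValueError(f"unknown trajectory kind {kind!r}")
    if model is None:
        model = build_hand_model()
    n = int(round(duration_s * rate_hz))
    times = np.arange(n) / rate_hz
    finger_index = {f: i for i, f in enumerate(FINGER_ORDER)}

    poses: list[HandPose] = []
    track: list[dict] = []
    for t in times:
        angles: dict[JointId, float] = {}
        for jid in model.joints:
            lo, hi = model.rom[jid]
            if jid.finger is Finger.I and jid.joint is Joint.CMC:
                angles[jid] = model.thumb_cmc_fixed_deg
                continue
            if kind == "grasp":
                frac = 0.5 * (1.0 - math.cos(2.0 * math.pi * t / duration_s))
            elif kind == "wave":
                phase = finger_index[jid.finger] * math.pi / 4.0
                frac = 0.5 * (1.0 - math.cos(2.0 * math.pi * t / duration_s - phase))
            else:  # sweep
                frac = t / duration_s
            angles[jid] = lo + frac * (hi - lo)
        poses.append(HandPose(angles))

        yaw = math.radians(yaw_rate_deg_s) * t
        quat = (math.cos(yaw / 2.0), 0.0, 0.0, math.sin(yaw / 2.0))
        track.append(
            {
                "quat": quat,
                "accel": (0.0, 0.0, 0.0),
                "gyro": (0.0, 0.0, yaw_rate_deg_s),
            }
        )
    return poses, track
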