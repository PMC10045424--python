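"""Accuracy validation: replay the neutral-zero sweep and report RMSE.

The protocol sweeps each sensorized finger over a grid of goniometer-set
(MCP, PIP-or-IP) angles, the DIP angle following from the 2/3 coupling, and
records repeated measurements at every set point.  Estimated angles from the
sensor decomposition are compared against the set angles; accuracy is the
root-mean-square error per joint, plus a combined per-finger value.

The combined value is computed either by pooling the squared errors of all
the finger's joints over all samples (``pooled_samples``, the default) or as
the RMS of the per-joint RMSE values (``rms_of_joint_rmse``); the two agree
when per-joint sample counts are equal.  Every value is checked against the
2.5-degree human perception threshold for finger-joint angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anthropometry import PlacementVariant
from .hand_model import Finger, HandModel, Joint, JointId, build_hand_model
from .sensor_decomposition import CalibrationModel, decompose_frame
from .synthetic_glove import NoiseModel, ValidationProtocol, generate_validation_sweep

#: Human perception threshold for finger-joint angles, degrees.
PERCEPTION_THRESHOLD_DEG = 2.5

POOLING_RULES = ("pooled_samples", "rms_of_joint_rmse")


def rmse(estimates: Sequence[float], references: Sequence[float]) -> float:
    """Root-mean-square error (degrees) between estimates and references."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimates and references must have equal length")
    if est.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def run_protocol(
    protocol: ValidationProtocol,
    variant: PlacementVariant,
    calib: CalibrationModel,
    noise: NoiseModel,
    model: HandModel | None = None,
    seed: int | None = None,
    grid_mask=None,
    reference_sigma_deg: float = 0.0,
) -> pd.DataFrame:
    """Execute the sweep and decompose every frame into a tidy table.

    Columns: ``finger``, ``joint``, ``theta_set_deg``, ``theta_est_deg``,
    ``rep``, ``timestamp_ms`` -- one row per measured joint per frame.
    Deterministic given the seed.  ``grid_mask`` and ``reference_sigma_deg``
    are forwarded to the sweep generator (partial grid coverage and
    goniometer reading uncertainty, both off by default).
    """
    if model is None:
        model = build_hand_model()
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    rows: list[tuple] = []
    for record in generate_validation_sweep(
        protocol, variant, calib, noise, model, rng,
        grid_mask=grid_mask, reference_sigma_deg=reference_sigma_deg,
    ):
        estimate = decompose_frame(record.frame, calib, variant, model)
        finger = record.finger
        joints = (
            (Joint.MCP, Joint.IP)
            if finger is Finger.I
            else (Joint.MCP, Joint.PIP, Joint.DIP)
        )
        for joint in joints:
            jid = JointId(finger, joint)
            rows.append(
                (
                    finger.value,
                    joint.value,
                    record.set_pose[jid],
                    estimate[jid],
                    record.rep,
                    record.frame.timestamp_ms,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["finger", "joint", "theta_set_deg", "theta_est_deg", "rep", "timestamp_ms"],
    )


@dataclass(frozen=True)
class AccuracyReport:
    """Per-joint and combined RMSE (degrees) with perception-threshold flags."""

    per_joint_rmse: Mapping[tuple[str, str], float]
    combined_rmse: Mapping[str, float]
    sample_counts: Mapping[tuple[str, str], int]
    below_threshold: Mapping[tuple[str, str], bool]
    pooling: str
    threshold_deg: float = PERCEPTION_THRESHOLD_DEG

    @property
    def max_per_joint_rmse(self) -> float:
        return max(self.per_joint_rmse.values())

    @property
    def all_below_threshold(self) -> bool:
        return all(self.below_threshold.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "finger": finger,
                "joint": joint,
                "rmse_deg": value,
                "n": self.sample_counts[(finger, joint)],
                "below_threshold": self.below_threshold[(finger, joint)],
            }
            for (finger, joint), value in self.per_joint_rmse.items()
        ]
        rows += [
            {
                "finger": finger,
                "joint": "combined",
                "rmse_deg": value,
                "n": sum(
                    n for (f, _), n in self.sample_counts.items() if f == finger
                ),
                "below_threshold": value < self.threshold_deg,
            }
            for finger, value in self.combined_rmse.items()
        ]
        return pd.DataFrame(rows)


def accuracy_report(
    table: pd.DataFrame,
    pooling: str = "pooled_samples",
    threshold_deg: float = PERCEPTION_THRESHOLD_DEG,
) -> AccuracyReport:
    """Summarize a measurement table into per-joint and combined RMSE."""
    if pooling not in POOLING_RULES:
        raise ValueError(f"pooling must be one of {POOLING_RULES}")
    if table.empty:
        raise ValueError("empty measurement table")

    per_joint: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for (finger, joint), sub in table.groupby(["finger", "joint"], sort=False):
        err = (sub["theta_est_deg"] - sub["theta_set_deg"]).to_numpy()
        per_joint[(finger, joint)] = float(np.sqrt(np.mean(err**2)))
        counts[(finger, joint)] = len(sub)

    combined: dict[str, float] = {}
    for finger, sub in table.groupby("finger"):
        if pooling == "pooled_samples":
            sub_err = (sub["theta_est_deg"] - sub["theta_set_deg"]).to_numpy()
            combined[finger] = float(np.sqrt(np.mean(sub_err**2)))
        else:
            joint_values = [v for (f, _), v in per_joint.items() if f == finger]
            combined[finger] = float(np.sqrt(np.mean(np.square(joint_values))))

    below = {key: value < threshold_deg for key, value in per_joint.items()}
    return AccuracyReport(
        per_joint_rmse=per_joint,
        combined_rmse=combined,
        sample_counts=counts,
        below_threshold=below,
        pooling=pooling,
        threshold_deg=threshold_deg,
    )
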