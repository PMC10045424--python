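"""Sensor semantics, per-finger decomposition, calibration, contacts, IMU."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flexglove import (
    CalibrationModel,
    Finger,
    HandPose,
    Joint,
    JointId,
    NoiseModel,
    PlacementVariant,
    build_hand_model,
    calibrate,
    contact_states,
    decompose_finger,
    decompose_frame,
    hand_orientation,
    long_sensor_expected,
    set_pose_for,
    simulate_frame,
)

VARIANTS = list(PlacementVariant)


def quat_to_matrix_oracle(w, x, y, z):
    """Independent oracle: textbook quaternion-to-rotation-matrix formula."""
    n = math.sqrt(w * w + x * x + y * y + z * z)
    w, x, y, z = w / n, x / n, y / n, z / n
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@pytest.fixture(scope="module")
def model():
    return build_hand_model()


class TestLongSensorExpected:
    @pytest.mark.parametrize(
        "variant, finger, angles, expected",
        [
            (PlacementVariant.SMALL, Finger.II, (30, 30, 20), 80.0),
            (PlacementVariant.MEDIUM, Finger.II, (30, 30, 20), 60.0),
            (PlacementVariant.LARGE, Finger.II, (0, 45, 30), 45.0),
            (PlacementVariant.SMALL, Finger.I, (20, 30), 50.0),
            (PlacementVariant.MEDIUM, Finger.I, (20, 30), 50.0),
            (PlacementVariant.LARGE, Finger.I, (20, 30), 30.0),
        ],
    )
    def test_spanned_joint_sums(self, model, variant, finger, angles, expected):
        if finger is Finger.I:
            mcp, ip = angles
            pose = HandPose.zero(model).replace_angles(
                {JointId(finger, Joint.MCP): mcp, JointId(finger, Joint.IP): ip}
            )
        else:
            mcp, pip, dip = angles
            pose = HandPose.zero(model).replace_angles(
                {
                    JointId(finger, Joint.MCP): mcp,
                    JointId(finger, Joint.PIP): pip,
                    JointId(finger, Joint.DIP): dip,
                }
            )
        assert long_sensor_expected(pose, finger, variant) == pytest.approx(expected)

    def test_unknown_variant_rejected(self, model):
        with pytest.raises(ValueError):
            long_sensor_expected(HandPose.zero(model), Finger.II, "huge")


class TestDecomposeFinger:
    @pytest.mark.parametrize(
        "variant, short, long, expected",
        [
            (PlacementVariant.SMALL, 30.0, 80.0, (30.0, 30.0, 20.0)),
            (PlacementVariant.MEDIUM, 20.0, 65.0, (20.0, 45.0, 30.0)),
            (PlacementVariant.LARGE, 20.0, 45.0, (20.0, 45.0, 30.0)),
        ],
    )
    def test_long_finger_decomposition(self, variant, short, long, expected):
        result = decompose_finger(short, long, Finger.III, variant)
        assert result == pytest.approx(expected)

    @pytest.mark.parametrize(
        "variant, short, long, expected",
        [
            (PlacementVariant.SMALL, 20.0, 50.0, (20.0, 30.0)),
            (PlacementVariant.MEDIUM, 20.0, 50.0, (20.0, 30.0)),
            (PlacementVariant.LARGE, 20.0, 30.0, (20.0, 30.0)),
        ],
    )
    def test_thumb_decomposition(self, variant, short, long, expected):
        assert decompose_finger(short, long, Finger.I, variant) == pytest.approx(expected)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_zero_inputs_give_zero_pose(self, variant):
        assert decompose_finger(0.0, 0.0, Finger.II, variant) == pytest.approx((0, 0, 0))

    @given(
        short=st.floats(-20, 70, allow_nan=False),
        long=st.floats(-20, 200, allow_nan=False),
        variant=st.sampled_from(VARIANTS),
    )
    def test_dip_pip_ratio_exact(self, short, long, variant):
        _, pip, dip = decompose_finger(short, long, Finger.IV, variant)
        assert dip == pytest.approx(pip * 2.0 / 3.0, abs=1e-12)

    @given(
        s1=st.floats(-20, 70), s2=st.floats(-20, 70),
        g1=st.floats(-20, 200), g2=st.floats(-20, 200),
        lam=st.floats(0, 1),
        variant=st.sampled_from(VARIANTS),
    )
    def test_affine_in_sensor_inputs(self, s1, s2, g1, g2, lam, variant):
        a = np.array(decompose_finger(s1, g1, Finger.II, variant))
        b = np.array(decompose_finger(s2, g2, Finger.II, variant))
        mixed = decompose_finger(
            lam * s1 + (1 - lam) * s2, lam * g1 + (1 - lam) * g2, Finger.II, variant
        )
        assert np.allclose(mixed, lam * a + (1 - lam) * b, atol=1e-9)

    def test_unknown_inputs_rejected(self):
        with pytest.raises(ValueError):
            decompose_finger(0.0, 0.0, "VI", PlacementVariant.SMALL)
        with pytest.raises(ValueError):
            decompose_finger(0.0, 0.0, Finger.II, "tiny")


class TestDecomposeFrame:
    def test_zero_frame_gives_zero_pose(self, model):
        calib = CalibrationModel.default()
        rng = np.random.default_rng(0)
        frame = simulate_frame(
            HandPose.zero(model), PlacementVariant.MEDIUM, calib, NoiseModel(0, 0), rng
        )
        pose = decompose_frame(frame, calib, PlacementVariant.MEDIUM, model)
        assert all(pose[jid] == pytest.approx(0.0, abs=1e-9) for jid in model.joints)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_round_trip_recovers_pose(self, model, variant):
        calib = CalibrationModel.default()
        rng = np.random.default_rng(1)
        pose = set_pose_for(Finger.II, 30.0, 45.0, model).replace_angles(
            {
                JointId(Finger.I, Joint.MCP): 20.0,
                JointId(Finger.I, Joint.IP): 40.0,
                JointId(Finger.III, Joint.MCP): 50.0,
            }
        )
        frame = simulate_frame(pose, variant, calib, NoiseModel(0, 0), rng)
        estimate = decompose_frame(frame, calib, variant, model)
        for jid in model.joints:
            assert estimate[jid] == pytest.approx(pose[jid], abs=1e-9)

    def test_long_below_short_clamped_and_flagged(self, model):
        calib = CalibrationModel.identity()
        frame = simulate_frame(
            HandPose.zero(model), PlacementVariant.MEDIUM, calib,
            NoiseModel(0, 0), np.random.default_rng(0),
        )
        # long reads 10 deg below short on finger II: negative PIP
        frame = type(frame)(
            timestamp_ms=frame.timestamp_ms,
            flex_short=(0, 30, 0, 0, 0),
            flex_long=(0, 20, 0, 0, 0),
            pressure_raw=frame.pressure_raw,
        )
        pose = decompose_frame(frame, calib, PlacementVariant.MEDIUM, model)
        pip = JointId(Finger.II, Joint.PIP)
        assert pose[pip] == 0.0
        assert pip in pose.out_of_range
        unclamped = decompose_frame(frame, calib, PlacementVariant.MEDIUM, model, clamp=False)
        assert unclamped[pip] == pytest.approx(-10.0)

    def test_thumb_cmc_takes_fixed_value(self):
        model = build_hand_model({"thumb_cmc_fixed_deg": 5.0})
        calib = CalibrationModel.default()
        frame = simulate_frame(
            HandPose.zero(build_hand_model()), PlacementVariant.SMALL, calib,
            NoiseModel(0, 0), np.random.default_rng(0),
        )
        pose = decompose_frame(frame, calib, PlacementVariant.SMALL, model)
        assert pose[JointId(Finger.I, Joint.CMC)] == 5.0

    def test_noise_propagates_with_predicted_variance(self, model):
        # MEDIUM: PIP = long - short, so var(PIP) = sigma_s^2 + sigma_l^2
        calib = CalibrationModel.default()
        noise = NoiseModel(0.5, 0.5)
        rng = np.random.default_rng(7)
        pose = set_pose_for(Finger.II, 30.0, 45.0, model)
        pip = JointId(Finger.II, Joint.PIP)
        errors = []
        for _ in range(3000):
            frame = simulate_frame(pose, PlacementVariant.MEDIUM, calib, noise, rng)
            est = decompose_frame(frame, calib, PlacementVariant.MEDIUM, model)
            errors.append(est[pip] - pose[pip])
        predicted = math.sqrt(0.5**2 + 0.5**2)
        assert np.std(errors) == pytest.approx(predicted, rel=0.05)


class TestCalibrate:
    def test_two_point_line(self):
        counts = [[0, 1023]] * 5
        degs = [[0, 90]] * 5
        model = calibrate(counts, degs)
        assert model.gain_deg_per_count == pytest.approx((90 / 1023,) * 5)
        assert model.offset_deg == pytest.approx((0.0,) * 5, abs=1e-12)
        assert model.residual_rms_deg == pytest.approx((0.0,) * 5, abs=1e-9)

    def test_exact_linear_data_zero_residuals(self):
        counts = [np.arange(0, 1000, 100)] * 5
        degs = [0.1 * np.arange(0, 1000, 100) - 25.0] * 5
        model = calibrate(counts, degs)
        assert model.residual_rms_deg == pytest.approx((0.0,) * 5, abs=1e-9)

    def test_noisy_fit_recovers_gain_within_standard_error(self):
        rng = np.random.default_rng(3)
        true_gain, true_offset, sigma = 0.125, -20.0, 0.5
        counts = np.linspace(0, 1023, 60)
        # OLS standard error of the slope for known sigma
        se = sigma / math.sqrt(np.sum((counts - counts.mean()) ** 2))
        raw, ref = [], []
        for _ in range(5):
            raw.append(counts)
            ref.append(true_gain * counts + true_offset + rng.normal(0, sigma, counts.size))
        model = calibrate(raw, ref)
        for gain in model.gain_deg_per_count:
            assert abs(gain - true_gain) < 3 * se

    def test_insufficient_or_singular_data_rejected(self):
        with pytest.raises(ValueError):
            calibrate([[0]] * 5, [[0]] * 5)
        with pytest.raises(ValueError):
            calibrate([[500, 500]] * 5, [[0, 90]] * 5)


class TestContactStates:
    def test_all_below_threshold(self):
        state = contact_states([0, 10, 100, 200, 511])
        assert state.contacts == (False,) * 5
        assert not state.hand_closed and not state.thumb_opposed

    def test_closed_hand_without_thumb(self):
        state = contact_states([100, 900, 900, 900, 900])
        assert state.hand_closed and not state.thumb_opposed

    def test_thumb_opposition_only(self):
        state = contact_states([900, 0, 0, 0, 0])
        assert state.thumb_opposed and not state.hand_closed

    @given(readings=st.lists(st.integers(0, 1023), min_size=5, max_size=5),
           channel=st.integers(0, 4), bump=st.integers(0, 1023))
    def test_monotone_in_each_reading(self, readings, channel, bump):
        before = contact_states(readings)
        raised = list(readings)
        raised[channel] = min(1023, raised[channel] + bump)
        after = contact_states(raised)
        assert all(b <= a for b, a in zip(before.contacts, after.contacts))


class TestHandOrientation:
    def test_identity_quaternion(self):
        assert np.allclose(hand_orientation((1, 0, 0, 0)), np.eye(3), atol=1e-12)

    def test_quarter_turn_about_z(self):
        s = math.sqrt(2) / 2
        expected = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        assert np.allclose(hand_orientation((s, 0, 0, s)), expected, atol=1e-12)

    @given(
        q=st.tuples(*[st.floats(-1, 1, allow_nan=False) for _ in range(4)]).filter(
            lambda q: sum(v * v for v in q) > 1e-4
        )
    )
    def test_matches_conversion_oracle(self, q):
        mat = hand_orientation(q)
        assert np.allclose(mat, quat_to_matrix_oracle(*q), atol=1e-9)
        assert np.linalg.det(mat) == pytest.approx(1.0, abs=1e-9)

    def test_zero_quaternion_rejected(self):
        with pytest.raises(ValueError):
            hand_orientation((0, 0, 0, 0))
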