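# Methods

## Hand model

The hand is reduced from its 23 anatomical degrees of freedom to 15 hinge
joints: abduction/adduction is dropped at every joint, the carpometacarpal
(CMC) joints of fingers IV and V are dropped entirely (they move only
minimally), and each remaining joint is a 1-DoF hinge. The thumb keeps CMC,
MCP and IP; each long finger keeps MCP, PIP and DIP. Angles follow the
neutral-zero convention — the anatomically neutral posture is 0°, flexion
positive, extension negative — and are degrees at every interface. The
global hand frame sits at the wrist centre with x distal, y radial,
z palmar.

The DIP–PIP tendon coupling is the linear law `θ_DIP = r·θ_PIP` with
`r = 2/3` by default (configurable in (0, 1]). It holds only in free motion
without external forces; the decomposition therefore clamps and flags,
rather than rejects, readings that violate it (e.g. a long-channel reading
below the short one), since on hardware such frames arise from exactly those
external forces. Person-specific quadratic couplings reported in the
literature are out of scope; the linear law is what keeps per-user
calibration minimal.

The 15 angles are carried as the model state even though the coupling makes
one of them dependent at measurement time: the coupling is treated as a
measurement-time constraint, not a reduction of the state, which keeps poses
from external sources (motion capture, trajectories) representable even when
they violate it.

Range-of-motion defaults come from the accuracy protocol's measurement
ranges (thumb MCP 0–50°, thumb IP 0–90°, finger II MCP 0–70°, finger III
MCP 0–80°, PIP 0–90°, DIP 0–60° via the coupling); fingers IV and V default
to finger III's values, as they are treated analogously throughout. All are
config-overridable. The thumb CMC is carried in every pose but never sensed
("14 of 15"); it takes a configurable fixed value, 0° by default.

## Forward kinematics

Consecutive joint frames follow the classic Denavit–Hartenberg convention,
`T = Rz(θ)·Tz(d)·Tx(a)·Rx(α)`, implemented in closed form and tested against
the explicit product of the four elementary motions (tolerance 1e-10).
Because abduction is excluded, each finger chain is planar: `d = 0`,
`α = 0`, `a` the functional phalanx length, `θ` the flexion angle. The
placement of each finger's flexion plane in the hand frame is a per-finger
base transform; the packaged defaults (knuckle line offset along y, thumb
base rotated 45° toward opposition) are illustrative and expected to be
overridden per subject. Orthonormality of rotation blocks is validated to
1e-9 on construction of base transforms.

Phalanx lengths for FK derive from the anthropometric profile: the proximal
phalanx is 0.58 of the finger length (the mean PIP–MCP/DIP–MCP ratio), and
the remaining 0.42 is split between middle and distal segments 0.55:0.45 by
default — the ratio literature gives only the proximal fraction, so the
split is exposed as a parameter rather than hidden.

## Anthropometric sizing

Skin lengthening over a flexing joint is the arc `ΔL = (2πθ/360)·R`,
treating the joint as a disc of constant radius; helical-axis migration of
the real joint (≤ 1 mm) is neglected. The flexed whole-finger skin length is
the extended length plus the MCP, PIP and DIP arcs at maximum flexion; the
flexed MCP-to-PIP span adds the MCP and PIP arcs to the extended PIP–MCP
distance `(0.58 ± 0.035)·(DIP–MCP distance)`, with the DIP–MCP distance
approximated upward by the total finger length unless an exact value is
supplied.

Placement selection takes the smallest variant whose flexed (worst-case)
span fits the long sensor's 130 mm active length: *small* needs the whole
flexed finger to fit, *medium* the flexed MCP+PIP span, *large* always
fits. A short sensor (55 mm) that would not cover the flexed MCP arc, or
would reach past the extended PIP joint when centred on the MCP, raises a
warning (`SHORT_SENSOR_FIT`) rather than an error — on the real device
sensor stretch is permitted, merely undesirable.

Published percentile tables of finger dimensions are not redistributed
here; the packaged `DEFAULT_PROFILES` are illustrative round-number
profiles bracketing small female and large male hands, and `HandProfile` is
designed to be user-supplied.

## Sensor decomposition

Short channels are 10-bit ADC counts mapped to degrees by a per-channel
linear calibration (least-squares fit from ≥ 2 reference points per
channel, residual RMS reported); long channels arrive angle-valued over a
digital bus and need no calibration. The default simulator calibration is
gain 0.125 °/count, offset −20° — a 10-bit span covering −20° to +107.9°,
with quantization step 0.125° well below the noise floor.

Pressure switches toggle at a configurable ADC threshold (default 512,
contact when the reading reaches the threshold: FSR conductance, and hence
the divider reading, rises with force — the polarity is a design choice, as
is the threshold, since only threshold switching is specified). Hand
closure is the conjunction of the four long-finger contacts; thumb
opposition is the thumb contact. The IMU quaternion, (w, x, y, z) order
everywhere, is normalized and converted to a rotation matrix; the IMU frame
is taken as congruent with the hand frame.

Under the *medium* variant the thumb's long-sensor span is taken as MCP+IP
(same as *small*), since the thumb has no third joint for the span to
drop; only *large* reduces it to IP alone.

## Synthetic glove

The simulator inverts the sensor semantics: short channel =
inverse-calibration of (θ_MCP + Gaussian noise), rounded and clipped to the
ADC range; long channel = spanned-joint sum + Gaussian noise; pressure from
explicit contact flags (a total-flexion closure heuristic is opt-in);
quaternion/accelerometer/gyro copied from the trajectory's motion track.
Defaults: σ = 0.5° on both channels, 10-bit ADC, 50 Hz sampling — the
sampling rate and ADC class match the reported device, while the noise
magnitudes are declared assumptions (the sensors' real noise, drift, creep
and nonlinearity near mechanical limits are not characterized and not
modelled). Zero-mean white Gaussian noise plus uniform quantization is
therefore what passing tests certify; they do not certify robustness to
drift, hysteresis, sensor-glove slip or soft-tissue artefact on a real
hand.

All randomness flows through one seeded `numpy` generator passed
explicitly; identical seeds yield bit-identical streams.

The validation protocol defaults mirror the accuracy sweep: per finger an
MCP grid in 10° steps over its measurement range (thumb 0–50°, index 0–70°,
middle 0–80°) crossed with a 0–90° PIP/IP grid, DIP set by the coupling,
50 repeats per set point at 100 ms intervals — 11 500 frames for fingers
I–III, which keeps a full run in the low seconds on one CPU.

## Validation and reporting

Each frame is decomposed and compared to its set pose; accuracy is RMSE per
joint plus a combined per-finger value, flagged against the 2.5° perception
threshold. Two pooling rules are provided for the combined value: pooling
all samples of all the finger's joints (default) or the RMS of the
per-joint RMSEs; they coincide when per-joint counts are equal. The default
was chosen because it is the natural equal-weight estimator; with unequal
per-joint coverage (the optional grid mask emulating set points unreachable
on stiff hardware) the two rules diverge, which is why both are exposed.

Reference-instrument uncertainty (a goniometer readable to half of its 5°
scale division, i.e. 2.5°) is not injected by default; an optional
reference-noise term exists for sensitivity studies. Decomposed angles are
clamped to the ROM before scoring, which slightly deflates RMSE at grid
edges (set points on the ROM boundary can only err inward); this mirrors
what the device firmware would report.

## Numerical choices

Degrees at all public interfaces, radians internally; orthonormality
tolerance 1e-9; zero-noise round-trip identity holds to 1e-9° for poses
whose MCP angles are representable on the calibration's count grid
(quantization bounds the error by half a count otherwise); human-readable
reports round to two decimals, machine outputs keep full precision; JSON
streams use fixed field order and decimal points regardless of locale.

## CLI

The command-line surface (`simulate`, `decompose`, `validate`, `size`,
`fk`, `budget`) is a thin click layer over the library; `validate` exits
nonzero when any joint exceeds the threshold, making it usable as a CI
gate for sensor configurations. Seeds are always logged.
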