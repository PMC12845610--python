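# Methods

This note records the scientific and numerical choices behind `coilpilot`:
what each model assumes, which parameters matter, what the simulator does
and does not emulate, and where the design was genuinely open.

## Scalp-target geometry

The simplified 10-20 model treats the preauricular-to-preauricular
transverse arc as 180°, so a 10-20 position at fraction *f* of the
transverse distance maps to an arc angle of *f* × 180° from the vertex —
36° for C3. The planar target equations (θ from the ear-axis difference,
α = 100 cos θ, Target_x = MP_x − α tan(36° + θ), Target_y = MP_y + α) are
evaluated with all trigonometry in degrees and solve the problem entirely
in the camera's image plane; depth is passed through unchanged, matching a
5-DOF robot that cannot translate freely along the camera axis.

Choices worth knowing about:

- **Arctangent form.** θ uses the single-argument arctangent, guarded by
  a degenerate-geometry error when |Ear_x| < 1e−6 mm (head rotated ~90° to
  the camera). A quadrant-aware variant (`quadrant_aware=True`) is
  available for poses where the subject may face away.
- **Tangent guard.** The target equation diverges as 36° + θ → 90°;
  inputs within 0.5° of that pole raise rather than return extreme
  coordinates.
- **Head pose.** The pitch/roll formulas from the nasion-ear triangle are
  this package's own definition: roll = arctan(Ear_y / Ear_x) (the ear
  axis's image rotation), pitch = arctan of nasion elevation over its
  forward distance from the preauricular midpoint. Other definitions are
  defensible; these are the simplest that vanish for a level head and are
  exercised end-to-end by the simulator.
- **Vertex proxy.** "Vertex" is not observable from the front. The default
  proxy lifts the preauricular midpoint along the pose-corrected up-axis
  (roll applied about the depth axis, then pitch about the lateral axis)
  by half the ear separation — a hemispherical-head assumption; a 3-point
  centroid base is available as `mode="centroid"`. The estimate is carried
  in the target record for audit but does not enter the planar target
  equations.
- **Pose correction.** Roll is already handled in-plane by θ, so the
  default pipeline applies the equations directly in the camera frame.
  `pose_correct=True` additionally levels head pitch (rotation about the
  lateral axis through the midpoint) before the planar equations and
  rotates the result back. Leveling roll *before* the equations would
  force θ ≡ 0 and bypass the model's own roll compensation, so it is
  deliberately not done.

## Contact sensing

Counts are arbitrary units; no newton calibration is attempted. The
baseline is the arithmetic mean of a pre-contact window (protocol default
50 samples). Negative adjusted counts are allowed — they indicate baseline
drift — and logged; normalization requires a total load above a contact
epsilon (default 1 count) and otherwise raises a no-contact error.

Load categories: ≤ ε no_contact, < 800 insufficient, [800, 1500)
marginal_low, [1500, 4000] optimal, (4000, 6000] marginal_high, > 6000
excessive. The optimal window and the poor-response bounds come from the
observed MEP/load relationship; the two gaps between them carry no
empirical label, hence the explicit *marginal* states. The optimal band is
closed at both ends so a load of exactly 1500 or 4000 counts as optimal.

Balance: deviation = Norm_0 − 0.5 with ch0 the upper sensor, so positive
deviation means the upper sensor is more compressed (coil tilted so its
top digs in). "Balanced" defaults to |deviation| ≤ 0.05; the threshold is
configurable and a sensitivity sweep over 0.02–0.10 is built into the
tilt-experiment module. The safety gate retracts at total ≥ max_load
(inclusive — fail-safe), with an optional hold band below it; the
hardware's actual stop threshold is deployment-specific, so `max_load` is
mandatory configuration with no default in the CLI.

## EMG and MEP analysis

Unit conversion is affine: µV = (raw − 2.5 V) / 500 × 1e6. The band-pass
is a Butterworth design of order 4 in the `butter(4, ...)` convention
(8th-order transfer function for the band), the notch a biquad at 50 Hz
with Q = 30; both run forward-backward (`filtfilt`) for zero net phase.
A Q = 30 notch rings for hundreds of milliseconds, far longer than one
160 ms epoch, so its steady-state rejection (> 40 dB) is only observable
on longer windows; the filter-contract tests therefore probe a 2 s tone
and read amplitudes off the central half of the window. Within a single
epoch the notch mainly suppresses sustained mains contamination, not
transients.

MEP amplitude is Vmax − Vmin over samples with time ∈ [20, 40] ms
(endpoints inclusive; sample time = index / rate, stimulus at t = 0).
Validity is strict: amplitude must *exceed* 50 µV.

The RMT staircase resolves an ambiguity in the clinical rule ("increase if
fewer, decrease if more responses"): the RMT is defined here as the lowest
tested intensity achieving ≥ 5/10 valid responses whose next-lower level
fails the criterion. The search is bidirectional with step 1 %MSO
(configurable 1–5), tests each level at most once, flags subjects who
respond even at the lower search bound, and raises a convergence error
(with full history) when 100 %MSO still fails. 120% RMT is rounded to the
nearest integer — the only rounding rule consistent with the recorded
subject intensities (62 → 74 and 64 → 77).

## Tilt-sweep analysis

The sweep enumerates reference − 4° … reference + 5° inclusive at 1°
steps. Peak ties break toward the lower pitch (toward the top of the
head), consistent with the observation that upward tilt preserves
amplitude. "Decreasing trend" is operationalized — no canonical statistic
exists for it — as a Spearman rank correlation ≤ −0.5 between pitch and
amplitude over the conditions at and above the peak pitch; constant
segments do not count. Each condition's single reading is taken as-is,
matching the logging protocol; `simulate_trial(n_sensor_samples=k)`
implements the proposed refinement of averaging k ≥ 10 sensor readings
per angle.

## Simulator

The simulator generates the study's data shapes with known ground truth;
its defaults are calibrated to the packaged example sweep so synthetic and
logged data are commensurate.

- **Head**: an ellipsoid (semi-axes 75 × 95 × 90 mm lateral × vertical ×
  depth) with preauricular points on the lateral axis, nasion at the front
  level with the ears, posed by yaw/pitch/roll (roll applied last, about
  the depth axis, so the programmed roll equals the in-image ear-axis
  angle). The true C3 sits at parametric angle 36° from the vertex toward
  the left ear on the transverse ellipse. Landmark noise is isotropic
  Gaussian.
- **Suspension**: counts = baseline + 400 counts/mm × compression,
  clipped to 8 mm of travel, with the two sensors 16 mm apart; a tilt
  error of φ adds ± 8 · sin φ mm to the upper/lower compression. At the
  default 2.2 mm approach depth this yields a total load of 1760 counts
  and a balance deviation of ≈ 0.032 per degree of tilt — both matching
  the packaged sweep log (total ≈ 1600–1900, Norm_0 0.37 → 0.69 across
  9°). The linear counts-vs-compression law reflects the suspension's
  capacitance-proportional-to-load behaviour; saturation is the clamp.
- **MEP response**: amplitude = 1800 µV × exp(−φ²/(2·3²)) ×
  trapezoid(load; 800, 1500, 4000, 6000) × logistic((I − RMT)/1 %MSO),
  plus optional Gaussian amplitude noise, floored at 0. The Gaussian tilt
  falloff and trapezoidal load efficacy encode the qualitative findings
  (peak at tangent, optimal pressure window); they are modelling choices,
  not measured curves. The 1800 µV ceiling matches the example sweep's
  peak; "moderate noise" in `simulate_study` means 25 counts of sensor
  noise and 120 µV of amplitude noise — enough to displace the peak by a
  degree or so, as the less-monotonic real trials show.
- **EMG synthesis**: a biphasic wavelet (positive then negative half-sine,
  8 ms total) at 25 ms latency — inside the 20–40 ms window by
  construction — with peak-to-peak amplitude equal to the requested MEP,
  plus background noise, encoded back through the 500×/2.5 V chain.
- **Threshold responder**: for staircase testing, each pulse is valid with
  probability logistic((I − RMT_true)/1 %MSO), so the 50%-response
  intensity is RMT_true exactly.

All randomness flows from explicit seeds (or a shared
`numpy.random.Generator`); identical seeds give identical outputs, to the
byte, in written logs.

What the simulator does **not** emulate: real skull/scalp geometry (the
ellipsoid has no hair, no tissue compliance gradients), electromagnetic
field physics, camera depth noise structure (landmark noise is isotropic,
real depth error is not), sensor hysteresis and drift, or inter-subject
physiological variability beyond the exposed parameters. Passing the
parameter-recovery tests therefore shows the *pipeline* is correct and
well-conditioned at realistic noise levels — not that the angular model
lands on anatomical C3 in real heads, which only the original
human-subject measurements address. The human-subject outcomes (the
12-of-15 balanced-at-peak proportion, the 9-of-15 trend count, individual
MEP magnitudes) are observational findings and are not reproduced here;
the analysis code that *would* compute them from real logs is what is
tested, on synthetic and on the packaged example data.

## Problem sizes

The test suite's statistical checks use 1,000 random landmark sets for the
geometry oracle, 100 seeded staircase runs, 100 noisy-landmark seeds, 50
noiseless trials, and 15-trial synthetic studies — sizes at which every
contract above is sharp (the binomial bands on the staircase and
balanced-at-peak checks are comfortably away from their thresholds) while
the full suite runs in seconds.

## Known limitations

- The pitch/roll and vertex definitions are stand-ins for an
  under-specified measurement procedure; swap them via the documented
  modes if your rig defines them differently.
- The reference robot pitch corresponding to the anatomical 36° varies
  with head tilt and is treated as an external calibration input
  throughout; nothing in this package computes it.
- Coil-thickness offsets are not modelled; tilt conditions are relative
  deviations from a contact reference, not absolute orientations.
- No closed-loop tilt correction is included — the analysis here is
  exactly the open-loop sensing and estimation layer.
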