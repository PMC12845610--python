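"""Ground-truth hardware simulator: head, suspension, and MEP response.

Every analysis module in this package can be exercised end-to-end without
hardware through three small generative models:

``HeadModel``
    An ellipsoidal scalp with a known pose.  Landmarks (nasion, left and
    right preauricular points) are read off the posed surface, optionally
    with isotropic measurement noise, and the true C3 surface point — the
    point 36 degrees from the vertex along the transverse arc toward the
    left ear — comes along as ground truth.

``SuspensionModel``
    A spring suspension holding two capacitive sensors one above the
    other.  Compression maps linearly to capacitance counts (counts =
    baseline + gain * compression, clipped at a maximum travel), and a
    coil tilt error compresses one sensor more than the other through the
    lever arm of half the sensor separation.

``MepModel``
    MEP amplitude as a separable product of a Gaussian falloff in tilt
    error, a trapezoidal efficacy in total load (ramping over
    800-1500 counts, flat to 4000, falling to zero by 6000), and a
    sigmoid recruitment in stimulator intensity around a true threshold —
    plus additive noise, floored at zero.  The same model synthesizes raw
    EMG epochs by embedding a biphasic wavelet of the target peak-to-peak
    amplitude at a 25 ms latency and encoding through the 500x/2.5 V
    acquisition chain.

All randomness flows from explicit seeds; identical seeds give identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .contact_sensing import (AdjustedSample, BaselineCalibration, RawSample,
                              adjust, normalize)
from .head_geometry import HeadLandmarks
from .mep_analysis import EmgEpoch
from .tilt_experiment import (DEFAULT_SWEEP_HIGH, DEFAULT_SWEEP_LOW,
                              DEFAULT_SWEEP_STEP, TiltCondition, TiltTrial,
                              build_sweep)

__all__ = [
    "HeadModel", "SuspensionModel", "MepModel",
    "sample_landmarks", "simulate_sensor_pair", "simulate_mep_amplitude",
    "rmt_pulse_callback", "synthesize_emg_epoch", "simulate_trial",
    "simulate_study",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _rotation(yaw: float, pitch: float, roll: float) -> np.ndarray:
    """World rotation: yaw about y, then pitch about x, then roll about z.

    Roll applied last keeps the in-image ear-axis angle equal to the
    programmed roll for an otherwise neutral pose.
    """
    cy, sy = math.cos(math.radians(yaw)), math.sin(math.radians(yaw))
    cp, sp = math.cos(math.radians(pitch)), math.sin(math.radians(pitch))
    cr, sr = math.cos(math.radians(roll)), math.sin(math.radians(roll))
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[1, 0, 0], [0, cp, -sp], [0, sp, cp]])
    rz = np.array([[cr, -sr, 0], [sr, cr, 0], [0, 0, 1]])
    return rz @ rx @ ry


@dataclass(frozen=True)
class HeadModel:
    """Ellipsoidal head: semi-axes (lateral, vertical, depth) in mm.

    In the head's own frame the preauricular points sit at (+-a, 0, 0),
    the nasion at (0, 0, c) (front of the face, level with the ears), the
    vertex at (0, b, 0).  The true C3 point lies at parametric angle
    ``true_c3_angle`` from the vertex toward the left ear on the
    transverse (x-y) ellipse.  ``yaw``/``pitch``/``roll`` (degrees) and
    ``center`` (mm) pose the head in the camera frame.
    """

    semi_axes: tuple[float, float, float] = (75.0, 95.0, 90.0)
    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    true_c3_angle: float = 36.0

    def __post_init__(self):
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi-axes must be positive")

    def _pose(self, p_local: np.ndarray) -> np.ndarray:
        rot = _rotation(self.yaw, self.pitch, self.roll)
        return rot @ p_local + np.asarray(self.center, dtype=float)

    @property
    def true_c3(self) -> np.ndarray:
        """Ground-truth C3 surface point in the camera frame."""
        a, b, _ = self.semi_axes
        t = math.radians(self.true_c3_angle)
        return self._pose(np.array([-a * math.sin(t), b * math.cos(t), 0.0]))

    @property
    def vertex(self) -> np.ndarray:
        return self._pose(np.array([0.0, self.semi_axes[1], 0.0]))


@dataclass(frozen=True)
class SuspensionModel:
    """Linear spring-suspension capacitance response.

    counts = baseline + counts_per_mm * compression (+ Gaussian noise),
    with per-sensor compression clipped to [0, max_compression].  A tilt
    error rotates the coil about the midpoint between the sensors, so the
    upper sensor (ch0) sees ``+ (separation/2) * sin(tilt)`` extra
    compression and the lower one the opposite.
    """

    sensor_separation: float = 16.0      # mm between upper and lower sensor
    counts_per_mm: float = 400.0         # sensor gain
    baseline_counts: tuple[float, float] = (1000.0, 1200.0)
    noise_sd: float = 0.0                # counts
    max_compression: float = 8.0         # mm of suspension travel

    def __post_init__(self):
        if self.counts_per_mm <= 0:
            raise ValueError("counts_per_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def calibration(self) -> BaselineCalibration:
        """Noise-free calibration at the model's own baseline counts."""
        return BaselineCalibration(baseline_ch0=self.baseline_counts[0],
                                   baseline_ch1=self.baseline_counts[1])


@dataclass(frozen=True)
class MepModel:
    """Separable MEP amplitude model with EMG synthesis parameters."""

    max_amplitude: float = 1800.0        # uV at ideal tilt/load/intensity
    tilt_sigma: float = 3.0              # deg, Gaussian falloff width
    load_window: tuple[float, float, float, float] = (800.0, 1500.0,
                                                      4000.0, 6000.0)
    rmt_true: float = 55.0               # %MSO
    response_scale: float = 1.0          # %MSO, sigmoid recruitment width
    latency_ms: float = 25.0             # MEP onset after the stimulus
    mep_duration_ms: float = 8.0         # biphasic wavelet length
    amplitude_noise_sd: float = 0.0      # uV, additive amplitude noise
    emg_noise_sd: float = 0.0            # uV, background EMG noise

    def __post_init__(self):
        if self.max_amplitude < 0:
            raise ValueError("max_amplitude must be non-negative")
        lo, rise, fall, hi = self.load_window
        if not (lo < rise <= fall < hi):
            raise ValueError(f"load_window must be ordered, got {self.load_window}")

    def load_efficacy(self, total_load: float) -> float:
        """Trapezoidal contact-pressure efficacy in [0, 1]."""
        lo, rise, fall, hi = self.load_window
        if total_load <= lo or total_load >= hi:
            return 0.0
        if total_load < rise:
            return (total_load - lo) / (rise - lo)
        if total_load <= fall:
            return 1.0
        return (hi - total_load) / (hi - fall)

    def response_factor(self, intensity: float) -> float:
        """Sigmoid recruitment in stimulator intensity around the true RMT."""
        z = (intensity - self.rmt_true) / self.response_scale
        return 1.0 / (1.0 + math.exp(-z))

    def response_probability(self, intensity: float) -> float:
        """Probability that one pulse yields a valid (>50 uV) MEP."""
        return self.response_factor(intensity)


def sample_landmarks(head: HeadModel, noise_sd: float = 0.0,
                     seed=None) -> tuple[HeadLandmarks, dict]:
    """Landmarks off the posed ellipsoid, plus ground truth.

    Returns ``(landmarks, truth)`` where ``truth`` carries the true C3
    surface point, the vertex, the (noise-free) preauricular midpoint and
    the target X-Y a direct evaluation of the planar targeting equations
    produces from the noise-free landmarks.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(seed)
    a, b, c = head.semi_axes
    nasion = head._pose(np.array([0.0, 0.0, c]))
    left = head._pose(np.array([-a, 0.0, 0.0]))
    right = head._pose(np.array([a, 0.0, 0.0]))

    # direct closed-form target from the noise-free landmarks
    ear = right - left
    theta = math.degrees(math.atan(ear[1] / ear[0]))
    alpha = 100.0 * math.cos(math.radians(theta))
    mp = 0.5 * (left + right)
    tx = mp[0] - alpha * math.tan(math.radians(36.0 + theta))
    ty = mp[1] + alpha
    truth = {
        "true_c3": head.true_c3, "vertex": head.vertex,
        "preauricular_midpoint": mp, "theta_deg": theta, "alpha_mm": alpha,
        "target_xy": (tx, ty),
    }
    if noise_sd > 0:
        nasion = nasion + rng.normal(0.0, noise_sd, 3)
        left = left + rng.normal(0.0, noise_sd, 3)
        right = right + rng.normal(0.0, noise_sd, 3)
    return HeadLandmarks(nasion, left, right, frame_id="sim"), truth


def simulate_sensor_pair(tilt_error: float, approach_depth: float,
                         model: SuspensionModel = SuspensionModel(),
                         seed=None) -> RawSample:
    """Raw two-channel counts for a coil at the given tilt and depth.

    ``tilt_error`` is the coil's angular deviation from tangential
    (degrees); positive tilt compresses the upper sensor (ch0) more.
    ``approach_depth`` is the common suspension compression in mm.
    """
    if approach_depth < 0:
        raise ValueError("approach_depth must be non-negative")
    rng = _rng(seed)
    lever = 0.5 * model.sensor_separation * math.sin(math.radians(tilt_error))
    comp0 = float(np.clip(approach_depth + lever, 0.0, model.max_compression))
    comp1 = float(np.clip(approach_depth - lever, 0.0, model.max_compression))
    b0, b1 = model.baseline_counts
    noise = rng.normal(0.0, model.noise_sd, 2) if model.noise_sd > 0 \
        else np.zeros(2)
    return RawSample(ch0=b0 + model.counts_per_mm * comp0 + noise[0],
                     ch1=b1 + model.counts_per_mm * comp1 + noise[1])


def simulate_mep_amplitude(tilt_error: float, total_load: float,
                           intensity: float,
                           model: MepModel = MepModel(),
                           seed=None) -> float:
    """One MEP amplitude draw (uV) under the separable response model."""
    if not (0 < intensity <= 100):
        raise ValueError("intensity must lie in (0, 100] %MSO")
    rng = _rng(seed)
    tilt_factor = math.exp(-tilt_error ** 2 / (2.0 * model.tilt_sigma ** 2))
    amp = (model.max_amplitude * tilt_factor
           * model.load_efficacy(total_load)
           * model.response_factor(intensity))
    if model.amplitude_noise_sd > 0:
        amp += rng.normal(0.0, model.amplitude_noise_sd)
    return max(amp, 0.0)


def rmt_pulse_callback(model: MepModel = MepModel(), seed=None, *,
                       validity_threshold: float = 50.0):
    """Stochastic single-pulse responder for threshold-staircase testing.

    Returns ``stimulate(intensity) -> amplitude_uV`` where each pulse is
    valid with probability ``model.response_probability(intensity)`` — a
    logistic in intensity crossing 50% exactly at ``model.rmt_true``.
    Valid pulses return a clearly supra-threshold amplitude, invalid ones
    a clearly sub-threshold one, with mild jitter.
    """
    rng = _rng(seed)

    def stimulate(intensity: float) -> float:
        p = model.response_probability(intensity)
        if rng.uniform() < p:
            return validity_threshold * 1.5 + rng.uniform(0.0, 10.0)
        return validity_threshold * 0.4 + rng.uniform(0.0, 5.0)

    return stimulate


def synthesize_emg_epoch(mep_amplitude: float,
                         model: MepModel = MepModel(),
                         seed=None, *,
                         sampling_rate: float = 5000.0,
                         duration_ms: float = 160.0,
                         gain: float = 500.0,
                         dc_offset: float = 2.5) -> EmgEpoch:
    """Raw EMG epoch containing a biphasic MEP of the given amplitude.

    The MEP is a positive then negative half-sine lobe pair (total
    ``mep_duration_ms``) starting at ``latency_ms``, with peak-to-peak
    amplitude exactly ``mep_amplitude`` before noise.  Gaussian background
    noise of ``emg_noise_sd`` uV is added, then the trace is encoded back
    through the acquisition chain: volts = offset + uV * 1e-6 * gain.
    """
    if mep_amplitude < 0:
        raise ValueError("mep_amplitude must be non-negative")
    rng = _rng(seed)
    n = int(round(sampling_rate * duration_ms / 1000.0))
    t_ms = np.arange(n) / sampling_rate * 1000.0
    uv = np.zeros(n)
    t0, dur = model.latency_ms, model.mep_duration_ms
    in_wave = (t_ms >= t0) & (t_ms < t0 + dur)
    phase = 2.0 * np.pi * (t_ms[in_wave] - t0) / dur
    uv[in_wave] = 0.5 * mep_amplitude * np.sin(phase)
    if model.emg_noise_sd > 0:
        uv = uv + rng.normal(0.0, model.emg_noise_sd, n)
    volts = dc_offset + uv * 1e-6 * gain
    return EmgEpoch(samples=volts, sampling_rate=sampling_rate,
                    gain=gain, dc_offset=dc_offset)


def simulate_trial(head: HeadModel = HeadModel(),
                   suspension: SuspensionModel = SuspensionModel(),
                   mep: MepModel = MepModel(),
                   tangent_pitch: float = 25.0,
                   seed=None, *,
                   reference_pitch: Optional[float] = None,
                   approach_depth: float = 2.2,
                   intensity: Optional[float] = None,
                   sweep_low: float = DEFAULT_SWEEP_LOW,
                   sweep_high: float = DEFAULT_SWEEP_HIGH,
                   sweep_step: float = DEFAULT_SWEEP_STEP,
                   n_sensor_samples: int = 1,
                   subject_id: str = "sim",
                   trial_id: str = "sim-1") -> tuple[TiltTrial, dict]:
    """One full tilt-sweep trial with ground truth.

    ``tangent_pitch`` is the robot pitch at which the coil is exactly
    tangential to the scalp; the sweep runs around ``reference_pitch``
    (defaulting to the tangent pitch) and at each angle the tilt error is
    ``pitch - tangent_pitch``.  ``n_sensor_samples > 1`` averages several
    sensor readings per condition (the protocol's proposed refinement of
    the single-reading default).  Stimulation defaults to 120% of the
    model's true threshold.

    Returns ``(trial, truth)``; ``truth`` records the tangent pitch, the
    per-condition tilt errors, and the noise-free amplitudes.
    """
    if n_sensor_samples < 1:
        raise ValueError("n_sensor_samples must be >= 1")
    rng = _rng(seed)
    if reference_pitch is None:
        reference_pitch = tangent_pitch
    if intensity is None:
        intensity = min(1.2 * mep.rmt_true, 100.0)
    cal = suspension.calibration
    conditions = []
    tilt_errors = []
    clean_amps = []
    for pitch in build_sweep(reference_pitch, sweep_low, sweep_high,
                             sweep_step):
        tilt_error = pitch - tangent_pitch
        raws = [simulate_sensor_pair(tilt_error, approach_depth, suspension,
                                     rng) for _ in range(n_sensor_samples)]
        raw = RawSample(ch0=float(np.mean([r.ch0 for r in raws])),
                        ch1=float(np.mean([r.ch1 for r in raws])))
        adj = adjust(raw, cal)
        ratio = normalize(adj)
        amp = simulate_mep_amplitude(tilt_error, adj.total_load, intensity,
                                     mep, rng)
        clean = simulate_mep_amplitude(
            tilt_error, adj.total_load, intensity,
            replace(mep, amplitude_noise_sd=0.0))
        conditions.append(TiltCondition(
            robot_pitch=pitch, relative_tilt=pitch - reference_pitch,
            total_load=adj.total_load, norm0=ratio.norm0, norm1=ratio.norm1,
            mep_amplitude=amp))
        tilt_errors.append(tilt_error)
        clean_amps.append(clean)
    trial = TiltTrial(subject_id=subject_id, trial_id=trial_id,
                      reference_pitch=reference_pitch,
                      conditions=tuple(conditions))
    truth = {"tangent_pitch": tangent_pitch, "tilt_errors": tilt_errors,
             "noise_free_amplitudes": clean_amps, "intensity": intensity}
    return trial, truth


def simulate_study(n_trials: int = 15, seed=None, *,
                   head: HeadModel = HeadModel(),
                   suspension: Optional[SuspensionModel] = None,
                   mep: Optional[MepModel] = None,
                   reference_pitch: float = 25.0,
                   tangent_jitter: tuple[float, float] = (-2.0, 3.0),
                   **trial_kwargs) -> list[TiltTrial]:
    """A study of seeded trials with per-trial tangent orientations.

    Each trial draws its true tangent pitch uniformly within
    ``reference_pitch + tangent_jitter`` (so the tangent always lies
    inside the sweep), emulating head-to-head variation in the reference
    calibration.  Default sensor and MEP noise levels are moderate:
    sensor noise 25 counts, amplitude noise 120 uV.
    """
    rng = _rng(seed)
    if suspension is None:
        suspension = SuspensionModel(noise_sd=25.0)
    if mep is None:
        mep = MepModel(amplitude_noise_sd=120.0)
    trials = []
    for i in range(n_trials):
        tangent = reference_pitch + rng.uniform(*tangent_jitter)
        trial, _ = simulate_trial(
            head, suspension, mep, tangent_pitch=tangent, seed=rng,
            reference_pitch=reference_pitch,
            subject_id=f"sim-{i // 3}", trial_id=f"trial-{i}",
            **trial_kwargs)
        trials.append(trial)
    return trials
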