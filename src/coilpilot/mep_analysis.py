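"""EMG preprocessing, MEP amplitude measurement, and motor-threshold search.

A transcranial magnetic stimulus over motor cortex elicits a motor evoked
potential (MEP) in a contralateral hand muscle, recorded by surface EMG.
The acquisition chain digitizes 160 ms epochs at 5000 Hz after a 500x
amplifier centred on a 2.5 V DC offset.  Analysis proceeds:

1.  unit conversion — ``(raw - offset) / gain``, expressed in microvolts;
2.  zero-phase band-pass (20-1000 Hz Butterworth) and 50 Hz notch
    filtering, each applied forward-backward (``filtfilt``) so latencies
    are preserved;
3.  peak-to-peak amplitude ``Vmax - Vmin`` inside the 20-40 ms
    post-stimulus window; responses exceeding 50 uV are valid MEPs.

The resting motor threshold (RMT) is the lowest stimulator intensity
(% of maximum stimulator output, MSO) at which at least 5 of 10 pulses
produce a valid MEP; experimental stimulation then runs at 120% RMT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ConvergenceError

__all__ = [
    "EmgEpoch", "FilterSpec", "MepMeasurement", "RmtResult",
    "to_microvolts", "preprocess", "measure_mep", "analyze_epoch",
    "measure_epochs", "determine_rmt", "suprathreshold_intensity",
]

#: Default MEP validity threshold in microvolts (strict: amplitude must exceed it).
DEFAULT_VALIDITY_UV = 50.0

#: Default post-stimulus measurement window in milliseconds.
DEFAULT_WINDOW_MS = (20.0, 40.0)


@dataclass
class EmgEpoch:
    """One stimulus-locked raw EMG window, in ADC volts.

    The stimulus fires at t = 0, the first sample.  At the defaults
    (160 ms at 5000 Hz) an epoch holds 800 samples.
    """

    samples: np.ndarray
    sampling_rate: float = 5000.0
    gain: float = 500.0
    dc_offset: float = 2.5
    trigger_time: float = 0.0  # ms relative to epoch start

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sampling_rate

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the stimulus."""
        return (np.arange(self.samples.size) / self.sampling_rate * 1000.0
                - self.trigger_time)


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase IIR filtering parameters.

    ``bandpass_order`` is the design order handed to the Butterworth
    band-pass design (the MATLAB ``butter(4, ...)`` convention); the notch
    is a biquad (2nd-order) with the given quality factor.
    """

    bandpass_low: float = 20.0
    bandpass_high: float = 1000.0
    bandpass_order: int = 4
    notch_freq: float = 50.0
    notch_q: float = 30.0
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not (0.0 < self.bandpass_low < self.bandpass_high < nyq):
            raise ValueError(
                f"band edges must satisfy 0 < {self.bandpass_low} < "
                f"{self.bandpass_high} < Nyquist ({nyq})")
        if not (0.0 < self.notch_freq < nyq):
            raise ValueError("notch frequency must lie below Nyquist")


@dataclass(frozen=True)
class MepMeasurement:
    """Peak-to-peak MEP result inside the measurement window."""

    vmax: float
    vmin: float
    amplitude: float
    window: tuple[float, float] = DEFAULT_WINDOW_MS
    valid: bool = False

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class RmtResult:
    """Outcome of a resting-motor-threshold staircase.

    ``history`` lists every tested ``(intensity %MSO, n_valid of
    pulses_per_level)`` in test order.  ``at_lower_bound`` flags the
    degenerate subject who responds even at the lowest allowed intensity.
    """

    rmt: int
    history: tuple[tuple[int, int], ...]
    converged: bool
    at_lower_bound: bool = False

    def __post_init__(self):
        if not (0 < self.rmt <= 100):
            raise ValueError("rmt must lie in (0, 100] %MSO")


def to_microvolts(epoch: EmgEpoch) -> np.ndarray:
    """Convert raw ADC volts to muscle-level microvolts.

    Removes the DC offset, divides out the amplifier gain, and rescales:
    ``uV = (raw - dc_offset) / gain * 1e6``.  Affine and exactly
    invertible.
    """
    return (epoch.samples - epoch.dc_offset) / epoch.gain * 1e6


def preprocess(trace: np.ndarray, spec: FilterSpec = FilterSpec(),
               sampling_rate: float = 5000.0) -> np.ndarray:
    """Band-pass then notch filter a microvolt trace, zero-phase.

    Both stages run forward-backward (``filtfilt``) so the net phase
    response is zero and MEP latencies survive filtering.  Output length
    equals input length.  Raises for traces too short for the filter
    warm-up.
    """
    trace = np.asarray(trace, dtype=float)
    spec.validate(sampling_rate)
    sos = signal.butter(spec.bandpass_order,
                        [spec.bandpass_low, spec.bandpass_high],
                        btype="bandpass", fs=sampling_rate, output="sos")
    # sosfiltfilt needs > 3 * (2 * n_sections + 1) samples of padding room
    min_len = 3 * (2 * sos.shape[0] + 1) + 1
    if trace.size < min_len:
        raise ValueError(
            f"trace of {trace.size} samples is too short for zero-phase "
            f"filtering (need > {min_len})")
    if spec.zero_phase:
        out = signal.sosfiltfilt(sos, trace)
    else:
        out = signal.sosfilt(sos, trace)
    b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=sampling_rate)
    if spec.zero_phase:
        out = signal.filtfilt(b, a, out)
    else:
        out = signal.lfilter(b, a, out)
    return out


def measure_mep(trace: np.ndarray, sampling_rate: float = 5000.0,
                window: tuple[float, float] = DEFAULT_WINDOW_MS,
                validity_threshold: float = DEFAULT_VALIDITY_UV,
                trigger_time: float = 0.0) -> MepMeasurement:
    """Peak-to-peak amplitude within the post-stimulus window.

    ``Vmax`` and ``Vmin`` are taken over samples whose time (ms after the
    stimulus) lies in ``[window[0], window[1]]`` — endpoints inclusive.
    Validity is strict: the amplitude must *exceed* the threshold.
    Content outside the window never affects the result.
    """
    trace = np.asarray(trace, dtype=float)
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window must be increasing, got {window}")
    t = np.arange(trace.size) / sampling_rate * 1000.0 - trigger_time
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError(
            f"measurement window [{lo}, {hi}] ms contains no samples of a "
            f"{trace.size}-sample trace at {sampling_rate} Hz")
    seg = trace[mask]
    vmax = float(seg.max())
    vmin = float(seg.min())
    amp = vmax - vmin
    return MepMeasurement(vmax=vmax, vmin=vmin, amplitude=amp,
                          window=(float(lo), float(hi)),
                          valid=amp > validity_threshold)


def analyze_epoch(epoch: EmgEpoch, spec: FilterSpec = FilterSpec(),
                  window: tuple[float, float] = DEFAULT_WINDOW_MS,
                  validity_threshold: float = DEFAULT_VALIDITY_UV
                  ) -> MepMeasurement:
    """Full single-epoch pipeline: convert, filter, measure."""
    uv = to_microvolts(epoch)
    filt = preprocess(uv, spec, epoch.sampling_rate)
    return measure_mep(filt, epoch.sampling_rate, window,
                       validity_threshold, epoch.trigger_time)


def measure_epochs(epochs: Sequence[EmgEpoch],
                   spec: FilterSpec = FilterSpec(),
                   window: tuple[float, float] = DEFAULT_WINDOW_MS,
                   validity_threshold: float = DEFAULT_VALIDITY_UV
                   ) -> pd.DataFrame:
    """Per-epoch vmax / vmin / amplitude / validity table."""
    rows = []
    for i, ep in enumerate(epochs):
        m = analyze_epoch(ep, spec, window, validity_threshold)
        rows.append({"epoch": i, "vmax_uV": m.vmax, "vmin_uV": m.vmin,
                     "amplitude_uV": m.amplitude, "valid": m.valid})
    return pd.DataFrame(rows)


def determine_rmt(stimulate: Callable[[int], float], *,
                  start_intensity: int = 50,
                  step: int = 1,
                  pulses_per_level: int = 10,
                  validity_threshold: float = DEFAULT_VALIDITY_UV,
                  lower_bound: int = 1,
                  upper_bound: int = 100) -> RmtResult:
    """Bidirectional staircase for the resting motor threshold.

    ``stimulate(intensity)`` delivers one pulse at the given %MSO and
    returns the measured MEP amplitude in microvolts.  At each level,
    ``pulses_per_level`` pulses are delivered and responses exceeding the
    validity threshold are counted.  Fewer than half valid -> raise the
    intensity by ``step``; at least half valid -> try one step lower.  The
    RMT is the lowest tested intensity achieving the >= 50% response rate
    whose next-lower level fails it (or the search's lower bound).  Each
    level is tested at most once; a revisit reuses the recorded count.

    Raises :class:`ConvergenceError` (with the full history) when even the
    upper bound fails the response criterion.
    """
    if not (1 <= step <= 5):
        raise ValueError("step must lie in [1, 5] %MSO")
    if not (0 < lower_bound <= start_intensity <= upper_bound <= 100):
        raise ValueError("need 0 < lower_bound <= start <= upper_bound <= 100")
    need = int(np.ceil(pulses_per_level / 2))  # 5 of 10 at the defaults

    tested: dict[int, int] = {}
    history: list[tuple[int, int]] = []

    def test(level: int) -> int:
        if level not in tested:
            n_valid = sum(
                1 for _ in range(pulses_per_level)
                if stimulate(level) > validity_threshold)
            tested[level] = n_valid
            history.append((level, n_valid))
        return tested[level]

    level = int(start_intensity)
    while True:
        n_valid = test(level)
        if n_valid >= need:
            below = level - step
            if below < lower_bound:
                return RmtResult(rmt=level, history=tuple(history),
                                 converged=True, at_lower_bound=True)
            if below in tested and tested[below] < need:
                return RmtResult(rmt=level, history=tuple(history),
                                 converged=True)
            level = below
        else:
            above = level + step
            if above > upper_bound:
                raise ConvergenceError(
                    f"no intensity up to {upper_bound}% MSO reached "
                    f"{need}/{pulses_per_level} valid responses",
                    history=history)
            if above in tested and tested[above] >= need:
                return RmtResult(rmt=above, history=tuple(history),
                                 converged=True)
            level = above


def suprathreshold_intensity(rmt: float) -> int:
    """Experimental stimulation intensity: 120% of RMT, in %MSO.

    Rounded to the nearest integer; values above 100% MSO are capped with
    a warning (the stimulator cannot exceed its maximum output).
    """
    if not (0 < rmt <= 100):
        raise ValueError("rmt must lie in (0, 100] %MSO")
    out = int(round(1.2 * rmt))
    if out > 100:
        warnings.warn(
            f"120% of RMT {rmt} exceeds maximum stimulator output; "
            "capping at 100% MSO", stacklevel=2)
        out = 100
    return out
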