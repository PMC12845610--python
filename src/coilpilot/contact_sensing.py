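"""Dual capacitive-sensor processing: load, balance, and safety gating.

Two textile capacitive sensors sit behind the TMS coil inside a compliant
suspension, one above the other.  Their digitized outputs ("capacitance
counts") grow with suspension compression, i.e. with coil-scalp contact
pressure.  The processing chain is:

1.  baseline calibration — average a short pre-contact window per channel;
2.  baseline subtraction  — ``adj = raw - baseline`` per channel;
3.  normalization         — ``norm_n = adj_n / (adj_0 + adj_1)``.

The normalized pair sums to one; values near 0.5/0.5 mean both sensors are
equally compressed, i.e. the coil face is tangential to the scalp.  The sum
of the adjusted channels ("total load") is a proxy for overall contact
pressure; empirically, moderate loads (1500-4000 counts) yield the
strongest motor responses, while loads below 800 or above 6000 do not.

Counts are arbitrary units: no conversion to newtons is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import NoContactError

__all__ = [
    "RawSample", "BaselineCalibration", "AdjustedSample", "NormalizedRatio",
    "LoadThresholds", "LoadState", "TiltDirection", "SafetyAction",
    "ContactAssessment", "compute_baseline", "adjust", "normalize",
    "classify_load", "tilt_balance", "safety_gate", "assess_sample",
    "process_stream",
]

logger = logging.getLogger(__name__)

#: Default number of pre-contact samples averaged into the baseline.
DEFAULT_BASELINE_SAMPLES = 50

#: Default minimum total adjusted load (counts) that counts as contact.
DEFAULT_CONTACT_EPSILON = 1.0

#: Default half-width of the "balanced" band around a 0.5/0.5 ratio.
DEFAULT_BALANCE_TOLERANCE = 0.05


@dataclass(frozen=True)
class RawSample:
    """One two-channel capacitance reading (ch0 = upper, ch1 = lower)."""

    ch0: float
    ch1: float
    timestamp: Optional[float] = None

    def __post_init__(self):
        if not (np.isfinite(self.ch0) and np.isfinite(self.ch1)):
            raise ValueError("raw counts must be finite")


@dataclass(frozen=True)
class BaselineCalibration:
    """Per-channel no-contact baseline (counts)."""

    baseline_ch0: float
    baseline_ch1: float
    n_samples: int = DEFAULT_BASELINE_SAMPLES
    sample_buffer: tuple = ()

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name, v in (("baseline_ch0", self.baseline_ch0),
                        ("baseline_ch1", self.baseline_ch1)):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass(frozen=True)
class AdjustedSample:
    """Baseline-subtracted channel counts; total_load is their sum."""

    adj0: float
    adj1: float

    @property
    def total_load(self) -> float:
        return self.adj0 + self.adj1


@dataclass(frozen=True)
class NormalizedRatio:
    """Per-channel share of the total load; the pair sums to one."""

    norm0: float
    norm1: float

    def __post_init__(self):
        if abs(self.norm0 + self.norm1 - 1.0) > 1e-9:
            raise ValueError(
                f"normalized channels must sum to 1, got "
                f"{self.norm0 + self.norm1}")


class LoadState(str, Enum):
    NO_CONTACT = "no_contact"
    INSUFFICIENT = "insufficient"
    MARGINAL_LOW = "marginal_low"
    OPTIMAL = "optimal"
    MARGINAL_HIGH = "marginal_high"
    EXCESSIVE = "excessive"


class TiltDirection(str, Enum):
    BALANCED = "balanced"
    TOWARD_CH0 = "toward_ch0"
    TOWARD_CH1 = "toward_ch1"


class SafetyAction(str, Enum):
    PROCEED = "proceed"
    HOLD = "hold"
    RETRACT = "retract"


@dataclass(frozen=True)
class LoadThresholds:
    """Total-load category boundaries, in counts.

    Defaults encode the empirically observed response window: loads in
    [optimal_low, optimal_high] gave the strongest and most consistent
    MEPs, loads below insufficient_below or above excessive_above gave
    poor ones; the two gaps in between are labelled marginal.
    """

    contact_epsilon: float = DEFAULT_CONTACT_EPSILON
    insufficient_below: float = 800.0
    optimal_low: float = 1500.0
    optimal_high: float = 4000.0
    excessive_above: float = 6000.0

    def __post_init__(self):
        seq = (self.contact_epsilon, self.insufficient_below,
               self.optimal_low, self.optimal_high, self.excessive_above)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"load thresholds must be strictly increasing: {seq}")


@dataclass(frozen=True)
class ContactAssessment:
    """Joint load / balance / safety verdict for one sample."""

    load_state: LoadState
    tilt_deviation: float
    tilt_direction: TiltDirection
    safety_action: SafetyAction


def compute_baseline(samples: Sequence[RawSample],
                     keep_buffer: bool = True) -> BaselineCalibration:
    """Arithmetic per-channel mean over a pre-contact sample window.

    The acquisition protocol collects 50 samples per sensor before the coil
    approaches; any non-empty window is accepted.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("cannot compute a baseline from zero samples")
    b0 = float(np.mean([s.ch0 for s in samples]))
    b1 = float(np.mean([s.ch1 for s in samples]))
    return BaselineCalibration(
        baseline_ch0=b0, baseline_ch1=b1, n_samples=len(samples),
        sample_buffer=tuple(samples) if keep_buffer else ())


def adjust(raw: RawSample, cal: BaselineCalibration) -> AdjustedSample:
    """Subtract the calibration baseline from a raw reading, per channel.

    Negative adjusted counts are permitted (sensor drift below baseline)
    but logged, since they usually indicate the baseline needs refreshing.
    """
    adj0 = raw.ch0 - cal.baseline_ch0
    adj1 = raw.ch1 - cal.baseline_ch1
    if adj0 < 0 or adj1 < 0:
        logger.warning(
            "adjusted counts below zero (adj0=%.1f, adj1=%.1f): "
            "possible baseline drift", adj0, adj1)
    return AdjustedSample(adj0=adj0, adj1=adj1)


def normalize(adj: AdjustedSample,
              contact_epsilon: float = DEFAULT_CONTACT_EPSILON
              ) -> NormalizedRatio:
    """Per-channel share of the total load: norm_n = adj_n / total.

    Raises :class:`NoContactError` when the total load is at or below the
    contact epsilon — without contact the ratio is meaningless.
    """
    total = adj.total_load
    if total <= contact_epsilon:
        raise NoContactError(
            f"total load {total:.2f} <= contact epsilon {contact_epsilon}: "
            "no scalp contact")
    return NormalizedRatio(norm0=adj.adj0 / total, norm1=adj.adj1 / total)


def classify_load(total_load: float,
                  thresholds: LoadThresholds = LoadThresholds()) -> LoadState:
    """Map a total load to its contact-pressure category.

    Boundaries: <= epsilon no_contact; < 800 insufficient; [800, 1500)
    marginal_low; [1500, 4000] optimal; (4000, 6000] marginal_high;
    > 6000 excessive (at the defaults).  The optimal band is closed on
    both ends.
    """
    t = thresholds
    if total_load <= t.contact_epsilon:
        return LoadState.NO_CONTACT
    if total_load < t.insufficient_below:
        return LoadState.INSUFFICIENT
    if total_load < t.optimal_low:
        return LoadState.MARGINAL_LOW
    if total_load <= t.optimal_high:
        return LoadState.OPTIMAL
    if total_load <= t.excessive_above:
        return LoadState.MARGINAL_HIGH
    return LoadState.EXCESSIVE


def tilt_balance(ratio: NormalizedRatio,
                 balance_tolerance: float = DEFAULT_BALANCE_TOLERANCE
                 ) -> tuple[float, TiltDirection]:
    """Deviation of the upper-channel share from 0.5, and its direction.

    Returns ``(deviation, direction)`` with ``deviation = norm0 - 0.5``.
    Positive deviation means the upper sensor (ch0) is the more compressed;
    |deviation| <= tolerance counts as balanced, i.e. the coil is
    approximately tangential to the scalp.
    """
    deviation = ratio.norm0 - 0.5
    if abs(deviation) <= balance_tolerance:
        direction = TiltDirection.BALANCED
    elif deviation > 0:
        direction = TiltDirection.TOWARD_CH0
    else:
        direction = TiltDirection.TOWARD_CH1
    return deviation, direction


def safety_gate(total_load: float, max_load: float,
                guard_band: float = 0.0) -> SafetyAction:
    """Fail-safe gate on total load.

    ``retract`` at or above ``max_load`` (inclusive boundary — fail-safe),
    ``hold`` within ``guard_band`` counts below it, ``proceed`` otherwise.
    """
    if max_load <= 0:
        raise ValueError("max_load must be positive")
    if guard_band < 0:
        raise ValueError("guard_band must be non-negative")
    if total_load >= max_load:
        return SafetyAction.RETRACT
    if total_load >= max_load - guard_band:
        return SafetyAction.HOLD
    return SafetyAction.PROCEED


def assess_sample(raw: RawSample, cal: BaselineCalibration, *,
                  thresholds: LoadThresholds = LoadThresholds(),
                  balance_tolerance: float = DEFAULT_BALANCE_TOLERANCE,
                  max_load: float = 6000.0,
                  guard_band: float = 0.0) -> ContactAssessment:
    """Full chain for one sample: adjust, classify, balance, safety-gate.

    When there is no contact the tilt fields degenerate to
    ``(0, balanced)`` — the ratio is undefined without load.
    """
    adj = adjust(raw, cal)
    state = classify_load(adj.total_load, thresholds)
    try:
        ratio = normalize(adj, thresholds.contact_epsilon)
        deviation, direction = tilt_balance(ratio, balance_tolerance)
    except NoContactError:
        deviation, direction = 0.0, TiltDirection.BALANCED
    action = safety_gate(adj.total_load, max_load, guard_band)
    return ContactAssessment(load_state=state, tilt_deviation=deviation,
                             tilt_direction=direction, safety_action=action)


def process_stream(stream: pd.DataFrame, cal: BaselineCalibration, *,
                   thresholds: LoadThresholds = LoadThresholds(),
                   balance_tolerance: float = DEFAULT_BALANCE_TOLERANCE,
                   max_load: float = 6000.0,
                   guard_band: float = 0.0) -> pd.DataFrame:
    """Assess every row of a (timestamp, ch0, ch1) stream.

    Returns a log DataFrame with the adjusted counts, total load,
    normalized ratios (NaN when no contact), and the categorical verdicts.
    The tilt sign convention (ch0 = upper sensor; positive deviation =
    upper more compressed) is recorded in ``DataFrame.attrs``.
    """
    rows = []
    for rec in stream.itertuples(index=False):
        raw = RawSample(ch0=float(rec.ch0), ch1=float(rec.ch1),
                        timestamp=float(getattr(rec, "timestamp", np.nan)))
        adj = adjust(raw, cal)
        try:
            ratio = normalize(adj, thresholds.contact_epsilon)
            n0, n1 = ratio.norm0, ratio.norm1
        except NoContactError:
            n0 = n1 = np.nan
        a = assess_sample(raw, cal, thresholds=thresholds,
                          balance_tolerance=balance_tolerance,
                          max_load=max_load, guard_band=guard_band)
        rows.append({
            "timestamp": raw.timestamp, "adj0": adj.adj0, "adj1": adj.adj1,
            "total_load": adj.total_load, "norm0": n0, "norm1": n1,
            "load_state": a.load_state.value,
            "tilt_deviation": a.tilt_deviation,
            "tilt_direction": a.tilt_direction.value,
            "safety_action": a.safety_action.value,
        })
    out = pd.DataFrame(rows)
    out.attrs["tilt_sign_convention"] = (
        "ch0 = upper sensor; positive deviation = upper more compressed")
    return out
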