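"""File schemas: landmarks, sensor streams, EMG epochs, tilt-trial logs.

All files are plain text: CSV for tabular data (comma-separated, UTF-8,
header row required, '.' decimal) and JSON for structured records.  Units
follow the package convention — millimetres and degrees in user-facing
files, microvolts for amplitudes, capacitance counts unlabelled (arbitrary
units).  Readers validate and reject rather than silently coerce; every
writer produces files its paired reader accepts.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .head_geometry import HeadLandmarks
from .mep_analysis import EmgEpoch, FilterSpec
from .tilt_experiment import TiltCondition, TiltTrial

__all__ = [
    "RunConfig", "read_landmarks", "write_landmarks", "read_sensor_stream",
    "read_trial_log", "write_trial_log", "read_epochs", "write_epochs",
    "reference_trial", "load_config",
]

TRIAL_LOG_COLUMNS = ["Trial", "RobotPitchAngle", "TotalLoad", "NormCh0",
                     "NormCh1", "MEP_uV"]

#: Assumed sweep span below the reference; used to infer the reference
#: pitch from a log that does not carry it (the -4 ... +5 protocol).
SWEEP_OFFSET_BELOW_REFERENCE = 4.0


@dataclass
class RunConfig:
    """Validated run configuration shared by the CLI commands."""

    balance_tolerance: float = 0.05
    validity_threshold_uv: float = 50.0
    max_load: float = 6000.0
    guard_band: float = 0.0
    load_thresholds: tuple[float, float, float, float] = (800.0, 1500.0,
                                                          4000.0, 6000.0)
    sweep: tuple[float, float, float] = (-4.0, 5.0, 1.0)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        t = self.load_thresholds
        if not all(a < b for a, b in zip(t, t[1:])):
            raise ValueError(f"load thresholds must be increasing: {t}")
        if not (0 < self.balance_tolerance < 0.5):
            raise ValueError("balance_tolerance must lie in (0, 0.5)")
        if self.max_load <= 0:
            raise ValueError("max_load must be positive")
        low, high, step = self.sweep
        if low > high or step <= 0:
            raise ValueError(f"invalid sweep spec {self.sweep}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else
                 v.__dict__ if isinstance(v, FilterSpec) else v)
             for k, v in self.__dict__.items()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read a JSON run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = json.load(fh)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    if "filter_spec" in raw:
        raw["filter_spec"] = FilterSpec(**raw["filter_spec"])
    for key in ("load_thresholds", "sweep"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# landmarks

def read_landmarks(path) -> HeadLandmarks:
    """Read landmarks from JSON ({key: [x, y, z]}) or CSV (name,x,y,z)."""
    path = Path(path)
    keys = ("nasion", "left_preauricular", "right_preauricular")
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        missing = [k for k in keys if k not in data]
        if missing:
            raise SchemaError(f"landmark file missing keys: {missing}")
        pts = {k: data[k] for k in keys}
        frame_id = data.get("frame_id", "file")
    else:
        df = pd.read_csv(path)
        for col in ("name", "x", "y", "z"):
            if col not in df.columns:
                raise SchemaError(f"landmark CSV missing column {col!r}")
        rows = {str(name): [x, y, z]
                for name, x, y, z in zip(df["name"], df["x"], df["y"],
                                         df["z"])}
        missing = [k for k in keys if k not in rows]
        if missing:
            raise SchemaError(f"landmark CSV missing rows: {missing}")
        pts = {k: rows[k] for k in keys}
        frame_id = "file"
    try:
        return HeadLandmarks(pts["nasion"], pts["left_preauricular"],
                             pts["right_preauricular"], frame_id=frame_id)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"invalid landmark coordinates: {exc}") from exc


def write_landmarks(landmarks: HeadLandmarks, path) -> None:
    payload = {
        "nasion": list(map(float, landmarks.nasion)),
        "left_preauricular": list(map(float, landmarks.left_preauricular)),
        "right_preauricular": list(map(float, landmarks.right_preauricular)),
        "frame_id": landmarks.frame_id,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# sensor streams

def read_sensor_stream(path) -> pd.DataFrame:
    """Read a (timestamp, ch0, ch1) CSV stream; all cells must be numeric."""
    df = pd.read_csv(path)
    for col in ("timestamp", "ch0", "ch1"):
        if col not in df.columns:
            raise SchemaError(f"sensor stream missing column {col!r}")
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(vals.isna().idxmax())
            raise SchemaError(
                f"non-numeric value in column {col!r} at row {bad}")
        df[col] = vals
    if df.empty:
        raise SchemaError("sensor stream has no rows")
    return df


# ---------------------------------------------------------------------------
# tilt-trial logs

def read_trial_log(path, *, reference_pitch: Optional[float] = None,
                   subject_id: Optional[str] = None) -> TiltTrial:
    """Parse a tilt-trial log CSV into a sorted :class:`TiltTrial`.

    The schema is one row per tilt condition with columns
    ``Trial, RobotPitchAngle, TotalLoad, NormCh0, NormCh1, MEP_uV``.
    When ``reference_pitch`` is not given it is inferred from the sweep
    protocol (4 degrees above the lowest pitch).  Norm pairs more than 0.1
    from summing to 1 raise a schema error; deviations beyond 0.01 (more
    than 2-dp rounding can explain) only warn.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("trial log is empty") from exc
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial log missing columns: {missing}")
    if df.empty:
        raise SchemaError("trial log has no rows")
    for col in TRIAL_LOG_COLUMNS[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(vals.isna().idxmax())
            raise SchemaError(
                f"non-numeric value in column {col!r} at row {bad}")
        df[col] = vals

    sums = (df["NormCh0"] + df["NormCh1"] - 1.0).abs()
    if (sums > 0.1).any():
        bad = int((sums > 0.1).idxmax())
        raise SchemaError(
            f"NormCh0 + NormCh1 far from 1 at row {bad}: "
            f"{df['NormCh0'][bad]} + {df['NormCh1'][bad]}")
    if (sums > 0.01).any():
        warnings.warn("normalized channel sums deviate from 1 by more than "
                      "0.01; check the log", stacklevel=2)

    trial_id = str(df["Trial"].iloc[0])
    if reference_pitch is None:
        reference_pitch = float(df["RobotPitchAngle"].min()
                                + SWEEP_OFFSET_BELOW_REFERENCE)
    conditions = tuple(
        TiltCondition(
            robot_pitch=float(r.RobotPitchAngle),
            relative_tilt=float(r.RobotPitchAngle) - reference_pitch,
            total_load=float(r.TotalLoad),
            norm0=float(r.NormCh0), norm1=float(r.NormCh1),
            mep_amplitude=float(r.MEP_uV))
        for r in df.itertuples(index=False))
    return TiltTrial(subject_id=subject_id or trial_id, trial_id=trial_id,
                     reference_pitch=reference_pitch, conditions=conditions)


def write_trial_log(trial: TiltTrial, path) -> None:
    trial.to_frame().to_csv(path, index=False)


def reference_trial() -> TiltTrial:
    """The packaged example tilt-sweep log (one subject, one session).

    A ten-condition sweep around a 25-degree robot-pitch reference,
    recorded with the dual-sensor coil holder; useful as a worked example
    and as a deterministic regression input.
    """
    ref = resources.files("coilpilot.data") / "reference_tilt_trial.csv"
    with resources.as_file(ref) as p:
        return read_trial_log(p, reference_pitch=25.0, subject_id="A")


# ---------------------------------------------------------------------------
# EMG epochs

def read_epochs(path, sidecar=None) -> list[EmgEpoch]:
    """Read EMG epochs from delimited text, one column per epoch.

    The optional JSON sidecar supplies ``sampling_rate``, ``gain`` and
    ``dc_offset`` (acquisition defaults otherwise).
    """
    meta = {}
    if sidecar is not None:
        with open(sidecar) as fh:
            meta = json.load(fh)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("epoch file is empty") from exc
    if df.empty:
        raise SchemaError("epoch file has no rows")
    arr = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise SchemaError("epoch file contains non-finite values")
    kwargs = {k: meta[k] for k in ("sampling_rate", "gain", "dc_offset")
              if k in meta}
    return [EmgEpoch(samples=arr[:, j], **kwargs)
            for j in range(arr.shape[1])]


def write_epochs(epochs: Sequence[EmgEpoch], path, sidecar=None) -> None:
    data = {f"epoch_{i}": ep.samples for i, ep in enumerate(epochs)}
    pd.DataFrame(data).to_csv(path, index=False)
    if sidecar is not None and epochs:
        with open(sidecar, "w") as fh:
            json.dump({"sampling_rate": epochs[0].sampling_rate,
                       "gain": epochs[0].gain,
                       "dc_offset": epochs[0].dc_offset}, fh, indent=2)
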