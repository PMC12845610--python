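"""Scalp-target estimation from three facial landmarks.

The C3 electrode position of the international 10-20 system (over left
primary motor cortex) is normally located with a tape measure using four
cranial landmarks, two of which (inion, vertex) a front-facing depth camera
cannot see.  This module implements the simplified angular model that works
from the three visible landmarks only — nasion and the two preauricular
points:

* the preauricular-to-preauricular distance is taken as the full transverse
  arc, 180 degrees in angular terms, so the 10-20 rule "C3 lies 20% of the
  transverse distance from the vertex" becomes a 36-degree arc angle;
* the in-image rotation of the ear axis (``theta``) corrects the target for
  head roll;
* a fixed approach reach of 100 mm from the preauricular midpoint stands in
  for the unmeasurable head height, foreshortened by ``cos(theta)``.

All angles in the public API are degrees.  The coordinate convention is a
camera-style frame: x toward the subject's right in the image, y toward the
vertex, z depth (toward the camera).  Ear differences are right-minus-left.
Depth (z) is passed through unchanged: the targeting problem is solved in
the image X-Y plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateGeometryError

__all__ = [
    "HeadLandmarks",
    "HeadPose",
    "C3Target",
    "c3_arc_angle",
    "ear_axis_angle",
    "approach_offset",
    "target_xy",
    "estimate_head_pose",
    "estimate_vertex",
    "localize_c3",
]

#: Default reach from the preauricular midpoint toward the target, in mm.
DEFAULT_REACH_MM = 100.0

#: Default transverse arc fraction for C3 (20% of the half-circumference).
DEFAULT_ARC_FRACTION = 0.20

#: Default transverse arc span in degrees (ear-to-ear treated as 180 deg).
DEFAULT_ARC_SPAN_DEG = 180.0

#: |Ear_x| below this (mm) means the head is rotated ~90 deg to the camera.
EAR_X_TOLERANCE_MM = 1e-6

#: How close (deg) the combined angle may come to 90 before tan() blows up.
TANGENT_GUARD_DEG = 0.5


def _as_point(p, name: str) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} has non-finite coordinates: {arr}")
    return arr


@dataclass(frozen=True)
class HeadLandmarks:
    """The three visible anatomical landmarks, in millimetres.

    Attributes
    ----------
    nasion : (3,) array
        Bridge of the nose, at the frontonasal suture.
    left_preauricular, right_preauricular : (3,) array
        Points just anterior to each ear ("left"/"right" are the
        subject's own sides).
    frame_id : str
        Label of the coordinate frame the points are expressed in.
    """

    nasion: np.ndarray
    left_preauricular: np.ndarray
    right_preauricular: np.ndarray
    frame_id: str = "camera"

    def __post_init__(self):
        object.__setattr__(self, "nasion", _as_point(self.nasion, "nasion"))
        object.__setattr__(
            self, "left_preauricular",
            _as_point(self.left_preauricular, "left_preauricular"))
        object.__setattr__(
            self, "right_preauricular",
            _as_point(self.right_preauricular, "right_preauricular"))
        if np.allclose(self.left_preauricular, self.right_preauricular):
            raise DegenerateGeometryError(
                "left and right preauricular points coincide")

    @property
    def preauricular_midpoint(self) -> np.ndarray:
        """Midpoint MP of the two preauricular points (mm)."""
        return 0.5 * (self.left_preauricular + self.right_preauricular)

    @property
    def ear_vector(self) -> np.ndarray:
        """Right-minus-left preauricular difference vector (mm)."""
        return self.right_preauricular - self.left_preauricular

    def translated(self, delta) -> "HeadLandmarks":
        d = _as_point(delta, "delta")
        return HeadLandmarks(self.nasion + d, self.left_preauricular + d,
                             self.right_preauricular + d, self.frame_id)


@dataclass(frozen=True)
class HeadPose:
    """Head orientation estimated from the nasion-ear triangle (degrees)."""

    pitch: float
    roll: float

    def __post_init__(self):
        for name, v in (("pitch", self.pitch), ("roll", self.roll)):
            if not (-90.0 < v < 90.0):
                raise ValueError(f"{name} must lie in (-90, 90) deg, got {v}")


@dataclass(frozen=True)
class C3Target:
    """Estimated C3 scalp target and the quantities that produced it."""

    target_x: float
    target_y: float
    target_z: float
    ear_axis_angle_theta: float
    offset_alpha: float
    c3_arc_angle: float
    vertex_estimate: np.ndarray = field(
        default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if not (0.0 < self.offset_alpha <= DEFAULT_REACH_MM):
            raise ValueError(
                f"offset_alpha must lie in (0, {DEFAULT_REACH_MM}] mm, "
                f"got {self.offset_alpha}")
        if not (0.0 < self.c3_arc_angle < 90.0):
            raise ValueError(
                f"c3_arc_angle must lie in (0, 90) deg, got {self.c3_arc_angle}")
        object.__setattr__(self, "vertex_estimate",
                           np.asarray(self.vertex_estimate, dtype=float))

    @property
    def target(self) -> np.ndarray:
        return np.array([self.target_x, self.target_y, self.target_z])

    def to_dict(self) -> dict:
        return {
            "target_x": self.target_x,
            "target_y": self.target_y,
            "target_z": self.target_z,
            "ear_axis_angle_theta": self.ear_axis_angle_theta,
            "offset_alpha": self.offset_alpha,
            "c3_arc_angle": self.c3_arc_angle,
            "vertex_estimate": list(map(float, self.vertex_estimate)),
        }


def c3_arc_angle(arc_fraction: float = DEFAULT_ARC_FRACTION,
                 arc_span: float = DEFAULT_ARC_SPAN_DEG) -> float:
    """Arc angle of the target from the vertex, in degrees.

    With the ear-to-ear transverse arc treated as ``arc_span`` degrees, a
    10-20 position at ``arc_fraction`` of the transverse distance sits at
    ``arc_fraction * arc_span`` degrees from the vertex.  For C3 the
    fraction is 0.20, giving 36 degrees.
    """
    if not (0.0 < arc_fraction < 1.0):
        raise ValueError(f"arc_fraction must lie in (0, 1), got {arc_fraction}")
    if arc_span <= 0.0:
        raise ValueError(f"arc_span must be positive, got {arc_span}")
    return arc_fraction * arc_span


def ear_axis_angle(landmarks: HeadLandmarks, *,
                   quadrant_aware: bool = False) -> float:
    """In-image rotation theta of the ear axis, in degrees.

    theta = arctan(Ear_y / Ear_x) with Ear = right - left preauricular.
    The single-argument arctangent keeps theta in (-90, 90); the
    ``quadrant_aware`` variant uses atan2 and can return the full circle
    (useful when the subject may face away from the camera).
    """
    ear = landmarks.ear_vector
    if abs(ear[0]) < EAR_X_TOLERANCE_MM:
        raise DegenerateGeometryError(
            "preauricular x-separation is ~0: head rotated ~90 deg to camera")
    if quadrant_aware:
        return math.degrees(math.atan2(ear[1], ear[0]))
    return math.degrees(math.atan(ear[1] / ear[0]))


def approach_offset(theta: float, reach: float = DEFAULT_REACH_MM) -> float:
    """Foreshortened approach offset alpha = reach * cos(theta), in mm.

    The reach (default 100 mm) is the fixed distance from the preauricular
    midpoint toward the scalp target, standing in for the head height the
    camera cannot measure; head roll theta foreshortens it in the image
    plane.
    """
    if not (-90.0 < theta < 90.0):
        raise ValueError(f"theta must lie in (-90, 90) deg, got {theta}")
    return reach * math.cos(math.radians(theta))


def target_xy(mp, theta: float, *,
              arc_angle: float | None = None,
              reach: float = DEFAULT_REACH_MM) -> tuple[float, float]:
    """Target X-Y from the preauricular midpoint MP and roll angle theta.

    Target_x = MP_x - alpha * tan(arc_angle + theta)
    Target_y = MP_y + alpha,          alpha = reach * cos(theta)

    All angles in degrees.  Raises when ``arc_angle + theta`` comes within
    half a degree of 90, where the tangent diverges.
    """
    if arc_angle is None:
        arc_angle = c3_arc_angle()
    combined = arc_angle + theta
    if abs(combined - 90.0) < TANGENT_GUARD_DEG:
        raise DegenerateGeometryError(
            f"arc_angle + theta = {combined:.3f} deg is within "
            f"{TANGENT_GUARD_DEG} deg of 90: tangent diverges")
    alpha = approach_offset(theta, reach)
    mp = np.asarray(mp, dtype=float)
    tx = float(mp[0]) - alpha * math.tan(math.radians(combined))
    ty = float(mp[1]) + alpha
    return tx, ty


def estimate_head_pose(landmarks: HeadLandmarks) -> HeadPose:
    """Pitch and roll of the head from the nasion-ear triangle, in degrees.

    roll
        Rotation of the ear axis in the image plane:
        arctan(Ear_y / Ear_x), positive when the subject's right ear sits
        higher in the image than the left.
    pitch
        Elevation of the nasion above the preauricular midpoint over its
        forward (x-z plane) distance: arctan(dy / d_forward), positive when
        the nasion is above the ear line (head tipped back).
    """
    ear = landmarks.ear_vector
    if abs(ear[0]) < EAR_X_TOLERANCE_MM:
        raise DegenerateGeometryError(
            "preauricular x-separation is ~0: cannot estimate roll")
    roll = math.degrees(math.atan(ear[1] / ear[0]))

    mp = landmarks.preauricular_midpoint
    rel = landmarks.nasion - mp
    forward = math.hypot(rel[0], rel[2])
    if forward < EAR_X_TOLERANCE_MM:
        raise DegenerateGeometryError(
            "nasion lies on the vertical axis through the preauricular "
            "midpoint: nasion-ear triangle is degenerate")
    pitch = math.degrees(math.atan(rel[1] / forward))
    return HeadPose(pitch=pitch, roll=roll)


def _up_axis(pose: HeadPose) -> np.ndarray:
    """Head-up unit vector: +y rotated by roll (about z) then pitch (about x)."""
    r = math.radians(pose.roll)
    p = math.radians(pose.pitch)
    rz = np.array([[math.cos(r), -math.sin(r), 0.0],
                   [math.sin(r), math.cos(r), 0.0],
                   [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0],
                   [0.0, math.cos(p), -math.sin(p)],
                   [0.0, math.sin(p), math.cos(p)]])
    return rx @ (rz @ np.array([0.0, 1.0, 0.0]))


def estimate_vertex(landmarks: HeadLandmarks, *, mode: str = "midpoint",
                    lift: float | None = None) -> np.ndarray:
    """Proxy for the vertex (Cz), which the camera cannot see directly.

    ``mode="midpoint"`` (default): the preauricular midpoint lifted along
    the pose-corrected head-up axis.  ``mode="centroid"``: the centroid of
    all three landmarks lifted the same way.  ``lift`` defaults to half the
    preauricular separation (a hemispherical-head assumption).
    """
    if mode not in ("midpoint", "centroid"):
        raise ValueError(f"unknown vertex mode {mode!r}")
    pose = estimate_head_pose(landmarks)
    if lift is None:
        lift = 0.5 * float(np.linalg.norm(landmarks.ear_vector))
    base = (landmarks.preauricular_midpoint if mode == "midpoint" else
            (landmarks.nasion + landmarks.left_preauricular
             + landmarks.right_preauricular) / 3.0)
    return base + lift * _up_axis(pose)


def localize_c3(landmarks: HeadLandmarks, *,
                arc_fraction: float = DEFAULT_ARC_FRACTION,
                arc_span: float = DEFAULT_ARC_SPAN_DEG,
                reach: float = DEFAULT_REACH_MM,
                pose_correct: bool = False,
                vertex_mode: str = "midpoint",
                quadrant_aware: bool = False) -> C3Target:
    """Full C3 localization pipeline from the three landmarks.

    Composes :func:`ear_axis_angle` -> :func:`approach_offset` ->
    :func:`target_xy` with MP the preauricular midpoint.  Depth (z) is the
    MP depth, passed through unchanged.

    ``pose_correct=True`` additionally removes head pitch before the planar
    equations are applied: the landmarks are rotated about the x-axis
    through MP by -pitch, the target is computed in that levelled frame and
    rotated back.  Roll needs no such treatment — it is already handled
    in-plane by theta.
    """
    work = landmarks
    rot = None
    mp0 = landmarks.preauricular_midpoint
    if pose_correct:
        pose = estimate_head_pose(landmarks)
        p = math.radians(-pose.pitch)
        rot = np.array([[1.0, 0.0, 0.0],
                        [0.0, math.cos(p), -math.sin(p)],
                        [0.0, math.sin(p), math.cos(p)]])
        def unpitch(pt):
            return mp0 + rot @ (pt - mp0)
        work = HeadLandmarks(unpitch(landmarks.nasion),
                             unpitch(landmarks.left_preauricular),
                             unpitch(landmarks.right_preauricular),
                             landmarks.frame_id)

    theta = ear_axis_angle(work, quadrant_aware=quadrant_aware)
    arc = c3_arc_angle(arc_fraction, arc_span)
    alpha = approach_offset(theta, reach)
    mp = work.preauricular_midpoint
    tx, ty = target_xy(mp[:2], theta, arc_angle=arc, reach=reach)
    target = np.array([tx, ty, mp[2]])
    if rot is not None:
        target = mp0 + rot.T @ (target - mp0)
    vertex = estimate_vertex(landmarks, mode=vertex_mode)
    return C3Target(target_x=float(target[0]), target_y=float(target[1]),
                    target_z=float(target[2]), ear_axis_angle_theta=theta,
                    offset_alpha=alpha, c3_arc_angle=arc,
                    vertex_estimate=vertex)
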