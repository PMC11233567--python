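"""IMU-based segment/joint kinematics, filtering, and gait segmentation.

Segment angles are computed from orientation quaternions under a hinge-joint
assumption: one sensor axis is taken to be perfectly aligned with the joint
axis, and the segment angle is the planar rotation about that axis measured
against the gravity-opposing direction.  Joint angles are differences of
adjacent segment angles (e.g. knee = thigh − shank).  Gait events are found
from the foot angle: heel strikes at prominent local maxima, toe-offs at the
foot angular-velocity minimum between consecutive heel strikes; stance
phases (heel strike → toe-off) are then time-normalised to a fixed number of
points for averaging across steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

__all__ = [
    "OrientationTrace",
    "AngleTrace",
    "GaitEvents",
    "lowpass_zero_lag",
    "segment_angle",
    "joint_angle",
    "detect_gait_events",
    "segment_and_normalize",
    "resample_to",
]

DEFAULT_MIN_CYCLE_S = 0.4
DEFAULT_PROMINENCE_FRAC = 0.2
DEFAULT_N_POINTS = 101


@dataclass
class AngleTrace:
    """Segment or joint angle in degrees per frame."""

    angle_deg: np.ndarray
    frame_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        if not np.all(np.isfinite(self.angle_deg)):
            raise ValueError("angle trace contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return self.angle_deg.size


@dataclass
class OrientationTrace:
    """Per-frame sensor orientation (local → global unit quaternions,
    scalar-first w,x,y,z) with the declared joint axis in the sensor local
    frame and the gravity direction in the global frame."""

    quaternions: np.ndarray
    frame_rate: float
    joint_axis: np.ndarray = (1.0, 0.0, 0.0)
    gravity: np.ndarray = (0.0, 0.0, -1.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.quaternions.ndim != 2 or self.quaternions.shape[1] != 4:
            raise ValueError("quaternions must be (n, 4) scalar-first")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions must be unit norm within 1e-6")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.joint_axis = np.asarray(self.joint_axis, dtype=float)
        self.gravity = np.asarray(self.gravity, dtype=float)


@dataclass
class GaitEvents:
    """Heel-strike and toe-off frame indices; each toe-off lies strictly
    between its heel strike and the next one (stance = strike → toe-off)."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=int)
        self.toe_offs = np.asarray(self.toe_offs, dtype=int)
        for name, idx in (("heel_strikes", self.heel_strikes), ("toe_offs", self.toe_offs)):
            if idx.size > 1 and np.any(np.diff(idx) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.toe_offs.size > self.heel_strikes.size:
            raise ValueError("more toe-offs than heel strikes")
        for k, to in enumerate(self.toe_offs):
            if k >= self.heel_strikes.size:
                break
            if not self.heel_strikes[k] < to:
                raise ValueError("each toe-off must follow its heel strike")
            if k + 1 < self.heel_strikes.size and not to < self.heel_strikes[k + 1]:
                raise ValueError("each toe-off must precede the next heel strike")

    def stance_segments(self) -> list[tuple[int, int]]:
        return [
            (int(hs), int(to))
            for hs, to in zip(self.heel_strikes, self.toe_offs)
        ]


def _trace_field(trace) -> str | None:
    for f in ("angle_deg", "torque_nm", "thickness_mm", "depth_mm"):
        if hasattr(trace, f):
            return f
    return None


def lowpass_zero_lag(trace, cutoff: float, order: int = 4, frame_rate: float | None = None):
    """Zero-lag low-pass filter (forward-backward Butterworth).

    Accepts any trace dataclass carrying a data array and ``frame_rate``
    (angle, torque, thickness, boundary) and returns the same type, or a
    plain array when ``frame_rate`` is given explicitly.  Joint traces are
    filtered at 5 Hz for dynamometer/dumbbell work and 10 Hz for locomotion.
    """
    field_name = _trace_field(trace)
    if field_name is not None:
        fs = trace.frame_rate
        x = getattr(trace, field_name)
    else:
        if frame_rate is None:
            raise ValueError("frame_rate required when filtering a plain array")
        fs = frame_rate
        x = np.asarray(trace, dtype=float)
    if cutoff <= 0 or cutoff >= fs / 2:
        raise ValueError(f"cutoff must lie in (0, Nyquist={fs / 2:g}) Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    if field_name is None:
        return y
    return replace(trace, **{field_name: y})


def _normalized(v: np.ndarray, axis: int | None = None) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=axis is not None)
    return v / n


def segment_angle(orient: OrientationTrace, min_axis_gravity_angle_deg: float = 5.0) -> AngleTrace:
    """Planar segment angle about the joint axis, relative to gravity-up.

    For each frame the joint axis is mapped to the global frame, the
    gravity-opposing direction and the rotated segment axis are projected
    into the plane normal to the joint axis, and their signed angle (about
    the joint axis) is returned in degrees, unwrapped over frames.  Zero
    rotation gives 0°; a pure rotation about the joint axis by φ gives φ.

    Raises if the joint axis comes within ``min_axis_gravity_angle_deg`` of
    the gravity line, where the reference plane is undefined.
    """
    a_local = _normalized(orient.joint_axis)
    up = _normalized(-orient.gravity)
    # local segment axis: the direction that is gravity-opposing in the
    # neutral (identity) pose, made orthogonal to the joint axis
    s_local = up - (up @ a_local) * a_local
    if np.linalg.norm(s_local) < math.sin(math.radians(min_axis_gravity_angle_deg)):
        raise ValueError("joint axis is (nearly) parallel to gravity; plane undefined")
    s_local = _normalized(s_local)

    rot = Rotation.from_quat(orient.quaternions, scalar_first=True)
    a_g = rot.apply(a_local)
    s_g = rot.apply(s_local)

    align = np.abs(a_g @ up)
    if np.any(align > math.cos(math.radians(min_axis_gravity_angle_deg))):
        raise ValueError(
            "joint axis within the minimum angle of the gravity line in some frame"
        )
    u_p = _normalized(up[None, :] - (a_g @ up)[:, None] * a_g, axis=1)
    s_p = _normalized(s_g - np.einsum("ij,ij->i", s_g, a_g)[:, None] * a_g, axis=1)
    sin_t = np.einsum("ij,ij->i", np.cross(u_p, s_p), a_g)
    cos_t = np.einsum("ij,ij->i", u_p, s_p)
    ang = np.degrees(np.unwrap(np.arctan2(sin_t, cos_t)))
    return AngleTrace(ang, orient.frame_rate, label=orient.label)


def joint_angle(proximal: AngleTrace, distal: AngleTrace) -> AngleTrace:
    """Joint angle = proximal segment angle − distal segment angle."""
    if len(proximal) != len(distal):
        raise ValueError("segment traces must have equal length")
    if not math.isclose(proximal.frame_rate, distal.frame_rate):
        raise ValueError("segment traces must share a frame rate")
    label = f"{proximal.label}-{distal.label}" if proximal.label or distal.label else ""
    return AngleTrace(proximal.angle_deg - distal.angle_deg, proximal.frame_rate, label)


def detect_gait_events(
    foot_angle: AngleTrace,
    min_cycle: float = DEFAULT_MIN_CYCLE_S,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> GaitEvents:
    """Detect heel strikes and toe-offs from the foot angle.

    Heel strikes are local maxima of the foot angle separated by at least
    ``min_cycle`` seconds with prominence at least ``prominence_frac`` of the
    trace's peak-to-peak amplitude; toe-offs are the minima of the foot
    angular velocity (centred finite difference) strictly between
    consecutive heel strikes.  Returns empty events with a warning when no
    maxima qualify.
    """
    x = foot_angle.angle_deg
    fs = foot_angle.frame_rate
    if x.size <= 2 * min_cycle * fs:
        raise ValueError("trace too short for the requested minimum cycle time")
    distance = max(1, int(round(min_cycle * fs)))
    prominence = prominence_frac * float(np.ptp(x))
    peaks, _ = signal.find_peaks(x, distance=distance, prominence=prominence or None)
    if peaks.size == 0:
        warnings.warn("no heel strikes found", stacklevel=2)
        return GaitEvents(np.empty(0, int), np.empty(0, int))
    velocity = np.gradient(x) * fs
    toe_offs = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        if b - a < 2:
            continue
        toe_offs.append(a + 1 + int(np.argmin(velocity[a + 1 : b])))
    return GaitEvents(peaks, np.asarray(toe_offs, int))


def segment_and_normalize(
    trace,
    segments,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Resample each segment onto ``n_points`` equally spaced relative times.

    ``segments`` is either a :class:`GaitEvents` (stance segments, heel
    strike → toe-off, are used) or an iterable of (start, end) frame index
    pairs with ``end`` inclusive.  Each segment is linearly interpolated
    onto [0, 1]; degenerate (< 2 frame) segments are skipped with a warning.
    Returns a (n_segments, n_points) matrix.
    """
    field_name = _trace_field(trace)
    x = getattr(trace, field_name) if field_name else np.asarray(trace, dtype=float)
    if isinstance(segments, GaitEvents):
        pairs = segments.stance_segments()
    else:
        pairs = [(int(a), int(b)) for a, b in segments]
    grid = np.linspace(0.0, 1.0, n_points)
    rows = []
    for a, b in pairs:
        if b <= a or b >= x.size:
            warnings.warn(f"skipping degenerate segment ({a}, {b})", stacklevel=2)
            continue
        seg = x[a : b + 1]
        rows.append(np.interp(grid, np.linspace(0.0, 1.0, seg.size), seg))
    return np.vstack(rows) if rows else np.empty((0, n_points))


def resample_to(values: np.ndarray, timestamps: np.ndarray, target_timestamps: np.ndarray) -> np.ndarray:
    """Linear interpolation of a trace onto new timestamps (no extrapolation)."""
    t = np.asarray(timestamps, dtype=float)
    tt = np.asarray(target_timestamps, dtype=float)
    x = np.asarray(values, dtype=float)
    if t.size != x.size:
        raise ValueError("values and timestamps lengths differ")
    if tt.min() < t.min() - 1e-12 or tt.max() > t.max() + 1e-12:
        raise ValueError("target timestamps extend beyond the source span")
    return np.interp(tt, t, x)
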