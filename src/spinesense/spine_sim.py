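"""Synthetic session generator for the spinal-curvature pipeline.

Emulates a data collection in which a 50 cm elastic strip carrying ten
retro-reflective markers (50 mm apart) and three accelerometers is worn
along the spine, anchored at C7, while the wearer performs slow scripted
trunk movements inside a motion-capture chamber.  The strip is modelled as
an inextensible chain of equal-length segments whose tangent direction
interpolates linearly (in arc length, on the rotation-vector manifold)
between the vertical base orientation and a top orientation set by the
trunk pose.  Motion is quasi-static, so a noiseless accelerometer reads
the unit gravity reaction expressed in its local frame.

Axis convention throughout: x = right, y = up, z = forward (right-handed).
Positions are in millimetres, accelerations in units of g, time in seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

UP = np.array([0.0, 1.0, 0.0])

#: arc-length positions of the three accelerometers, measured from the top
#: (C7) end of the strip, mm — the clinical attachment offsets.
DEFAULT_SENSOR_ARC_MM = (115.0, 320.0, 440.0)

DEFAULT_N_MARKERS = 10
DEFAULT_SPACING_MM = 50.0

_POSE_BOUNDS = {
    "flexion_deg": (-45.0, 95.0),
    "lateral_deg": (-60.0, 60.0),
    "twist_deg": (-45.0, 45.0),
    "head_raise_deg": (0.0, 90.0),
}


@dataclass(frozen=True)
class PoseParams:
    """Trunk pose: sagittal flexion (+forward), coronal lateral bend
    (+left), axial twist, and the partial-unbend head-raise used by the
    second motion set (degrees)."""

    flexion_deg: float = 0.0
    lateral_deg: float = 0.0
    twist_deg: float = 0.0
    head_raise_deg: float = 0.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in _POSE_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"{name}={v} outside allowed range [{lo}, {hi}]"
                )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.flexion_deg, self.lateral_deg, self.twist_deg, self.head_raise_deg]
        )


NEUTRAL = PoseParams()


@dataclass(frozen=True)
class MotionScript:
    """Ordered key poses with per-pose dwell and inter-pose transition
    durations.  With ``return_to_neutral`` the samplers insert a neutral
    dwell between consecutive key poses (the wearers stood back upright
    between the steps of the first motion set)."""

    keyposes: tuple[PoseParams, ...]
    dwell_s: float = 1.4
    transition_s: float = 1.4
    return_to_neutral: bool = False

    def __post_init__(self) -> None:
        if len(self.keyposes) < 2:
            raise ValueError("a MotionScript needs at least 2 keyposes")
        if self.dwell_s <= 0 or self.transition_s <= 0:
            raise ValueError("dwell_s and transition_s must be > 0")

    @property
    def expanded_poses(self) -> tuple[PoseParams, ...]:
        if not self.return_to_neutral:
            return self.keyposes
        out: list[PoseParams] = [NEUTRAL]
        for p in self.keyposes:
            out.append(p)
            out.append(NEUTRAL)
        return tuple(out)

    @property
    def duration_s(self) -> float:
        n = len(self.expanded_poses)
        return n * self.dwell_s + (n - 1) * self.transition_s


@dataclass
class MocapStream:
    """Timestamped marker frames.  ``points`` is (n_frames, 10, 3) mm with
    NaN rows for markers invisible in that frame; marker row order within a
    frame carries no identity (the capture system reports them unordered)."""

    times: np.ndarray
    points: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("mocap timestamps must be strictly increasing")


@dataclass
class IMUStream:
    """Timestamped accelerometer frames: ``readings`` is (n_frames, 3, 3) g,
    sensors ordered bottom/middle/top along the strip."""

    times: np.ndarray
    readings: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("IMU timestamps must be strictly increasing")


@dataclass
class SimSession:
    participant_id: str
    motion_set: int
    mocap: MocapStream
    imu: IMUStream
    truth_times: np.ndarray
    truth_curves: np.ndarray  # (n_frames, 10, 3) mm, base-anchored, noiseless
    sensor_arc_mm: tuple[float, float, float] = DEFAULT_SENSOR_ARC_MM
    seed: int = 0
    metadata: dict = field(default_factory=dict)


def _top_rotation_rotvec(poses: np.ndarray) -> np.ndarray:
    """Rotation vector of the strip-top orientation for pose parameter rows
    (flexion, lateral, twist, head_raise), degrees.  The head raise undoes
    part of the flexion (raising the head 22.5 deg from a 90 deg forward
    bend leaves 67.5 deg of effective flexion)."""
    flex = poses[:, 0] - poses[:, 3]
    lat = poses[:, 1]
    twist = poses[:, 2]
    # extrinsic y-x-z: R = Rz(lateral) @ Rx(flexion) @ Ry(twist);
    # +flexion about +x tips the top forward, +lateral about +z tips it left.
    eul = np.stack([twist, flex, lat], axis=1)
    return Rotation.from_euler("yxz", eul, degrees=True).as_rotvec()


def _segment_fractions(n_markers: int) -> np.ndarray:
    if n_markers == 2:
        return np.array([1.0])
    return np.arange(n_markers - 1) / (n_markers - 2)


def _curves_from_poses(
    poses: np.ndarray, n_markers: int = DEFAULT_N_MARKERS, spacing_mm: float = DEFAULT_SPACING_MM
) -> np.ndarray:
    """Base-anchored marker positions (n_poses, n_markers, 3) mm for pose
    parameter rows.  Each of the n_markers-1 inter-marker segments is a
    straight 'spacing_mm' link pointing along the interpolated tangent, so
    consecutive marker distances and total strip length are exact."""
    rotvecs = _top_rotation_rotvec(poses)  # (P, 3)
    fr = _segment_fractions(n_markers)  # (S,)
    seg_rv = rotvecs[:, None, :] * fr[None, :, None]  # (P, S, 3)
    P, S, _ = seg_rv.shape
    dirs = Rotation.from_rotvec(seg_rv.reshape(-1, 3)).apply(UP).reshape(P, S, 3)
    pts = np.zeros((P, n_markers, 3))
    pts[:, 1:, :] = np.cumsum(dirs * spacing_mm, axis=1)
    return pts


def spine_from_pose(
    pose: PoseParams,
    n_markers: int = DEFAULT_N_MARKERS,
    spacing_mm: float = DEFAULT_SPACING_MM,
) -> np.ndarray:
    """Marker positions (n_markers, 3) mm for a single pose, first marker at
    the origin, consecutive markers exactly ``spacing_mm`` apart."""
    if n_markers < 2:
        raise ValueError("n_markers must be >= 2")
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")
    return _curves_from_poses(pose.as_array()[None, :], n_markers, spacing_mm)[0]


def script_motion(set_id: int) -> MotionScript:
    """The two scripted motion sets of the data collection.

    Set 1 (10 steps, neutral stance between steps): 90 deg forward flexion,
    maximal extension, left/right lateral flexion, the four
    flexion/extension x lateral combinations, and left/right axial rotation.

    Set 2 (9 steps, continuous): starting from 90 deg flexion bent to the
    right, alternating lateral sweeps and head raises (22.5, 30, 45 deg
    above horizontal), ending back at upright stance.
    """
    if set_id == 1:
        steps = [
            PoseParams(flexion_deg=90.0),
            PoseParams(flexion_deg=-30.0),
            PoseParams(lateral_deg=45.0),
            PoseParams(lateral_deg=-45.0),
            PoseParams(flexion_deg=45.0, lateral_deg=30.0),
            PoseParams(flexion_deg=45.0, lateral_deg=-30.0),
            PoseParams(flexion_deg=-20.0, lateral_deg=30.0),
            PoseParams(flexion_deg=-20.0, lateral_deg=-30.0),
            PoseParams(twist_deg=30.0),
            PoseParams(twist_deg=-30.0),
        ]
        return MotionScript(tuple(steps), return_to_neutral=True)
    if set_id == 2:
        f, lat = 90.0, 30.0
        steps = [
            PoseParams(flexion_deg=f, lateral_deg=-lat),
            PoseParams(flexion_deg=f, lateral_deg=lat),
            PoseParams(flexion_deg=f, lateral_deg=lat, head_raise_deg=22.5),
            PoseParams(flexion_deg=f, lateral_deg=-lat, head_raise_deg=22.5),
            PoseParams(flexion_deg=f, lateral_deg=-lat, head_raise_deg=30.0),
            PoseParams(flexion_deg=f, lateral_deg=lat, head_raise_deg=30.0),
            PoseParams(flexion_deg=f, lateral_deg=lat, head_raise_deg=45.0),
            PoseParams(flexion_deg=f, lateral_deg=-lat, head_raise_deg=45.0),
            NEUTRAL,
        ]
        return MotionScript(tuple(steps), return_to_neutral=False)
    raise ValueError(f"unknown motion set id {set_id}; valid ids are 1 and 2")


def _pose_track(script: MotionScript, times: np.ndarray) -> np.ndarray:
    """Piecewise-linear pose parameters (n_times, 4) along the script
    timeline: hold each expanded pose for dwell_s, interpolate linearly over
    transition_s between consecutive poses."""
    poses = np.array([p.as_array() for p in script.expanded_poses])
    n = len(poses)
    knot_t, knot_v = [], []
    t = 0.0
    for i in range(n):
        knot_t.extend([t, t + script.dwell_s])
        knot_v.extend([poses[i], poses[i]])
        t += script.dwell_s + (script.transition_s if i < n - 1 else 0.0)
    knot_t = np.array(knot_t)
    knot_v = np.array(knot_v)
    out = np.empty((len(times), 4))
    for j in range(4):
        out[:, j] = np.interp(times, knot_t, knot_v[:, j])
    return out


def sample_mocap(
    script: MotionScript,
    rate_hz: float = 120.0,
    dropout_prob: float = 0.02,
    jitter_mm: float = 0.5,
    seed: int = 0,
    n_markers: int = DEFAULT_N_MARKERS,
    spacing_mm: float = DEFAULT_SPACING_MM,
    chamber_offset_mm: np.ndarray | None = None,
) -> MocapStream:
    """Simulate the optical capture of the marker strip.

    Frames are sampled at ``rate_hz`` over the script's duration; marker
    positions get Gaussian jitter of SD ``jitter_mm``, each frame's marker
    rows are randomly permuted (the capture system reports markers without
    identity), and with probability ``dropout_prob`` a frame loses one or
    two markers (rows set to NaN).  Positions are chamber-centred: the strip
    base sits at ``chamber_offset_mm`` (random within +-0.5 m if None).
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be > 0")
    if not (0.0 <= dropout_prob < 1.0):
        raise ValueError("dropout_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, script.duration_s, 1.0 / rate_hz)
    curves = _curves_from_poses(_pose_track(script, times), n_markers, spacing_mm)
    if chamber_offset_mm is None:
        chamber_offset_mm = rng.uniform(-500.0, 500.0, size=3)
    pts = curves + np.asarray(chamber_offset_mm, float)
    if jitter_mm > 0:
        pts = pts + rng.normal(0.0, jitter_mm, size=pts.shape)
    F = len(times)
    for i in range(F):
        pts[i] = pts[i][rng.permutation(n_markers)]
    drop = rng.random(F) < dropout_prob
    for i in np.flatnonzero(drop):
        k = rng.integers(1, 3)
        gone = rng.choice(n_markers, size=k, replace=False)
        pts[i, gone, :] = np.nan
    return MocapStream(times=times, points=pts)


def sample_imu(
    script: MotionScript,
    sensor_arc_mm: tuple[float, float, float] = DEFAULT_SENSOR_ARC_MM,
    rate_hz: float = 100.0,
    noise_sd_g: float = 0.02,
    seed: int = 0,
    n_markers: int = DEFAULT_N_MARKERS,
    spacing_mm: float = DEFAULT_SPACING_MM,
) -> IMUStream:
    """Simulate the three strip accelerometers under quasi-static motion.

    A noiseless sensor reads the unit gravity reaction (specific force)
    expressed in its local frame, whose up-axis is the strip tangent at the
    sensor's arc position; ``sensor_arc_mm`` gives positions from the strip
    top.  The sampling grid is phase-offset from the mocap grid (the two
    systems run on independent clocks), and Gaussian noise of SD
    ``noise_sd_g`` is added per axis.
    """
    arc = np.asarray(sensor_arc_mm, float)
    if not np.all(np.diff(arc) > 0):
        raise ValueError("sensor_arc_mm must be strictly increasing")
    span = (n_markers - 1) * spacing_mm
    if np.any(arc < 0) or np.any(arc > span):
        raise ValueError(f"sensor positions must lie within the strip span [0, {span}] mm")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.05, 0.95) / rate_hz
    times = phase + np.arange(0.0, script.duration_s, 1.0 / rate_hz)
    times = times[times < script.duration_s]
    rotvecs = _top_rotation_rotvec(_pose_track(script, times))  # (F, 3)
    # bottom/middle/top sensor order = descending distance from the top
    frac = np.sort((span - arc) / span)
    sens_rv = rotvecs[:, None, :] * frac[None, :, None]
    F = len(times)
    readings = (
        Rotation.from_rotvec(sens_rv.reshape(-1, 3)).apply(UP, inverse=True).reshape(F, 3, 3)
    )
    if noise_sd_g > 0:
        readings = readings + rng.normal(0.0, noise_sd_g, size=readings.shape)
    return IMUStream(times=times, readings=readings)


def simulate_session(
    participant_id: str,
    motion_set: int,
    seed: int,
    mocap_rate_hz: float = 120.0,
    imu_rate_hz: float = 100.0,
    dropout_prob: float = 0.02,
    jitter_mm: float = 0.5,
    noise_sd_g: float = 0.02,
    sensor_arc_mm: tuple[float, float, float] = DEFAULT_SENSOR_ARC_MM,
    metadata: dict | None = None,
) -> SimSession:
    """One paired recording session: mocap at 120 Hz, IMU at 100 Hz on an
    offset clock, plus the noiseless base-anchored truth curves at the mocap
    timestamps.  Deterministic given (participant_id, motion_set, seed)."""
    script = script_motion(motion_set)
    mocap = sample_mocap(
        script, rate_hz=mocap_rate_hz, dropout_prob=dropout_prob,
        jitter_mm=jitter_mm, seed=seed,
    )
    imu = sample_imu(
        script, sensor_arc_mm=sensor_arc_mm, rate_hz=imu_rate_hz,
        noise_sd_g=noise_sd_g, seed=seed + 1,
    )
    truth = _curves_from_poses(_pose_track(script, mocap.times))
    return SimSession(
        participant_id=participant_id,
        motion_set=motion_set,
        mocap=mocap,
        imu=imu,
        truth_times=mocap.times,
        truth_curves=truth,
        sensor_arc_mm=tuple(sensor_arc_mm),
        seed=seed,
        metadata=dict(metadata or {}),
    )


def default_cohort(n_participants: int = 6, base_seed: int = 0) -> list[SimSession]:
    """A small synthetic cohort: participants alternate male/female and each
    contributes one set-1 and one set-2 session (the real collection used a
    2:1 repetition ratio of the two sets; one of each keeps the desk-scale
    cohort balanced while exercising both scripts)."""
    sessions: list[SimSession] = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        sex = "M" if p % 2 == 0 else "F"
        for k, ms in enumerate([1, 2]):
            sessions.append(
                simulate_session(
                    pid, ms, seed=base_seed + 1000 * p + 10 * k,
                    metadata={"sex": sex, "participant_index": p},
                )
            )
    return sessions
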