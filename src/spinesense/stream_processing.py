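"""Mocap/IMU session files and the marker-processing chain.

The optical capture system reports, per frame, an unordered bag of marker
positions relative to the chamber centre, with markers occasionally
invisible.  The processing chain mirrors how such streams are prepared for
model training: incomplete frames are eliminated; markers are sorted by
nearest-neighbour chaining starting from the marker closest to the ground;
the origin is moved to the first (lowest) marker; finally positions are
scaled anisotropically — right and forward axes by 50 mm, the up axis by
500 mm — so a typical curve lands near the [-1, 1] cube (values beyond
+-1 are allowed and pass through).

Session files are plain CSV, one per stream: mocap columns
``t, m1x, m1y, m1z, ..., m10z`` (mm) and IMU columns ``t, a1x ... a3z``
(g), with a YAML manifest carrying participant metadata.  Missing markers
are empty cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spine_sim import IMUStream, MocapStream, SimSession

N_MARKERS = 10
UP_AXIS = 1  # y

MOCAP_COLUMNS = ["t"] + [f"m{i + 1}{ax}" for i in range(N_MARKERS) for ax in "xyz"]
IMU_COLUMNS = ["t"] + [f"a{i + 1}{ax}" for i in range(3) for ax in "xyz"]


@dataclass(frozen=True)
class NormalizationSpec:
    """Anisotropic scale: right/forward axes divided by ``horizontal_scale``
    (50 mm), the up axis by ``vertical_scale`` (500 mm)."""

    horizontal_scale: float = 50.0
    vertical_scale: float = 500.0

    def __post_init__(self) -> None:
        if self.horizontal_scale <= 0 or self.vertical_scale <= 0:
            raise ValueError("normalization scales must be > 0")

    @property
    def divisors(self) -> np.ndarray:
        return np.array(
            [self.horizontal_scale, self.vertical_scale, self.horizontal_scale]
        )


@dataclass
class SessionRecord:
    participant_id: str
    session_id: str
    motion_set: int
    mocap: MocapStream
    imu: IMUStream
    metadata: dict = field(default_factory=dict)


class SessionParseError(ValueError):
    pass


def write_session(session: SimSession, out_dir: str | Path, session_id: str) -> Path:
    """Write a session as ``<session_id>.mocap.csv`` + ``<session_id>.imu.csv``
    + ``<session_id>.manifest.yaml`` under ``out_dir``; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    F = len(session.mocap.times)
    moc = np.column_stack([session.mocap.times, session.mocap.points.reshape(F, -1)])
    pd.DataFrame(moc, columns=MOCAP_COLUMNS).to_csv(
        out / f"{session_id}.mocap.csv", index=False, float_format="%.6f"
    )
    G = len(session.imu.times)
    imu = np.column_stack([session.imu.times, session.imu.readings.reshape(G, -1)])
    pd.DataFrame(imu, columns=IMU_COLUMNS).to_csv(
        out / f"{session_id}.imu.csv", index=False, float_format="%.8f"
    )
    manifest = {
        "participant_id": session.participant_id,
        "session_id": session_id,
        "motion_set": session.motion_set,
        "seed": session.seed,
        "sensor_arc_mm": list(session.sensor_arc_mm),
        **session.metadata,
    }
    (out / f"{session_id}.manifest.yaml").write_text(yaml.safe_dump(manifest))
    return out


def _load_csv(path: Path, columns: list[str]) -> np.ndarray:
    if not path.exists():
        raise SessionParseError(f"missing stream file {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise SessionParseError(f"{path.name}: no frames")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SessionParseError(f"{path.name}: missing columns {missing}")
    df = df[columns]
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.any().any():
        r = int(np.flatnonzero(bad.any(axis=1))[0])
        c = bad.columns[bad.iloc[r].to_numpy()][0]
        raise SessionParseError(
            f"{path.name}: non-numeric value at row {r + 2} column '{c}'"
        )
    t = num["t"].to_numpy()
    if np.any(~np.isfinite(t)):
        r = int(np.flatnonzero(~np.isfinite(t))[0])
        raise SessionParseError(f"{path.name}: missing timestamp at row {r + 2}")
    if np.any(np.diff(t) <= 0):
        r = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise SessionParseError(
            f"{path.name}: timestamps not strictly increasing at row {r + 2}"
        )
    return num.to_numpy()


def read_session(session_dir: str | Path, session_id: str) -> SessionRecord:
    """Load one recorded session (mocap mm, IMU g, time s) from CSV."""
    d = Path(session_dir)
    moc = _load_csv(d / f"{session_id}.mocap.csv", MOCAP_COLUMNS)
    imu = _load_csv(d / f"{session_id}.imu.csv", IMU_COLUMNS)
    manifest_path = d / f"{session_id}.manifest.yaml"
    meta = yaml.safe_load(manifest_path.read_text()) if manifest_path.exists() else {}
    return SessionRecord(
        participant_id=str(meta.get("participant_id", "unknown")),
        session_id=session_id,
        motion_set=int(meta.get("motion_set", 0)),
        mocap=MocapStream(times=moc[:, 0], points=moc[:, 1:].reshape(-1, N_MARKERS, 3)),
        imu=IMUStream(times=imu[:, 0], readings=imu[:, 1:].reshape(-1, 3, 3)),
        metadata=meta,
    )


def clean_frames(
    stream: MocapStream, expected: int = N_MARKERS
) -> tuple[MocapStream, int]:
    """Eliminate frames in which any marker was invisible (or a ghost marker
    appeared); returns the complete-frame stream and the removed count."""
    visible = np.sum(~np.isnan(stream.points).any(axis=2), axis=1)
    keep = visible == expected
    removed = int(np.sum(~keep))
    if removed == len(stream.times):
        warnings.warn("all frames incomplete; cleaned stream is empty", stacklevel=2)
        return MocapStream(times=stream.times[:0], points=stream.points[:0]), removed
    return MocapStream(times=stream.times[keep], points=stream.points[keep]), removed


def order_markers(points: np.ndarray) -> np.ndarray:
    """Sort one frame's unordered markers along the strip.

    The marker with the minimal up-coordinate (closest to the ground) comes
    first; each subsequent marker is the nearest unused marker (Euclidean)
    to its predecessor, ties broken toward the lower original index.
    """
    pts = np.asarray(points, float)
    if pts.shape != (N_MARKERS, 3):
        raise ValueError(
            f"order_markers expects exactly {N_MARKERS} points, got {pts.shape};"
            " run clean_frames first"
        )
    order = np.empty(N_MARKERS, dtype=int)
    used = np.zeros(N_MARKERS, dtype=bool)
    cur = int(np.argmin(pts[:, UP_AXIS]))
    order[0] = cur
    used[cur] = True
    for k in range(1, N_MARKERS):
        d = np.linalg.norm(pts - pts[cur], axis=1)
        d[used] = np.inf
        cur = int(np.argmin(d))  # argmin takes the first (lowest index) on ties
        order[k] = cur
        used[cur] = True
    return pts[order]


def chain_is_plausible(ordered: np.ndarray, factor: float = 1.5) -> bool:
    """Guard against nearest-neighbour chaining failures on hairpin
    geometry: every consecutive distance must stay below ``factor`` x the
    median inter-marker spacing."""
    d = np.linalg.norm(np.diff(ordered, axis=0), axis=1)
    return bool(np.all(d < factor * np.median(d)))


def order_stream(stream: MocapStream) -> tuple[np.ndarray, np.ndarray, int]:
    """Order every frame of a cleaned stream; frames failing the chain
    plausibility guard are dropped.  Returns (times, curves, n_flagged)."""
    F = len(stream.times)
    curves = np.empty_like(stream.points)
    ok = np.ones(F, dtype=bool)
    for i in range(F):
        curves[i] = order_markers(stream.points[i])
        if not chain_is_plausible(curves[i]):
            ok[i] = False
    return stream.times[ok], curves[ok], int(np.sum(~ok))


def recenter(curve: np.ndarray) -> np.ndarray:
    """Move the origin to the first (lowest) marker; works on a single
    (10, 3) curve or a batch (F, 10, 3)."""
    c = np.asarray(curve, float)
    if c.ndim == 2:
        return c - c[0]
    return c - c[:, :1, :]


def normalize(curve: np.ndarray, spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Apply the anisotropic scaling to a base-relative curve (mm -> unitless)."""
    return np.asarray(curve, float) / spec.divisors


def denormalize(curve: np.ndarray, spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Exact inverse of :func:`normalize` (unitless -> mm)."""
    return np.asarray(curve, float) * spec.divisors


def load_dataset_dir(root: str | Path) -> list[SessionRecord]:
    """Load every session under ``root`` (recursively, by manifest files,
    else by ``*.mocap.csv`` stem).  This is also the adapter point for the
    public release of the study's recordings: if its files use a different
    schema, map them to the (t, m1x..m10z) / (t, a1x..a3z) dialect here."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory {root} not found")
    stems = sorted(p.name[: -len(".mocap.csv")] for p in root.rglob("*.mocap.csv"))
    if not stems:
        raise FileNotFoundError(f"no *.mocap.csv session files under {root}")
    return [read_session(next(root.rglob(f"{s}.mocap.csv")).parent, s) for s in stems]


def dataset_integrity_counts(
    sessions: list[SessionRecord], crossval_participants: tuple[str, ...] = ("5", "13")
) -> dict[str, int]:
    """Total mocap frame count and the frame count contributed by the
    cross-validation participants (by trailing-number id match)."""

    def _pid_matches(pid: str, target: str) -> bool:
        digits = "".join(ch for ch in pid if ch.isdigit()).lstrip("0")
        return digits == target.lstrip("0")

    total = sum(len(s.mocap.times) for s in sessions)
    cv = sum(
        len(s.mocap.times)
        for s in sessions
        if any(_pid_matches(s.participant_id, t) for t in crossval_participants)
    )
    return {"total_frames": total, "crossval_frames": cv}


@dataclass
class ProcessingReport:
    frames_read: int
    frames_removed_incomplete: int
    frames_flagged_chain: int
    frames_out: int


def process_mocap(
    stream: MocapStream, spec: NormalizationSpec = NormalizationSpec()
) -> tuple[np.ndarray, np.ndarray, ProcessingReport]:
    """Full chain: clean -> order -> recenter -> normalize.

    Returns (times, normalized curves (F, 10, 3), report).
    """
    cleaned, removed = clean_frames(stream)
    times, curves, flagged = order_stream(cleaned)
    curves = normalize(recenter(curves), spec)
    report = ProcessingReport(
        frames_read=len(stream.times),
        frames_removed_incomplete=removed,
        frames_flagged_chain=flagged,
        frames_out=len(times),
    )
    return times, curves, report
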