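"""Error statistics, participant-holdout cross-validation, and Cobb angles.

Accuracy is reported the way the reconstruction is used clinically:
signed component-wise errors of the estimated marker positions in cm
(mean +- population SD, per axis, per marker, and overall), the mean
Euclidean per-marker position error in mm, and the Cobb angle read off an
estimated curve as the angle between its most and least tilted segments
in the coronal plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

MM_PER_CM = 10.0


@dataclass
class ErrorReport:
    """Signed prediction errors (predicted - truth) in cm.

    ``per_axis_marker_mean``/``sd`` are (3 axes, 10 markers); the overall
    statistics aggregate the 27 predicted components (markers 2..10 — the
    first marker is pinned to the origin on both sides and carries no
    error).  ``mean_abs`` is the mean absolute component error, reported
    alongside the signed mean because the two are easily conflated.
    """

    per_axis_marker_mean: np.ndarray
    per_axis_marker_sd: np.ndarray
    overall_mean_cm: float
    overall_sd_cm: float
    overall_abs_mean_cm: float
    mean_marker_error_mm: float
    n_frames: int
    mse_normalized: dict[str, float] = field(default_factory=dict)


def component_errors(predicted_mm: np.ndarray, truth_mm: np.ndarray) -> ErrorReport:
    """Aggregate signed component-wise errors between predicted and
    ground-truth curves, both (F, 10, 3) in mm."""
    pred = np.asarray(predicted_mm, float)
    truth = np.asarray(truth_mm, float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: predicted {pred.shape} vs truth {truth.shape}")
    err_cm = (pred - truth) / MM_PER_CM  # (F, 10, 3)
    free = err_cm[:, 1:, :]  # the 27 predicted components
    marker_dist_mm = np.linalg.norm(pred[:, 1:, :] - truth[:, 1:, :], axis=2)
    return ErrorReport(
        per_axis_marker_mean=err_cm.mean(axis=0).T,
        per_axis_marker_sd=err_cm.std(axis=0).T,
        overall_mean_cm=float(free.mean()),
        overall_sd_cm=float(free.std()),
        overall_abs_mean_cm=float(np.abs(free).mean()),
        mean_marker_error_mm=float(marker_dist_mm.mean()),
        n_frames=len(pred),
    )


@dataclass(frozen=True)
class HoldoutSpec:
    """Participants excluded from every training/validation/test part and
    evaluated once, after training — generalization across bodies."""

    participant_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.participant_ids) == 0:
            raise ValueError("holdout needs at least one participant id")


def choose_holdout(participant_sex: dict[str, str], seed: int) -> HoldoutSpec:
    """Randomly pick one male and one female participant for holdout."""
    rng = np.random.default_rng(seed)
    males = sorted(p for p, s in participant_sex.items() if s.upper().startswith("M"))
    females = sorted(p for p, s in participant_sex.items() if s.upper().startswith("F"))
    if not males or not females:
        raise ValueError("cohort must contain at least one male and one female")
    return HoldoutSpec((str(rng.choice(males)), str(rng.choice(females))))


def crossval_holdout(
    sessions: Sequence,
    train_fn: Callable[[list], object],
    predict_fn: Callable[[object, object], tuple[np.ndarray, np.ndarray]],
    spec: HoldoutSpec,
) -> tuple[ErrorReport, object]:
    """Train without the held-out participants, evaluate only on them.

    ``sessions`` need a ``participant_id`` attribute; ``train_fn`` maps the
    retained sessions to a fitted model; ``predict_fn(model, session)``
    returns (predicted, truth) curve stacks in mm.  Leakage is structurally
    impossible: the held-out sessions are removed before training and the
    removal is asserted.
    """
    held = [s for s in sessions if s.participant_id in spec.participant_ids]
    kept = [s for s in sessions if s.participant_id not in spec.participant_ids]
    for pid in spec.participant_ids:
        if not any(s.participant_id == pid for s in held):
            raise ValueError(f"held-out participant {pid!r} has no sessions")
    assert not any(s.participant_id in spec.participant_ids for s in kept)
    model = train_fn(kept)
    preds, truths = [], []
    for s in held:
        p, t = predict_fn(model, s)
        preds.append(p)
        truths.append(t)
    report = component_errors(np.concatenate(preds), np.concatenate(truths))
    return report, model


@dataclass
class CobbResult:
    angle_deg: float
    index_most_tilted: int
    index_least_tilted: int
    tilt_profile_deg: np.ndarray


def cobb_angle(curve: np.ndarray, plane: str = "coronal") -> CobbResult:
    """Cobb angle of a spinal curve: the angle between its most and least
    tilted segments.

    Tilt of segment i (markers i -> i+1) is the signed angle of the segment
    from the up axis, measured in the coronal (right-up) plane by default;
    ``plane='3d'`` uses the full 3D angle from the up axis instead.  The
    returned angle is the unsigned angle between the two extreme segment
    directions (projected for the coronal case), in degrees — invariant to
    uniform scaling, translation, and sagittal reflection.
    """
    pts = np.asarray(curve, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("cobb_angle needs an (n>=3, 3) curve")
    seg = np.diff(pts, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate (zero-length) segment in curve")
    if plane == "coronal":
        proj = seg[:, [0, 1]]  # (right, up)
        pn = np.linalg.norm(proj, axis=1)
        if np.any(pn < 1e-12):
            raise ValueError("segment vanishes in the coronal projection")
        tilt = np.degrees(np.arctan2(proj[:, 0], proj[:, 1]))
        i_max = int(np.argmax(tilt))
        i_min = int(np.argmin(tilt))
        angle = abs(tilt[i_max] - tilt[i_min])
    elif plane == "3d":
        up_cos = np.clip(seg[:, 1] / norms, -1.0, 1.0)
        tilt = np.degrees(np.arccos(up_cos))
        i_max = int(np.argmax(tilt))
        i_min = int(np.argmin(tilt))
        u, v = seg[i_max] / norms[i_max], seg[i_min] / norms[i_min]
        angle = float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))
    else:
        raise ValueError("plane must be 'coronal' or '3d'")
    return CobbResult(
        angle_deg=float(angle),
        index_most_tilted=i_max,
        index_least_tilted=i_min,
        tilt_profile_deg=tilt,
    )
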