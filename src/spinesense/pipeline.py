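"""End-to-end glue: session -> processed pairs -> trained model -> report.

This module wires the stages together the way the experiment ran: mocap
frames are cleaned, ordered, re-centred and normalized; the accelerometer
stream is linearly interpolated onto the surviving mocap timestamps;
whole sessions are assigned to train/validation/test; the hourglass
regressor is trained; and held-out participants (one male, one female)
are evaluated once, after training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import curvenet, evaluation, stream_processing, sync
from .curvenet import ModelConfig, SplitSpec, TrainedModel, TrainingConfig
from .evaluation import ErrorReport, HoldoutSpec
from .stream_processing import NormalizationSpec
from .sync import SyncPolicy


@dataclass
class PreparedSession:
    participant_id: str
    session_id: str
    times: np.ndarray
    x: np.ndarray  # (F, 9) accelerometer channels at mocap timestamps
    y: np.ndarray  # (F, 27) normalized target coordinates, markers 2..10
    curves_mm: np.ndarray  # (F, 10, 3) processed ground-truth curves, mm
    report: stream_processing.ProcessingReport
    metadata: dict = field(default_factory=dict)


def prepare_session(
    session,
    session_id: str | None = None,
    norm_spec: NormalizationSpec = NormalizationSpec(),
    policy: SyncPolicy = SyncPolicy(),
) -> PreparedSession:
    """Run the full preprocessing chain on one session (simulated or read
    from disk) and pair every surviving mocap frame with the synchronized
    9-channel accelerometer input."""
    times, curves_norm, report = stream_processing.process_mocap(session.mocap, norm_spec)
    imu9 = session.imu.readings.reshape(len(session.imu.times), 9)
    kept_times, imu_at, _ = sync.synchronize(session.imu.times, imu9, times, policy)
    if policy.out_of_range == "drop":
        keep = np.isin(times, kept_times)
        curves_norm = curves_norm[keep]
        times = kept_times
    x, y = curvenet.make_training_pairs(imu_at, curves_norm)
    sid = session_id or getattr(session, "session_id", None) or (
        f"{session.participant_id}-set{getattr(session, 'motion_set', 0)}-s{getattr(session, 'seed', 0)}"
    )
    return PreparedSession(
        participant_id=session.participant_id,
        session_id=sid,
        times=times,
        x=x,
        y=y,
        curves_mm=stream_processing.denormalize(
            curves_norm.reshape(-1, 10, 3), norm_spec
        ),
        report=report,
        metadata=dict(getattr(session, "metadata", {}) or {}),
    )


def _stack(parts: list[PreparedSession]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.concatenate([p.x for p in parts]),
        np.concatenate([p.y for p in parts]),
    )


@dataclass
class ExperimentResult:
    model: TrainedModel
    split: dict[str, str]
    holdout: HoldoutSpec
    mse: dict[str, float]
    holdout_report: ErrorReport
    test_report: ErrorReport


def run_experiment(
    sessions: list,
    holdout: HoldoutSpec,
    model_config: ModelConfig = ModelConfig(),
    training_config: TrainingConfig = TrainingConfig(),
    split_spec: SplitSpec = SplitSpec(),
    norm_spec: NormalizationSpec = NormalizationSpec(),
    policy: SyncPolicy = SyncPolicy(),
) -> ExperimentResult:
    """Train and evaluate on prepared sessions with participant holdout.

    The held-out participants' sessions never enter the session split; the
    remaining sessions are split 50/25/25 by whole session on frame counts.
    Normalized-unit MSE is reported for all four parts, and signed
    component errors (cm) for the test part and the held-out participants.
    """
    prepared = [
        s if isinstance(s, PreparedSession)
        else prepare_session(s, norm_spec=norm_spec, policy=policy)
        for s in sessions
    ]
    held = [p for p in prepared if p.participant_id in holdout.participant_ids]
    kept = [p for p in prepared if p.participant_id not in holdout.participant_ids]
    for pid in holdout.participant_ids:
        if not any(p.participant_id == pid for p in held):
            raise ValueError(f"held-out participant {pid!r} has no sessions")

    split = curvenet.split_sessions(
        {p.session_id: len(p.x) for p in kept}, split_spec
    )
    parts = {
        name: [p for p in kept if split[p.session_id] == name]
        for name in ("train", "validation", "test")
    }
    for name, plist in parts.items():
        if not plist:
            raise ValueError(f"session split left the {name} part empty")
    x_tr, y_tr = _stack(parts["train"])
    x_va, y_va = _stack(parts["validation"])
    x_te, y_te = _stack(parts["test"])

    net = curvenet.build_model(model_config)
    model = curvenet.train(
        net, x_tr, y_tr, x_va, y_va,
        config=training_config, norm_spec=norm_spec, model_config=model_config,
    )
    mse = {
        "train": curvenet.mse(net, x_tr, y_tr),
        "validation": curvenet.mse(net, x_va, y_va),
        "test": curvenet.mse(net, x_te, y_te),
    }

    def _report(plist: list[PreparedSession]) -> ErrorReport:
        pred = np.concatenate([curvenet.predict_curve(model, p.x) for p in plist])
        truth = np.concatenate([p.curves_mm for p in plist])
        return evaluation.component_errors(pred, truth)

    holdout_report = _report(held)
    x_ho, y_ho = _stack(held)
    mse["holdout"] = curvenet.mse(net, x_ho, y_ho)
    holdout_report.mse_normalized = dict(mse)
    return ExperimentResult(
        model=model,
        split=split,
        holdout=holdout,
        mse=mse,
        holdout_report=holdout_report,
        test_report=_report(parts["test"]),
    )
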