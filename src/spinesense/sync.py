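"""Alignment of the asynchronous accelerometer stream to mocap timestamps.

The strip and the capture system run on independent hardware clocks, so
their frames never share a sampling grid.  Each mocap timestamp t is
served either by an IMU frame recorded at exactly t (used unchanged) or by
linear interpolation between the bracketing frames at t0 < t < t1:

    IMU(t) = IMU(t0) + (IMU(t1) - IMU(t0)) * (t - t0) / (t1 - t0)

applied per channel.  Targets outside the IMU record are dropped (and
reported) by default, or clamped to the nearest endpoint frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SyncPolicy:
    """Boundary behaviour for targets outside the IMU time span."""

    out_of_range: str = "drop"

    def __post_init__(self) -> None:
        if self.out_of_range not in ("drop", "clamp"):
            raise ValueError("out_of_range must be 'drop' or 'clamp'")


def synchronize(
    imu_times: np.ndarray,
    imu_values: np.ndarray,
    target_times: np.ndarray,
    policy: SyncPolicy = SyncPolicy(),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Resample IMU channels at mocap timestamps.

    Parameters
    ----------
    imu_times : (N,) strictly increasing seconds
    imu_values : (N, ...) per-frame channels (any trailing shape)
    target_times : (M,) sorted seconds
    policy : out-of-range handling

    Returns
    -------
    (kept_times, values_at_kept_times, n_dropped)
    """
    t = np.asarray(imu_times, float)
    v = np.asarray(imu_values, float)
    tgt = np.asarray(target_times, float)
    if t.ndim != 1 or len(t) != len(v):
        raise ValueError("imu_times and imu_values lengths differ")
    dt = np.diff(t)
    if np.any(dt < 0):
        raise ValueError("imu_times must be sorted")
    if np.any(dt == 0):
        raise ValueError("duplicate IMU timestamps (t1 = t0) — cannot interpolate")
    if np.any(np.diff(tgt) < 0):
        raise ValueError("target_times must be sorted")

    if policy.out_of_range == "drop":
        keep = (tgt >= t[0]) & (tgt <= t[-1])
        dropped = int(np.sum(~keep))
        tgt = tgt[keep]
    else:
        dropped = 0

    flat = v.reshape(len(t), -1)
    # exact-timestamp targets reuse the stored frame bitwise; the rest are
    # linearly interpolated between their bracketing frames
    idx = np.searchsorted(t, tgt)
    exact = (idx < len(t)) & (t[np.minimum(idx, len(t) - 1)] == tgt)
    out = np.empty((len(tgt), flat.shape[1]))
    if np.any(exact):
        out[exact] = flat[idx[exact]]
    rest = ~exact
    if np.any(rest):
        tt = np.clip(tgt[rest], t[0], t[-1])  # only clamps under the clamp policy
        hi = np.clip(np.searchsorted(t, tt), 1, len(t) - 1)
        lo = hi - 1
        alpha = (tt - t[lo]) / (t[hi] - t[lo])
        out[rest] = flat[lo] + (flat[hi] - flat[lo]) * alpha[:, None]
    return tgt, out.reshape((len(tgt),) + v.shape[1:]), dropped
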