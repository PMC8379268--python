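"""Stimulus-onset reconstruction from video frame streams.

Only the event time is unknown, not the response: the participant's click
is time-stamped, so scanning the frame stream backward from the click for
the most recent supra-threshold inter-frame change recovers the moment the
character appeared, and the response time follows by subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

#: Default lookback window: the decision deadline, since the triggering
#: event cannot precede the trial's decision window.
DEFAULT_LOOKBACK_S = 2.5


@dataclass
class FrameStream:
    """Timestamps plus per-frame mean-RGB triplets."""

    timestamps: np.ndarray
    mean_rgb: np.ndarray  # (n_frames, 3), channel means in [0, 255]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.mean_rgb = np.asarray(self.mean_rgb, dtype=float)
        if self.mean_rgb.ndim != 2 or self.mean_rgb.shape[1] != 3:
            raise ParameterError("mean_rgb must be (n_frames, 3)")
        if len(self.timestamps) != len(self.mean_rgb):
            raise ParameterError("timestamps and mean_rgb lengths differ")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ParameterError("timestamps must be strictly increasing")

    def changes(self, per_channel: bool = False) -> np.ndarray:
        """Inter-frame change magnitudes (length n_frames - 1).

        Default metric: absolute difference of the frame means pooled over
        the three colour channels.  With ``per_channel`` the maximum
        absolute per-channel difference is used instead.
        """
        diff = np.diff(self.mean_rgb, axis=0)
        if per_channel:
            return np.abs(diff).max(axis=1)
        return np.abs(diff.mean(axis=1))


@dataclass
class OnsetEstimate:
    onset_time: float | None
    source: str  # "detected" | "fallback_previous" | "none"
    change_magnitude: float | None = None


def auto_threshold(frames: FrameStream, k: float = 8.0, per_channel: bool = False) -> float:
    """Robust change threshold: median + k * MAD of inter-frame changes."""
    c = frames.changes(per_channel=per_channel)
    if c.size == 0:
        raise ParameterError("cannot calibrate a threshold on a single frame")
    mad = np.median(np.abs(c - np.median(c)))
    return float(np.median(c) + k * max(mad, 1e-9))


def session_threshold(
    frames_by_trial: dict[int, FrameStream], k: float = 8.0, per_channel: bool = False
) -> float:
    """Auto-calibrated threshold over the pooled changes of a whole session.

    Pooling makes the median/MAD estimate stable (per-trial streams are
    short); the rare character-onset steps are outliers that the robust
    statistics ignore.
    """
    c = np.concatenate(
        [fs.changes(per_channel=per_channel) for fs in frames_by_trial.values()]
    )
    if c.size == 0:
        raise ParameterError("cannot calibrate a threshold without changes")
    mad = np.median(np.abs(c - np.median(c)))
    return float(np.median(c) + k * max(mad, 1e-9))


def detect_onset(
    frames: FrameStream,
    response_time: float,
    threshold: float,
    previous_onset: float | None = None,
    lookback_s: float = DEFAULT_LOOKBACK_S,
    per_channel: bool = False,
) -> OnsetEstimate:
    """Backward scan for the most recent supra-threshold frame change.

    Starting from the last frame at or before ``response_time``, walk
    backward until a frame differs from its predecessor by more than
    ``threshold``; that frame's timestamp is the estimated onset.  If no
    change is found within ``lookback_s``, the previous trial's onset is
    used as a fallback.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    ts = frames.timestamps
    if ts.size == 0:
        raise ParameterError("empty frame stream")
    if response_time < ts[0]:
        raise ParameterError(
            f"response at {response_time:.3f}s precedes first frame at {ts[0]:.3f}s"
        )
    last = int(np.searchsorted(ts, response_time, side="right") - 1)
    changes = frames.changes(per_channel=per_channel)
    for i in range(last, 0, -1):  # change[i-1] is frame i vs frame i-1
        if ts[i] < response_time - lookback_s:
            break
        if changes[i - 1] > threshold:
            return OnsetEstimate(float(ts[i]), "detected", float(changes[i - 1]))
    if previous_onset is not None:
        return OnsetEstimate(float(previous_onset), "fallback_previous", None)
    return OnsetEstimate(None, "none", None)


def reconstruct_rt(onset: OnsetEstimate, response_time: float) -> float | None:
    """Response time = response event time - stimulus event time.

    Returns None when no onset is available; callers propagate this as a
    missing RT.
    """
    if onset.onset_time is None:
        return None
    return float(response_time - onset.onset_time)


def detect_trial_onsets(
    frames_by_trial: dict[int, FrameStream],
    response_times: dict[int, float],
    threshold: float | None = None,
    lookback_s: float = DEFAULT_LOOKBACK_S,
    auto_k: float = 8.0,
) -> dict[int, OnsetEstimate]:
    """Run onset detection across a session, trial-id order, with fallback
    chaining: a missed detection inherits the previous trial's onset."""
    estimates: dict[int, OnsetEstimate] = {}
    previous: float | None = None
    if threshold is None:
        threshold = session_threshold(frames_by_trial, k=auto_k)
    for tid in sorted(frames_by_trial):
        fs = frames_by_trial[tid]
        if tid not in response_times or response_times[tid] is None:
            continue
        thr = threshold
        est = detect_onset(
            fs, response_times[tid], thr, previous_onset=previous, lookback_s=lookback_s
        )
        estimates[tid] = est
        if est.onset_time is not None:
            previous = est.onset_time
    return estimates
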