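"""Synthetic multi-participant decision experiments.

Generates, from a single seeded configuration, the three artefacts the
pipeline consumes: per-participant behavioural trial tables, raw-rate
response-locked EEG epochs with a condition-dependent pre-response
component, and per-trial frame streams with a hidden character-appearance
step.  The generative choices are deliberately minimal:

* per-participant accuracy drawn uniformly in ``accuracy_range`` and
  rank-correlated (Gaussian copula) with lognormal RT location, so better
  performers respond faster when ``acc_rt_correlation`` is negative;
* incorrect trials draw their RT with a positive location shift, giving
  RT-only estimators a usable signal;
* the pre-response component is a half-cosine bump inside
  ``erp_window_ms``, weighted toward fronto-central channels, whose
  amplitude differs by ``erp_effect`` between correct and incorrect
  trials, on top of 1/f-shaped noise;
* reported confidence is a noisy, grid-rounded affine function of
  correctness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ParameterError
from .io import TrialRecord
from .onsets import FrameStream
from .preprocess import EpochSet, RAW_WINDOW_MS

# 64-channel layout (10-20 extended).  The first entries include every
# channel required downstream (ocular regression and fronto-central ERP
# reporting), so truncated montages remain valid.
CHANNEL_NAMES_64 = [
    "Fp1", "Fp2", "F1", "F2", "FCz", "Fz", "Cz", "Pz",
    "Oz", "FC1", "FC2", "C3", "C4", "P3", "P4", "O1",
    "O2", "F3", "F4", "F7", "F8", "FC3", "FC4", "FC5",
    "FC6", "FT7", "FT8", "C1", "C2", "C5", "C6", "T7",
    "T8", "CP1", "CP2", "CP3", "CP4", "CP5", "CP6", "TP7",
    "TP8", "CPz", "P1", "P2", "P5", "P6", "P7", "P8",
    "PO3", "PO4", "PO7", "PO8", "POz", "AF3", "AF4", "AF7",
    "AF8", "AFz", "Fpz", "F5", "F6", "FT9", "FT10", "Iz",
]

#: Fronto-central spatial profile of the simulated pre-response component.
ERP_TOPOGRAPHY = {
    "FCz": 1.0, "Fz": 0.8, "Cz": 0.8, "FC1": 0.7, "FC2": 0.7,
    "F1": 0.5, "F2": 0.5, "C1": 0.4, "C2": 0.4, "Fp1": 0.2, "Fp2": 0.2,
}
ERP_BASELINE_WEIGHT = 0.1  # all other channels


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment."""

    n_participants: int = 10
    n_blocks: int = 12
    trials_per_block: int = 42
    fraction_empty: float = 1.0 / 3.0
    accuracy_range: tuple[float, float] = (0.65, 0.95)
    erp_effect: float = 9.0  # µV amplitude gap, correct vs incorrect
    erp_window_ms: tuple[float, float] = (-500.0, 0.0)
    noise_sd: float = 10.0  # µV
    fs_raw: float = 2048.0
    n_channels: int = 64
    rt_lognorm_params: tuple[tuple[float, float], float] = ((-1.1, -0.3), 0.35)
    rt_incorrect_shift: float = 0.35  # added to the log-location on errors
    acc_rt_correlation: float = -0.8
    conf_base: float = 45.0
    conf_effect: float = 25.0  # mean reported-confidence gap, correct vs not
    conf_noise_sd: float = 15.0
    response_deadline_s: float = 2.5
    conf_deadline_s: float = 2.0
    disappearance_range_s: tuple[float, float] | None = None
    frame_rate_hz: float = 4.0
    frame_base_rgb: tuple[float, float, float] = (90.0, 90.0, 90.0)
    frame_jitter_sd: float = 0.5
    frame_step: float = 12.0  # RGB units added when the character appears
    fraction_missed: float = 0.0  # trials whose step is sub-threshold
    missed_step: float = 0.05
    onset_lead_s: float = 1.0  # stream start to earliest possible onset
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_blocks, self.trials_per_block) <= 0:
            raise ParameterError("counts must be positive")
        lo, hi = self.accuracy_range
        if not (0.5 < lo <= hi <= 1.0):
            raise ParameterError("accuracy_range must lie within (0.5, 1.0]")
        if not 0.0 <= self.fraction_empty < 1.0:
            raise ParameterError("fraction_empty must be in [0, 1)")
        if not -1.0 <= self.acc_rt_correlation <= 1.0:
            raise ParameterError("acc_rt_correlation must be in [-1, 1]")
        if self.fs_raw <= 0 or abs(self.fs_raw / 32.0 - round(self.fs_raw / 32.0)) > 1e-9:
            raise ParameterError("fs_raw must be a positive multiple of 32 Hz")
        if self.n_channels < 5 or self.n_channels > len(CHANNEL_NAMES_64):
            raise ParameterError("n_channels must be in [5, 64]")
        (mu_lo, mu_hi), sigma = self.rt_lognorm_params
        if sigma <= 0:
            raise ParameterError("RT lognormal scale must be positive")
        slow_median = float(np.exp(mu_hi + self.rt_incorrect_shift))
        if slow_median >= self.response_deadline_s:
            raise ParameterError(
                "response deadline shorter than the slowest participant's "
                f"median RT ({slow_median:.2f}s >= {self.response_deadline_s}s)"
            )
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be positive")
        if not 0.0 <= self.fraction_missed <= 1.0:
            raise ParameterError("fraction_missed must be in [0, 1]")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def channel_names(self) -> list[str]:
        return CHANNEL_NAMES_64[: self.n_channels]

    @property
    def trial_slot_s(self) -> float:
        """Length of each trial's time slot in the session timeline."""
        return self.onset_lead_s + self.response_deadline_s + self.conf_deadline_s + 1.0


@dataclass
class Behaviour:
    trials: dict[str, list[TrialRecord]]
    schedule: pd.DataFrame  # trial_id, block, true_label, t_start_s, onset_s, ...
    participants: pd.DataFrame  # participant_id, accuracy, rt_mu, rt_sigma


@dataclass
class SimDataset:
    """Everything one synthetic experiment produced."""

    config: SimConfig
    trials: dict[str, list[TrialRecord]]
    epochs: dict[str, EpochSet]
    frames: dict[int, FrameStream]
    schedule: pd.DataFrame
    participants: pd.DataFrame

    def true_rt(self, pid: str, trial_id: int) -> float | None:
        rec = next(r for r in self.trials[pid] if r.trial_id == trial_id)
        if rec.response_timestamp_s is None:
            return None
        onset = float(self.schedule.loc[self.schedule.trial_id == trial_id, "onset_s"].iloc[0])
        return rec.response_timestamp_s - onset


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _draw_participants(config: SimConfig) -> pd.DataFrame:
    """Accuracies and RT locations linked by a Gaussian copula."""
    rng = _rng(config, 0)
    n = config.n_participants
    lo, hi = config.accuracy_range
    (mu_lo, mu_hi), sigma = config.rt_lognorm_params
    rho = config.acc_rt_correlation
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
    u1, u2 = norm.cdf(z1), norm.cdf(z2)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:02d}" for i in range(n)],
            "accuracy": lo + (hi - lo) * u1,
            "rt_mu": mu_lo + (mu_hi - mu_lo) * u2,
            "rt_sigma": sigma,
        }
    )


def _draw_schedule(config: SimConfig) -> pd.DataFrame:
    """Trial sequence shared by all participants (as in the experiments)."""
    rng = _rng(config, 1)
    n = config.n_trials
    n_empty = int(round(config.fraction_empty * n))
    n_target = n - n_empty
    labels = np.concatenate(
        [
            np.zeros(n_empty, dtype=int),
            np.ones((n_target + 1) // 2, dtype=int),
            -np.ones(n_target // 2, dtype=int),
        ]
    )
    rng.shuffle(labels)
    slot = config.trial_slot_s
    period = 1.0 / config.frame_rate_hz
    t_start = slot * np.arange(n)
    jitter_frames = rng.integers(0, max(1, int(round(config.frame_rate_hz))), size=n)
    onset = t_start + (
        np.round(config.onset_lead_s * config.frame_rate_hz) + jitter_frames
    ) * period
    if config.disappearance_range_s is not None:
        d_lo, d_hi = config.disappearance_range_s
        disappear = rng.uniform(d_lo, d_hi, size=n)
    else:
        disappear = np.full(n, np.nan)
    missed = rng.random(n) < config.fraction_missed
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "block": np.arange(n) // config.trials_per_block,
            "true_label": labels,
            "t_start_s": t_start,
            "t_end_s": t_start + slot,
            "onset_s": np.where(labels != 0, onset, np.nan),
            "disappear_s": disappear,
            "missed": missed,
        }
    )


def _round_to_grid(values: np.ndarray) -> np.ndarray:
    return np.clip(np.round(values / 10.0) * 10.0, 0.0, 100.0).astype(int)


def simulate_behaviour(config: SimConfig) -> Behaviour:
    """Decisions, RTs, and reported confidences for every participant.

    RTs are lognormal (slower on errors), truncated at the response
    deadline.  With a disappearance window configured, trials whose
    sampled RT exceeds the sampled disappearance time produce no decision
    and are labelled incorrect.
    """
    participants = _draw_participants(config)
    schedule = _draw_schedule(config)
    rng = _rng(config, 2)
    trials: dict[str, list[TrialRecord]] = {}
    deadline = config.response_deadline_s
    for _, prow in participants.iterrows():
        pid = prow.participant_id
        recs = []
        for _, trow in schedule.iterrows():
            label = int(trow.true_label)
            if label == 0:
                recs.append(
                    TrialRecord(pid, int(trow.block), int(trow.trial_id), 0)
                )
                continue
            correct = bool(rng.random() < prow.accuracy)
            mu = prow.rt_mu + (0.0 if correct else config.rt_incorrect_shift)
            rt = float(rng.lognormal(mu, prow.rt_sigma))
            for _ in range(100):  # truncate at the deadline by redraw
                if rt < deadline:
                    break
                rt = float(rng.lognormal(mu, prow.rt_sigma))
            rt = min(rt, deadline * 0.999)
            if not np.isnan(trow.disappear_s) and rt > trow.disappear_s:
                recs.append(
                    TrialRecord(
                        pid,
                        int(trow.block),
                        int(trow.trial_id),
                        label,
                        correctness="incorrect",  # deadline rule
                    )
                )
                continue
            decision = label if correct else -label
            conf_raw = (
                config.conf_base
                + config.conf_effect * correct
                + rng.normal(0.0, config.conf_noise_sd)
            )
            resp_t = float(trow.onset_s) + rt
            recs.append(
                TrialRecord(
                    pid,
                    int(trow.block),
                    int(trow.trial_id),
                    label,
                    decision=decision,
                    response_timestamp_s=resp_t,
                    reported_confidence=int(_round_to_grid(np.array([conf_raw]))[0]),
                    confidence_timestamp_s=resp_t
                    + float(rng.uniform(0.2, config.conf_deadline_s)),
                )
            )
        trials[pid] = recs
    return Behaviour(trials=trials, schedule=schedule, participants=participants)


def _pink_noise(
    rng: np.random.Generator, shape: tuple[int, ...], fs: float, sd: float
) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise along the last axis."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], 1.0 / fs)
    spec *= 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    out = np.fft.irfft(spec, n=shape[-1], axis=-1)
    scale = out.std()
    return out * (sd / scale) if scale > 0 else out


def erp_channel_weights(channel_names: list[str]) -> np.ndarray:
    return np.array(
        [ERP_TOPOGRAPHY.get(c, ERP_BASELINE_WEIGHT) for c in channel_names]
    )


def simulate_epochs(
    trials: Mapping[str, list[TrialRecord]], config: SimConfig
) -> dict[str, EpochSet]:
    """Raw-rate response-locked epochs for every answered trial.

    Window (-1700, +200) ms at ``fs_raw``: pink noise plus the
    fronto-central half-cosine component (amplitude ``erp_effect`` on
    correct trials, 0 on incorrect ones) inside ``erp_window_ms``.
    Empty and no-response trials produce no epoch.
    """
    rng = _rng(config, 3)
    fs = config.fs_raw
    n_samp = int(round((RAW_WINDOW_MS[1] - RAW_WINDOW_MS[0]) / 1000.0 * fs))
    r0 = int(round(-RAW_WINDOW_MS[0] / 1000.0 * fs))
    t_ms = (np.arange(n_samp) - r0) / fs * 1000.0
    w0, w1 = config.erp_window_ms
    u = (t_ms - w0) / (w1 - w0)
    in_win = (u >= 0) & (u <= 1)
    bump = np.where(in_win, np.sin(np.pi * np.clip(u, 0, 1)), 0.0)
    # Orthogonalize the component against {1, t} on its own support so the
    # per-epoch linear detrend in conditioning cannot smear a
    # condition-dependent offset outside the window.
    basis = np.vstack([np.ones(in_win.sum()), u[in_win]]).T
    coef, *_ = np.linalg.lstsq(basis, bump[in_win], rcond=None)
    bump[in_win] -= basis @ coef
    bump /= np.abs(bump).max()  # erp_effect stays a peak amplitude in µV
    weights = erp_channel_weights(config.channel_names)
    template = weights[:, None] * bump[None, :]  # (channels, samples)

    out: dict[str, EpochSet] = {}
    for pid, recs in trials.items():
        answered = [r for r in recs if r.answered]
        labels = np.array([r.correctness == "correct" for r in answered])
        tids = np.array([r.trial_id for r in answered])
        data = _pink_noise(
            rng, (len(answered), len(weights), n_samp), fs, config.noise_sd
        )
        amp = np.where(labels, config.erp_effect, 0.0)
        data += amp[:, None, None] * template[None, :, :]
        out[pid] = EpochSet(
            data=data,
            fs=fs,
            window_ms=RAW_WINDOW_MS,
            channel_names=config.channel_names,
            trial_ids=tids,
            labels=labels,
        )
    return out


def simulate_frames(schedule: pd.DataFrame, config: SimConfig) -> dict[int, FrameStream]:
    """Per-trial mean-RGB frame streams.

    Background jitter around ``frame_base_rgb``, plus a step of
    ``frame_step`` (or ``missed_step`` for designated missed-character
    trials) on every frame from the hidden onset onward — until the
    disappearance time when one is configured.  Empty trials get no step.
    """
    rng = _rng(config, 4)
    period = 1.0 / config.frame_rate_hz
    base = np.asarray(config.frame_base_rgb, dtype=float)
    out: dict[int, FrameStream] = {}
    for _, trow in schedule.iterrows():
        n_frames = int(round((trow.t_end_s - trow.t_start_s) * config.frame_rate_hz))
        ts = trow.t_start_s + period * np.arange(n_frames)
        rgb = base[None, :] + rng.normal(0.0, config.frame_jitter_sd, (n_frames, 3))
        if trow.true_label != 0:
            step = config.missed_step if trow.missed else config.frame_step
            on = ts >= trow.onset_s - 1e-9
            if not np.isnan(trow.disappear_s):
                on &= ts < trow.onset_s + trow.disappear_s - 1e-9
            rgb[on] += step
        out[int(trow.trial_id)] = FrameStream(timestamps=ts, mean_rgb=rgb)
    return out


def simulate_dataset(config: SimConfig, seed: int | None = None) -> SimDataset:
    """Full synthetic experiment: behaviour, epochs and frame streams."""
    if seed is not None:
        config = replace(config, seed=seed)
    beh = simulate_behaviour(config)
    epochs = simulate_epochs(beh.trials, config)
    frames = simulate_frames(beh.schedule, config)
    return SimDataset(
        config=config,
        trials=beh.trials,
        epochs=epochs,
        frames=frames,
        schedule=beh.schedule,
        participants=beh.participants,
    )
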