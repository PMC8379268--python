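"""Continuous-EEG conditioning and response-locked epoching.

The target representation for the confidence decoder is a response-locked
epoch set at 32 Hz covering the 1500 ms ending at the response (48 samples
per channel).  Raw epochs are cut wider, (-1700, +200) ms, so that the
low-pass/decimation stage has edge material to discard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import MissingChannelError, ParameterError

logger = logging.getLogger(__name__)

#: Channels used by the ocular-artifact regression.
OCULAR_CHANNELS = ("Fp1", "F1", "Fp2", "F2")

#: Raw epoch window around the response (ms) and the retained window after
#: conditioning.  The retained 1500 ms at 32 Hz is exactly 48 samples.
RAW_WINDOW_MS = (-1700.0, 200.0)
FINAL_WINDOW_MS = (-1500.0, 0.0)
TARGET_FS = 32.0


@dataclass
class ContinuousEEG:
    """A continuous multichannel recording in microvolts."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_names: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ParameterError("samples must be a channels x time matrix")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ParameterError("one channel name per row required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ParameterError("channel names must be unique")

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise MissingChannelError(name) from None


@dataclass
class EpochSet:
    """Trials x channels x samples, response-locked."""

    data: np.ndarray
    fs: float
    window_ms: tuple[float, float]
    channel_names: list[str] = field(default_factory=list)
    trial_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    labels: np.ndarray | None = None  # True = correct decision

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.data.ndim != 3:
            raise ParameterError("epoch data must be 3-D (trials, channels, samples)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool)
            if self.labels.shape[0] != self.data.shape[0]:
                raise ParameterError("labels must align one-to-one with trials")
        if self.trial_ids.size and self.trial_ids.shape[0] != self.data.shape[0]:
            raise ParameterError("trial_ids must align one-to-one with trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Per-sample latencies relative to the response, in ms.

        The last sample sits exactly at the response (0 ms) for conditioned
        sets with window (-1500, 0).
        """
        n = self.data.shape[2]
        step = 1000.0 / self.fs
        return self.window_ms[1] - step * np.arange(n - 1, -1, -1)

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            window_ms=self.window_ms,
            channel_names=list(self.channel_names),
            trial_ids=self.trial_ids[mask] if self.trial_ids.size else self.trial_ids,
            labels=None if self.labels is None else self.labels[mask],
        )


def rereference(eeg: ContinuousEEG, reference: str | list[str] = "average") -> ContinuousEEG:
    """Re-reference to the channel average or to named channels.

    Off by default in the pipeline: inputs are assumed already referenced
    (or simulated reference-free).
    """
    if reference == "average":
        ref = eeg.samples.mean(axis=0)
    else:
        idx = [eeg.channel_index(c) for c in reference]
        ref = eeg.samples[idx].mean(axis=0)
    return ContinuousEEG(
        eeg.samples - ref[None, :], eeg.fs, list(eeg.channel_names), eeg.start_time
    )


def bandpass_continuous(
    eeg: ContinuousEEG, low: float = 0.15, high: float = 40.0, order: int = 6
) -> ContinuousEEG:
    """Zero-phase Butterworth band-pass of a continuous recording.

    Applied forward-backward (``sosfiltfilt``) so response-locked latencies
    are not shifted.  The band-pass has a zero at DC, so constant offsets
    are removed.
    """
    if not 0 < low < high < eeg.fs / 2:
        raise ParameterError(f"band edges ({low}, {high}) invalid for fs={eeg.fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=eeg.fs, output="sos")
    out = signal.sosfiltfilt(sos, eeg.samples, axis=-1)
    return ContinuousEEG(out, eeg.fs, list(eeg.channel_names), eeg.start_time)


def ocular_reference(eeg: ContinuousEEG) -> np.ndarray:
    """v(t) = mean of the Fp1-F1 and Fp2-F2 bipolar derivations."""
    idx = [eeg.channel_index(c) for c in OCULAR_CHANNELS]
    fp1, f1, fp2, f2 = (eeg.samples[i] for i in idx)
    return 0.5 * ((fp1 - f1) + (fp2 - f2))


def remove_ocular(eeg: ContinuousEEG) -> ContinuousEEG:
    """Regress the ocular reference out of every channel.

    Each channel c becomes c - beta_c * v with beta_c = cov(c, v)/var(v),
    fitted on the whole record; the residuals are uncorrelated with v.
    """
    v = ocular_reference(eeg)
    vc = v - v.mean()
    var = float(vc @ vc)
    if var == 0.0:
        return ContinuousEEG(
            eeg.samples.copy(), eeg.fs, list(eeg.channel_names), eeg.start_time
        )
    x = eeg.samples
    beta = (x - x.mean(axis=1, keepdims=True)) @ vc / var
    out = x - beta[:, None] * v[None, :]
    return ContinuousEEG(out, eeg.fs, list(eeg.channel_names), eeg.start_time)


def extract_epochs(
    eeg: ContinuousEEG,
    response_times: np.ndarray,
    trial_ids: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    window_ms: tuple[float, float] = RAW_WINDOW_MS,
) -> EpochSet:
    """Cut response-locked raw-rate epochs spanning ``window_ms``.

    Responses whose window falls outside the recording are skipped with a
    warning.  The response lands on a fixed in-epoch sample index
    (``round(-window_ms[0]/1000 * fs)``) for every retained trial.
    """
    response_times = np.asarray(response_times, dtype=float)
    fs = eeg.fs
    pre = int(round(-window_ms[0] / 1000.0 * fs))
    n_samp = int(round((window_ms[1] - window_ms[0]) / 1000.0 * fs))
    n_total = eeg.samples.shape[1]
    kept_data, kept_idx = [], []
    for i, t in enumerate(response_times):
        r0 = int(round((t - eeg.start_time) * fs))
        start = r0 - pre
        if start < 0 or start + n_samp > n_total:
            logger.warning(
                "response at %.3f s: window outside recording, trial skipped", t
            )
            continue
        kept_data.append(eeg.samples[:, start : start + n_samp])
        kept_idx.append(i)
    data = (
        np.stack(kept_data)
        if kept_data
        else np.empty((0, eeg.samples.shape[0], n_samp))
    )
    kept_idx = np.asarray(kept_idx, dtype=int)
    return EpochSet(
        data=data,
        fs=fs,
        window_ms=window_ms,
        channel_names=list(eeg.channel_names),
        trial_ids=(
            np.asarray(trial_ids)[kept_idx] if trial_ids is not None else kept_idx
        ),
        labels=None if labels is None else np.asarray(labels)[kept_idx],
    )


def design_lowpass(
    fs: float,
    pass_hz: float = 14.0,
    stop_hz: float = 16.0,
    stop_atten_db: float = 40.0,
    max_taps: int = 2049,
) -> np.ndarray:
    """Equiripple (Remez exchange) linear-phase low-pass FIR.

    The order is chosen from the Kaiser estimate for the requested stopband
    attenuation, forced odd (type-I symmetric, so zero phase under 'same'
    convolution) and capped at ``max_taps``.  Falls back to a Kaiser-window
    design if the exchange iteration fails to converge at very high orders.
    """
    if not 0 < pass_hz < stop_hz < fs / 2:
        raise ParameterError(f"low-pass edges ({pass_hz}, {stop_hz}) invalid for fs={fs}")
    numtaps, _ = signal.kaiserord(stop_atten_db + 5, (stop_hz - pass_hz) / (fs / 2))
    numtaps = min(numtaps | 1, max_taps | 1)
    bands = [0.0, pass_hz, stop_hz, fs / 2]
    try:
        taps = signal.remez(numtaps, bands, [1.0, 0.0], fs=fs)
        if not np.all(np.isfinite(taps)):
            raise ValueError("remez produced non-finite taps")
    except Exception:  # pragma: no cover - very high orders only
        logger.warning("Remez design failed at %d taps; using Kaiser window", numtaps)
        beta = signal.kaiser_beta(stop_atten_db + 5)
        taps = signal.firwin(
            numtaps, (pass_hz + stop_hz) / 2, window=("kaiser", beta), fs=fs
        )
    return taps


def condition_epochs(
    epochs: EpochSet,
    fs_out: float = TARGET_FS,
    pass_hz: float = 14.0,
    stop_hz: float = 16.0,
    final_window_ms: tuple[float, float] = FINAL_WINDOW_MS,
) -> EpochSet:
    """Detrend, low-pass, decimate and trim raw epochs.

    Per-epoch linear detrend; zero-phase equiripple low-pass (14 Hz pass /
    16 Hz stop); decimation to ``fs_out`` phased so the response sample is
    kept; trim to the final window ending at the response.  For the default
    windows the output is exactly 48 samples per channel.
    """
    fs = epochs.fs
    factor = fs / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ParameterError(f"fs={fs} is not an integer multiple of {fs_out}")
    factor = int(round(factor))
    r0 = int(round(-epochs.window_ms[0] / 1000.0 * fs))  # response sample index
    n_out = int(round((final_window_ms[1] - final_window_ms[0]) / 1000.0 * fs_out))
    idx = r0 - factor * np.arange(n_out - 1, -1, -1)
    if idx[0] < 0 or idx[-1] >= epochs.data.shape[2]:
        raise ParameterError("final window does not fit inside the raw epoch")

    data = signal.detrend(epochs.data, axis=-1, type="linear")
    n = data.shape[2]
    taps = design_lowpass(fs, pass_hz, stop_hz, max_taps=min(2049, 2 * (n // 2) - 3))
    # odd-reflection padding keeps the zero-phase convolution clean at the
    # epoch edges (the response sample sits close to the trailing edge)
    p = len(taps)
    left = 2 * data[..., :1] - data[..., p:0:-1]
    right = 2 * data[..., -1:] - data[..., -2 : -p - 2 : -1]
    padded = np.concatenate([left, data, right], axis=-1)
    data = signal.fftconvolve(padded, taps[None, None, :], mode="same", axes=-1)
    data = data[..., p : p + n]
    data = data[:, :, idx]
    return EpochSet(
        data=data,
        fs=fs_out,
        window_ms=final_window_ms,
        channel_names=list(epochs.channel_names),
        trial_ids=epochs.trial_ids,
        labels=epochs.labels,
    )


def preprocess_continuous(
    eeg: ContinuousEEG,
    response_times: np.ndarray,
    trial_ids: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    low: float = 0.15,
    high: float = 40.0,
    remove_ocular_artifacts: bool = True,
) -> EpochSet:
    """Full pipeline: band-pass, ocular regression, epoching, conditioning."""
    eeg = bandpass_continuous(eeg, low, high)
    if remove_ocular_artifacts:
        eeg = remove_ocular(eeg)
    raw = extract_epochs(eeg, response_times, trial_ids=trial_ids, labels=labels)
    return condition_epochs(raw)
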