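"""Data contracts and file formats.

Trial tables are CSV, epochs travel in HDF5, frame streams in long-format
CSV.  All timestamps are absolute seconds from the start of the session
(float).  Missing values are encoded as empty CSV fields.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: Valid values of the reported-confidence scale: 0..100 in steps of ten.
CONFIDENCE_GRID: tuple[int, ...] = tuple(range(0, 101, 10))

#: Column set of the trial-table CSV, in order.
TRIAL_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "block",
    "trial_id",
    "true_label",
    "decision",
    "response_timestamp_s",
    "reported_confidence",
    "confidence_timestamp_s",
    "correctness",
)

FRAME_COLUMNS: tuple[str, ...] = (
    "trial_id",
    "frame_index",
    "timestamp_s",
    "mean_r",
    "mean_g",
    "mean_b",
)


def is_valid_confidence(value: float) -> bool:
    """True iff *value* sits on the 11-point reporting grid (0, 10, ..., 100)."""
    return value in CONFIDENCE_GRID


@dataclass
class TrialRecord:
    """One decision event of one participant.

    ``true_label`` is +1/-1 for the two response alternatives and 0 for
    empty (no-target) trials.  ``decision`` is None when the participant
    never responded.  ``correctness`` is derived: equal labels mean
    "correct"; a missing decision is "incorrect" only when the
    no-response-deadline rule is in force (set it explicitly then).
    """

    participant_id: str
    block: int
    trial_id: int
    true_label: int
    decision: int | None = None
    response_timestamp_s: float | None = None
    reported_confidence: int | None = None
    confidence_timestamp_s: float | None = None
    correctness: str | None = None

    def __post_init__(self) -> None:
        if self.true_label not in (-1, 0, 1):
            raise FormatError(f"true_label must be -1, 0 or +1, got {self.true_label}")
        if self.decision is not None and self.decision not in (-1, 1):
            raise FormatError(f"decision must be -1 or +1, got {self.decision}")
        if self.reported_confidence is not None and not is_valid_confidence(
            self.reported_confidence
        ):
            raise FormatError(
                f"reported_confidence {self.reported_confidence} is off the "
                f"0-100 step-10 grid"
            )
        if (
            self.confidence_timestamp_s is not None
            and self.response_timestamp_s is not None
            and self.confidence_timestamp_s < self.response_timestamp_s
        ):
            raise FormatError("confidence timestamp precedes response timestamp")
        if self.correctness is None and self.decision is not None:
            self.correctness = (
                "correct" if self.decision == self.true_label else "incorrect"
            )
        if self.correctness not in (None, "correct", "incorrect"):
            raise FormatError(f"bad correctness value {self.correctness!r}")

    @property
    def answered(self) -> bool:
        return self.decision is not None


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        rows.append({k: ("" if d[k] is None else d[k]) for k in TRIAL_COLUMNS})
    pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)).to_csv(path, index=False)


def read_trials(
    path: str | Path, no_response_incorrect: bool = False
) -> list[TrialRecord]:
    """Read a trial-table CSV.

    With ``no_response_incorrect`` (the timed-disappearance rule), rows
    with a missing decision are labelled incorrect.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if tuple(df.columns) != TRIAL_COLUMNS:
        raise FormatError(
            f"{path}: header {tuple(df.columns)} != expected {TRIAL_COLUMNS}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            decision = int(row.decision) if row.decision != "" else None
            correctness = row.correctness or None
            if decision is None and correctness is None and no_response_incorrect:
                correctness = "incorrect"
            records.append(
                TrialRecord(
                    participant_id=str(row.participant_id),
                    block=int(row.block),
                    trial_id=int(row.trial_id),
                    true_label=int(row.true_label),
                    decision=decision,
                    response_timestamp_s=(
                        float(row.response_timestamp_s)
                        if row.response_timestamp_s != ""
                        else None
                    ),
                    reported_confidence=(
                        int(float(row.reported_confidence))
                        if row.reported_confidence != ""
                        else None
                    ),
                    confidence_timestamp_s=(
                        float(row.confidence_timestamp_s)
                        if row.confidence_timestamp_s != ""
                        else None
                    ),
                    correctness=correctness,
                )
            )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    return records


def trials_by_participant(
    records: Iterable[TrialRecord],
) -> dict[str, list[TrialRecord]]:
    out: dict[str, list[TrialRecord]] = {}
    for r in records:
        out.setdefault(r.participant_id, []).append(r)
    for rs in out.values():
        rs.sort(key=lambda r: r.trial_id)
    return out


# ---------------------------------------------------------------------------
# Epoch container (HDF5): /participants/<id>/data with attrs fs, window_ms,
# channel_names, trial_ids, labels.
# ---------------------------------------------------------------------------


def write_epochs(epochs_by_participant: Mapping[str, "EpochSet"], path: str | Path) -> None:
    from .preprocess import EpochSet  # noqa: F401  (type only)

    with h5py.File(path, "w") as f:
        root = f.create_group("participants")
        for pid, es in epochs_by_participant.items():
            g = root.create_group(str(pid))
            g.create_dataset("data", data=es.data)
            g.attrs["fs"] = float(es.fs)
            g.attrs["window_ms"] = np.asarray(es.window_ms, dtype=float)
            g.attrs["channel_names"] = [str(c) for c in es.channel_names]
            g.create_dataset("trial_ids", data=np.asarray(es.trial_ids, dtype=np.int64))
            if es.labels is not None:
                g.create_dataset("labels", data=np.asarray(es.labels, dtype=bool))


def read_epochs(path: str | Path) -> dict[str, "EpochSet"]:
    from .preprocess import EpochSet

    out: dict[str, EpochSet] = {}
    with h5py.File(path, "r") as f:
        for pid, g in f["participants"].items():
            data = np.asarray(g["data"])
            if data.ndim != 3:
                raise FormatError(f"{path}:{pid}: data must be 3-D, got {data.shape}")
            out[pid] = EpochSet(
                data=data,
                fs=float(g.attrs["fs"]),
                window_ms=tuple(np.asarray(g.attrs["window_ms"], dtype=float)),
                channel_names=[str(c) for c in g.attrs["channel_names"]],
                trial_ids=np.asarray(g["trial_ids"]),
                labels=np.asarray(g["labels"]) if "labels" in g else None,
            )
    return out


def read_bdf(path: str | Path) -> "ContinuousEEG":
    """Import a continuous BDF/EDF recording (requires mne or pyedflib)."""
    from .preprocess import ContinuousEEG

    try:
        import mne  # type: ignore

        raw = mne.io.read_raw(str(path), preload=True, verbose="error")
        return ContinuousEEG(
            samples=raw.get_data() * 1e6,  # volts -> microvolts
            fs=float(raw.info["sfreq"]),
            channel_names=list(raw.ch_names),
        )
    except ImportError:
        pass
    try:
        import pyedflib  # type: ignore
    except ImportError as exc:
        raise CbciImportError(
            "reading BDF/EDF requires the optional dependency 'mne' or 'pyedflib'"
        ) from exc
    with pyedflib.EdfReader(str(path)) as r:
        sig = np.vstack([r.readSignal(i) for i in range(r.signals_in_file)])
        return ContinuousEEG(
            samples=sig,
            fs=float(r.getSampleFrequency(0)),
            channel_names=list(r.getSignalLabels()),
        )


class CbciImportError(FormatError, ImportError):
    pass


# ---------------------------------------------------------------------------
# Frame streams (long CSV, one row per frame, keyed by trial_id)
# ---------------------------------------------------------------------------


def write_frames(frames_by_trial: Mapping[int, "FrameStream"], path: str | Path) -> None:
    parts = []
    for tid, fs in frames_by_trial.items():
        parts.append(
            pd.DataFrame(
                {
                    "trial_id": tid,
                    "frame_index": np.arange(len(fs.timestamps)),
                    "timestamp_s": fs.timestamps,
                    "mean_r": fs.mean_rgb[:, 0],
                    "mean_g": fs.mean_rgb[:, 1],
                    "mean_b": fs.mean_rgb[:, 2],
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_frames(path: str | Path) -> dict[int, "FrameStream"]:
    from .onsets import FrameStream

    df = pd.read_csv(path)
    if tuple(df.columns) != FRAME_COLUMNS:
        raise FormatError(f"{path}: header {tuple(df.columns)} != {FRAME_COLUMNS}")
    out = {}
    for tid, sub in df.groupby("trial_id", sort=True):
        sub = sub.sort_values("frame_index")
        out[int(tid)] = FrameStream(
            timestamps=sub["timestamp_s"].to_numpy(float),
            mean_rgb=sub[["mean_r", "mean_g", "mean_b"]].to_numpy(float),
        )
    return out


def load_frames_from_pngs(
    directory: str | Path, frame_rate_hz: float, t0: float = 0.0
) -> "FrameStream":
    """Reduce a directory of full frames (sorted by name) to a mean-RGB
    stream; downstream logic operates only on the reduced stream."""
    import imageio.v3 as iio

    from .onsets import FrameStream

    paths = sorted(Path(directory).glob("*.png"))
    if not paths:
        raise FormatError(f"no PNG frames found in {directory}")
    means = []
    for p in paths:
        img = np.asarray(iio.imread(p), dtype=float)
        if img.ndim == 2:  # greyscale -> replicate
            img = img[:, :, None].repeat(3, axis=2)
        means.append(img[:, :, :3].reshape(-1, img.shape[-1])[:, :3].mean(axis=0))
    ts = t0 + np.arange(len(paths)) / frame_rate_hz
    return FrameStream(timestamps=ts, mean_rgb=np.asarray(means))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS = ("simulate", "detect", "train", "decide", "anytime", "evaluate")


@dataclass
class RunConfig:
    """Declarative configuration covering every pipeline stage.

    Unknown sections or keys are rejected; the fully resolved document is
    logged so a run can be reproduced from its log alone.
    """

    simulate: dict = dataclasses.field(default_factory=dict)
    detect: dict = dataclasses.field(default_factory=dict)
    train: dict = dataclasses.field(default_factory=dict)
    decide: dict = dataclasses.field(default_factory=dict)
    anytime: dict = dataclasses.field(default_factory=dict)
    evaluate: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise FormatError(f"{path}: config root must be a mapping")
        unknown = set(doc) - set(_CONFIG_SECTIONS)
        if unknown:
            raise FormatError(f"{path}: unknown config sections {sorted(unknown)}")
        cfg = cls(**{k: dict(v or {}) for k, v in doc.items()})
        logger.info("resolved config: %s", json.dumps(dataclasses.asdict(cfg), sort_keys=True))
        return cfg
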