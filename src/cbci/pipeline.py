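"""End-to-end driver: simulate (or load), preprocess, reconstruct RTs,
fit confidence estimators, and assemble the participant x trial matrices
that the group and anytime evaluations consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import anytime as at
from . import groups as gp
from .confidence import SCHEMAS, ConfidenceEstimator, fit_confidence
from .errors import ParameterError
from .onsets import detect_trial_onsets, reconstruct_rt
from .preprocess import EpochSet, condition_epochs
from .simulate import SimConfig, SimDataset, simulate_dataset

logger = logging.getLogger(__name__)

#: Weights are clipped away from 0 so a cast vote never silently vanishes
#: (the zero-weight convention is reserved for "not yet responded").
MIN_WEIGHT = 0.01

DEFAULT_SCHEMAS = ("rt", "rt+conf", "nf+rt", "nf+rt+conf")


@dataclass
class BenchmarkResult:
    """Aligned matrices over the decision trials of one experiment.

    All (participants, trials) matrices are aligned to ``trial_ids`` (the
    decision trials, i.e. those with a target present).  ``decisions`` is
    0 and times are NaN where a participant never responded.
    """

    config: SimConfig
    dataset: SimDataset
    trial_ids: np.ndarray
    truth: np.ndarray  # (trials,) in {-1, +1}
    participant_ids: list[str]
    decisions: np.ndarray  # (P, T) in {-1, 0, +1}
    correct: np.ndarray  # (P, T) bool (timeouts count as incorrect)
    response_times: np.ndarray  # (P, T), NaN if unanswered
    report_times: np.ndarray
    reported_conf: np.ndarray  # (P, T), NaN if unanswered
    rts_true: np.ndarray
    rts_reconstructed: np.ndarray
    weights: dict[str, np.ndarray] = field(default_factory=dict)  # schema -> (P, T)
    estimators: dict[tuple[str, str], ConfidenceEstimator] = field(default_factory=dict)
    training_accuracies: np.ndarray = field(default_factory=lambda: np.empty(0))
    conditioned_epochs: dict[str, EpochSet] = field(default_factory=dict)

    @property
    def static_weight(self) -> float:
        """Pre-report weight of the majority pair: the average training
        accuracy of all participants."""
        return float(self.training_accuracies.mean())

    def weight_matrix(self, source: str) -> np.ndarray:
        """Resolve a weight source name to a (P, T) matrix.

        Sources: a schema name, "static", "repconf", or "ones" (plain
        majority).  Weights are zero exactly where decisions are zero.
        """
        answered = self.decisions != 0
        if source in self.weights:
            w = self.weights[source]
        elif source == "static":
            w = np.full(self.decisions.shape, self.static_weight)
        elif source == "repconf":
            w = self.reported_conf / 100.0
        elif source == "ones":
            w = np.ones(self.decisions.shape)
        else:
            raise ParameterError(f"unknown weight source {source!r}")
        return np.where(answered, np.clip(np.nan_to_num(w), MIN_WEIGHT, None), 0.0)


def run_benchmark(
    config: SimConfig,
    seed: int | None = None,
    schemas: tuple[str, ...] = DEFAULT_SCHEMAS,
    detect_threshold: float | None = None,
    class_weight: str | dict | None = None,
    shrinkage: float | None = 0.1,
) -> BenchmarkResult:
    """Simulate an experiment and run the full decoding pipeline on it."""
    ds = simulate_dataset(config, seed=seed)
    return analyse_dataset(
        ds,
        schemas=schemas,
        detect_threshold=detect_threshold,
        class_weight=class_weight,
        shrinkage=shrinkage,
    )


def analyse_dataset(
    ds: SimDataset,
    schemas: tuple[str, ...] = DEFAULT_SCHEMAS,
    detect_threshold: float | None = None,
    class_weight: str | dict | None = None,
    shrinkage: float | None = 0.1,
) -> BenchmarkResult:
    config = ds.config
    sched = ds.schedule
    dec_trials = sched.loc[sched.true_label != 0].reset_index(drop=True)
    trial_ids = dec_trials.trial_id.to_numpy()
    truth = dec_trials.true_label.to_numpy()
    tid_pos = {int(t): i for i, t in enumerate(trial_ids)}
    onset_by_tid = dict(zip(dec_trials.trial_id, dec_trials.onset_s))
    pids = list(ds.trials)
    n_p, n_t = len(pids), len(trial_ids)

    decisions = np.zeros((n_p, n_t))
    correct = np.zeros((n_p, n_t), dtype=bool)
    resp_t = np.full((n_p, n_t), np.nan)
    rep_t = np.full((n_p, n_t), np.nan)
    rep_conf = np.full((n_p, n_t), np.nan)
    rts_true = np.full((n_p, n_t), np.nan)
    rts_rec = np.full((n_p, n_t), np.nan)

    for pi, pid in enumerate(pids):
        responses = {}
        for rec in ds.trials[pid]:
            if rec.true_label == 0:
                continue
            j = tid_pos[rec.trial_id]
            correct[pi, j] = rec.correctness == "correct"
            if rec.answered:
                decisions[pi, j] = rec.decision
                resp_t[pi, j] = rec.response_timestamp_s
                rep_t[pi, j] = rec.confidence_timestamp_s
                rep_conf[pi, j] = rec.reported_confidence
                rts_true[pi, j] = rec.response_timestamp_s - onset_by_tid[rec.trial_id]
                responses[rec.trial_id] = rec.response_timestamp_s
        estimates = detect_trial_onsets(
            ds.frames, responses, threshold=detect_threshold,
            lookback_s=config.response_deadline_s,
        )
        for tid, est in estimates.items():
            rt = reconstruct_rt(est, responses[tid])
            if rt is not None:
                rts_rec[pi, tid_pos[tid]] = rt

    training_acc = correct.mean(axis=1)

    result = BenchmarkResult(
        config=config,
        dataset=ds,
        trial_ids=trial_ids,
        truth=truth,
        participant_ids=pids,
        decisions=decisions,
        correct=correct,
        response_times=resp_t,
        report_times=rep_t,
        reported_conf=rep_conf,
        rts_true=rts_true,
        rts_reconstructed=rts_rec,
        training_accuracies=training_acc,
    )

    needs_neural = any(SCHEMAS[s].use_neural for s in schemas)
    if needs_neural:
        result.conditioned_epochs = {
            pid: condition_epochs(es) for pid, es in ds.epochs.items()
        }

    for schema_name in schemas:
        schema = SCHEMAS[schema_name]
        w = np.zeros((n_p, n_t))
        for pi, pid in enumerate(pids):
            answered = decisions[pi] != 0
            idx = np.where(answered)[0]
            labels = correct[pi, idx]
            rts = rts_rec[pi, idx]
            # a missing reconstructed RT (no onset, no fallback) -> deadline
            rts = np.where(np.isnan(rts), config.response_deadline_s, rts)
            epochs = None
            if schema.use_neural:
                es = result.conditioned_epochs[pid]
                if not np.array_equal(np.sort(es.trial_ids), np.sort(trial_ids[idx])):
                    raise ParameterError(f"{pid}: epoch/trial alignment mismatch")
                order = np.argsort(es.trial_ids)
                pos = order[np.searchsorted(es.trial_ids[order], trial_ids[idx])]
                epochs = es.data[pos]
            est = fit_confidence(
                labels,
                schema,
                seed=ds.config.seed + 1000 * pi,
                epochs=epochs,
                rts=rts,
                reported_conf=(
                    rep_conf[pi, idx] if schema.use_reported_confidence else None
                ),
                class_weight=class_weight,
                shrinkage=shrinkage,
            )
            result.estimators[(pid, schema_name)] = est
            w[pi, idx] = est.confidences_
        result.weights[schema_name] = w
    return result


# ---------------------------------------------------------------------------
# Convenience evaluations used by the CLI and the acceptance suite
# ---------------------------------------------------------------------------

#: Strategy name -> (aggregation, weight source).
STRATEGIES = {
    "majority": ("majority", None),
    "dictator": ("dictator", None),
    "rt": ("weighted", "rt"),
    "rt+conf": ("weighted", "rt+conf"),
    "nf+rt": ("weighted", "nf+rt"),
    "nf+rt+conf": ("weighted", "nf+rt+conf"),
}


def strategy_table(
    result: BenchmarkResult,
    strategies=("majority", "dictator", "rt", "rt+conf", "nf+rt", "nf+rt+conf"),
    group_sizes=range(1, 11),
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean accuracy +- bootstrap SEM per size for each strategy."""
    frames = []
    for name in strategies:
        kind, source = STRATEGIES[name]
        df = gp.strategy_accuracy(
            result.decisions,
            result.truth,
            kind,
            group_sizes,
            weights=result.weight_matrix(source) if source else None,
            training_accuracies=result.training_accuracies,
            n_boot=n_boot,
            seed=seed,
        )
        df["strategy"] = name
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def anytime_table(
    result: BenchmarkResult,
    pair: at.AnytimePair,
    group_sizes=range(2, 6),
    tick_s: float = at.TICK_S,
    seed: int = 0,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Accuracy-vs-time curves for one morphing pair."""
    at.check_pair(pair)
    return at.accuracy_vs_time(
        result.decisions,
        result.truth,
        result.response_times,
        result.report_times,
        result.weight_matrix(pair.pre),
        result.weight_matrix(pair.post),
        group_sizes,
        tick_s=tick_s,
        seed=seed,
        n_boot=n_boot,
    )
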