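"""Anytime group decisions: a decision at every 100 ms tick after the
first response, morphing each member between the without- and
with-reported-confidence estimators as their data arrive.

At any tick a member contributes weight 0 (not yet responded), their
pre-report confidence (responded, report pending) or their post-report
confidence (report arrived); the group decision is the confidence-weighted
vote over those contributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .groups import MemberVote, enumerate_groups, weighted_decision
from .stats import bootstrap_sem

TICK_S = 0.1


@dataclass(frozen=True)
class AnytimePair:
    """A without/with-reported-confidence estimator pair.

    ``pre`` and ``post`` name weight sources: a feature-schema name
    ("rt", "nf+rt", ...), "static" (the average training accuracy of all
    participants) or "repconf" (the reported confidence itself).
    """

    name: str
    pre: str
    post: str


def anytime_pairs() -> list[AnytimePair]:
    """The three morphing pairs evaluated in the study."""
    return [
        AnytimePair("cbci", "nf+rt", "nf+rt+conf"),
        AnytimePair("rt", "rt", "rt+conf"),
        AnytimePair("majority", "static", "repconf"),
    ]


@dataclass
class MemberTimeline:
    """One member's events and confidences for one trial."""

    participant: int
    decision: int  # -1/+1, or 0 if the member never responded
    response_time: float | None
    report_time: float | None
    weight_pre: float
    weight_post: float


@dataclass
class AnytimeTrace:
    trial_id: int
    tick_times: np.ndarray  # seconds from the first response, 0.1 s apart
    responders: list[frozenset]
    reporters: list[frozenset]
    weights: list[dict[int, float]]
    decisions: np.ndarray
    final_decision: int | None


def anytime_trace(
    trial_id: int,
    members: Mapping[int, MemberTimeline],
    tick_s: float = TICK_S,
    horizon_s: float | None = None,
    rng: np.random.Generator | None = None,
) -> AnytimeTrace:
    """Evolve one trial's group decision on the 100 ms tick grid.

    Tick 0 sits at the first response; the trace runs until ``horizon_s``
    (default: until the last member event) and is constant once every
    member's decision and report are in.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    resp = {p: m.response_time for p, m in members.items() if m.response_time is not None}
    if not resp:
        return AnytimeTrace(trial_id, np.empty(0), [], [], [], np.empty(0, int), None)
    t0 = min(resp.values())
    events = list(resp.values()) + [
        m.report_time for m in members.values() if m.report_time is not None
    ]
    if horizon_s is None:
        horizon_s = max(events) - t0
    n_ticks = int(np.ceil(horizon_s / tick_s - 1e-9)) + 1
    ticks = tick_s * np.arange(n_ticks)

    responders, reporters, weights, decisions = [], [], [], []
    for tk in ticks:
        now = t0 + tk + 1e-9
        in_resp = frozenset(p for p, t in resp.items() if t <= now)
        in_rep = frozenset(
            p
            for p in in_resp
            if members[p].report_time is not None and members[p].report_time <= now
        )
        w = {
            p: (members[p].weight_post if p in in_rep else members[p].weight_pre)
            for p in in_resp
        }
        votes = [
            MemberVote(p, members[p].decision, w[p]) for p in sorted(in_resp)
        ]
        decisions.append(weighted_decision(votes, rng))
        responders.append(in_resp)
        reporters.append(in_rep)
        weights.append(w)
    decisions = np.asarray(decisions, dtype=int)
    return AnytimeTrace(
        trial_id, ticks, responders, reporters, weights, decisions, int(decisions[-1])
    )


def accuracy_vs_time(
    decisions: np.ndarray,
    truth: np.ndarray,
    response_times: np.ndarray,
    report_times: np.ndarray,
    weights_pre: np.ndarray,
    weights_post: np.ndarray,
    group_sizes,
    tick_s: float = TICK_S,
    horizon_s: float | None = None,
    seed: int = 0,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Mean anytime group accuracy at every tick, per group size.

    All arrays are (participants, trials); times are absolute seconds with
    NaN for members who never responded/reported.  Tick 0 is each group's
    own first response.  Returns one row per (size, tick) with the mean
    accuracy over all member combinations, a bootstrap SEM over groups,
    and the average responder and reporter counts.
    """
    decisions = np.asarray(decisions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    response_times = np.asarray(response_times, dtype=float)
    report_times = np.asarray(report_times, dtype=float)
    n_p, n_t = decisions.shape
    rng = np.random.default_rng(seed)
    if horizon_s is None:
        span = np.nanmax(
            np.where(np.isnan(report_times), response_times, report_times), axis=0
        ) - np.nanmin(response_times, axis=0)
        horizon_s = float(np.nanmax(span))
    n_ticks = int(np.ceil(horizon_s / tick_s - 1e-9)) + 1
    ticks = tick_s * np.arange(n_ticks)

    rows = []
    for m in group_sizes:
        groups = enumerate_groups(n_p, m)
        acc = np.empty((len(groups), n_ticks))
        n_resp = np.empty((len(groups), n_ticks))
        n_rep = np.empty((len(groups), n_ticks))
        for g, grp in enumerate(groups):
            gi = list(grp)
            rt_g = response_times[gi]  # (m, trials)
            rep_g = report_times[gi]
            with np.errstate(all="ignore"):
                t0 = np.nanmin(rt_g, axis=0)  # (trials,)
            now = t0[None, None, :] + ticks[:, None, None] + 1e-9  # (K, 1, T)
            responded = rt_g[None, :, :] <= now  # (K, m, T)
            reported = responded & (rep_g[None, :, :] <= now)
            w = np.where(
                reported,
                weights_post[gi][None, :, :],
                np.where(responded, weights_pre[gi][None, :, :], 0.0),
            )
            s = np.einsum("kmt,mt->kt", w, decisions[gi])
            gd = np.sign(s)
            zeros = gd == 0  # ties and no-response trials: fair coin
            if zeros.any():
                gd[zeros] = np.where(rng.random(zeros.sum()) < 0.5, 1.0, -1.0)
            acc[g] = (gd == truth[None, :]).mean(axis=1)
            n_resp[g] = responded.sum(axis=1).mean(axis=1)
            n_rep[g] = reported.sum(axis=1).mean(axis=1)
        for k in range(n_ticks):
            rows.append(
                {
                    "size": m,
                    "tick": k,
                    "time_s": ticks[k],
                    "accuracy": float(acc[:, k].mean()),
                    "sem": bootstrap_sem(acc[:, k], n_boot=n_boot, seed=seed + k),
                    "mean_responders": float(n_resp[:, k].mean()),
                    "mean_reporters": float(n_rep[:, k].mean()),
                }
            )
    return pd.DataFrame(rows)


def final_decisions(
    decisions: np.ndarray,
    response_times: np.ndarray,
    report_times: np.ndarray,
    weights_pre: np.ndarray,
    weights_post: np.ndarray,
    group: tuple[int, ...],
    seed: int = 0,
) -> np.ndarray:
    """Terminal anytime decision for one group over all trials.

    Equals the non-anytime weighted vote with the post-report weights
    whenever at least one member responded (all events have occurred by
    the horizon); used by the equivalence checks.
    """
    gi = list(group)
    rng = np.random.default_rng(seed)
    answered = ~np.isnan(np.asarray(response_times, dtype=float)[gi])
    reported = answered & ~np.isnan(np.asarray(report_times, dtype=float)[gi])
    w = np.where(reported, weights_post[gi], np.where(answered, weights_pre[gi], 0.0))
    s = np.einsum("mt,mt->t", w, decisions[gi])
    gd = np.sign(s)
    zeros = gd == 0
    if zeros.any():
        gd[zeros] = np.where(rng.random(zeros.sum()) < 0.5, 1.0, -1.0)
    return gd.astype(int)


def check_pair(pair: AnytimePair) -> None:
    if pair.pre == pair.post:
        raise ParameterError("an anytime pair needs distinct pre/post sources")
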