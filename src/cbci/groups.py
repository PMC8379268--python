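"""Group decisions: enumeration of member combinations and the six
aggregation strategies (majority, dictator, and confidence-weighted votes
with weights from any of the four feature schemas).

The weighted vote is sign(sum_p w_p * d_p) with d in {-1, +1} (0 before a
member has decided, with weight 0); an exactly-zero sum is broken by a
seeded fair coin, consistent with the majority tie rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .stats import bootstrap_sem

#: A group is a sorted tuple of member indices.
GroupSpec = tuple[int, ...]


@dataclass(frozen=True)
class MemberVote:
    participant: int
    decision: int  # -1, +1, or 0 = no decision yet
    weight: float  # nonnegative; must be 0 iff decision == 0

    def __post_init__(self) -> None:
        if self.decision not in (-1, 0, 1):
            raise ParameterError(f"decision must be in {{-1, 0, +1}}: {self.decision}")
        if self.weight < 0:
            raise ParameterError("weights must be nonnegative")
        if (self.decision == 0) != (self.weight == 0):
            raise ParameterError("weight must be zero exactly when decision is zero")


def enumerate_groups(n_participants: int, m: int) -> list[GroupSpec]:
    """All C(n, m) member combinations in lexicographic order."""
    if not 1 <= m <= n_participants:
        raise ParameterError(f"group size {m} invalid for {n_participants} participants")
    return [tuple(c) for c in combinations(range(n_participants), m)]


def _coin(rng: np.random.Generator) -> int:
    return 1 if rng.random() < 0.5 else -1


def _as_arrays(votes: Iterable[MemberVote]) -> tuple[np.ndarray, np.ndarray]:
    votes = list(votes)
    d = np.array([v.decision for v in votes], dtype=float)
    w = np.array([v.weight for v in votes], dtype=float)
    if not np.any(d != 0):
        raise ParameterError("no member has decided yet")
    return d, w


def weighted_decision(votes: Iterable[MemberVote], tie_rng: np.random.Generator) -> int:
    """Confidence-weighted vote: the sign of the weighted decision sum."""
    d, w = _as_arrays(votes)
    s = float(w @ d)
    if s == 0.0:
        return _coin(tie_rng)
    return 1 if s > 0 else -1


def majority_decision(votes: Iterable[MemberVote], tie_rng: np.random.Generator) -> int:
    """Unweighted vote count; exact ties broken by a seeded fair coin."""
    d, _ = _as_arrays(votes)
    s = float(d.sum())
    if s == 0.0:
        return _coin(tie_rng)
    return 1 if s > 0 else -1


def dictator_decision(
    votes: Sequence[MemberVote], training_accuracies: Sequence[float]
) -> int:
    """Decision of the most accurate member (training-set accuracy).

    Accuracy ties go to the lowest participant id; if the best member has
    not decided, the next best is consulted.
    """
    votes = list(votes)
    if len(training_accuracies) != len(votes):
        raise ParameterError("one training accuracy per vote required")
    order = sorted(
        range(len(votes)),
        key=lambda i: (-training_accuracies[i], votes[i].participant),
    )
    for i in order:
        if votes[i].decision != 0:
            return votes[i].decision
    raise ParameterError("no member has decided yet")


# ---------------------------------------------------------------------------
# Dataset-level evaluation
# ---------------------------------------------------------------------------


def _group_decisions(
    decisions: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised sign(sum w*d) per trial with coin-flip tie-breaks.

    ``decisions``/``weights`` are (members, trials); trials where nobody
    decided also get a coin (the group must still answer).
    """
    s = np.einsum("mt,mt->t", weights, decisions)
    out = np.sign(s).astype(int)
    ties = out == 0
    if ties.any():
        out[ties] = np.where(rng.random(ties.sum()) < 0.5, 1, -1)
    return out


def group_accuracies(
    decisions: np.ndarray,
    truth: np.ndarray,
    strategy: str,
    group_sizes: Iterable[int],
    weights: np.ndarray | None = None,
    training_accuracies: np.ndarray | None = None,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Per-group accuracy vectors for every size in ``group_sizes``.

    ``decisions`` is (participants, trials) in {-1, 0, +1}; ``truth`` is
    (trials,) in {-1, +1}.  ``strategy`` is "majority", "dictator" or
    "weighted" (the latter requires ``weights`` of the same shape as
    ``decisions``, zero wherever the decision is zero).
    """
    decisions = np.asarray(decisions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    n_p, n_t = decisions.shape
    rng = np.random.default_rng(seed)
    if strategy == "weighted":
        if weights is None:
            raise ParameterError("weighted strategy requires weights")
        weights = np.asarray(weights, dtype=float)
        if weights.shape != decisions.shape:
            raise ParameterError("weights shape must match decisions shape")
        if np.any((weights == 0) != (decisions == 0)):
            raise ParameterError("weight must be zero exactly when decision is zero")
    elif strategy == "majority":
        weights = (decisions != 0).astype(float)
    elif strategy == "dictator":
        if training_accuracies is None:
            raise ParameterError("dictator strategy requires training accuracies")
    else:
        raise ParameterError(f"unknown strategy {strategy!r}")

    out: dict[int, np.ndarray] = {}
    for m in group_sizes:
        accs = []
        for grp in enumerate_groups(n_p, m):
            gi = list(grp)
            if strategy == "dictator":
                order = sorted(gi, key=lambda i: (-training_accuracies[i], i))
                gd = np.zeros(n_t)
                for i in order:  # first decided member in skill order
                    fill = (gd == 0) & (decisions[i] != 0)
                    gd[fill] = decisions[i, fill]
                undecided = gd == 0
                if undecided.any():
                    gd[undecided] = np.where(
                        rng.random(undecided.sum()) < 0.5, 1, -1
                    )
                gd = gd.astype(int)
            else:
                gd = _group_decisions(decisions[gi], weights[gi], rng)
            accs.append(float(np.mean(gd == truth)))
        out[m] = np.asarray(accs)
    return out


def strategy_accuracy(
    decisions: np.ndarray,
    truth: np.ndarray,
    strategy: str,
    group_sizes: Iterable[int],
    weights: np.ndarray | None = None,
    training_accuracies: np.ndarray | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean accuracy over all groups of each size, with bootstrap SEM.

    The SEM resamples over groups; for m = n (a single group) it is NaN.
    """
    per_size = group_accuracies(
        decisions,
        truth,
        strategy,
        group_sizes,
        weights=weights,
        training_accuracies=training_accuracies,
        seed=seed,
    )
    rows = [
        {
            "size": m,
            "strategy": strategy,
            "mean_accuracy": float(a.mean()),
            "sem": bootstrap_sem(a, n_boot=n_boot, seed=seed + m),
            "n_groups": a.size,
        }
        for m, a in per_size.items()
    ]
    return pd.DataFrame(rows)
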