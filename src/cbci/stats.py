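"""Statistical machinery: signed-rank tests, Holm step-down correction,
bootstrap standard errors, and grand-average ERP comparisons.

The signed-rank test is implemented here (rather than delegated) because
the exact-with-midranks small-sample path is asserted against brute-force
sign-pattern enumeration in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ParameterError
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

#: Largest n for which the exact null distribution is enumerated.
EXACT_LIMIT = 25


class WilcoxonResult(NamedTuple):
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    n_used: int  # pairs remaining after dropping zero differences


def wilcoxon_signed_rank(x, y=None) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ties receive midranks.  For n <= 25 the
    exact null distribution of W+ is computed by dynamic programming over
    all 2^n sign assignments (equivalent to full enumeration); beyond that
    a normal approximation with continuity and tie corrections is used.
    The two-tailed p-value is P(|W - mu| >= |w - mu|) under the null,
    where mu = n(n+1)/4.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0)  # degenerate: all differences zero
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= EXACT_LIMIT:
        # Work in doubled-rank units so midranks become integers.
        dr = np.rint(2 * ranks).astype(np.int64)
        pmf = np.zeros(int(dr.sum()) + 1)
        pmf[0] = 1.0
        for r in dr:
            shifted = np.zeros_like(pmf)
            shifted[r:] = pmf[: pmf.size - r]
            pmf = pmf + shifted
        pmf /= 2.0**n
        support = np.arange(pmf.size)  # values of 2*W+
        dev = abs(2 * w_plus - 2 * mu)
        p = float(pmf[np.abs(support - 2 * mu) >= dev - 1e-9].sum())
    else:
        ties = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (ties**3 - ties).sum() / 48.0
        diff = w_plus - mu
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if var > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(w_plus, min(p, 1.0), n)


def rank_biserial(x, y=None) -> float:
    """Matched-pairs rank-biserial correlation (effect size for the test)."""
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0
    ranks = sps.rankdata(np.abs(d))
    total = ranks.sum()
    return float((ranks[d > 0].sum() - ranks[d < 0].sum()) / total)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment, returned in input order.

    adjusted_(i) = max_{j<=i} (m-j+1) * p_(j) over the ascending ordering,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = (m - np.arange(m)) * p[order]
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def bootstrap_sem(values, n_boot: int = 1000, seed: int = 0) -> float:
    """SEM of the mean of ``values`` via bootstrap resampling (seeded)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")  # undefined for a single group
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    return float(v[idx].mean(axis=1).std(ddof=1))


# ---------------------------------------------------------------------------
# ERP grand averages and pointwise significance
# ---------------------------------------------------------------------------


@dataclass
class ErpComparison:
    channel: str
    times_ms: np.ndarray
    mean_correct: np.ndarray
    mean_incorrect: np.ndarray
    pointwise_p: np.ndarray
    significance_mask: np.ndarray
    n_participants: int


def _condition_means(
    epochs_by_participant: Mapping[str, EpochSet], ch_idx: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-participant mean waveform for correct and incorrect trials."""
    corr, incorr, used = [], [], []
    for pid, es in epochs_by_participant.items():
        if es.labels is None:
            raise ParameterError(f"participant {pid}: epochs carry no labels")
        c_mask, i_mask = es.labels, ~es.labels
        if not c_mask.any() or not i_mask.any():
            logger.warning("participant %s lacks one condition; excluded from ERP", pid)
            continue
        corr.append(es.data[c_mask, ch_idx, :].mean(axis=0))
        incorr.append(es.data[i_mask, ch_idx, :].mean(axis=0))
        used.append(pid)
    if len(used) < 2:
        raise InsufficientDataError("need >= 2 participants with both conditions")
    return np.asarray(corr), np.asarray(incorr), used


def erp_compare(
    epochs_by_participant: Mapping[str, EpochSet],
    channel: str = "FCz",
    alpha: float = 0.05,
) -> ErpComparison:
    """Grand-average correct vs incorrect waveforms with a pointwise
    significance mask (two-tailed signed-rank across participants).

    No correction is applied across timepoints; the mask shades raw
    p < alpha.
    """
    first = next(iter(epochs_by_participant.values()))
    ch_idx = first.channel_names.index(channel)
    corr, incorr, used = _condition_means(epochs_by_participant, ch_idx)
    n_t = corr.shape[1]
    pvals = np.array(
        [wilcoxon_signed_rank(corr[:, t], incorr[:, t]).pvalue for t in range(n_t)]
    )
    return ErpComparison(
        channel=channel,
        times_ms=first.times_ms,
        mean_correct=corr.mean(axis=0),
        mean_incorrect=incorr.mean(axis=0),
        pointwise_p=pvals,
        significance_mask=pvals < alpha,
        n_participants=len(used),
    )


def scalp_snapshot(
    epochs_by_participant: Mapping[str, EpochSet],
    latencies_ms: tuple[float, ...] = (-300.0, -80.0),
) -> pd.DataFrame:
    """Per-channel condition means and signed-rank p at fixed latencies."""
    first = next(iter(epochs_by_participant.values()))
    times = first.times_ms
    rows = []
    for lat in latencies_ms:
        t_idx = int(np.argmin(np.abs(times - lat)))
        for ch_idx, ch in enumerate(first.channel_names):
            corr, incorr, _ = _condition_means(epochs_by_participant, ch_idx)
            res = wilcoxon_signed_rank(corr[:, t_idx], incorr[:, t_idx])
            rows.append(
                {
                    "latency_ms": times[t_idx],
                    "channel": ch,
                    "mean_correct": corr[:, t_idx].mean(),
                    "mean_incorrect": incorr[:, t_idx].mean(),
                    "p": res.pvalue,
                }
            )
    return pd.DataFrame(rows)


def pairwise_strategy_comparison(
    accuracies: Mapping[str, Mapping[int, np.ndarray]],
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Signed-rank comparisons between strategies, per group size, with
    Holm adjustment within each pair's family of sizes.

    ``accuracies[strategy][size]`` is the vector of per-group accuracies
    (one entry per member combination).  Returns statistic, raw and
    adjusted p, rank-biserial effect size and the pair count.
    """
    names = list(accuracies)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        sizes = sorted(set(accuracies[a]) & set(accuracies[b]))
        raw = []
        for m in sizes:
            res = wilcoxon_signed_rank(accuracies[a][m], accuracies[b][m])
            raw.append(res)
        adj = holm_adjust([r.pvalue for r in raw])
        for m, res, ap in zip(sizes, raw, adj):
            rows.append(
                {
                    "strategy_a": a,
                    "strategy_b": b,
                    "size": m,
                    "statistic": res.statistic,
                    "p_raw": res.pvalue,
                    "p_holm": ap,
                    "effect_size": rank_biserial(accuracies[a][m], accuracies[b][m]),
                    "n_pairs": res.n_used,
                }
            )
    return pd.DataFrame(rows)
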