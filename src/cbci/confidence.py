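"""Per-trial decision-confidence estimation.

Neural features are CSP log-variances (first and last components of the
two-class simultaneous diagonalization of regularized class covariances);
they are combined with reconstructed RT and, optionally, reported
confidence, and fed to cross-validated random forests.  Every trial's
confidence is an out-of-fold probability of "correct", so no estimate is
produced by a model that saw that trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import InsufficientDataError, MissingFeatureError, ParameterError

logger = logging.getLogger(__name__)

N_FOLDS = 8
N_TREES = 100
#: Leaf-size floor for the forests.  Fully grown trees yield overconfident
#: out-of-fold probabilities; this floor keeps the reliability slope near 1.
MIN_SAMPLES_LEAF = 40


@dataclass(frozen=True)
class FeatureSchema:
    """Which inputs a confidence estimator consumes."""

    use_neural: bool = False
    use_rt: bool = True
    use_reported_confidence: bool = False

    def __post_init__(self) -> None:
        if not (self.use_neural or self.use_rt or self.use_reported_confidence):
            raise ParameterError("a feature schema must enable at least one input")

    @property
    def name(self) -> str:
        parts = []
        if self.use_neural:
            parts.append("nf")
        if self.use_rt:
            parts.append("rt")
        if self.use_reported_confidence:
            parts.append("conf")
        return "+".join(parts)


#: The four schemas evaluated in the study.
SCHEMAS: dict[str, FeatureSchema] = {
    "rt": FeatureSchema(use_neural=False, use_rt=True, use_reported_confidence=False),
    "rt+conf": FeatureSchema(use_neural=False, use_rt=True, use_reported_confidence=True),
    "nf+rt": FeatureSchema(use_neural=True, use_rt=True, use_reported_confidence=False),
    "nf+rt+conf": FeatureSchema(use_neural=True, use_rt=True, use_reported_confidence=True),
}


@dataclass
class CspModel:
    """Spatial projection from a two-class simultaneous diagonalization."""

    projection: np.ndarray  # (channels, components), eigenvalue-ordered
    eigenvalues: np.ndarray
    kept_components: tuple[int, int]
    class_order: tuple[str, str] = ("correct", "incorrect")
    covariance_regularization: float = 0.0

    def transform(self, epochs: np.ndarray) -> np.ndarray:
        """Log-variance of the kept components for each epoch."""
        comps = np.einsum("cd,tcs->tds", self.projection[:, list(self.kept_components)], epochs)
        var = comps.var(axis=-1, ddof=0)
        return np.log(np.maximum(var, 1e-30))


def _trial_covariances(epochs: np.ndarray) -> np.ndarray:
    """Per-trial spatial covariance, trace-normalized."""
    c = np.einsum("tcs,tds->tcd", epochs, epochs)
    tr = np.trace(c, axis1=1, axis2=2)
    return c / np.maximum(tr, 1e-30)[:, None, None]


def _class_covariance(epochs: np.ndarray, shrinkage: float) -> np.ndarray:
    cov = _trial_covariances(epochs).mean(axis=0)
    d = cov.shape[0]
    # trace-normalized input => shrink toward identity/d (same trace)
    return (1.0 - shrinkage) * cov + shrinkage * np.trace(cov) / d * np.eye(d)


def _auto_shrinkage(epochs_a: np.ndarray, epochs_b: np.ndarray) -> float:
    """Ledoit-Wolf shrinkage intensity estimated from the pooled samples."""
    from sklearn.covariance import ledoit_wolf

    vals = []
    for ep in (epochs_a, epochs_b):
        x = np.concatenate([e.T for e in ep], axis=0)  # (trials*samples, channels)
        x = x - x.mean(axis=0)
        vals.append(ledoit_wolf(x, assume_centered=True)[1])
    return float(np.clip(np.mean(vals), 0.0, 1.0))


def fit_csp(
    epochs_correct: np.ndarray,
    epochs_incorrect: np.ndarray,
    shrinkage: float | None = None,
) -> CspModel:
    """Two-class CSP via the generalized eigenproblem C_a v = l (C_a+C_b) v.

    Inputs are (trials, channels, samples) arrays for the two classes.
    Components are ordered by descending eigenvalue; the first maximizes
    the correct-class variance ratio, the last the incorrect-class ratio,
    and both are retained.  ``shrinkage=None`` selects a Ledoit-Wolf
    estimate of the regularization coefficient.
    """
    for name, ep in (("correct", epochs_correct), ("incorrect", epochs_incorrect)):
        if ep.ndim != 3 or ep.shape[0] < 2:
            raise InsufficientDataError(f"need >= 2 {name} trials for CSP")
    if epochs_correct.shape[1] != epochs_incorrect.shape[1]:
        raise ParameterError("channel counts differ between classes")
    if shrinkage is None:
        shrinkage = _auto_shrinkage(epochs_correct, epochs_incorrect)
    ca = _class_covariance(epochs_correct, shrinkage)
    cb = _class_covariance(epochs_incorrect, shrinkage)
    evals, evecs = linalg.eigh(ca, ca + cb)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    return CspModel(
        projection=evecs,
        eigenvalues=evals,
        kept_components=(0, evecs.shape[1] - 1),
        covariance_regularization=shrinkage,
    )


def extract_features(
    schema: FeatureSchema,
    csp: CspModel | None = None,
    epochs: np.ndarray | None = None,
    rts: np.ndarray | None = None,
    reported_conf: np.ndarray | None = None,
) -> np.ndarray:
    """Feature matrix in the fixed order (csp_first, csp_last, rt, conf)."""
    cols = []
    if schema.use_neural:
        if csp is None or epochs is None:
            raise MissingFeatureError("schema requires neural input (csp + epochs)")
        cols.append(csp.transform(np.asarray(epochs, dtype=float)))
    if schema.use_rt:
        if rts is None:
            raise MissingFeatureError("schema requires RTs")
        cols.append(np.asarray(rts, dtype=float)[:, None])
    if schema.use_reported_confidence:
        if reported_conf is None:
            raise MissingFeatureError("schema requires reported confidence")
        cols.append(np.asarray(reported_conf, dtype=float)[:, None])
    return np.hstack(cols)


@dataclass
class ConfidenceEstimator:
    """Fold-aware confidence model for one participant.

    ``confidences_`` holds each trial's out-of-fold probability of being
    a correct decision, in [0, 1].
    """

    schema: FeatureSchema
    fold_assignment: np.ndarray  # trial -> fold index
    confidences_: np.ndarray
    csp_per_fold: list[CspModel | None] = field(default_factory=list)
    forests: list[RandomForestClassifier] = field(default_factory=list)
    n_trees: int = N_TREES
    seed: int = 0


def fit_confidence(
    labels: np.ndarray,
    schema: FeatureSchema,
    seed: int = 0,
    epochs: np.ndarray | None = None,
    rts: np.ndarray | None = None,
    reported_conf: np.ndarray | None = None,
    n_folds: int = N_FOLDS,
    n_trees: int = N_TREES,
    min_samples_leaf: int = MIN_SAMPLES_LEAF,
    shrinkage: float | None = None,
    class_weight: str | dict | None = None,
) -> ConfidenceEstimator:
    """Cross-validated random-forest confidence estimation.

    The trials are split into ``n_folds`` stratified folds (fixed by
    ``seed``).  For each fold, a CSP projection (when the schema uses
    neural features) and a 100-tree Gini forest are fitted on the training
    folds only, and the held-out trials receive the forest's probability
    of the "correct" class as their confidence.
    """
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    if n < n_folds:
        raise InsufficientDataError(f"need >= {n_folds} trials, got {n}")
    if labels.all() or not labels.any():
        raise InsufficientDataError("both classes required to fit confidence")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_assignment = np.full(n, -1, dtype=int)
    confidences = np.full(n, np.nan)
    csps: list[CspModel | None] = []
    forests: list[RandomForestClassifier] = []

    for k, (train, test) in enumerate(skf.split(np.zeros(n), labels)):
        y_train = labels[train]
        if y_train.all() or not y_train.any():
            raise InsufficientDataError(f"fold {k}: single-class training data")
        csp = None
        if schema.use_neural:
            if epochs is None:
                raise MissingFeatureError("schema requires epochs")
            try:
                csp = fit_csp(
                    epochs[train][y_train], epochs[train][~y_train], shrinkage=shrinkage
                )
            except InsufficientDataError:
                raise
        x_train = extract_features(
            schema,
            csp=csp,
            epochs=None if epochs is None else epochs[train],
            rts=None if rts is None else np.asarray(rts)[train],
            reported_conf=(
                None if reported_conf is None else np.asarray(reported_conf)[train]
            ),
        )
        x_test = extract_features(
            schema,
            csp=csp,
            epochs=None if epochs is None else epochs[test],
            rts=None if rts is None else np.asarray(rts)[test],
            reported_conf=(
                None if reported_conf is None else np.asarray(reported_conf)[test]
            ),
        )
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            criterion="gini",
            min_samples_leaf=min_samples_leaf,
            random_state=seed * n_folds + k,
            class_weight=class_weight,
            n_jobs=1,
        )
        forest.fit(x_train, y_train)
        proba = forest.predict_proba(x_test)
        correct_col = list(forest.classes_).index(True)
        confidences[test] = proba[:, correct_col]
        fold_assignment[test] = k
        csps.append(csp)
        forests.append(forest)

    return ConfidenceEstimator(
        schema=schema,
        fold_assignment=fold_assignment,
        confidences_=confidences,
        csp_per_fold=csps,
        forests=forests,
        n_trees=n_trees,
        seed=seed,
    )


def confidence_separation(
    confidences: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """(mean over correct, mean over incorrect, difference).

    The difference is NaN when one class is absent.
    """
    confidences = np.asarray(confidences, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if confidences.size == 0:
        raise InsufficientDataError("no trials")
    mc = float(confidences[labels].mean()) if labels.any() else float("nan")
    mi = float(confidences[~labels].mean()) if (~labels).any() else float("nan")
    return mc, mi, mc - mi


def reliability_slope(
    confidences: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> float:
    """Slope of binned empirical correctness vs mean confidence.

    Equal-count bins; a well-calibrated estimator has slope ~ 1.
    """
    confidences = np.asarray(confidences, dtype=float)
    labels = np.asarray(labels, dtype=float)
    order = np.argsort(confidences)
    edges = np.array_split(order, n_bins)
    xs = np.array([confidences[e].mean() for e in edges if e.size])
    ys = np.array([labels[e].mean() for e in edges if e.size])
    if xs.size < 2 or np.ptp(xs) == 0:
        return float("nan")
    return float(np.polyfit(xs, ys, 1)[0])
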