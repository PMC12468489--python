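"""Shallow feedforward classifier, pooled 10-fold cross-validation, and the
incremental feature-count sweep.

The network has one hidden layer (default 10 tanh units) and a two-unit
softmax output; responders ("R") are the positive class.  Cross-validation
pools the confusion counts over all folds and reports

    ACC = (TTP + TTN) / total * 100
    SEN = TTP / (TTP + TFN) * 100
    SPE = TTN / (TTN + TFP) * 100

where TTP/TTN/TFP/TFN are totals accumulated across the k test folds, so
every segment is tested exactly once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .fusion import FeatureMatrix
from .nca import FeatureWeights, select_top

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "R"


@dataclass
class ConfusionTotals:
    """Confusion counts pooled over all cross-validation folds."""

    ttp: int = 0
    ttn: int = 0
    tfp: int = 0
    tfn: int = 0
    per_fold: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.ttp + self.ttn + self.tfp + self.tfn

    def add(self, y_true, y_pred) -> None:
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == POSITIVE_LABEL
        pos_p = y_pred == POSITIVE_LABEL
        fold = {
            "tp": int(np.sum(pos_t & pos_p)),
            "tn": int(np.sum(~pos_t & ~pos_p)),
            "fp": int(np.sum(~pos_t & pos_p)),
            "fn": int(np.sum(pos_t & ~pos_p)),
        }
        self.ttp += fold["tp"]
        self.ttn += fold["tn"]
        self.tfp += fold["fp"]
        self.tfn += fold["fn"]
        self.per_fold.append(fold)


@dataclass
class CVReport:
    """ACC/SEN/SPE percentages derived from pooled confusion counts."""

    acc: float
    sen: float
    spe: float
    counts: ConfusionTotals
    k_features: int = -1
    fold_seed: int = 0


def metrics(c: ConfusionTotals, k_features: int = -1, fold_seed: int = 0) -> CVReport:
    """Accuracy, sensitivity and specificity (percent) from pooled counts.

    SEN is NaN when no positives were evaluated, SPE likewise for negatives;
    both emit a warning rather than raising.
    """
    if c.total <= 0:
        raise ValueError("confusion totals are empty")
    acc = 100.0 * (c.ttp + c.ttn) / c.total
    if c.ttp + c.tfn > 0:
        sen = 100.0 * c.ttp / (c.ttp + c.tfn)
    else:
        logger.warning("no positive examples evaluated; SEN undefined")
        sen = float("nan")
    if c.ttn + c.tfp > 0:
        spe = 100.0 * c.ttn / (c.ttn + c.tfp)
    else:
        logger.warning("no negative examples evaluated; SPE undefined")
        spe = float("nan")
    return CVReport(
        acc=acc, sen=sen, spe=spe, counts=c,
        k_features=k_features, fold_seed=fold_seed,
    )


def train_ffnn(features, labels, hidden_units: int = 10, seed: int = 0):
    """Train the shallow network; returns a fitted scikit-learn pipeline-like
    object exposing ``predict`` and ``predict_proba`` (rows sum to 1)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    scaler = StandardScaler().fit(X)
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden_units,),
        activation="tanh",
        solver="lbfgs",
        max_iter=2000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(scaler.transform(X), y)

    class _Model:
        def predict(self, Xq):
            return clf.predict(scaler.transform(np.asarray(Xq, dtype=float)))

        def predict_proba(self, Xq):
            return clf.predict_proba(scaler.transform(np.asarray(Xq, dtype=float)))

    return _Model()


def _knn_model(features, labels, k_neighbors: int):
    X = np.asarray(features, dtype=float)
    scaler = StandardScaler().fit(X)
    clf = KNeighborsClassifier(n_neighbors=k_neighbors).fit(
        scaler.transform(X), np.asarray(labels)
    )

    class _Model:
        def predict(self, Xq):
            return clf.predict(scaler.transform(np.asarray(Xq, dtype=float)))

    return _Model()


def _draw_folds(y, groups, k_folds, grouping, seed, max_retries=10):
    """Stratified fold assignment; re-drawn (bounded) if a training split
    would miss a class."""
    y = np.asarray(y)
    for attempt in range(max_retries):
        if grouping == "subject":
            splitter = StratifiedGroupKFold(
                n_splits=k_folds, shuffle=True, random_state=seed + attempt
            )
            splits = list(splitter.split(np.zeros(y.size), y, groups))
        else:
            splitter = StratifiedKFold(
                n_splits=k_folds, shuffle=True, random_state=seed + attempt
            )
            splits = list(splitter.split(np.zeros(y.size), y))
        if all(np.unique(y[tr]).size >= 2 for tr, _ in splits):
            return splits
    raise ValueError(
        f"could not build {k_folds} folds with both classes in every "
        f"training split after {max_retries} attempts"
    )


def crossval_10fold(
    features,
    labels,
    subject_ids=None,
    k_folds: int = 10,
    grouping: str = "segment",
    seed: int = 0,
    classifier: str = "ffnn",
    hidden_units: int = 10,
    k_neighbors: int = 5,
) -> ConfusionTotals:
    """k-fold cross-validation with pooled confusion counts.

    ``grouping='segment'`` stratifies rows directly (the protocol used for
    per-segment evaluation); ``grouping='subject'`` keeps all segments of a
    subject in the same fold, avoiding subject-identity leakage.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] < k_folds:
        raise ValueError("fewer rows than folds")
    if grouping not in ("segment", "subject"):
        raise ValueError("grouping must be 'segment' or 'subject'")
    if grouping == "subject" and subject_ids is None:
        raise ValueError("subject grouping requires subject_ids")
    splits = _draw_folds(y, subject_ids, k_folds, grouping, seed)
    totals = ConfusionTotals()
    for fold_i, (train_idx, test_idx) in enumerate(splits):
        if classifier == "ffnn":
            model = train_ffnn(
                X[train_idx], y[train_idx],
                hidden_units=hidden_units, seed=seed + fold_i,
            )
        elif classifier == "knn":
            model = _knn_model(X[train_idx], y[train_idx], k_neighbors)
        else:
            raise ValueError("classifier must be 'ffnn' or 'knn'")
        totals.add(y[test_idx], model.predict(X[test_idx]))
    assert totals.total == X.shape[0], "every row must be tested exactly once"
    return totals


def knn_baseline(
    features,
    labels,
    subject_ids=None,
    k_neighbors: int = 5,
    k_folds: int = 10,
    grouping: str = "segment",
    seed: int = 0,
) -> CVReport:
    """Cross-validated nearest-neighbor baseline (same fold protocol)."""
    totals = crossval_10fold(
        features, labels, subject_ids=subject_ids, k_folds=k_folds,
        grouping=grouping, seed=seed, classifier="knn",
        k_neighbors=k_neighbors,
    )
    return metrics(totals, k_features=np.asarray(features).shape[1], fold_seed=seed)


def feature_sweep(
    features: FeatureMatrix,
    weights: FeatureWeights,
    k_range,
    k_folds: int = 10,
    grouping: str = "segment",
    seed: int = 0,
    classifier: str = "ffnn",
    hidden_units: int = 10,
) -> dict:
    """Evaluate increasing feature counts in ranked order.

    Returns ``{"k": [...], "acc": [...], "best_k": int, "best_report":
    CVReport}``; the best k is the smallest one achieving the maximal
    accuracy.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > features.n_features:
        raise ValueError("k_range must lie within 1..n_features")
    accs, reports = [], []
    for k in ks:
        sub = select_top(features, weights, k)
        totals = crossval_10fold(
            sub.values, sub.labels, subject_ids=sub.subject_ids,
            k_folds=k_folds, grouping=grouping, seed=seed,
            classifier=classifier, hidden_units=hidden_units,
        )
        rep = metrics(totals, k_features=k, fold_seed=seed)
        accs.append(rep.acc)
        reports.append(rep)
    best_pos = int(np.argmax(accs))  # argmax takes the first (smallest k) tie
    return {
        "k": ks,
        "acc": accs,
        "best_k": ks[best_pos],
        "best_report": reports[best_pos],
    }


def channel_contributions(weights: FeatureWeights, k: int) -> dict:
    """Count how many of the top-k ranked features belong to each channel.

    Channels are identified by the ``ch<name>_bin<code>`` naming scheme;
    counts sum to k.
    """
    p = weights.w.size
    if not 1 <= k <= p:
        raise ValueError(f"k must be in 1..{p}")
    names = weights.feature_names or [f"f{i}" for i in range(p)]
    counts: dict = {}
    for idx in weights.ranking[:k]:
        name = names[idx]
        channel = name.split("_bin")[0].removeprefix("ch")
        counts[channel] = counts.get(channel, 0) + 1
    return counts
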