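"""Genre classification: baselines, budgeted model search, weighted ensemble.

The training objective throughout is multiclass log loss.  A model zoo of
standard scikit-learn families is sampled for a fixed budget of candidate
configurations; each candidate is scored on an inner validation split, and
a greedy weighted ensemble (repeated selection with replacement, at most
``ensemble_size`` picks) is assembled to minimize inner-validation log
loss.  The final prediction is the weight-averaged probability vector of
the selected members.  Features are standardized with statistics fitted on
the training set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier, HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, Perceptron, RidgeClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, DataError, LabelError, SchemaError
from .features import FeatureMatrix

__all__ = [
    "TrainConfig",
    "EnsembleModel",
    "ClassificationReport",
    "multiclass_log_loss",
    "train_baseline",
    "automl_fit",
    "predict_proba",
    "evaluate",
]

EPS = 1e-15


def multiclass_log_loss(true_labels, predicted_probabilities, class_labels) -> float:
    """Multiclass cross-entropy: ``-(1/M) sum_m sum_k y_mk log p_mk``.

    ``y_mk`` is the one-hot indicator of the true class; probabilities are
    clipped to ``[1e-15, 1 - 1e-15]``.  Rows must sum to 1 within 1e-6.
    """
    p = np.asarray(predicted_probabilities, dtype=float)
    labels = list(true_labels)
    class_labels = list(class_labels)
    if p.ndim != 2 or p.shape != (len(labels), len(class_labels)):
        raise SchemaError(
            f"probability array {p.shape} does not match {len(labels)} instances x "
            f"{len(class_labels)} classes"
        )
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise DataError("probability rows must sum to 1")
    index = {c: k for k, c in enumerate(class_labels)}
    try:
        true_idx = np.array([index[lab] for lab in labels])
    except KeyError as exc:
        raise LabelError(f"label {exc.args[0]!r} not in class vocabulary") from exc
    p_true = np.clip(p[np.arange(len(labels)), true_idx], EPS, 1 - EPS)
    return float(-np.mean(np.log(p_true)))


class SoftmaxProbWrapper:
    """Gives decision-function-only estimators a probability contract.

    Wraps an estimator whose ``decision_function`` returns margins and maps
    them through a softmax.  This is a monotone calibration surrogate, not
    a fitted calibration; it preserves the argmax.
    """

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, y)
        self.classes_ = self.estimator.classes_
        return self

    def predict_proba(self, X):
        scores = self.estimator.decision_function(X)
        if scores.ndim == 1:  # binary margins
            scores = np.column_stack([-scores, scores])
        return softmax(scores, axis=1)

    def predict(self, X):
        return self.estimator.predict(X)

    def get_params(self, deep=True):  # clone support
        return {"estimator": self.estimator}

    def set_params(self, **params):
        if "estimator" in params:
            self.estimator = params["estimator"]
        return self


@dataclass
class TrainConfig:
    """Search and ensembling configuration; the objective is multiclass log loss."""

    search_budget: int = 40
    ensemble_size: int = 20
    inner_validation: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ConfigError("ensemble_size must be >= 1")
        if self.search_budget < 1:
            raise ConfigError("search_budget must be >= 1")
        if not 0 < self.inner_validation < 1:
            raise ConfigError("inner_validation must be in (0, 1)")


def _sample_candidate(rng: np.random.Generator, seed: int, max_neighbors: int = 15):
    """Draw one model configuration from the zoo's hyperparameter space."""
    family = rng.choice(
        ["logreg", "ridge", "rf", "extratrees", "hgb", "svc", "knn", "gnb"],
    )
    if family == "logreg":
        return LogisticRegression(C=10 ** rng.uniform(-2, 2), max_iter=2000)
    if family == "ridge":
        return SoftmaxProbWrapper(RidgeClassifier(alpha=10 ** rng.uniform(-2, 2)))
    if family == "rf":
        return RandomForestClassifier(
            n_estimators=int(rng.integers(50, 201)),
            max_depth=int(rng.integers(3, 16)),
            max_features=rng.choice(["sqrt", "log2", None]),
            random_state=seed,
        )
    if family == "extratrees":
        return ExtraTreesClassifier(
            n_estimators=int(rng.integers(50, 201)),
            max_depth=int(rng.integers(3, 16)),
            random_state=seed,
        )
    if family == "hgb":
        return HistGradientBoostingClassifier(
            learning_rate=10 ** rng.uniform(-2, -0.3),
            max_iter=int(rng.integers(40, 151)),
            max_depth=int(rng.integers(2, 9)),
            random_state=seed,
        )
    if family == "svc":
        return SoftmaxProbWrapper(
            SVC(C=10 ** rng.uniform(-1, 2), gamma=10 ** rng.uniform(-3, 0))
        )
    if family == "knn":
        hi = max(2, min(16, max_neighbors + 1))
        return KNeighborsClassifier(
            n_neighbors=int(rng.integers(1, hi)), weights=rng.choice(["uniform", "distance"])
        )
    return GaussianNB()


@dataclass
class EnsembleModel:
    """Weighted set of fitted probabilistic base classifiers."""

    members: list[tuple[float, object]]
    class_labels: tuple[str, ...]
    scaler: StandardScaler
    feature_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        weights = np.array([w for w, _ in self.members])
        if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-9:
            raise ConfigError("ensemble weights must be non-negative and sum to 1")

    def _as_X(self, X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            if X.feature_names != tuple(self.feature_names):
                raise SchemaError("feature matrix keys do not match the training registry")
            return X.X()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise SchemaError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        Z = self.scaler.transform(self._as_X(X))
        out = np.zeros((Z.shape[0], len(self.class_labels)))
        for weight, member in self.members:
            out += weight * _aligned_proba(member, Z, self.class_labels)
        out /= out.sum(axis=1, keepdims=True)
        return out

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # argmax breaks ties toward the lowest class index
        return np.array([self.class_labels[i] for i in proba.argmax(axis=1)])


def _aligned_proba(member, Z, class_labels) -> np.ndarray:
    """Member probabilities re-indexed onto the ensemble's class order."""
    p = member.predict_proba(Z)
    member_classes = list(member.classes_)
    if list(class_labels) == member_classes:
        return p
    out = np.zeros((Z.shape[0], len(class_labels)))
    for i, c in enumerate(member_classes):
        out[:, class_labels.index(c)] = p[:, i]
    return out


def _check_trainable(y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DataError("training data must contain at least two classes")
    if counts.min() < 2:
        raise DataError("every class needs at least two training rows")


def train_baseline(train: FeatureMatrix, kind: str, seed: int = 0):
    """Fit a standardized linear baseline: ``ridge`` or ``perceptron``.

    Returns a fitted object with ``predict``/``predict_proba`` (ridge and
    perceptron margins are softmax-mapped) and ``classes_``.
    """
    X, y = train.X(), np.asarray(train.labels())
    if any(lab is None for lab in train.labels()):
        raise LabelError("baseline training requires labeled rows")
    _check_trainable(y)
    if kind == "ridge":
        est = RidgeClassifier()
    elif kind == "perceptron":
        est = Perceptron(random_state=seed)
    else:
        raise ConfigError(f"unknown baseline kind {kind!r}")
    scaler = StandardScaler().fit(X)
    model = SoftmaxProbWrapper(est).fit(scaler.transform(X), y)
    return EnsembleModel(
        members=[(1.0, model)],
        class_labels=tuple(model.classes_),
        scaler=scaler,
        feature_names=train.feature_names,
        metadata={"kind": kind, "seed": seed},
    )


def automl_fit(train: FeatureMatrix, config: TrainConfig | None = None) -> EnsembleModel:
    """Budgeted model-zoo search plus greedy weighted ensemble selection.

    Candidates are sampled from the zoo, fitted on an inner training split
    and scored by validation log loss.  Greedy forward selection with
    replacement (Caruana-style) picks up to ``ensemble_size`` members,
    stopping early when no addition improves the validation loss; member
    weights are selection counts normalized to 1.  Selected members are
    refitted on the full training set.  Deterministic given seed and budget.
    """
    config = config or TrainConfig()
    X, y = train.X(), np.asarray(train.labels())
    if any(lab is None for lab in train.labels()):
        raise LabelError("training requires labeled rows")
    _check_trainable(y)
    rng = np.random.default_rng(config.seed)
    class_labels = tuple(np.unique(y))

    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    # validation split must hold at least one row per class for stratification
    n_val = max(int(round(config.inner_validation * len(y))), len(class_labels))
    Z_tr, Z_val, y_tr, y_val = train_test_split(
        Z, y, test_size=n_val, random_state=config.seed, stratify=y
    )

    candidates, val_probas, val_losses = [], [], []
    for i in range(config.search_budget):
        cand = _sample_candidate(rng, seed=config.seed + i, max_neighbors=len(Z_tr))
        try:
            fitted = clone(cand).fit(Z_tr, y_tr)
            proba = _aligned_proba(fitted, Z_val, class_labels)
            loss = multiclass_log_loss(y_val, proba, class_labels)
        except Exception:  # a candidate outside its validity domain is skipped
            continue
        candidates.append(cand)
        val_probas.append(proba)
        val_losses.append(loss)
    if not candidates:
        raise DataError("no candidate model could be fitted")

    best_single = int(np.argmin(val_losses))
    # Greedy forward selection with replacement.
    picks: list[int] = []
    running = np.zeros_like(val_probas[0])
    current_loss = np.inf
    for _ in range(config.ensemble_size):
        best_i, best_loss = None, current_loss
        for i, proba in enumerate(val_probas):
            mixed = (running * len(picks) + proba) / (len(picks) + 1)
            loss = multiclass_log_loss(y_val, mixed, class_labels)
            if loss < best_loss - 1e-12:
                best_i, best_loss = i, loss
        if best_i is None:
            break
        picks.append(best_i)
        running = (running * (len(picks) - 1) + val_probas[best_i]) / len(picks)
        current_loss = best_loss

    if not picks:  # degenerate: fall back to the single best candidate
        picks = [best_single]
        current_loss = val_losses[best_single]

    counts: dict[int, int] = {}
    for i in picks:
        counts[i] = counts.get(i, 0) + 1
    total = sum(counts.values())
    members = []
    for i, count in sorted(counts.items()):
        refitted = clone(candidates[i]).fit(Z, y)
        members.append((count / total, refitted))

    return EnsembleModel(
        members=members,
        class_labels=class_labels,
        scaler=scaler,
        feature_names=train.feature_names,
        metadata={
            "seed": config.seed,
            "search_budget": config.search_budget,
            "ensemble_size": config.ensemble_size,
            "n_candidates": len(candidates),
            "inner_val_log_loss": current_loss,
            "best_single_log_loss": float(val_losses[best_single]),
        },
    )


def predict_proba(model: EnsembleModel, X) -> np.ndarray:
    """Weighted-sum ensemble probabilities; rows sum to 1."""
    return model.predict_proba(X)


@dataclass
class ClassificationReport:
    """Accuracy, per-class precision/recall/F1/support, and confusion counts."""

    accuracy: float
    class_labels: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    confusion: np.ndarray  # rows = true class, columns = predicted
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    log_loss: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "log_loss": self.log_loss,
            "class_labels": list(self.class_labels),
            "per_class": {
                c: {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                    "support": self.support[c],
                }
                for c in self.class_labels
            },
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
            "confusion": self.confusion.tolist(),
        }


def report_from_predictions(y_true, y_pred, class_labels, proba=None) -> ClassificationReport:
    """Build a report from label vectors (used for external studies too)."""
    class_labels = tuple(class_labels)
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    cm = confusion_matrix(y_true, y_pred, labels=list(class_labels))
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_true, y_pred, labels=list(class_labels), zero_division=0
    )
    mprec, mrec, mf1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(class_labels), average="macro", zero_division=0
    )
    wprec, wrec, wf1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(class_labels), average="weighted", zero_division=0
    )
    ll = multiclass_log_loss(y_true, proba, class_labels) if proba is not None else None
    return ClassificationReport(
        accuracy=float((y_true == y_pred).mean()),
        class_labels=class_labels,
        precision=dict(zip(class_labels, prec.tolist())),
        recall=dict(zip(class_labels, rec.tolist())),
        f1=dict(zip(class_labels, f1.tolist())),
        support=dict(zip(class_labels, supp.astype(int).tolist())),
        confusion=cm,
        macro_avg={"precision": float(mprec), "recall": float(mrec), "f1": float(mf1)},
        weighted_avg={"precision": float(wprec), "recall": float(wrec), "f1": float(wf1)},
        log_loss=ll,
    )


def report_from_confusion(confusion, class_labels) -> ClassificationReport:
    """Build a report from a confusion-count matrix (rows = true class).

    Useful for external studies that publish only a confusion matrix,
    e.g. a human-perception experiment to compare against the model.
    """
    cm = np.asarray(confusion, dtype=int)
    class_labels = tuple(class_labels)
    if cm.shape != (len(class_labels), len(class_labels)):
        raise SchemaError("confusion matrix shape does not match the class vocabulary")
    y_true = np.repeat(np.arange(cm.shape[0]), cm.sum(axis=1))
    y_pred = np.concatenate([np.repeat(np.arange(cm.shape[1]), row) for row in cm])
    labels = np.array(class_labels)
    return report_from_predictions(labels[y_true], labels[y_pred], class_labels)


def evaluate(model: EnsembleModel, test: FeatureMatrix) -> ClassificationReport:
    """Score a fitted model on a labeled feature matrix."""
    y_true = test.labels()
    if any(lab is None for lab in y_true):
        raise LabelError("evaluation requires labeled rows")
    proba = model.predict_proba(test)
    y_pred = np.array([model.class_labels[i] for i in proba.argmax(axis=1)])
    return report_from_predictions(y_true, y_pred, model.class_labels, proba=proba)
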