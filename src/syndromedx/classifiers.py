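"""The six classifier families in multiclass and multilabel modes.

Multiclass models map a document representation directly to one of the
ten syndrome patterns (the MBR path); multilabel models emit per-label
probabilities over the nine syndrome elements (the MBR+RBR path).  SVM
is a multiclass-only family here, matching the algorithm roster of the
hybrid path.

Reference hyperparameters: random forest with 1000 trees; linear-kernel
SVM; MLP with 6 hidden layers, widths within [64, 1024]; CNN with an
embedding layer, one convolution, max-pooling and two dense layers.
KNN and XGBoost settings are recorded explicitly in the spec object so
every experiment is self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .cnn import TextCNN
from .embeddings import ContractError
from .rulebase import ELEMENTS

__all__ = [
    "ALGORITHMS",
    "ClassifierSpec",
    "TrainedModel",
    "PredictionSet",
    "UnsupportedPairError",
    "default_spec",
    "train",
    "predict",
]

ALGORITHMS = ("rf", "xgboost", "svm", "knn", "mlp", "cnn")


class UnsupportedPairError(ValueError):
    """Algorithm/mode combination outside the supported roster."""


@dataclass
class ClassifierSpec:
    algorithm: str
    mode: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    labels: list[str]
    impl: object
    n_features: int
    meta: dict = field(default_factory=dict)


@dataclass
class PredictionSet:
    """Per-record scores and hard labels.

    ``probabilities`` rows sum to 1 (multiclass) or hold independent
    per-label probabilities in [0, 1] (multilabel).  ``labels`` holds the
    argmax pattern (ties go to the lexicographically first label) or the
    thresholded element set (possibly empty).
    """

    probabilities: np.ndarray
    labels: list
    label_inventory: list[str]


_DEFAULTS = {
    ("rf", None): {"n_estimators": 1000},
    ("xgboost", None): {"n_estimators": 100, "max_depth": 6, "learning_rate": 0.3},
    ("svm", "multiclass"): {"kernel": "linear", "C": 1.0},
    ("knn", None): {"n_neighbors": 5},
    ("mlp", None): {
        "hidden_layer_sizes": (1024, 512, 256, 128, 64, 64),
        "max_iter": 200,
    },
    ("cnn", None): {
        "filters": 128,
        "kernel_size": 3,
        "dense_units": 128,
        "learning_rate": 1e-3,
        "batch_size": 64,
        "epochs": 30,
        "patience": 5,
        "val_fraction": 0.1,
        "trainable_embeddings": True,
    },
}


def default_spec(algorithm: str, mode: str, seed: int = 0, **overrides) -> ClassifierSpec:
    """Reference hyperparameters for an algorithm/mode pair."""
    if algorithm not in ALGORITHMS:
        raise UnsupportedPairError(f"unknown algorithm {algorithm!r}")
    if mode not in ("multiclass", "multilabel"):
        raise UnsupportedPairError(f"unknown mode {mode!r}")
    if algorithm == "svm" and mode == "multilabel":
        raise UnsupportedPairError(
            "SVM is not part of the multilabel (element) roster"
        )
    params = dict(_DEFAULTS.get((algorithm, mode), _DEFAULTS.get((algorithm, None))))
    params.update(overrides)
    return ClassifierSpec(algorithm=algorithm, mode=mode, hyperparameters=params, seed=seed)


class _MultiLabelXGB:
    """Per-label one-vs-rest XGBoost that tolerates constant columns."""

    def __init__(self, params: dict, seed: int):
        self.params = params
        self.seed = seed
        self.columns_: list = []

    def fit(self, X, Y):
        for j in range(Y.shape[1]):
            col = Y[:, j]
            if len(np.unique(col)) < 2:
                self.columns_.append(float(col[0]))
            else:
                est = XGBClassifier(
                    random_state=self.seed, n_jobs=1, verbosity=0,
                    objective="binary:logistic", **self.params,
                )
                est.fit(X, col)
                self.columns_.append(est)
        return self

    def predict_proba_matrix(self, X):
        cols = []
        for c in self.columns_:
            if isinstance(c, float):
                cols.append(np.full(len(X), c))
            else:
                cols.append(c.predict_proba(X)[:, 1])
        return np.stack(cols, axis=1)


def _positive_proba(est, X, n_labels: int) -> np.ndarray:
    """Per-label positive-class probabilities from a native multilabel estimator."""
    raw = est.predict_proba(X)
    if isinstance(raw, list):
        cols = []
        for j, block in enumerate(raw):
            classes = est.classes_[j] if isinstance(est.classes_, list) else est.classes_
            if block.shape[1] == 1:
                cols.append(np.full(len(X), float(classes[0])))
            else:
                pos = int(np.where(classes == 1)[0][0])
                cols.append(block[:, pos])
        return np.stack(cols, axis=1)
    return np.asarray(raw)


def _one_hot(y_idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(y_idx), n))
    out[np.arange(len(y_idx)), y_idx] = 1.0
    return out


def train(
    spec: ClassifierSpec,
    X: np.ndarray,
    labels: Sequence,
    label_inventory: Optional[Sequence[str]] = None,
    embedding_matrix: Optional[np.ndarray] = None,
) -> TrainedModel:
    """Fit one classifier on representations ``X`` and gold labels.

    Multiclass ``labels`` are pattern strings; multilabel ``labels`` are
    element sets (binarized over the nine-element inventory).  The CNN
    requires integer index sequences plus an ``embedding_matrix``; all
    other families require real-valued feature vectors.
    """
    X = np.asarray(X)
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "cnn":
        if X.ndim != 2 or not np.issubdtype(X.dtype, np.integer):
            raise ContractError(
                "cnn requires index_sequence representations (2-D integer array)"
            )
        if embedding_matrix is None:
            raise ContractError("cnn requires an embedding_matrix initializer")
    else:
        if not np.issubdtype(X.dtype, np.floating):
            X = X.astype(np.float64)

    if spec.mode == "multiclass":
        inventory = sorted(label_inventory) if label_inventory else sorted(set(labels))
        missing = sorted(set(inventory) - set(labels))
        if missing:
            raise ValueError(f"classes with zero training instances: {missing}")
        unknown = sorted(set(labels) - set(inventory))
        if unknown:
            raise ValueError(f"labels outside the inventory: {unknown}")
        y_idx = np.array([inventory.index(l) for l in labels])
    else:
        inventory = sorted(label_inventory) if label_inventory else sorted(ELEMENTS)
        Y = np.zeros((len(labels), len(inventory)))
        for i, els in enumerate(labels):
            for e in els:
                if e not in inventory:
                    raise ValueError(f"element {e!r} outside the inventory")
                Y[i, inventory.index(e)] = 1.0

    algo, seed = spec.algorithm, spec.seed
    if algo == "rf":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
        est.fit(X, y_idx if spec.mode == "multiclass" else Y)
    elif algo == "knn":
        est = KNeighborsClassifier(n_jobs=1, **hp)
        est.fit(X, y_idx if spec.mode == "multiclass" else Y)
    elif algo == "mlp":
        est = MLPClassifier(random_state=seed, **hp)
        est.fit(X, y_idx if spec.mode == "multiclass" else Y)
    elif algo == "svm":
        hp.pop("kernel", None)  # LinearSVC is the linear kernel
        est = LinearSVC(random_state=seed, **hp)
        est.fit(X, y_idx)
    elif algo == "xgboost":
        if spec.mode == "multiclass":
            est = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0, **hp)
            est.fit(X, y_idx)
        else:
            est = _MultiLabelXGB(hp, seed).fit(X, Y)
    elif algo == "cnn":
        est = TextCNN(
            vocab_size=embedding_matrix.shape[0],
            embed_dim=embedding_matrix.shape[1],
            n_outputs=len(inventory),
            mode=spec.mode,
            seed=seed,
            embeddings=embedding_matrix,
            **hp,
        )
        ytrain = _one_hot(y_idx, len(inventory)) if spec.mode == "multiclass" else Y
        est.fit(X, ytrain)
    else:  # pragma: no cover
        raise UnsupportedPairError(algo)
    return TrainedModel(
        spec=spec, labels=list(inventory), impl=est, n_features=X.shape[1]
    )


def predict(model: TrainedModel, X: np.ndarray, threshold: float = 0.5) -> PredictionSet:
    """Probabilities and hard labels for new representations."""
    X = np.asarray(X)
    if X.ndim != 2:
        raise ContractError("X must be 2-D")
    if model.spec.algorithm != "cnn" and X.shape[1] != model.n_features:
        raise ContractError(
            f"feature dimension {X.shape[1]} != training dimension {model.n_features}"
        )
    est, mode = model.impl, model.spec.mode
    n_labels = len(model.labels)
    if mode == "multiclass":
        if model.spec.algorithm == "svm":
            scores = est.decision_function(X)
            if scores.ndim == 1:  # binary: margin for class 1
                scores = np.stack([-scores, scores], axis=1)
            scores = scores - scores.max(axis=1, keepdims=True)
            e = np.exp(scores)
            probs_raw = e / e.sum(axis=1, keepdims=True)
            classes = est.classes_
        elif model.spec.algorithm == "cnn":
            probs_raw = est.predict_proba(X)
            classes = np.arange(n_labels)
        else:
            probs_raw = est.predict_proba(X)
            classes = est.classes_
        probs = np.zeros((len(X), n_labels))
        for col, cls in enumerate(np.asarray(classes, dtype=int)):
            probs[:, cls] = probs_raw[:, col]
        hard = [model.labels[i] for i in probs.argmax(axis=1)]
    else:
        if model.spec.algorithm == "cnn":
            probs = est.predict_proba(X)
        elif model.spec.algorithm == "xgboost":
            probs = est.predict_proba_matrix(X)
        else:
            probs = _positive_proba(est, X, n_labels)
        hard = [
            frozenset(model.labels[j] for j in np.flatnonzero(row >= threshold))
            for row in probs
        ]
    return PredictionSet(probabilities=probs, labels=hard, label_inventory=list(model.labels))
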