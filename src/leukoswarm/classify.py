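"""Classifier backends behind one train/predict contract.

The probabilistic neural network (PNN) — a Parzen kernel-density
("kernel discriminant") classifier that stores the training patterns in
a single pass — is implemented here in full.  Naive Bayes, SVM and
random forest satisfy the same contract through scikit-learn estimators
with pinned seeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

__all__ = ["TrainedModel", "pnn_train", "train", "predict", "CLASSIFIER_KINDS"]

CLASSIFIER_KINDS = ("PNN", "NBC", "SVM", "RF")


@dataclass
class TrainedModel:
    """Fitted classifier: ``kind`` tag, opaque state, binary class labels."""

    kind: str
    state: object
    classes: np.ndarray
    hyperparams: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


class _PNNState:
    """Stored patterns + smoothing width; one 'epoch' of training."""

    def __init__(self, X, y, sigma, prior_weighted):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.sigma = float(sigma)
        self.prior_weighted = bool(prior_weighted)


def default_pnn_sigma(X: np.ndarray) -> float:
    """Median pairwise training distance / sqrt(2); guards degenerate data."""
    X = np.asarray(X, dtype=float)
    if len(X) < 2:
        return 1.0
    d = cdist(X, X)
    vals = d[np.triu_indices(len(X), k=1)]
    med = float(np.median(vals))
    if med <= 0:
        nz = vals[vals > 0]
        med = float(nz.min()) if len(nz) else 1.0
    return med / np.sqrt(2.0)


def pnn_train(
    X: np.ndarray,
    y: np.ndarray,
    sigma: float | None = None,
    prior_weighted: bool = False,
) -> TrainedModel:
    """Store training patterns for Parzen-density classification.

    The class score of a query x is the class-conditional density
    (1/n_c) sum_i exp(-||x - x_i||^2 / (2 sigma^2)); ``prior_weighted``
    multiplies by the class prior.  ``sigma`` defaults to the median
    pairwise training distance / sqrt(2).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if sigma is None:
        sigma = default_pnn_sigma(X)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    state = _PNNState(X, y, sigma, prior_weighted)
    return TrainedModel(
        kind="PNN", state=state, classes=classes, hyperparams={"sigma": sigma}
    )


def _pnn_log_scores(state: _PNNState, X: np.ndarray, classes) -> np.ndarray:
    d2 = cdist(np.asarray(X, float), state.X, "sqeuclidean")
    loglik = -d2 / (2.0 * state.sigma**2)
    n = len(state.y)
    out = np.empty((len(X), len(classes)))
    for ci, c in enumerate(classes):
        mask = state.y == c
        n_c = int(mask.sum())
        out[:, ci] = logsumexp(loglik[:, mask], axis=1) - np.log(n_c)
        if state.prior_weighted:
            out[:, ci] += np.log(n_c / n)
    return out


def train(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit a classifier of the given kind; deterministic given ``seed``.

    Hyperparameters: PNN ``sigma``; SVM ``C``/``kernel``; RF ``n_trees``;
    NBC ``var_smoothing``.
    """
    hp = dict(hyperparams or {})
    kind = kind.upper()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if kind == "PNN":
        return pnn_train(X, y, sigma=hp.get("sigma"), prior_weighted=hp.get("prior_weighted", False))
    if kind == "NBC":
        model = GaussianNB(var_smoothing=hp.get("var_smoothing", 1e-9)).fit(X, y)
    elif kind == "SVM":
        model = SVC(
            C=hp.get("C", 1.0), kernel=hp.get("kernel", "linear"), random_state=seed
        ).fit(X, y)
    elif kind == "RF":
        model = RandomForestClassifier(
            n_estimators=hp.get("n_trees", 100), random_state=seed
        ).fit(X, y)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
    return TrainedModel(kind=kind, state=model, classes=np.unique(y), hyperparams=hp)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if model.kind == "PNN":
        scores = _pnn_log_scores(model.state, X, model.classes)
        return model.classes[scores.argmax(axis=1)]
    return np.asarray(model.state.predict(X), dtype=int)
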