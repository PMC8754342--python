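"""Live/dead classification of segmented cell crops.

Dead cells and debris differ from live cells in size, shape and texture and
would contaminate the learned latent space, so crops are screened by a small
neural classifier before encoding.  Training labels come from manual
annotation; at inference, crops scoring below the decision threshold are
flagged Dead and discarded from the analysis stream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import MLP, Adam, binary_cross_entropy

__all__ = [
    "ViabilityClassifier",
    "train_viability",
    "classify_viability",
    "cross_entropy",
    "roc_curve",
]

cross_entropy = binary_cross_entropy


def _stack_crops(crops) -> np.ndarray:
    imgs = [np.asarray(getattr(c, "image", c), dtype=float).ravel() for c in crops]
    X = np.asarray(imgs)
    if X.ndim != 2 or len({img.size for img in imgs}) > 1:
        raise ValueError("crops must share one shape")
    return X


class ViabilityClassifier(BaseEstimator, ClassifierMixin):
    """Binary live/dead classifier on flattened brightfield crops.

    A small dense network with a sigmoid output, trained with binary
    cross-entropy and Adam.  ``predict_proba`` returns P(live); a crop is
    Live iff that probability is at least ``threshold``.
    """

    def __init__(self, hidden: int = 64, steps: int = 800,
                 batch_size: int = 32, lr: float = 1e-3,
                 threshold: float = 0.5, seed: int = 0):
        self.hidden = hidden
        self.steps = steps
        self.batch_size = batch_size
        self.lr = lr
        self.threshold = threshold
        self.seed = seed

    def fit(self, crops, y):
        """Fit on crops with 0/1 labels (1 = Live)."""
        X = _stack_crops(crops)
        y = np.asarray(y, dtype=float).ravel()
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(self.seed)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        self.net_ = MLP([X.shape[1], self.hidden, 1], rng, out="sigmoid")
        opt = Adam(self.net_.params, lr=self.lr)
        self.loss_history_ = []
        n = len(X)
        for _ in range(self.steps):
            idx = rng.integers(0, n, size=min(self.batch_size, n))
            xb, yb = X[idx], y[idx][:, None]
            p = self.net_.forward(xb)
            self.loss_history_.append(binary_cross_entropy(p, yb))
            # d BCE / d p, mean-reduced over the batch
            p_c = np.clip(p, 1e-7, 1 - 1e-7)
            grad = (p_c - yb) / (p_c * (1 - p_c)) / len(yb)
            self.net_.backward(grad)
            opt.step(self.net_.grads)
        return self

    def predict_proba(self, crops) -> np.ndarray:
        X = _stack_crops(crops)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("crop shape differs from the training shape")
        p = self.net_.forward(X).ravel()
        return np.column_stack([1 - p, p])

    def decision_scores(self, crops) -> np.ndarray:
        """P(live) per crop."""
        return self.predict_proba(crops)[:, 1]

    def predict(self, crops) -> np.ndarray:
        return (self.decision_scores(crops) >= self.threshold).astype(int)


def train_viability(crops, y, steps: int = 800, seed: int = 0,
                    **kwargs) -> ViabilityClassifier:
    return ViabilityClassifier(steps=steps, seed=seed, **kwargs).fit(crops, y)


def classify_viability(model: ViabilityClassifier, crops,
                       threshold: float | None = None) -> pd.DataFrame:
    """Score crops and flag Dead ones for removal.

    Returns a table (crop_id, score, label) where label is "Live" iff
    score >= threshold.  An empty input yields an empty table.
    """
    thr = model.threshold if threshold is None else threshold
    if len(crops) == 0:
        return pd.DataFrame(columns=["crop_id", "score", "label"])
    scores = model.decision_scores(crops)
    ids = [getattr(c, "crop_id", i) for i, c in enumerate(crops)]
    labels = np.where(scores >= thr, "Live", "Dead")
    return pd.DataFrame({"crop_id": ids, "score": scores, "label": labels})


def roc_curve(scores, labels):
    """Receiver operating characteristic and its area under the curve.

    Returns ``(fpr, tpr, auc)``.  The curve is traced by sweeping the
    decision threshold over the sorted scores; AUC is the trapezoidal area.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC undefined with a single class")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    tpr = np.concatenate([[0.0], tps / tps[-1]])
    fpr = np.concatenate([[0.0], fps / fps[-1]])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
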