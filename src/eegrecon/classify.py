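"""Maximum-margin linear classification and the evaluation battery.

The classifier is a linear soft-margin SVM trained in the dual:

    max_a  sum_i a_i - (1/2) sum_ij a_i a_j y_i y_j <x_i, x_j>
    s.t.   sum_i a_i y_i = 0,   0 <= a_i <= C,

solved by SMO-style pairwise coordinate ascent with deterministic
maximally-violating-pair selection (ties broken by lowest index).  The
box constant ``C`` (default 1.0) is the standard soft-margin relaxation;
as ``C -> inf`` the solution reduces to the hard-margin maximum-margin
hyperplane.  KKT residuals are checked after every fit.

Evaluation mirrors the usual motor-imagery reporting: confusion matrix,
accuracy, Cohen's kappa, and per-class precision/recall/F1/support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from .csp import FeatureBlock

__all__ = [
    "MarginClassifier",
    "EvalReport",
    "ConvergenceError",
    "stratified_split_indices",
    "split_train_test",
    "train_margin_classifier",
    "predict",
    "decision_values",
    "evaluate",
]


class ConvergenceError(RuntimeError):
    """Dual solver failed to reach the requested KKT tolerance."""


def stratified_split_indices(classes: np.ndarray, ratio: float,
                             seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/test indices (sorted within sides)."""
    if not 0 < ratio < 1:
        raise ValueError("split ratio must lie strictly between 0 and 1")
    classes = np.asarray(classes)
    idx = np.arange(len(classes))
    train, test = train_test_split(idx, train_size=ratio, stratify=classes,
                                   random_state=seed)
    train, test = np.sort(train), np.sort(test)
    for side, name in ((train, "train"), (test, "test")):
        counts = pd.Series(classes[side]).value_counts()
        if (counts < 1).any() or len(counts) < len(np.unique(classes)):
            raise ValueError(f"a class has no trials on the {name} side")
    return train, test


def split_train_test(features: FeatureBlock, ratio: float = 0.7,
                     seed: int = 42) -> tuple[FeatureBlock, FeatureBlock]:
    """Stratified split of a feature block (default 70/30)."""
    tr, te = stratified_split_indices(features.classes, ratio, seed)
    return (
        FeatureBlock(features.values[tr], features.feature_names,
                     features.classes[tr]),
        FeatureBlock(features.values[te], features.feature_names,
                     features.classes[te]),
    )


@dataclass
class MarginClassifier:
    """Trained linear maximum-margin classifier.

    ``w`` is the hyperplane normal, ``b`` the bias, ``alphas`` the dual
    coefficients for every training sample (zero off the support set).
    ``classes`` holds the two original class ids sorted ascending; the
    internal encoding maps ``classes[0] -> -1`` and ``classes[1] -> +1``.
    """

    w: np.ndarray
    b: float
    alphas: np.ndarray
    sv_indices: np.ndarray
    C: float
    classes: tuple[int, int]


def _as_xy(train: FeatureBlock | tuple[np.ndarray, np.ndarray]
           ) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    if isinstance(train, FeatureBlock):
        X, labels = train.values, train.classes
    else:
        X, labels = train
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels, dtype=int)
    ids = sorted(int(c) for c in np.unique(labels))
    if len(ids) != 2:
        raise ValueError(f"binary classifier needs exactly 2 classes, "
                         f"got {ids}")
    y = np.where(labels == ids[1], 1.0, -1.0)
    return X, y, (ids[0], ids[1])


def train_margin_classifier(train: FeatureBlock | tuple[np.ndarray, np.ndarray],
                            C: float = 1.0, tol: float = 1e-8,
                            max_iter: int = 200_000) -> MarginClassifier:
    """Solve the soft-margin dual by deterministic SMO.

    Pair selection follows the maximal-violating-pair rule on the KKT
    gradient; the loop stops when the duality-gap surrogate
    ``m(a) - M(a)`` falls below ``tol``.  Non-convergence raises
    :class:`ConvergenceError` with iteration diagnostics.
    """
    X, y, class_ids = _as_xy(train)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if C <= 0:
        raise ValueError("C must be positive")
    n = len(y)
    K = X @ X.T
    Q = (y[:, None] * y[None, :]) * K
    a = np.zeros(n)
    grad = -np.ones(n)  # gradient of (1/2)a'Qa - e'a at a = 0
    eps = 1e-12
    it = 0
    for it in range(max_iter):
        yg = -y * grad
        up = ((y > 0) & (a < C - eps)) | ((y < 0) & (a > eps))
        low = ((y > 0) & (a > eps)) | ((y < 0) & (a < C - eps))
        if not up.any() or not low.any():
            break
        i = int(np.flatnonzero(up)[np.argmax(yg[up])])
        j = int(np.flatnonzero(low)[np.argmin(yg[low])])
        violation = yg[i] - yg[j]
        if violation < tol:
            break
        quad = K[i, i] + K[j, j] - 2 * K[i, j]
        quad = max(quad, 1e-12)
        # step t moves a_i by +y_i t and a_j by -y_j t (keeps sum a.y fixed)
        t = violation / quad
        t_max = min(
            (C - a[i]) if y[i] > 0 else a[i],
            a[j] if y[j] > 0 else (C - a[j]),
        )
        t = min(t, t_max)
        da_i, da_j = y[i] * t, -y[j] * t
        a[i] += da_i
        a[j] += da_j
        grad += Q[:, i] * da_i + Q[:, j] * da_j
    else:
        yg = -y * grad
        raise ConvergenceError(
            f"SMO did not converge in {max_iter} iterations "
            f"(violation {yg.max() - yg.min():.3g})")
    w = X.T @ (a * y)
    free = (a > eps) & (a < C - eps)
    scores = X @ w
    if free.any():
        b = float(np.mean(y[free] - scores[free]))
    else:
        # no free SVs: bias anywhere between the KKT bounds; take midpoint
        yg = -y * grad
        up = ((y > 0) & (a < C - eps)) | ((y < 0) & (a > eps))
        low = ((y > 0) & (a > eps)) | ((y < 0) & (a < C - eps))
        hi = yg[up].max() if up.any() else 0.0
        lo = yg[low].min() if low.any() else 0.0
        b = float((hi + lo) / 2)
    sv = np.flatnonzero(a > eps)
    return MarginClassifier(w=w, b=b, alphas=a, sv_indices=sv, C=C,
                            classes=class_ids)


def decision_values(model: MarginClassifier,
                    features: FeatureBlock | np.ndarray) -> np.ndarray:
    X = features.values if isinstance(features, FeatureBlock) \
        else np.asarray(features, dtype=float)
    if X.shape[1] != len(model.w):
        raise ValueError(
            f"feature dimension {X.shape[1]} != weight dimension "
            f"{len(model.w)}")
    return X @ model.w + model.b


def predict(model: MarginClassifier,
            features: FeatureBlock | np.ndarray) -> np.ndarray:
    """Predicted class ids; a decision value of exactly 0 goes to the
    positive class (``classes[1]``)."""
    g = decision_values(model, features)
    return np.where(g >= 0, model.classes[1], model.classes[0])


@dataclass
class EvalReport:
    """Confusion matrix and derived classification metrics.

    ``confusion`` rows are true classes, columns predicted, ordered as
    ``class_ids``.  ``kappa`` is Cohen's chance-corrected agreement; it is
    ``None`` when expected agreement is 1 (degenerate marginals).
    """

    class_ids: tuple[int, ...]
    confusion: np.ndarray
    accuracy: float
    kappa: float | None
    per_class: pd.DataFrame

    def metrics_frame(self) -> pd.DataFrame:
        """One-row summary mirroring the usual accuracy/kappa table."""
        return pd.DataFrame({
            "Accuracy %": [100.0 * self.accuracy],
            "Kappa": [self.kappa if self.kappa is not None else np.nan],
        })

    def confusion_frame(self) -> pd.DataFrame:
        labels = [str(c) for c in self.class_ids]
        return pd.DataFrame(self.confusion,
                            index=pd.Index(labels, name="true"),
                            columns=pd.Index(labels, name="predicted"))


def _kappa_from_confusion(cm: np.ndarray) -> float | None:
    total = cm.sum()
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total ** 2
    if p_e >= 1.0:
        return None
    return float((p_o - p_e) / (1 - p_e))


def evaluate(true_labels: np.ndarray, pred_labels: np.ndarray,
             class_ids: tuple[int, ...] | None = None) -> EvalReport:
    """Full metric battery from true/predicted label vectors."""
    true_labels = np.asarray(true_labels, dtype=int)
    pred_labels = np.asarray(pred_labels, dtype=int)
    if len(true_labels) == 0:
        raise ValueError("empty label vectors")
    if len(true_labels) != len(pred_labels):
        raise ValueError("label vectors must have equal length")
    if class_ids is None:
        class_ids = tuple(sorted(
            set(true_labels.tolist()) | set(pred_labels.tolist())))
    cm = confusion_matrix(true_labels, pred_labels, labels=list(class_ids))
    accuracy = float(np.trace(cm) / cm.sum())
    kappa = _kappa_from_confusion(cm)
    prec, rec, f1, support = precision_recall_fscore_support(
        true_labels, pred_labels, labels=list(class_ids), zero_division=0)
    per_class = pd.DataFrame({
        "Class": list(class_ids),
        "Precision": prec,
        "Recall": rec,
        "F1-score": f1,
        "Support": support,
    })
    return EvalReport(class_ids=tuple(class_ids), confusion=cm,
                      accuracy=accuracy, kappa=kappa, per_class=per_class)
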