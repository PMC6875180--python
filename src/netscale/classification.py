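"""Linear SVM classification with repeated stratified cross-validation.

The classifier is a linear maximum-margin SVM (LIBSVM via scikit-learn,
tolerance 1e-3, default C = 1).  Performance is estimated with stratified
10-fold cross-validation repeated many times; features are standardized using
training-fold statistics only, so no test information leaks into the model.
Sensitivity treats patients (label 1) as positives.

Two evaluation protocols beyond plain repeated CV are provided:

* an accuracy-vs-feature-count sweep that adds features in ascending-P order
  in blocks, tracing the rise-then-fall curve used to probe the P < 0.05
  selection threshold;
* a nested 70/30 holdout protocol that tunes C = 2**c, c in -5..5, by inner
  10-fold CV on the training split and regresses test accuracy on validation
  accuracy across repeats to quantify overfitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CVResult",
    "confusion_rates",
    "repeated_kfold",
    "accuracy_vs_feature_count",
    "nested_holdout_protocol",
    "default_c_grid",
]


def default_c_grid() -> np.ndarray:
    """Penalty grid C = 2**c for c = -5..5."""
    return 2.0 ** np.arange(-5, 6)


def _svm(C: float = 1.0, tol: float = 1e-3):
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=C, tol=tol))


def confusion_rates(predictions, labels) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with patients (1) as positives.

    A rate whose denominator is empty (no positives or no negatives in
    ``labels``) is returned as NaN with a warning.
    """
    pred = np.asarray(predictions)
    y = np.asarray(labels)
    if pred.shape != y.shape:
        raise ValueError("predictions and labels differ in length")
    acc = float(np.mean(pred == y))
    pos, neg = y == 1, y == 0
    if pos.any():
        sens = float(np.mean(pred[pos] == 1))
    else:
        warnings.warn("no positive labels; sensitivity undefined")
        sens = float("nan")
    if neg.any():
        spec = float(np.mean(pred[neg] == 0))
    else:
        warnings.warn("no negative labels; specificity undefined")
        spec = float("nan")
    return acc, sens, spec


@dataclass
class CVResult:
    """Aggregate and per-repeat cross-validation performance."""

    accuracy: float
    sensitivity: float
    specificity: float
    train_accuracy: float
    per_repeat: np.ndarray = field(repr=False)  # (repeats, 4) columns as above
    k: int = 10
    repeats: int = 100
    seed: int = 0


def repeated_kfold(
    X: np.ndarray,
    y: np.ndarray,
    feature_idx=None,
    k: int = 10,
    repeats: int = 100,
    seed: int = 0,
    C: float = 1.0,
    tol: float = 1e-3,
    stratified: bool = True,
) -> CVResult:
    """Repeated k-fold cross-validation of the linear SVM.

    Per repeat, the subjects are split into ``k`` folds (stratified by
    default); each fold serves once as the test set while the remaining
    folds train the model.  Test predictions are pooled within a repeat to
    compute accuracy / sensitivity / specificity; training accuracy is the
    mean over folds of the fitted model's accuracy on its own training data.
    Fully deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if feature_idx is not None:
        X = X[:, np.asarray(feature_idx, dtype=int)]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both classes present")
    min_class = int(counts.min())
    if stratified and k > min_class:
        warnings.warn(f"k={k} exceeds smallest class size {min_class}; clipping")
        k = min_class
    if X.shape[0] < k:
        raise ValueError(f"k={k} exceeds subject count {X.shape[0]}")
    if k < 2:
        raise ValueError("need at least 2 folds (2 subjects per class)")
    rng = np.random.default_rng(seed)
    rows = np.empty((repeats, 4))
    for rep in range(repeats):
        rs = int(rng.integers(2**31))
        splitter = (
            StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
            if stratified
            else KFold(n_splits=k, shuffle=True, random_state=rs)
        )
        pred = np.full(y.shape, -1, dtype=int)
        train_accs = []
        for tr, te in splitter.split(X, y):
            if np.unique(y[tr]).size < 2:
                continue  # degenerate fold; its test subjects stay unpredicted
            model = _svm(C=C, tol=tol).fit(X[tr], y[tr])
            pred[te] = model.predict(X[te])
            train_accs.append(np.mean(model.predict(X[tr]) == y[tr]))
        acc, sens, spec = confusion_rates(pred, y)
        rows[rep] = (acc, sens, spec, float(np.mean(train_accs)))
    means = rows.mean(axis=0)
    return CVResult(
        accuracy=float(means[0]),
        sensitivity=float(means[1]),
        specificity=float(means[2]),
        train_accuracy=float(means[3]),
        per_repeat=rows,
        k=k,
        repeats=repeats,
        seed=seed,
    )


def accuracy_vs_feature_count(
    X: np.ndarray,
    y: np.ndarray,
    p_order: np.ndarray,
    step: int = 3,
    repeats: int = 5,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
    max_features: int | None = None,
) -> dict:
    """Mean CV accuracy as features are added in ascending-P order.

    ``p_order`` ranks all candidate features by raw screening P (smallest
    first).  Subsets grow in blocks of ``step``; each subset is scored with
    ``repeats`` rounds of stratified k-fold CV.  Returns the curve and its
    argmax.
    """
    p_order = np.asarray(p_order, dtype=int)
    if p_order.size == 0:
        raise ValueError("empty feature ranking")
    if step <= 0:
        raise ValueError("step must be positive")
    limit = p_order.size if max_features is None else min(max_features, p_order.size)
    sizes = list(range(step, limit + 1, step))
    if not sizes or sizes[-1] != limit:
        sizes.append(limit)
    rng = np.random.default_rng(seed)
    counts, accs = [], []
    for m in sizes:
        res = repeated_kfold(
            X, y, feature_idx=p_order[:m], k=k, repeats=repeats,
            seed=int(rng.integers(2**31)), C=C,
        )
        counts.append(m)
        accs.append(res.accuracy)
    accs = np.array(accs)
    best = int(np.argmax(accs))
    return {
        "n_features": np.array(counts),
        "accuracy": accs,
        "best_n_features": counts[best],
        "best_accuracy": float(accs[best]),
    }


def nested_holdout_protocol(
    X: np.ndarray,
    y: np.ndarray,
    feature_idx=None,
    ratio: float = 0.7,
    repeats: int = 100,
    C_grid=None,
    k: int = 10,
    seed: int = 0,
) -> dict:
    """Repeated 70/30 holdout with inner 10-fold C selection.

    Per repeat: a stratified ``ratio`` split; on the training part an inner
    stratified k-fold chooses the C from ``C_grid`` with the best inner
    accuracy (the recorded validation accuracy); the winning C is refit on
    the whole training part and scored on the untouched holdout.  Returns the
    paired (validation, test) accuracies and an OLS regression of test on
    validation accuracy (slope, adjusted R^2, two-sided P).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if feature_idx is not None:
        X = X[:, np.asarray(feature_idx, dtype=int)]
    if C_grid is None:
        C_grid = default_c_grid()
    C_grid = np.asarray(C_grid, dtype=float)
    if C_grid.size == 0:
        raise ValueError("C_grid must be nonempty")
    rng = np.random.default_rng(seed)
    val_acc = np.empty(repeats)
    test_acc = np.empty(repeats)
    for rep in range(repeats):
        rs = int(rng.integers(2**31))
        sss = StratifiedShuffleSplit(n_splits=1, train_size=ratio, random_state=rs)
        tr, te = next(sss.split(X, y))
        inner = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        folds = list(inner.split(X[tr], y[tr]))
        best_c, best_score = C_grid[0], -np.inf
        for c in C_grid:
            scores = []
            for itr, ite in folds:
                model = _svm(C=c).fit(X[tr][itr], y[tr][itr])
                scores.append(np.mean(model.predict(X[tr][ite]) == y[tr][ite]))
            score = float(np.mean(scores))
            if score > best_score:
                best_c, best_score = c, score
        val_acc[rep] = best_score
        model = _svm(C=best_c).fit(X[tr], y[tr])
        test_acc[rep] = np.mean(model.predict(X[te]) == y[te])
    reg = stats.linregress(val_acc, test_acc)
    n = repeats
    r2 = reg.rvalue**2
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - 2)
    return {
        "validation_accuracy": val_acc,
        "test_accuracy": test_acc,
        "slope": float(reg.slope),
        "adjusted_r2": float(adj_r2),
        "p_value": float(reg.pvalue),
    }
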