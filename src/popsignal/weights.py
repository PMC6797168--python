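"""Decoding-weight estimation.

Multivariate weights are the feature weights of a soft-margin linear
support vector machine trained on z-scored spike counts and L2-normalized,
so that each neuron's weight expresses its role for the binary match /
non-match discrimination relative to the rest of the population.
Univariate weights are centered per-neuron ROC-AUC scores.  Trials are
split into training and validation halves with Monte-Carlo (repeated
random stratified) cross-validation; the SVM regularization parameter C
is chosen on the training set by stratified 5-fold cross-validation
maximizing balanced accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

from .core import CountMatrix

#: Regularization grid searched for the linear SVM.
C_GRID = (0.0012, 0.0015, 0.002, 0.005, 0.01, 0.05, 0.1, 0.5)
#: Number of Monte-Carlo cross-validation runs.
DEFAULT_N_RUNS = 100


@dataclass
class WeightVector:
    """Per-neuron decoding weights with offset and provenance.

    ``method`` is ``"svm"`` (multivariate), ``"auc"`` (univariate) or
    ``"perturbed:<mode>"`` for null-model variants.  For the SVM the
    weight vector is L2-normalized (``norm_applied``); the offset is the
    raw intercept and is only meaningful for prediction with the
    unnormalized weights.
    """

    weights: np.ndarray
    offset: float = 0.0
    method: str = "svm"
    regularization: float | None = None
    norm_applied: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)

    def __len__(self) -> int:
        return self.weights.size


@dataclass
class SplitSpec:
    """One Monte-Carlo train/validation split (disjoint trial indices)."""

    train_idx: np.ndarray
    valid_idx: np.ndarray
    run_id: int
    seed: int


def _as_features(zscores) -> np.ndarray:
    """Accept a CountMatrix or a (neuron x trial) array; return trials x neurons."""
    if isinstance(zscores, CountMatrix):
        zscores = zscores.zscores
    return np.asarray(zscores, dtype=float).T


def monte_carlo_splits(labels, n_runs: int = DEFAULT_N_RUNS, seed: int = 0) -> list[SplitSpec]:
    """Repeated random half/half splits, stratified by class.

    The training set gets floor(J/2) trials; splits are reproducible
    from ``seed`` and both classes are present on both sides.
    """
    labels = np.asarray(labels)
    j = labels.size
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2 or counts.min() < 4:
        raise ValueError("need two classes with at least 4 trials each")
    sss = StratifiedShuffleSplit(n_splits=n_runs, train_size=j // 2, random_state=seed)
    splits = []
    for run_id, (tr, va) in enumerate(sss.split(np.zeros(j), labels)):
        splits.append(SplitSpec(train_idx=np.sort(tr), valid_idx=np.sort(va), run_id=run_id, seed=seed))
    return splits


def balanced_accuracy(predictions, labels) -> float:
    """Mean of sensitivity and specificity: BAC = (TP/(TP+FN) + TN/(TN+FP)) / 2."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have the same length")
    pos = labels == 1
    neg = labels == -1
    if not (pos.any() and neg.any()):
        raise ValueError("labels must contain both classes")
    tpr = (predictions[pos] == 1).mean()
    tnr = (predictions[neg] == -1).mean()
    return 0.5 * tpr + 0.5 * tnr


def _fit_svm(x: np.ndarray, y: np.ndarray, c: float) -> SVC:
    clf = SVC(kernel="linear", C=c, tol=1e-6, shrinking=False)
    clf.fit(x, y)
    return clf


def select_regularization(zscores, labels, grid=C_GRID, seed: int = 0, n_folds: int = 5) -> float:
    """Choose C by stratified ``n_folds``-fold CV maximizing mean balanced accuracy.

    Ties are broken toward the smallest (most regularized) C.
    """
    grid = tuple(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    x = _as_features(zscores)
    y = np.asarray(labels)
    if len(grid) == 1:
        return grid[0]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    best_c, best_bac = None, -np.inf
    for c in sorted(grid):
        bacs = []
        for tr, va in folds:
            if np.unique(y[va]).size < 2:
                raise ValueError("validation fold with a single class")
            clf = _fit_svm(x[tr], y[tr], c)
            pred = np.where(clf.decision_function(x[va]) > 0, 1, -1)
            bacs.append(balanced_accuracy(pred, y[va]))
        mean_bac = float(np.mean(bacs))
        if mean_bac > best_bac:  # strict: ties keep the smaller C
            best_bac, best_c = mean_bac, c
    return best_c


def learn_weights(zscores, labels, C: float = 0.01) -> WeightVector:
    """Fit the soft-margin linear SVM and return the L2-normalized weights.

    The normalization keeps weights comparable across sessions whose
    selected C (and hence raw weight scale) differs; the intercept is
    kept on its raw scale.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    x = _as_features(zscores)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need at least 2 trials per class")
    clf = _fit_svm(x, y, C)
    if clf.fit_status_ != 0:
        raise RuntimeError(f"SVM solver did not converge (fit_status={clf.fit_status_}, C={C})")
    w = clf.coef_.ravel().astype(float)
    # libsvm orders classes ascending: decision_function > 0 predicts classes_[1]
    if clf.classes_[1] != 1:
        w = -w
    b = float(clf.intercept_[0])
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    return WeightVector(weights=w, offset=b, method="svm", regularization=C, norm_applied=True)


def predict(weights: WeightVector, zscores) -> np.ndarray:
    """Classify trials by the sign of w^T s + b (0 maps to +1)."""
    x = _as_features(zscores)
    score = x @ weights.weights + weights.offset
    return np.where(score > 0, 1, -1)


def auc_weights(counts, labels) -> WeightVector:
    """Univariate decoding weights from per-neuron ROC-AUC of spike counts.

    AUC_n is the probability that a random "match" trial has a larger
    count than a random "non-match" trial (ties counted 1/2), computed
    via the rank form of the Mann-Whitney U statistic (exactly the pair
    count with midrank ties).  Scores are centered at the chance level
    1/2 and the centered vector is scaled to unit L2 norm.  A neuron
    with identical count distributions gets weight 0.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    y = np.asarray(labels)
    if not ((y == 1).any() and (y == -1).any()):
        raise ValueError("both classes must be present")
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    auc = np.empty(counts.shape[0])
    for n in range(counts.shape[0]):
        ranks = rankdata(counts[n])  # midranks for ties
        u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
        auc[n] = u / (n1 * n0)
    centered = auc - 0.5
    norm = np.linalg.norm(centered)
    w = centered / norm if norm > 0 else centered
    return WeightVector(weights=w, offset=0.0, method="auc", regularization=None, norm_applied=norm > 0)
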