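"""Classifier suite and repeated stratified cross-validation.

Eight model families are registered: single classifiers (decision tree,
naive Bayes, a tree-augmented Bayesian network, a small feedforward
network) and tree ensembles (random forest, bagging, AdaBoost, rotation
forest). Evaluation is k-fold stratified cross-validation repeated R times
with fresh seeded partitions; the per-repetition accuracy is pooled over
folds, and the 95% confidence interval uses the t statistic with R − 1
degrees of freedom. Per-class precision/recall/F come from the confusion
matrix pooled over all folds and repetitions.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` substreams.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .dataset import DesignMatrix, apply_minmax, fit_minmax_bounds, fit_pca

MODEL_NAMES: tuple[str, ...] = (
    "decision_tree",
    "naive_bayes",
    "bayes_net",
    "neural_net",
    "random_forest",
    "bagging_trees",
    "adaboost_trees",
    "rotation_forest",
)

NA = math.nan


@dataclass(frozen=True)
class ModelSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def add(self, y_true: np.ndarray, y_pred: np.ndarray) -> None:
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        self.tp += int(np.sum((y_true == 1) & (y_pred == 1)))
        self.fn += int(np.sum((y_true == 1) & (y_pred == 0)))
        self.fp += int(np.sum((y_true == 0) & (y_pred == 1)))
        self.tn += int(np.sum((y_true == 0) & (y_pred == 0)))


@dataclass
class CVResult:
    accuracies: list[float]
    mean_accuracy: float
    ci_halfwidth: float
    metrics: dict[str, dict[str, float]]  # class -> {precision, recall, f}
    confusion: ConfusionMatrix
    spec: ModelSpec
    dataset: str
    folds: int
    repetitions: int


# ---------------------------------------------------------------------------
# Discretization helper (shared by TAN and info-gain users)

def equal_frequency_bins(values: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Quantile cut points (interior edges); duplicate edges collapse, so
    heavily tied data may produce fewer bins."""
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.unique(qs)


def discretize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.searchsorted(edges, values, side="right")


# ---------------------------------------------------------------------------
# Tree-augmented naive Bayes

class TanBayesClassifier(BaseEstimator, ClassifierMixin):
    """Tree-augmented naive Bayes over equal-frequency-discretized features.

    Structure: every feature's parent set is {class, one other feature},
    with the feature tree chosen by maximum conditional mutual information
    (Chow-Liu on I(Xi; Xj | Y)). Probabilities use Laplace smoothing.
    """

    def __init__(self, n_bins: int = 5, random_state: int | None = None):
        self.n_bins = n_bins
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        n, p = X.shape
        self.edges_ = [equal_frequency_bins(X[:, j], self.n_bins) for j in range(p)]
        Z = np.column_stack([discretize(X[:, j], self.edges_[j]) for j in range(p)])
        self.n_levels_ = [len(e) + 1 for e in self.edges_]

        # Chow-Liu tree on conditional mutual information given the class
        cmi = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                cmi[i, j] = cmi[j, i] = self._cmi(Z[:, i], Z[:, j], y)
        self.parents_ = self._max_spanning_tree(cmi)

        # CPTs: P(y), P(x_root | y), P(x_j | y, x_parent)
        self.class_log_prior_ = {}
        self.tables_ = {}
        for c in self.classes_:
            mask = y == c
            self.class_log_prior_[c] = math.log((mask.sum() + 1) / (n + len(self.classes_)))
            for j in range(p):
                kj = self.n_levels_[j]
                parent = self.parents_[j]
                if parent is None:
                    counts = np.ones(kj)
                    for v in Z[mask, j]:
                        counts[v] += 1
                    self.tables_[(c, j)] = np.log(counts / counts.sum())
                else:
                    kp = self.n_levels_[parent]
                    counts = np.ones((kp, kj))
                    for v, u in zip(Z[mask, j], Z[mask, parent]):
                        counts[u, v] += 1
                    self.tables_[(c, j)] = np.log(counts / counts.sum(axis=1, keepdims=True))
        return self

    @staticmethod
    def _cmi(a: np.ndarray, b: np.ndarray, y: np.ndarray) -> float:
        total = 0.0
        n = len(y)
        for c in np.unique(y):
            mask = y == c
            nc = mask.sum()
            if nc == 0:
                continue
            ac, bc = a[mask], b[mask]
            joint: dict[tuple[int, int], int] = {}
            pa: dict[int, int] = {}
            pb: dict[int, int] = {}
            for u, v in zip(ac, bc):
                joint[(u, v)] = joint.get((u, v), 0) + 1
                pa[u] = pa.get(u, 0) + 1
                pb[v] = pb.get(v, 0) + 1
            for (u, v), cnt in joint.items():
                pj = cnt / nc
                total += (nc / n) * pj * math.log2(pj / (pa[u] / nc * pb[v] / nc))
        return total

    @staticmethod
    def _max_spanning_tree(weights: np.ndarray) -> list[int | None]:
        """Prim's algorithm; node 0 is the root (parent None)."""
        p = weights.shape[0]
        parents: list[int | None] = [None] * p
        if p <= 1:
            return parents
        in_tree = {0}
        while len(in_tree) < p:
            best, best_edge = -np.inf, None
            for i in in_tree:
                for j in range(p):
                    if j not in in_tree and weights[i, j] >= best:
                        best, best_edge = weights[i, j], (i, j)
            i, j = best_edge
            parents[j] = i
            in_tree.add(j)
        return parents

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Z = np.column_stack(
            [discretize(X[:, j], self.edges_[j]) for j in range(X.shape[1])]
        )
        out = np.empty(len(X), dtype=self.classes_.dtype)
        for r in range(len(X)):
            best_c, best_ll = None, -np.inf
            for c in self.classes_:
                ll = self.class_log_prior_[c]
                for j in range(Z.shape[1]):
                    parent = self.parents_[j]
                    table = self.tables_[(c, j)]
                    ll += table[Z[r, j]] if parent is None else table[Z[r, parent], Z[r, j]]
                if ll > best_ll:
                    best_c, best_ll = c, ll
            out[r] = best_c
        return out


# ---------------------------------------------------------------------------
# Rotation forest

class RotationForestClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of decision trees, each trained on a randomly partitioned,
    per-partition PCA-rotated view of the features; majority vote.

    Per tree: features are shuffled and split into groups of
    ``partition_size``; for each group a bootstrap subsample of rows fits a
    full PCA whose components rotate that group's columns; the rotated
    blocks are concatenated and a tree is grown on the result.
    """

    def __init__(
        self,
        n_estimators: int = 10,
        partition_size: int = 3,
        bootstrap_fraction: float = 0.75,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.partition_size = partition_size
        self.bootstrap_fraction = bootstrap_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)
        n, p = X.shape
        self.rotations_: list[tuple[list[np.ndarray], np.ndarray]] = []
        self.trees_: list[DecisionTreeClassifier] = []
        for _ in range(self.n_estimators):
            order = rng.permutation(p)
            groups = [order[i : i + self.partition_size] for i in range(0, p, self.partition_size)]
            rotation = np.zeros((p, p))
            for g in groups:
                rows = rng.choice(n, size=max(2, int(self.bootstrap_fraction * n)), replace=True)
                sub = X[np.ix_(rows, g)]
                sub = sub - sub.mean(axis=0)
                try:
                    _, _, vt = np.linalg.svd(sub, full_matrices=True)
                except np.linalg.LinAlgError:  # pragma: no cover
                    vt = np.eye(len(g))
                rotation[np.ix_(g, g)] = vt.T
            Xr = X @ rotation
            tree = DecisionTreeClassifier(random_state=int(rng.integers(2**31)))
            tree.fit(Xr, y)
            self.rotations_.append((groups, rotation))
            self.trees_.append(tree)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        votes = np.zeros((len(X), len(self.classes_)), dtype=int)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for (_, rotation), tree in zip(self.rotations_, self.trees_):
            pred = tree.predict(X @ rotation)
            for r, c in enumerate(pred):
                votes[r, class_index[c]] += 1
        return self.classes_[np.argmax(votes, axis=1)]


# ---------------------------------------------------------------------------
# Model factory

def make_classifier(spec: ModelSpec, seed: int | None = None):
    """Instantiate a fresh, seeded classifier for a spec."""
    seed = spec.seed if seed is None else seed
    h = spec.hyperparameters
    if spec.name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **h)
    if spec.name == "naive_bayes":
        return GaussianNB(**h)
    if spec.name == "bayes_net":
        return TanBayesClassifier(random_state=seed, **h)
    if spec.name == "neural_net":
        params = dict(hidden_layer_sizes=(10,), activation="logistic", max_iter=500)
        params.update(h)
        return MLPClassifier(random_state=seed, **params)
    if spec.name == "random_forest":
        params = dict(n_estimators=100)
        params.update(h)
        return RandomForestClassifier(random_state=seed, **params)
    if spec.name == "bagging_trees":
        params = dict(n_estimators=10)
        params.update(h)
        return BaggingClassifier(estimator=DecisionTreeClassifier(random_state=seed), random_state=seed, **params)
    if spec.name == "adaboost_trees":
        params = dict(n_estimators=50)
        params.update(h)
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, random_state=seed),
            random_state=seed, **params,
        )
    if spec.name == "rotation_forest":
        return RotationForestClassifier(random_state=seed, **h)
    raise ValueError(spec.name)  # pragma: no cover


def train_model(spec: ModelSpec, matrix: DesignMatrix):
    """Fit a classifier on the whole matrix; deterministic given the seed."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 rows")
    if len(np.unique(matrix.y)) < 2:
        raise ValueError("training set contains a single class")
    clf = make_classifier(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(matrix.X.to_numpy(), matrix.y)
    return clf


# ---------------------------------------------------------------------------
# Evaluation

def confidence_interval(accuracies: Sequence[float], level: float = 0.95) -> float:
    """t-based CI halfwidth: t_{(1+level)/2, n-1} * sd / sqrt(n), sample sd."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(np.std(acc, ddof=1))
    if sd == 0.0:
        return 0.0
    tcrit = float(sps.t.ppf((1 + level) / 2, acc.size - 1))
    return tcrit * sd / math.sqrt(acc.size)


def class_metrics(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """Per-class precision/recall/F; 0/0 ratios are not-available (NaN)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def _metrics(tp: int, fn: int, fp: int) -> dict[str, float]:
        precision = tp / (tp + fp) if tp + fp else NA
        recall = tp / (tp + fn) if tp + fn else NA
        if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
            f = NA
        else:
            f = 2 * precision * recall / (precision + recall)
        return {"precision": precision, "recall": recall, "f": f}

    return {
        "progress": _metrics(cm.tp, cm.fn, cm.fp),
        "no_progress": _metrics(cm.tn, cm.fp, cm.fn),
    }


def repeated_stratified_cv(
    spec: ModelSpec,
    matrix: DesignMatrix,
    folds: int = 10,
    repetitions: int = 10,
    seed: int = 0,
    normalize: bool = False,
    pca_threshold: float | None = None,
) -> CVResult:
    """Repeated stratified k-fold CV with fold-internal preprocessing.

    Normalization bounds and PCA rotations, when requested, are re-fit on
    each training fold and applied to its test fold — never fit on the full
    dataset. Per repetition the accuracy is pooled correct/total over all
    folds; the CI is over the R repetition accuracies.
    """
    X = matrix.X.to_numpy(dtype=float)
    y = matrix.y
    n = len(y)
    if n < folds:
        raise ValueError(f"dataset of {n} rows is smaller than {folds} folds")
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    if class_counts.min() < folds:
        warnings.warn(
            f"reducing folds from {folds} to {class_counts.min()} (smallest class)",
            stacklevel=2,
        )
        folds = int(class_counts.min())

    ss = np.random.SeedSequence(seed, spawn_key=(zlib.crc32(spec.name.encode()),))
    rep_seeds = ss.generate_state(repetitions)
    fit_seeds = ss.generate_state(repetitions * folds, dtype=np.uint32)

    accuracies: list[float] = []
    pooled = ConfusionMatrix()
    k = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(repetitions):
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rep_seeds[r] % (2**31)))
            correct = 0
            for train_idx, test_idx in skf.split(X, y):
                Xtr, Xte = X[train_idx], X[test_idx]
                if normalize:
                    cols = [str(i) for i in range(X.shape[1])]
                    tr_df = pd.DataFrame(Xtr, columns=cols)
                    bounds = fit_minmax_bounds(tr_df)
                    Xtr = apply_minmax(tr_df, bounds).to_numpy()
                    Xte = apply_minmax(pd.DataFrame(Xte, columns=cols), bounds).to_numpy()
                if pca_threshold is not None:
                    model = fit_pca(Xtr, pca_threshold)
                    Xtr = model.transform(Xtr)
                    Xte = model.transform(Xte)
                clf = make_classifier(spec, seed=int(fit_seeds[k]))
                k += 1
                clf.fit(Xtr, y[train_idx])
                pred = np.asarray(clf.predict(Xte))
                correct += int(np.sum(pred == y[test_idx]))
                pooled.add(y[test_idx], pred)
            accuracies.append(correct / n)

    mean_acc = float(np.mean(accuracies))
    ci = confidence_interval(accuracies) if repetitions >= 2 else 0.0
    return CVResult(
        accuracies=accuracies,
        mean_accuracy=mean_acc,
        ci_halfwidth=ci,
        metrics=class_metrics(pooled),
        confusion=pooled,
        spec=spec,
        dataset=f"{matrix.game_id}/{matrix.area}",
        folds=folds,
        repetitions=repetitions,
    )
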