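"""Optimizable ensemble classification with three cross-validation schemes.

Five ensemble families are supported: bagged trees, boosted trees,
random-undersampling boosted trees, random-subspace kNN and random-subspace
discriminant.  Bagging follows the bootstrap-aggregation scheme directly
(L bootstrap resamples of size M, one base estimator each, majority vote);
base estimators come from scikit-learn.  A random search over the family
and its hyper-parameters plays the role of the optimizable ensemble: the
best mean-CV-accuracy configuration is the meta-classifier.

Evaluation schemes: HOCV (stratified 80:20 holdout), FFCV (stratified
5-fold) and TFCV (stratified 10-fold), with pooled out-of-fold confusion
metrics per class (one-vs-rest recall, specificity, precision, F1) and
overall accuracy.  Iterative majority voting (IMV) repeats TFCV with fresh
fold seeds and reports the best overall and best fold-wise accuracy.

Note on the printed metric formulas: the source formulation swaps the
roles of true positives and true negatives in recall and specificity.  The
conventional definitions (recall = Tp/(Tp+Fn) on positives) are the
default; ``paper_eq11=True`` reproduces the swapped variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone as sk_clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .feature_bank import FeatureMatrix

METHODS = (
    "bagged_tree",
    "boosted_tree",
    "rus_boosted_tree",
    "subspace_knn",
    "subspace_discriminant",
)


@dataclass(frozen=True)
class LearnerSpec:
    """One ensemble configuration: family plus hyper-parameters.

    Recognised hyper-parameters: ``L`` (number of base learners),
    ``max_splits`` (tree split limit), ``learning_rate`` (boosting),
    ``subspace_dim`` (random-subspace width), ``n_neighbors`` (kNN).
    """

    method: str = "bagged_tree"
    L: int = 50
    max_splits: int | None = None
    learning_rate: float = 0.1
    subspace_dim: int | None = None
    n_neighbors: int = 5

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; known: {METHODS}")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning rate must be in (0, 1]")


@dataclass(frozen=True)
class CVScheme:
    kind: str = "kfold_10"
    stratified: bool = True
    seed: int = 0

    _FOLDS = {"kfold_5": 5, "kfold_10": 10}

    def __post_init__(self) -> None:
        if self.kind not in ("holdout_80_20", "kfold_5", "kfold_10"):
            raise ValueError(f"unknown CV scheme {self.kind!r}")

    @property
    def n_folds(self) -> int:
        return self._FOLDS.get(self.kind, 1)


# ---------------------------------------------------------------------------
# ensemble estimators


class VotingEnsembleBase:
    """Common majority-vote machinery (prediction from stored votes)."""

    classes_: np.ndarray
    estimators_: list
    feature_subsets_: list

    def _votes(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_classes) vote counts, optionally weighted."""
        X = np.asarray(X)
        votes = np.zeros((X.shape[0], self.classes_.size))
        weights = getattr(self, "weights_", None)
        for i, (est, cols) in enumerate(zip(self.estimators_, self.feature_subsets_)):
            pred = est.predict(X[:, cols] if cols is not None else X)
            idx = np.searchsorted(self.classes_, pred)
            w = 1.0 if weights is None else weights[i]
            votes[np.arange(X.shape[0]), idx] += w
        return votes

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self._votes(X), axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        """Vote fractions -- the scores used for ROC curves."""
        votes = self._votes(X)
        return votes / votes.sum(axis=1, keepdims=True)


class BaggedEnsemble(VotingEnsembleBase):
    """Bootstrap-aggregated (and/or random-subspace) majority-vote ensemble.

    With ``bootstrap=True`` each of the L base estimators is fit on a
    resample of size M drawn with replacement; a resample that collapses to
    a single class is redrawn (bounded retries).  With ``subspace_dim`` set,
    each estimator sees a random feature subset of that width.
    """

    def __init__(self, base, L: int = 50, bootstrap: bool = True,
                 subspace_dim: int | None = None, random_state: int = 0):
        self.base = base
        self.L = L
        self.bootstrap = bootstrap
        self.subspace_dim = subspace_dim
        self.random_state = random_state

    def clone(self) -> "BaggedEnsemble":
        return BaggedEnsemble(
            sk_clone(self.base), self.L, self.bootstrap,
            self.subspace_dim, self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        self.classes_ = np.unique(y)
        n, d = X.shape
        self.estimators_ = []
        self.feature_subsets_ = []
        for _ in range(self.L):
            if self.bootstrap:
                for _retry in range(10):
                    idx = rng.integers(0, n, size=n)
                    if np.unique(y[idx]).size > 1:
                        break
                else:
                    raise RuntimeError("could not draw a multi-class bootstrap sample")
            else:
                idx = np.arange(n)
            cols = None
            if self.subspace_dim is not None:
                cols = np.sort(
                    rng.choice(d, size=min(self.subspace_dim, d), replace=False)
                )
            est = sk_clone(self.base)
            if "random_state" in est.get_params():
                est.set_params(random_state=int(rng.integers(2**31 - 1)))
            est.fit(X[idx][:, cols] if cols is not None else X[idx], y[idx])
            self.estimators_.append(est)
            self.feature_subsets_.append(cols)
        return self


class RUSBoost(VotingEnsembleBase):
    """Boosting with per-round random undersampling of majority classes.

    Each round draws, within every class, ``min-class-count`` samples
    (weighted by the current boosting distribution), fits a tree on the
    balanced subset, and applies the usual multiclass (SAMME) weight and
    vote-weight updates on the full training set.
    """

    def __init__(self, L: int = 50, learning_rate: float = 0.1,
                 max_splits: int | None = None, random_state: int = 0):
        self.L = L
        self.learning_rate = learning_rate
        self.max_splits = max_splits
        self.random_state = random_state

    def clone(self) -> "RUSBoost":
        return RUSBoost(self.L, self.learning_rate, self.max_splits,
                        self.random_state)

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        self.classes_ = np.unique(y)
        K = self.classes_.size
        n = y.size
        w = np.full(n, 1.0 / n)
        min_count = np.min([np.sum(y == c) for c in self.classes_])
        self.estimators_ = []
        self.feature_subsets_ = []
        self.weights_ = []
        for _ in range(self.L):
            idx_parts = []
            for c in self.classes_:
                members = np.flatnonzero(y == c)
                p = w[members] / w[members].sum()
                take = min(min_count, members.size)
                idx_parts.append(rng.choice(members, size=take, replace=False, p=p))
            idx = np.concatenate(idx_parts)
            tree = DecisionTreeClassifier(
                max_leaf_nodes=None if self.max_splits is None else self.max_splits + 1,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            pred = tree.predict(X)
            miss = pred != y
            err = float(np.sum(w[miss]))
            if err >= 1.0 - 1.0 / K:
                continue  # worse than chance on this round; drop it
            err = max(err, 1e-10)
            alpha = self.learning_rate * (np.log((1 - err) / err) + np.log(K - 1))
            w *= np.exp(alpha * miss)
            w /= w.sum()
            self.estimators_.append(tree)
            self.feature_subsets_.append(None)
            self.weights_.append(alpha)
        if not self.estimators_:  # all rounds rejected: fall back to one tree
            tree = DecisionTreeClassifier(random_state=self.random_state)
            tree.fit(X, y)
            self.estimators_ = [tree]
            self.feature_subsets_ = [None]
            self.weights_ = [1.0]
        return self


def build_learner(spec: LearnerSpec, seed: int = 0):
    """Instantiate the (unfitted) model a LearnerSpec describes."""
    leaf = None if spec.max_splits is None else spec.max_splits + 1
    if spec.method == "bagged_tree":
        return BaggedEnsemble(
            DecisionTreeClassifier(max_leaf_nodes=leaf), spec.L, random_state=seed
        )
    if spec.method == "boosted_tree":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_leaf_nodes=leaf if leaf is not None else 8
            ),
            n_estimators=spec.L,
            learning_rate=spec.learning_rate,
            random_state=seed,
        )
    if spec.method == "rus_boosted_tree":
        return RUSBoost(spec.L, spec.learning_rate, spec.max_splits, random_state=seed)
    if spec.method == "subspace_knn":
        return BaggedEnsemble(
            KNeighborsClassifier(n_neighbors=spec.n_neighbors),
            spec.L,
            bootstrap=False,
            subspace_dim=spec.subspace_dim or 1,
            random_state=seed,
        )
    if spec.method == "subspace_discriminant":
        return BaggedEnsemble(
            LinearDiscriminantAnalysis(),
            spec.L,
            bootstrap=False,
            subspace_dim=spec.subspace_dim or 1,
            random_state=seed,
        )
    raise ValueError(spec.method)


def _clone_model(model):
    return model.clone() if hasattr(model, "clone") else sk_clone(model)


def bagging_fit(data: FeatureMatrix, base, L: int, seed: int = 0) -> BaggedEnsemble:
    """Fit a bagged majority-vote ensemble of ``base`` on a FeatureMatrix."""
    if np.unique(data.labels).size < 2:
        raise ValueError("bagging needs at least two classes")
    model = BaggedEnsemble(base, L=L, random_state=seed)
    return model.fit(data.values, data.labels)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class MetricsReport:
    """Pooled out-of-fold metrics for one evaluation run."""

    accuracy: float
    per_class: pd.DataFrame  # recall, specificity, precision, f1, tp/tn/fp/fn
    confusion: pd.DataFrame  # true class x predicted class counts
    fold_accuracies: list[float] = field(default_factory=list)

    def to_json(self, path) -> None:
        import json

        payload = {
            "accuracy": self.accuracy,
            "fold_accuracies": self.fold_accuracies,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.to_dict(orient="index"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _split_indices(y: np.ndarray, cv: CVScheme):
    if cv.kind == "holdout_80_20":
        tr, te = train_test_split(
            np.arange(y.size),
            test_size=0.2,
            random_state=cv.seed,
            stratify=y if cv.stratified else None,
        )
        return [(tr, te)]
    splitter = (StratifiedKFold if cv.stratified else KFold)(
        n_splits=cv.n_folds, shuffle=True, random_state=cv.seed
    )
    return list(splitter.split(np.zeros(y.size), y))


def metrics_from_confusion(
    confusion: np.ndarray, classes, paper_eq11: bool = False
) -> pd.DataFrame:
    """One-vs-rest recall/specificity/precision/F1 per class."""
    total = confusion.sum()
    rows = {}
    for i, c in enumerate(classes):
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = total - tp - fn - fp
        if paper_eq11:
            recall = tn / (fp + tn) if fp + tn else 0.0
            spe = tp / (fn + tp) if fn + tp else 0.0
        else:
            recall = tp / (tp + fn) if tp + fn else 0.0
            spe = tn / (tn + fp) if tn + fp else 0.0
        ppv = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * recall * ppv / (recall + ppv) if recall + ppv else 0.0
        rows[c] = {
            "recall": recall, "specificity": spe, "precision": ppv, "f1": f1,
            "tp": int(tp), "tn": int(tn), "fp": int(fp), "fn": int(fn),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def evaluate(
    model, data: FeatureMatrix, cv: CVScheme, paper_eq11: bool = False
) -> MetricsReport:
    """Train/test under a CV scheme and pool out-of-fold predictions."""
    X, y = data.values, data.labels
    classes = np.unique(y)
    pooled = np.zeros((classes.size, classes.size), dtype=int)
    fold_acc = []
    for f, (tr, te) in enumerate(_split_indices(y, cv)):
        if np.unique(y[tr]).size < classes.size:
            raise ValueError(
                "a training fold is missing a class; use a stratified scheme"
            )
        m = _clone_model(model)
        if hasattr(m, "random_state"):
            m.random_state = cv.seed * 1009 + f
        m.fit(X[tr], y[tr])
        pred = m.predict(X[te])
        ti = np.searchsorted(classes, y[te])
        pi = np.searchsorted(classes, pred)
        np.add.at(pooled, (ti, pi), 1)
        fold_acc.append(float(np.mean(pred == y[te])))
    accuracy = float(np.trace(pooled) / pooled.sum())
    return MetricsReport(
        accuracy=accuracy,
        per_class=metrics_from_confusion(pooled, classes, paper_eq11),
        confusion=pd.DataFrame(pooled, index=classes, columns=classes),
        fold_accuracies=fold_acc,
    )


# ---------------------------------------------------------------------------
# hyper-parameter search


@dataclass
class OptimizeResult:
    best_spec: LearnerSpec
    best_score: float
    model: object  # best configuration fitted on the full data
    history: pd.DataFrame  # one row per candidate: spec fields + cv accuracy


def sample_spec(rng: np.random.Generator, n_samples: int, n_features: int) -> LearnerSpec:
    """Draw one random configuration from the search space."""
    method = METHODS[rng.integers(len(METHODS))]
    log_u = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return LearnerSpec(
        method=method,
        L=int(round(log_u(10, 500))),
        max_splits=int(round(log_u(1, max(2, n_samples - 1)))),
        learning_rate=min(1.0, log_u(1e-3, 1.0)),
        subspace_dim=int(rng.integers(1, max(2, n_features // 2) + 1)),
        n_neighbors=int(rng.integers(1, 21)),
    )


def optimize_ensemble(
    data: FeatureMatrix, budget: int, cv: CVScheme, seed: int = 0
) -> OptimizeResult:
    """Random search over the five ensemble families; argmax CV accuracy."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    best = None
    for i in range(budget):
        spec = sample_spec(rng, data.n_segments, data.n_columns)
        model = build_learner(spec, seed=seed * 10007 + i)
        try:
            score = evaluate(model, data, cv).accuracy
        except Exception:  # an unusable candidate costs budget, not the run
            score = np.nan
        rows.append({"candidate": i, **spec.__dict__, "cv_accuracy": score})
        if np.isfinite(score) and (best is None or score > best[1]):
            best = (spec, score)
    if best is None:
        raise RuntimeError("every candidate in the search budget failed to fit")
    final = build_learner(best[0], seed=seed)
    final.fit(data.values, data.labels)
    return OptimizeResult(best[0], best[1], final, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# iterative majority voting


@dataclass
class IMVResult:
    round_accuracies: list[float]
    fold_accuracies: list[list[float]]  # rounds x folds
    best_round: int
    best_overall: float
    best_foldwise: float


def imv_tfcv(
    data: FeatureMatrix, model, rounds: int = 10, base_seed: int = 0,
    paper_eq11: bool = False,
) -> IMVResult:
    """Repeated ten-fold CV; keep the best overall and fold-wise accuracy."""
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    overall, per_fold = [], []
    for r in range(rounds):
        rep = evaluate(
            model, data, CVScheme("kfold_10", seed=base_seed + r), paper_eq11
        )
        overall.append(rep.accuracy)
        per_fold.append(rep.fold_accuracies)
    best_round = int(np.argmax(overall))
    return IMVResult(
        round_accuracies=overall,
        fold_accuracies=per_fold,
        best_round=best_round,
        best_overall=float(np.max(overall)),
        best_foldwise=float(np.max([a for fold in per_fold for a in fold])),
    )
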