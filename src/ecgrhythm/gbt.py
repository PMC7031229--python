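"""K-class gradient boosting with regression trees, written from scratch.

The model is an additive ensemble: per boosting iteration m and class k a
least-squares regression tree is fit to the residuals

    r_ikm = y_ik - p_k(x_i),

the negative gradient of the multinomial deviance under the softmax link

    p_k(x) = exp(f_k(x)) / sum_l exp(f_l(x)).

Each terminal region j receives the one-step multiclass leaf value

    gamma_jkm = (K-1)/K * sum(r_ikm) / sum(|r_ikm| (1 - |r_ikm|)),

guarded to 0 when the denominator vanishes (pure leaves), and the class
score is updated by a shrunken tree contribution

    f_km(x) = f_{k,m-1}(x) + learning_rate * sum_j gamma_jkm I(x in R_jkm).

Trees use exact greedy least-squares splitting with midpoint thresholds
(ties broken toward the lowest feature index), optional per-split feature
subsampling and per-iteration row subsampling without replacement; all
randomness flows from one seed, so fits are reproducible tree by tree.
Scores start at the constant model f_k0 = 0 (an optional class-log-prior
start is provided).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

_LEAF_EPS = 1e-12


def _softmax(F: np.ndarray) -> np.ndarray:
    Z = F - F.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def multinomial_deviance(Y: np.ndarray, F: np.ndarray) -> float:
    """Mean negative log-likelihood of one-hot targets under softmax(F)."""
    P = _softmax(F)
    return float(-np.mean(np.sum(Y * np.log(np.clip(P, 1e-300, None)),
                                 axis=1)))


@dataclass
class RegressionTree:
    """A binary least-squares regression tree stored as flat node arrays.

    ``feature[i] == -1`` marks a leaf; ``value`` holds the leaf constants
    (gamma after the multiclass leaf update).
    """

    max_depth: int = 3
    min_samples_leaf: int = 1
    max_features: int | None = None   # features sampled per split

    feature: list[int] = field(default_factory=list)
    threshold: list[float] = field(default_factory=list)
    left: list[int] = field(default_factory=list)
    right: list[int] = field(default_factory=list)
    value: list[float] = field(default_factory=list)

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(0.0)
        return len(self.feature) - 1

    def _best_split(self, X: np.ndarray, r: np.ndarray,
                    rng: np.random.Generator) -> tuple[int, float] | None:
        n, p = X.shape
        if n < 2 * self.min_samples_leaf:
            return None
        if self.max_features is not None and self.max_features < p:
            feats = np.sort(rng.choice(p, self.max_features, replace=False))
        else:
            feats = np.arange(p)
        Xs = X[:, feats]
        order = np.argsort(Xs, axis=0, kind="stable")
        xs = np.take_along_axis(Xs, order, axis=0)
        rs = r[order]                                    # (n, f)
        csum = np.cumsum(rs, axis=0)
        total = csum[-1]
        nl = np.arange(1, n, dtype=float)[:, None]
        sl = csum[:-1]
        # SSE reduction ∝ sum_l^2/n_l + sum_r^2/n_r (parent term constant)
        score = sl ** 2 / nl + (total - sl) ** 2 / (n - nl)
        valid = xs[1:] > xs[:-1]
        if self.min_samples_leaf > 1:
            k = self.min_samples_leaf
            valid[:k - 1] = False
            if k > 1:
                valid[-(k - 1):] = False
        score = np.where(valid, score, -np.inf)
        # feature-major flattening → argmax ties resolve to lowest feature
        flat = np.argmax(score.T)
        if not np.isfinite(score.T.flat[flat]):
            return None
        f_local, s = divmod(flat, n - 1)
        thr = 0.5 * (xs[s, f_local] + xs[s + 1, f_local])
        return int(feats[f_local]), float(thr)

    def fit(self, X: np.ndarray, r: np.ndarray,
            rng: np.random.Generator) -> dict[int, np.ndarray]:
        """Grow the tree on residuals ``r``; returns leaf -> row indices."""
        X = np.asarray(X, float)
        r = np.asarray(r, float)
        leaves: dict[int, np.ndarray] = {}
        root = self._new_node()
        stack = [(root, np.arange(X.shape[0]), 0)]
        while stack:
            node, rows, depth = stack.pop()
            rn = r[rows]
            split = None
            if depth < self.max_depth and rows.size >= 2 and np.ptp(rn) > 0:
                split = self._best_split(X[rows], rn, rng)
            if split is None:
                self.value[node] = float(np.mean(rn))
                leaves[node] = rows
                continue
            f, thr = split
            go_left = X[rows, f] <= thr
            self.feature[node] = f
            self.threshold[node] = thr
            ln, rnode = self._new_node(), self._new_node()
            self.left[node], self.right[node] = ln, rnode
            stack.append((rnode, rows[~go_left], depth + 1))
            stack.append((ln, rows[go_left], depth + 1))
        return leaves

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        out = np.empty(X.shape[0])
        feature = np.asarray(self.feature)
        for i, x in enumerate(X):
            node = 0
            while feature[node] != -1:
                node = (self.left[node] if x[feature[node]]
                        <= self.threshold[node] else self.right[node])
            out[i] = self.value[node]
        return out

    def to_dict(self) -> dict:
        return {"max_depth": self.max_depth,
                "min_samples_leaf": self.min_samples_leaf,
                "feature": list(map(int, self.feature)),
                "threshold": list(map(float, self.threshold)),
                "left": list(map(int, self.left)),
                "right": list(map(int, self.right)),
                "value": list(map(float, self.value))}

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        t = cls(max_depth=d["max_depth"],
                min_samples_leaf=d["min_samples_leaf"])
        t.feature = list(d["feature"])
        t.threshold = list(d["threshold"])
        t.left = list(d["left"])
        t.right = list(d["right"])
        t.value = list(d["value"])
        return t


def leaf_value(residuals: np.ndarray, K: int) -> float:
    """Multiclass one-step leaf constant with a vanishing-denominator guard."""
    r = np.asarray(residuals, float)
    denom = float(np.sum(np.abs(r) * (1.0 - np.abs(r))))
    if denom < _LEAF_EPS:
        return 0.0
    return (K - 1) / K * float(np.sum(r)) / denom


@dataclass
class BoostedForest:
    """Fitted K-class boosted tree ensemble (M iterations x K trees)."""

    K: int
    M: int
    learning_rate: float
    subsample: float
    classes: np.ndarray
    f0: np.ndarray
    trees: list[list[RegressionTree]]   # trees[m][k]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        F = np.tile(self.f0, (X.shape[0], 1))
        for per_class in self.trees:
            for k, tree in enumerate(per_class):
                F[:, k] += self.learning_rate * tree.predict(X)
        return F

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {"K": self.K, "M": self.M,
               "learning_rate": self.learning_rate,
               "subsample": self.subsample,
               "classes": [c.item() if hasattr(c, "item") else c
                           for c in self.classes],
               "f0": list(map(float, self.f0)),
               "trees": [[t.to_dict() for t in row] for row in self.trees]}
        path.write_text(json.dumps(doc))
        return path

    @classmethod
    def load_json(cls, path: str | Path) -> "BoostedForest":
        d = json.loads(Path(path).read_text())
        return cls(K=d["K"], M=d["M"], learning_rate=d["learning_rate"],
                   subsample=d["subsample"], classes=np.asarray(d["classes"]),
                   f0=np.asarray(d["f0"], float),
                   trees=[[RegressionTree.from_dict(t) for t in row]
                          for row in d["trees"]])


def _resolve_max_features(max_features, p: int) -> int | None:
    if max_features in (None, "none", "None"):
        return None
    if max_features in ("auto", "sqrt"):
        return max(1, int(np.sqrt(p)))
    if max_features == "log2":
        return max(1, int(np.log2(p)))
    if isinstance(max_features, float):
        return max(1, int(max_features * p))
    return int(max_features)


def fit_gbt(X: np.ndarray, y: np.ndarray, n_estimators: int = 100,
            learning_rate: float = 0.1, subsample: float = 1.0,
            max_depth: int = 3, min_samples_leaf: int = 1,
            max_features=None, seed: int = 0,
            init: str = "zero") -> BoostedForest:
    """Fit the K-class boosted tree ensemble.

    ``subsample`` < 1 draws that fraction of rows without replacement for
    every (iteration, class) tree from a seeded stream.  ``init`` is the
    constant start: "zero" (uniform prior) or "prior" (class log-priors).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    classes, y_idx = np.unique(y, return_inverse=True)
    K = classes.size
    if K < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    n, p = X.shape
    if n < K:
        raise ValueError("need at least K observations")
    Y = np.zeros((n, K))
    Y[np.arange(n), y_idx] = 1.0

    if init == "prior":
        f0 = np.log(np.clip(Y.mean(axis=0), 1e-12, None))
        f0 = f0 - f0.mean()
    else:
        f0 = np.zeros(K)
    F = np.tile(f0, (n, 1))
    rng = np.random.default_rng(seed)
    mf = _resolve_max_features(max_features, p)

    trees: list[list[RegressionTree]] = []
    n_sub = max(2, int(round(subsample * n))) if subsample < 1 else n
    for m in range(n_estimators):
        P = _softmax(F)
        R = Y - P
        per_class: list[RegressionTree] = []
        for k in range(K):
            rows = (rng.choice(n, n_sub, replace=False)
                    if n_sub < n else np.arange(n))
            tree = RegressionTree(max_depth=max_depth,
                                  min_samples_leaf=min_samples_leaf,
                                  max_features=mf)
            leaves = tree.fit(X[rows], R[rows, k], rng)
            for node, leaf_rows in leaves.items():
                tree.value[node] = leaf_value(R[rows[leaf_rows], k], K)
            F[:, k] += learning_rate * tree.predict(X)
            per_class.append(tree)
        trees.append(per_class)
    return BoostedForest(K=K, M=n_estimators, learning_rate=learning_rate,
                         subsample=subsample, classes=classes, f0=f0,
                         trees=trees)


def predict_proba(model: BoostedForest, X: np.ndarray) -> np.ndarray:
    """Softmax class probabilities; rows sum to 1."""
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    return _softmax(model.decision_function(X))


def predict(model: BoostedForest, X: np.ndarray) -> np.ndarray:
    """Most probable class per row; ties go to the lowest class index."""
    return model.classes[np.argmax(predict_proba(model, X), axis=1)]


class PaperGBTClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn-compatible wrapper around :func:`fit_gbt`.

    Lets the home-grown booster plug into the model registry, the
    ensemble/multiclass strategy wrappers and cross-validation.
    """

    def __init__(self, n_estimators: int = 100, learning_rate: float = 0.1,
                 subsample: float = 1.0, max_depth: int = 3,
                 min_samples_leaf: int = 1, max_features=None,
                 random_state: int = 0, init: str = "zero"):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.random_state = random_state
        self.init = init

    def fit(self, X, y) -> "PaperGBTClassifier":
        self.model_ = fit_gbt(
            X, y, n_estimators=self.n_estimators,
            learning_rate=self.learning_rate, subsample=self.subsample,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features, seed=self.random_state,
            init=self.init)
        self.classes_ = self.model_.classes
        return self

    def predict_proba(self, X) -> np.ndarray:
        return predict_proba(self.model_, X)

    def predict(self, X) -> np.ndarray:
        return predict(self.model_, X)
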