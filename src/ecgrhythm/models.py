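"""Classifier registry, evaluation metrics, cross-validation, grid search.

The registry exposes the nineteen base algorithms of the comparison study
under their acronyms (DT, KNN, NC, GNB, MNB, CNB, BNB, LC, QDA, MLR, MPN,
RRC, LCSGD, PAC, SVC, RF, ERT, GBT, EGBT), each delegating to an
established scikit-learn or xgboost estimator, plus ``paper_gbt`` — the
home-grown K-class booster from :mod:`ecgrhythm.gbt`.  Any base algorithm
can be composed with an ensemble or multiclass-decomposition strategy
(bagging, AdaBoost, one-vs-rest, one-vs-one, error-correcting output
codes).

Evaluation follows the study protocol: per-class F1

    F1_j = 2 * precision_j * recall_j / (precision_j + recall_j)

aggregated as the support-weighted average

    weighted F1 = sum_j F1_j * N_j / sum_j N_j

with N_j the true-class supports; model selection maximises the mean
weighted F1 over 10 stratified 80/20 shuffle splits.  (A classical k-fold
mode is available; the shuffle-split protocol matches the stated 80/20
train/test fractions.)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

STRATEGIES = ("none", "bagging", "adaboost", "one_vs_rest", "one_vs_one",
              "ecoc")


class CapabilityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# registry

def _make_base(algorithm: str, params: dict, seed: int):
    """Instantiate a base estimator by acronym with translated options."""
    from sklearn.discriminant_analysis import (
        LinearDiscriminantAnalysis, QuadraticDiscriminantAnalysis)
    from sklearn.ensemble import (ExtraTreesClassifier,
                                  GradientBoostingClassifier,
                                  RandomForestClassifier)
    from sklearn.linear_model import (LogisticRegression,
                                      PassiveAggressiveClassifier,
                                      RidgeClassifier, SGDClassifier)
    from sklearn.naive_bayes import (BernoulliNB, ComplementNB, GaussianNB,
                                     MultinomialNB)
    from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import LinearSVC
    from sklearn.tree import DecisionTreeClassifier
    from xgboost import XGBClassifier

    from .gbt import PaperGBTClassifier

    p = dict(params)
    # translate option spellings that newer library versions renamed
    if p.get("max_features") == "auto":
        p["max_features"] = "sqrt"
    if algorithm == "GBT" and p.get("loss") == "deviance":
        p["loss"] = "log_loss"
    if algorithm == "LCSGD" and p.get("loss") == "log":
        p["loss"] = "log_loss"

    seeded = {"random_state": seed}
    factories = {
        "DT": lambda: DecisionTreeClassifier(**p, **seeded),
        "KNN": lambda: KNeighborsClassifier(**p),
        "NC": lambda: NearestCentroid(**p),
        "GNB": lambda: GaussianNB(**p),
        "MNB": lambda: MultinomialNB(**p),
        "CNB": lambda: ComplementNB(**p),
        "BNB": lambda: BernoulliNB(**p),
        "LC": lambda: LinearDiscriminantAnalysis(**p),
        "QDA": lambda: QuadraticDiscriminantAnalysis(**p),
        "MLR": lambda: LogisticRegression(max_iter=1000, **p, **seeded),
        "MPN": lambda: MLPClassifier(max_iter=500, **p, **seeded),
        "RRC": lambda: RidgeClassifier(**p, **seeded),
        "LCSGD": lambda: SGDClassifier(**p, **seeded),
        "PAC": lambda: PassiveAggressiveClassifier(**p, **seeded),
        "SVC": lambda: LinearSVC(**p, **seeded),
        "RF": lambda: RandomForestClassifier(**p, **seeded),
        "ERT": lambda: ExtraTreesClassifier(**p, **seeded),
        "GBT": lambda: GradientBoostingClassifier(**p, **seeded),
        "EGBT": lambda: XGBClassifier(
            use_label_encoder=False, eval_metric="mlogloss", **p, **seeded),
        "paper_gbt": lambda: PaperGBTClassifier(**p, **seeded),
    }
    if algorithm not in factories:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; valid: {sorted(factories)}")
    return factories[algorithm]()


ALGORITHM_NAMES = ("DT", "KNN", "NC", "GNB", "MNB", "CNB", "BNB", "LC",
                   "QDA", "MLR", "MPN", "RRC", "LCSGD", "PAC", "SVC", "RF",
                   "ERT", "GBT", "EGBT", "paper_gbt")


def default_grids() -> dict[str, dict[str, list]]:
    """The shipped hyperparameter grids (one block per algorithm)."""
    with resources.files("ecgrhythm").joinpath("grids.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class ModelSpec:
    """One configuration of the comparison study.

    ``params`` are fixed hyperparameters; ``grid`` maps hyperparameter names
    to candidate value lists for :func:`grid_search`; ``strategy`` optionally
    wraps the base estimator.
    """

    algorithm: str
    params: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    strategy: str = "none"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHM_NAMES:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")


def make_strategy(base, strategy: str, seed: int = 0):
    """Wrap a fitted-API estimator in an ensemble/multiclass strategy."""
    if strategy == "none":
        return base
    from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
    from sklearn.multiclass import (OneVsOneClassifier, OneVsRestClassifier,
                                    OutputCodeClassifier)
    if strategy == "bagging":
        return BaggingClassifier(estimator=base, n_estimators=10,
                                 random_state=seed)
    if strategy == "adaboost":
        if not hasattr(base, "predict_proba"):
            raise CapabilityError(
                "adaboost requires a probabilistic base estimator")
        return AdaBoostClassifier(estimator=base, random_state=seed)
    if strategy == "one_vs_rest":
        return OneVsRestClassifier(base)
    if strategy == "one_vs_one":
        return OneVsOneClassifier(base)
    if strategy == "ecoc":
        return OutputCodeClassifier(base, code_size=2.0, random_state=seed)
    raise ValueError(f"unknown strategy {strategy!r}")


def make_estimator(spec: ModelSpec, seed: int = 0,
                   params: dict | None = None):
    base = _make_base(spec.algorithm,
                      params if params is not None else spec.params, seed)
    return make_strategy(base, spec.strategy, seed=seed)


# ---------------------------------------------------------------------------
# metrics

@dataclass
class EvaluationReport:
    """Confusion matrix and per-class / averaged precision, recall, F1."""

    labels: list
    confusion_matrix: np.ndarray            # rows true, cols predicted
    per_class: pd.DataFrame                 # precision, recall, f1, support
    macro_f1: float
    micro_f1: float
    weighted_f1: float

    @property
    def normalized_confusion(self) -> np.ndarray:
        row_sums = self.confusion_matrix.sum(axis=1, keepdims=True)
        out = np.zeros_like(self.confusion_matrix, dtype=float)
        np.divide(self.confusion_matrix, row_sums, out=out,
                  where=row_sums > 0)
        return out


def f1_report(y_true, y_pred, labels: list | None = None) -> EvaluationReport:
    """Precision/recall/F1 per class plus macro, micro and weighted averages.

    F1 is 0 when its denominator vanishes; the weighted average uses
    true-class supports N_j, so classes absent from ``y_true`` carry no
    weight; micro-F1 equals global accuracy for single-label problems.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if labels is None:
        labels = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    index = {lab: i for i, lab in enumerate(labels)}
    K = len(labels)
    cm = np.zeros((K, K), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1

    tp = np.diag(cm).astype(float)
    support = cm.sum(axis=1).astype(float)      # N_j
    predicted = cm.sum(axis=0).astype(float)
    precision = np.divide(tp, predicted, out=np.zeros(K),
                          where=predicted > 0)
    recall = np.divide(tp, support, out=np.zeros(K), where=support > 0)
    pr_sum = precision + recall
    f1 = np.divide(2 * precision * recall, pr_sum, out=np.zeros(K),
                   where=pr_sum > 0)

    weighted = float(np.sum(f1 * support) / np.sum(support))
    macro = float(np.mean(f1))
    micro = float(tp.sum() / cm.sum())
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1,
         "support": support.astype(int)}, index=labels)
    return EvaluationReport(labels=list(labels), confusion_matrix=cm,
                            per_class=per_class, macro_f1=macro,
                            micro_f1=micro, weighted_f1=weighted)


# ---------------------------------------------------------------------------
# cross-validation and grid search

@dataclass
class CVResult:
    fold_reports: list[EvaluationReport]
    mean_weighted_f1: float
    mean_macro_f1: float
    mean_micro_f1: float

    @property
    def fold_weighted_f1(self) -> list[float]:
        return [r.weighted_f1 for r in self.fold_reports]


def cross_validate(X, y, spec: ModelSpec | None = None, estimator=None,
                   n_splits: int = 10, test_fraction: float = 0.2,
                   seed: int = 0, mode: str = "shuffle",
                   params: dict | None = None) -> CVResult:
    """Stratified seeded cross-validation returning per-fold F1 reports.

    ``mode="shuffle"`` (default) draws ``n_splits`` stratified shuffle
    splits at the given test fraction; ``mode="kfold"`` runs classical
    stratified k-fold instead.
    """
    from sklearn.base import clone
    from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

    X = np.asarray(X, float)
    y = np.asarray(y)
    labels = sorted(np.unique(y).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    if mode == "shuffle":
        splitter = StratifiedShuffleSplit(
            n_splits=n_splits, test_size=test_fraction, random_state=seed)
    elif mode == "kfold":
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                   random_state=seed)
    else:
        raise ValueError("mode must be 'shuffle' or 'kfold'")

    reports = []
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        if spec is not None:
            est = make_estimator(spec, seed=seed + fold, params=params)
        else:
            est = clone(estimator)
        est.fit(X[tr], y[tr])
        reports.append(f1_report(y[te], est.predict(X[te]), labels=labels))
    return CVResult(
        fold_reports=reports,
        mean_weighted_f1=float(np.mean([r.weighted_f1 for r in reports])),
        mean_macro_f1=float(np.mean([r.macro_f1 for r in reports])),
        mean_micro_f1=float(np.mean([r.micro_f1 for r in reports])))


def grid_search(X, y, spec: ModelSpec, seed: int = 0, n_splits: int = 10,
                test_fraction: float = 0.2,
                ) -> tuple[dict, float, pd.DataFrame]:
    """Exhaustive grid search scored by mean weighted F1 over CV splits.

    Enumeration order is the deterministic Cartesian product of the grid in
    its declared key order; ties keep the first configuration.  Returns
    (best params, best score, full results table).
    """
    if not spec.grid:
        raise ValueError("empty hyperparameter grid")
    # validate names before any fit
    probe = _make_base(spec.algorithm, {}, seed)
    if hasattr(probe, "get_params"):
        valid = set(probe.get_params())
        bad = set(spec.grid) - valid
        if bad:
            raise ValueError(
                f"invalid hyperparameters for {spec.algorithm}: {sorted(bad)}")

    keys = list(spec.grid)
    rows = []
    best_params: dict = {}
    best_score = -np.inf
    for combo in itertools.product(*(spec.grid[k] for k in keys)):
        params = {**spec.params, **dict(zip(keys, combo))}
        cv = cross_validate(X, y, spec=spec, n_splits=n_splits,
                            test_fraction=test_fraction, seed=seed,
                            params=params)
        rows.append({**{f"param_{k}": v for k, v in zip(keys, combo)},
                     "mean_weighted_f1": cv.mean_weighted_f1,
                     "mean_macro_f1": cv.mean_macro_f1})
        if cv.mean_weighted_f1 > best_score:
            best_score = cv.mean_weighted_f1
            best_params = dict(zip(keys, combo))
    return best_params, float(best_score), pd.DataFrame(rows)
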