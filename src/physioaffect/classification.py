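"""Subgroup-specific affect classification with wrapper feature selection.

Subjects are split by gender and an age cutoff into nine (overlapping)
subgroups.  Within a subgroup, an RBF-kernel SVM is evaluated under
leave-one-subject-out (LOSO) cross-validation: for every outer fold, feature
scaling is fit on the training subjects only, a wrapper feature-selection
pass (sequential forward selection or backward elimination, scored by an
inner subject-wise cross-validation on the training subjects) picks the
feature subset, the SVM is refit on that subset, and the held-out subject's
rows are predicted.  Both selection methods are run and the higher LOSO
accuracy is reported.

Three task families are supported: three-class valence (neutral / positive
/ negative), five-class core affect, and neutral-vs-one-condition binaries.
Class imbalance (valence3 pools two conditions per pole) is handled with
inverse-frequency class weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import config_context as sklearn_config_context
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConfigurationError, InsufficientDataError
from .features import FEATURE_NAMES, SIGNAL_GROUPS
from .screening import profiles_frame
from .synth import CONDITIONS

SUBGROUP_NAMES = (
    "all",
    "young_all",
    "young_female",
    "young_male",
    "elderly_all",
    "elderly_female",
    "elderly_male",
    "female",
    "male",
)


@dataclass(frozen=True)
class Subgroup:
    name: str
    subject_ids: tuple


@dataclass(frozen=True)
class TaskSpec:
    """Mapping from induction conditions to classification labels."""

    name: str
    classes: dict  # condition -> class label

    def validate(self) -> None:
        unknown = [c for c in self.classes if c not in CONDITIONS]
        if unknown:
            raise ConfigurationError(f"task {self.name}: unknown conditions {unknown}")
        if len(set(self.classes.values())) < 2:
            raise ConfigurationError(f"task {self.name} needs >= 2 classes")

    @property
    def n_classes(self) -> int:
        return len(set(self.classes.values()))

    @property
    def chance_level(self) -> float:
        """Uniform-prediction chance accuracy in percent."""
        return 100.0 / self.n_classes


def valence3_task() -> TaskSpec:
    return TaskSpec(
        "valence3",
        {
            "neutral": "neutral",
            "HVHA": "positive",
            "HVLA": "positive",
            "LVHA": "negative",
            "LVLA": "negative",
        },
    )


def affect5_task() -> TaskSpec:
    return TaskSpec("affect5", {c: c for c in CONDITIONS})


def binary_task(condition: str) -> TaskSpec:
    if condition not in CONDITIONS or condition == "neutral":
        raise ConfigurationError(f"binary task needs a non-neutral condition, got {condition!r}")
    return TaskSpec(f"neutral_vs_{condition}", {"neutral": "neutral", condition: condition})


TASK_FACTORIES = {
    "valence3": valence3_task,
    "affect5": affect5_task,
    "neutral_vs_HVHA": lambda: binary_task("HVHA"),
    "neutral_vs_HVLA": lambda: binary_task("HVLA"),
    "neutral_vs_LVHA": lambda: binary_task("LVHA"),
    "neutral_vs_LVLA": lambda: binary_task("LVLA"),
}


def split_subgroups(profiles, age_cutoff: float = 45.0) -> list[Subgroup]:
    """The nine gender x age subgroups (age < cutoff -> young, else elderly)."""
    if isinstance(profiles, list):
        profiles = profiles_frame(profiles)
    if len(profiles) == 0:
        raise InsufficientDataError("no subject profiles to split")
    young = profiles["age"] < age_cutoff
    female = profiles["gender"] == "female"
    masks = {
        "all": np.ones(len(profiles), dtype=bool),
        "young_all": young.to_numpy(),
        "young_female": (young & female).to_numpy(),
        "young_male": (young & ~female).to_numpy(),
        "elderly_all": (~young).to_numpy(),
        "elderly_female": (~young & female).to_numpy(),
        "elderly_male": (~young & ~female).to_numpy(),
        "female": female.to_numpy(),
        "male": (~female).to_numpy(),
    }
    subgroups = []
    for name in SUBGROUP_NAMES:
        ids = tuple(profiles.loc[masks[name], "subject_id"])
        if not ids:
            warnings.warn(f"subgroup {name!r} is empty and will be skipped downstream", UserWarning)
        subgroups.append(Subgroup(name, ids))
    return subgroups


def loso_folds(subject_ids) -> list[tuple[list, object]]:
    """Leave-one-subject-out folds: one (train_ids, test_id) per subject."""
    ids = list(dict.fromkeys(subject_ids))
    if len(ids) < 2:
        raise InsufficientDataError("leave-one-subject-out needs >= 2 subjects")
    return [([s for s in ids if s != test], test) for test in ids]


# ---------------------------------------------------------------------------
# wrapper feature selection


def _inner_splits(groups: np.ndarray, inner_cv) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-wise inner folds: LOSO if inner_cv is None, else ~inner_cv group folds."""
    uniq = list(dict.fromkeys(groups))
    if inner_cv is None or inner_cv >= len(uniq):
        parts = [[u] for u in uniq]
    else:
        k = max(int(inner_cv), 2)
        parts = [uniq[i::k] for i in range(k)]
    splits = []
    groups = np.asarray(groups)
    for part in parts:
        test_mask = np.isin(groups, part)
        if test_mask.all() or not test_mask.any():
            continue
        splits.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
    return splits


def _cv_accuracy(X, y, splits, feature_idx, make_estimator) -> float:
    """Pooled held-out accuracy of the estimator on the given feature subset."""
    correct = 0
    total = 0
    for train, test in splits:
        if len(np.unique(y[train])) < 2:
            continue
        est = make_estimator()
        est.fit(X[np.ix_(train, feature_idx)], y[train])
        pred = est.predict(X[np.ix_(test, feature_idx)])
        correct += int(np.sum(pred == y[test]))
        total += len(test)
    return correct / total if total else 0.0


def wrapper_select(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    method: str = "forward",
    *,
    inner_cv: int | None = None,
    C: float = 1.0,
    gamma="scale",
    class_weight="balanced",
) -> list[int]:
    """Greedy wrapper feature selection scored by inner subject-wise CV.

    ``forward`` starts empty and adds the feature that most improves the
    inner-validation accuracy, stopping when no addition strictly improves
    it.  ``backward`` starts from the full set and removes the feature whose
    removal yields the best (not worse) accuracy, stopping when every
    removal would hurt.  Ties are broken by canonical feature order.  The
    returned subset is never empty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ConfigurationError("wrapper selection needs >= 2 classes in the training labels")
    if method not in ("forward", "backward"):
        raise ConfigurationError(f"unknown selection method {method!r}")
    splits = _inner_splits(np.asarray(groups), inner_cv)
    n_features = X.shape[1]

    # Standardise once per inner split (training statistics only); candidate
    # subsets then only refit the SVM on column slices.  Class weights are
    # precomputed per split so the inner loop avoids repeated bookkeeping.
    prepared = []
    for train, test in splits:
        if len(np.unique(y[train])) < 2:
            continue
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        cw = class_weight
        if class_weight == "balanced":
            classes, counts = np.unique(y[train], return_counts=True)
            cw = {c: len(train) / (len(classes) * k) for c, k in zip(classes, counts)}
        prepared.append(((X[train] - mu) / sd, y[train], (X[test] - mu) / sd, y[test], cw))

    def score(idx):
        idx = list(idx)
        correct = 0
        total = 0
        with sklearn_config_context(assume_finite=True):
            for X_tr, y_tr, X_te, y_te, cw in prepared:
                svm = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=cw)
                svm.fit(X_tr[:, idx], y_tr)
                correct += int(np.sum(svm.predict(X_te[:, idx]) == y_te))
                total += len(y_te)
        return correct / total if total else 0.0

    if method == "forward":
        selected: list[int] = []
        best = -np.inf
        remaining = list(range(n_features))
        while remaining:
            scores = [score(selected + [f]) for f in remaining]
            k = int(np.argmax(scores))
            if scores[k] > best:
                best = scores[k]
                selected.append(remaining.pop(k))
            else:
                break
        return sorted(selected)

    selected = list(range(n_features))
    current = score(selected)
    while len(selected) > 1:
        scores = [score([f for f in selected if f != cand]) for cand in selected]
        k = int(np.argmax(scores))
        if scores[k] >= current:
            current = scores[k]
            selected.pop(k)
        else:
            break
    return sorted(selected)


# ---------------------------------------------------------------------------
# the classifier


class AffectClassifier(ClassifierMixin, BaseEstimator):
    """RBF-SVM affect classifier with embedded wrapper feature selection.

    Scaling is fit on the training data, a wrapper pass (scored by inner
    subject-wise cross-validation when ``groups`` are given to :meth:`fit`)
    picks the feature subset, and the SVM is refit on that subset.

    Parameters
    ----------
    C, gamma : SVM hyperparameters (fixed by default; see ``param_grid``).
    selection : {"forward", "backward", None}
        Wrapper method; ``None`` uses all features.
    inner_cv : int or None
        Number of inner subject folds for the selection scorer; ``None``
        means full inner leave-one-subject-out.
    param_grid : dict or None
        Optional ``{"C": [...], "gamma": [...]}`` grid evaluated with the
        inner CV on the full feature set before selection.
    class_weight : passed to the SVM ("balanced" handles task imbalance).

    Attributes
    ----------
    classes_ : ndarray of class labels.
    selected_idx_ : list of selected feature column indices.
    scaler_, svm_ : fitted preprocessing and kernel classifier.
    C_, gamma_ : hyperparameters actually used.
    """

    def __init__(
        self,
        C: float = 1.0,
        gamma="scale",
        selection: str | None = "forward",
        inner_cv: int | None = None,
        param_grid: dict | None = None,
        class_weight="balanced",
    ):
        self.C = C
        self.gamma = gamma
        self.selection = selection
        self.inner_cv = inner_cv
        self.param_grid = param_grid
        self.class_weight = class_weight

    def _make_svm(self, C, gamma):
        return SVC(kernel="rbf", C=C, gamma=gamma, class_weight=self.class_weight)

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ConfigurationError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ConfigurationError("training data contains a single class")
        if groups is None:
            groups = np.arange(len(y))
        groups = np.asarray(groups)

        self.C_, self.gamma_ = self.C, self.gamma
        if self.param_grid:
            splits = _inner_splits(groups, self.inner_cv)
            best = (-np.inf, self.C, self.gamma)
            for C in self.param_grid.get("C", [self.C]):
                for gamma in self.param_grid.get("gamma", [self.gamma]):
                    make = lambda C=C, gamma=gamma: make_pipeline(
                        StandardScaler(), self._make_svm(C, gamma)
                    )
                    acc = _cv_accuracy(X, y, splits, list(range(X.shape[1])), make)
                    if acc > best[0]:
                        best = (acc, C, gamma)
            _, self.C_, self.gamma_ = best

        if self.selection is None:
            self.selected_idx_ = list(range(X.shape[1]))
        else:
            self.selected_idx_ = wrapper_select(
                X, y, groups, self.selection,
                inner_cv=self.inner_cv, C=self.C_, gamma=self.gamma_,
                class_weight=self.class_weight,
            )

        self.scaler_ = StandardScaler().fit(X[:, self.selected_idx_])
        self.svm_ = self._make_svm(self.C_, self.gamma_).fit(
            self.scaler_.transform(X[:, self.selected_idx_]), y
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "svm_")
        X = np.asarray(X, dtype=float)
        return self.svm_.predict(self.scaler_.transform(X[:, self.selected_idx_]))


# ---------------------------------------------------------------------------
# LOSO task evaluation


@dataclass
class TaskResult:
    subgroup: str
    task: str
    accuracy: float  # % correct, max over selection methods
    method: str  # selection method achieving `accuracy`
    accuracy_by_method: dict
    selected_features: list  # majority-vote set of the winning method
    selected_by_fold: dict  # method -> list of per-fold feature-name lists
    n_subjects: int
    n_rows: int
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subgroup": self.subgroup,
            "task": self.task,
            "accuracy": self.accuracy,
            "method": self.method,
            "accuracy_by_method": self.accuracy_by_method,
            "selected_features": list(self.selected_features),
            "n_subjects": self.n_subjects,
            "n_rows": self.n_rows,
            "warnings": list(self.warnings),
        }


def _task_arrays(matrix: pd.DataFrame, subgroup: Subgroup, task: TaskSpec):
    feature_cols = [c for c in matrix.columns if c in FEATURE_NAMES]
    sub = matrix[
        matrix["subject_id"].isin(subgroup.subject_ids)
        & matrix["condition"].isin(task.classes)
    ]
    X = sub[feature_cols].to_numpy(dtype=float)
    y = sub["condition"].map(task.classes).to_numpy()
    groups = sub["subject_id"].to_numpy()
    return X, y, groups, feature_cols


def classify_task(
    matrix: pd.DataFrame,
    subgroup: Subgroup,
    task: TaskSpec,
    *,
    selection_methods: tuple = ("forward", "backward"),
    inner_cv: int | None = None,
    C: float = 1.0,
    gamma="scale",
    param_grid: dict | None = None,
) -> TaskResult:
    """LOSO evaluation of one (subgroup, task) cell; reports the better method."""
    task.validate()
    X, y, groups, feature_cols = _task_arrays(matrix, subgroup, task)
    uniq_subjects = list(dict.fromkeys(groups))
    if len(uniq_subjects) < 2:
        raise InsufficientDataError(
            f"subgroup {subgroup.name!r} has {len(uniq_subjects)} subjects; LOSO needs >= 2"
        )
    folds = loso_folds(uniq_subjects)
    fold_warnings: list[str] = []
    accuracy_by_method: dict[str, float] = {}
    selected_by_fold: dict[str, list] = {m: [] for m in selection_methods}

    for method in selection_methods:
        correct = 0
        total = 0
        for train_ids, test_id in folds:
            train_mask = np.isin(groups, train_ids)
            test_mask = groups == test_id
            y_train = y[train_mask]
            if len(np.unique(y_train)) < 2:
                fold_warnings.append(f"{method}: fold {test_id} skipped (single training class)")
                continue
            clf = AffectClassifier(
                C=C, gamma=gamma, selection=method, inner_cv=inner_cv, param_grid=param_grid
            )
            clf.fit(X[train_mask], y_train, groups=groups[train_mask])
            pred = clf.predict(X[test_mask])
            correct += int(np.sum(pred == y[test_mask]))
            total += int(test_mask.sum())
            selected_by_fold[method].append([feature_cols[i] for i in clf.selected_idx_])
        accuracy_by_method[method] = 100.0 * correct / total if total else float("nan")

    best_method = max(
        selection_methods, key=lambda m: (accuracy_by_method[m], -selection_methods.index(m))
    )
    majority = _majority_features(selected_by_fold[best_method])
    return TaskResult(
        subgroup=subgroup.name,
        task=task.name,
        accuracy=accuracy_by_method[best_method],
        method=best_method,
        accuracy_by_method=accuracy_by_method,
        selected_features=majority,
        selected_by_fold=selected_by_fold,
        n_subjects=len(uniq_subjects),
        n_rows=len(y),
        warnings=fold_warnings,
    )


def _majority_features(fold_selections: list) -> list:
    """Features chosen in more than half of the folds, canonical order."""
    if not fold_selections:
        return []
    counts: dict[str, int] = {}
    for fold in fold_selections:
        for name in fold:
            counts[name] = counts.get(name, 0) + 1
    half = len(fold_selections) / 2.0
    return [n for n in FEATURE_NAMES if counts.get(n, 0) > half]


def rank_selected_features(results: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Selection-frequency ranking and per-signal-group normalized shares.

    The ranking counts, per feature, in how many (subgroup x task) runs the
    winning method's majority set contained it.  Shares divide each signal
    group's count by the number of available features in that group and
    normalize to sum 1 within each subgroup.
    """
    if not results:
        raise InsufficientDataError("no classification results to rank")
    feature_pool: list[str] = []
    for res in results:
        for fold in res.selected_by_fold.get(res.method, []):
            for name in fold:
                if name not in feature_pool:
                    feature_pool.append(name)
    for res in results:
        for name in res.selected_features:
            if name not in feature_pool:
                feature_pool.append(name)
    feature_pool = [n for n in FEATURE_NAMES if n in feature_pool]

    counts = {n: 0 for n in feature_pool}
    for res in results:
        for name in res.selected_features:
            counts[name] += 1
    ranking = pd.DataFrame(
        {
            "feature": list(counts),
            "signal": [SIGNAL_GROUPS[n] for n in counts],
            "amount": list(counts.values()),
        }
    ).sort_values(["amount", "feature"], ascending=[False, True], kind="stable")
    ranking["ranking"] = np.arange(1, len(ranking) + 1)
    ranking = ranking.reset_index(drop=True)

    group_sizes: dict[str, int] = {}
    for name in feature_pool:
        group_sizes[SIGNAL_GROUPS[name]] = group_sizes.get(SIGNAL_GROUPS[name], 0) + 1
    share_rows = []
    for subgroup in dict.fromkeys(res.subgroup for res in results):
        sub_counts: dict[str, float] = {g: 0.0 for g in group_sizes}
        for res in results:
            if res.subgroup != subgroup:
                continue
            for name in res.selected_features:
                sub_counts[SIGNAL_GROUPS[name]] += 1
        normalized = {g: sub_counts[g] / group_sizes[g] for g in group_sizes}
        total = sum(normalized.values())
        for g in group_sizes:
            share_rows.append(
                {
                    "subgroup": subgroup,
                    "signal": g,
                    "share": normalized[g] / total if total else 0.0,
                }
            )
    shares = pd.DataFrame(share_rows)
    return ranking, shares
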