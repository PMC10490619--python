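"""Leave-one-subject-out classification with t-ranked feature elimination.

Protocol: features are ranked once on the full matrix by the absolute value
of their paired statistic (t or z, whichever the normality gate selects);
backward elimination drops the weakest remaining feature at each step and
re-runs grid search + leave-one-subject-out CV on the surviving subset.
Within each fold, z-scoring uses the training subjects only — the held-out
subject never influences normalization, hyperparameter choice (in
rank-per-fold mode, nor the ranking).

Four classifier families are supported: RBF-kernel SVM, KNN (with a
nearest-neighbor tie-break for even k), LDA, and random forest. "Distracted"
is the positive class (label 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .errors import FoldError, InvalidArgumentError, StructuralError
from .hrv import HRV_FEATURE_NAMES
from .eda import GSR_FEATURE_NAMES
from .paired import PairedSample, compare_conditions
from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "FeatureMatrix",
    "Hyperparameters",
    "CVResult",
    "EvaluationReport",
    "EliminationTrace",
    "FAMILIES",
    "build_feature_matrix",
    "zscore_normalize",
    "rank_features",
    "loso_cv",
    "grid_search",
    "default_grid",
    "backward_elimination",
    "evaluate",
]

POSITIVE = "distracted"
NEGATIVE = "focused"
FAMILIES = ("svm_rbf", "knn", "lda", "rf")

#: Latency is undefined for sessions without any SCR; "no response within
#: the window" is encoded as the window length itself.
LATENCY_IMPUTE = 300.0


@dataclass
class FeatureMatrix:
    """Long-format matrix: one row per (subject, condition)."""

    X: pd.DataFrame  # numeric feature columns only
    subject_ids: np.ndarray
    labels: np.ndarray  # 1 = distracted, 0 = focused

    def __post_init__(self) -> None:
        if len(self.X) != len(self.subject_ids) or len(self.X) != len(self.labels):
            raise InvalidArgumentError("rows, ids and labels must align")
        counts = pd.Series(self.subject_ids).value_counts()
        bad = counts[counts != 2]
        if len(bad):
            raise StructuralError(f"subjects without exactly 2 sessions: {sorted(bad.index)}")
        if self.X.isna().any().any():
            raise StructuralError("feature matrix contains missing values after imputation")

    @property
    def feature_names(self) -> list:
        return list(self.X.columns)

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def select(self, features: list) -> "FeatureMatrix":
        return FeatureMatrix(self.X[list(features)], self.subject_ids, self.labels)


@dataclass
class Hyperparameters:
    family: str
    C: float | None = None
    gamma: float | None = None
    k: int | None = None
    trees: int = 500
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidArgumentError(f"unknown family {self.family!r}")
        for name in ("C", "gamma", "k", "trees"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidArgumentError(f"{name} must be positive")


@dataclass
class CVResult:
    predictions: np.ndarray  # predicted label per row
    scores: np.ndarray  # decision score per row (higher = more positive)
    fold_subject: np.ndarray  # held-out subject id per row
    labels: np.ndarray  # true label per row
    train_subjects: dict = field(default_factory=dict)  # fold -> train subject ids


@dataclass
class EvaluationReport:
    TP: int
    FN: int
    TN: int
    FP: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    F1: float
    AUC: float | None
    roc_points: list  # [(FPR, TPR)]

    def to_dict(self) -> dict:
        return {
            "TP": self.TP, "FN": self.FN, "TN": self.TN, "FP": self.FP,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "F1": self.F1, "AUC": self.AUC, "roc_points": self.roc_points,
        }


@dataclass
class EliminationTrace:
    ranking: list  # features by descending |statistic|
    subsets: list  # evaluated subsets (suffix-nested), largest first
    accuracies: list
    hyperparams: list
    best_subset: list
    best_accuracy: float


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------


def build_feature_matrix(
    hrv: pd.DataFrame,
    eda: pd.DataFrame,
    latency_impute: float = LATENCY_IMPUTE,
) -> FeatureMatrix:
    """Inner-join HRV and EDA per-session tables on (subject_id, condition).

    Column order is fixed: the 14 HRV features then the 7 EDA features.
    Raises a structural error naming any subject lacking either source or a
    complete session pair.
    """
    keys = ["subject_id", "condition"]
    for df, cols, tag in ((hrv, HRV_FEATURE_NAMES, "HRV"), (eda, GSR_FEATURE_NAMES, "EDA")):
        missing = [c for c in keys + cols if c not in df.columns]
        if missing:
            raise StructuralError(f"{tag} table missing columns: {missing}")
    merged = hrv[keys + HRV_FEATURE_NAMES].merge(
        eda[keys + GSR_FEATURE_NAMES], on=keys, how="outer", indicator=True
    )
    incomplete = merged.loc[merged["_merge"] != "both", "subject_id"].unique()
    if len(incomplete):
        raise StructuralError(f"sessions missing a data source for subjects: {sorted(incomplete)}")
    merged = merged.drop(columns="_merge")
    if merged["Latency"].isna().any():
        warnings.warn("imputing missing Latency with the window length", stacklevel=2)
        merged["Latency"] = merged["Latency"].fillna(latency_impute)
    labels = (merged["condition"] == POSITIVE).astype(int).to_numpy()
    return FeatureMatrix(
        merged[HRV_FEATURE_NAMES + GSR_FEATURE_NAMES].astype(float).reset_index(drop=True),
        merged["subject_id"].to_numpy(),
        labels,
    )


def zscore_normalize(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Standardize both frames with train-fold statistics only.

    Constant training columns are dropped (from both frames) with a warning;
    returns (train_z, test_z, kept_columns).
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    kept = list(train.columns[sd > 0])
    dropped = [c for c in train.columns if c not in kept]
    if dropped:
        warnings.warn(f"dropping constant training columns: {dropped}", stacklevel=2)
    train_z = (train[kept] - mean[kept]) / sd[kept]
    test_z = (test[kept] - mean[kept]) / sd[kept]
    return train_z, test_z, kept


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def rank_features(matrix: FeatureMatrix, alpha: float = 0.05) -> list:
    """Features ordered by descending |paired statistic| (t or z).

    Ties (and degenerate features, which rank last) are broken by original
    column order, so the ranking is deterministic.
    """
    if len(matrix.subjects) < 2:
        raise InvalidArgumentError("ranking needs at least 2 subjects")
    df = matrix.X.copy()
    df["subject_id"] = matrix.subject_ids
    df["label"] = matrix.labels
    wide = df.pivot(index="subject_id", columns="label")
    scores = []
    for j, col in enumerate(matrix.feature_names):
        x = wide[(col, 0)].to_numpy(dtype=float)  # focused
        y = wide[(col, 1)].to_numpy(dtype=float)  # distracted
        try:
            res = compare_conditions(PairedSample(wide.index.to_numpy(), x, y), alpha=alpha)
            stat = abs(res.statistic)
        except (DegenerateInputError, InsufficientDataError):
            warnings.warn(f"feature {col!r} degenerate; ranked last", stacklevel=2)
            stat = -np.inf
        scores.append((-stat, j, col))
    return [col for _, _, col in sorted(scores)]


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


class _TieBreakKNN:
    """KNN voting with ties resolved by the single nearest neighbor; the
    decision score is the fraction of positive neighbors."""

    def __init__(self, k: int):
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_TieBreakKNN":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y, dtype=int)
        return self

    def _neighbors(self, X: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(self._X[None, :, :] - np.asarray(X, dtype=float)[:, None, :], axis=2)
        return np.argsort(d, axis=1, kind="stable")[:, : self.k]

    def predict_and_score(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nbrs = self._neighbors(X)
        votes = self._y[nbrs]
        frac_pos = votes.mean(axis=1)
        pred = (frac_pos > 0.5).astype(int)
        tied = frac_pos == 0.5
        pred[tied] = votes[tied, 0]  # nearest neighbor decides
        return pred, frac_pos


def _fit_predict(
    family: str,
    hp: Hyperparameters,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    if family == "svm_rbf":
        model = SVC(C=hp.C or 1.0, gamma=hp.gamma or "scale", kernel="rbf")
        model.fit(X_tr, y_tr)
        return model.predict(X_te), model.decision_function(X_te)
    if family == "knn":
        model = _TieBreakKNN(k=hp.k or 3).fit(X_tr, y_tr)
        return model.predict_and_score(X_te)
    if family == "lda":
        model = LinearDiscriminantAnalysis()
        model.fit(X_tr, y_tr)
        return model.predict(X_te), model.predict_proba(X_te)[:, 1]
    if family == "rf":
        model = RandomForestClassifier(
            n_estimators=hp.trees, max_depth=hp.max_depth, random_state=seed
        )
        model.fit(X_tr, y_tr)
        return model.predict(X_te), model.predict_proba(X_te)[:, 1]
    raise InvalidArgumentError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def loso_cv(matrix: FeatureMatrix, hp: Hyperparameters, seed: int = 0) -> CVResult:
    """Leave-one-subject-out CV: both sessions of one subject form the test
    fold; z-scoring and fitting use the remaining subjects only."""
    subjects = matrix.subjects
    if len(subjects) < 3:
        raise InvalidArgumentError("LOSO needs at least 3 subjects")
    n = len(matrix.X)
    preds = np.full(n, -1, dtype=int)
    scores = np.full(n, np.nan)
    fold_subject = np.empty(n, dtype=object)
    train_subjects: dict = {}
    for subj in subjects:
        test_mask = matrix.subject_ids == subj
        train_mask = ~test_mask
        y_tr = matrix.labels[train_mask]
        if len(np.unique(y_tr)) < 2:
            raise FoldError(f"fold {subj!r}: training set has a single class")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X_tr, X_te, kept = zscore_normalize(
                matrix.X.loc[train_mask], matrix.X.loc[test_mask]
            )
        if not kept:
            raise FoldError(f"fold {subj!r}: no usable features")
        p, s = _fit_predict(hp.family, hp, X_tr.to_numpy(), y_tr, X_te.to_numpy(), seed)
        preds[test_mask] = p
        scores[test_mask] = s
        fold_subject[test_mask] = subj
        train_subjects[subj] = np.unique(matrix.subject_ids[train_mask])
    return CVResult(preds, scores, fold_subject, matrix.labels.copy(), train_subjects)


def default_grid(family: str) -> list:
    """Documented default hyperparameter grids, in tie-break order."""
    if family == "svm_rbf":
        return [
            Hyperparameters("svm_rbf", C=2.0**i, gamma=2.0**j)
            for i, j in product(range(-5, 16, 2), range(-15, 4, 2))
        ]
    if family == "knn":
        return [Hyperparameters("knn", k=k) for k in range(1, 16)]
    if family == "lda":
        return [Hyperparameters("lda")]
    if family == "rf":
        return [Hyperparameters("rf", trees=500, max_depth=d) for d in (None, 3, 5, 10)]
    raise InvalidArgumentError(f"unknown family {family!r}")


def grid_search(
    matrix: FeatureMatrix,
    family: str,
    grid: list | None = None,
    seed: int = 0,
) -> tuple[Hyperparameters, float]:
    """Pick the grid point maximizing LOSO accuracy (ties: first in grid)."""
    grid = default_grid(family) if grid is None else list(grid)
    if not grid:
        raise InvalidArgumentError("grid must be non-empty")
    best_hp, best_acc = None, -1.0
    for hp in grid:
        cv = loso_cv(matrix, hp, seed=seed)
        acc = float(np.mean(cv.predictions == cv.labels))
        if acc > best_acc:
            best_hp, best_acc = hp, acc
    return best_hp, best_acc


def _loso_accuracy_per_fold_features(
    matrix: FeatureMatrix,
    hp: Hyperparameters,
    fold_features: dict,
    seed: int,
) -> float:
    """LOSO accuracy where each fold uses its own feature subset (the
    leakage-safe mode: rankings were computed on training subjects only)."""
    correct = total = 0
    for subj in matrix.subjects:
        sub = matrix.select(fold_features[subj])
        test_mask = sub.subject_ids == subj
        y_tr = sub.labels[~test_mask]
        if len(np.unique(y_tr)) < 2:
            raise FoldError(f"fold {subj!r}: training set has a single class")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X_tr, X_te, kept = zscore_normalize(
                sub.X.loc[~test_mask], sub.X.loc[test_mask]
            )
        p, _ = _fit_predict(hp.family, hp, X_tr.to_numpy(), y_tr, X_te.to_numpy(), seed)
        correct += int(np.sum(p == sub.labels[test_mask]))
        total += int(test_mask.sum())
    return correct / total


def backward_elimination(
    matrix: FeatureMatrix,
    family: str,
    grid: list | None = None,
    seed: int = 0,
    ranking: list | None = None,
    rank_per_fold: bool = False,
) -> EliminationTrace:
    """Drop the weakest-ranked remaining feature one at a time, re-running
    grid search + LOSO at every subset size from all features down to 1.

    With ``rank_per_fold=True`` each fold ranks features on its training
    subjects only (no ranking leakage); the reported trace subsets then
    refer to the full-matrix ranking for readability while the accuracies
    come from the fold-local subsets.
    """
    if len(matrix.feature_names) < 2:
        raise InvalidArgumentError("elimination needs at least 2 features")
    ranking = rank_features(matrix) if ranking is None else list(ranking)
    grid_eval = default_grid(family) if grid is None else list(grid)
    if not grid_eval:
        raise InvalidArgumentError("grid must be non-empty")

    fold_rankings = None
    if rank_per_fold:
        fold_rankings = {}
        for subj in matrix.subjects:
            train_mask = matrix.subject_ids != subj
            train = FeatureMatrix(
                matrix.X.loc[train_mask].reset_index(drop=True),
                matrix.subject_ids[train_mask],
                matrix.labels[train_mask],
            )
            fold_rankings[subj] = rank_features(train)

    subsets, accs, hps = [], [], []
    for size in range(len(ranking), 0, -1):
        subset = ranking[:size]
        if rank_per_fold:
            fold_features = {s: r[:size] for s, r in fold_rankings.items()}
            best_hp, best_acc = None, -1.0
            for hp in grid_eval:
                acc = _loso_accuracy_per_fold_features(matrix, hp, fold_features, seed)
                if acc > best_acc:
                    best_hp, best_acc = hp, acc
            hp, acc = best_hp, best_acc
        else:
            hp, acc = grid_search(matrix.select(subset), family, grid_eval, seed=seed)
        subsets.append(subset)
        accs.append(acc)
        hps.append(hp)
    best_idx = int(np.argmax(accs))
    return EliminationTrace(
        ranking=ranking, subsets=subsets, accuracies=accs, hyperparams=hps,
        best_subset=subsets[best_idx], best_accuracy=accs[best_idx],
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate(cv: CVResult) -> EvaluationReport:
    """Confusion counts and derived metrics; distracted (1) is positive."""
    y, p = cv.labels, cv.predictions
    tp = int(np.sum((y == 1) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    total = tp + fn + tn + fp
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity > 0
        else 0.0
    )
    if np.all(np.isfinite(cv.scores)):
        fpr, tpr, _ = roc_curve(y, cv.scores)
        auc_val = float(_auc(fpr, tpr))
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    else:
        warnings.warn("scores missing; AUC omitted", stacklevel=2)
        auc_val, roc_points = None, []
    return EvaluationReport(
        TP=tp, FN=fn, TN=tn, FP=fp, accuracy=accuracy, sensitivity=sensitivity,
        specificity=specificity, precision=precision, F1=f1, AUC=auc_val,
        roc_points=roc_points,
    )
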