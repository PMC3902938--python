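"""One-vs-rest Random Forest classification of translational classes.

The forest learner itself is scikit-learn's; this module owns the protocol
around it: binary one-vs-rest label construction, (ntree, mtry) grid
tuning by out-of-bag (OOB) error with balanced class weights, the OOB
confusion matrix, pooled 10-fold cross-validated ROC/AUC, and a feature
importance report combining mean Gini decrease, per-tree OOB permutation
importance and a rank-biserial effect sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

try:  # per-tree OOB masks; fall back to whole-X permutation importance
    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    _HAVE_OOB_INDICES = True
except ImportError:  # pragma: no cover
    _HAVE_OOB_INDICES = False


def make_binary_labels(
    calls: pd.DataFrame, positive: str
) -> tuple[np.ndarray, pd.Index]:
    """One-vs-rest labels: the chosen class (``up`` or ``down``) against
    all other transcripts (opposite class plus unchanged)."""
    if positive not in ("up", "down"):
        raise ValueError("positive must be 'up' or 'down'")
    if "label" not in calls or calls.empty:
        raise ValueError("calls must be a non-empty table with a 'label' column")
    y = (calls["label"] == positive).to_numpy(dtype=int)
    if y.sum() == 0:
        raise ValueError(f"no transcripts with label {positive!r}")
    return y, calls.index


@dataclass
class ForestConfig:
    """Tuning grid and evaluation settings for the forest."""

    ntree_grid: tuple[int, ...] = (250, 500, 1000)
    mtry_grid: tuple[int, ...] | None = None  # None -> sqrt(p)/2, sqrt(p), 2 sqrt(p)
    class_weighting: str = "balanced"  # balanced | none
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ntree_grid:
            raise ValueError("ntree_grid must be non-empty")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.class_weighting not in ("balanced", "none"):
            raise ValueError("class_weighting must be 'balanced' or 'none'")

    def resolve_mtry(self, n_features: int) -> tuple[int, ...]:
        if self.mtry_grid:
            return tuple(self.mtry_grid)
        root = np.sqrt(n_features)
        grid = sorted({
            max(1, int(root // 2)), max(1, int(root)), max(1, int(2 * root))
        })
        return tuple(grid)


class TranslationForestClassifier(BaseEstimator, ClassifierMixin):
    """Class-weighted Random Forest with OOB grid tuning.

    ``fit`` grid-searches (ntree, mtry) by OOB classification error under
    a fixed seed, breaking ties toward smaller ntree then smaller mtry,
    and stores the tuned forest plus an OOB confusion matrix.

    Attributes (after ``fit``)
    --------------------------
    best_params_ : dict with ntree and mtry of the winning grid point.
    oob_error_ : OOB misclassification rate of the tuned forest.
    oob_confusion_ : dict TP/FP/TN/FN from OOB votes (positive class = 1).
    grid_trace_ : DataFrame of the full OOB-error grid.
    forest_ : the fitted sklearn RandomForestClassifier.
    """

    def __init__(
        self,
        ntree_grid: tuple[int, ...] = (250, 500, 1000),
        mtry_grid: tuple[int, ...] | None = None,
        class_weighting: str = "balanced",
        n_folds: int = 10,
        seed: int = 0,
    ):
        self.ntree_grid = ntree_grid
        self.mtry_grid = mtry_grid
        self.class_weighting = class_weighting
        self.n_folds = n_folds
        self.seed = seed

    # -- helpers -------------------------------------------------------
    def _config(self) -> ForestConfig:
        return ForestConfig(
            ntree_grid=tuple(self.ntree_grid),
            mtry_grid=tuple(self.mtry_grid) if self.mtry_grid else None,
            class_weighting=self.class_weighting,
            n_folds=self.n_folds,
            seed=self.seed,
        )

    def _new_forest(self, ntree: int, mtry: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=ntree,
            max_features=mtry,
            oob_score=True,
            bootstrap=True,
            class_weight=(
                "balanced" if self.class_weighting == "balanced" else None
            ),
            random_state=self.seed,
            n_jobs=1,
        )

    @staticmethod
    def _as_array(X) -> np.ndarray:
        arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if np.isnan(arr).any():
            raise ValueError("feature matrix contains NaN; impute first")
        return arr

    @staticmethod
    def _oob_predictions(forest: RandomForestClassifier) -> np.ndarray:
        votes = forest.oob_decision_function_
        # samples never left out get a NaN row; call them class 0
        votes = np.nan_to_num(votes, nan=0.0)
        return forest.classes_[np.argmax(votes, axis=1)]

    # -- estimator API -------------------------------------------------
    def fit(self, X, y) -> "TranslationForestClassifier":
        cfg = self._config()
        arr = self._as_array(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("y must contain both classes")
        if len(y) != arr.shape[0]:
            raise ValueError("X and y length mismatch")
        self.feature_names_ = (
            list(X.columns) if isinstance(X, pd.DataFrame)
            else [f"x{i}" for i in range(arr.shape[1])]
        )
        mtry_grid = cfg.resolve_mtry(arr.shape[1])
        trace = []
        best = None
        for ntree in sorted(cfg.ntree_grid):
            for mtry in sorted(mtry_grid):
                forest = self._new_forest(ntree, mtry).fit(arr, y)
                oob_err = float(np.mean(self._oob_predictions(forest) != y))
                trace.append({"ntree": ntree, "mtry": mtry, "oob_error": oob_err})
                if best is None or oob_err < best[0] - 1e-12:
                    best = (oob_err, ntree, mtry, forest)
        self.grid_trace_ = pd.DataFrame(trace)
        self.oob_error_, ntree, mtry, self.forest_ = best
        self.best_params_ = {"ntree": ntree, "mtry": mtry}
        self.classes_ = self.forest_.classes_

        pred = self._oob_predictions(self.forest_)
        self.oob_confusion_ = {
            "TP": int(np.sum((pred == 1) & (y == 1))),
            "FP": int(np.sum((pred == 1) & (y == 0))),
            "TN": int(np.sum((pred == 0) & (y == 0))),
            "FN": int(np.sum((pred == 0) & (y == 1))),
        }
        self._X_fit = arr
        self._y_fit = y
        return self

    def predict(self, X):
        return self.forest_.predict(self._as_array(X))

    def predict_proba(self, X):
        return self.forest_.predict_proba(self._as_array(X))


def roc_from_scores(y: np.ndarray, scores: np.ndarray) -> dict:
    """ROC points and trapezoid AUC from pooled scores.

    The trapezoid AUC equals the concordance probability: the chance a
    random positive outscores a random negative, ties counted half.
    """
    fpr, tpr, thresholds = roc_curve(y, scores)
    return {
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thresholds,
        "auc": float(_trapezoid_auc(fpr, tpr)),
        "scores": np.asarray(scores),
    }


def crossval_roc(
    X, y, config: ForestConfig | None = None,
    ntree: int | None = None, mtry: int | None = None,
) -> dict:
    """Pooled out-of-fold ROC from stratified k-fold cross-validation.

    Each fold's held-out vote fractions are pooled and a single ROC curve
    is swept over thresholds; AUC is the trapezoid integral, equal to the
    probability that a random positive outscores a random negative (ties
    counted half).
    """
    cfg = config or ForestConfig()
    arr = TranslationForestClassifier._as_array(X)
    y = np.asarray(y)
    if ntree is None:
        ntree = cfg.ntree_grid[0]
    if mtry is None:
        mtry = cfg.resolve_mtry(arr.shape[1])[0]
    counts = np.bincount(y)
    if counts.min() < cfg.n_folds:
        raise ValueError(
            f"minority class ({counts.min()}) smaller than n_folds ({cfg.n_folds})"
        )
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    scores = np.empty(len(y))
    for train, test in skf.split(arr, y):
        forest = RandomForestClassifier(
            n_estimators=ntree, max_features=mtry, bootstrap=True,
            class_weight=("balanced" if cfg.class_weighting == "balanced" else None),
            random_state=cfg.seed, n_jobs=1,
        ).fit(arr[train], y[train])
        pos = list(forest.classes_).index(1)
        scores[test] = forest.predict_proba(arr[test])[:, pos]
    return roc_from_scores(y, scores)


def _rank_biserial_sign(x: np.ndarray, y: np.ndarray) -> str:
    """'+' when the feature tends higher in the positive class
    (rank-biserial correlation > 0), else '-'."""
    pos = x[y == 1]
    neg = x[y == 0]
    if len(pos) == 0 or len(neg) == 0 or np.all(x == x[0]):
        return "+"
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    rb = 2.0 * u / (len(pos) * len(neg)) - 1.0
    return "+" if rb >= 0 else "-"


def _oob_permutation_importance(
    model: TranslationForestClassifier, rng: np.random.Generator
) -> np.ndarray:
    """Mean over trees of the OOB error increase after permuting each
    feature column within that tree's OOB samples."""
    forest = model.forest_
    X, y = model._X_fit, model._y_fit
    n_samples, n_features = X.shape
    if not _HAVE_OOB_INDICES:  # pragma: no cover
        from sklearn.inspection import permutation_importance

        res = permutation_importance(
            forest, X, y, n_repeats=5,
            random_state=int(rng.integers(2**31 - 1)),
        )
        return res.importances_mean
    try:
        n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples, None)
    except TypeError:  # older signature without sample_weight
        n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples)

    def _oob_indices(tree):
        try:
            return _generate_unsampled_indices(
                tree.random_state, n_samples, n_boot, None
            )
        except TypeError:
            return _generate_unsampled_indices(
                tree.random_state, n_samples, n_boot
            )

    totals = np.zeros(n_features)
    for tree in forest.estimators_:
        oob = _oob_indices(tree)
        if len(oob) == 0:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        base_err = np.mean(tree.predict(X_oob) != y_oob)
        perm = rng.permutation(len(oob))
        for j in range(n_features):
            col = X_oob[:, j].copy()
            X_oob[:, j] = col[perm]
            totals[j] += np.mean(tree.predict(X_oob) != y_oob) - base_err
            X_oob[:, j] = col
    return totals / len(forest.estimators_)


def importance_report(
    model: TranslationForestClassifier,
    permutation: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """Feature importance table sorted by mean Gini decrease.

    Columns: feature, gini (mean decrease in impurity), permutation
    (OOB-error increase after within-column permutation, averaged over
    trees; NaN when disabled), sign ('+' / '-' rank-biserial direction
    with respect to the positive class), rank (1 = most important).
    """
    if not hasattr(model, "forest_"):
        raise ValueError("model is not fitted")
    gini = model.forest_.feature_importances_
    rng = np.random.default_rng(model.seed if seed is None else seed)
    if permutation:
        perm = _oob_permutation_importance(model, rng)
    else:
        perm = np.full(len(gini), np.nan)
    X, y = model._X_fit, model._y_fit
    signs = [_rank_biserial_sign(X[:, j], y) for j in range(X.shape[1])]
    df = pd.DataFrame(
        {
            "feature": model.feature_names_,
            "gini": gini,
            "permutation": perm,
            "sign": signs,
        }
    ).sort_values("gini", ascending=False, ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class ForestReport:
    """Consolidated evaluation of one one-vs-rest task."""

    positive: str
    best_params: dict
    oob_error: float
    confusion: dict
    auc: float
    roc: pd.DataFrame
    importance: pd.DataFrame
    grid_trace: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "positive": self.positive,
            "best_params": self.best_params,
            "oob_error": self.oob_error,
            "confusion": self.confusion,
            "auc": self.auc,
            "top_features": self.importance.head(3)[
                ["feature", "gini", "sign"]
            ].to_dict(orient="records"),
        }


def tune_and_train(
    X, y, config: ForestConfig | None = None, positive: str = "down",
    permutation_importance: bool = True,
) -> tuple[TranslationForestClassifier, ForestReport]:
    """Tune, train and fully evaluate one one-vs-rest forest."""
    cfg = config or ForestConfig()
    model = TranslationForestClassifier(
        ntree_grid=cfg.ntree_grid, mtry_grid=cfg.mtry_grid,
        class_weighting=cfg.class_weighting, n_folds=cfg.n_folds, seed=cfg.seed,
    ).fit(X, y)
    roc = crossval_roc(
        X, y, cfg, ntree=model.best_params_["ntree"],
        mtry=model.best_params_["mtry"],
    )
    imp = importance_report(model, permutation=permutation_importance)
    report = ForestReport(
        positive=positive,
        best_params=model.best_params_,
        oob_error=model.oob_error_,
        confusion=model.oob_confusion_,
        auc=roc["auc"],
        roc=pd.DataFrame({"fpr": roc["fpr"], "tpr": roc["tpr"]}),
        importance=imp,
        grid_trace=model.grid_trace_,
    )
    return model, report
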