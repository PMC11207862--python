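"""Repeated stratified-holdout validation harness over five classifier
families (KNN, SVM, single-hidden-layer neural network, random forest,
gradient boosting), with per-split grid tuning, pooled confusion matrices,
pooled ROC/AUC, and importance-intersection feature selection.

The harness mirrors a common microbiome-classification protocol: each of
``n_iterations`` rounds draws a stratified 80/20 train/test split, tunes each
family by stratified 5-fold cross-validated grid search on the training
split, refits the winner on the whole training split, and records the test
predictions and class-1 scores.  Results are *pooled* across iterations —
confusion counts are summed and one ROC curve is built from the concatenated
score/label pairs — so the reported numbers integrate all rounds rather than
averaging per-round statistics.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import xgboost as xgb
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "HarnessConfig",
    "FamilyResult",
    "EnsembleResult",
    "ImportanceRanking",
    "EnsembleValidator",
    "run_ensemble",
    "roc_auc",
    "feature_importance",
    "top_n_intersection",
    "summarize_ensemble",
]

FAMILIES = ("knn", "svm", "bpnn", "rf", "xgb")

_DECADES = [10.0**e for e in range(-3, 4)]


def _default_grids(n_features: int, full_rf_grid: bool = False) -> dict:
    mtry_max = min(59, n_features)
    if full_rf_grid:
        mtry = list(range(1, mtry_max + 1))
    else:
        # quartet spanning the 1..min(59, p) range; full scan is configurable
        mtry = sorted(
            {1, max(1, int(np.sqrt(n_features))), max(1, n_features // 3), mtry_max}
        )
    return {
        "knn": {"model__n_neighbors": list(range(1, 21))},
        "svm": {"model__C": _DECADES, "model__gamma": [1.0 / (2 * s**2) for s in _DECADES]},
        "bpnn": {
            "model__hidden_layer_sizes": [(2,), (4,), (8,), (16,)],
            "model__alpha": [1e-8, 0.01, 0.1],
        },
        "rf": {"model__max_features": mtry},
        "xgb": {
            "model__n_estimators": [50, 150],
            "model__max_depth": [3, 6],
            "model__learning_rate": [0.1, 0.3],
            "model__colsample_bytree": [0.6, 1.0],
            "model__min_child_weight": [1, 5],
            "model__subsample": [0.8, 1.0],
        },
    }


@dataclasses.dataclass
class HarnessConfig:
    """Split sizes, iteration count, inner-CV folds and per-family grids."""

    train_fraction: float = 0.8
    n_iterations: int = 100
    inner_cv_folds: int = 5
    master_seed: int = 0
    families: Sequence[str] = FAMILIES
    n_trees: int = 500
    grids: dict | None = None  # None -> defaults sized to the data
    full_rf_grid: bool = False

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families {sorted(unknown)}")

    @classmethod
    def fast(cls, master_seed: int = 0, n_iterations: int = 10) -> "HarnessConfig":
        """Desk-scale preset: few iterations and thinned tuning grids."""
        return cls(
            n_iterations=n_iterations,
            master_seed=master_seed,
            n_trees=200,
            grids={
                "knn": {"model__n_neighbors": [1, 5, 11]},
                "svm": {"model__C": [0.1, 1, 100], "model__gamma": ["scale", 0.01]},
                "bpnn": {"model__hidden_layer_sizes": [(4,), (8,)], "model__alpha": [0.01]},
                "rf": {"model__max_features": ["sqrt"]},
                "xgb": {"model__n_estimators": [100], "model__max_depth": [3, 6]},
            },
        )


@dataclasses.dataclass
class FamilyResult:
    family: str
    confusion: np.ndarray  # pooled 2x2, rows = true class, cols = predicted
    accuracy: float
    auc: float
    roc_points: np.ndarray  # (fpr, tpr) pairs on the pooled scores
    chosen_params: list[dict]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray


@dataclasses.dataclass
class EnsembleResult:
    families: dict[str, FamilyResult]
    classes: np.ndarray
    n_iterations: int
    test_size: int
    mean_auc: float
    mean_accuracy: float


@dataclasses.dataclass
class ImportanceRanking:
    family: str
    scores: dict[str, float]
    ranking: list[str]  # descending importance


def _make_estimator(family: str, cfg: HarnessConfig, seed: int) -> BaseEstimator:
    if family == "knn":
        model = KNeighborsClassifier()
    elif family == "svm":
        model = SVC(kernel="rbf", random_state=seed)
    elif family == "bpnn":
        model = MLPClassifier(
            activation="logistic",
            solver="lbfgs",
            max_iter=500,
            random_state=seed,
        )
    elif family == "rf":
        model = RandomForestClassifier(n_estimators=cfg.n_trees, random_state=seed)
    elif family == "xgb":
        model = xgb.XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
            tree_method="exact",
        )
    else:
        raise ValueError(f"unknown family {family!r}")
    steps = [("scale", StandardScaler()), ("model", model)]
    if family in ("rf", "xgb"):  # trees are scale-invariant
        steps = steps[1:]
    return Pipeline(steps)


def _class1_scores(est: Pipeline, X: np.ndarray) -> np.ndarray:
    model = est.named_steps["model"]
    if isinstance(model, SVC):
        # signed margin through a logistic link, for pooling comparability
        return 1.0 / (1.0 + np.exp(-est.decision_function(X)))
    return est.predict_proba(X)[:, 1]


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC by the rank (Mann-Whitney) formulation, ties counted 1/2, plus the
    pooled ROC points (fpr, tpr) at every distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("ROC needs both classes present")
    pos = labels == classes[1]
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = _midranks(scores)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(pos[order])
    fp = np.cumsum(~pos[order])
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), scores.size - 1]
    points = np.column_stack([fp[distinct] / n0, tp[distinct] / n1])
    points = np.vstack([[0.0, 0.0], points])
    return float(auc), points


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


class EnsembleValidator(BaseEstimator):
    """Runs the repeated-holdout harness; ``fit`` performs the full protocol
    and stores an :class:`EnsembleResult` in ``result_``."""

    def __init__(self, config: HarnessConfig | None = None):
        self.config = config

    def fit(self, X, y):
        cfg = self.config or HarnessConfig()
        cfg.validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("harness requires exactly 2 classes")
        for cls in classes:
            if (y == cls).sum() < 5:
                raise ValueError(f"need >=5 samples in class {cls!r}")

        grids = cfg.grids or _default_grids(X.shape[1], cfg.full_rf_grid)
        n_test = X.shape[0] - int(round(cfg.train_fraction * X.shape[0]))
        y01 = (y == classes[1]).astype(int)

        store = {
            f: {"scores": [], "labels": [], "preds": [], "params": []}
            for f in cfg.families
        }
        for it in range(cfg.n_iterations):
            seed = cfg.master_seed + it
            idx_tr, idx_te = train_test_split(
                np.arange(X.shape[0]),
                test_size=n_test,
                stratify=y01,
                random_state=seed,
            )
            Xtr, Xte = X[idx_tr], X[idx_te]
            ytr, yte = y01[idx_tr], y01[idx_te]
            inner = StratifiedKFold(
                n_splits=min(cfg.inner_cv_folds, np.bincount(ytr).min()),
                shuffle=True,
                random_state=seed,
            )
            for fam in cfg.families:
                est = _make_estimator(fam, cfg, seed)
                search = GridSearchCV(
                    est, grids[fam], cv=inner, scoring="accuracy", n_jobs=1
                )
                search.fit(Xtr, ytr)
                best = search.best_estimator_
                s = _class1_scores(best, Xte)
                if not np.all(np.isfinite(s)):
                    est = _make_estimator(fam, cfg, seed + 10_007)
                    search = GridSearchCV(
                        est, grids[fam], cv=inner, scoring="accuracy", n_jobs=1
                    )
                    search.fit(Xtr, ytr)
                    best = search.best_estimator_
                    s = _class1_scores(best, Xte)
                    if not np.all(np.isfinite(s)):
                        raise RuntimeError(f"non-finite scores from {fam}")
                store[fam]["scores"].append(s)
                store[fam]["labels"].append(yte)
                store[fam]["preds"].append(best.predict(Xte))
                store[fam]["params"].append(dict(search.best_params_))

        families = {}
        for fam in cfg.families:
            scores = np.concatenate(store[fam]["scores"])
            labels = np.concatenate(store[fam]["labels"])
            preds = np.concatenate(store[fam]["preds"])
            conf = np.zeros((2, 2), dtype=int)
            for t, p in zip(labels, preds):
                conf[t, p] += 1
            auc, points = roc_auc(scores, labels)
            families[fam] = FamilyResult(
                family=fam,
                confusion=conf,
                accuracy=float(np.trace(conf) / conf.sum()),
                auc=auc,
                roc_points=points,
                chosen_params=store[fam]["params"],
                pooled_scores=scores,
                pooled_labels=labels,
            )
        self.result_ = EnsembleResult(
            families=families,
            classes=classes,
            n_iterations=cfg.n_iterations,
            test_size=n_test,
            mean_auc=float(np.mean([f.auc for f in families.values()])),
            mean_accuracy=float(np.mean([f.accuracy for f in families.values()])),
        )
        return self


def run_ensemble(X, y, cfg: HarnessConfig | None = None) -> EnsembleResult:
    """Run the five-family repeated-holdout validation protocol."""
    return EnsembleValidator(cfg).fit(X, y).result_


def feature_importance(
    X, y, family: str, cfg: HarnessConfig | None = None, seed: int = 0,
    feature_names=None,
) -> ImportanceRanking:
    """Importance ranking from a full-data fit: mean decrease in impurity for
    the random forest, total gain per feature for gradient boosting."""
    cfg = cfg or HarnessConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    y01 = (y == classes[1]).astype(int)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    feature_names = [str(f) for f in feature_names]

    if family == "rf":
        model = RandomForestClassifier(n_estimators=cfg.n_trees, random_state=seed)
        model.fit(X, y01)
        imp = model.feature_importances_
    elif family in ("xgb", "boosting"):
        model = xgb.XGBClassifier(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
            tree_method="exact",
            importance_type="total_gain",
        )
        model.fit(X, y01)
        imp = model.feature_importances_
    else:
        raise ValueError(f"importance is defined for 'rf' or 'xgb', not {family!r}")

    scores = {f: float(s) for f, s in zip(feature_names, imp)}
    order = np.argsort(-imp, kind="stable")
    return ImportanceRanking(
        family=family, scores=scores, ranking=[feature_names[j] for j in order]
    )


def top_n_intersection(
    rank_a: ImportanceRanking, rank_b: ImportanceRanking, n: int = 30
) -> list[str]:
    """Features present in both top-n prefixes, sorted by summed rank."""
    if n > len(rank_a.ranking) or n > len(rank_b.ranking):
        raise ValueError(f"n={n} exceeds ranking length")
    if set(rank_a.ranking) != set(rank_b.ranking):
        raise ValueError("rankings cover different feature universes")
    top_a = rank_a.ranking[:n]
    top_b = set(rank_b.ranking[:n])
    shared = [f for f in top_a if f in top_b]
    pos_a = {f: i for i, f in enumerate(rank_a.ranking)}
    pos_b = {f: i for i, f in enumerate(rank_b.ranking)}
    return sorted(shared, key=lambda f: (pos_a[f] + pos_b[f], f))


def summarize_ensemble(
    aucs: Sequence[float] | EnsembleResult,
    accuracies: Sequence[float] | None = None,
) -> dict:
    """Cross-family arithmetic means at reporting precision (AUC 2 dp,
    accuracy 2 dp percent).  Accepts an :class:`EnsembleResult` or raw
    per-family value sequences."""
    if isinstance(aucs, EnsembleResult):
        res = aucs
        aucs = [f.auc for f in res.families.values()]
        accuracies = [f.accuracy for f in res.families.values()]
    out = {"mean_auc": round(float(np.mean(aucs)), 2)}
    if accuracies is not None:
        acc = np.asarray(accuracies, dtype=float)
        if np.all(acc <= 1.0):
            acc = acc * 100.0
        out["mean_accuracy_pct"] = round(float(np.mean(acc)), 2)
    return out
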