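"""Orthogonal partial least squares discriminant analysis (O-PLS-DA).

Two-class discriminant PLS in which variation in X that is orthogonal to the
class label is stripped into separate components before a single predictive
component is fit by NIPALS.  The split makes the predictive score directly
interpretable: between-class variation lives in ``t_p``, within-class
structure in the orthogonal scores.

Model quality is summarized by R2Y (in-sample fraction of label variance
explained) and Q2 (the cross-validated analogue, via 7-fold venetian-blind
CV), and model validity by a label-permutation test.  Variable influence is
ranked by VIP computed on the predictive component, which for this
single-component model satisfies mean(VIP^2) = 1 exactly.

X is autoscaled (zero mean, unit variance) by default, the convention for
O-PLS-DA of compositional omics tables; Pareto scaling is available.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "OPLSDA",
    "PermutationResult",
    "SPlotRow",
    "fit_oplsda",
    "permutation_test",
    "splot",
    "screen_key_taxa",
]


@dataclasses.dataclass
class PermutationResult:
    observed_r2y: float
    observed_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    p_r2y: float
    p_q2: float
    intercept_r2y: float  # intercept of permuted R2Y regressed on |corr(y, y_perm)|
    intercept_q2: float


@dataclasses.dataclass
class SPlotRow:
    feature: str
    p1: float  # covariance of the scaled variable with t_p (magnitude)
    pcorr1: float  # correlation with t_p (reliability)
    vip: float
    excluded: bool = False


def _scale_matrix(X: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if mode == "uv":
        scale = sd.copy()
    elif mode == "pareto":
        scale = np.sqrt(sd)
    else:
        raise ValueError(f"unknown scaling {mode!r}")
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def _opls_core(X: np.ndarray, y: np.ndarray, n_ortho: int):
    """One pass of the orthogonal-filtering + predictive-component algorithm.

    X must already be scaled, y centered.  Returns the predictive weight
    vector, score and loading, the orthogonal weight/score/loading stacks and
    the regression coefficient c linking t_p to y.
    """
    Xf = X.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_ortho):
        w = Xf.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:  # no y-orthogonal variation left
            break
        w_o /= n_o
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf -= np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)
    w = Xf.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("labels carry no covariance with X")
    w /= nw
    t_p = Xf @ w
    p_p = Xf.T @ t_p / (t_p @ t_p)
    c = (y @ t_p) / (t_p @ t_p)
    return w, t_p, p_p, c, (np.array(W_o), np.array(T_o), np.array(P_o)), Xf


def _predict_scores(X: np.ndarray, w, ortho_w, ortho_p) -> np.ndarray:
    Xf = X.copy()
    for w_o, p_o in zip(ortho_w, ortho_p):
        t_o = Xf @ w_o
        Xf -= np.outer(t_o, p_o)
    return Xf @ w


def _q2_cv(X: np.ndarray, y: np.ndarray, n_ortho: int, n_folds: int) -> float:
    """Q2 by venetian-blind cross-validation (fold = sample index mod folds)."""
    n = X.shape[0]
    n_folds = min(n_folds, n)
    folds = np.arange(n) % n_folds
    press = 0.0
    for f in range(n_folds):
        test = folds == f
        Xtr, ytr = X[~test], y[~test]
        w, _, _, c, (W_o, _, P_o), _ = _opls_core(Xtr, ytr, n_ortho)
        t_new = _predict_scores(X[test], w, W_o, P_o)
        press += float(((y[test] - c * t_new) ** 2).sum())
    tss = float((y**2).sum())
    return 1.0 - press / tss


class OPLSDA(BaseEstimator, ClassifierMixin, TransformerMixin):
    """Two-class O-PLS-DA with a single predictive component.

    Parameters
    ----------
    n_ortho : int or "auto", default="auto"
        Number of orthogonal components.  "auto" adds components while
        cross-validated Q2 improves by more than ``auto_tol``, up to
        ``max_ortho``; with no orthogonal structure the model degrades
        gracefully to plain PLS-DA (0 orthogonal components).
    scaling : {"uv", "pareto"}, default="uv"
        Column scaling; "uv" is autoscaling to unit variance.
    n_folds : int, default=7
        Folds for the venetian-blind Q2 estimate (reduced to n_samples when
        larger, with a warning).
    max_ortho : int, default=5
    auto_tol : float, default=0.01

    Attributes
    ----------
    classes_ : ndarray of the two class labels (sorted; second coded +1).
    scores_ : predictive score t_p per training sample.
    loadings_ : predictive loading p_p per variable.
    weights_ : predictive weight vector w.
    ortho_scores_, ortho_loadings_, ortho_weights_ : stacks of shape
        (n_ortho_, n) / (n_ortho_, p).
    r2y_, q2_ : model fit and cross-validated predictability.
    vip_ : VIP per variable (NaN for variables dropped as zero-variance).
    n_ortho_ : orthogonal components actually fitted.
    """

    def __init__(self, n_ortho="auto", scaling="uv", n_folds=7, max_ortho=5, auto_tol=0.01):
        self.n_ortho = n_ortho
        self.scaling = scaling
        self.n_folds = n_folds
        self.max_ortho = max_ortho
        self.auto_tol = auto_tol

    def _encode_y(self, y) -> np.ndarray:
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(f"O-PLS-DA needs exactly 2 classes, got {self.classes_}")
        coded = np.where(y == self.classes_[1], 1.0, -1.0)
        for cls in self.classes_:
            if (y == cls).sum() < 3:
                raise ValueError(f"need >=3 samples per class (class {cls!r})")
        return coded

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be samples x variables")
        coded = self._encode_y(y)
        n, p = X.shape

        variances = X.std(axis=0, ddof=1)
        keep = variances > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance variable(s)",
                UserWarning,
                stacklevel=2,
            )
        self.retained_ = keep
        Xk = X[:, keep]

        Z, self.x_mean_, self.x_scale_ = _scale_matrix(Xk, self.scaling)
        self.y_mean_ = coded.mean()
        yc = coded - self.y_mean_

        n_folds = self.n_folds
        if n_folds > n:
            warnings.warn(f"reducing CV folds to n_samples={n}", UserWarning, stacklevel=2)
            n_folds = n

        if self.n_ortho == "auto":
            best_no, best_q2 = 0, _q2_cv(Z, yc, 0, n_folds)
            for cand in range(1, self.max_ortho + 1):
                q2 = _q2_cv(Z, yc, cand, n_folds)
                if q2 > best_q2 + self.auto_tol:
                    best_no, best_q2 = cand, q2
                else:
                    break
            n_ortho = best_no
            self.q2_ = best_q2
        else:
            n_ortho = int(self.n_ortho)
            self.q2_ = _q2_cv(Z, yc, n_ortho, n_folds)

        w, t_p, p_p, c, (W_o, T_o, P_o), Xf = _opls_core(Z, yc, n_ortho)
        self.weights_ = w
        self.scores_ = t_p
        self.loadings_ = p_p
        self.coef_c_ = float(c)
        self.ortho_weights_ = W_o.reshape(-1, Z.shape[1])
        self.ortho_scores_ = T_o.reshape(-1, n)
        self.ortho_loadings_ = P_o.reshape(-1, Z.shape[1])
        self.n_ortho_ = self.ortho_weights_.shape[0]
        self._filtered_X_ = Xf

        resid = yc - c * t_p
        self.r2y_ = 1.0 - float((resid**2).sum()) / float((yc**2).sum())

        # VIP on the predictive component: with one component the usual
        # weighted sum collapses to sqrt(p) * |w_j| / ||w||.
        vip_kept = np.sqrt(Z.shape[1]) * np.abs(w) / np.linalg.norm(w)
        self.vip_ = np.full(p, np.nan)
        self.vip_[keep] = vip_kept
        self.n_features_in_ = p
        return self

    def _scale_new(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.retained_]
        return (X - self.x_mean_) / self.x_scale_

    def transform(self, X) -> np.ndarray:
        """Predictive score t_p for new samples (orthogonal variation removed)."""
        check_is_fitted(self, "weights_")
        Z = self._scale_new(X)
        return _predict_scores(Z, self.weights_, self.ortho_weights_, self.ortho_loadings_)

    def decision_function(self, X) -> np.ndarray:
        return self.coef_c_ * self.transform(X) + self.y_mean_

    def predict(self, X):
        check_is_fitted(self, "weights_")
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def fit_oplsda(X, y, n_ortho="auto", **kwargs) -> OPLSDA:
    """Convenience wrapper: fit an :class:`OPLSDA` model."""
    return OPLSDA(n_ortho=n_ortho, **kwargs).fit(X, y)


def permutation_test(
    X,
    y,
    n_ortho="auto",
    n_perm: int = 200,
    seed: int | None = None,
    **model_kwargs,
) -> PermutationResult:
    """Label-permutation validity test for the O-PLS-DA model.

    The model is refit on ``n_perm`` random permutations of y; p-values use
    the add-one estimator (#{permuted >= observed} + 1) / (n_perm + 1), so the
    attainable minimum at 200 permutations is 1/201 < 0.005.
    """
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives very coarse p-values", UserWarning, stacklevel=2)
    y = np.asarray(y)
    model = OPLSDA(n_ortho=n_ortho, **model_kwargs).fit(X, y)
    rng = np.random.default_rng(seed)
    r2s = np.empty(n_perm)
    q2s = np.empty(n_perm)
    cors = np.empty(n_perm)
    coded = np.where(y == model.classes_[1], 1.0, -1.0)
    for i in range(n_perm):
        perm = rng.permutation(y.shape[0])
        m = OPLSDA(n_ortho=n_ortho, **model_kwargs).fit(X, y[perm])
        r2s[i], q2s[i] = m.r2y_, m.q2_
        cors[i] = abs(float(np.corrcoef(coded, coded[perm])[0, 1]))
    p_r2y = (int((r2s >= model.r2y_).sum()) + 1) / (n_perm + 1)
    p_q2 = (int((q2s >= model.q2_).sum()) + 1) / (n_perm + 1)

    def _intercept(stat: np.ndarray) -> float:
        slope, intercept = np.polyfit(cors, stat, 1)
        return float(intercept)

    return PermutationResult(
        observed_r2y=model.r2y_,
        observed_q2=model.q2_,
        permuted_r2y=r2s,
        permuted_q2=q2s,
        p_r2y=p_r2y,
        p_q2=p_q2,
        intercept_r2y=_intercept(r2s),
        intercept_q2=_intercept(q2s),
    )


def splot(model: OPLSDA, X, feature_names=None) -> list[SPlotRow]:
    """S-plot statistics: covariance (p1) vs correlation (pcorr1) of each
    variable with the predictive score, on the model's training X."""
    check_is_fitted(model, "weights_")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    t = model.scores_
    tc = t - t.mean()
    rows = []
    for j in range(p):
        if not model.retained_[j]:
            rows.append(SPlotRow(str(feature_names[j]), np.nan, np.nan, np.nan, excluded=True))
            continue
        xj = X[:, j]
        xc = xj - xj.mean()
        # covariance on the scaled variable, correlation on the raw one
        jj = int(model.retained_[: j + 1].sum()) - 1
        z = xc / model.x_scale_[jj]
        p1 = float((tc * z).sum() / (n - 1))
        denom = np.sqrt(float((tc**2).sum()) * float((xc**2).sum()))
        pcorr1 = float((tc * xc).sum() / denom) if denom > 0 else np.nan
        rows.append(SPlotRow(str(feature_names[j]), p1, pcorr1, float(model.vip_[j])))
    rows.sort(key=lambda r: (np.isnan(r.p1), r.p1))
    return rows


def screen_key_taxa(
    model: OPLSDA, feature_names=None, threshold: float = 1.0
) -> list[str]:
    """Features with VIP strictly above ``threshold``, ranked by VIP descending."""
    check_is_fitted(model, "vip_")
    vip = model.vip_
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(vip.size)]
    order = [
        j for j in np.argsort(-np.nan_to_num(vip, nan=-1.0), kind="stable")
        if np.isfinite(vip[j]) and vip[j] > threshold
    ]
    return [str(feature_names[j]) for j in order]
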