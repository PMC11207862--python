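"""Taxa / nutrient / quality interaction analyses: redundancy analysis,
correlation networks, and PLS path modeling (PLS-SEM).

The path model is the Lohmoller PLS-PM algorithm with mode-A (correlation)
outer weights and the centroid inner scheme: latent scores are iterated
between outer and inner approximations to convergence, path coefficients are
then ordinary least squares of each endogenous latent on its predecessors,
and significance comes from bootstrap resampling of samples.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "RdaResult",
    "NetworkEdge",
    "CorrelationNetwork",
    "PathModelResult",
    "RDA",
    "rda",
    "correlation_network",
    "PLSPathModel",
    "pls_sem",
]


# ---------------------------------------------------------------------------
# Redundancy analysis
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RdaResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    proportion_constrained: float
    site_scores: np.ndarray  # samples x constrained axes
    response_scores: np.ndarray  # response variables x constrained axes
    biplot_scores: np.ndarray  # explanatory variables x constrained axes


class RDA(BaseEstimator):
    """Correlation RDA: responses and constraints are both standardized, each
    response column is regressed on the constraints, and the fitted and
    residual covariances are eigen-decomposed separately."""

    def __init__(self, scale_responses: bool = True):
        self.scale_responses = scale_responses

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must cover the same samples")
        n = X.shape[0]

        def _std(M, scale=True):
            M = M - M.mean(axis=0)
            if scale:
                sd = M.std(axis=0, ddof=1)
                sd[sd == 0] = 1.0
                M = M / sd
            return M

        Xs = _std(X)
        Ys = _std(Y, scale=self.scale_responses)

        # rank-reduced least squares guards against collinear constraints
        B, _, rank, _ = np.linalg.lstsq(Xs, Ys, rcond=None)
        if rank < X.shape[1]:
            logger.info("collinear constraints: rank %d < %d columns", rank, X.shape[1])
        if n <= rank:
            raise ValueError("need more samples than the rank of the constraints")
        Yhat = Xs @ B
        Yres = Ys - Yhat

        def _eig(M):
            cov = M.T @ M / (n - 1)
            vals, vecs = np.linalg.eigh(cov)
            order = np.argsort(vals)[::-1]
            vals = np.clip(vals[order], 0, None)
            return vals, vecs[:, order]

        c_vals, c_vecs = _eig(Yhat)
        u_vals, _ = _eig(Yres)
        n_axes = min(rank, Y.shape[1])
        c_vals, c_vecs = c_vals[:n_axes], c_vecs[:, :n_axes]

        total = float(Ys.var(axis=0, ddof=1).sum())
        site = Yhat @ c_vecs
        with np.errstate(invalid="ignore", divide="ignore"):
            biplot = np.corrcoef(Xs.T, site.T)[: X.shape[1], X.shape[1]:]
        self.result_ = RdaResult(
            constrained_eigenvalues=c_vals,
            unconstrained_eigenvalues=u_vals,
            proportion_constrained=float(c_vals.sum() / total),
            site_scores=site,
            response_scores=c_vecs,
            biplot_scores=np.nan_to_num(biplot),
        )
        return self


def rda(Y, X) -> RdaResult:
    """Redundancy analysis of responses ``Y`` constrained by ``X``."""
    return RDA().fit(X, Y).result_


# ---------------------------------------------------------------------------
# Correlation network
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    r: float
    p_adjusted: float
    sign: int


@dataclasses.dataclass
class CorrelationNetwork:
    nodes: list[str]
    edges: list[NetworkEdge]


def correlation_network(
    features: pd.DataFrame, r_min: float = 0.6, p_max: float = 0.05
) -> CorrelationNetwork:
    """All-pairs Pearson network with BH-adjusted two-sided p-values; keeps
    edges with |r| >= r_min and adjusted p <= p_max."""
    n = features.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for correlation p-values")
    keep = [c for c in features.columns if features[c].std() > 0]
    dropped = set(features.columns) - set(keep)
    if dropped:
        logger.info("excluding zero-variance variables: %s", sorted(dropped))
    M = features[keep].to_numpy(dtype=float)
    r = np.corrcoef(M.T)
    names = [str(c) for c in keep]

    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    rs = np.array([r[i, j] for i, j in pairs])
    # two-sided p from the t transform of r
    with np.errstate(divide="ignore"):
        t = rs * np.sqrt((n - 2) / np.clip(1 - rs**2, 1e-300, None))
    ps = 2 * stats.t.sf(np.abs(t), df=n - 2)
    _, adj, _, _ = multipletests(ps, method="fdr_bh")

    edges = [
        NetworkEdge(names[i], names[j], float(rv), float(q), 1 if rv >= 0 else -1)
        for (i, j), rv, q in zip(pairs, rs, adj)
        if abs(rv) >= r_min and q <= p_max
    ]
    return CorrelationNetwork(nodes=names, edges=edges)


# ---------------------------------------------------------------------------
# PLS path modeling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PathModelResult:
    blocks: dict[str, list[str]]
    latent_scores: pd.DataFrame  # samples x latents, standardized
    outer_weights: dict[str, dict[str, float]]
    path_coefficients: dict[tuple[str, str], float]  # (source, target) -> beta
    bootstrap_se: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    r_squared: dict[str, float]
    n_iterations: int


def _toposort(paths: dict[str, list[str]], latents: list[str]) -> list[str]:
    order, seen, visiting = [], set(), set()

    def visit(node):
        if node in seen:
            return
        if node in visiting:
            raise ValueError("cyclic path matrix")
        visiting.add(node)
        for pred in paths.get(node, []):
            visit(pred)
        visiting.discard(node)
        seen.add(node)
        order.append(node)

    for lv in latents:
        visit(lv)
    return order


class PLSPathModel(BaseEstimator):
    """PLS-SEM with mode-A outer weights and the centroid inner scheme.

    Parameters
    ----------
    blocks : dict latent name -> list of indicator column names
    inner_paths : dict target latent -> list of source latents (a DAG)
    n_boot : int, default=500
        Bootstrap resamples for path-coefficient standard errors; p-values
        use the normal approximation coefficient/SE.
    tol : float, default=1e-6
        Convergence threshold on the change in outer weights.
    max_iter : int, default=300
    seed : int or None
    """

    def __init__(self, blocks=None, inner_paths=None, n_boot=500, tol=1e-6,
                 max_iter=300, seed=None):
        self.blocks = blocks
        self.inner_paths = inner_paths
        self.n_boot = n_boot
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def _neighbors(self) -> dict[str, list[str]]:
        adj: dict[str, set] = {lv: set() for lv in self.blocks}
        for tgt, srcs in self.inner_paths.items():
            for s in srcs:
                adj[tgt].add(s)
                adj[s].add(tgt)
        return {lv: sorted(nb) for lv, nb in adj.items()}

    def _iterate_weights(self, Xb: dict[str, np.ndarray]):
        latents = list(self.blocks)
        adj = self._neighbors()
        n = next(iter(Xb.values())).shape[0]

        def _std(v):
            return (v - v.mean()) / v.std()

        weights = {lv: np.ones(Xb[lv].shape[1]) for lv in latents}
        scores = {lv: _std(Xb[lv] @ weights[lv]) for lv in latents}
        trace = []
        for it in range(self.max_iter):
            # inner approximation, centroid scheme
            inner = {}
            for lv in latents:
                z = np.zeros(n)
                for nb in adj[lv]:
                    e = np.corrcoef(scores[lv], scores[nb])[0, 1]
                    z += np.sign(e) * scores[nb]
                inner[lv] = _std(z) if z.std() > 0 else scores[lv]
            # outer approximation, mode A: correlation weights
            new_weights, new_scores, delta = {}, {}, 0.0
            for lv in latents:
                w = Xb[lv].T @ inner[lv] / n
                if np.linalg.norm(w) == 0:
                    raise ValueError(f"block {lv!r} uncorrelated with inner estimate")
                if w.sum() < 0:  # deterministic orientation
                    w = -w
                wn = w / np.linalg.norm(w)
                old = weights[lv] / np.linalg.norm(weights[lv])
                delta = max(delta, float(np.abs(wn - old).max()))
                new_weights[lv] = w
                new_scores[lv] = _std(Xb[lv] @ w)
            weights, scores = new_weights, new_scores
            trace.append(delta)
            if delta < self.tol:
                return weights, scores, it + 1
        raise RuntimeError(
            f"PLS-PM did not converge in {self.max_iter} iterations; "
            f"last weight changes: {trace[-5:]}"
        )

    def _paths_from_scores(self, scores: dict[str, np.ndarray]):
        coefs: dict[tuple[str, str], float] = {}
        r2: dict[str, float] = {}
        for tgt, srcs in self.inner_paths.items():
            if not srcs:
                continue
            A = np.column_stack([scores[s] for s in srcs])
            b, _, _, _ = np.linalg.lstsq(
                np.column_stack([np.ones(A.shape[0]), A]), scores[tgt], rcond=None
            )
            for s, beta in zip(srcs, b[1:]):
                coefs[(s, tgt)] = float(beta)
            fitted = np.column_stack([np.ones(A.shape[0]), A]) @ b
            r2[tgt] = float(1 - ((scores[tgt] - fitted) ** 2).sum()
                            / (scores[tgt] ** 2).sum())
        return coefs, r2

    def fit(self, data: pd.DataFrame):
        if not self.blocks or self.inner_paths is None:
            raise ValueError("blocks and inner_paths are required")
        _toposort(self.inner_paths, list(self.blocks))  # raises on cycles
        for lv, inds in self.blocks.items():
            if not inds:
                raise ValueError(f"block {lv!r} has no indicators")
            missing = [c for c in inds if c not in data.columns]
            if missing:
                raise KeyError(f"indicators missing from data: {missing}")

        def _block_matrices(df: pd.DataFrame) -> dict[str, np.ndarray]:
            out = {}
            for lv, inds in self.blocks.items():
                M = df[inds].to_numpy(dtype=float)
                sd = M.std(axis=0)
                if np.any(sd == 0):
                    raise ValueError(f"zero-variance indicator in block {lv!r}")
                out[lv] = (M - M.mean(axis=0)) / sd
            return out

        Xb = _block_matrices(data)
        weights, scores, n_iter = self._iterate_weights(Xb)
        coefs, r2 = self._paths_from_scores(scores)

        rng = np.random.default_rng(self.seed)
        boot: dict[tuple[str, str], list[float]] = {k: [] for k in coefs}
        n = data.shape[0]
        failures = 0
        for _ in range(self.n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                Xb_b = _block_matrices(data.iloc[idx])
                _, scores_b, _ = self._iterate_weights(Xb_b)
                coefs_b, _ = self._paths_from_scores(scores_b)
            except (ValueError, RuntimeError):
                failures += 1
                continue
            for k in boot:
                boot[k].append(coefs_b[k])
        if failures:
            logger.info("%d bootstrap resamples failed and were skipped", failures)

        se = {k: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
              for k, v in boot.items()}
        pvals = {}
        for k, beta in coefs.items():
            if se[k] > 0:
                pvals[k] = float(2 * stats.norm.sf(abs(beta) / se[k]))
            else:
                pvals[k] = float("nan")

        self.result_ = PathModelResult(
            blocks={lv: list(inds) for lv, inds in self.blocks.items()},
            latent_scores=pd.DataFrame(
                {lv: scores[lv] for lv in self.blocks}, index=data.index
            ),
            outer_weights={
                lv: {ind: float(w) for ind, w in zip(self.blocks[lv], weights[lv])}
                for lv in self.blocks
            },
            path_coefficients=coefs,
            bootstrap_se=se,
            p_values=pvals,
            r_squared=r2,
            n_iterations=n_iter,
        )
        return self


def pls_sem(
    data: pd.DataFrame,
    blocks: dict[str, list[str]],
    inner_paths: dict[str, list[str]],
    n_boot: int = 500,
    seed: int | None = None,
) -> PathModelResult:
    """Fit the PLS path model and return its result record."""
    if n_boot < 100:
        logger.warning("n_boot < 100 gives unreliable bootstrap p-values")
    model = PLSPathModel(
        blocks=blocks, inner_paths=inner_paths, n_boot=n_boot, seed=seed
    )
    return model.fit(data).result_
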