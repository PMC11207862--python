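"""Alpha-diversity estimators, sampling-adequacy curves and Bray-Curtis
dissimilarity.

Conventions: Shannon uses the natural log (a log2 variant is available via
``base``); Simpson is reported as Gini-Simpson, 1 - sum(p_i^2); Chao1 uses the
classic singleton/doubleton estimator with the bias-corrected fallback only
when no doubletons are present.  Rarefaction is the analytic hypergeometric
expectation, not Monte Carlo.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from .tables import AbundanceTable, to_relative_abundance
from .simulate import subsample_reads

__all__ = [
    "AlphaDiversity",
    "Curve",
    "alpha_diversity",
    "alpha_diversity_table",
    "rarefaction_curve",
    "shannon_depth_curve",
    "rank_abundance",
    "species_accumulation",
    "bray_curtis_matrix",
]


@dataclasses.dataclass(frozen=True)
class AlphaDiversity:
    observed_richness: int
    shannon: float
    simpson: float
    chao1: float


@dataclasses.dataclass(frozen=True)
class Curve:
    x: np.ndarray
    y: np.ndarray
    dispersion: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y lengths differ")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")


def _check_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("expected a single sample's count vector")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if counts.sum() == 0:
        raise ValueError("all-zero count vector")
    return counts


def shannon(counts, base: float = math.e) -> float:
    counts = _check_counts(counts)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum() / math.log(base))


def simpson(counts) -> float:
    """Gini-Simpson index, 1 - sum p_i^2."""
    counts = _check_counts(counts)
    p = counts / counts.sum()
    return float(1.0 - (p**2).sum())


def chao1(counts) -> float:
    counts = _check_counts(counts)
    if not np.allclose(counts, counts.round()):
        raise ValueError("Chao1 requires integer counts")
    counts = counts.round().astype(int)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1**2 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / 2


def alpha_diversity(counts, base: float = math.e) -> AlphaDiversity:
    """All alpha estimators for one sample's counts."""
    counts = _check_counts(counts)
    return AlphaDiversity(
        observed_richness=int((counts > 0).sum()),
        shannon=shannon(counts, base=base),
        simpson=simpson(counts),
        chao1=chao1(counts),
    )


def alpha_diversity_table(table: AbundanceTable, base: float = math.e) -> pd.DataFrame:
    """Per-sample alpha diversity as a DataFrame indexed by sample id."""
    rows = {
        s: dataclasses.asdict(alpha_diversity(table.values[:, j], base=base))
        for j, s in enumerate(table.sample_ids)
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefaction_curve(counts, depths) -> Curve:
    """Analytic expected richness at each subsampling depth:
    E[S(d)] = sum_i 1 - C(N - N_i, d) / C(N, d)."""
    counts = _check_counts(counts)
    if not np.allclose(counts, counts.round()):
        raise ValueError("rarefaction requires integer counts")
    counts = counts.round().astype(np.int64)
    n_total = int(counts.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if np.any(depths > n_total):
        raise ValueError(f"depth exceeds total reads ({n_total})")
    if np.any(depths < 0):
        raise ValueError("negative depth")
    pos = counts[counts > 0]
    expected = np.empty(depths.shape, dtype=float)
    for k, d in enumerate(depths):
        # log C(N - N_i, d) - log C(N, d), with C(m, d) = 0 when m < d
        m = n_total - pos
        ok = m >= d
        log_ratio = np.full(pos.shape, -np.inf)
        log_ratio[ok] = (
            gammaln(m[ok] + 1)
            - gammaln(d + 1)
            - gammaln(m[ok] - d + 1)
            - (gammaln(n_total + 1) - gammaln(d + 1) - gammaln(n_total - d + 1))
        )
        expected[k] = (1.0 - np.exp(log_ratio)).sum()
    return Curve(x=depths.astype(float), y=expected)


def shannon_depth_curve(counts, depths, n_rep: int = 10, seed: int | None = None) -> Curve:
    """Mean Shannon index over ``n_rep`` random subsamples at each depth."""
    counts = _check_counts(counts)
    table = AbundanceTable(
        pd.DataFrame({"s": counts.round().astype(int)}), unit="counts"
    )
    rng = np.random.default_rng(seed)
    depths = np.asarray(depths, dtype=int)
    means, sds = [], []
    for d in depths:
        vals = []
        for _ in range(n_rep):
            sub = subsample_reads(table, int(d), seed=int(rng.integers(2**31)))
            vals.append(shannon(sub.values[:, 0]))
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals)))
    return Curve(x=depths.astype(float), y=np.array(means), dispersion=np.array(sds))


def rank_abundance(counts) -> Curve:
    """Relative abundances sorted descending; zeros dropped; rank starts at 1.

    Ties keep the original taxon order (stable sort)."""
    counts = _check_counts(counts)
    p = counts / counts.sum()
    order = np.argsort(-p, kind="stable")
    y = p[order]
    y = y[y > 0]
    return Curve(x=np.arange(1, y.size + 1, dtype=float), y=y)


def species_accumulation(
    table: AbundanceTable, n_perm: int = 100, seed: int | None = None
) -> Curve:
    """Mean richness of the union of k samples over random sample orders."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    present = table.values > 0
    rng = np.random.default_rng(seed)
    n = table.n_samples
    acc = np.zeros(n)
    for _ in range(n_perm):
        order = rng.permutation(n)
        seen = np.zeros(table.n_taxa, dtype=bool)
        for k, j in enumerate(order):
            seen |= present[:, j]
            acc[k] += seen.sum()
    return Curve(x=np.arange(1, n + 1, dtype=float), y=acc / n_perm)


def bray_curtis_matrix(table: AbundanceTable, on_relative: bool = True) -> pd.DataFrame:
    """Symmetric sample-by-sample Bray-Curtis dissimilarity matrix.

    Computed on relative abundances by default so unequal sequencing depths do
    not register as community differences."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    values = table.values
    if np.any(values.sum(axis=0) == 0):
        raise ValueError("all-zero sample column")
    if on_relative:
        values = to_relative_abundance(table).values
    d = squareform(pdist(values.T, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)
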