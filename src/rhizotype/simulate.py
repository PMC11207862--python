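"""Dirichlet-multinomial simulator for genus-level abundance tables with a
planted two-group structure and chained nutrient -> quality phenotypes.

The generator emulates a rhizosphere 16S study design: two groups of tea
cultivars (default 31 + 13 = 44 samples) sharing one steep power-law
rank-abundance background, with a small panel of "characteristic" genera
(default 23, of which 19 are enriched in group A and 4 in group B) whose base
proportions are shifted by a factor of 2^(log2_effect) between groups.  Soil
available N/P/K track the characteristic-taxon load, and leaf quality traits
(polyphenols, theanine, caffeine) track the nutrients — never the taxa
directly — giving the chained causal structure taxa -> nutrients -> quality
that the path-modeling stage is meant to recover.

Counts are drawn per sample as Multinomial(depth_s, p_s) with
p_s ~ Dirichlet(alpha * profile_group), so a single concentration scalar
controls biological overdispersion on top of multinomial sampling noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .tables import AbundanceTable, SampleMetadata, to_relative_abundance

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "subsample_reads",
]

# Per-group (lo, hi) mg/kg ranges observed for soil nutrients and leaf quality.
DEFAULT_NUTRIENT_RANGES = {
    "available_N": {"A": (30.52, 96.38), "B": (20.19, 40.08)},
    "available_P": {"A": (4.95, 12.03), "B": (3.49, 6.02)},
    "available_K": {"A": (60.25, 107.32), "B": (30.24, 68.13)},
}
DEFAULT_QUALITY_RANGES = {
    "polyphenols": {"A": (30.31, 36.90), "B": (23.60, 28.93)},
    "theanine": {"A": (2.94, 4.73), "B": (2.42, 2.91)},
    "caffeine": {"A": (3.02, 5.40), "B": (2.75, 3.13)},
}


@dataclasses.dataclass
class SimulationConfig:
    """Study-design parameters of the simulated dataset."""

    n_samples: int = 44
    group_sizes: tuple[int, int] = (31, 13)
    n_taxa: int = 745
    n_characteristic: int = 23
    n_enriched_in_A: int = 19
    log2_effect: float = 1.6
    sequencing_depth: int = 50_000
    overdispersion: float = 5000.0  # Dirichlet concentration; larger = less noise
    power_law_exponent: float = 0.9
    nutrient_ranges: dict = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_NUTRIENT_RANGES.items()}
    )
    quality_ranges: dict = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_QUALITY_RANGES.items()}
    )
    path_strength: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if sum(self.group_sizes) != self.n_samples:
            raise ValueError("group sizes must sum to n_samples")
        if not (self.n_enriched_in_A <= self.n_characteristic <= self.n_taxa):
            raise ValueError("need n_enriched_in_A <= n_characteristic <= n_taxa")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if self.overdispersion <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if not 0 <= self.path_strength <= 1:
            raise ValueError("path_strength must be in [0, 1]")
        for ranges in (self.nutrient_ranges, self.quality_ranges):
            for var, per_group in ranges.items():
                for g, (lo, hi) in per_group.items():
                    if not lo < hi:
                        raise ValueError(f"range lo >= hi for {var} group {g}")


@dataclasses.dataclass
class GroundTruth:
    """Planted structure used as the oracle in recovery tests."""

    characteristic_taxa: dict[str, str]  # taxon id -> enriched group ("A"/"B")
    groups: dict[str, str]  # sample id -> group label
    taxon_load: dict[str, float]  # latent driver of nutrients
    nutrient_load: dict[str, float]  # latent driver of quality


def _base_profile(cfg: SimulationConfig) -> np.ndarray:
    ranks = np.arange(1, cfg.n_taxa + 1, dtype=float)
    p = ranks ** (-cfg.power_law_exponent)
    return p / p.sum()


def _characteristic_indices(cfg: SimulationConfig) -> np.ndarray:
    # Moderately abundant ranks: detectable but not community-dominating.
    hi = min(250, cfg.n_taxa)
    lo = min(10, hi - cfg.n_characteristic)
    return np.unique(
        np.linspace(lo, hi - 1, cfg.n_characteristic).round().astype(int)
    )


def simulate_dataset(
    cfg: SimulationConfig | None = None,
) -> tuple[AbundanceTable, SampleMetadata, GroundTruth]:
    """Draw one complete synthetic dataset (counts, metadata, ground truth)."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_a, n_b = cfg.group_sizes
    sample_ids = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    groups = ["A"] * n_a + ["B"] * n_b
    taxa_ids = [f"g{i + 1:04d}" for i in range(cfg.n_taxa)]

    base = _base_profile(cfg)
    char_idx = _characteristic_indices(cfg)
    if char_idx.size != cfg.n_characteristic:
        raise ValueError("could not place characteristic taxa distinctly")
    directions = np.array(
        ["A"] * cfg.n_enriched_in_A
        + ["B"] * (cfg.n_characteristic - cfg.n_enriched_in_A)
    )

    profile_b = base.copy()
    profile_a = base.copy()
    factor = 2.0 ** cfg.log2_effect
    profile_a[char_idx[directions == "A"]] *= factor
    profile_a[char_idx[directions == "B"]] /= factor
    profile_a /= profile_a.sum()
    profile_b /= profile_b.sum()

    counts = np.zeros((cfg.n_taxa, cfg.n_samples), dtype=int)
    for j, g in enumerate(groups):
        profile = profile_a if g == "A" else profile_b
        p = rng.dirichlet(cfg.overdispersion * profile)
        depth = rng.poisson(cfg.sequencing_depth)
        counts[:, j] = rng.multinomial(depth, p)

    table = AbundanceTable(
        pd.DataFrame(counts, index=taxa_ids, columns=sample_ids), unit="counts"
    )

    # Latent taxon load: direction-signed z-scores of characteristic relative
    # abundances, averaged and re-standardized across samples.
    rel = to_relative_abundance(table).values
    sign = np.where(directions == "A", 1.0, -1.0)
    char_rel = rel[char_idx, :]
    mu = char_rel.mean(axis=1, keepdims=True)
    sd = char_rel.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    load = (sign[:, None] * (char_rel - mu) / sd).mean(axis=0)
    load = (load - load.mean()) / load.std()

    group_arr = np.array(groups)

    def _chained(ranges: dict, driver: np.ndarray) -> dict[str, np.ndarray]:
        # Phenotypes are functions of the driver alone; group differences
        # emerge through the driver, never from the group label directly.
        # The linear map is anchored so that at full path strength the group
        # means land on the midpoints of the per-group printed ranges.
        mask_a = group_arr == "A"
        mu_a, mu_b = driver[mask_a].mean(), driver[~mask_a].mean()
        out = {}
        for var, per_group in ranges.items():
            mid_a = sum(per_group["A"]) / 2
            mid_b = sum(per_group["B"]) / 2
            half = (per_group["A"][1] - per_group["A"][0]
                    + per_group["B"][1] - per_group["B"][0]) / 4
            if mu_a != mu_b:
                amp = (mid_a - mid_b) / (mu_a - mu_b)
            else:
                amp = half
            # Anchored so that at full path strength the group means sit on
            # the printed midpoints; the half/2 Gaussian term gives
            # within-group spread on the scale of the printed ranges.
            eps = rng.normal(size=cfg.n_samples)
            vals = (
                (mid_a - amp * mu_a)
                + amp * cfg.path_strength * driver
                + (half / 2) * eps
            )
            out[var] = np.clip(vals, 0, None)
        return out

    nutrients = _chained(cfg.nutrient_ranges, load)

    # Quality depends on taxa only through the nutrients.
    nmat = np.column_stack(list(nutrients.values()))
    nz = (nmat - nmat.mean(axis=0)) / nmat.std(axis=0)
    nutrient_load = nz.mean(axis=1)
    nutrient_load = (nutrient_load - nutrient_load.mean()) / nutrient_load.std()
    quality = _chained(cfg.quality_ranges, nutrient_load)

    meta = SampleMetadata(
        pd.DataFrame({"group": groups, **nutrients, **quality}, index=sample_ids)
    )
    truth = GroundTruth(
        characteristic_taxa={
            taxa_ids[i]: d for i, d in zip(char_idx, directions)
        },
        groups=dict(zip(sample_ids, groups)),
        taxon_load=dict(zip(sample_ids, load)),
        nutrient_load=dict(zip(sample_ids, nutrient_load)),
    )
    return table, meta, truth


def subsample_reads(
    table: AbundanceTable, depth: int, seed: int | None = None
) -> AbundanceTable:
    """Rarefy each sample to ``depth`` reads without replacement
    (multivariate hypergeometric draw per column)."""
    if table.unit != "counts":
        raise ValueError("subsampling requires a counts table")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    counts = table.values
    if not np.allclose(counts, counts.round()):
        raise ValueError("subsampling requires integer counts")
    counts = counts.round().astype(np.int64)
    sums = counts.sum(axis=0)
    short = np.flatnonzero(sums < depth)
    if short.size:
        raise ValueError(
            f"depth {depth} exceeds total reads of sample {table.sample_ids[short[0]]!r}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return AbundanceTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        unit="counts",
    )
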