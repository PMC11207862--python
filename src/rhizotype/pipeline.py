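"""End-to-end orchestration: simulate/ingest -> diversity -> cluster ->
screen -> validate -> select -> re-validate -> downstream, from one config.

Each stage writes its summary into a :class:`ResultBundle`; stage outputs are
files (JSON/TSV) so stages can be re-run and inspected independently.  The
whole run is deterministic under a fixed master seed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from .ensemble import (
    HarnessConfig,
    feature_importance,
    run_ensemble,
    summarize_ensemble,
    top_n_intersection,
)
from .grouping import kmeans_groups
from .oplsda import OPLSDA, permutation_test, screen_key_taxa
from .downstream import correlation_network, pls_sem, rda
from .simulate import SimulationConfig, simulate_dataset
from .tables import (
    AbundanceTable,
    ResultBundle,
    SampleMetadata,
    read_abundance_table,
    read_sample_metadata,
    to_relative_abundance,
    write_abundance_table,
    write_results,
    write_sample_metadata,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]

ALL_STAGES = (
    "diversity",
    "cluster",
    "screen",
    "validate",
    "select",
    "revalidate",
    "downstream",
)

NUTRIENTS = ["available_N", "available_P", "available_K"]
QUALITY = ["polyphenols", "theanine", "caffeine"]


@dataclasses.dataclass
class PipelineConfig:
    """One config object driving the whole pipeline."""

    table_path: str | None = None  # None -> simulate
    metadata_path: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    outdir: str = "results"
    simulation: SimulationConfig | None = None
    n_permutations: int = 200
    vip_threshold: float = 1.0
    top_n: int = 30
    harness_iterations: int = 25
    n_boot: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if cfg.stages is not None:
            cfg.stages = tuple(cfg.stages)
        return cfg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _cluster_to_groups(labels: dict[str, int]) -> pd.Series:
    """Name the larger cluster "A" (the convention used throughout)."""
    s = pd.Series(labels)
    counts = s.value_counts()
    mapping = {counts.index[0]: "A"}
    for other in counts.index[1:]:
        mapping[other] = "B" if len(counts) == 2 else f"G{other}"
    return s.map(mapping)


def run_pipeline(cfg: PipelineConfig) -> ResultBundle:
    """Execute the enabled stages in dependency order."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle()
    bundle.stamp(cfg.as_dict(), cfg.seed)

    truth = None
    if cfg.table_path is not None:
        table = read_abundance_table(cfg.table_path)
        meta = (
            read_sample_metadata(cfg.metadata_path)
            if cfg.metadata_path
            else SampleMetadata(pd.DataFrame(index=table.sample_ids))
        )
        bundle.add("input", {"source": str(cfg.table_path),
                             "n_taxa": table.n_taxa, "n_samples": table.n_samples})
    else:
        sim = cfg.simulation or SimulationConfig(seed=cfg.seed)
        table, meta, truth = simulate_dataset(sim)
        write_abundance_table(table, outdir / "abundance.tsv")
        write_sample_metadata(meta, outdir / "metadata.tsv")
        bundle.add("input", {
            "source": "simulation",
            "n_taxa": table.n_taxa,
            "n_samples": table.n_samples,
            "characteristic_taxa": truth.characteristic_taxa,
        })

    rel = to_relative_abundance(table)
    features = rel.data.T  # samples x taxa
    state: dict[str, Any] = {}

    for stage in cfg.stages:
        try:
            _run_stage(stage, cfg, bundle, table, rel, features, meta, state, outdir)
        except Exception as exc:
            write_results(bundle, outdir)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    write_results(bundle, outdir)
    return bundle


def _run_stage(stage, cfg, bundle, table, rel, features, meta, state, outdir):
    seed = cfg.seed

    if stage == "diversity":
        alpha = dv.alpha_diversity_table(table)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        bc = dv.bray_curtis_matrix(table)
        bc.to_csv(outdir / "bray_curtis.tsv", sep="\t")
        bundle.add("diversity", {
            "alpha_mean": alpha.mean().to_dict(),
            "alpha_min": alpha.min().to_dict(),
            "alpha_max": alpha.max().to_dict(),
            "bray_curtis_mean": float(bc.to_numpy()[np.triu_indices(len(bc), 1)].mean()),
        })

    elif stage == "cluster":
        assignment = kmeans_groups(features, k=2, seed=seed)
        groups = _cluster_to_groups(assignment.labels)
        state["groups"] = groups
        groups.rename("group").to_csv(outdir / "groups.tsv", sep="\t")
        bundle.add("cluster", {
            "k": assignment.k,
            "inertia": assignment.inertia,
            "group_sizes": groups.value_counts().to_dict(),
            "groups": groups.to_dict(),
        })

    elif stage == "screen":
        groups = state.get("groups")
        if groups is None:
            groups = meta.groups()
        y = groups.loc[features.index].to_numpy()
        model = OPLSDA(n_ortho="auto").fit(features.to_numpy(), y)
        key = screen_key_taxa(model, features.columns, threshold=cfg.vip_threshold)
        perm = permutation_test(
            features.to_numpy(), y, n_ortho=model.n_ortho_,
            n_perm=cfg.n_permutations, seed=seed,
        )
        state["key_taxa"] = key
        state["groups"] = groups
        pd.Series(model.vip_, index=features.columns, name="vip").to_csv(
            outdir / "vip.tsv", sep="\t"
        )
        bundle.add("screen", {
            "r2y": model.r2y_,
            "q2": model.q2_,
            "n_ortho": model.n_ortho_,
            "p_r2y": perm.p_r2y,
            "p_q2": perm.p_q2,
            "n_key_taxa": len(key),
            "key_taxa": key,
        })

    elif stage in ("validate", "revalidate"):
        feats = state.get("selected_taxa" if stage == "revalidate" else "key_taxa")
        if feats is None:
            raise ValueError(f"{stage} requires a prior screening/selection stage")
        groups = state["groups"]
        hc = HarnessConfig.fast(master_seed=seed, n_iterations=cfg.harness_iterations)
        res = run_ensemble(
            features[feats].to_numpy(), groups.loc[features.index].to_numpy(), hc
        )
        state[f"{stage}_result"] = res
        bundle.add(stage, {
            "n_features": len(feats),
            "per_family": {
                f: {"auc": fr.auc, "accuracy": fr.accuracy,
                    "confusion": fr.confusion.tolist()}
                for f, fr in res.families.items()
            },
            "summary": summarize_ensemble(res),
        })

    elif stage == "select":
        key = state.get("key_taxa")
        if key is None:
            raise ValueError("select requires the screen stage")
        groups = state["groups"]
        y = groups.loc[features.index].to_numpy()
        X = features[key].to_numpy()
        rf = feature_importance(X, y, "rf", seed=seed, feature_names=key)
        boost = feature_importance(X, y, "xgb", seed=seed, feature_names=key)
        selected = top_n_intersection(rf, boost, n=min(cfg.top_n, len(key)))
        state["selected_taxa"] = selected
        bundle.add("select", {
            "top_n": cfg.top_n,
            "n_selected": len(selected),
            "selected_taxa": selected,
            "rf_top": rf.ranking[: cfg.top_n],
            "xgb_top": boost.ranking[: cfg.top_n],
        })

    elif stage == "downstream":
        selected = state.get("selected_taxa") or state.get("key_taxa")
        if selected is None:
            raise ValueError("downstream requires screening/selection")
        chem = meta.measurements(NUTRIENTS + QUALITY)
        taxa_df = features[selected]
        r = rda(taxa_df.to_numpy(), chem.to_numpy())
        net = correlation_network(pd.concat([taxa_df, chem], axis=1))
        blocks = {
            "taxa": list(selected),
            "nutrients": NUTRIENTS,
            "quality": QUALITY,
        }
        paths = {"nutrients": ["taxa"], "quality": ["nutrients"]}
        sem = pls_sem(
            pd.concat([taxa_df, chem], axis=1), blocks, paths,
            n_boot=cfg.n_boot, seed=seed,
        )
        bundle.add("downstream", {
            "rda_proportion_constrained": r.proportion_constrained,
            "network_n_edges": len(net.edges),
            "path_coefficients": {
                f"{s}->{t}": c for (s, t), c in sem.path_coefficients.items()
            },
            "path_p_values": {
                f"{s}->{t}": p for (s, t), p in sem.p_values.items()
            },
            "r_squared": sem.r_squared,
        })

    else:
        raise ValueError(f"unknown stage {stage!r}")


def render_report(bundle: ResultBundle, directory: str | Path) -> Path:
    """Write a human-readable markdown summary of a pipeline run."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["# Pipeline report", ""]

    def section(title, name, body):
        lines.append(f"## {title}")
        if name not in bundle.stages:
            lines.append("_not run_")
        else:
            body(bundle.stages[name])
        lines.append("")

    def _input(s):
        lines.append(f"- source: {s['source']}")
        lines.append(f"- table: {s['n_taxa']} taxa x {s['n_samples']} samples")

    def _cluster(s):
        sizes = ", ".join(f"{g}: {n}" for g, n in sorted(s["group_sizes"].items()))
        lines.append(f"- k = {s['k']}; group sizes: {sizes}")

    def _screen(s):
        lines.append(f"- R2Y = {s['r2y']:.3f}, Q2 = {s['q2']:.3f} "
                     f"({s['n_ortho']} orthogonal components)")
        lines.append(f"- permutation p(R2Y) = {s['p_r2y']:.4g}, "
                     f"p(Q2) = {s['p_q2']:.4g}")
        lines.append(f"- key taxa (VIP > 1): {s['n_key_taxa']}")

    def _validate(s):
        lines.append(f"- features used: {s['n_features']}")
        lines.append("")
        lines.append("| family | AUC | accuracy |")
        lines.append("|--------|-----|----------|")
        for fam, fr in s["per_family"].items():
            lines.append(f"| {fam} | {fr['auc']:.2f} | {fr['accuracy'] * 100:.2f}% |")
        summ = s["summary"]
        lines.append(f"| **mean** | **{summ['mean_auc']:.2f}** | "
                     f"**{summ['mean_accuracy_pct']:.2f}%** |")

    def _select(s):
        lines.append(f"- RF top-{s['top_n']} / boosting top-{s['top_n']} "
                     f"intersection: {s['n_selected']} taxa")

    def _downstream(s):
        lines.append(f"- RDA proportion constrained: "
                     f"{s['rda_proportion_constrained']:.3f}")
        lines.append(f"- network edges kept: {s['network_n_edges']}")
        for path, coef in s["path_coefficients"].items():
            p = s["path_p_values"][path]
            lines.append(f"- path {path}: beta = {coef:.3f} (p = {p:.2g})")

    section("Input", "input", _input)
    section("Diversity", "diversity", lambda s: lines.extend(
        f"- {k}: mean {v:.4g}" for k, v in s["alpha_mean"].items()))
    section("Grouping", "cluster", _cluster)
    section("Key-taxon screening (O-PLS-DA)", "screen", _screen)
    section("Validation on screened taxa", "validate", _validate)
    section("Importance intersection", "select", _select)
    section("Re-validation on selected taxa", "revalidate", _validate)
    section("Taxa / nutrients / quality", "downstream", _downstream)

    path = directory / "report.md"
    path.write_text("\n".join(lines))
    return path
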