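"""Canonical abundance-table data model, readers/writers and basic transforms.

The canonical orientation is taxa rows x sample columns, the usual OTU-table
convention.  Tables carry a ``unit`` tag distinguishing raw read counts from
relative abundances (columns summing to one); operations that require one or
the other validate the tag and fail fast.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "ResultBundle",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "to_relative_abundance",
    "dominant_taxa",
    "write_results",
    "read_results",
]

Unit = Literal["counts", "relative"]

_METADATA_COLUMNS = (
    "group",
    "available_N",
    "available_P",
    "available_K",
    "polyphenols",
    "theanine",
    "caffeine",
)


@dataclasses.dataclass(frozen=True)
class AbundanceTable:
    """Taxa x samples abundance matrix with axis labels.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative matrix, taxa as the index and samples as columns.
    unit : {"counts", "relative"}
        Whether entries are raw read counts or per-sample fractions.
    """

    data: pd.DataFrame
    unit: Unit = "counts"

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxa ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("abundance table must be numeric")
        if not np.all(np.isfinite(values)):
            raise ValueError("abundance table contains non-finite values")
        neg = np.argwhere(values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative abundance at taxon {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        if self.unit == "relative":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = df.columns[np.argmax(np.abs(sums - 1.0))]
                raise ValueError(f"relative-abundance column {bad!r} does not sum to 1")
        elif self.unit != "counts":
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def taxa_ids(self) -> list[str]:
        return [str(t) for t in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_taxa(self, taxa: list[str]) -> "AbundanceTable":
        missing = [t for t in taxa if t not in self.data.index]
        if missing:
            raise KeyError(f"taxa not in table: {missing}")
        return AbundanceTable(self.data.loc[taxa], unit=self.unit)

    def select_samples(self, samples: list[str]) -> "AbundanceTable":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.data[samples], unit=self.unit)


@dataclasses.dataclass(frozen=True)
class SampleMetadata:
    """Per-sample records: group label plus soil-nutrient and quality assays.

    Stored as a DataFrame indexed by sample id with columns ``group`` (optional
    "A"/"B"), ``available_N/P/K`` and ``polyphenols``, ``theanine``,
    ``caffeine`` (all mg/kg).  Missing measurements are allowed (NaN / None);
    stages that need a field raise naming it.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        for col in df.columns:
            if col == "group":
                continue
            vals = pd.to_numeric(df[col], errors="coerce")
            if (vals.dropna() < 0).any():
                bad = df.index[vals < 0][0]
                raise ValueError(f"negative {col} for sample {bad!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def groups(self) -> pd.Series:
        if "group" not in self.data.columns or self.data["group"].isna().any():
            raise ValueError("metadata field 'group' is missing or incomplete")
        return self.data["group"]

    def measurements(self, fields: list[str]) -> pd.DataFrame:
        missing = [f for f in fields if f not in self.data.columns]
        if missing:
            raise ValueError(f"metadata fields missing: {missing}")
        out = self.data[fields].apply(pd.to_numeric)
        if out.isna().any().any():
            col = out.columns[out.isna().any()][0]
            raise ValueError(f"metadata field {col!r} has missing values")
        return out


@dataclasses.dataclass
class ResultBundle:
    """Stage name -> JSON-serializable result record, plus provenance."""

    stages: dict[str, Any] = dataclasses.field(default_factory=dict)
    provenance: dict[str, Any] = dataclasses.field(default_factory=dict)

    def add(self, name: str, record: Any) -> None:
        self.stages[name] = record

    def stamp(self, config: Any, seed: int) -> None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        self.provenance = {
            "config_hash": hashlib.sha256(blob).hexdigest(),
            "master_seed": int(seed),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }


def read_abundance_table(
    path: str | Path,
    orientation: Literal["taxa_rows", "samples_rows", "auto"] = "taxa_rows",
    unit: Unit = "counts",
    known_samples: list[str] | None = None,
) -> AbundanceTable:
    """Read a TSV/CSV abundance table (header row, label column first).

    ``orientation="auto"`` transposes when the row labels, not the column
    labels, match ``known_samples``.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "auto":
        if known_samples is None:
            raise ValueError("orientation='auto' requires known_samples")
        cols_match = len(set(df.columns) & set(known_samples))
        rows_match = len(set(df.index) & set(known_samples))
        if rows_match > cols_match:
            df = df.T
    elif orientation == "samples_rows":
        df = df.T
    elif orientation != "taxa_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return AbundanceTable(df, unit=unit)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.data.to_csv(path, sep=sep, index_label="taxon")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    meta.data.to_csv(path, sep=sep, index_label="sample_id")


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Normalize each sample column to sum to one.

    Idempotent on tables already tagged ``relative``.
    """
    if table.unit == "relative":
        return table
    sums = table.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"all-zero sample column {table.sample_ids[zero[0]]!r}")
    return AbundanceTable(table.data / sums, unit="relative")


def dominant_taxa(table: AbundanceTable, threshold: float = 0.01) -> list[str]:
    """Taxa whose mean relative abundance across samples strictly exceeds
    ``threshold``, sorted by descending mean abundance.

    The mean-of-relative convention keeps unequal sequencing depths from
    biasing the ranking toward deeply-sequenced samples.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    rel = to_relative_abundance(table)
    means = rel.data.mean(axis=1)
    keep = means[means > threshold].sort_values(ascending=False, kind="stable")
    return [str(t) for t in keep.index]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def write_results(bundle: ResultBundle, directory: str | Path) -> list[Path]:
    """Write one JSON file per stage plus a manifest, deterministic key order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(bundle.stages):
        p = directory / f"{name}.json"
        p.write_text(
            json.dumps(_jsonable(bundle.stages[name]), sort_keys=True, indent=1)
        )
        written.append(p)
    manifest = {
        "stages": sorted(bundle.stages),
        "provenance": _jsonable(bundle.provenance),
    }
    mp = directory / "manifest.json"
    mp.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    written.append(mp)
    return written


def read_results(directory: str | Path) -> ResultBundle:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    bundle = ResultBundle(provenance=manifest.get("provenance", {}))
    for name in manifest["stages"]:
        bundle.stages[name] = json.loads((directory / f"{name}.json").read_text())
    return bundle
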