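"""Readers, writers and the shared data model.

Longitudinal microbiome data enters the pipeline as two tab-separated
files: an abundance table (samples x genera, counts or closed relative
abundances) and a sample-metadata table giving, for every sample, the
subject it belongs to, the day it was collected (relative to the
subject's baseline), and optional study / intervention / enterotype
labels.  Optional extras are a rooted Newick tree with branch lengths
(for weighted UniFrac) and a metabolite-exchange table (genus,
metabolite, import/export) emulating curated cross-feeding databases.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "AbundanceTable",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "read_exchange_table",
    "validate_join",
]

_META_REQUIRED = ("sample_id", "subject_id", "day")
_META_OPTIONAL = {"study_id": "none", "intervention": "none", "enterotype": None}


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix.

    ``kind`` is ``"counts"`` for integer read counts and ``"relative"``
    for rows closed to 1.  The matrix is stored as a DataFrame indexed
    by sample id with taxon names as columns.
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"unknown table kind {self.kind!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate taxon names")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("non-finite abundance")
        if (values < 0).any():
            raise ValueError("negative abundance")
        if self.kind == "relative":
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError("relative-abundance rows must sum to 1")

    # -- convenience accessors ------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def to_relative(self) -> "AbundanceTable":
        """Close each row to 1 (identity if already relative)."""
        if self.kind == "relative":
            return self
        sums = self.data.sum(axis=1)
        if (sums <= 0).any():
            bad = self.data.index[sums <= 0][0]
            raise ValueError(f"sample {bad!r} has zero total abundance")
        return AbundanceTable(self.data.div(sums, axis=0), kind="relative")

    def select(self, samples=None, taxa=None) -> "AbundanceTable":
        data = self.data
        if samples is not None:
            data = data.loc[list(samples)]
        if taxa is not None:
            data = data[list(taxa)]
        return AbundanceTable(data, kind=self.kind)


def _infer_kind(data: pd.DataFrame) -> str:
    values = data.to_numpy(dtype=float)
    if np.allclose(values, np.round(values)) and values.max(initial=0) > 1.5:
        return "counts"
    if np.allclose(values.sum(axis=1), 1.0, atol=1e-6):
        return "relative"
    # integer-valued small tables (e.g. presence counts) default to counts
    if np.allclose(values, np.round(values)):
        return "counts"
    raise ValueError("cannot infer table kind: neither integer counts nor closed rows")


def read_abundance_table(
    path, orientation: str = "samples_as_rows", sep: str = "\t", kind: str | None = None
) -> AbundanceTable:
    """Read a TSV abundance table.

    ``orientation`` is explicit (``samples_as_rows`` or ``taxa_as_rows``)
    because square-ish tables are ambiguous.  ``kind`` is inferred when
    not given: integer matrices are counts, rows summing to ~1 are
    relative abundances.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    data = pd.read_csv(path, sep=sep, index_col=0)
    if data.isna().any().any():
        raise ValueError("ragged or missing entries in abundance table")
    if orientation == "taxa_as_rows":
        data = data.T
    data.index = data.index.astype(str)
    data.columns = data.columns.astype(str)
    if kind is None:
        kind = _infer_kind(data)
    return AbundanceTable(data.astype(float), kind=kind)


def write_abundance_table(table: AbundanceTable, path, sep: str = "\t") -> None:
    data = table.data
    if table.kind == "counts":
        data = data.astype(np.int64)
    data.to_csv(path, sep=sep, index_label="sample_id")


def read_metadata(path, sep: str = "\t") -> pd.DataFrame:
    """Read sample metadata; returns rows sorted by (subject_id, day).

    Required columns: sample_id, subject_id, day (integer days from the
    subject's baseline).  Optional: study_id, intervention, enterotype.
    """
    meta = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "subject_id": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    for col in _META_REQUIRED:
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    day = pd.to_numeric(meta["day"], errors="coerce")
    if day.isna().any() or not np.allclose(day, np.round(day)):
        raise ValueError("non-integer day in metadata")
    meta["day"] = day.astype(int)
    if (meta["day"] < 0).any():
        raise ValueError("negative day in metadata")
    for col, default in _META_OPTIONAL.items():
        if col not in meta.columns:
            meta[col] = default
        meta[col] = meta[col].where(meta[col].notna(), default)
    if meta.duplicated(["subject_id", "day"]).any():
        pair = meta[meta.duplicated(["subject_id", "day"])].iloc[0]
        raise ValueError(
            f"duplicate (subject, day) pair ({pair['subject_id']!r}, {pair['day']})"
        )
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return meta.sort_values(["subject_id", "day"], kind="mergesort").reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path, sep: str = "\t") -> None:
    meta.to_csv(path, sep=sep, index=False)


def validate_join(table: AbundanceTable, meta: pd.DataFrame) -> None:
    """Refuse to start the pipeline if any table sample lacks metadata."""
    missing = set(table.sample_ids) - set(meta["sample_id"])
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")


def read_newick(path_or_str, default_length: float | None = None) -> skbio.TreeNode:
    """Parse a rooted Newick tree with branch lengths.

    Missing branch lengths raise unless ``default_length`` is given.
    """
    tree = skbio.TreeNode.read(
        path_or_str if hasattr(path_or_str, "read") else str(path_or_str),
        format="newick",
    )
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if default_length is None:
                raise ValueError("tree has branches without lengths")
            node.length = default_length
        elif node.length < 0:
            raise ValueError("negative branch length")
    return tree


def read_exchange_table(path, sep: str = "\t", source: str = "unknown") -> pd.DataFrame:
    """Read a (genus, metabolite, direction) exchange table.

    Direction is normalised case-insensitively to import/export; rows
    with any other direction are dropped with a warning; duplicate
    triples are deduplicated.  The result carries a ``source`` attr.
    """
    records = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("genus", "metabolite", "direction"):
        if col not in records.columns:
            raise ValueError(f"exchange table missing column {col!r}")
    records = records[["genus", "metabolite", "direction"]].copy()
    records["direction"] = records["direction"].str.lower().str.strip()
    bad = ~records["direction"].isin(["import", "export"])
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} exchange rows with direction outside import/export"
        )
        records = records[~bad]
    records = records.drop_duplicates().reset_index(drop=True)
    if records.empty:
        raise ValueError("exchange table has no valid records")
    records.attrs["source"] = source
    return records


@dataclass
class RunSummary:
    """Provenance record written next to pipeline outputs."""

    seed: int
    config: dict = field(default_factory=dict)

    def write(self, path) -> None:
        import microstab

        payload = {
            "seed": self.seed,
            "config": self.config,
            "microstab_version": microstab.__version__,
            "numpy_version": np.__version__,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
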