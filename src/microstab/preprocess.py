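"""Sample/taxon filtering, rarefaction, alpha diversity and log-ratio transforms.

The filters mirror a common meta-analysis recipe for longitudinal 16S
genus tables: drop shallow samples (and subjects left with a single
sample), keep only genera that recur across studies and are repeatedly
non-rare within subjects, and, within an enterotype stratum, cap the
taxon count at the square root of the sample count so that community
dynamics models stay identifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceTable

__all__ = [
    "FilterReport",
    "filter_samples_by_depth",
    "filter_taxa_cross_study",
    "filter_taxa_enterotype",
    "rarefy",
    "shannon_alpha",
    "close_and_transform",
    "clr_matrix",
]


@dataclass
class FilterReport:
    rule: str
    n_samples_in: int
    n_samples_out: int
    n_taxa_in: int
    n_taxa_out: int
    removed_samples: dict = field(default_factory=dict)
    removed_taxa: dict = field(default_factory=dict)


def _subset_meta(meta: pd.DataFrame, sample_ids) -> pd.DataFrame:
    return meta[meta["sample_id"].isin(set(sample_ids))].reset_index(drop=True)


def filter_samples_by_depth(
    table: AbundanceTable, meta: pd.DataFrame, min_reads: int = 3000
) -> tuple[AbundanceTable, FilterReport]:
    """Drop samples below ``min_reads`` total reads, then orphaned subjects.

    A subject left with fewer than two samples after the depth cut is
    removed entirely: a single time point carries no dynamics.
    """
    if table.kind != "counts":
        raise ValueError("depth filter needs counts")
    depths = table.data.sum(axis=1)
    shallow = list(table.data.index[depths < min_reads])
    keep = [s for s in table.sample_ids if s not in set(shallow)]
    meta_kept = _subset_meta(meta, keep)
    counts_per_subject = meta_kept.groupby("subject_id")["sample_id"].count()
    lonely_subjects = set(counts_per_subject.index[counts_per_subject < 2])
    orphaned = list(
        meta_kept.loc[meta_kept["subject_id"].isin(lonely_subjects), "sample_id"]
    )
    keep = [s for s in keep if s not in set(orphaned)]
    out = table.select(samples=keep)
    report = FilterReport(
        rule="sample_depth",
        n_samples_in=table.n_samples,
        n_samples_out=out.n_samples,
        n_taxa_in=table.n_taxa,
        n_taxa_out=out.n_taxa,
        removed_samples={"below_depth": shallow, "orphaned_subject": orphaned},
    )
    return out, report


def _subject_support(
    rel: AbundanceTable,
    meta: pd.DataFrame,
    abund_thr: float,
    min_consecutive: int,
) -> pd.Series:
    """Number of subjects in which each taxon exceeds ``abund_thr`` at
    >= ``min_consecutive`` consecutive (day-adjacent) time points."""
    meta = meta[meta["sample_id"].isin(set(rel.sample_ids))]
    support = np.zeros(rel.n_taxa, dtype=int)
    for _, grp in meta.groupby("subject_id"):
        order = grp.sort_values("day")["sample_id"]
        above = rel.data.loc[order].to_numpy() > abund_thr
        if above.shape[0] < min_consecutive:
            continue
        # taxon supported if any run of consecutive True of required length
        hit = np.zeros(rel.n_taxa, dtype=bool)
        streak = np.zeros(rel.n_taxa, dtype=int)
        for row in above:
            streak = np.where(row, streak + 1, 0)
            hit |= streak >= min_consecutive
        support += hit
    return pd.Series(support, index=rel.taxon_names)


def filter_taxa_cross_study(
    table: AbundanceTable,
    meta: pd.DataFrame,
    min_studies: int = 3,
    abund_thr: float = 0.01,
    min_consecutive: int = 2,
    min_subjects: int = 100,
) -> tuple[AbundanceTable, FilterReport]:
    """Keep genera seen in enough studies and repeatedly non-rare.

    A taxon survives iff (a) it is non-zero in >= ``min_studies``
    distinct studies and (b) it exceeds ``abund_thr`` relative abundance
    at >= ``min_consecutive`` consecutive time points in >=
    ``min_subjects`` subjects.
    """
    meta = _subset_meta(meta, table.sample_ids)
    if min_studies > 1 and (meta["study_id"] == "none").all() and meta["study_id"].nunique() == 1:
        raise ValueError("cross-study filter needs a study_id column")
    rel = table.to_relative()
    sample_study = meta.set_index("sample_id")["study_id"]
    present = rel.data > 0
    studies_per_taxon = pd.Series(0, index=rel.data.columns)
    for study, grp in meta.groupby("study_id"):
        in_study = present.loc[grp["sample_id"]].any(axis=0)
        studies_per_taxon += in_study.astype(int)
    support = _subject_support(rel, meta, abund_thr, min_consecutive)
    keep_mask = (studies_per_taxon >= min_studies) & (support >= min_subjects)
    removed = {
        "too_few_studies": list(studies_per_taxon.index[studies_per_taxon < min_studies]),
        "insufficient_subject_support": [
            t
            for t in support.index[support < min_subjects]
            if studies_per_taxon[t] >= min_studies
        ],
    }
    out = table.select(taxa=list(keep_mask.index[keep_mask]))
    report = FilterReport(
        rule="taxa_cross_study",
        n_samples_in=table.n_samples,
        n_samples_out=out.n_samples,
        n_taxa_in=table.n_taxa,
        n_taxa_out=out.n_taxa,
        removed_taxa=removed,
    )
    return out, report


def filter_taxa_enterotype(
    table: AbundanceTable,
    meta: pd.DataFrame,
    min_subject_support: int = 25,
    abund_thr: float = 0.01,
    min_consecutive: int = 2,
) -> tuple[AbundanceTable, FilterReport]:
    """Within one enterotype, keep the top ceil(sqrt(n_samples)) taxa.

    Taxa are ranked by the number of subjects supporting them (> 1 %
    abundance at >= 2 consecutive time points); rank ties are broken by
    higher mean abundance, then name.  Among the retained, taxa
    supported by fewer than ``min_subject_support`` subjects are
    dropped.
    """
    meta = _subset_meta(meta, table.sample_ids)
    enterotypes = set(meta["enterotype"].dropna())
    if len(enterotypes) > 1:
        raise ValueError(f"mixed enterotypes in table: {sorted(enterotypes)}")
    rel = table.to_relative()
    support = _subject_support(rel, meta, abund_thr, min_consecutive)
    mean_abund = rel.data.mean(axis=0)
    ranking = sorted(
        rel.taxon_names, key=lambda t: (-support[t], -mean_abund[t], t)
    )
    k = math.ceil(math.sqrt(table.n_samples))
    top = ranking[:k]
    kept = [t for t in top if support[t] >= min_subject_support]
    removed = {
        "below_rank_cutoff": [t for t in rel.taxon_names if t not in set(top)],
        "insufficient_subject_support": [t for t in top if support[t] < min_subject_support],
    }
    out = table.select(taxa=[t for t in table.taxon_names if t in set(kept)])
    report = FilterReport(
        rule="taxa_enterotype",
        n_samples_in=table.n_samples,
        n_samples_out=out.n_samples,
        n_taxa_in=table.n_taxa,
        n_taxa_out=out.n_taxa,
        removed_taxa=removed,
    )
    return out, report


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample's reads without replacement to ``depth``.

    Single deterministic draw (multivariate hypergeometric) per sample.
    """
    if table.kind != "counts":
        raise ValueError("rarefaction needs counts")
    counts = np.round(table.values).astype(np.int64)
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        total = int(row.sum())
        if total < depth:
            raise ValueError(
                f"sample {table.sample_ids[i]!r} has only {total} reads (< depth {depth})"
            )
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return AbundanceTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        kind="counts",
    )


def shannon_alpha(counts_row) -> float:
    """Shannon diversity H = -sum p ln p (nats) of one sample."""
    row = np.asarray(counts_row, dtype=float)
    if (row < 0).any():
        raise ValueError("negative abundance")
    total = row.sum()
    if total <= 0:
        raise ValueError("all-zero row has undefined diversity")
    p = row[row > 0] / total
    return float(-(p * np.log(p)).sum())


def close_and_transform(row, transform: str = "relative", pseudocount: float = 1e-5):
    """Close a row to the simplex and optionally log-transform it.

    ``relative``: row / sum.  ``clr``: replace zeros in the relative
    vector by ``pseudocount``, re-close, then ln(x) - mean(ln x).
    ``log``: same zero replacement, then ln (no re-closure).
    """
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        raise ValueError("negative abundance")
    total = row.sum()
    if total <= 0:
        raise ValueError("row with zero total")
    rel = row / total
    if transform == "relative":
        return rel
    filled = np.where(rel == 0, pseudocount, rel)
    if transform == "log":
        return np.log(filled)
    if transform == "clr":
        filled = filled / filled.sum()
        logs = np.log(filled)
        return logs - logs.mean()
    raise ValueError(f"unknown transform {transform!r}")


def clr_matrix(table: AbundanceTable, pseudocount: float = 1e-5) -> pd.DataFrame:
    """clr-transform every sample of a table (rows independently)."""
    out = np.vstack(
        [close_and_transform(r, "clr", pseudocount) for r in table.values]
    )
    return pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
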