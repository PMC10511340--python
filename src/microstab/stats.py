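"""Covariate adjustment, cross-correlation, clustering, taxa associations.

Stability measures computed on longitudinal samples are confounded by
the sampling interval, by whatever intervention fell between the two
time points, and by baseline alpha diversity (beta diversity is
computationally coupled to alpha diversity).  Every measure is
therefore residualised on [1, interval, intervention dummies, Shannon]
by OLS before measures are compared with Pearson correlation,
Benjamini-Hochberg corrected, and hierarchically clustered
(complete linkage on 1 - r).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "adjust_covariates",
    "bh_qvalues",
    "pearson_with_p",
    "correlate_residuals",
    "CorrelationResult",
    "cluster_metrics",
    "taxa_associations",
]


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design with intercept; categorical columns become
    drop-first indicator contrasts."""
    parts = [pd.Series(1.0, index=covariates.index, name="const")]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float))
    return pd.concat(parts, axis=1)


def adjust_covariates(values, covariates: pd.DataFrame) -> pd.Series:
    """OLS residuals of a measure on the covariates.

    Aliased (linearly dependent) design columns are resolved through the
    minimum-norm least-squares solution, with a warning; residuals have
    mean zero by construction (intercept included).
    """
    values = pd.Series(values).astype(float)
    covariates = pd.DataFrame(covariates).loc[values.index]
    if len(values) < 5:
        raise ValueError("covariate adjustment needs at least 5 complete rows")
    X = _design_matrix(covariates).to_numpy(dtype=float)
    y = values.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient adjustment design; aliased columns dropped")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid, index=values.index)


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def pearson_with_p(x, y) -> tuple[float, float]:
    res = sstats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n: pd.DataFrame
    excluded: list = field(default_factory=list)


def correlate_residuals(
    panel: pd.DataFrame,
    metric_cols,
    covariate_cols=("delta_t", "intervention", "shannon_baseline"),
    min_rows: int = 10,
) -> CorrelationResult:
    """Pairwise-complete Pearson correlation of covariate-adjusted measures.

    Each metric pair is adjusted and correlated on its own complete
    rows (some metrics, e.g. tree-dependent ones, may be missing for
    subsets of subjects).  BH correction runs over all off-diagonal
    pairs.  Zero-variance metrics are excluded with a flag.
    """
    metric_cols = [c for c in metric_cols if c in panel.columns]
    covs = [c for c in covariate_cols if c in panel.columns]
    excluded = []
    usable = []
    for c in metric_cols:
        col = panel[c].dropna()
        if len(col) < min_rows or float(col.std()) == 0.0 or not np.isfinite(col.std()):
            excluded.append(c)
        else:
            usable.append(c)
    m = len(usable)
    r = pd.DataFrame(np.eye(m), index=usable, columns=usable)
    p = pd.DataFrame(np.zeros((m, m)), index=usable, columns=usable)
    n = pd.DataFrame(np.zeros((m, m), dtype=int), index=usable, columns=usable)
    pair_ps = []
    pairs = []
    for a in range(m):
        n.iloc[a, a] = panel[usable[a]].notna().sum()
        for b in range(a + 1, m):
            ca, cb = usable[a], usable[b]
            sub = panel[[ca, cb] + covs].dropna()
            n.iloc[a, b] = n.iloc[b, a] = len(sub)
            if len(sub) < min_rows:
                r.iloc[a, b] = r.iloc[b, a] = np.nan
                p.iloc[a, b] = p.iloc[b, a] = np.nan
                continue
            ra = adjust_covariates(sub[ca], sub[covs])
            rb = adjust_covariates(sub[cb], sub[covs])
            if ra.std() == 0 or rb.std() == 0:
                r.iloc[a, b] = r.iloc[b, a] = np.nan
                p.iloc[a, b] = p.iloc[b, a] = np.nan
                continue
            rv, pv = pearson_with_p(ra, rb)
            r.iloc[a, b] = r.iloc[b, a] = rv
            p.iloc[a, b] = p.iloc[b, a] = pv
            pairs.append((a, b))
            pair_ps.append(pv)
    q = pd.DataFrame(np.full((m, m), np.nan), index=usable, columns=usable)
    np.fill_diagonal(q.values, 0.0)
    if pair_ps:
        qs = bh_qvalues(pair_ps)
        for (a, b), qv in zip(pairs, qs):
            q.iloc[a, b] = q.iloc[b, a] = qv
    return CorrelationResult(r=r, p=p, q=q, n=n, excluded=excluded)


def cluster_metrics(
    correlation: pd.DataFrame, n_clusters: int = 2
) -> tuple[pd.Series, np.ndarray]:
    """Complete-linkage clustering of metrics at distance 1 - r.

    Missing correlations are imputed at the maximum distance (2) with a
    warning.  Returns (labels, scipy linkage matrix); the default cut
    yields two clusters.
    """
    corr = correlation.to_numpy(dtype=float).copy()
    if corr.shape[0] != corr.shape[1] or not np.allclose(np.diag(corr), 1.0):
        raise ValueError("need a square correlation matrix with unit diagonal")
    dist = 1.0 - corr
    if np.isnan(dist).any():
        warnings.warn("missing correlations imputed at maximal distance")
        dist = np.where(np.isnan(dist), 2.0, dist)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    linkage = hierarchy.linkage(condensed, method="complete")
    labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=correlation.index, name="cluster"), linkage


def taxa_associations(
    panel: pd.DataFrame,
    clr_abundances: pd.DataFrame,
    metric_cols,
    covariate_cols=("delta_t", "intervention", "shannon_baseline"),
) -> pd.DataFrame:
    """Per-(taxon, metric) linear association of clr baseline abundance
    with a stability measure, covariate-adjusted, BH-corrected.

    ``clr_abundances`` is indexed by subject (baseline sample clr).
    Subjects absent from either side are dropped row-wise; constant clr
    columns are skipped.
    """
    metric_cols = [c for c in metric_cols if c in panel.columns]
    covs = [c for c in covariate_cols if c in panel.columns]
    shared = panel.index.intersection(clr_abundances.index)
    rows = []
    for taxon in clr_abundances.columns:
        clr_col = clr_abundances.loc[shared, taxon]
        if float(clr_col.std()) == 0.0:
            continue
        for metric in metric_cols:
            sub = panel.loc[shared, [metric] + covs].join(clr_col.rename("clr")).dropna()
            if len(sub) < 5:
                rows.append(
                    {"taxon": taxon, "metric": metric, "coef": np.nan,
                     "p": np.nan, "n": len(sub)}
                )
                continue
            X = _design_matrix(sub[covs])
            X["clr"] = sub["clr"]
            fit = sm.OLS(sub[metric].astype(float), X.astype(float)).fit()
            rows.append(
                {
                    "taxon": taxon,
                    "metric": metric,
                    "coef": float(fit.params["clr"]),
                    "p": float(fit.pvalues["clr"]),
                    "n": len(sub),
                }
            )
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        out.loc[mask, "q"] = bh_qvalues(out.loc[mask, "p"].to_numpy())
    return out
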