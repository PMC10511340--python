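"""Interaction networks and their summary statistics.

Two network provenances are supported.  ``clv`` networks take the
relative interaction matrix A of a fitted model, restricted to a
subject's baseline taxa: a directed edge j -> i with weight A_ij for
every non-zero entry (the denominator taxon has no incoming edges by
construction).  ``exchange`` networks are built from metabolite
import/export tables: an (undirected) interaction exists between two
genera whenever their cross-feeding or competition index is non-zero.

Summary statistics: connectance C = L/N (directed edges counted
separately), heterogeneity H = population variance of node degrees
(in + out), interaction strength S, competition and mutualism strengths
S_c / S_m, and the link-scaling decomposition coefficient
b = ln L / ln N.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clv import CLVModel
from .io import AbundanceTable

__all__ = [
    "InteractionNetwork",
    "NetworkStats",
    "subject_network",
    "network_stats",
    "decomposition_b",
    "exchange_indices",
    "exchange_network",
    "stability_network_associations",
    "subject_network_panel",
]


@dataclass
class InteractionNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # columns: source, target, weight
    provenance: str = "clv"  # clv | exchange

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class NetworkStats:
    C: float  # connectance, edges per node
    H: float  # heterogeneity, variance of node degrees
    S: float  # mean |non-zero interaction|
    S_c: float  # competition strength (all ordered pairs in denominator)
    S_m: float  # mutualism strength (idem)
    b: float  # ln L / ln N (NaN if L == 0)
    L: int
    N: int
    S_c_nonzero: float = np.nan  # variant: averaged over mutually-negative pairs only
    S_m_nonzero: float = np.nan

    def as_dict(self) -> dict:
        return {
            "C": self.C, "H": self.H, "S": self.S, "S_c": self.S_c,
            "S_m": self.S_m, "b": self.b, "L": self.L, "N": self.N,
        }


def subject_network(model: CLVModel, baseline_composition) -> InteractionNetwork:
    """cLV interaction network on a subject's baseline support."""
    pi0 = np.asarray(baseline_composition, dtype=float)
    support = np.flatnonzero(pi0 > 0)
    if support.size == 0:
        raise ValueError("empty baseline support")
    names = model.taxon_names
    records = []
    for i in support:
        if i == model.denominator:
            continue  # denominator row is zero: no incoming edges
        for j in support:
            w = model.A[i, j]
            if w != 0:
                records.append({"source": names[j], "target": names[i], "weight": w})
    edges = pd.DataFrame(records, columns=["source", "target", "weight"])
    return InteractionNetwork(
        nodes=[names[i] for i in support], edges=edges, provenance="clv"
    )


def network_stats(network: InteractionNetwork) -> NetworkStats:
    """Connectance, heterogeneity and interaction strengths of a network.

    Ordered pairs (i, j) and (j, i) count as separate edges.  S_c sums
    |weights| over mutually negative ordered pairs and S_m sums weights
    over mutually positive ones, both divided by N(N-1) (pairs without
    the reciprocal pattern enter as zeros); the ``*_nonzero`` variants
    average over the qualifying pairs only.
    """
    N = network.n_nodes
    if N < 2:
        raise ValueError("network statistics need at least 2 nodes")
    L = network.n_edges
    degrees = dict.fromkeys(network.nodes, 0)
    for _, e in network.edges.iterrows():
        degrees[e["source"]] += 1
        degrees[e["target"]] += 1
    deg = np.array([degrees[n] for n in network.nodes], dtype=float)
    C = L / N
    H = float(deg.var())  # population variance
    weights = network.edges["weight"].to_numpy(dtype=float) if L else np.array([])
    nz = weights[weights != 0]
    S = float(np.abs(nz).mean()) if nz.size else 0.0
    # reciprocal-pattern strengths over ordered off-diagonal pairs
    w = {
        (e["source"], e["target"]): e["weight"] for _, e in network.edges.iterrows()
    }
    neg_sum = pos_sum = 0.0
    neg_cnt = pos_cnt = 0
    for a, b_node in itertools.permutations(network.nodes, 2):
        wij = w.get((a, b_node), 0.0)
        wji = w.get((b_node, a), 0.0)
        if wij < 0 and wji < 0:
            neg_sum += abs(wij)
            neg_cnt += 1
        if wij > 0 and wji > 0:
            pos_sum += wij
            pos_cnt += 1
    denom = N * (N - 1)
    return NetworkStats(
        C=C,
        H=H,
        S=S,
        S_c=neg_sum / denom,
        S_m=pos_sum / denom,
        b=decomposition_b(L, N),
        L=L,
        N=N,
        S_c_nonzero=neg_sum / neg_cnt if neg_cnt else np.nan,
        S_m_nonzero=pos_sum / pos_cnt if pos_cnt else np.nan,
    )


def decomposition_b(L: int, N: int) -> float:
    """Link-scaling exponent b = ln L / ln N (NaN when L = 0)."""
    if N < 2:
        raise ValueError("b needs at least 2 nodes")
    if L == 0:
        return np.nan
    return float(np.log(L) / np.log(N))


# ---------------------------------------------------------------------------
# metabolite-exchange-derived networks


def exchange_indices(
    exchange: pd.DataFrame, prevalence_cap: float = 0.70
) -> pd.DataFrame:
    """Cross-feeding and competition indices for every genus pair.

    Metabolites linked (in any direction) to both genera of more than
    ``prevalence_cap`` of all genus pairs are dropped first.  For a pair
    (X, Y) with metabolite universe M_XY = metabolites linked to X or Y:
    crossfeeding = |(exp_X & imp_Y) | (exp_Y & imp_X)| / |M_XY| and
    competition = |imp_X & imp_Y| / |M_XY|.
    """
    genera = sorted(exchange["genus"].unique())
    if len(genera) < 2:
        raise ValueError("exchange table must cover at least 2 genera")
    links: dict[str, dict[str, set]] = {
        g: {"import": set(), "export": set()} for g in genera
    }
    for _, rec in exchange.iterrows():
        links[rec["genus"]][rec["direction"]].add(rec["metabolite"])
    touched = {g: links[g]["import"] | links[g]["export"] for g in genera}
    pairs = list(itertools.combinations(genera, 2))
    # prevalence filter: a metabolite "appears in" a pair when it is
    # linked to both genera; ubiquitously shared metabolites are dropped
    metabolites = sorted(set(exchange["metabolite"]))
    drop = set()
    for m in metabolites:
        share = sum(1 for x, y in pairs if m in touched[x] and m in touched[y])
        if pairs and share / len(pairs) > prevalence_cap:
            drop.add(m)
    if drop:
        for g in genera:
            links[g]["import"] -= drop
            links[g]["export"] -= drop
            touched[g] -= drop
    empty = [g for g in genera if not touched[g]]
    if empty:
        warnings.warn(f"genera with no exchange records after filtering: {empty}")
    rows = []
    for x, y in pairs:
        universe = touched[x] | touched[y]
        if not universe:
            cf = comp = 0.0
        else:
            cf_set = (links[x]["export"] & links[y]["import"]) | (
                links[y]["export"] & links[x]["import"]
            )
            cf = len(cf_set) / len(universe)
            comp = len(links[x]["import"] & links[y]["import"]) / len(universe)
        rows.append(
            {"genus_x": x, "genus_y": y, "crossfeeding": cf, "competition": comp}
        )
    return pd.DataFrame(rows)


def exchange_network(
    indices: pd.DataFrame, baseline_taxa
) -> tuple[InteractionNetwork, NetworkStats]:
    """Exchange-derived network on the covered baseline taxa.

    An interaction exists where either index is non-zero; undirected
    pairs expand into two directed edges.  S_m / S_c are the average
    cross-feeding / competition indices over the pair-edges; S averages
    the non-zero per-edge means of the two indices.
    """
    covered_genera = set(indices["genus_x"]) | set(indices["genus_y"])
    nodes = [t for t in baseline_taxa if t in covered_genera]
    skipped = [t for t in baseline_taxa if t not in covered_genera]
    if skipped:
        warnings.warn(f"baseline taxa without exchange coverage: {skipped}")
    if not nodes:
        raise ValueError("no baseline taxa covered by the exchange indices")
    nodeset = set(nodes)
    records = []
    cf_vals, comp_vals, edge_means = [], [], []
    for _, rec in indices.iterrows():
        x, y = rec["genus_x"], rec["genus_y"]
        if x not in nodeset or y not in nodeset:
            continue
        cf, comp = rec["crossfeeding"], rec["competition"]
        if cf == 0 and comp == 0:
            continue
        mean_idx = (cf + comp) / 2.0
        cf_vals.append(cf)
        comp_vals.append(comp)
        if mean_idx != 0:
            edge_means.append(mean_idx)
        records.append({"source": x, "target": y, "weight": mean_idx})
        records.append({"source": y, "target": x, "weight": mean_idx})
    edges = pd.DataFrame(records, columns=["source", "target", "weight"])
    net = InteractionNetwork(nodes=nodes, edges=edges, provenance="exchange")
    N = len(nodes)
    if N < 2:
        raise ValueError("exchange network needs at least 2 covered taxa")
    L = len(edges)
    degrees = dict.fromkeys(nodes, 0)
    for _, e in edges.iterrows():
        degrees[e["source"]] += 1
        degrees[e["target"]] += 1
    deg = np.array([degrees[n] for n in nodes], dtype=float)
    stats = NetworkStats(
        C=L / N,
        H=float(deg.var()),
        S=float(np.mean(edge_means)) if edge_means else 0.0,
        S_c=float(np.mean(comp_vals)) if comp_vals else 0.0,
        S_m=float(np.mean(cf_vals)) if cf_vals else 0.0,
        b=decomposition_b(L, N),
        L=L,
        N=N,
    )
    return net, stats


# ---------------------------------------------------------------------------
# association with stability measures


def subject_network_panel(
    model: CLVModel, table: AbundanceTable, meta: pd.DataFrame
) -> pd.DataFrame:
    """Network statistics of every subject's baseline cLV network."""
    rel = table.to_relative()
    meta = meta[meta["sample_id"].isin(set(rel.sample_ids))]
    rows = []
    for subject, grp in meta.groupby("subject_id"):
        baseline_id = grp.sort_values("day")["sample_id"].iloc[0]
        pi0 = rel.data.loc[baseline_id].to_numpy()
        if (pi0 > 0).sum() < 2:
            continue
        net = subject_network(model, pi0)
        stats = network_stats(net)
        rows.append({"subject_id": subject, **stats.as_dict()})
    return pd.DataFrame(rows).set_index("subject_id")


def stability_network_associations(
    panel: pd.DataFrame,
    net_stats: pd.DataFrame,
    covariate_cols=("delta_t", "intervention", "shannon_baseline"),
    metric_cols=None,
) -> pd.DataFrame:
    """Correlate network characteristics with stability measures.

    Both sides are covariate-adjusted (OLS residuals) before Pearson
    correlation; p-values are BH-corrected over all (statistic, metric)
    pairs.  Pairs with fewer than 10 complete observations are flagged
    ``underpowered``.
    """
    from .stats import adjust_covariates, bh_qvalues, pearson_with_p

    joined = panel.join(net_stats, how="inner", rsuffix="_net")
    if metric_cols is None:
        from .obs import OBS_METRICS

        metric_cols = [c for c in OBS_METRICS if c in panel.columns]
        metric_cols += [
            c
            for c in ("neg_lambda_max", "neg_lambda_max_tangent", "stp_bc", "stp_ait", "rob50")
            if c in panel.columns
        ]
    stat_cols = [c for c in ("C", "H", "S", "S_c", "S_m", "b") if c in net_stats.columns]
    covs = joined[[c for c in covariate_cols if c in joined.columns]]
    rows = []
    for stat in stat_cols:
        for metric in metric_cols:
            sub = joined[[stat, metric]].join(covs).dropna()
            n = len(sub)
            if n < 10 or sub[stat].std() == 0 or sub[metric].std() == 0:
                rows.append(
                    {"stat": stat, "metric": metric, "r": np.nan, "p": np.nan,
                     "n": n, "flag": "underpowered" if n < 10 else "constant"}
                )
                continue
            rs = adjust_covariates(sub[stat], sub.drop(columns=[stat, metric]))
            rm = adjust_covariates(sub[metric], sub.drop(columns=[stat, metric]))
            r, p = pearson_with_p(rs, rm)
            rows.append({"stat": stat, "metric": metric, "r": r, "p": p, "n": n, "flag": ""})
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        out.loc[mask, "q"] = bh_qvalues(out.loc[mask, "p"].to_numpy())
    return out
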