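"""Observational stability: inverse community change between time points.

Nine measures are computed per subject.  Seven are inverse beta
diversities between the subject's first two samples — 1-BC, 1-WUni,
Pearson correlation, 1-Euc(log), -Aitchison, 1-Jaccard and the inverse
Raup-Crick metric standardised against a null assembly model over the
subject's enterotype context.  Two are predictive: the inverse response
potential of the baseline sample, i.e. its mean Bray-Curtis (or
Aitchison) distance to the baselines of all other subjects in the same
enterotype, inverted.  "Inverse" means 1 - d for metrics bounded in
[0, 1] and -d otherwise, so that larger always means more stable.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .clv import aitchison_distance, bray_curtis
from .io import AbundanceTable
from .preprocess import close_and_transform, rarefy, shannon_alpha

__all__ = [
    "beta_diversity",
    "weighted_unifrac",
    "raup_crick_bray",
    "response_potential",
    "stability_panel",
    "OBS_METRICS",
]

PSEUDOCOUNT = 1e-5

OBS_METRICS = [
    "inv_bc",
    "inv_wuni",
    "cor",
    "inv_euclog",
    "neg_ait",
    "inv_jaccard",
    "neg_rc_bray",
    "p_inv_bc",
    "p_neg_ait",
]


def beta_diversity(x, y, metric: str, pseudocount: float = PSEUDOCOUNT) -> float:
    """Pairwise dissimilarity (or correlation, for ``cor``) of two profiles.

    ``bc``: Bray-Curtis; ``jaccard``: 1 - |intersection|/|union| of
    presences; ``euclog``: Euclidean after zero-filled log; ``aitchison``:
    Euclidean between clr vectors; ``cor``: Pearson correlation (NaN when
    either profile has zero variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must share the taxon set")
    if metric == "bc":
        return bray_curtis(x, y)
    if metric == "jaccard":
        px, py = x > 0, y > 0
        union = (px | py).sum()
        if union == 0:
            return 0.0
        return float(1.0 - (px & py).sum() / union)
    if metric == "euclog":
        lx = close_and_transform(x, "log", pseudocount)
        ly = close_and_transform(y, "log", pseudocount)
        return float(np.linalg.norm(lx - ly))
    if metric == "aitchison":
        return aitchison_distance(x, y, pseudocount)
    if metric == "cor":
        if x.std() == 0 or y.std() == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])
    raise ValueError(f"unknown metric {metric!r}")


def weighted_unifrac(x, y, tree, taxon_names) -> float:
    """Normalised weighted UniFrac between two relative profiles.

    sum_b l_b |p_b - q_b| / sum_b l_b (p_b + q_b) over all branches,
    where p_b is the leaf mass below branch b.  Every non-zero taxon
    must resolve to a tree leaf.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x / x.sum()
    y = y / y.sum()
    mass_x = dict(zip(taxon_names, x))
    mass_y = dict(zip(taxon_names, y))
    leaf_names = {leaf.name for leaf in tree.tips()}
    for name, m in list(mass_x.items()) + list(mass_y.items()):
        if m > 0 and name not in leaf_names:
            raise ValueError(f"taxon {name!r} missing from the tree")
    num = 0.0
    den = 0.0
    below: dict[int, tuple[float, float]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            p = mass_x.get(node.name, 0.0)
            q = mass_y.get(node.name, 0.0)
        else:
            p = sum(below[id(c)][0] for c in node.children)
            q = sum(below[id(c)][1] for c in node.children)
        below[id(node)] = (p, q)
        if node.length is not None and not node.is_root():
            num += node.length * abs(p - q)
            den += node.length * (p + q)
    if den == 0:
        return 0.0
    return float(num / den)


def _null_community(
    rng: np.random.Generator,
    richness: int,
    depth: int,
    occ_freq: np.ndarray,
    mean_rel: np.ndarray,
) -> np.ndarray:
    """One null assembly: pick ``richness`` taxa by occurrence frequency,
    fill to ``depth`` by mean context relative abundance."""
    n = len(occ_freq)
    available = np.flatnonzero(occ_freq > 0)
    k = min(richness, len(available))
    p_occ = occ_freq[available] / occ_freq[available].sum()
    chosen = rng.choice(available, size=k, replace=False, p=p_occ)
    counts = np.zeros(n, dtype=np.int64)
    # each chosen taxon gets one founding read; the rest fill by abundance
    counts[chosen] = 1
    remaining = depth - k
    if remaining > 0:
        p_fill = mean_rel[chosen]
        if p_fill.sum() == 0:
            p_fill = np.ones(k)
        p_fill = p_fill / p_fill.sum()
        counts[chosen] += rng.multinomial(remaining, p_fill)
    return counts


def raup_crick_bray(
    x,
    y,
    context: AbundanceTable | np.ndarray,
    reps: int = 999,
    seed: int = 0,
) -> float:
    """Raup-Crick standardised Bray-Curtis in [-1, 1].

    ``x`` and ``y`` are count vectors rarefied to a common depth; the
    null model preserves each community's richness (taxa drawn with
    probability proportional to occurrence frequency in the context) and
    its depth (multinomial fill proportional to mean context relative
    abundance).  rc = 2 ((#null < obs + 0.5 #null = obs)/reps - 0.5):
    -1 means far more similar than null assembly predicts.
    """
    import warnings

    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.sum() != y.sum():
        raise ValueError("profiles must be rarefied to a common depth")
    if reps < 100:
        warnings.warn("raup_crick_bray with reps < 100 is poorly resolved")
    ctx = context.values if isinstance(context, AbundanceTable) else np.asarray(context, float)
    if ctx.shape[0] < 10:
        raise ValueError("Raup-Crick context needs at least 10 samples")
    occ_freq = (ctx > 0).mean(axis=0)
    rel = ctx / ctx.sum(axis=1, keepdims=True)
    mean_rel = rel.mean(axis=0)
    obs = bray_curtis(x, y)
    depth = int(x.sum())
    rich_x = int((x > 0).sum())
    rich_y = int((y > 0).sum())
    rng = np.random.default_rng(seed)
    less = equal = 0
    for _ in range(reps):
        nx = _null_community(rng, rich_x, depth, occ_freq, mean_rel)
        ny = _null_community(rng, rich_y, depth, occ_freq, mean_rel)
        null_bc = bray_curtis(nx, ny)
        if null_bc < obs - 1e-12:
            less += 1
        elif abs(null_bc - obs) <= 1e-12:
            equal += 1
    return float(2.0 * ((less + 0.5 * equal) / reps - 0.5))


def response_potential(
    x,
    context_baselines: np.ndarray,
    metric: str = "bc",
    k: int | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> float:
    """Mean distance from a sample to (the k nearest of) the context
    baselines; larger values predict larger forthcoming change."""
    context_baselines = np.atleast_2d(np.asarray(context_baselines, dtype=float))
    if context_baselines.shape[0] == 0:
        raise ValueError("response potential needs a non-empty context")
    dists = np.array(
        [beta_diversity(x, row, metric, pseudocount) for row in context_baselines]
    )
    if k is not None:
        dists = np.sort(dists)[: max(1, k)]
    return float(dists.mean())


def stability_panel(
    table: AbundanceTable,
    meta: pd.DataFrame,
    tree=None,
    eco_panel: pd.DataFrame | None = None,
    context_by: str = "enterotype",
    rc_reps: int = 999,
    rp_k: int | None = None,
    seed: int = 0,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-subject observational (and optionally ecological) stability.

    Uses each subject's first two samples for the seven measured
    metrics and the baseline for the two predictive ones.  Counts are
    rarefied to the minimum sample depth for the Jaccard presence call,
    Shannon covariate and the Raup-Crick null; relative abundances feed
    the remaining metrics.  Rows also carry the adjustment covariates
    (time interval, intervention of the first interval, baseline
    Shannon).  Subjects with fewer than two samples are excluded.
    """
    meta = meta[meta["sample_id"].isin(set(table.sample_ids))]
    if table.kind == "counts":
        depth = int(table.data.sum(axis=1).min())
        rare = rarefy(table, depth, seed)
    else:
        rare = None
    rel = table.to_relative()
    data = rel.data

    # subject -> (first, second) sample ids and enterotype
    subject_rows = []
    for subject, grp in meta.groupby("subject_id"):
        grp = grp.sort_values("day")
        if len(grp) < 2:
            continue
        subject_rows.append(
            {
                "subject_id": subject,
                "s1": grp["sample_id"].iloc[0],
                "s2": grp["sample_id"].iloc[1],
                "delta_t": int(grp["day"].iloc[1] - grp["day"].iloc[0]),
                "intervention": grp["intervention"].iloc[0],
                "enterotype": grp["enterotype"].iloc[0],
            }
        )
    if not subject_rows:
        raise ValueError("no subject has two or more samples")
    subjects = pd.DataFrame(subject_rows).set_index("subject_id")

    # context groups for Raup-Crick and response potential
    sample_groups = meta.set_index("sample_id")["enterotype" if context_by == "enterotype" else "study_id"]

    rows = []
    for subject, info in subjects.iterrows():
        x = data.loc[info["s1"]].to_numpy()
        y = data.loc[info["s2"]].to_numpy()
        row = {
            "subject_id": subject,
            "delta_t": info["delta_t"],
            "intervention": info["intervention"],
            "enterotype": info["enterotype"],
        }
        row["inv_bc"] = 1.0 - beta_diversity(x, y, "bc", pseudocount)
        row["cor"] = beta_diversity(x, y, "cor", pseudocount)
        row["inv_euclog"] = 1.0 - beta_diversity(x, y, "euclog", pseudocount)
        row["neg_ait"] = -beta_diversity(x, y, "aitchison", pseudocount)
        if tree is not None:
            row["inv_wuni"] = 1.0 - weighted_unifrac(x, y, tree, rel.taxon_names)
        else:
            row["inv_wuni"] = np.nan
        if rare is not None:
            rx = rare.data.loc[info["s1"]].to_numpy()
            ry = rare.data.loc[info["s2"]].to_numpy()
            row["inv_jaccard"] = 1.0 - beta_diversity(rx, ry, "jaccard")
            row["shannon_baseline"] = shannon_alpha(rx)
            group = sample_groups.get(info["s1"])
            ctx_ids = [
                s
                for s in rare.sample_ids
                if sample_groups.get(s) == group
            ]
            if len(ctx_ids) >= 10:
                subject_salt = zlib.crc32(str(subject).encode()) % (2**16)
                row["neg_rc_bray"] = -raup_crick_bray(
                    rx,
                    ry,
                    rare.data.loc[ctx_ids].to_numpy(),
                    reps=rc_reps,
                    seed=seed + subject_salt,
                )
            else:
                row["neg_rc_bray"] = np.nan
        else:
            row["inv_jaccard"] = 1.0 - beta_diversity(x, y, "jaccard")
            row["shannon_baseline"] = shannon_alpha(x)
            row["neg_rc_bray"] = np.nan
        # predictive metrics from the baseline against other subjects' baselines
        group = info["enterotype"]
        ctx = [
            data.loc[other_info["s1"]].to_numpy()
            for other, other_info in subjects.iterrows()
            if other != subject and other_info["enterotype"] == group
        ]
        if ctx:
            row["p_inv_bc"] = 1.0 - response_potential(
                x, np.vstack(ctx), "bc", rp_k, pseudocount
            )
            row["p_neg_ait"] = -response_potential(
                x, np.vstack(ctx), "aitchison", rp_k, pseudocount
            )
        else:
            row["p_inv_bc"] = np.nan
            row["p_neg_ait"] = np.nan
        rows.append(row)
    panel = pd.DataFrame(rows).set_index("subject_id")
    if eco_panel is not None:
        panel = panel.join(
            eco_panel[
                [
                    c
                    for c in (
                        "neg_lambda_max",
                        "neg_lambda_max_tangent",
                        "stp_bc",
                        "stp_ait",
                        "rob50",
                        "rob50_secondary",
                    )
                    if c in eco_panel.columns
                ]
            ]
        )
    return panel
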