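"""Observational stability and its correlation with the ecological measures.

Nine observational measures per subject: seven inverse beta diversities
between the first two time points (1-BC, 1-WUni, Cor, 1-Euc(log),
-Ait, 1-Jaccard, -RC_bray) and two predictive inverse response
potentials from the baseline (P(1-BC), P(-Ait)).  All measures are
adjusted for sampling interval, intervention and baseline Shannon
diversity before Pearson cross-correlation, BH correction, and
complete-linkage clustering into two families.
"""

import io

import microstab as ms

cfg = ms.SyntheticConfig(n_taxa=10, n_subjects=24, seed=42)
model, truth = ms.generate_clv_system(cfg)
table, meta, _ = ms.simulate_cohort(model, cfg, attractor=truth.attractor)
tree = ms.read_newick(io.StringIO(ms.random_ultrametric_tree(model.taxon_names, seed=1)))

eco = ms.eco_stability_panel(model, table, meta, seed=1, reps=5)
panel = ms.stability_panel(table, meta, tree=tree, eco_panel=eco, rc_reps=199, seed=2)

metrics = [c for c in ms.OBS_METRICS if panel[c].notna().any()]
metrics += ["neg_lambda_max_tangent", "stp_bc", "stp_ait", "rob50"]
print(f"panel: {len(panel)} subjects x {len(metrics)} stability measures")

res = ms.correlate_residuals(panel, metrics)
print(f"strongest adjusted correlations (of {res.r.shape[0]} usable measures):")
pairs = res.r.where(~(res.r == 1.0)).abs().stack().sort_values(ascending=False)
for (a, b), v in pairs.drop_duplicates().head(3).items():
    print(f"  r({a}, {b}) = {res.r.loc[a, b]:+.2f}  (BH q = {res.q.loc[a, b]:.3f})")

labels, _ = ms.cluster_metrics(res.r, n_clusters=2)
print("two metric families from complete-linkage clustering at 1 - r:")
for k in (1, 2):
    print(f"  cluster {k}:", list(labels.index[labels == k]))
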