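"""Fit cLV dynamics to a cohort and cross-validate against a static model.

The fit is one-step gradient matching with an elastic-net penalty:
per-interval log-ratio velocities regressed on the starting composition
and intervention indicators.  Cross-validation splits subjects 25:75,
selects the penalty on the training group, then predicts each held-out
subject from its baseline; errors are compared to the static
(no-change) prediction with a Wilcoxon rank-sum test.  Lower cLV error
with small p means the model captured real dynamics.
"""

import numpy as np

import microstab as ms

cfg = ms.SyntheticConfig(
    n_taxa=6, n_subjects=16, timepoints_range=(3, 5), gap_range=(2, 7),
    sigma_eta=0.02, seed=7,
)
model, truth = ms.generate_clv_system(cfg)
table, meta, _ = ms.simulate_cohort(model, cfg, attractor=truth.attractor)

fit = ms.fit_clv(table, meta, denominator=model.denominator, alpha=1e-3)
nz = model.A != 0
agree = (np.sign(fit.A[nz]) == np.sign(model.A[nz])).mean()
print(f"interaction-sign agreement with ground truth: {100 * agree:.0f}% "
      f"({int(nz.sum())} non-zero entries)")

cv = ms.crossvalidate_clv(table, meta, seed=1)
med = cv.errors.groupby("metric")[["clv", "static"]].median()
for metric in ("rmse", "rmsle", "aitchison"):
    p = cv.tests[metric]["pvalue"]
    print(f"{metric:>9}: cLV median {med.loc[metric, 'clv']:.4f} vs "
          f"static {med.loc[metric, 'static']:.4f}  (rank-sum p = {p:.3g})")
print("Lower cLV error than static means the inferred interactions "
      "predict where each microbiome is heading; the p-values show how "
      "strong that evidence is at this cohort size.")
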