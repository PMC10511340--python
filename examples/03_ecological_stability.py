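"""Ecological stability: steady states, local stability, robustness.

Starts with a hand-solvable 2-taxon system (d eta/dt = 1 - 2 pi_1,
equilibrium (0.5, 0.5), eigenvalues {0, -0.5}), then computes the full
four-measure panel on a synthetic cohort: -R(lambda_max) (local
stability), 1-BC and -Aitchison distances from baseline to steady
state, and Rob_0.5 (fraction of taxa to remove to halve richness).
"""

import numpy as np

import microstab as ms

# worked example ------------------------------------------------------
m2 = ms.CLVModel(
    taxon_names=["a", "d"], denominator=1,
    g=[1.0, 0.0], A=[[-2.0, 0.0], [0.0, 0.0]], B=np.zeros((2, 0)),
)
st = ms.solve_equilibrium(m2, [0, 1])
print(f"worked 2-taxon system: pi* = {st.pi_star}, residual {st.residual:.1e}")
print(f"  local stability raw = {ms.local_stability(m2, st, 'raw'):.3f} "
      f"(structural zero mode), tangent = {ms.local_stability(m2, st, 'tangent'):.3f} "
      f"(return rate 0.5/day)")

# cohort panel --------------------------------------------------------
cfg = ms.SyntheticConfig(n_taxa=10, n_subjects=12, seed=42)
model, truth = ms.generate_clv_system(cfg)
table, meta, _ = ms.simulate_cohort(model, cfg, attractor=truth.attractor)
panel = ms.eco_stability_panel(model, table, meta, seed=1)
print(f"\nper-subject ecological stability ({len(panel)} subjects):")
print(panel[["neg_lambda_max_tangent", "stp_bc", "stp_ait", "rob50"]]
      .describe().loc[["mean", "min", "max"]].round(3))
print("stp_bc near 1 = baseline already close to its steady state; "
      "rob50 = 0.5 = no secondary extinction cascade.")
print(f"steady-state match to simulation (Bray-Curtis): "
      f"{panel['steady_state_match_bc'].mean():.2e} on average")
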