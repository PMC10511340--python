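# Methods

This note records the models, estimators, numerical choices and known
limitations behind `microstab`, in the order a pipeline run encounters
them.

## Data model and preprocessing

Input is a samples × genera table (counts or closed relative
abundances) plus per-sample metadata (subject, integer day from the
subject's baseline, optional study / intervention / enterotype labels).
The pipeline refuses to start when any sample lacks metadata.

Filtering follows the common meta-analysis recipe for longitudinal 16S
genus tables, in a fixed order recorded in the reports:

1. **depth** — samples under 3000 reads are dropped, and any subject
   left with a single sample is dropped entirely (one time point has no
   dynamics);
2. **cross-study** — a genus is kept iff it is non-zero in ≥ 3 studies
   and exceeds 1 % relative abundance at ≥ 2 consecutive time points in
   ≥ 100 subjects ("consecutive" = adjacent in the subject's day-sorted
   list, with no maximum-gap rule, since study windows are capped at 63
   days anyway). Support counts are computed on the table as given,
   i.e. after depth filtering;
3. **enterotype** — within one enterotype stratum, taxa are ranked by
   the same subject-support count and the top ⌈√n_samples⌉ kept (a
   conventional taxa-per-sample cap for dynamical-model
   identifiability), then taxa supported by < 25 subjects dropped.
   Rank ties break by higher mean abundance, then name, so output is
   deterministic.

All three filters are idempotent. Rarefaction is a single seeded
multivariate-hypergeometric draw per sample (without replacement);
Shannon diversity is −Σ p ln p in nats on rarefied counts. Zeros are
replaced by a 10⁻⁵ pseudocount before any log-ratio work; for clr the
filled vector is re-closed first, which keeps clr scale-invariant and
zero-sum.

## The cLV model

With denominator taxon D (minimal log-abundance variance) and
η_i = ln(π_i/π_D), the dynamics are dη_i/dt = g_i + (Aπ)_i + (Bu)_i.
Compositions are recovered through the softmax-like map
π_i = e^{η_i}/(1 + Σ_m e^{η_m}), so simulated states are on the simplex
by construction and taxa absent at baseline stay absent (their
equations are removed, mirroring per-individual model restriction).

**Gauge fixing.** On the simplex Σπ_j = 1, so the intercept and the π
predictors are collinear: (g_i, A_i·) and (g_i + c, A_i· − c·1)
generate identical dynamics. We fix the gauge by dropping the
denominator column from the regression design and reporting A_iD ≡ 0.
All dynamical quantities are gauge-invariant; the gauge only matters
when reading individual matrix entries, and the synthetic generator
produces ground truth in the same gauge so that parameter-recovery
experiments are well-posed.

**Inference** is one-step gradient matching: every consecutive
same-subject pair (t, t+Δ) contributes responses
y_i = (η_i(t+Δ) − η_i(t))/Δ and predictors [1, π(t)₋D, u(t)], where
u_k = 1 iff the interval's start sample is annotated with intervention
k. Per-target elastic-net regressions (mixing 0.5, penalty grid
logarithmic over six decades) are pooled over all pairs; the penalty is
selected per target by 5-fold subject-grouped cross-validation. Δt
enters only as the normaliser of the response, not as a covariate.
`fit_clv_pairs` exposes the same estimator for explicit composition
pairs (fractional intervals, dense designs).

**Cross-validation** splits subjects 25:75 (stratifying on
interventions held by > 3 subjects; rarer labels are pooled before
stratification), selects the penalty once on the 75 % group, then
leave-one-out over the 25 % group: each held-out subject is predicted
from its own baseline by integrating over the true intervals with the
true intervention indicators, against the static no-change baseline.
Errors are RMSE on relative abundances, plus RMSLE and Aitchison
distance after the 10⁻⁵ pseudocount; cLV and static error sets are
compared with a Wilcoxon rank-sum test per metric.

**Integration** is fixed-step RK4 in η-space: step 0.1 day for
within-study horizons (≤ 63 days), 1.0 day for the long steady-state
runs. η is clipped at ±500 (the composition map saturates far earlier)
and computed with a max-shift to avoid overflow. Halving the step
changes 30-day endpoints by < 10⁻⁶ in L1 on the test systems.

## Steady states and ecological stability

A steady state on support S (∋ D) solves the linear system
g_i + Σ_{j∈S} A_ij π_j = 0 (i ∈ S∖{D}) plus closure Σ_{j∈S} π_j = 1;
solutions with any non-positive abundance, or singular systems, are
infeasible. `find_steady_state` integrates the subject's restricted
system (nominal horizon 10⁵ days; the integrator stops as soon as the
one-day Bray-Curtis drift falls below 10⁻¹⁰, far below the 10⁻³
convergence control it also enforces, which typically happens within a
few hundred days), takes the endpoint's ≥ 10⁻⁵ taxa (plus D) as the
candidate support, and accepts the analytic solution when it lies
within Bray-Curtis 10⁻² of the endpoint; otherwise supports obtained by
additionally dropping taxa within 10× of the zero threshold are tried
and the feasible solution closest to the endpoint wins.

When the *denominator* taxon itself decays below the zero threshold,
the boundary equilibrium is not representable in its log-ratio basis
(η diverges). The system is then re-expressed exactly against the
dominant endpoint taxon (`change_denominator`: g′ = g − g_D′,
A′ = A − A_D′-row — the induced simplex dynamics are identical) and
solved there; the returned state records the working basis so that
Jacobians are evaluated consistently.

**Jacobian.** The π-space dynamics induced by the η-equations are the
replicator-form field dπ_i/dt = π_i(F_i − πᵀF) with F = g + Aπ and
F_D = 0. A Jacobian requires extending this field off the simplex; we
differentiate the normalisation-aware extension (drift evaluated at
x/Σx), giving the closed form

    J_il = δ_il (F_i − φ) + π_i [A_il − F_l − (πᵀA)_l − ((Aπ)_i − φ − πᵀAπ)]

with φ = πᵀF. Its columns sum to zero at every simplex point, so one
eigenvalue is always ~0 (left eigenvector **1**). Different extensions
of the same on-simplex field differ by a rank-one w·1ᵀ term and share
the tangent-restricted spectrum, so every stability measure is
extension-independent. Local stability is reported both **raw**
(−max Re λ over the full spectrum — ≤ 0 by the structural zero, and
the value a direct reading of "Jacobian eigenvalues" produces) and
**tangent** (after projecting J onto {δ : Σδ = 0} with an orthonormal
basis, removing exactly the zero mode). Rows of off-support taxa
reduce to their invasion rates F_i − φ, so invasibility shows up in the
raw spectrum.

**Distances to steady state** are the inverse forms 1 − BC(π₀, π*) and
−Aitchison(π₀, π*) (pseudocount 10⁻⁵ on both vectors).

**Robustness.** For r = 1..⌊N/2⌋ (N = baseline richness) and 10 seeded
draws per r, r random non-denominator taxa are removed, the remainder
renormalised, the system rerun to steady state, and survivors below
10⁻⁵ counted as secondary extinctions E. A least-squares cubic through
the total-loss curve T(r) = r + E(r) gives the smallest r* with
T(r*) = N/2 (piecewise-linear interpolation through the empirical
points, extrapolating the last segment, when the cubic has no root in
range); Rob₀.₅ = r*/N. Because definitions differ on whether the
removed taxa count toward the 50 % loss, the secondary-only variant
(root of E(r) = N/2, NaN when no cascade reaches that depth) is
emitted alongside; the total-loss form is the default. When a removal
profile reaches no analytic equilibrium (e.g. a cycling subsystem), the
long-simulation endpoint composition stands in for counting
extinctions. For N ≤ 6 the Monte-Carlo estimate is validated against
exhaustive enumeration of all removal subsets.

## Observational stability

Seven measured metrics between each subject's first two samples —
1−BC, 1−WUni, Pearson correlation, 1−Euc(log), −Aitchison, 1−Jaccard,
−RC_bray — and two predictive ones from the baseline (inverse response
potential via BC and Aitchison). "Inverse" is 1 − d for [0, 1]-bounded
metrics and −d otherwise, so larger is always more stable.

Weighted UniFrac is the normalised form Σ_b l_b |p_b − q_b| /
Σ_b l_b (p_b + q_b) over branches (p_b = leaf mass below b); on a unit
star tree it reduces to Bray-Curtis, and the implementation is checked
against scikit-bio's. The Raup–Crick null (999 reps) preserves each
community's richness — taxa drawn with probability ∝ occurrence
frequency in the enterotype context — and its rarefied depth
(multinomial fill ∝ mean context relative abundance); ties count half,
rc = 2((#null<obs + ½#null=obs)/reps − ½) ∈ [−1, 1]. Rarefied counts
are used for the null (and the Jaccard presence call) because the fill
step needs a defined depth. Response potential is the mean distance
from a baseline to the baselines of all other subjects in the same
enterotype (neighbourhood size k is exposed; the default uses the full
context).

## Networks

cLV networks take a subject's baseline-support taxa as nodes and each
non-zero A_ij as a directed edge j → i (the denominator node has no
incoming edges by construction, and none outgoing under the gauge
above). Connectance C = L/N with ordered pairs counted separately;
H = population variance of (in+out) degrees; S = mean |non-zero
weight|; S_c (S_m) sums |weights| over mutually negative (weights over
mutually positive) ordered pairs divided by N(N−1) — pairs without the
reciprocal pattern enter as zeros, with nonzero-only variants also
emitted; b = ln L / ln N, the one link–node scaling coefficient
computable from (L, N) alone, which are always emitted for
re-derivation.

Exchange-derived indices for a genus pair (X, Y) use the metabolite
universe M_XY = metabolites linked to either genus (the smallest
universe keeping both indices ≤ 1): crossfeeding =
|(exp_X∩imp_Y) ∪ (exp_Y∩imp_X)|/|M_XY|, competition =
|imp_X∩imp_Y|/|M_XY|. Metabolites shared by > 70 % of genus pairs
(linked to both members) are dropped first — the ubiquitous-currency
filter. Exchange networks connect pairs with either index non-zero;
S_m/S_c are average cross-feeding/competition indices over edges and S
averages the non-zero per-edge means of the two.

## Meta-statistics

Every stability measure is residualised by OLS on [1, Δt, intervention
indicator contrasts, baseline Shannon] (adjusting for alpha diversity
breaks the computational alpha–beta coupling). Aliased design columns
resolve through the minimum-norm solution with a warning;
residualisation is a projection (idempotent to 10⁻¹²). Residual pairs
are compared with pairwise-complete Pearson correlation (per-pair n
reported; tree-dependent metrics may be missing), BH-corrected over all
off-diagonal pairs within a stratum, and clustered by complete linkage
at distance 1 − r (not 1 − |r|: the clusters of interest are
positively-correlated families), default cut at two clusters. Taxa
associations regress each measure on each baseline clr abundance with
the same covariates, BH over all (taxon, metric) tests.

## Synthetic cohorts

The generator emulates the structure of multi-study interventional 16S
time series: per-subject series of 2–8 time points (range allows up to
56) at 3–21-day gaps (within the 1–63-day envelope of such designs),
read depths LogNormal(ln 30000, 0.3), ~50 % of subjects assigned one of
K = 2 intervention labels, subjects round-robined over 3 study labels,
and an enterotype-style label from the nearest of two archetype
compositions.

Systems are sampled with Bernoulli(connectance) × Normal(0, 0.4)
off-diagonal interactions and −|Normal(1.5, 0.4)| self-limitation.
Growth rates are **constructed**, g = −Aπ* for a Dirichlet-drawn target
composition π*, making π* an exact interior equilibrium; candidates are
rejected until π* is tangent-stable and a 1000-day simulation from the
uniform composition stays finite. This emulates the coexisting
communities the method targets — purely random growth rates collapse
roughly half the taxa by competitive exclusion, leaving baselines too
species-poor for the removal protocol. σ_g adds optional jitter on top
(default 0). Baselines perturb the attractor with
Dirichlet(50·π*) noise and per-taxon knockouts (p = 0.2); trajectories
between sampling days use an RK4 drift step (consistent with the
deterministic simulator) plus Euler–Maruyama η-noise of 0.05 √day;
observations are multinomial draws at the sampled depth. Exchange
tables are built sign-consistently: mutually negative pairs share an
imported metabolite, mutually positive pairs get an export→import
chain, plus a configurable fraction of spurious records.

What the generator does **not** emulate: absolute-load variation,
per-subject parameter heterogeneity, taxonomic mis-assignment,
compositional batch effects between studies, or non-stationary
dynamics. Passing tests therefore demonstrate correctness of the
estimators and measures under the model's own assumptions, not
robustness to their violation on real data.

## Problem sizes and determinism

Validation runs use deliberately compact designs: equilibrium matching
on 50 twelve-taxon subjects, robustness oracles on ten 6-taxon systems
(where exhaustive enumeration is exact), recovery on 5-taxon systems
with 200 dense pairs, and a ~110-system connectance sweep (0.1–0.9,
8 taxa) for the stability/robustness trade-off — sizes at which every
check, including the brute-force oracles, completes in minutes on one
CPU. The noisy recovery condition is reported as the mean over five
replicate noise draws, since a single 200-pair draw quantises sign
agreement in steps of ~1/9. All randomness flows from explicit seeds;
reruns are bit-identical.

On the trade-off: in this ensemble the b-dependence reproduces the
expected directions (robustness decreases with b; local stability does
not), but the *direct* Spearman correlation between Rob₀.₅ and tangent
local stability comes out positive rather than negative. The negative
trade-off reported for fitted gut communities involves heterogeneous,
partially unstable steady states across enterotype-specific models;
an ensemble of globally stable random interior equilibria is a
different population, and the direction of the direct correlation is
reported, not asserted.

## Known limitations

* Inference is one-step gradient matching, not a state-space or
  spline-based estimator; long gaps between samples bias A toward zero
  (attenuation), mitigated but not removed by the elastic net.
* The raw local-stability value is structurally ≤ 0 (zero mode); use
  the tangent variant when a strictly negative return rate is needed.
* Raup–Crick and response potential need ≥ 10 context samples; WUni
  needs a tree covering all non-zero taxa — missing inputs yield
  flagged NaNs, and correlations run pairwise-complete.
* `find_steady_state` can fail on systems with limit cycles or
  near-degenerate interaction matrices; callers receive an explicit
  error (the robustness protocol falls back to endpoint compositions).
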