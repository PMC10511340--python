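"""Ground-truth cLV systems and synthetic longitudinal cohorts.

The generator emulates the structure of multi-study gut-microbiome time
series: a known cLV system drives per-subject trajectories started from
perturbed steady-state baselines, observed through multinomial read
sampling at lognormal depths, with log-ratio (eta-space) process noise
between sampling days so that compositions stay on the simplex by
construction.  Every cohort ships with its generating model, so
inference, stability and network computations can be validated against
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clv import CLVModel, bray_curtis, simulate_clv, _pi_from_eta
from .eco import NoEquilibriumError, find_steady_state
from .io import AbundanceTable

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_clv_system",
    "simulate_cohort",
    "generate_exchange_table",
    "random_ultrametric_tree",
]


@dataclass
class SyntheticConfig:
    """Study-design and dynamical parameters of a synthetic cohort.

    Defaults give a cohort of 120 subjects with 2-8 time points at
    3-21-day gaps (within the 1-63-day window of typical interventional
    designs), read depths LogNormal(ln 30000, 0.3), moderate interaction
    density and eta-space process noise of 0.05 per sqrt(day).
    """

    n_taxa: int = 12
    connectance: float = 0.3  # probability of a non-zero off-diagonal A entry
    sigma_A: float = 0.4  # scale of interaction strengths, 1/(day * rel.ab.)
    diag_mean: float = 1.5  # mean magnitude of (negative) self-limitation
    sigma_g: float = 0.0  # jitter on the equilibrium-constructed growth rates, 1/day
    n_interventions: int = 2
    sigma_B: float = 0.2  # scale of intervention effects, 1/day
    sigma_eta: float = 0.05  # process noise on eta per sqrt(day)
    depth_log_mean: float = float(np.log(30000))
    depth_log_sd: float = 0.3
    n_subjects: int = 120
    timepoints_range: tuple[int, int] = (2, 8)  # inclusive, within [2, 56]
    gap_range: tuple[int, int] = (3, 21)  # days, within [1, 63]
    baseline_concentration: float = 50.0  # Dirichlet concentration around pi*
    knockout_prob: float = 0.2  # per-taxon baseline support knockout
    intervened_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if not (0 < self.connectance <= 1):
            raise ValueError("connectance must lie in (0, 1]")
        lo, hi = self.gap_range
        if lo < 1 or hi > 63 or lo > hi:
            raise ValueError("gaps must lie within [1, 63] days")
        lo, hi = self.timepoints_range
        if lo < 2 or hi > 56 or lo > hi:
            raise ValueError("time-point counts must lie within [2, 56]")
        for name in ("sigma_A", "sigma_g", "sigma_B", "sigma_eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    model: CLVModel
    baseline_supports: dict = field(default_factory=dict)  # subject -> taxon indices
    interventions: dict = field(default_factory=dict)  # subject -> label
    attractor: np.ndarray | None = None


def generate_clv_system(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[CLVModel, GroundTruth]:
    """Sample a cLV system with a rich, locally stable interior attractor.

    Off-diagonal interactions are Bernoulli(connectance) *
    Normal(0, sigma_A); diagonals are -|Normal(diag_mean, sigma_A)|
    (self-limitation); the last taxon is the denominator (row zeroed).
    Growth rates are constructed as g = -A pi* for a Dirichlet-drawn
    target composition pi*, which makes pi* an exact interior
    equilibrium — emulating a coexisting community rather than one
    collapsing by competitive exclusion; ``sigma_g`` adds optional
    jitter on top.  Candidate systems are rejected until pi* is locally
    stable in the simplex tangent space and a 1000-day simulation from
    the uniform composition stays finite.
    """
    from .eco import local_stability

    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_taxa
    names = [f"g{i:02d}" for i in range(n)]
    for attempt in range(100):
        A = rng.normal(0.0, config.sigma_A, size=(n, n))
        mask = rng.random((n, n)) < config.connectance
        np.fill_diagonal(mask, False)
        A = np.where(mask, A, 0.0)
        np.fill_diagonal(A, -np.abs(rng.normal(config.diag_mean, config.sigma_A, n)))
        # gauge convention shared with the estimator: the denominator
        # column of the relative interaction matrix is zero
        A[:, n - 1] = 0.0
        pi_target = rng.dirichlet(np.full(n, 3.0))
        g = -(A @ pi_target)
        if config.sigma_g > 0:
            g = g + rng.normal(0.0, config.sigma_g, n)
        B = rng.normal(0.0, config.sigma_B, (n, config.n_interventions))
        model = CLVModel(
            taxon_names=names,
            denominator=n - 1,
            g=g,
            A=A,
            B=B,
            intervention_levels=[f"I{k+1}" for k in range(config.n_interventions)],
        )
        if config.sigma_g == 0:
            # pi_target is an exact equilibrium; require tangent stability
            if local_stability(model, pi_target, "tangent") <= 0:
                continue
        uniform = np.full(n, 1.0 / n)
        try:
            traj = simulate_clv(
                model, uniform, horizon_days=1000.0, step=0.5, record_every=10**6
            )
        except FloatingPointError:
            continue
        end = traj.compositions[-1]
        if np.isfinite(end).all() and end[model.denominator] > 1e-12:
            truth = GroundTruth(model=model, attractor=pi_target if config.sigma_g == 0 else None)
            return model, truth
    raise RuntimeError(
        "no bounded stable system found in 100 attempts; reduce sigma_A or connectance"
    )


def _euler_maruyama_segment(
    model: CLVModel,
    pi0: np.ndarray,
    days: float,
    u: np.ndarray | None,
    sigma_eta: float,
    rng: np.random.Generator,
    step: float = 0.1,
) -> np.ndarray:
    """Integrate one inter-sample interval with eta-space process noise."""
    n = model.n_taxa
    D = model.denominator
    active = np.flatnonzero((pi0 > 0) & (np.arange(n) != D))
    eta = np.log(pi0[active] / pi0[D])
    g = model.g[active]
    A = model.A[active]
    Bu = (model.B[active] @ u) if (u is not None and model.n_interventions) else 0.0
    n_steps = max(1, int(round(days / step)))
    h = days / n_steps
    sq = sigma_eta * np.sqrt(h)

    def drift(e):
        return g + A @ _pi_from_eta(e, active, D, n) + Bu

    for _ in range(n_steps):
        # RK4 drift (consistent with the deterministic simulator) plus
        # Euler-Maruyama diffusion on eta
        k1 = drift(eta)
        k2 = drift(eta + 0.5 * h * k1)
        k3 = drift(eta + 0.5 * h * k2)
        k4 = drift(eta + h * k3)
        eta = eta + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if sigma_eta > 0:
            eta = eta + sq * rng.standard_normal(len(active))
        np.clip(eta, -500.0, 500.0, out=eta)
        if not np.isfinite(eta).all():
            raise FloatingPointError("stochastic trajectory blew up")
    return _pi_from_eta(eta, active, D, n)


def _default_archetypes(n: int) -> dict[str, np.ndarray]:
    """Two simplex archetypes used only to assign enterotype-style labels."""
    a = np.ones(n)
    a[: n // 2] = 4.0
    b = np.ones(n)
    b[n // 2 :] = 4.0
    return {"Rum": a / a.sum(), "Prev": b / b.sum()}


def simulate_cohort(
    model: CLVModel,
    config: SyntheticConfig,
    seed: int | None = None,
    archetypes: dict[str, np.ndarray] | None = None,
    study_assignment: int = 3,
    attractor: np.ndarray | None = None,
) -> tuple[AbundanceTable, pd.DataFrame, GroundTruth]:
    """Generate a longitudinal multi-subject cohort from a known system.

    Baselines perturb the system's attractor with Dirichlet noise and
    random support knockouts; trajectories evolve with Euler-Maruyama
    noise between sampling days; each sampled composition becomes a
    multinomial count vector at a lognormal depth.  Subjects are
    round-robined over ``study_assignment`` study labels, and labelled
    with the nearest of two archetype compositions (enterotype stand-in).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = model.n_taxa
    D = model.denominator
    uniform = np.full(n, 1.0 / n)
    if attractor is None:
        try:
            attractor = find_steady_state(model, uniform).pi_star
        except (NoEquilibriumError, FloatingPointError):
            traj = simulate_clv(
                model, uniform, horizon_days=2000.0, step=0.5, record_every=10**6
            )
            attractor = traj.compositions[-1]
    if archetypes is None:
        archetypes = _default_archetypes(n)
    levels = model.intervention_levels
    truth = GroundTruth(model=model, attractor=attractor)
    records = []
    meta_rows = []
    sample_counter = 0
    for s in range(config.n_subjects):
        subject = f"S{s:03d}"
        if levels and rng.random() < config.intervened_fraction:
            label = levels[rng.integers(len(levels))]
        else:
            label = "none"
        u = None
        if label != "none":
            u = np.zeros(len(levels))
            u[levels.index(label)] = 1.0
        for _attempt in range(20):
            # baseline: Dirichlet perturbation of the attractor + knockouts
            keep = np.ones(n, dtype=bool)
            for i in range(n):
                if i != D and rng.random() < config.knockout_prob:
                    keep[i] = False
            base = np.where(attractor > 0, attractor, 1e-4) * keep
            if keep.sum() < 3 or base[D] <= 0:
                continue
            alpha = config.baseline_concentration * base[keep] / base[keep].sum()
            pi = np.zeros(n)
            pi[keep] = rng.dirichlet(np.maximum(alpha, 1e-3))
            if pi[D] <= 0:
                continue
            n_tp = int(rng.integers(config.timepoints_range[0], config.timepoints_range[1] + 1))
            gaps = rng.integers(config.gap_range[0], config.gap_range[1] + 1, size=n_tp - 1)
            days = np.concatenate([[0], np.cumsum(gaps)])
            try:
                compositions = [pi.copy()]
                cur = pi
                for gap in gaps:
                    cur = _euler_maruyama_segment(
                        model, cur, float(gap), u, config.sigma_eta, rng
                    )
                    compositions.append(cur.copy())
            except FloatingPointError:
                continue
            break
        else:
            raise RuntimeError(f"could not generate a bounded trajectory for {subject}")
        truth.baseline_supports[subject] = np.flatnonzero(pi > 0)
        truth.interventions[subject] = label
        # enterotype-style label by nearest archetype to the baseline
        ent = min(archetypes, key=lambda k: bray_curtis(pi, archetypes[k]))
        for day, comp in zip(days, compositions):
            depth = int(round(rng.lognormal(config.depth_log_mean, config.depth_log_sd)))
            counts = rng.multinomial(depth, comp / comp.sum())
            sid = f"smp{sample_counter:05d}"
            sample_counter += 1
            records.append(pd.Series(counts, name=sid))
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subject,
                    "study_id": f"study{s % study_assignment}",
                    "day": int(day),
                    "intervention": label,
                    "enterotype": ent,
                }
            )
    data = pd.DataFrame(records)
    data.columns = model.taxon_names
    table = AbundanceTable(data.astype(float), kind="counts")
    meta = pd.DataFrame(meta_rows)
    meta = meta.sort_values(["subject_id", "day"]).reset_index(drop=True)
    return table, meta, truth


def generate_exchange_table(
    model: CLVModel, noise_rate: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Exchange records whose indices are sign-consistent with A.

    Mutually negative interaction pairs share an imported metabolite
    (competition index > 0); mutually positive pairs get an export ->
    import chain (cross-feeding index > 0).  ``noise_rate`` adds that
    fraction of spurious random records on top.
    """
    rng = np.random.default_rng(seed)
    names = model.taxon_names
    n = model.n_taxa
    rows = []
    met = 0
    for i in range(n):
        for j in range(i + 1, n):
            if model.A[i, j] < 0 and model.A[j, i] < 0:
                m = f"met{met:03d}"
                met += 1
                rows.append({"genus": names[i], "metabolite": m, "direction": "import"})
                rows.append({"genus": names[j], "metabolite": m, "direction": "import"})
            if model.A[i, j] > 0 and model.A[j, i] > 0:
                m = f"met{met:03d}"
                met += 1
                rows.append({"genus": names[i], "metabolite": m, "direction": "export"})
                rows.append({"genus": names[j], "metabolite": m, "direction": "import"})
    n_noise = int(round(noise_rate * len(rows)))
    for _ in range(n_noise):
        m = f"noise{rng.integers(10**6):06d}"
        rows.append(
            {
                "genus": names[rng.integers(n)],
                "metabolite": m,
                "direction": "import" if rng.random() < 0.5 else "export",
            }
        )
    out = pd.DataFrame(rows, columns=["genus", "metabolite", "direction"])
    out = out.drop_duplicates().reset_index(drop=True)
    out.attrs["source"] = "synthetic"
    return out


def random_ultrametric_tree(taxon_names, seed: int = 0) -> str:
    """Random ultrametric Newick string over the given leaves.

    Utility for weighted-UniFrac tests; pairs of clades are merged at
    increasing heights so root-to-tip distances are equal.
    """
    rng = np.random.default_rng(seed)
    clades = [(name, 0.0) for name in taxon_names]
    height = 0.0
    while len(clades) > 1:
        height += float(rng.uniform(0.2, 1.0))
        i, j = rng.choice(len(clades), size=2, replace=False)
        (na, ha), (nb, hb) = clades[i], clades[j]
        merged = f"({na}:{height - ha:.6f},{nb}:{height - hb:.6f})"
        clades = [c for k, c in enumerate(clades) if k not in (i, j)]
        clades.append((merged, height))
    return clades[0][0] + ";"
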