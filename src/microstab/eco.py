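"""Steady states and ecological stability of cLV communities.

Four measures are computed per community (subject baseline):

* local stability: -max Re(lambda) of the Jacobian of the simplex
  (replicator-form) vector field at the steady state, raw and after
  projecting out the structural zero mode tangent to the simplex;
* two distances-to-steady-state: 1 - Bray-Curtis and -Aitchison between
  the baseline composition and its attracting equilibrium;
* robustness Rob_0.5: the fraction of taxa whose removal halves the
  community richness, estimated by removal-resimulation experiments.

The simplex field is dpi_i/dt = pi_i (F_i - sum_m pi_m F_m) with
F_i = g_i + (A pi)_i and F_D = 0; it is the unique pi-space dynamics
induced by the log-ratio (eta) equations and admits a closed-form
Jacobian.  Its column sums vanish identically (left null vector 1), so
one eigenvalue is always ~0 and the raw local-stability value is <= 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .clv import CLVModel, aitchison_distance, bray_curtis, simulate_clv
from .io import AbundanceTable

__all__ = [
    "SteadyState",
    "EcoStability",
    "RobustnessResult",
    "NoEquilibriumError",
    "solve_equilibrium",
    "find_steady_state",
    "jacobian_at",
    "local_stability",
    "state_distance",
    "robustness",
    "eco_stability_panel",
]


class NoEquilibriumError(RuntimeError):
    """No feasible analytic equilibrium matches the simulation endpoint."""


@dataclass
class SteadyState:
    support: np.ndarray  # sorted taxon indices, includes the denominator
    pi_star: np.ndarray  # full-length simplex vector, zero off support
    residual: float
    match_bc: float | None = None  # Bray-Curtis to the simulation endpoint
    feasible: bool = True
    # model in whose log-ratio basis the state was solved; differs from
    # the caller's model only when the original denominator went extinct
    # and the system was re-expressed against a surviving reference
    model: "CLVModel | None" = None


@dataclass
class EcoStability:
    neg_lambda_max: float  # raw full-spectrum value (<= 0 by the zero mode)
    neg_lambda_max_tangent: float  # after removing the structural zero mode
    stp_bc: float  # 1 - BC(baseline, steady state)
    stp_ait: float  # -Aitchison(baseline, steady state)
    rob50: float  # total-loss definition (removed + secondary) / N target
    rob50_secondary: float  # secondary-extinctions-only variant (may be NaN)
    steady_state: SteadyState | None = None


@dataclass
class RobustnessResult:
    rob50: float
    rob50_secondary: float
    r_values: np.ndarray
    mean_extinctions: np.ndarray  # E(r)
    se_extinctions: np.ndarray  # Monte-Carlo SE of E(r)
    n_taxa: int


# ---------------------------------------------------------------------------
# analytic equilibria


def solve_equilibrium(model: CLVModel, support) -> SteadyState:
    """Solve the cLV equilibrium equations on a taxon subset.

    Unknowns are the support abundances; equations are
    g_i + sum_{j in S} A_ij pi_j = 0 for i in S \\ {D} plus closure
    sum pi_j = 1.  Singular systems or any non-positive abundance are
    reported as infeasible.
    """
    support = np.asarray(sorted(set(int(i) for i in support)), dtype=int)
    D = model.denominator
    if D not in support:
        raise ValueError("support must contain the denominator")
    m = len(support)
    pi_star = np.zeros(model.n_taxa)
    if m == 1:
        pi_star[D] = 1.0
        return SteadyState(support=support, pi_star=pi_star, residual=0.0)
    rows = [i for i in support if i != D]
    M = np.zeros((m, m))
    rhs = np.zeros(m)
    for r, i in enumerate(rows):
        M[r, :] = model.A[i, support]
        rhs[r] = -model.g[i]
    M[m - 1, :] = 1.0
    rhs[m - 1] = 1.0
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        return SteadyState(
            support=support, pi_star=pi_star, residual=np.inf, feasible=False
        )
    if not np.isfinite(sol).all() or (sol <= 0).any():
        return SteadyState(
            support=support, pi_star=pi_star, residual=np.inf, feasible=False
        )
    pi_star[support] = sol
    resid = max(
        abs(float(model.g[i] + model.A[i, support] @ sol)) for i in rows
    ) if rows else 0.0
    resid = max(resid, abs(float(sol.sum() - 1.0)))
    return SteadyState(support=support, pi_star=pi_star, residual=resid)


def find_steady_state(
    model: CLVModel,
    pi0,
    horizon_days: float = 1e5,
    zero_thr: float = 1e-5,
    step: float = 1.0,
    stop_bc_tol: float = 1e-10,
    drift_tol: float = 1e-3,
    match_tol: float = 1e-2,
) -> SteadyState:
    """Simulate to (numerical) convergence and match an analytic equilibrium.

    The trajectory is integrated without interventions until either the
    horizon or until the one-day Bray-Curtis drift falls below
    ``stop_bc_tol``; the endpoint must drift by < ``drift_tol`` per day.
    The candidate support is the set of taxa above ``zero_thr`` at the
    endpoint (plus the denominator); if its analytic solution is
    infeasible or farther than ``match_tol`` (Bray-Curtis) from the
    endpoint, supports obtained by also dropping taxa within 10x of
    ``zero_thr`` are tried and the feasible solution closest to the
    endpoint wins.
    """
    pi0 = np.asarray(pi0, dtype=float)
    traj = simulate_clv(
        model,
        pi0,
        u=None,
        horizon_days=horizon_days,
        step=step,
        record_every=10**9,
        stop_bc_tol=stop_bc_tol,
    )
    end = traj.compositions[-1]
    # verify residual drift over one more simulated day
    tail = simulate_clv(model, end, u=None, horizon_days=1.0, step=min(step, 1.0))
    drift = bray_curtis(tail.compositions[-1], end)
    if drift > drift_tol:
        raise NoEquilibriumError(
            f"trajectory still drifting at horizon (daily BC {drift:.2e})"
        )
    idx = np.arange(model.n_taxa)
    baseline_support = set(idx[pi0 > 0])
    work = model
    if end[model.denominator] < zero_thr:
        # the reference taxon itself went (near-)extinct: the boundary
        # equilibrium is not representable in its log-ratio basis, so
        # re-express the identical dynamics against the dominant taxon
        work = model.change_denominator(int(np.argmax(end)))
    D = work.denominator
    candidate = sorted({i for i in idx[end >= zero_thr]} | {D})
    borderline = [
        i for i in candidate if i != D and end[i] < 10 * zero_thr
    ]
    tried: list[SteadyState] = []

    def try_support(supp):
        st = solve_equilibrium(work, supp)
        if st.feasible:
            st.match_bc = bray_curtis(end, st.pi_star)
            st.model = work
            tried.append(st)
        return st

    first = try_support(candidate)
    if first.feasible and first.match_bc <= match_tol:
        best = first
    else:
        for k in range(1, len(borderline) + 1):
            for drop in itertools.combinations(borderline, k):
                supp = [i for i in candidate if i not in set(drop)]
                try_support(supp)
        feasible = [s for s in tried if s.match_bc is not None]
        if not feasible:
            raise NoEquilibriumError(
                f"no matching equilibrium: candidate support {candidate}, "
                f"endpoint {np.round(end, 4)}"
            )
        best = min(feasible, key=lambda s: s.match_bc)
    if not set(best.support) <= baseline_support:
        raise NoEquilibriumError("equilibrium support escapes the baseline support")
    return best


# ---------------------------------------------------------------------------
# Jacobian and local stability


def jacobian_at(model: CLVModel, state) -> np.ndarray:
    """Closed-form Jacobian of the simplex field at a composition.

    The simplex field dpi_i/dt = pi_i (F_i - phi), F = g + A pi
    (F_D = 0), phi = pi^T F, is extended off the simplex by evaluating
    the drift at the closed composition x / sum(x); differentiating that
    extension gives

        J_il = d_il (F_i - phi)
               + pi_i [ A_il - F_l - (pi^T A)_l - ((A pi)_i - phi - pi^T A pi) ]

    whose columns sum to zero at *every* simplex point (left null vector
    1^T), not just at equilibria.  Any two extensions of the same
    on-simplex field differ by a rank-one w 1^T term, so the
    tangent-restricted spectrum — and with it every stability measure —
    is extension-independent; rows of off-support taxa reduce to their
    diagonal invasion rate F_i - phi.
    """
    pi = state.pi_star if isinstance(state, SteadyState) else np.asarray(state, float)
    F = model.g + model.A @ pi
    F[model.denominator] = 0.0
    phi = float(pi @ F)
    piA = pi @ model.A  # (pi^T A)_l
    Api = model.A @ pi  # (A pi)_i
    correction = Api - phi - float(pi @ Api)
    J = np.diag(F - phi) + pi[:, None] * (
        model.A - F[None, :] - piA[None, :] - correction[:, None]
    )
    return J


def _tangent_projection(n: int) -> np.ndarray:
    # orthonormal basis of {x : sum x = 0}
    return sla.null_space(np.ones((1, n)))


def local_stability(model: CLVModel, state, mode: str = "raw") -> float:
    """Negative of the largest real eigenvalue part of the Jacobian.

    ``raw`` keeps the structural zero mode (so the value is <= 0);
    ``tangent`` restricts the Jacobian to the simplex tangent space
    first, removing that mode.
    """
    J = jacobian_at(model, state)
    if mode == "raw":
        eig = np.linalg.eigvals(J)
    elif mode == "tangent":
        V = _tangent_projection(J.shape[0])
        eig = np.linalg.eigvals(V.T @ J @ V)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(-np.max(eig.real))


def state_distance(pi0, steady_state, metric: str = "bc") -> float:
    """Inverse distance from a baseline to its steady state.

    ``bc`` returns 1 - Bray-Curtis; ``aitchison`` returns -Aitchison
    (1e-5 pseudocount on both vectors).
    """
    pi_star = (
        steady_state.pi_star
        if isinstance(steady_state, SteadyState)
        else np.asarray(steady_state, float)
    )
    pi0 = np.asarray(pi0, dtype=float)
    if metric == "bc":
        return 1.0 - bray_curtis(pi0, pi_star)
    if metric == "aitchison":
        return -aitchison_distance(pi0, pi_star)
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# robustness to species loss


def _longrun_composition(model: CLVModel, pi, zero_thr: float):
    """Long-run composition after a removal: analytic steady state when
    one matches, otherwise the (possibly non-equilibrium) endpoint of
    the long simulation."""
    try:
        st = find_steady_state(model, pi, zero_thr=zero_thr)
        return st.pi_star
    except (NoEquilibriumError, FloatingPointError):
        traj = simulate_clv(
            model, pi, u=None, horizon_days=1e5, step=1.0,
            record_every=10**9, stop_bc_tol=1e-10,
        )
        return traj.compositions[-1]


def _removal_extinctions(
    model: CLVModel, pi0: np.ndarray, removed, zero_thr: float
) -> int:
    pi = pi0.copy()
    pi[list(removed)] = 0.0
    pi = pi / pi.sum()
    end = _longrun_composition(model, pi, zero_thr)
    survivors = np.flatnonzero(pi > 0)
    return int((end[survivors] < zero_thr).sum())


def _first_crossing(r: np.ndarray, total: np.ndarray, target: float) -> float:
    """Smallest r where the piecewise-linear curve through (0,0) and the
    empirical points reaches ``target``; extrapolates the last segment."""
    rr = np.concatenate([[0.0], r.astype(float)])
    tt = np.concatenate([[0.0], total.astype(float)])
    for a in range(len(rr) - 1):
        lo, hi = tt[a], tt[a + 1]
        if (lo < target <= hi) or (lo <= target < hi):
            if hi == lo:
                return float(rr[a])
            return float(rr[a] + (target - lo) * (rr[a + 1] - rr[a]) / (hi - lo))
    slope = (tt[-1] - tt[-2]) / (rr[-1] - rr[-2]) if len(rr) > 1 else 1.0
    if slope <= 0:
        return np.nan
    return float(rr[-1] + (target - tt[-1]) / slope)


def _poly_root(r: np.ndarray, total: np.ndarray, target: float) -> float:
    """Smallest root of the least-squares cubic of total(r) = target in
    [1, max r]; NaN if none."""
    deg = min(3, len(r) - 1)
    if deg < 1:
        return np.nan
    coef = np.polyfit(r, total, deg)
    coef = coef.copy()
    coef[-1] -= target
    roots = np.roots(coef)
    real = roots[np.abs(roots.imag) < 1e-9].real
    in_range = real[(real >= 1.0 - 1e-9) & (real <= r[-1] + 1e-9)]
    if in_range.size == 0:
        return np.nan
    return float(in_range.min())


def robustness(
    model: CLVModel,
    pi0,
    reps: int = 10,
    zero_thr: float = 1e-5,
    seed: int = 0,
    exhaustive: bool = False,
) -> RobustnessResult:
    """Rob_0.5 by removal-resimulation experiments.

    For r = 1..floor(N/2) (N = baseline richness) remove r random
    non-denominator taxa (``reps`` seeded draws each, or every subset
    when ``exhaustive``), renormalise, rerun to steady state and count
    secondary extinctions (survivors below ``zero_thr``).  A cubic fit
    to the total loss T(r) = r + E(r) gives the smallest r* with
    T(r*) = N/2 (piecewise-linear fallback); rob50 = r*/N.  The
    secondary-only variant solves E(r) = N/2 instead and is NaN when no
    cascade ever reaches that depth.
    """
    pi0 = np.asarray(pi0, dtype=float)
    support = np.flatnonzero(pi0 > 0)
    N = len(support)
    if N < 4:
        raise ValueError("robustness needs a baseline richness of at least 4")
    if model.denominator not in support:
        raise ValueError("denominator absent from the baseline support")
    removable = [int(i) for i in support if i != model.denominator]
    rng = np.random.default_rng(seed)
    r_values = np.arange(1, N // 2 + 1)
    means, ses = [], []
    for r in r_values:
        if exhaustive:
            draws = list(itertools.combinations(removable, r))
        else:
            draws = [
                tuple(rng.choice(removable, size=r, replace=False))
                for _ in range(reps)
            ]
        ext = np.array(
            [_removal_extinctions(model, pi0, d, zero_thr) for d in draws],
            dtype=float,
        )
        means.append(ext.mean())
        ses.append(ext.std(ddof=1) / np.sqrt(len(ext)) if len(ext) > 1 else 0.0)
    E = np.asarray(means)
    target = N / 2.0
    total = r_values + E
    r_star = _poly_root(r_values.astype(float), total, target)
    if not np.isfinite(r_star):
        r_star = _first_crossing(r_values, total, target)
    r_sec = _poly_root(r_values.astype(float), E, target)
    if not np.isfinite(r_sec):
        r_sec = _first_crossing(r_values, E, target)
    return RobustnessResult(
        rob50=float(r_star / N) if np.isfinite(r_star) else np.nan,
        rob50_secondary=float(r_sec / N) if np.isfinite(r_sec) else np.nan,
        r_values=r_values,
        mean_extinctions=E,
        se_extinctions=np.asarray(ses),
        n_taxa=N,
    )


# ---------------------------------------------------------------------------
# per-subject panel


def eco_stability_panel(
    model: CLVModel,
    table: AbundanceTable,
    meta: pd.DataFrame,
    seed: int = 0,
    reps: int = 10,
    zero_thr: float = 1e-5,
    min_richness: int = 4,
) -> pd.DataFrame:
    """All four ecological stability measures per subject baseline.

    Each subject's baseline (earliest sample) defines an individual
    dynamical system restricted to its non-zero taxa; measures that
    cannot be computed (too-small support, no matching equilibrium) are
    NaN for that subject.
    """
    rel = table.to_relative()
    meta = meta[meta["sample_id"].isin(set(rel.sample_ids))]
    rows = []
    for k, (subject, grp) in enumerate(meta.groupby("subject_id")):
        baseline_id = grp.sort_values("day")["sample_id"].iloc[0]
        pi_full = rel.data.loc[baseline_id].to_numpy()
        row = {"subject_id": subject, "baseline_sample": baseline_id}
        # each subject's dynamical system keeps only its baseline taxa
        support = np.flatnonzero(pi_full > 0)
        if model.denominator not in support:
            rows.append({**row, "neg_lambda_max": np.nan, "rob50": np.nan})
            continue
        sub = model.restrict(support)
        pi0 = pi_full[support] / pi_full[support].sum()
        try:
            st = find_steady_state(sub, pi0, zero_thr=zero_thr)
            basis = st.model if st.model is not None else sub
            row["neg_lambda_max"] = local_stability(basis, st, "raw")
            row["neg_lambda_max_tangent"] = local_stability(basis, st, "tangent")
            row["stp_bc"] = state_distance(pi0, st, "bc")
            row["stp_ait"] = state_distance(pi0, st, "aitchison")
            row["steady_state_match_bc"] = st.match_bc
        except (NoEquilibriumError, FloatingPointError, ValueError):
            row.update(
                neg_lambda_max=np.nan,
                neg_lambda_max_tangent=np.nan,
                stp_bc=np.nan,
                stp_ait=np.nan,
                steady_state_match_bc=np.nan,
            )
        try:
            if len(support) >= min_richness:
                rob = robustness(
                    sub, pi0, reps=reps, zero_thr=zero_thr, seed=seed + k
                )
                row["rob50"] = rob.rob50
                row["rob50_secondary"] = rob.rob50_secondary
            else:
                row["rob50"] = np.nan
                row["rob50_secondary"] = np.nan
        except (NoEquilibriumError, FloatingPointError, ValueError):
            row["rob50"] = np.nan
            row["rob50_secondary"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
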