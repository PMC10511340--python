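"""Compositional Lotka-Volterra (cLV) dynamics: model, simulator, inference.

The cLV model describes relative-abundance dynamics through additive
log-ratios to a designated denominator taxon D.  With eta_i =
ln(pi_i / pi_D) for every other taxon i, the dynamics are linear in the
composition::

    d eta_i / dt = g_i + sum_j A_ij pi_j + sum_k B_ik u_k

where g holds relative growth rates (1/day), A the relative interaction
matrix (columns span *all* taxa, including D), and B the relative
influence of binary external effects u_k (interventions).  Relative
interactions are absolute (gLV) interactions minus each source taxon's
influence on the denominator, so a denominator with near-constant
log-abundance keeps them close to the absolute ones.

Inference here is one-step gradient matching: every pair of consecutive
same-subject samples (t, t+dt) contributes a response row
(eta(t+dt) - eta(t)) / dt regressed on [1, pi(t), u(t)] with an elastic
net penalty, pooled across subjects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import GroupKFold, train_test_split

from .io import AbundanceTable
from .preprocess import close_and_transform

__all__ = [
    "CLVModel",
    "Trajectory",
    "CVResult",
    "select_denominator",
    "clv_vector_field",
    "simulate_clv",
    "fit_clv",
    "fit_clv_pairs",
    "crossvalidate_clv",
    "bray_curtis",
    "aitchison_distance",
]

PSEUDOCOUNT = 1e-5


@dataclass
class CLVModel:
    """Parameters of a compositional Lotka-Volterra system.

    Arrays are stored full-size (n taxa) with the denominator's row of
    ``g``, ``A`` and ``B`` identically zero, which keeps indexing
    uniform; the denominator has no equation of its own.
    """

    taxon_names: list[str]
    denominator: int
    g: np.ndarray
    A: np.ndarray
    B: np.ndarray
    intervention_levels: list[str] = field(default_factory=list)
    alphas_: np.ndarray | None = None  # per-target selected penalty (diagnostic)

    def __post_init__(self) -> None:
        n = len(self.taxon_names)
        if n < 2:
            raise ValueError("cLV needs at least 2 taxa")
        self.g = np.asarray(self.g, dtype=float).reshape(n)
        self.A = np.asarray(self.A, dtype=float).reshape(n, n)
        B = np.asarray(self.B, dtype=float)
        self.B = B.reshape(n, -1) if B.size else B.reshape(n, 0)
        if not (0 <= self.denominator < n):
            raise ValueError("denominator index out of range")
        for arr in (self.g, self.A, self.B):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite model parameters")
        # denominator has no equation; force its row to zero
        self.g[self.denominator] = 0.0
        self.A[self.denominator, :] = 0.0
        if self.B.size:
            self.B[self.denominator, :] = 0.0

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_interventions(self) -> int:
        return self.B.shape[1] if self.B.ndim == 2 else 0

    # -- serialisation --------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "taxon_names": self.taxon_names,
            "denominator": int(self.denominator),
            "g": self.g.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "intervention_levels": self.intervention_levels,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CLVModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            taxon_names=payload["taxon_names"],
            denominator=payload["denominator"],
            g=np.array(payload["g"]),
            A=np.array(payload["A"]),
            B=np.array(payload["B"]),
            intervention_levels=payload.get("intervention_levels", []),
        )

    def change_denominator(self, new_d: int) -> "CLVModel":
        """Re-express the same dynamics with another reference taxon.

        ln(pi_i/pi_D') = eta_i - eta_D', so g' = g - g_D', A' = A minus
        the D' row, B' likewise; the induced simplex dynamics are
        identical.  Useful when the original denominator goes extinct
        along a trajectory (its log-ratios diverge).
        """
        if not (0 <= new_d < self.n_taxa):
            raise ValueError("denominator index out of range")
        if new_d == self.denominator:
            return self
        g = self.g - self.g[new_d]
        A = self.A - self.A[new_d, :][None, :]
        B = self.B - self.B[new_d, :][None, :] if self.B.size else self.B
        out = CLVModel(
            taxon_names=list(self.taxon_names),
            denominator=new_d,
            g=g,
            A=A,
            B=B.copy() if B.size else np.zeros((self.n_taxa, 0)),
            intervention_levels=list(self.intervention_levels),
        )
        return out

    def restrict(self, support: np.ndarray) -> "CLVModel":
        """Sub-model on a taxon subset (must contain the denominator)."""
        support = np.asarray(sorted(support), dtype=int)
        if self.denominator not in support:
            raise ValueError("support must contain the denominator")
        new_d = int(np.searchsorted(support, self.denominator))
        return CLVModel(
            taxon_names=[self.taxon_names[i] for i in support],
            denominator=new_d,
            g=self.g[support].copy(),
            A=self.A[np.ix_(support, support)].copy(),
            B=self.B[support].copy() if self.B.size else np.zeros((len(support), 0)),
            intervention_levels=list(self.intervention_levels),
        )


@dataclass
class Trajectory:
    times: np.ndarray
    compositions: np.ndarray  # (timepoints x n) on the simplex
    u: np.ndarray | None = None


@dataclass
class CVResult:
    errors: pd.DataFrame  # subject, day, metric, clv, static
    tests: dict  # metric -> {"statistic": ..., "pvalue": ...}
    train_subjects: list[str] = field(default_factory=list)
    test_subjects: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# distances used across the package


def bray_curtis(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        return 0.0
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def aitchison_distance(x, y, pseudocount: float = PSEUDOCOUNT) -> float:
    cx = close_and_transform(x, "clr", pseudocount)
    cy = close_and_transform(y, "clr", pseudocount)
    return float(np.linalg.norm(cx - cy))


# ---------------------------------------------------------------------------
# vector field and simulation


def select_denominator(table: AbundanceTable, pseudocount: float = PSEUDOCOUNT) -> int:
    """Taxon with the lowest variance of log relative abundance.

    A low-variance denominator keeps relative interactions close to the
    absolute (gLV) ones.  Ties break to the lower index.
    """
    if table.n_taxa < 2:
        raise ValueError("need at least 2 taxa to pick a denominator")
    if table.n_samples < 2:
        raise ValueError("variance undefined for a single-sample table")
    rel = table.to_relative().values
    logs = np.log(np.where(rel == 0, pseudocount, rel))
    variances = logs.var(axis=0)
    return int(np.argmin(variances))


def _pi_from_eta(eta: np.ndarray, active: np.ndarray, denominator: int, n: int) -> np.ndarray:
    """Map log-ratios on the active set back to a full simplex vector."""
    shift = max(0.0, float(eta.max(initial=0.0)))
    ex = np.exp(eta - shift)
    denom = np.exp(-shift) + ex.sum()
    pi = np.zeros(n)
    pi[active] = ex / denom
    pi[denominator] = np.exp(-shift) / denom
    return pi


def clv_vector_field(model: CLVModel, pi, u=None) -> np.ndarray:
    """d eta/dt for every non-denominator taxon (full-length vector).

    Taxa at exactly zero abundance are frozen: their entry is 0 and they
    contribute nothing through A.  Requires a live denominator.
    """
    pi = np.asarray(pi, dtype=float)
    if pi[model.denominator] <= 0:
        raise ValueError("denominator extinct: eta undefined")
    out = np.zeros(model.n_taxa)
    live = (pi > 0) & (np.arange(model.n_taxa) != model.denominator)
    out[live] = model.g[live] + model.A[live] @ pi
    if u is not None and model.n_interventions:
        u = np.asarray(u, dtype=float)
        out[live] += model.B[live] @ u
    return out


def _resolve_u(u, t: float, k: int) -> np.ndarray | None:
    if u is None or k == 0:
        return None
    if callable(u):
        return np.asarray(u(t), dtype=float)
    return np.asarray(u, dtype=float)


def simulate_clv(
    model: CLVModel,
    pi0,
    u=None,
    horizon_days: float = 100.0,
    step: float = 0.1,
    record_every: int = 1,
    stop_bc_tol: float | None = None,
) -> Trajectory:
    """Integrate the cLV dynamics with fixed-step RK4 in eta-space.

    The state is restricted to the baseline support (taxa at zero stay
    at zero); compositions are recovered via the softmax-like map, so
    every recorded state lies on the simplex by construction.  ``u`` may
    be None, a constant indicator vector, or a callable t -> vector.
    When ``stop_bc_tol`` is set, integration halts early once the
    Bray-Curtis drift over one day falls below it (used for the long
    steady-state runs; drift is checked once per simulated day).
    """
    pi0 = np.asarray(pi0, dtype=float)
    if pi0.shape != (model.n_taxa,):
        raise ValueError("pi0 has wrong length")
    if not np.isclose(pi0.sum(), 1.0, atol=1e-6):
        raise ValueError("pi0 must lie on the simplex")
    if horizon_days <= 0:
        raise ValueError("horizon must be positive")
    if pi0[model.denominator] <= 0:
        raise ValueError("denominator extinct at baseline")
    n = model.n_taxa
    active = np.flatnonzero((pi0 > 0) & (np.arange(n) != model.denominator))
    g = model.g[active]
    A = model.A[active]
    B = model.B[active] if model.n_interventions else None
    D = model.denominator

    eta = np.log(pi0[active] / pi0[D])

    def field(eta_vec: np.ndarray, t: float) -> np.ndarray:
        pi = _pi_from_eta(eta_vec, active, D, n)
        d = g + A @ pi
        uv = _resolve_u(u, t, model.n_interventions)
        if uv is not None and B is not None:
            d = d + B @ uv
        return d

    n_steps = int(round(horizon_days / step))
    steps_per_day = max(1, int(round(1.0 / step)))
    times = [0.0]
    states = [pi0.copy()]
    pi_prev_day = pi0.copy()
    t = 0.0
    for k in range(1, n_steps + 1):
        k1 = field(eta, t)
        k2 = field(eta + 0.5 * step * k1, t + 0.5 * step)
        k3 = field(eta + 0.5 * step * k2, t + 0.5 * step)
        k4 = field(eta + step * k3, t + step)
        eta = eta + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        # cap |eta| so that near-extinct taxa cannot overflow the map
        np.clip(eta, -500.0, 500.0, out=eta)
        t = k * step
        if not np.isfinite(eta).all():
            raise FloatingPointError(f"cLV integration blew up at t={t:.2f} days")
        if k % record_every == 0 or k == n_steps:
            times.append(t)
            states.append(_pi_from_eta(eta, active, D, n))
        if stop_bc_tol is not None and k % steps_per_day == 0:
            pi_now = _pi_from_eta(eta, active, D, n)
            if bray_curtis(pi_now, pi_prev_day) < stop_bc_tol:
                if times[-1] != t:
                    times.append(t)
                    states.append(pi_now)
                break
            pi_prev_day = pi_now
    return Trajectory(times=np.asarray(times), compositions=np.vstack(states))


# ---------------------------------------------------------------------------
# inference


def _intervention_levels(meta: pd.DataFrame) -> list[str]:
    levels = sorted(set(meta["intervention"]) - {"none"})
    return levels


def _encode_u(label: str, levels: list[str]) -> np.ndarray:
    u = np.zeros(len(levels))
    if label in levels:
        u[levels.index(label)] = 1.0
    return u


def _pair_design(
    table: AbundanceTable,
    meta: pd.DataFrame,
    denominator: int,
    pseudocount: float,
    subjects=None,
):
    """Build the gradient-matching regression design.

    Returns X (pairs x [n_taxa + K]), Y (pairs x n_taxa, denominator
    column zero), groups (subject per pair), levels.
    """
    rel = table.to_relative()
    levels = _intervention_levels(meta)
    meta = meta[meta["sample_id"].isin(set(rel.sample_ids))]
    if subjects is not None:
        meta = meta[meta["subject_id"].isin(set(subjects))]
    rows_X, rows_Y, groups = [], [], []
    data = rel.data
    n = rel.n_taxa
    for subject, grp in meta.groupby("subject_id"):
        grp = grp.sort_values("day")
        ids = list(grp["sample_id"])
        days = grp["day"].to_numpy()
        for a in range(len(ids) - 1):
            dt = float(days[a + 1] - days[a])
            if dt <= 0:
                raise ValueError(f"zero time interval for subject {subject!r}")
            pi_t = data.loc[ids[a]].to_numpy()
            pi_next = data.loc[ids[a + 1]].to_numpy()
            eta_t = _eta(pi_t, denominator, pseudocount)
            eta_next = _eta(pi_next, denominator, pseudocount)
            y = (eta_next - eta_t) / dt
            u = _encode_u(grp["intervention"].iloc[a], levels)
            # denominator column dropped: with it, [1, pi] is collinear
            # (pi sums to 1) and (g, A) are identified only up to a
            # per-row shift; the fitted A carries A_iD = 0 as the gauge.
            rows_X.append(np.concatenate([np.delete(pi_t, denominator), u]))
            rows_Y.append(y)
            groups.append(subject)
    if not rows_X:
        raise ValueError("no consecutive same-subject sample pairs to fit on")
    return np.vstack(rows_X), np.vstack(rows_Y), np.asarray(groups), levels


def _eta(pi: np.ndarray, denominator: int, pseudocount: float) -> np.ndarray:
    filled = np.where(pi == 0, pseudocount, pi)
    out = np.log(filled) - np.log(filled[denominator])
    out[denominator] = 0.0
    return out


def fit_clv(
    table: AbundanceTable,
    meta: pd.DataFrame,
    denominator: int | None = None,
    l1_ratio: float = 0.5,
    alpha=None,
    alpha_grid=None,
    pseudocount: float = PSEUDOCOUNT,
    seed: int = 0,
    n_splits: int = 5,
    max_iter: int = 20000,
) -> CLVModel:
    """Fit a cLV model by penalised one-step gradient matching.

    Each non-denominator taxon gets its own elastic-net regression of
    the per-interval log-ratio velocity on [1, pi(t), u(t)].  ``alpha``
    may be a fixed penalty (scalar or per-target array); when None the
    penalty is selected per target by subject-grouped K-fold CV over a
    logarithmic grid spanning six decades.
    """
    rel = table.to_relative()
    if denominator is None:
        denominator = select_denominator(rel, pseudocount)
    X, Y, groups, levels = _pair_design(table, meta, denominator, pseudocount)
    return _fit_elastic_net(
        X, Y, groups, rel.taxon_names, denominator, levels,
        l1_ratio=l1_ratio, alpha=alpha, alpha_grid=alpha_grid,
        seed=seed, n_splits=n_splits, max_iter=max_iter,
    )


def fit_clv_pairs(
    pi_start,
    pi_end,
    dt,
    taxon_names,
    denominator: int,
    u=None,
    groups=None,
    l1_ratio: float = 0.5,
    alpha=None,
    alpha_grid=None,
    pseudocount: float = PSEUDOCOUNT,
    seed: int = 0,
    n_splits: int = 5,
    max_iter: int = 20000,
) -> CLVModel:
    """Fit from explicit composition pairs (e.g. densely sampled data).

    ``pi_start``/``pi_end`` are (pairs x n) simplex matrices, ``dt`` the
    per-pair interval in days (scalar or array, may be fractional), and
    ``u`` an optional (pairs x K) intervention indicator matrix.
    """
    pi_start = np.atleast_2d(np.asarray(pi_start, dtype=float))
    pi_end = np.atleast_2d(np.asarray(pi_end, dtype=float))
    m, n = pi_start.shape
    dt = np.broadcast_to(np.asarray(dt, dtype=float), (m,))
    if (dt <= 0).any():
        raise ValueError("pair intervals must be positive")
    u_mat = (
        np.atleast_2d(np.asarray(u, dtype=float))
        if u is not None
        else np.zeros((m, 0))
    )
    levels = [f"I{k+1}" for k in range(u_mat.shape[1])]
    Y = np.vstack(
        [
            (_eta(pi_end[a], denominator, pseudocount) - _eta(pi_start[a], denominator, pseudocount))
            / dt[a]
            for a in range(m)
        ]
    )
    X = np.hstack([np.delete(pi_start, denominator, axis=1), u_mat])
    if groups is None:
        groups = np.arange(m)
    return _fit_elastic_net(
        X, Y, np.asarray(groups), list(taxon_names), denominator, levels,
        l1_ratio=l1_ratio, alpha=alpha, alpha_grid=alpha_grid,
        seed=seed, n_splits=n_splits, max_iter=max_iter,
    )


def _fit_elastic_net(
    X, Y, groups, taxon_names, denominator, levels,
    l1_ratio, alpha, alpha_grid, seed, n_splits, max_iter,
) -> CLVModel:
    n = len(taxon_names)
    K = len(levels)
    src_cols = [j for j in range(n) if j != denominator]  # X taxon columns
    if alpha_grid is None:
        alpha_grid = np.logspace(-6, 0, 13)
    unique_groups = np.unique(groups)
    g = np.zeros(n)
    A = np.zeros((n, n))
    B = np.zeros((n, K))
    chosen = np.zeros(n)
    alphas_fixed = None
    if alpha is not None:
        alphas_fixed = np.broadcast_to(np.asarray(alpha, dtype=float), (n,)).copy()
    for i in range(n):
        if i == denominator:
            continue
        y = Y[:, i]
        if alphas_fixed is not None:
            reg = ElasticNet(
                alpha=float(alphas_fixed[i]), l1_ratio=l1_ratio, max_iter=max_iter
            )
            reg.fit(X, y)
            chosen[i] = alphas_fixed[i]
        else:
            splits = min(n_splits, len(unique_groups))
            if splits >= 2:
                cv = list(GroupKFold(n_splits=splits).split(X, y, groups))
            else:
                cv = 2  # degenerate fallback: plain 2-fold
            reg = ElasticNetCV(
                alphas=alpha_grid, l1_ratio=l1_ratio, cv=cv, max_iter=max_iter
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reg.fit(X, y)
            chosen[i] = reg.alpha_
        g[i] = reg.intercept_
        A[i, src_cols] = reg.coef_[: n - 1]
        B[i, :] = reg.coef_[n - 1 :]
    model = CLVModel(
        taxon_names=taxon_names,
        denominator=denominator,
        g=g,
        A=A,
        B=B,
        intervention_levels=levels,
    )
    model.alphas_ = chosen
    return model


# ---------------------------------------------------------------------------
# cross-validation against the static (no-change) baseline


def _rmse(pred: np.ndarray, true: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - true) ** 2)))


def _rmsle(pred: np.ndarray, true: np.ndarray, pseudocount: float) -> float:
    lp = np.log(np.where(pred == 0, pseudocount, pred))
    lt = np.log(np.where(true == 0, pseudocount, true))
    return float(np.sqrt(np.mean((lp - lt) ** 2)))


def _subject_intervention(meta_subject: pd.DataFrame) -> str:
    labels = [x for x in meta_subject["intervention"] if x != "none"]
    return labels[0] if labels else "none"


def _predict_subject(
    model: CLVModel, grp: pd.DataFrame, data: pd.DataFrame, step: float
) -> dict[str, np.ndarray]:
    """Integrate from the subject's baseline to every later sample day,
    applying the intervention indicator of each interval's start sample."""
    grp = grp.sort_values("day")
    ids = list(grp["sample_id"])
    days = grp["day"].to_numpy(dtype=float)
    levels = model.intervention_levels
    pi = data.loc[ids[0]].to_numpy().copy()
    preds = {}
    for a in range(len(ids) - 1):
        span = days[a + 1] - days[a]
        u = _encode_u(grp["intervention"].iloc[a], levels)
        traj = simulate_clv(
            model, pi, u=u if len(levels) else None, horizon_days=span, step=step,
            record_every=max(1, int(round(span / step))),
        )
        pi = traj.compositions[-1]
        preds[ids[a + 1]] = pi.copy()
    return preds


def crossvalidate_clv(
    table: AbundanceTable,
    meta: pd.DataFrame,
    test_fraction: float = 0.25,
    l1_ratio: float = 0.5,
    alpha_grid=None,
    pseudocount: float = PSEUDOCOUNT,
    seed: int = 0,
    step: float = 0.1,
    denominator: int | None = None,
) -> CVResult:
    """Leave-one-out CV of cLV against the static no-change baseline.

    Subjects are split test:train = ``test_fraction`` : rest, balancing
    interventions held by more than 3 subjects.  The elastic-net penalty
    is selected once on the training group; each test subject is then
    predicted by a model refit on everyone else with that penalty.
    Errors (RMSE / RMSLE / Aitchison, the latter two after a 1e-5
    pseudocount) are compared to the static baseline with a Wilcoxon
    rank-sum test per metric.
    """
    rel = table.to_relative()
    meta = meta[meta["sample_id"].isin(set(rel.sample_ids))]
    subjects = sorted(meta["subject_id"].unique())
    if len(subjects) < 8:
        raise ValueError("cross-validation needs at least 8 subjects")
    labels = pd.Series(
        {s: _subject_intervention(meta[meta["subject_id"] == s]) for s in subjects}
    )
    counts = labels.value_counts()
    strat = labels.where(labels.map(counts) > 3, other="_rare")
    try:
        train_subj, test_subj = train_test_split(
            subjects,
            test_size=test_fraction,
            stratify=strat[subjects].to_numpy(),
            random_state=seed,
        )
    except ValueError:
        warnings.warn("intervention balancing impossible; falling back to random split")
        train_subj, test_subj = train_test_split(
            subjects, test_size=test_fraction, random_state=seed
        )
    if denominator is None:
        denominator = select_denominator(rel, pseudocount)
    # penalty selection once, on the training group only
    train_meta = meta[meta["subject_id"].isin(set(train_subj))]
    base_model = fit_clv(
        table,
        train_meta,
        denominator=denominator,
        l1_ratio=l1_ratio,
        alpha_grid=alpha_grid,
        pseudocount=pseudocount,
        seed=seed,
    )
    alphas = base_model.alphas_
    data = rel.data
    records = []
    for test_subject in sorted(test_subj):
        fit_subjects = set(subjects) - {test_subject}
        fit_meta = meta[meta["subject_id"].isin(fit_subjects)]
        model = fit_clv(
            table,
            fit_meta,
            denominator=denominator,
            l1_ratio=l1_ratio,
            alpha=alphas,
            pseudocount=pseudocount,
            seed=seed,
        )
        grp = meta[meta["subject_id"] == test_subject].sort_values("day")
        preds = _predict_subject(model, grp, data, step)
        baseline = data.loc[grp["sample_id"].iloc[0]].to_numpy()
        for sid, day in zip(grp["sample_id"].iloc[1:], grp["day"].iloc[1:]):
            true = data.loc[sid].to_numpy()
            pred = preds[sid]
            for metric, fn in (
                ("rmse", lambda p, t: _rmse(p, t)),
                ("rmsle", lambda p, t: _rmsle(p, t, pseudocount)),
                ("aitchison", lambda p, t: aitchison_distance(p, t, pseudocount)),
            ):
                records.append(
                    {
                        "subject_id": test_subject,
                        "day": int(day),
                        "metric": metric,
                        "clv": fn(pred, true),
                        "static": fn(baseline, true),
                    }
                )
    errors = pd.DataFrame.from_records(records)
    tests = {}
    for metric, grp_err in errors.groupby("metric"):
        if np.allclose(grp_err["clv"], grp_err["static"]):
            tests[metric] = {"statistic": 0.0, "pvalue": 1.0}
            continue
        res = sstats.ranksums(grp_err["clv"], grp_err["static"])
        tests[metric] = {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}
    return CVResult(
        errors=errors,
        tests=tests,
        train_subjects=sorted(train_subj),
        test_subjects=sorted(test_subj),
    )
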