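"""Nonparametric maximum-likelihood population PK fitting.

The population parameter distribution is estimated as a discrete
distribution on support points in (ka, ke, v) space — the NPML estimate —
via an adaptive-grid scheme: an initial space-filling grid, EM
multiplicative updates for the mixture weights (the convex subproblem),
pruning of negligible-weight points, and local refinement by perturbed
copies of surviving points with a shrinking step. Individual Bayesian
posteriors, goodness-of-fit diagnostics, and covariate screening follow
standard pharmacometric practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .pk import (
    ASSAY_ERROR,
    DEFAULT_BIOAVAILABILITY,
    DoseEvent,
    ErrorModel,
    Observation,
    PKParams,
    _bateman,
    mg_to_nmol,
)

__all__ = [
    "SubjectRecord",
    "NPDistribution",
    "FitConfig",
    "FitResult",
    "FitDiagnostics",
    "SubjectPosterior",
    "DEFAULT_RANGES",
    "init_grid",
    "subject_loglik",
    "optimize_weights",
    "fit",
    "posterior",
    "diagnostics",
    "covariate_screen",
    "weighted_median",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: Default search box, wide enough to contain published atorvastatin
#: estimates for both lumped analytes (volumes are central V with F = 0.125,
#: i.e. apparent V/F of 40-800 L).
DEFAULT_RANGES = {"ka": (0.01, 9.0), "ke": (0.01, 0.6), "v": (5.0, 100.0)}

_PARAM_NAMES = ("ka", "ke", "v")


@dataclass(frozen=True)
class SubjectRecord:
    """Dosing history, timed observations and covariates for one subject."""

    id: str
    events: tuple
    observations: tuple
    c_ini: float = 0.0
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "observations", tuple(self.observations))
        if len(self.observations) == 0:
            raise ValueError(f"subject {self.id!r} has no observations")
        if self.c_ini < 0:
            raise ValueError(f"subject {self.id!r}: c_ini must be >= 0")


@dataclass
class NPDistribution:
    """Discrete population distribution: support points with probability weights."""

    points: list
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.points = list(self.points)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.points) != self.weights.size:
            raise ValueError("points and weights length mismatch")
        if len(self.points) == 0:
            raise ValueError("distribution needs at least one support point")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        total = self.weights.sum()
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")
        self.weights = self.weights / total

    def __len__(self) -> int:
        return len(self.points)

    def param_array(self) -> np.ndarray:
        """Support point coordinates, shape (K, 3) ordered (ka, ke, v)."""
        return np.array([[p.ka, p.ke, p.v] for p in self.points], dtype=float)

    def mean(self) -> np.ndarray:
        return self.weights @ self.param_array()

    def marginal_sd(self) -> np.ndarray:
        theta = self.param_array()
        mu = self.weights @ theta
        return np.sqrt(self.weights @ (theta - mu) ** 2)

    def weighted_medians(self) -> dict:
        theta = self.param_array()
        return {
            name: weighted_median(theta[:, j], self.weights)
            for j, name in enumerate(_PARAM_NAMES)
        }


def weighted_median(values, weights) -> float:
    """Smallest value whose cumulative weight reaches half the total."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(values[order][min(idx, values.size - 1)])


@dataclass
class FitConfig:
    """Settings for the adaptive-grid NPML fit."""

    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    analyte: str = "ATR_ATRL"
    error_model: ErrorModel | None = None
    f: float = DEFAULT_BIOAVAILABILITY
    n_init: int = 60
    n_global: int = 20
    seed: int = 0
    converge_tol: float = 1e-4
    max_cycles: int = 5000
    prune_eps: float = 1e-8
    delta0: float = 0.1
    delta_floor: float = 1e-4
    em_tol: float = 1e-9
    em_max_iter: int = 4000
    # "observed" evaluates the error SD at the measured concentration (the
    # published weighting); "predicted" evaluates it at the model prediction.
    sd_mode: str = "observed"

    def resolved_error_model(self) -> ErrorModel:
        return self.error_model if self.error_model is not None else ASSAY_ERROR[self.analyte]


@dataclass
class SubjectPosterior:
    weights: np.ndarray
    mean: PKParams


@dataclass
class FitDiagnostics:
    """Goodness-of-fit summaries of a population model."""

    pop_slope: float
    pop_intercept: float
    pop_r: float
    post_slope: float
    post_intercept: float
    post_r: float
    mwpe: float
    mwspe: float
    bias_t_p: float
    residual_normality_p: float
    neg2ll: float
    aic: float
    bic: float
    n_support: int
    n_obs: int
    shrinkage_pct: dict = field(default_factory=dict)


@dataclass
class FitResult:
    distribution: NPDistribution
    loglik: float
    n_cycles: int
    converged: bool
    posteriors: dict
    diagnostics: FitDiagnostics | None = None
    objective_history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# likelihood machinery


def _subject_arrays(subject: SubjectRecord):
    times = np.array([o.time_h for o in subject.observations], dtype=float)
    concs = np.array([o.conc for o in subject.observations], dtype=float)
    ev_times = np.array([ev.time_h for ev in subject.events], dtype=float)
    ev_nmol = np.array([mg_to_nmol(ev.amount_mg) for ev in subject.events], dtype=float)
    return times, concs, ev_times, ev_nmol


def _predict_points(subject: SubjectRecord, ka, ke, v, f):
    """Model predictions at all observation times for K parameter points.

    Returns shape (K, n_obs).
    """
    times, _, ev_times, ev_nmol = _subject_arrays(subject)
    ka = np.atleast_1d(np.asarray(ka, dtype=float))[:, None]
    ke = np.atleast_1d(np.asarray(ke, dtype=float))[:, None]
    v = np.atleast_1d(np.asarray(v, dtype=float))[:, None]
    pred = subject.c_ini * np.exp(-ke * times[None, :])
    for t0, d in zip(ev_times, ev_nmol):
        if d == 0:
            continue
        pred = pred + _bateman(ka, ke, v, f, d, (times - t0)[None, :])
    return pred


def _loglik_block(subjects, pts: np.ndarray, em: ErrorModel, f: float, sd_mode: str):
    """Log-likelihood matrix, shape (n_subjects, K), for points pts (K, 3)."""
    n, K = len(subjects), pts.shape[0]
    L = np.empty((n, K), dtype=float)
    for i, s in enumerate(subjects):
        _, obs, _, _ = _subject_arrays(s)
        pred = _predict_points(s, pts[:, 0], pts[:, 1], pts[:, 2], f)
        sd = em.total_sd(obs[None, :] if sd_mode == "observed" else pred)
        z = (obs[None, :] - pred) / sd
        ll = (-0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI).sum(axis=1)
        L[i] = np.where(np.isfinite(ll), ll, -np.inf)
    return L


def subject_loglik(
    subject: SubjectRecord,
    point: PKParams,
    em: ErrorModel,
    sd_mode: str = "observed",
) -> float:
    """Gaussian log-likelihood of one subject's observations at one point."""
    pts = np.array([[point.ka, point.ke, point.v]])
    return float(_loglik_block([subject], pts, em, point.f, sd_mode)[0, 0])


# ---------------------------------------------------------------------------
# grid and weight optimisation


def init_grid(ranges: dict, n_points: int, seed: int) -> list:
    """Deterministic starting grid: midpoint, box corners (n >= 8), seeded fill."""
    for name in _PARAM_NAMES:
        lo, hi = ranges[name]
        if not lo < hi:
            raise ValueError(f"invalid range for {name}: [{lo}, {hi}]")
    lo = np.array([ranges[n][0] for n in _PARAM_NAMES])
    hi = np.array([ranges[n][1] for n in _PARAM_NAMES])
    mid = 0.5 * (lo + hi)

    coords = []
    if n_points < 8:
        coords.append(mid)
    else:
        for mask in range(8):
            corner = np.where([(mask >> j) & 1 for j in range(3)], hi, lo)
            coords.append(corner)
        if n_points > 8:
            coords.append(mid)
    rng = np.random.default_rng(seed)
    while len(coords) < n_points:
        coords.append(lo + (hi - lo) * rng.random(3))
    coords = coords[:n_points]
    return [PKParams(ka=c[0], ke=c[1], v=c[2]) for c in coords]


@dataclass
class EMResult:
    weights: np.ndarray
    objective: float
    history: list
    n_iter: int
    converged: bool


def optimize_weights(L, tol: float = 1e-10, max_iter: int = 2000, w0=None) -> EMResult:
    """Maximize the mixture log-likelihood over the weight simplex.

    The base step is the EM multiplicative update
    w_k <- w_k * mean_i[ p(obs_i | k) / mix_i ], whose objective
    sum_i log sum_k w_k exp(L_ik) is non-decreasing; plain EM is
    painfully slow near the optimum, so each iteration extrapolates two EM
    steps (SQUAREM-style squared step) and falls back to the plain EM
    result whenever the extrapolated point does not improve the objective —
    the recorded objective history is therefore still non-decreasing.
    Rows are log-sum-exp stabilized.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[1] < 1:
        raise ValueError("L must be a 2-D subjects x points matrix")
    rowmax = np.max(L, axis=1)
    bad = ~np.isfinite(rowmax)
    if np.any(bad):
        raise ValueError(
            f"subject row(s) {np.flatnonzero(bad).tolist()} have zero likelihood "
            "at every support point"
        )
    a = np.exp(L - rowmax[:, None])  # -inf -> 0
    n, K = L.shape
    if w0 is None:
        w = np.full(K, 1.0 / K)
    else:
        w = np.asarray(w0, dtype=float)
        w = w / w.sum()
    const = rowmax.sum()

    def em_step(wv):
        denom = a @ wv
        wn = wv * (a / denom[:, None]).mean(axis=0)
        return wn / wn.sum()

    def objective(wv):
        return float(np.log(a @ wv).sum() + const)

    history = [objective(w)]
    converged = False
    it = 0
    while it < max_iter and not converged:
        chunk_end = min(it + 200, max_iter)
        while it < chunk_end:
            it += 1
            w1 = em_step(w)
            w2 = em_step(w1)
            r = w1 - w
            v = (w2 - w1) - r
            vv = float(v @ v)
            w_next, obj_next = w2, objective(w2)
            if vv > 0:
                alpha = -math.sqrt(float(r @ r) / vv)
                w_acc = np.maximum(w - 2.0 * alpha * r + alpha * alpha * v, 0.0)
                s = w_acc.sum()
                if s > 0:
                    w_acc = em_step(w_acc / s)  # stabilization EM step
                    obj_acc = objective(w_acc)
                    if obj_acc > obj_next:
                        w_next, obj_next = w_acc, obj_acc
            if obj_next < history[-1]:  # safeguard: never step downhill
                break
            w = w_next
            history.append(obj_next)
            if history[-1] - history[-2] < tol:
                converged = True
                break
        if converged or K == 1:
            break
        # quasi-Newton polish on the softmax parametrization; accepted only
        # if it beats the current point, so the history stays monotone
        w_p = _polish_weights(a, w, const)
        obj_p = objective(w_p)
        if obj_p > history[-1] + tol:
            w = w_p
            history.append(obj_p)
        else:
            converged = True
    return EMResult(weights=w, objective=history[-1], history=history,
                    n_iter=len(history), converged=converged)


def _polish_weights(a: np.ndarray, w: np.ndarray, const: float) -> np.ndarray:
    """L-BFGS refinement of mixture weights via w = softmax(z)."""
    from scipy.optimize import minimize

    def negf(z):
        z = z - z.max()
        wv = np.exp(z)
        wv /= wv.sum()
        m = a @ wv
        if np.any(m <= 0) or not np.all(np.isfinite(m)):
            return 1e300, np.zeros_like(z)
        f = -(np.log(m).sum() + const)
        g_w = -(a / m[:, None]).sum(axis=0)
        g_z = wv * (g_w - float(wv @ g_w))
        return f, g_z

    z0 = np.log(np.maximum(w, 1e-300))
    res = minimize(negf, z0, jac=True, method="L-BFGS-B", options={"maxiter": 500})
    z = res.x - res.x.max()
    wv = np.exp(z)
    return wv / wv.sum()


def _propose(pts: np.ndarray, delta: float, ranges: dict, existing_keys) -> np.ndarray:
    """Perturbed copies of each point: +/- delta * range per coordinate, clipped."""
    lo = np.array([ranges[n][0] for n in _PARAM_NAMES])
    hi = np.array([ranges[n][1] for n in _PARAM_NAMES])
    step = delta * (hi - lo)
    proposals = []
    seen = set(existing_keys)
    for p in pts:
        for j in range(3):
            for sign in (1.0, -1.0):
                q = p.copy()
                q[j] = min(max(q[j] + sign * step[j], lo[j]), hi[j])
                key = tuple(np.round(q, 12))
                if key not in seen:
                    seen.add(key)
                    proposals.append(q)
    return np.array(proposals) if proposals else np.empty((0, 3))


def _optimize_positions(subjects, pts, w, L, em, f, sd_mode, ranges, min_weight=1e-6):
    """EM M-step for support point positions.

    For each point with non-negligible weight, maximize the posterior-
    weighted sum of subject log-likelihoods over the point's coordinates
    (bounded by the search box, on the log scale). Pools subjects sharing a
    support point, which resolves directions that single subjects leave
    flat. Returns updated (pts, L); the caller re-optimizes weights.
    """
    from scipy.optimize import minimize

    lo = np.log([ranges[n][0] for n in _PARAM_NAMES])
    hi = np.log([ranges[n][1] for n in _PARAM_NAMES])
    with np.errstate(divide="ignore"):
        logmix = L + np.log(w)[None, :]
    denom = logsumexp(logmix, axis=1)
    post = np.exp(logmix - denom[:, None])  # p_ik
    pts = pts.copy()
    L = L.copy()
    for k in range(pts.shape[0]):
        if w[k] < min_weight:
            continue
        p_k = post[:, k]

        def negq(x, p_k=p_k):
            col = _loglik_block(subjects, np.exp(x)[None, :], em, f, sd_mode)[:, 0]
            col = np.where(np.isfinite(col), col, -1e300)
            return -float(p_k @ col)

        x0 = np.clip(np.log(pts[k]), lo, hi)
        res = minimize(negq, x0, method="L-BFGS-B",
                       bounds=list(zip(lo, hi)), options={"maxiter": 60})
        if res.fun < negq(x0):
            pts[k] = np.exp(res.x)
            L[:, k] = _loglik_block(subjects, pts[k][None, :], em, f, sd_mode)[:, 0]
    return pts, L


def _condense(pts: np.ndarray, w: np.ndarray, L: np.ndarray, ranges: dict, resolution: float):
    """Merge support points within ``resolution`` of each other (fraction of
    each range): one grid cell keeps its heaviest point with the summed weight.

    Keeps the support sparse; the follow-up weight re-optimisation restores
    the objective, guarded by the caller.
    """
    lo = np.array([ranges[n][0] for n in _PARAM_NAMES])
    hi = np.array([ranges[n][1] for n in _PARAM_NAMES])
    cells = np.floor((pts - lo) / ((hi - lo) * resolution)).astype(np.int64)
    reps: dict = {}
    sums: dict = {}
    for i, key in enumerate(map(tuple, cells)):
        sums[key] = sums.get(key, 0.0) + w[i]
        if key not in reps or w[i] > w[reps[key]]:
            reps[key] = i
    idx = np.array(sorted(reps.values()))
    w_new = np.array([sums[tuple(cells[i])] for i in idx])
    return pts[idx], w_new / w_new.sum(), L[:, idx]


def fit(subjects, config: FitConfig | None = None) -> FitResult:
    """Adaptive-grid NPML fit of the population distribution.

    Cycles of weight optimisation (EM), pruning of points below
    ``prune_eps`` weight plus condensation of near-duplicates, and
    refinement with perturbed copies at step delta (fraction of each
    range). delta halves whenever a cycle improves the objective by less
    than ``converge_tol`` and re-expands to ``delta0`` at the floor;
    convergence is declared once an entire coarse-to-fine pass gains less
    than ``converge_tol``. Hitting ``max_cycles`` flags converged=False.
    """
    config = config or FitConfig()
    em = config.resolved_error_model()
    subjects = list(subjects)
    if not subjects:
        raise ValueError("no subjects to fit")

    pts = np.array(
        [[p.ka, p.ke, p.v] for p in init_grid(config.ranges, config.n_init, config.seed)]
    )
    L = _loglik_block(subjects, pts, em, config.f, config.sd_mode)
    # name the subject, not the row, if someone is impossible everywhere
    finite_rows = np.isfinite(np.max(L, axis=1))
    if not np.all(finite_rows):
        bad_ids = [subjects[i].id for i in np.flatnonzero(~finite_rows)]
        raise ValueError(f"subjects {bad_ids} have zero likelihood at every grid point")

    def solve(L_mat, w0=None):
        res = optimize_weights(L_mat, tol=config.em_tol,
                               max_iter=config.em_max_iter, w0=w0)
        return res.weights, res.objective

    rng = np.random.default_rng(config.seed + 1)
    lo = np.array([config.ranges[n][0] for n in _PARAM_NAMES])
    hi = np.array([config.ranges[n][1] for n in _PARAM_NAMES])

    w, obj = solve(L)
    keep = w > config.prune_eps
    pts, w, L = pts[keep], w[keep] / w[keep].sum(), L[:, keep]

    delta = config.delta0
    pass_start_obj = obj  # objective at the start of the current descent pass
    history = [obj]
    converged = False
    n_cycles = 0
    cache: dict = {tuple(np.round(p, 12)): L[:, i] for i, p in enumerate(pts)}

    for _ in range(config.max_cycles):
        n_cycles += 1
        cycle_start_obj = obj
        # refinement: perturbed copies of the surviving support, plus a few
        # seeded global candidates to escape local structure
        props = _propose(pts, delta, config.ranges, cache.keys())
        if config.n_global:
            glob = lo + (hi - lo) * rng.random((config.n_global, 3))
            props = np.vstack([props, glob]) if props.shape[0] else glob
        if props.shape[0]:
            L_new = _loglik_block(subjects, props, em, config.f, config.sd_mode)
            for i, p in enumerate(props):
                cache[tuple(np.round(p, 12))] = L_new[:, i]
            L_all = np.hstack([L, L_new])
            pts_all = np.vstack([pts, props])
            eps = 1e-3
            w0 = np.concatenate(
                [w * (1 - eps), np.full(props.shape[0], eps / props.shape[0])]
            )
            w2, obj2 = solve(L_all, w0)
            if obj2 > obj:  # keep proposals only when they raise the objective
                pts, w, L, obj = pts_all, w2, L_all, obj2

        # M-step on support point positions (posterior-weighted pooled fit),
        # then re-optimize weights; adopt only if the objective improves
        pts_m, L_m = _optimize_positions(
            subjects, pts, w, L, em, config.f, config.sd_mode, config.ranges
        )
        w_m, obj_m = solve(L_m, w)
        if obj_m > obj:
            pts, w, L, obj = pts_m, w_m, L_m, obj_m
            for i, p_row in enumerate(pts):
                cache.setdefault(tuple(np.round(p_row, 12)), L[:, i])

        # prune negligible weights, then condense near-duplicates; revert if
        # the sparser support cannot match the incumbent objective
        keep = w > config.prune_eps
        if not np.all(keep):
            pts, L = pts[keep], L[:, keep]
            w = w[keep] / w[keep].sum()
        pts_c, w_c, L_c = _condense(pts, w, L, config.ranges, 0.5 * delta)
        if pts_c.shape[0] < pts.shape[0]:
            w3, obj3 = solve(L_c, w_c)
            if obj3 >= obj - 1e-9:
                pts, w, L, obj = pts_c, w3, L_c, obj3

        gain = obj - cycle_start_obj
        history.append(obj)
        if gain < config.converge_tol:
            if delta > config.delta_floor:
                delta = max(delta * 0.5, config.delta_floor)
            elif obj - pass_start_obj < config.converge_tol:
                converged = True  # a whole coarse-to-fine pass gained nothing
                break
            else:  # re-expand and sweep coarse-to-fine again
                pass_start_obj = obj
                delta = config.delta0

    # final cleanup: collapse near-duplicate support points (flat directions
    # of the mixture likelihood) when the sparser support costs less than
    # converge_tol in log-likelihood
    for resolution in (1e-3, 2e-3, 5e-3):
        pts_c, w_c, L_c = _condense(pts, w, L, config.ranges, resolution)
        if pts_c.shape[0] < pts.shape[0]:
            w3, obj3 = solve(L_c, w_c)
            if obj3 >= obj - config.converge_tol:
                keep = w3 > config.prune_eps
                pts, L = pts_c[keep], L_c[:, keep]
                w = w3[keep] / w3[keep].sum()
                obj = obj3

    dist = NPDistribution(
        points=[PKParams(ka=p[0], ke=p[1], v=p[2], f=config.f) for p in pts],
        weights=w,
    )
    posteriors = {
        s.id: posterior(s, dist, em, sd_mode=config.sd_mode) for s in subjects
    }
    result = FitResult(
        distribution=dist,
        loglik=obj,
        n_cycles=n_cycles,
        converged=converged,
        posteriors=posteriors,
        objective_history=history,
    )
    result.diagnostics = diagnostics(result, subjects, em, sd_mode=config.sd_mode)
    return result


# ---------------------------------------------------------------------------
# posteriors, diagnostics, covariate screening


def posterior(
    subject: SubjectRecord,
    dist: NPDistribution,
    em: ErrorModel,
    sd_mode: str = "observed",
) -> SubjectPosterior:
    """Bayesian posterior over support points: p_k proportional to w_k * L_k."""
    theta = dist.param_array()
    f = dist.points[0].f
    ll = _loglik_block([subject], theta, em, f, sd_mode)[0]
    with np.errstate(divide="ignore"):
        logp = np.log(dist.weights) + ll
    norm = logsumexp(logp)
    if not np.isfinite(norm):
        raise ValueError(f"subject {subject.id!r} has zero posterior mass everywhere")
    p = np.exp(logp - norm)
    mean = p @ theta
    return SubjectPosterior(weights=p, mean=PKParams(ka=mean[0], ke=mean[1], v=mean[2], f=f))


def _prediction_vectors(fitres: FitResult, subjects, em: ErrorModel, sd_mode: str):
    """Observed values, prior-weighted and posterior-weighted predictions."""
    theta = fitres.distribution.param_array()
    f = fitres.distribution.points[0].f
    obs_all, pop_all, post_all = [], [], []
    for s in subjects:
        _, obs, _, _ = _subject_arrays(s)
        pred = _predict_points(s, theta[:, 0], theta[:, 1], theta[:, 2], f)
        obs_all.append(obs)
        pop_all.append(fitres.distribution.weights @ pred)
        post_all.append(fitres.posteriors[s.id].weights @ pred)
    return (np.concatenate(obs_all), np.concatenate(pop_all), np.concatenate(post_all))


def diagnostics(
    fitres: FitResult,
    subjects,
    em: ErrorModel,
    sd_mode: str = "observed",
) -> FitDiagnostics:
    """Prediction-error, regression, information-criterion and shrinkage summaries.

    Weighted prediction errors use the published weighting 1/(lam+c0+c1*c).
    The parameter count for AIC/BIC is 4K - 1 for K support points (three
    coordinates each plus K - 1 free weights).
    """
    subjects = list(subjects)
    obs, pop_pred, post_pred = _prediction_vectors(fitres, subjects, em, sd_mode)
    wts = em.weight(obs)
    e = (obs - post_pred) * wts
    mwpe = float(e.mean())
    mwspe = float((e * e).mean())

    n_obs = obs.size
    if n_obs >= 3 and np.ptp(post_pred) > 0 and np.ptp(pop_pred) > 0:
        pop_fit = stats.linregress(pop_pred, obs)
        post_fit = stats.linregress(post_pred, obs)
        pop_stats = (pop_fit.slope, pop_fit.intercept, pop_fit.rvalue)
        post_stats = (post_fit.slope, post_fit.intercept, post_fit.rvalue)
    else:
        import warnings

        warnings.warn("too few or degenerate observations; regression skipped")
        pop_stats = post_stats = (math.nan, math.nan, math.nan)

    if n_obs >= 2 and np.ptp(e) > 0:
        bias_t_p = float(stats.ttest_1samp(e, 0.0).pvalue)
    else:
        bias_t_p = math.nan
    if n_obs >= 3 and np.ptp(e) > 0:
        normality_p = float(stats.shapiro(e).pvalue)
    else:
        normality_p = math.nan

    K = len(fitres.distribution)
    n_par = 4 * K - 1
    neg2ll = -2.0 * fitres.loglik
    aic = neg2ll + 2.0 * n_par
    bic = neg2ll + n_par * math.log(n_obs)

    post_means = np.array(
        [[fitres.posteriors[s.id].mean.ka,
          fitres.posteriors[s.id].mean.ke,
          fitres.posteriors[s.id].mean.v] for s in subjects]
    )
    pop_sd = fitres.distribution.marginal_sd()
    shrinkage = {}
    for j, name in enumerate(_PARAM_NAMES):
        if pop_sd[j] > 0:
            shrinkage[name] = float(100.0 * (1.0 - post_means[:, j].std() / pop_sd[j]))
        else:
            shrinkage[name] = math.nan

    return FitDiagnostics(
        pop_slope=pop_stats[0], pop_intercept=pop_stats[1], pop_r=pop_stats[2],
        post_slope=post_stats[0], post_intercept=post_stats[1], post_r=post_stats[2],
        mwpe=mwpe, mwspe=mwspe, bias_t_p=bias_t_p,
        residual_normality_p=normality_p,
        neg2ll=neg2ll, aic=aic, bic=bic,
        n_support=K, n_obs=n_obs, shrinkage_pct=shrinkage,
    )


def covariate_screen(fitres: FitResult, subjects) -> pd.DataFrame:
    """Screen covariates against posterior parameter estimates.

    Numeric covariates: Pearson r, flagged when |r| >= 0.7. Two-level
    covariates (dose, gender): Wilcoxon rank-sum with normal approximation,
    flagged when p < 0.010. Constant covariates are reported not-screenable.
    """
    subjects = list(subjects)
    names = sorted({k for s in subjects for k in s.covariates})
    post_means = {
        name: np.array(
            [getattr(fitres.posteriors[s.id].mean, name) for s in subjects]
        )
        for name in _PARAM_NAMES
    }
    rows = []
    for cov in names:
        vals = [s.covariates.get(cov) for s in subjects]
        present = np.array([v is not None for v in vals])
        uniq = sorted({v for v in vals if v is not None}, key=str)
        for par in _PARAM_NAMES:
            y = post_means[par][present]
            row = {"parameter": par, "covariate": cov, "kind": None,
                   "r": math.nan, "p": math.nan, "flagged": False, "note": ""}
            if len(uniq) < 2:
                row["kind"] = "constant"
                row["note"] = "constant covariate; not screenable"
            elif len(uniq) == 2:
                row["kind"] = "categorical"
                g = np.array([v for v in vals if v is not None], dtype=object)
                p = float(stats.ranksums(y[g == uniq[0]], y[g == uniq[1]]).pvalue)
                row["p"] = p
                row["flagged"] = p < 0.010
            else:
                row["kind"] = "numeric"
                x = np.array([v for v in vals if v is not None], dtype=float)
                if np.ptp(x) == 0:
                    row["kind"] = "constant"
                    row["note"] = "constant covariate; not screenable"
                else:
                    r = float(np.corrcoef(x, y)[0, 1]) if np.ptp(y) > 0 else math.nan
                    row["r"] = r
                    row["flagged"] = bool(abs(r) >= 0.7) if math.isfinite(r) else False
            rows.append(row)
    return pd.DataFrame(rows, columns=["parameter", "covariate", "kind", "r", "p", "flagged", "note"])
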