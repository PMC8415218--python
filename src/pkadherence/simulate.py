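"""Monte Carlo simulation of virtual cohorts under three adherence levels.

Each virtual subject receives 14 once-daily doses; serum is sampled at the
first sampling time (FST, 1-24 h after the last dose) for full adherence,
at FST+24 h to represent omission of the last dose (partial adherence), and
at FST+72 h for omission of the last three doses (nonadherence).
Concentrations are dose-normalized, which removes the dose under linear
kinetics with dose-independent parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .npml import NPDistribution
from .pk import PKParams, _bateman, mg_to_nmol

__all__ = ["SimSettings", "ScenarioGrid", "SCENARIOS", "sample_params", "simulate_scenarios"]

#: Scenario names in order of increasing sampling delay past the FST.
SCENARIOS = ("adherent", "partial", "nonadherent")


@dataclass
class SimSettings:
    """Monte Carlo design: cohort size, doses, regimen and sampling grid."""

    n_per_dose: int = 10_000
    doses_mg: tuple = (5.0, 10.0, 20.0, 40.0, 80.0)
    n_loading_doses: int = 14
    dosing_interval_h: float = 24.0
    fst_grid_h: tuple = tuple(range(1, 25))
    scenario_offsets_h: dict = field(
        default_factory=lambda: {"adherent": 0.0, "partial": 24.0, "nonadherent": 72.0}
    )
    seed: int = 0
    jitter: str = "off"  # "off" | "mvn"

    def __post_init__(self) -> None:
        if self.n_per_dose < 1:
            raise ValueError("n_per_dose must be >= 1")
        offsets = [self.scenario_offsets_h[s] for s in SCENARIOS]
        if not all(a < b for a, b in zip(offsets, offsets[1:])):
            raise ValueError("scenario offsets must be strictly increasing")
        fst = list(self.fst_grid_h)
        if not all(a < b for a, b in zip(fst, fst[1:])):
            raise ValueError("fst grid must be strictly increasing")

    @property
    def n_total(self) -> int:
        return self.n_per_dose * len(self.doses_mg)


@dataclass
class ScenarioGrid:
    """Dose-normalized concentrations, shape (n_subjects, n_fst, n_scenarios)."""

    values: np.ndarray
    fst_grid_h: np.ndarray
    scenarios: tuple
    doses_mg: np.ndarray
    settings: SimSettings
    source_hash: str = ""

    def group(self, fst_h: float, scenario: str) -> np.ndarray:
        """All virtual subjects' values at one FST under one scenario."""
        idx = np.flatnonzero(np.isclose(self.fst_grid_h, fst_h))
        if idx.size == 0:
            raise ValueError(f"FST {fst_h} h is not on the simulated grid")
        return self.values[:, int(idx[0]), self.scenarios.index(scenario)]

    def nearest_fst(self, t_h: float) -> float:
        lo, hi = self.fst_grid_h[0], self.fst_grid_h[-1]
        if not (lo - 0.5 <= t_h <= hi + 0.5):
            raise ValueError(
                f"sampling time {t_h} h outside simulated FST grid [{lo}, {hi}] h; "
                "re-simulate with an extended grid"
            )
        return float(self.fst_grid_h[int(np.argmin(np.abs(self.fst_grid_h - t_h)))])


def _dist_hash(dist: NPDistribution) -> str:
    payload = json.dumps(
        {"points": dist.param_array().tolist(), "weights": dist.weights.tolist()},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def sample_params(
    dist: NPDistribution,
    n: int,
    seed: int,
    jitter: str = "off",
    ranges: dict | None = None,
) -> list:
    """Draw n parameter vectors from the fitted discrete distribution.

    Default is a weighted categorical draw of support points (the fitted
    NPML object). ``jitter="mvn"`` adds multivariate-normal noise with the
    population covariance around each drawn point, truncated to the
    parameter box (semi-parametric sampling).
    """
    if len(dist) == 0:
        raise ValueError("empty distribution")
    rng = np.random.default_rng(seed)
    theta = dist.param_array()
    idx = rng.choice(len(dist), size=n, p=dist.weights)
    draws = theta[idx]
    if jitter == "mvn":
        mu = dist.weights @ theta
        centered = theta - mu
        cov = (dist.weights[:, None] * centered).T @ centered
        draws = draws + rng.multivariate_normal(np.zeros(3), cov, size=n)
        if ranges is not None:
            lo = np.array([ranges[k][0] for k in ("ka", "ke", "v")])
            hi = np.array([ranges[k][1] for k in ("ka", "ke", "v")])
        else:
            lo, hi = theta.min(axis=0), theta.max(axis=0)
        lo = np.maximum(lo, 1e-9)
        draws = np.clip(draws, lo, hi)
    elif jitter != "off":
        raise ValueError(f"unknown jitter mode {jitter!r}")
    f = dist.points[0].f
    return [PKParams(ka=d[0], ke=d[1], v=d[2], f=f) for d in draws]


def simulate_scenarios(dist: NPDistribution, settings: SimSettings | None = None) -> ScenarioGrid:
    """Simulate the virtual cohort and return the dose-normalized grid."""
    settings = settings or SimSettings()
    params = sample_params(dist, settings.n_total, settings.seed, jitter=settings.jitter)
    ka = np.array([p.ka for p in params])[:, None]
    ke = np.array([p.ke for p in params])[:, None]
    v = np.array([p.v for p in params])[:, None]
    f = dist.points[0].f

    doses = np.repeat(np.asarray(settings.doses_mg, dtype=float), settings.n_per_dose)
    fst = np.asarray(settings.fst_grid_h, dtype=float)
    offsets = np.array([settings.scenario_offsets_h[s] for s in SCENARIOS])
    t_last = (settings.n_loading_doses - 1) * settings.dosing_interval_h
    # flattened sampling times: (n_fst * n_scenarios,)
    times = (t_last + fst[:, None] + offsets[None, :]).reshape(-1)

    conc = np.zeros((settings.n_total, times.size))
    unit_dose = mg_to_nmol(1.0)
    for k in range(settings.n_loading_doses):
        elapsed = times[None, :] - k * settings.dosing_interval_h
        conc += _bateman(ka, ke, v, f, unit_dose * doses[:, None], elapsed)
    normalized = conc / doses[:, None]
    values = normalized.reshape(settings.n_total, fst.size, len(SCENARIOS))
    return ScenarioGrid(
        values=values,
        fst_grid_h=fst,
        scenarios=SCENARIOS,
        doses_mg=doses,
        settings=settings,
        source_hash=_dist_hash(dist),
    )
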