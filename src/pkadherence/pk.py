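"""One-compartment oral pharmacokinetics for atorvastatin serum concentrations.

Closed-form Bateman kinetics with first-order absorption, repeat dosing by
superposition, an optional pre-dose concentration as initial condition, and
the assay-error/weighting model used throughout fitting and simulation.

Units are fixed package-wide: time in hours, amounts in nmol, volumes in
litres, concentrations in nmol/L. Doses are accepted in mg and converted
through the atorvastatin molar mass; dose-normalized concentrations are in
nmol per mg dose per litre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ATORVASTATIN_MOLAR_MASS_G_MOL",
    "DEFAULT_BIOAVAILABILITY",
    "ANALYTES",
    "PKParams",
    "DoseEvent",
    "Observation",
    "ErrorModel",
    "ASSAY_ERROR",
    "mg_to_nmol",
    "half_life",
    "conc_single_dose",
    "conc_profile",
    "dose_normalize",
    "error_sd",
    "obs_weight",
]

ATORVASTATIN_MOLAR_MASS_G_MOL = 558.64
#: Absolute oral bioavailability of atorvastatin, treated as a fixed effect.
DEFAULT_BIOAVAILABILITY = 0.125
#: Lumped analytes: parent + lactone, and parent + all measured metabolites.
ANALYTES = ("ATR_ATRL", "ATR_MET")

# Relative tolerance below which ka and ke are treated as equal and the
# Bateman equation is replaced by its analytic limit (avoids catastrophic
# cancellation in ka - ke without a visible discontinuity).
KA_KE_REL_TOL = 1e-6

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PKParams:
    """Kinetic triplet of one subject or support point.

    ka : absorption rate constant (1/h)
    ke : elimination rate constant (1/h)
    v  : volume of distribution (L); the apparent oral volume is v / f
    f  : oral bioavailability (fixed effect)
    """

    ka: float
    ke: float
    v: float
    f: float = DEFAULT_BIOAVAILABILITY

    def __post_init__(self) -> None:
        if not (self.ka > 0 and self.ke > 0 and self.v > 0):
            raise ValueError(f"ka, ke, v must be positive, got {self}")
        if not (0 < self.f <= 1):
            raise ValueError(f"bioavailability f must be in (0, 1], got {self.f}")


@dataclass(frozen=True)
class DoseEvent:
    """One oral dose. Negative times encode doses taken before the reference dose."""

    time_h: float
    amount_mg: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_h):
            raise ValueError("dose time must be finite")
        if self.amount_mg < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount_mg}")


@dataclass(frozen=True)
class Observation:
    """One timed serum concentration of a lumped analyte."""

    time_h: float
    conc: float
    analyte: str = "ATR_ATRL"

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_h):
            raise ValueError("observation time must be finite")
        if self.conc < 0:
            raise ValueError(f"concentration must be >= 0, got {self.conc}")
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}; expected one of {ANALYTES}")


@dataclass(frozen=True)
class ErrorModel:
    """Assay + process error: SD(c) = c0 + c1*c, total SD = lam + c0 + c1*c.

    c0/c1 come from assay validation; lam absorbs clinical and preanalytical
    noise. Observation weights in diagnostics are 1 / total SD.
    """

    c0: float
    c1: float
    lam: float = 0.01

    def __post_init__(self) -> None:
        if self.c0 < 0 or self.c1 < 0 or self.lam < 0:
            raise ValueError("error-model coefficients must be >= 0")
        if self.lam + self.c0 <= 0:
            raise ValueError("total SD must be positive at zero concentration")

    def sd(self, conc):
        return self.c0 + self.c1 * np.asarray(conc, dtype=float)

    def total_sd(self, conc):
        return self.lam + self.sd(conc)

    def weight(self, conc):
        return 1.0 / self.total_sd(conc)


#: Assay-error coefficients per lumped analyte (nmol/L scale).
ASSAY_ERROR = {
    "ATR_ATRL": ErrorModel(c0=8.26e-5, c1=3.53e-2),
    "ATR_MET": ErrorModel(c0=3.86e-5, c1=3.32e-2),
}


def mg_to_nmol(dose_mg: float) -> float:
    """Convert an atorvastatin dose from mg to nmol (558.64 g/mol)."""
    if dose_mg < 0:
        raise ValueError(f"dose must be >= 0 mg, got {dose_mg}")
    return dose_mg / ATORVASTATIN_MOLAR_MASS_G_MOL * 1e6


def half_life(ke: float) -> float:
    """Elimination half-life t1/2 = ln(2)/ke in hours."""
    if ke <= 0:
        raise ValueError(f"ke must be positive, got {ke}")
    return math.log(2.0) / ke


def _bateman(ka, ke, v, f, dose_nmol, t):
    """Concentration after a single oral bolus; broadcasts over parameter arrays.

    Elapsed times <= 0 contribute zero. Near-degenerate ka == ke switches to
    the limit f*D*ke*t*exp(-ke*t)/v.
    """
    ka = np.asarray(ka, dtype=float)
    ke = np.asarray(ke, dtype=float)
    v = np.asarray(v, dtype=float)
    t = np.maximum(np.asarray(t, dtype=float), 0.0)

    degenerate = np.abs(ka - ke) < KA_KE_REL_TOL * np.maximum(ka, ke)
    safe_diff = np.where(degenerate, 1.0, ka - ke)
    general = f * dose_nmol * ka / (v * safe_diff) * (np.exp(-ke * t) - np.exp(-ka * t))
    limit = f * dose_nmol * ke * t * np.exp(-ke * t) / v
    return np.where(degenerate, limit, general)


def conc_single_dose(params: PKParams, dose_mg: float, t):
    """Serum concentration (nmol/L) at time(s) t hours after a single dose."""
    t_arr = np.asarray(t, dtype=float)
    out = _bateman(params.ka, params.ke, params.v, params.f, mg_to_nmol(dose_mg), t_arr)
    return float(out) if np.ndim(t) == 0 else out


def conc_profile(params: PKParams, events, times, c_ini: float = 0.0):
    """Concentration profile under repeat dosing by superposition.

    Prior drug history may be encoded either as dose events with negative
    times or as a pre-dose concentration ``c_ini`` that decays
    mono-exponentially from t = 0; supplying both is ambiguous and rejected.
    """
    times_arr = np.asarray(times, dtype=float)
    if c_ini < 0:
        raise ValueError(f"c_ini must be >= 0, got {c_ini}")
    if c_ini > 0 and any(ev.time_h < 0 for ev in events):
        raise ValueError(
            "ambiguous prior history: supply either negative-time dose events "
            "or a nonzero c_ini, not both"
        )
    total = c_ini * np.exp(-params.ke * times_arr)
    dose = mg_to_nmol(1.0)
    for ev in events:
        if ev.amount_mg == 0:
            continue
        total = total + _bateman(
            params.ka, params.ke, params.v, params.f,
            dose * ev.amount_mg, times_arr - ev.time_h,
        )
    return float(total) if np.ndim(times) == 0 else total


def dose_normalize(conc, dose_mg: float):
    """Concentration per mg of prescribed dose, nmol·(mg dose)^-1·L^-1."""
    if dose_mg <= 0:
        raise ValueError(f"dose must be positive for normalization, got {dose_mg}")
    return np.asarray(conc, dtype=float) / dose_mg if np.ndim(conc) else conc / dose_mg


def error_sd(em: ErrorModel, conc):
    """Assay SD at a concentration: c0 + c1*conc."""
    return em.sd(conc)


def obs_weight(em: ErrorModel, conc):
    """Observation weight 1/(lam + c0 + c1*conc)."""
    return em.weight(conc)
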