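"""Seeded synthetic cohorts mirroring the study design.

Training design: 39 subjects with a witnessed dose and samples at 0, 2, 4
and 6 h. Twenty-nine are dose-naive (24 on 20 mg, 5 on 40 mg) with a zero
pre-dose sample; ten have prior drug history (4 on 20 mg, 6 on 40 mg) with
a prior dose 36 h before the witnessed one (a single subject 14 h), so
their pre-dose concentration c_ini is nonzero and serves as the model's
initial condition.

Testing design: 26 patients on chronic therapy (10/20/40/80 mg taken by
1/18/5/2 patients), a single sample on an integer hour 2-20 h post dose,
and a hidden adherence state driving the dosing history actually simulated
(full: 14 doses; partial: last dose omitted; nonadherent: last three doses
omitted). Truth (parameters and states) is emitted alongside for
closed-loop recovery tests.

Assay noise is Gaussian with SD = lam + C0 + C1*c, truncated at zero
(assays report non-negative values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import PatientMeasurement
from .npml import NPDistribution, SubjectRecord
from .pk import ASSAY_ERROR, ANALYTES, DoseEvent, Observation, PKParams, conc_profile

__all__ = [
    "CohortConfig",
    "default_true_distribution",
    "generate_training",
    "generate_testing",
]

#: Population medians (ka 1/h, ke 1/h, central V in L) behind the default
#: synthetic truth, per lumped analyte. V is apparent volume times F = 0.125.
_TRUE_MEDIANS = {
    "ATR_ATRL": (1.74, 0.135, 0.125 * 358.0),
    "ATR_MET": (1.12, 0.110, 0.125 * 220.0),
}


def default_true_distribution(analyte: str = "ATR_ATRL") -> NPDistribution:
    """Three support points at the median and +/-50%, weights 0.5/0.3/0.2.

    Multimodal by construction so the nonparametric fitter has structure to
    find; the weighted median of every coordinate equals the central point.
    """
    m = np.array(_TRUE_MEDIANS[analyte])
    points = [
        PKParams(*(m * 1.0)),
        PKParams(*(m * 1.5)),
        PKParams(*(m * 0.5)),
    ]
    return NPDistribution(points=points, weights=np.array([0.5, 0.3, 0.2]))


@dataclass
class CohortConfig:
    """Design, truth and noise settings for a synthetic cohort."""

    design: str = "training"
    analyte: str = "ATR_ATRL"
    seed: int = 0
    true_distribution: NPDistribution | None = None
    # training design
    naive_doses: dict = field(default_factory=lambda: {20.0: 24, 40.0: 5})
    prior_doses: dict = field(default_factory=lambda: {20.0: 4, 40.0: 6})
    prior_offset_h: float = 36.0
    prior_offset_alt_h: float = 14.0  # one subject took the prior dose 14 h before
    sampling_times_h: tuple = (0.0, 2.0, 4.0, 6.0)
    noise_scale: float = 1.0
    missing_rate: float = 0.0
    # testing design
    testing_doses: dict = field(default_factory=lambda: {10.0: 1, 20.0: 18, 40.0: 5, 80.0: 2})
    testing_time_range_h: tuple = (2, 20)
    adherence_mix: dict = field(default_factory=lambda: {"A": 16 / 26, "PA": 10 / 26, "NA": 0.0})
    n_loading_doses: int = 14
    dosing_interval_h: float = 24.0

    def __post_init__(self) -> None:
        # dose maps may arrive with string keys from JSON/YAML configs
        self.naive_doses = {float(k): int(v) for k, v in self.naive_doses.items()}
        self.prior_doses = {float(k): int(v) for k, v in self.prior_doses.items()}
        self.testing_doses = {float(k): int(v) for k, v in self.testing_doses.items()}
        if self.design not in ("training", "testing"):
            raise ValueError("design must be 'training' or 'testing'")
        mix_total = sum(self.adherence_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ValueError(f"adherence_mix must sum to 1, got {mix_total}")
        if self.noise_scale < 0 or not (0 <= self.missing_rate < 1):
            raise ValueError("invalid noise_scale or missing_rate")


def _truth_for(config: CohortConfig, analyte: str) -> NPDistribution:
    if config.true_distribution is not None:
        return config.true_distribution
    return default_true_distribution(analyte)


def _draw_params(dist: NPDistribution, rng: np.random.Generator) -> PKParams:
    idx = rng.choice(len(dist), p=dist.weights)
    return dist.points[idx]


def _noisy(conc: float, em, rng: np.random.Generator, scale: float) -> float:
    if scale == 0:
        return float(conc)
    sd = float(em.total_sd(conc)) * scale
    return float(max(conc + rng.normal(0.0, sd), 0.0))


def generate_training(config: CohortConfig):
    """Generate the training cohort.

    Returns ``(subjects, truth)`` where ``subjects`` is a list of
    SubjectRecord ready for fitting (prior history summarized by the
    measured c_ini, not by negative-time dose events) and ``truth`` is a
    DataFrame of each subject's true parameters and group.
    """
    rng = np.random.default_rng(config.seed)
    dist = _truth_for(config, config.analyte)
    em = ASSAY_ERROR[config.analyte]
    subjects, rows = [], []
    counter = 0
    post_dose_times = [t for t in config.sampling_times_h if t > 0]

    def next_id():
        nonlocal counter
        counter += 1
        return f"S{counter:02d}"

    for dose_mg, count in config.naive_doses.items():
        for _ in range(count):
            sid = next_id()
            params = _draw_params(dist, rng)
            events = (DoseEvent(0.0, dose_mg),)
            obs = [Observation(0.0, 0.0, config.analyte)]  # drug-naive pre-dose
            for t in post_dose_times:
                if rng.random() < config.missing_rate:
                    continue
                c = conc_profile(params, events, t)
                obs.append(Observation(t, _noisy(c, em, rng, config.noise_scale), config.analyte))
            subjects.append(SubjectRecord(id=sid, events=events, observations=tuple(obs)))
            rows.append({"id": sid, "group": "naive", "dose_mg": dose_mg,
                         "ka": params.ka, "ke": params.ke, "v": params.v})

    first_prior = True
    for dose_mg, count in config.prior_doses.items():
        for _ in range(count):
            sid = next_id()
            params = _draw_params(dist, rng)
            offset = config.prior_offset_alt_h if first_prior else config.prior_offset_h
            first_prior = False
            true_events = (DoseEvent(-offset, dose_mg), DoseEvent(0.0, dose_mg))
            c_ini = _noisy(
                conc_profile(params, true_events[:1], 0.0), em, rng, config.noise_scale
            )
            obs = [Observation(0.0, c_ini, config.analyte)]
            for t in post_dose_times:
                if rng.random() < config.missing_rate:
                    continue
                c = conc_profile(params, true_events, t)
                obs.append(Observation(t, _noisy(c, em, rng, config.noise_scale), config.analyte))
            subjects.append(
                SubjectRecord(
                    id=sid, events=(DoseEvent(0.0, dose_mg),),
                    observations=tuple(obs), c_ini=c_ini,
                )
            )
            rows.append({"id": sid, "group": "prior", "dose_mg": dose_mg,
                         "ka": params.ka, "ke": params.ke, "v": params.v})

    return subjects, pd.DataFrame(rows)


def _testing_history(state: str, dose_mg: float, n_doses: int, interval: float):
    """Dose events actually taken under an adherence state; the reference
    schedule has n_doses once-daily doses ending at t_last."""
    omitted = {"A": 0, "PA": 1, "NA": 3}[state]
    return tuple(
        DoseEvent(k * interval, dose_mg) for k in range(n_doses - omitted)
    )


def generate_testing(config: CohortConfig):
    """Generate the adherence-testing cohort.

    Returns ``(patients, truth)``: PatientMeasurement objects carrying both
    analytes' measured concentrations, and a DataFrame with the hidden
    adherence state and true parameters per analyte.
    """
    rng = np.random.default_rng(config.seed)
    dists = {a: _truth_for(config, a) for a in ANALYTES}
    states = list(config.adherence_mix)
    probs = np.array([config.adherence_mix[s] for s in states])
    t_lo, t_hi = config.testing_time_range_h
    t_last = (config.n_loading_doses - 1) * config.dosing_interval_h

    patients, rows = [], []
    counter = 0
    for dose_mg, count in config.testing_doses.items():
        for _ in range(count):
            counter += 1
            pid = f"T{counter:02d}"
            t_sample = float(rng.integers(t_lo, t_hi + 1))
            state = states[rng.choice(len(states), p=probs)]
            conc = {}
            row = {"id": pid, "dose_mg": dose_mg, "time_h": t_sample, "state": state}
            for analyte in ANALYTES:
                params = _draw_params(dists[analyte], rng)
                events = _testing_history(
                    state, dose_mg, config.n_loading_doses, config.dosing_interval_h
                )
                c = conc_profile(params, events, t_last + t_sample)
                conc[analyte] = _noisy(c, ASSAY_ERROR[analyte], rng, config.noise_scale)
                row.update({f"ka_{analyte}": params.ka, f"ke_{analyte}": params.ke,
                            f"v_{analyte}": params.v})
            patients.append(
                PatientMeasurement(id=pid, dose_mg=dose_mg,
                                   time_since_dose_h=t_sample, conc=conc)
            )
            rows.append(row)
    return patients, pd.DataFrame(rows)
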