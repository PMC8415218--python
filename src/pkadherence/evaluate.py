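"""ROC analysis of the simulated cohorts and per-patient adherence calls.

Dose-normalized simulated concentrations at each sampling time are turned
into ROC curves discriminating full from partial adherence and partial
adherence from nonadherence; the recommended cutoff minimizes
|specificity - sensitivity| over the cutoff grid. A measured patient
concentration is scored by its attainment probability — the fraction of
simulated subjects of each adherence level whose concentration is at least
the measured one — and classified A / PA / NA from those probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pk import ANALYTES, dose_normalize
from .simulate import SCENARIOS, ScenarioGrid

__all__ = [
    "ROCResult",
    "PatientMeasurement",
    "AttainmentReport",
    "COMPARISONS",
    "roc_curve",
    "auc",
    "optimal_cutoff",
    "attainment",
    "classify",
    "evaluate_patient",
]

#: comparison name -> (less adherent group, more adherent group)
COMPARISONS = {
    "full_vs_partial": ("partial", "adherent"),
    "partial_vs_non": ("nonadherent", "partial"),
}

DEFAULT_THETA = 0.85


@dataclass
class ROCResult:
    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    opt_cutoff: float
    sens_at_opt: float
    spec_at_opt: float
    comparison: str
    fst_h: float


@dataclass(frozen=True)
class PatientMeasurement:
    """A single adherence-testing sample: dose, time since last reported dose,
    and measured concentration (nmol/L) per lumped analyte."""

    id: str
    dose_mg: float
    time_since_dose_h: float
    conc: dict

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError(f"patient {self.id!r}: dose must be positive")
        if self.time_since_dose_h <= 0:
            raise ValueError(f"patient {self.id!r}: sampling time must be positive")
        for analyte in self.conc:
            if analyte not in ANALYTES:
                raise ValueError(f"unknown analyte {analyte!r}")


@dataclass
class AttainmentReport:
    """Attainment probabilities per analyte and adherence level, plus the call."""

    id: str
    probabilities: dict  # {analyte: {scenario: p}}
    call: str
    narrative: list = field(default_factory=list)


def roc_curve(
    grid: ScenarioGrid,
    fst_h: float,
    comparison: str,
    cutoff_lo: float = 0.002,
    cutoff_hi: float = 10.0,
    step: float = 0.002,
) -> ROCResult:
    """ROC over the cutoff grid at one sampling time.

    TPR(c) = fraction of the less-adherent group strictly below c (detection
    of reduced adherence); FPR(c) = same fraction in the more-adherent group.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"comparison must be one of {sorted(COMPARISONS)}")
    less, more = COMPARISONS[comparison]
    vals_less = np.sort(grid.group(fst_h, less))
    vals_more = np.sort(grid.group(fst_h, more))
    if vals_less.size == 0 or vals_more.size == 0:
        raise ValueError("empty scenario group")

    n_steps = int(round((cutoff_hi - cutoff_lo) / step)) + 1
    cutoffs = cutoff_lo + step * np.arange(n_steps)
    tpr = np.searchsorted(vals_less, cutoffs, side="left") / vals_less.size
    fpr = np.searchsorted(vals_more, cutoffs, side="left") / vals_more.size

    roc = ROCResult(
        cutoffs=cutoffs, tpr=tpr, fpr=fpr, auc=math.nan,
        opt_cutoff=math.nan, sens_at_opt=math.nan, spec_at_opt=math.nan,
        comparison=comparison, fst_h=fst_h,
    )
    roc.auc = auc(roc)
    roc.opt_cutoff, roc.sens_at_opt, roc.spec_at_opt = optimal_cutoff(roc)
    return roc


def auc(roc: ROCResult) -> float:
    """Trapezoid area under TPR(FPR), anchored at (0,0) and (1,1)."""
    if roc.cutoffs.size < 2:
        raise ValueError("need at least two cutoffs for an AUC")
    x = np.concatenate([[0.0], roc.fpr, [1.0]])
    y = np.concatenate([[0.0], roc.tpr, [1.0]])
    return float(np.trapezoid(y, x))


def optimal_cutoff(roc: ROCResult):
    """Cutoff minimizing |specificity - sensitivity|; ties -> smallest cutoff."""
    sens = roc.tpr
    spec = 1.0 - roc.fpr
    i = int(np.argmin(np.abs(spec - sens)))  # argmin returns the first minimum
    return float(roc.cutoffs[i]), float(sens[i]), float(spec[i])


def attainment(grid: ScenarioGrid, m: PatientMeasurement, analyte: str, scenario: str) -> float:
    """Probability that a simulated subject of the given adherence level
    attains (>=) the patient's dose-normalized measured concentration, at the
    FST grid point nearest the reported sampling time."""
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if analyte not in m.conc:
        raise ValueError(f"patient {m.id!r} has no {analyte} measurement")
    measured = dose_normalize(m.conc[analyte], m.dose_mg)
    vals = grid.group(grid.nearest_fst(m.time_since_dose_h), scenario)
    return float(np.count_nonzero(vals >= measured) / vals.size)


def classify(
    probabilities: dict,
    theta1: float = DEFAULT_THETA,
    theta2: float = DEFAULT_THETA,
):
    """Categorical adherence call from attainment probabilities.

    ``probabilities`` maps analyte -> {scenario: p} with p in [0, 1]. The
    decisive analyte is ATR+MET (slower turnover, longer memory of missed
    doses): reduced adherence is suspected when the probability of an
    adherent subject attaining the measured concentration is >= theta1
    (the measurement sits in the low tail of the adherent distribution);
    nonadherence is called when even partially adherent subjects attain it
    with probability >= theta2. The narrative reports ATR+ATRL evidence
    first, as it is consulted first in practice.

    Returns ``(call, narrative)`` with call in {"A", "PA", "NA"}.
    """
    for analyte, probs in probabilities.items():
        for scen, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1]: {analyte}/{scen}={p}")

    narrative = []
    atrl = probabilities.get("ATR_ATRL")
    if atrl is not None:
        narrative.append(
            "ATR+ATRL attainment: adherent {:.1%}, partial {:.1%}, nonadherent {:.1%}".format(
                atrl.get("adherent", math.nan),
                atrl.get("partial", math.nan),
                atrl.get("nonadherent", math.nan),
            )
        )

    met = probabilities.get("ATR_MET")
    if met is None:
        warnings.warn(
            "ATR+MET probabilities missing; falling back to a single-analyte "
            "rule on ATR+ATRL"
        )
        met = atrl
        if met is None:
            raise ValueError("no analyte probabilities supplied")
    else:
        narrative.append(
            "ATR+MET attainment: adherent {:.1%}, partial {:.1%}, nonadherent {:.1%}".format(
                met.get("adherent", math.nan),
                met.get("partial", math.nan),
                met.get("nonadherent", math.nan),
            )
        )

    p_adh = met["adherent"]
    p_par = met["partial"]
    if p_adh >= theta1:
        if p_par >= theta2:
            call = "NA"
            narrative.append(
                "even partially adherent subjects would usually attain the "
                "measured level: nonadherence is the best estimate"
            )
        else:
            call = "PA"
            narrative.append(
                "most adherent but few partially adherent subjects would attain "
                "the measured level: partial adherence is the best estimate"
            )
    else:
        call = "A"
        narrative.append(
            "the measured level is typical of adherent subjects: full adherence "
            "is the best estimate"
        )
    return call, narrative


def evaluate_patient(
    grids: dict,
    m: PatientMeasurement,
    theta1: float = DEFAULT_THETA,
    theta2: float = DEFAULT_THETA,
) -> AttainmentReport:
    """Compute all attainment probabilities for one patient and classify.

    ``grids`` maps analyte -> ScenarioGrid simulated from that analyte's
    fitted population model.
    """
    probabilities = {}
    for analyte in ANALYTES:
        if analyte in grids and analyte in m.conc:
            probabilities[analyte] = {
                scen: attainment(grids[analyte], m, analyte, scen) for scen in SCENARIOS
            }
    call, narrative = classify(probabilities, theta1=theta1, theta2=theta2)
    return AttainmentReport(id=m.id, probabilities=probabilities, call=call, narrative=narrative)
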