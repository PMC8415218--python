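import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

import pkadherence as pa
from pkadherence.cohort import CohortConfig, default_true_distribution, generate_training

RECOVERY_SEEDS = (0, 1, 2, 3, 4)

#: Population medians behind the default synthetic truth (per analyte);
#: also the truth's weighted medians, since the central point carries
#: half the probability mass.
TRUTH_MEDIANS = {
    "ATR_ATRL": {"ka": 1.74, "ke": 0.135, "v": 0.125 * 358.0},
    "ATR_MET": {"ka": 1.12, "ke": 0.110, "v": 0.125 * 220.0},
}


@pytest.fixture(scope="session")
def truth_dist():
    return default_true_distribution("ATR_ATRL")


@pytest.fixture(scope="session")
def training_cohort():
    """Default study-design training cohort (seed 0) with its truth table."""
    return generate_training(CohortConfig(seed=0))


def _fit_training(analyte: str, seed: int) -> pa.FitResult:
    subjects, _ = generate_training(CohortConfig(seed=seed, analyte=analyte))
    return pa.fit(subjects, pa.FitConfig(analyte=analyte, seed=seed))


@pytest.fixture(scope="session")
def atrl_fits():
    """Study-scale ATR+ATRL fits for the recovery seeds (shared: expensive)."""
    return {seed: _fit_training("ATR_ATRL", seed) for seed in RECOVERY_SEEDS}


@pytest.fixture(scope="session")
def met_fits():
    """Study-scale ATR+MET fits for the recovery seeds (shared: expensive)."""
    return {seed: _fit_training("ATR_MET", seed) for seed in RECOVERY_SEEDS}


@pytest.fixture(scope="session")
def truth_grid(truth_dist):
    """Scenario grid simulated from the known truth distribution."""
    return pa.simulate_scenarios(truth_dist, pa.SimSettings(n_per_dose=2000, seed=11))


def toy_grid(adherent, partial=(), nonadherent=(), fst_h=(12,)):
    """Hand-built single-FST ScenarioGrid for ROC/attainment unit tests."""
    groups = [np.asarray(adherent, dtype=float),
              np.asarray(partial if len(partial) else adherent, dtype=float),
              np.asarray(nonadherent if len(nonadherent) else adherent, dtype=float)]
    n = groups[0].size
    values = np.stack(groups, axis=1)[:, None, :]
    values = np.broadcast_to(values, (n, len(fst_h), 3)).copy()
    settings = pa.SimSettings(n_per_dose=n, doses_mg=(20.0,), fst_grid_h=tuple(fst_h))
    return pa.ScenarioGrid(
        values=values, fst_grid_h=np.asarray(fst_h, dtype=float),
        scenarios=("adherent", "partial", "nonadherent"),
        doses_mg=np.full(n, 20.0), settings=settings,
    )
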