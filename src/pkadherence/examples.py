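"""Bundled worked example: a published adherence-testing evaluation.

Twenty-six patients on chronic atorvastatin therapy, each with one serum
sample 2-20 h post dose, scored against Monte Carlo cohorts simulated from
nonparametric population PK models of ATR+ATRL and ATR+MET. For every
patient the table carries the dose, reported sampling time, dose-normalized
measured concentrations [nmol (mg dose)^-1 L^-1], the attainment
probabilities (percent of simulated fully/partially/non-adherent subjects
whose concentration reaches the measured one), and the adherence call that
the study reported. The probabilities are inputs to the classifier here;
the calls are the reference output the default decision rule reproduces.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["example_probability_table", "example_probabilities"]

_COLUMNS = [
    "id", "dose_mg", "time_h", "dn_atr_atrl", "dn_atr_met",
    "p_atrl_adherent", "p_atrl_partial", "p_atrl_nonadherent",
    "p_met_adherent", "p_met_partial", "p_met_nonadherent",
    "reported_call",
]

# Attainment probabilities are in percent, as reported.
_ROWS = [
    ("A1", 40, 12, 0.312, 0.775, 79.74, 3.62, 0.03, 95.29, 25.67, 2.65, "PA"),
    ("A2", 20, 16, 0.312, 0.782, 71.59, 2.31, 0.30, 78.48, 19.04, 2.44, "A"),
    ("A3", 20, 12, 0.064, 0.174, 97.69, 29.54, 1.13, 99.98, 64.82, 9.87, "PA"),
    ("A4", 20, 16, 1.032, 2.474, 13.59, 0.33, 0.00, 33.69, 3.45, 1.03, "A"),
    ("A5", 40, 16, 0.015, 0.117, 96.84, 59.72, 1.79, 97.79, 63.84, 11.57, "PA"),
    ("A6", 20, 15, 0.497, 1.081, 61.03, 1.47, 0.20, 75.18, 13.75, 1.97, "A"),
    ("A7", 20, 16, 0.492, 1.393, 55.38, 1.33, 0.20, 70.14, 8.79, 1.60, "A"),
    ("A8", 20, 15, 0.323, 1.253, 73.45, 2.49, 0.30, 73.84, 11.15, 1.74, "A"),
    ("A9", 20, 16, 0.145, 0.538, 78.40, 5.63, 0.61, 89.94, 28.15, 3.36, "PA"),
    ("A10", 20, 16, 0.378, 0.960, 66.44, 1.86, 0.28, 75.36, 14.93, 2.08, "A"),
    ("A11", 20, 18, 0.222, 0.926, 72.19, 2.75, 0.42, 73.61, 13.56, 2.06, "A"),
    ("A12", 40, 2, 0.274, 0.572, 100.0, 21.8, 0.56, 100.0, 63.19, 4.87, "PA"),
    ("A13", 20, 13, 0.533, 1.098, 68.72, 1.63, 0.19, 78.00, 15.48, 2.00, "A"),
    ("A14", 40, 12, 0.223, 0.367, 83.57, 5.56, 0.49, 98.40, 45.95, 5.33, "PA"),
    ("A15", 80, 20, 0.567, 0.952, 24.33, 0.88, 0.12, 68.63, 11.55, 1.96, "A"),
    ("A16", 20, 10, 0.294, 0.623, 87.72, 5.15, 0.42, 98.98, 36.03, 3.49, "PA"),
    ("A17", 10, 18, 0.364, 0.973, 57.53, 1.61, 0.28, 72.97, 12.83, 2.00, "A"),
    ("A18", 40, 12, 0.533, 2.176, 72.33, 1.87, 0.20, 67.12, 5.81, 1.16, "A"),
    ("A19", 20, 12, 0.734, 1.679, 61.47, 1.21, 0.09, 74.19, 8.87, 1.44, "A"),
    ("A20", 20, 14, 0.227, 0.670, 78.57, 4.18, 0.46, 91.40, 25.96, 2.89, "PA"),
    ("A21", 20, 12, 0.154, 0.398, 89.12, 9.04, 0.65, 98.20, 43.84, 4.95, "PA"),
    ("A22", 20, 12, 0.617, 1.722, 68.86, 1.49, 0.15, 73.84, 8.49, 1.42, "A"),
    ("A23", 20, 2, 1.562, 3.560, 84.74, 1.26, 0.02, 73.48, 5.60, 0.95, "A"),
    ("A24", 20, 2, 0.949, 2.351, 94.51, 3.29, 0.10, 93.20, 12.61, 1.29, "PA"),
    ("A25", 80, 15, 0.850, 1.778, 35.80, 0.82, 0.06, 63.57, 6.53, 1.29, "A"),
    ("A26", 20, 12, 0.700, 1.727, 63.75, 1.26, 0.11, 73.82, 8.46, 1.41, "A"),
]


def example_probability_table() -> pd.DataFrame:
    """The worked-example table, probabilities in percent as reported."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def example_probabilities(row) -> dict:
    """Classifier input (probabilities as fractions) for one table row."""
    return {
        "ATR_ATRL": {
            "adherent": row["p_atrl_adherent"] / 100.0,
            "partial": row["p_atrl_partial"] / 100.0,
            "nonadherent": row["p_atrl_nonadherent"] / 100.0,
        },
        "ATR_MET": {
            "adherent": row["p_met_adherent"] / 100.0,
            "partial": row["p_met_partial"] / 100.0,
            "nonadherent": row["p_met_nonadherent"] / 100.0,
        },
    }
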