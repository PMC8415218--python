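"""Reading and writing the package's file formats.

Subject data: long-format CSV with columns
``subject,event_type,time_h,amount_mg,conc_nmol_l,analyte,c_ini_nmol_l``.
Fitted models: JSON (support points, weights, diagnostics, posteriors).
Scenario grids: long CSV ``subject,dose_mg,fst_h,scenario,conc_norm`` or
NumPy ``.npz``. Attainment reports: one CSV row per patient.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import AttainmentReport, PatientMeasurement
from .npml import (
    FitDiagnostics,
    FitResult,
    NPDistribution,
    SubjectPosterior,
    SubjectRecord,
)
from .pk import ANALYTES, DoseEvent, Observation, PKParams
from .simulate import SCENARIOS, ScenarioGrid, SimSettings

__all__ = [
    "read_subjects",
    "write_subjects",
    "write_fit_result",
    "read_fit_result",
    "write_grid",
    "read_grid",
    "read_patients",
    "write_patients",
    "write_reports",
]

SUBJECT_COLUMNS = [
    "subject", "event_type", "time_h", "amount_mg", "conc_nmol_l",
    "analyte", "c_ini_nmol_l",
]


def write_subjects(subjects, path) -> None:
    rows = []
    for s in subjects:
        for ev in s.events:
            rows.append({"subject": s.id, "event_type": "dose", "time_h": ev.time_h,
                         "amount_mg": ev.amount_mg, "conc_nmol_l": "",
                         "analyte": "", "c_ini_nmol_l": s.c_ini})
        for o in s.observations:
            rows.append({"subject": s.id, "event_type": "obs", "time_h": o.time_h,
                         "amount_mg": "", "conc_nmol_l": o.conc,
                         "analyte": o.analyte, "c_ini_nmol_l": s.c_ini})
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(path, index=False)


def read_subjects(path) -> list:
    df = pd.read_csv(path, dtype={"subject": str})
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    subjects = []
    for sid, grp in df.groupby("subject", sort=False):
        events, observations = [], []
        c_ini = 0.0
        for idx, row in grp.iterrows():
            line_no = idx + 2  # header is line 1
            kind = row["event_type"]
            if not math.isnan(c := _float_or_nan(row["c_ini_nmol_l"])):
                c_ini = c
            try:
                if kind == "dose":
                    events.append(DoseEvent(float(row["time_h"]), float(row["amount_mg"])))
                elif kind == "obs":
                    analyte = row["analyte"]
                    if analyte not in ANALYTES:
                        raise ValueError(
                            f"unknown analyte {analyte!r}; valid labels: {list(ANALYTES)}"
                        )
                    observations.append(
                        Observation(float(row["time_h"]), float(row["conc_nmol_l"]), analyte)
                    )
                else:
                    raise ValueError(f"event_type must be 'dose' or 'obs', got {kind!r}")
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path} line {line_no} (subject {sid}): {exc}") from exc
        if not observations:
            raise ValueError(f"{path}: subject {sid} has no observations")
        subjects.append(
            SubjectRecord(id=str(sid), events=tuple(events),
                          observations=tuple(observations), c_ini=c_ini)
        )
    return subjects


def _float_or_nan(x) -> float:
    try:
        return float(x)
    except (TypeError, ValueError):
        return math.nan


# ---------------------------------------------------------------------------
# fitted models


def write_fit_result(result: FitResult, path) -> None:
    dist = result.distribution
    payload = {
        "support_points": dist.param_array().tolist(),
        "weights": dist.weights.tolist(),
        "f": dist.points[0].f,
        "loglik": result.loglik,
        "n_cycles": result.n_cycles,
        "converged": result.converged,
        "posteriors": {
            sid: {"weights": post.weights.tolist(),
                  "mean": [post.mean.ka, post.mean.ke, post.mean.v]}
            for sid, post in result.posteriors.items()
        },
        "diagnostics": dataclasses.asdict(result.diagnostics)
        if result.diagnostics is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit_result(path) -> FitResult:
    payload = json.loads(Path(path).read_text())
    f = payload["f"]
    dist = NPDistribution(
        points=[PKParams(ka=p[0], ke=p[1], v=p[2], f=f) for p in payload["support_points"]],
        weights=np.array(payload["weights"]),
    )
    posteriors = {
        sid: SubjectPosterior(
            weights=np.array(d["weights"]),
            mean=PKParams(ka=d["mean"][0], ke=d["mean"][1], v=d["mean"][2], f=f),
        )
        for sid, d in payload["posteriors"].items()
    }
    diag = payload.get("diagnostics")
    return FitResult(
        distribution=dist,
        loglik=payload["loglik"],
        n_cycles=payload["n_cycles"],
        converged=payload["converged"],
        posteriors=posteriors,
        diagnostics=FitDiagnostics(**diag) if diag else None,
    )


# ---------------------------------------------------------------------------
# scenario grids


def write_grid(grid: ScenarioGrid, path) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path, values=grid.values, fst_grid_h=grid.fst_grid_h,
            doses_mg=grid.doses_mg, scenarios=np.array(grid.scenarios),
            source_hash=np.array(grid.source_hash),
        )
        return
    n, n_fst, n_scen = grid.values.shape
    subj = np.repeat(np.arange(n), n_fst * n_scen)
    dose = np.repeat(grid.doses_mg, n_fst * n_scen)
    fst = np.tile(np.repeat(grid.fst_grid_h, n_scen), n)
    scen = np.tile(np.array(grid.scenarios), n * n_fst)
    pd.DataFrame(
        {"subject": subj, "dose_mg": dose, "fst_h": fst, "scenario": scen,
         "conc_norm": grid.values.reshape(-1)}
    ).to_csv(path, index=False)


def read_grid(grid_path) -> ScenarioGrid:
    path = Path(grid_path)
    if path.suffix == ".npz":
        data = np.load(path, allow_pickle=False)
        values = data["values"]
        fst = data["fst_grid_h"]
        doses = data["doses_mg"]
        scenarios = tuple(str(s) for s in data["scenarios"])
        source_hash = str(data["source_hash"])
    else:
        df = pd.read_csv(path)
        fst = np.array(sorted(df["fst_h"].unique()), dtype=float)
        scenarios = tuple(s for s in SCENARIOS if s in set(df["scenario"]))
        n = df["subject"].nunique()
        df = df.sort_values(["subject", "fst_h"])
        df["scenario"] = pd.Categorical(df["scenario"], categories=scenarios, ordered=True)
        df = df.sort_values(["subject", "fst_h", "scenario"])
        values = df["conc_norm"].to_numpy().reshape(n, fst.size, len(scenarios))
        doses = df.groupby("subject", sort=True)["dose_mg"].first().to_numpy()
        source_hash = ""
    settings = SimSettings(
        n_per_dose=max(1, values.shape[0] // max(1, np.unique(doses).size)),
        doses_mg=tuple(np.unique(doses)),
        fst_grid_h=tuple(fst),
    )
    return ScenarioGrid(values=values, fst_grid_h=fst, scenarios=scenarios,
                        doses_mg=doses, settings=settings, source_hash=source_hash)


# ---------------------------------------------------------------------------
# patients and reports


def write_patients(patients, path) -> None:
    rows = []
    for p in patients:
        rows.append({
            "id": p.id, "dose_mg": p.dose_mg, "time_h": p.time_since_dose_h,
            "conc_atr_atrl": p.conc.get("ATR_ATRL", ""),
            "conc_atr_met": p.conc.get("ATR_MET", ""),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_patients(path) -> list:
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "dose_mg", "time_h"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    patients = []
    for idx, row in df.iterrows():
        conc = {}
        if "conc_atr_atrl" in df.columns and not math.isnan(_float_or_nan(row["conc_atr_atrl"])):
            conc["ATR_ATRL"] = float(row["conc_atr_atrl"])
        if "conc_atr_met" in df.columns and not math.isnan(_float_or_nan(row["conc_atr_met"])):
            conc["ATR_MET"] = float(row["conc_atr_met"])
        if not conc:
            raise ValueError(f"{path} line {idx + 2}: patient {row['id']} has no concentrations")
        patients.append(
            PatientMeasurement(id=str(row["id"]), dose_mg=float(row["dose_mg"]),
                               time_since_dose_h=float(row["time_h"]), conc=conc)
        )
    return patients


def write_reports(reports, path) -> None:
    rows = []
    for r in reports:
        row = {"id": r.id, "call": r.call}
        for analyte in ANALYTES:
            probs = r.probabilities.get(analyte, {})
            short = "atrl" if analyte == "ATR_ATRL" else "met"
            for scen in SCENARIOS:
                row[f"p_{short}_{scen}"] = probs.get(scen, math.nan)
        row["narrative"] = " | ".join(r.narrative)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
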