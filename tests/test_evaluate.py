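"""ROC construction, trapezoid AUC, attainment probabilities and the
categorical adherence call."""

import numpy as np
import pytest

import pkadherence as pa
from pkadherence.evaluate import ROCResult
from pkadherence.examples import example_probabilities, example_probability_table

from conftest import toy_grid


class TestROC:
    def test_cutoff_above_everything(self):
        grid = toy_grid(adherent=[0.5, 0.7], partial=[0.1, 0.3])
        roc = pa.roc_curve(grid, 12, "full_vs_partial", cutoff_hi=2.0)
        assert roc.tpr[-1] == 1.0 and roc.fpr[-1] == 1.0

    def test_cutoff_below_everything(self):
        grid = toy_grid(adherent=[0.5, 0.7], partial=[0.1, 0.3])
        roc = pa.roc_curve(grid, 12, "full_vs_partial")
        assert roc.tpr[0] == 0.0 and roc.fpr[0] == 0.0

    def test_hand_counted_rates(self):
        grid = toy_grid(adherent=[0.5, 0.7], partial=[0.1, 0.3])
        roc = pa.roc_curve(grid, 12, "full_vs_partial", cutoff_hi=2.0)
        i = int(np.argmin(np.abs(roc.cutoffs - 0.4)))
        assert roc.tpr[i] == 1.0 and roc.fpr[i] == 0.0

    def test_monotone_in_cutoff(self, truth_grid):
        roc = pa.roc_curve(truth_grid, 6, "full_vs_partial")
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert 0.0 <= roc.auc <= 1.0

    def test_partial_vs_non_group_selection(self):
        grid = toy_grid(adherent=[9.0, 9.0], partial=[0.5, 0.7], nonadherent=[0.001, 0.0015])
        roc = pa.roc_curve(grid, 12, "partial_vs_non")
        assert roc.auc == pytest.approx(1.0)

    def test_unknown_comparison_rejected(self, truth_grid):
        with pytest.raises(ValueError):
            pa.roc_curve(truth_grid, 6, "adherent_vs_absent")


class TestAUC:
    def test_separated_groups_give_auc_one(self):
        grid = toy_grid(adherent=[5.0, 6.0, 7.0], partial=[0.1, 0.2, 0.3])
        roc = pa.roc_curve(grid, 12, "full_vs_partial")
        assert roc.auc == pytest.approx(1.0)

    def test_identical_groups_give_half(self):
        vals = [0.5, 1.0, 1.5, 2.0]
        grid = toy_grid(adherent=vals, partial=vals)
        roc = pa.roc_curve(grid, 12, "full_vs_partial")
        assert roc.auc == pytest.approx(0.5, abs=1e-9)

    def test_matches_hand_trapezoid_on_three_point_curve(self):
        roc = ROCResult(
            cutoffs=np.array([1.0, 2.0, 3.0]),
            tpr=np.array([0.2, 0.8, 1.0]),
            fpr=np.array([0.0, 0.5, 1.0]),
            auc=np.nan, opt_cutoff=np.nan, sens_at_opt=np.nan, spec_at_opt=np.nan,
            comparison="full_vs_partial", fst_h=1.0,
        )
        # segments: (0,0)-(0,.2): 0 ; (0,.2)-(.5,.8): .25 ; (.5,.8)-(1,1): .45
        assert pa.auc(roc) == pytest.approx(0.70)

    def test_invariant_under_monotone_transform(self, truth_grid):
        roc1 = pa.roc_curve(truth_grid, 6, "full_vs_partial")
        transformed = toy_grid(
            adherent=np.sqrt(truth_grid.group(6, "adherent")),
            partial=np.sqrt(truth_grid.group(6, "partial")),
        )
        roc2 = pa.roc_curve(transformed, 12, "full_vs_partial", cutoff_hi=5.0, step=0.0005)
        assert roc2.auc == pytest.approx(roc1.auc, abs=0.01)


class TestOptimalCutoff:
    def test_gap_tie_broken_to_smallest_cutoff(self):
        grid = toy_grid(adherent=[5.0, 6.0], partial=[0.1, 0.2])
        roc = pa.roc_curve(grid, 12, "full_vs_partial")
        # every cutoff in (0.2, 5.0] gives sens = spec = 1; smallest returned
        assert roc.sens_at_opt == 1.0 and roc.spec_at_opt == 1.0
        assert roc.opt_cutoff == pytest.approx(0.202)

    def test_identical_groups_minimizer_near_median(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(0.0, 0.5, size=4000)
        grid = toy_grid(adherent=vals, partial=vals)
        roc = pa.roc_curve(grid, 12, "full_vs_partial")
        assert roc.opt_cutoff == pytest.approx(np.median(vals), rel=0.05)


class TestAttainment:
    def test_everyone_attains_zero(self, truth_grid):
        m = pa.PatientMeasurement(id="z", dose_mg=20, time_since_dose_h=6,
                                  conc={"ATR_ATRL": 0.0})
        for scen in ("adherent", "partial", "nonadherent"):
            assert pa.attainment(truth_grid, m, "ATR_ATRL", scen) == 1.0

    def test_above_simulated_maximum(self, truth_grid):
        m = pa.PatientMeasurement(id="x", dose_mg=20, time_since_dose_h=6,
                                  conc={"ATR_ATRL": 1e9})
        assert pa.attainment(truth_grid, m, "ATR_ATRL", "adherent") == 0.0

    def test_hand_counted_probability(self):
        grid = toy_grid(adherent=[0.1, 0.2, 0.3, 0.4])
        m = pa.PatientMeasurement(id="h", dose_mg=20, time_since_dose_h=12,
                                  conc={"ATR_ATRL": 20 * 0.25})
        assert pa.attainment(grid, m, "ATR_ATRL", "adherent") == 0.5

    def test_tie_counts_as_attained(self):
        grid = toy_grid(adherent=[0.1, 0.2, 0.3, 0.4])
        m = pa.PatientMeasurement(id="t", dose_mg=20, time_since_dose_h=12,
                                  conc={"ATR_ATRL": 20 * 0.2})
        assert pa.attainment(grid, m, "ATR_ATRL", "adherent") == 0.75

    def test_non_increasing_in_measured_concentration(self, truth_grid):
        probs = [
            pa.attainment(
                truth_grid,
                pa.PatientMeasurement(id="m", dose_mg=20, time_since_dose_h=8,
                                      conc={"ATR_ATRL": c}),
                "ATR_ATRL", "adherent",
            )
            for c in np.linspace(0.0, 100.0, 25)
        ]
        assert np.all(np.diff(probs) <= 1e-12)

    def test_time_outside_grid_advises_resimulation(self, truth_grid):
        m = pa.PatientMeasurement(id="late", dose_mg=20, time_since_dose_h=40,
                                  conc={"ATR_ATRL": 1.0})
        with pytest.raises(ValueError, match="re-simulate"):
            pa.attainment(truth_grid, m, "ATR_ATRL", "adherent")


class TestClassify:
    @pytest.mark.parametrize(
        "row_id, expected",
        [("A1", "PA"), ("A2", "A"), ("A5", "PA")],
    )
    def test_published_worked_examples(self, row_id, expected):
        tab = example_probability_table()
        row = tab[tab.id == row_id].iloc[0]
        call, narrative = pa.classify(example_probabilities(row))
        assert call == expected
        assert any("ATR+ATRL" in line for line in narrative)

    def test_all_printed_rows_reproduced(self):
        tab = example_probability_table()
        calls = [pa.classify(example_probabilities(r))[0] for _, r in tab.iterrows()]
        assert calls == list(tab.reported_call)
        assert calls.count("PA") == 10
        assert calls.count("A") == 16
        assert calls.count("NA") == 0

    def test_nonadherent_call_when_even_partial_attains(self):
        probs = {"ATR_MET": {"adherent": 0.99, "partial": 0.95, "nonadherent": 0.40}}
        call, _ = pa.classify(probs)
        assert call == "NA"

    def test_missing_met_falls_back_to_atrl_with_warning(self):
        probs = {"ATR_ATRL": {"adherent": 0.20, "partial": 0.01, "nonadherent": 0.0}}
        with pytest.warns(UserWarning, match="ATR\\+MET"):
            call, _ = pa.classify(probs)
        assert call == "A"

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pa.classify({"ATR_MET": {"adherent": 1.2, "partial": 0.1, "nonadherent": 0.0}})


def test_evaluate_patient_end_to_end(truth_grid):
    grids = {"ATR_ATRL": truth_grid, "ATR_MET": truth_grid}
    m = pa.PatientMeasurement(id="p", dose_mg=20, time_since_dose_h=12,
                              conc={"ATR_ATRL": 6.0, "ATR_MET": 6.0})
    report = pa.evaluate_patient(grids, m)
    assert report.call in {"A", "PA", "NA"}
    assert set(report.probabilities) == {"ATR_ATRL", "ATR_MET"}
    for probs in report.probabilities.values():
        assert all(0.0 <= p <= 1.0 for p in probs.values())
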