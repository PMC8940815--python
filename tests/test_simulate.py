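"""Synthetic-data tests: rich profiles, population variability, dataset IO."""

import numpy as np
import pandas as pd
import pytest

from pulmodeconv.models import ConfigurationError, ParameterSet, Route, VariantName
from pulmodeconv.models import AbsorptionVariant
from pulmodeconv.simulate import (
    Occasion,
    PKDataset,
    StudyArm,
    TrialDesign,
    VariabilityModel,
    read_dataset,
    simulate_rich,
    simulate_trial,
    single_dose_occasion,
    write_dataset,
)


class TestRichSimulation:
    def test_default_grid_has_4801_points(self, model_i):
        variant, params = model_i
        prof = simulate_rich(variant, params, 100.0)
        assert len(prof.times) == 4801
        assert prof.times[-1] == pytest.approx(48.0)

    def test_deterministic(self, model_ii):
        variant, params = model_ii
        a = simulate_rich(variant, params, 100.0)
        b = simulate_rich(variant, params, 100.0)
        np.testing.assert_array_equal(a.c_plasma, b.c_plasma)
        np.testing.assert_array_equal(a.c_lung, b.c_lung)

    def test_initial_lung_concentration(self, model_ii):
        variant, params = model_ii
        prof = simulate_rich(variant, params, 100.0)
        assert prof.c_lung[0] == pytest.approx(params.f_pul * 100.0 / params.v_lung)
        assert prof.c_plasma[0] == pytest.approx(0.0, abs=1e-12)

    def test_dt_must_divide_horizon(self, model_i):
        variant, params = model_i
        with pytest.raises(ConfigurationError, match="divide"):
            simulate_rich(variant, params, 100.0, horizon_h=48.0, dt_h=0.07)


class TestTrialSimulation:
    def test_zero_variability_gives_population_prediction(self, model_i):
        variant, params = model_i
        design = TrialDesign(
            arms=(StudyArm(Route.INHALED, 4, (single_dose_occasion(100.0),)),)
        )
        ds, truth = simulate_trial(variant, params, design, VariabilityModel.none(), seed=0)
        obs = ds.observations()
        profiles = obs.groupby("ID")["DV"].apply(np.array)
        for sid in profiles.index[1:]:
            np.testing.assert_array_equal(profiles[sid], profiles[profiles.index[0]])

    def test_iiv_standard_deviation_recovered(self, model_i):
        """Law of large numbers: the sample SD of log individual CL over
        10,000 subjects approaches omega = 0.3 within 0.01."""
        variant, params = model_i
        design = TrialDesign(
            arms=(StudyArm(Route.INHALED, 10_000,
                           (Occasion(((0.0, 100.0),), (1.0,)),)),)
        )
        var = VariabilityModel(iiv={"cl": 0.3})
        _, truth = simulate_trial(variant, params, design, var, seed=42)
        sd = np.std(np.log(truth["cl"].to_numpy()))
        assert sd == pytest.approx(0.3, abs=0.01)

    def test_residual_cv_converges_to_sigma(self, model_i):
        variant, params = model_i
        design = TrialDesign(
            arms=(StudyArm(Route.INHALED, 4000,
                           (Occasion(((0.0, 100.0),), (2.0, 8.0)),)),)
        )
        var = VariabilityModel(residual_proportional_sd=0.2)
        ds, _ = simulate_trial(variant, params, design, var, seed=7)
        from pulmodeconv.models import solve_profiles

        pred = solve_profiles(variant, params, 100.0, Route.INHALED, [2.0, 8.0]).c_plasma
        obs = ds.observations()
        eps = np.concatenate([
            obs[obs["TIME"] == 2.0]["DV"].to_numpy() / pred[0] - 1.0,
            obs[obs["TIME"] == 8.0]["DV"].to_numpy() / pred[1] - 1.0,
        ])
        assert np.std(eps) == pytest.approx(0.2, abs=0.015)

    def test_truncation_keeps_observations_positive(self, model_i):
        variant, params = model_i
        design = TrialDesign(
            arms=(StudyArm(Route.INHALED, 50, (single_dose_occasion(100.0),)),)
        )
        var = VariabilityModel(residual_proportional_sd=0.8)
        ds, _ = simulate_trial(variant, params, design, var, seed=3)
        assert (ds.observations()["DV"] > 0).all()

    def test_crossover_shares_subjects_and_effects(self, model_ii, small_crossover_design):
        variant, params = model_ii
        var = VariabilityModel(iiv={"cl": 0.3}, residual_proportional_sd=0.0)
        ds, truth = simulate_trial(variant, params, small_crossover_design, var, seed=5)
        assert ds.subject_ids("iv") == ds.subject_ids("inhaled")
        # same individual CL in both arms
        per_route = truth.pivot_table(index="ID", columns="ROUTE", values="cl")
        np.testing.assert_allclose(per_route["iv"], per_route["inhaled"])

    def test_parallel_design_has_disjoint_ids(self, model_ii):
        variant, params = model_ii
        design = TrialDesign(
            arms=(
                StudyArm(Route.IV, 5, (single_dose_occasion(50.0),)),
                StudyArm(Route.INHALED, 7, (single_dose_occasion(100.0),)),
            ),
            crossover=False,
        )
        ds, _ = simulate_trial(variant, params, design, VariabilityModel.none(), seed=1)
        assert not set(ds.subject_ids("iv")) & set(ds.subject_ids("inhaled"))

    def test_seeded_reproducibility(self, model_ii, small_crossover_design, mild_variability):
        variant, params = model_ii
        a, _ = simulate_trial(variant, params, small_crossover_design, mild_variability, seed=9)
        b, _ = simulate_trial(variant, params, small_crossover_design, mild_variability, seed=9)
        assert a == b
        c, _ = simulate_trial(variant, params, small_crossover_design, mild_variability, seed=10)
        assert not (a == c)

    def test_iov_varies_between_occasions(self, model_i):
        variant, params = model_i
        occ = Occasion(((0.0, 100.0),), (1.0, 4.0))
        design = TrialDesign(
            arms=(StudyArm(Route.INHALED, 30, (occ, occ)),)
        )
        var = VariabilityModel(iov={"f_pul": 0.3})
        _, truth = simulate_trial(variant, params, design, var, seed=11)
        per_occ = truth.pivot_table(index="ID", columns="OCC", values="f_pul")
        assert np.std(np.log(per_occ[1]) - np.log(per_occ[2])) > 0.1

    def test_at_most_four_random_effect_terms(self):
        with pytest.raises(ConfigurationError, match="at most 4"):
            VariabilityModel(iiv={"cl": 0.1, "v1": 0.1, "q2": 0.1},
                             iov={"f_pul": 0.1, "k_fast": 0.1})


class TestDatasetIO:
    def _dataset(self, model_ii, variability=None):
        variant, params = model_ii
        design = TrialDesign(
            arms=(
                StudyArm(Route.IV, 3, (single_dose_occasion(50.0),)),
                StudyArm(Route.INHALED, 3, (single_dose_occasion(100.0),)),
            ),
            crossover=True,
        )
        ds, _ = simulate_trial(
            variant, params, design,
            variability or VariabilityModel(residual_proportional_sd=0.1), seed=2,
        )
        return ds

    def test_round_trip(self, tmp_path, model_ii):
        ds = self._dataset(model_ii)
        path = tmp_path / "study.csv"
        write_dataset(ds, path)
        assert read_dataset(path) == ds

    def test_dose_rows_use_dot_for_dv(self, tmp_path, model_ii):
        ds = self._dataset(model_ii)
        path = tmp_path / "study.csv"
        write_dataset(ds, path)
        raw = pd.read_csv(path, dtype=str)
        dose_rows = raw[raw["EVID"] == "1"]
        assert (dose_rows["DV"] == ".").all()
        assert (dose_rows["AMT"] != ".").all()

    def test_malformed_value_reports_line(self, tmp_path, model_ii):
        ds = self._dataset(model_ii)
        path = tmp_path / "study.csv"
        write_dataset(ds, path)
        lines = path.read_text().splitlines()
        lines[3] = lines[3].replace(lines[3].split(",")[1], "oops", 1)
        bad = tmp_path / "bad.csv"
        bad.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="line 4"):
            read_dataset(bad)

    def test_non_monotone_time_rejected(self, tmp_path, model_ii):
        ds = self._dataset(model_ii)
        frame = ds.frame.copy()
        obs_idx = frame[frame["EVID"] == 0].index
        frame.loc[obs_idx[1], "TIME"] = frame.loc[obs_idx[0], "TIME"] - 0.05
        path = tmp_path / "swapped.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="monotone"):
            read_dataset(path)

    def test_nonpositive_observation_rejected(self):
        frame = pd.DataFrame(
            {
                "ID": [1, 1], "TIME": [0.0, 1.0], "AMT": [100.0, np.nan],
                "DV": [np.nan, 0.0], "EVID": [1, 0], "CMT": [1, 2],
                "OCC": [1, 1], "ROUTE": ["inhaled", "inhaled"],
            }
        )
        with pytest.raises(ValueError, match="positive"):
            PKDataset(frame)
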