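import logging

import numpy as np
import pandas as pd
import pytest

import lesionatoms as la


def normal_equations_residuals(values, vol):
    """Closed-form OLS residual oracle on [1, log1p(vol)]."""
    x = np.column_stack([np.ones_like(vol), np.log1p(vol)])
    beta = np.linalg.solve(x.T @ x, x.T @ values)
    return values - x @ beta


class TestResidualizeVolume:
    def test_exact_multiple_vanishes(self):
        vol = np.linspace(0, 50, 60)
        values = 2.0 * np.log1p(vol)
        resid = la.residualize_volume(values, vol)
        assert np.max(np.abs(resid)) < 1e-10

    def test_orthogonal_input_unchanged(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(0, 40, 100)
        raw = rng.normal(size=100)
        clean = normal_equations_residuals(raw, vol)  # orthogonal, mean 0
        resid = la.residualize_volume(clean, vol)
        assert np.allclose(resid, clean, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        vol = rng.uniform(0, 80, 150)
        values = rng.normal(size=(150, 4))
        resid = la.residualize_volume(values, vol)
        oracle = normal_equations_residuals(values, vol)
        assert np.allclose(resid, oracle, atol=1e-10)
        x = np.log1p(vol)
        for j in range(4):
            assert abs(np.corrcoef(resid[:, j], x)[0, 1]) < 1e-10
            assert abs(resid[:, j].mean()) < 1e-10

    def test_constant_volume_centers_with_warning(self, caplog):
        values = np.array([1.0, 2.0, 3.0])
        with caplog.at_level(logging.WARNING):
            resid = la.residualize_volume(values, np.full(3, 5.0))
        assert np.allclose(resid, values - 2.0)
        assert any("constant" in r.message for r in caplog.records)


class TestBuildModelInput:
    def test_matches_scripted_oracle(self, default_cohort):
        """Each output column equals an independently scripted transform
        of the cohort table."""
        _, cohort, loads, truth = default_cohort
        scores = truth.scores_true
        inp = la.build_model_input(cohort, scores)

        age = cohort["age"].to_numpy()
        age_z = (age - age.mean()) / age.std()
        assert np.allclose(inp.age_z, age_z)
        assert np.allclose(inp.age_z_sq, age_z ** 2)
        assert np.allclose(inp.log_wmhv,
                           np.log1p(cohort["wmh_volume_ml"].to_numpy()))
        assert np.array_equal(inp.sex, cohort["sex"].to_numpy())

        vol = cohort["lesion_volume_ml"].to_numpy()
        resid_y = normal_equations_oracle_outcome(cohort, vol)
        assert np.allclose(inp.outcome, resid_y, atol=1e-8)
        # scores residualized then unit-variance
        x = np.column_stack([np.ones_like(vol), np.log1p(vol)])
        beta = np.linalg.lstsq(x, scores, rcond=None)[0]
        rs = scores - x @ beta
        rs = rs / rs.std(axis=0)
        assert np.allclose(inp.atom_scores, rs, atol=1e-8)
        assert np.allclose(inp.atom_scores.std(axis=0), 1.0)

    def test_residuals_uncorrelated_with_volume(self, default_cohort):
        _, cohort, _, truth = default_cohort
        inp = la.build_model_input(cohort, truth.scores_true)
        x = np.log1p(cohort["lesion_volume_ml"].to_numpy())
        assert abs(np.corrcoef(inp.outcome, x)[0, 1]) < 1e-10
        for k in range(inp.n_atoms):
            assert abs(np.corrcoef(inp.atom_scores[:, k], x)[0, 1]) < 1e-9

    def test_missing_values_listed(self, default_cohort):
        _, cohort, _, truth = default_cohort
        bad = cohort.copy()
        bad.loc[3, "nihss"] = np.nan
        bad.loc[17, "age"] = np.nan
        with pytest.raises(ValueError) as err:
            la.build_model_input(bad, truth.scores_true)
        assert "sub-0003" in str(err.value) and "sub-0017" in str(err.value)

    def test_wmhv_zero_maps_to_zero(self):
        cohort = pd.DataFrame({
            "sex": [0, 1, 0, 1], "age": [60.0, 70, 65, 55],
            "nihss": [2.0, 5, 3, 4], "lesion_volume_ml": [1.0, 2, 3, 4],
            "wmh_volume_ml": [0.0, 0, 0, 0],
            "hypertension": 0, "diabetes": 0, "atrial_fibrillation": 0,
            "coronary_artery_disease": 0})
        inp = la.build_model_input(cohort, np.ones((4, 2)))
        assert np.all(inp.log_wmhv == 0)

    def test_constant_age_warns(self, caplog):
        cohort = pd.DataFrame({
            "sex": [0, 1, 0, 1], "age": [60.0] * 4,
            "nihss": [2.0, 5, 3, 4], "lesion_volume_ml": [1.0, 2, 3, 4],
            "wmh_volume_ml": [1.0] * 4,
            "hypertension": 0, "diabetes": 0, "atrial_fibrillation": 0,
            "coronary_artery_disease": 0})
        with caplog.at_level(logging.WARNING):
            inp = la.build_model_input(cohort, np.ones((4, 2)))
        assert np.all(inp.age_z == 0)
        assert any("age" in r.message for r in caplog.records)


class TestDesignTransform:
    def test_reapplying_own_transform_is_identity(self, default_cohort):
        _, cohort, _, truth = default_cohort
        inp, transform = la.build_model_input(cohort, truth.scores_true,
                                              return_transform=True)
        again = la.apply_design_transform(cohort, truth.scores_true,
                                          transform)
        assert np.allclose(again.outcome, inp.outcome)
        assert np.allclose(again.atom_scores, inp.atom_scores)
        assert np.allclose(again.age_z, inp.age_z)

    def test_json_round_trip(self, default_cohort, tmp_path):
        _, cohort, _, truth = default_cohort
        _, transform = la.build_model_input(cohort, truth.scores_true,
                                            return_transform=True)
        path = tmp_path / "transform.json"
        transform.to_json(path)
        back = la.DesignTransform.from_json(path)
        assert back == transform

    def test_cross_cohort_application_uses_stored_parameters(self):
        """A validation cohort processed with the derivation transform is
        scaled by the derivation statistics, not its own."""
        cfg_a = la.SimConfig(n_patients=200, seed=61, basis_seed=5)
        cfg_b = la.SimConfig(n_patients=200, seed=62, basis_seed=5)
        cohort_a, _, truth_a = la.generate_cohort(cfg_a)
        cohort_b, _, truth_b = la.generate_cohort(cfg_b)
        _, transform = la.build_model_input(cohort_a, truth_a.scores_true,
                                            return_transform=True)
        applied = la.apply_design_transform(cohort_b, truth_b.scores_true,
                                            transform)
        age_b = cohort_b["age"].to_numpy()
        expected = (age_b - transform.age_mean) / transform.age_sd
        assert np.allclose(applied.age_z, expected)
        refit = la.build_model_input(cohort_b, truth_b.scores_true)
        assert not np.allclose(applied.age_z, refit.age_z)


def normal_equations_oracle_outcome(cohort, vol):
    y = cohort["nihss"].to_numpy()
    x = np.column_stack([np.ones_like(vol), np.log1p(vol)])
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    return y - x @ beta
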