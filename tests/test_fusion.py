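import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import surveyfuse as sf
from surveyfuse.fusion import FusionError

from conftest import make_gaussian_surveys


def tiny_survey_pair(n_A=1000, n_B=3000, seed=0):
    """Minimal A/B pair with one shared covariate x, outcome y, exposure z."""
    rng = np.random.default_rng(seed)
    cb = sf.Codebook(
        variables={
            "x": sf.VariableDef("x", "demographic"),
            "y": sf.VariableDef("y", "outcome"),
            "z": sf.VariableDef("z", "exposure_score"),
        }
    )
    xa, xb = rng.standard_normal(n_A), rng.standard_normal(n_B)
    A = sf.SurveyFrame(
        pd.DataFrame({"x": xa, "y": 1 + 2 * xa + rng.standard_normal(n_A)}),
        cb.subset(["x", "y"]), name="A",
    )
    B = sf.SurveyFrame(
        pd.DataFrame({"x": xb, "z": -1 + xb + rng.standard_normal(n_B)}),
        cb.subset(["x", "z"]), name="B",
    )
    return A, B


class TestConcatenate:
    def test_equal_share_weights(self):
        A, B = tiny_survey_pair(1000, 3000)
        stacked = sf.concatenate_with_weights(A, B, "y", "z", ["x"])
        w = stacked.weights
        assert np.allclose(w[stacked.is_A], 2.0)
        assert np.allclose(w[~stacked.is_A], 2.0 / 3.0)
        assert np.isclose(w[stacked.is_A].sum(), 2000)
        assert np.isclose(w[~stacked.is_A].sum(), 2000)

    def test_equal_sizes_give_unit_weights(self):
        A, B = tiny_survey_pair(500, 500)
        stacked = sf.concatenate_with_weights(A, B, "y", "z", ["x"])
        assert np.allclose(stacked.weights, 1.0)

    def test_proportional_scheme_unit_weights(self):
        A, B = tiny_survey_pair(200, 800)
        stacked = sf.concatenate_with_weights(A, B, "y", "z", ["x"], scheme="proportional")
        assert np.allclose(stacked.weights, 1.0)

    def test_missing_blocks_exactly_complementary(self):
        A, B = tiny_survey_pair(100, 100)
        stacked = sf.concatenate_with_weights(A, B, "y", "z", ["x"])
        assert np.isnan(stacked.z[stacked.is_A]).all()
        assert not np.isnan(stacked.z[~stacked.is_A]).any()
        assert np.isnan(stacked.y[~stacked.is_A]).all()
        assert not np.isnan(stacked.y[stacked.is_A]).any()

    def test_codebook_mismatch_rejected(self):
        A, B = tiny_survey_pair(50, 50)
        B2 = sf.SurveyFrame(
            B.data.rename(columns={"x": "w"}),
            sf.Codebook(variables={
                "w": sf.VariableDef("w", "demographic"),
                "z": sf.VariableDef("z", "exposure_score"),
            }),
            name="B",
        )
        with pytest.raises(sf.CodebookError, match="x"):
            sf.concatenate_with_weights(A, B2, "y", "z", ["x"])


class TestConditionalModels:
    def test_noiseless_line_exact(self):
        cb = sf.Codebook(variables={
            "x": sf.VariableDef("x", "demographic"),
            "y": sf.VariableDef("y", "outcome"),
            "z": sf.VariableDef("z", "exposure_score"),
        })
        x = np.array([0.0, 1.0, 2.0])
        A = sf.SurveyFrame(pd.DataFrame({"x": x, "y": 1 + 2 * x}), cb.subset(["x", "y"]))
        B = sf.SurveyFrame(pd.DataFrame({"x": x, "z": 5 - x}), cb.subset(["x", "z"]))
        stacked = sf.concatenate_with_weights(A, B, "y", "z", ["x"])
        models = sf.fit_conditional_models(stacked)
        np.testing.assert_allclose(models.beta_y, [1.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(models.beta_z, [5.0, -1.0], atol=1e-12)
        assert models.sigma_y == pytest.approx(0.0, abs=1e-10)

    def test_wls_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(10)
        A, B = tiny_survey_pair(50, 60, seed=10)
        stacked = sf.concatenate_with_weights(A, B, "y", "z", ["x"])
        models = sf.fit_conditional_models(stacked)
        isA = stacked.is_A
        X, w, y = stacked.X[isA], stacked.weights[isA], stacked.y[isA]
        oracle = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        np.testing.assert_allclose(models.beta_y, oracle, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        A, B = tiny_survey_pair(50, 50)
        A.data["x2"] = A.data["x"] * 2
        B.data["x2"] = B.data["x"] * 2
        A.codebook.variables["x2"] = sf.VariableDef("x2", "demographic")
        B.codebook.variables["x2"] = sf.VariableDef("x2", "demographic")
        stacked = sf.concatenate_with_weights(A, B, "y", "z", ["x", "x2"])
        with pytest.raises(FusionError, match="collinear"):
            sf.fit_conditional_models(stacked)


def manual_models(beta_y, sigma_y, beta_z, sigma_z):
    return sf.ConditionalModels(
        beta_y=np.asarray(beta_y, float), sigma_y=sigma_y,
        beta_z=np.asarray(beta_z, float), sigma_z=sigma_z,
    )


def manual_stacked(x, y, z, origin):
    df = pd.DataFrame({
        "x": x, "y": y, "z": z, "origin": origin,
        "fusion_weight": np.ones(len(x)),
    })
    cb = sf.Codebook(variables={
        "x": sf.VariableDef("x", "demographic"),
        "y": sf.VariableDef("y", "outcome"),
    })
    X = np.column_stack([np.ones(len(x)), np.asarray(x, float)])
    return sf.StackedFile(data=df, X=X, x_names=["const", "x"], y_col="y",
                          z_col="z", codebook=cb)


class TestPredictJoint:
    def test_conditional_mean_hand_example(self):
        # beta_Y=beta_Z=(0,1), sigma_Y=2, sigma_Z=1, row (x=2, y=6), rho=0.5
        # -> Zhat = 2 + 0.5*(1/2)*(6-2) = 3.0
        stacked = manual_stacked([2.0], [6.0], [np.nan], ["A"])
        models = manual_models([0, 1], 2.0, [0, 1], 1.0)
        zhat, _ = sf.predict_joint(stacked, models, 0.5)
        assert zhat[0] == pytest.approx(3.0)

    def test_rho_zero_reduces_to_marginal_regression(self):
        stacked = manual_stacked([2.0, -1.0], [6.0, 0.0], [np.nan, np.nan], ["A", "A"])
        models = manual_models([0, 1], 2.0, [1, 3], 1.5)
        zhat, _ = sf.predict_joint(stacked, models, 0.0)
        np.testing.assert_allclose(zhat, stacked.X @ models.beta_z)

    def test_near_perfect_rho_transfers_residual(self):
        stacked = manual_stacked([2.0], [6.0], [np.nan], ["A"])
        models = manual_models([0, 1], 1.3, [0, 1], 1.3)
        rho = 1 - 1e-12
        zhat, _ = sf.predict_joint(stacked, models, rho)
        y_resid = 6.0 - 2.0
        assert zhat[0] - 2.0 == pytest.approx(y_resid, abs=1e-9)

    def test_b_side_z_prediction_is_marginal(self):
        stacked = manual_stacked([1.0, 1.0], [4.0, np.nan], [np.nan, 9.0], ["A", "B"])
        models = manual_models([0, 1], 1.0, [0, 2], 1.0)
        zhat, yhat = sf.predict_joint(stacked, models, 0.7)
        assert zhat[1] == pytest.approx(2.0)  # x'beta_Z only on B rows
        # B row Yhat conditions on observed z
        assert yhat[1] == pytest.approx(1.0 + 0.7 * (9.0 - 2.0))

    def test_zero_sigma_with_nonzero_rho_signalled(self):
        stacked = manual_stacked([1.0], [2.0], [np.nan], ["A"])
        models = manual_models([0, 1], 0.0, [0, 1], 1.0)
        with pytest.raises(FusionError, match="rho"):
            sf.predict_joint(stacked, models, 0.5)

    def test_invalid_rho_rejected(self):
        stacked = manual_stacked([1.0], [2.0], [np.nan], ["A"])
        models = manual_models([0, 1], 1.0, [0, 1], 1.0)
        with pytest.raises(FusionError):
            sf.predict_joint(stacked, models, 1.5)


class TestMatching:
    def test_hand_example(self):
        # A predicted [1.1, 3.9]; B predicted [1.0, 2.0, 4.0], observed Z [10, 20, 40]
        idx = sf.nearest_donor(np.array([1.1, 3.9]), np.array([1.0, 2.0, 4.0]))
        observed = np.array([10.0, 20.0, 40.0])
        np.testing.assert_array_equal(observed[idx], [10.0, 40.0])

    def test_single_donor_forced_match(self):
        idx = sf.nearest_donor(np.array([0.0, 5.0, -3.0]), np.array([1.7]))
        np.testing.assert_array_equal(idx, [0, 0, 0])

    def test_empty_donor_pool_rejected(self):
        with pytest.raises(FusionError):
            sf.nearest_donor(np.array([1.0]), np.array([]))

    @given(st.integers(0, 1000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        nr, nd = rng.integers(1, 200, size=2)
        # duplicate-heavy values to exercise the tie rule
        rec = rng.integers(0, 40, size=nr) / 7.0
        don = rng.integers(0, 40, size=nd) / 7.0
        idx = sf.nearest_donor(rec, don)
        brute = np.argmin(np.abs(rec[:, None] - don[None, :]), axis=1)
        np.testing.assert_array_equal(idx, brute)


@pytest.fixture(scope="module")
def fused_run():
    A, B, truth = make_gaussian_surveys(2000, seed=20)
    anchor = truth.true_rho[("provider_comfort", "hiv_testing")]
    grid = sf.rho_grid(anchor)
    fused, models = sf.fuse(A, B, "hiv_testing", "provider_comfort",
                            sf.REGRESSION_COVARIATES_FULL, grid)
    return A, B, fused, models


class TestFuse:

    def test_one_fused_dataset_per_grid_value_with_size_conservation(self, fused_run):
        A, B, fused, _ = fused_run
        assert len(fused) == 5
        for f in fused:
            assert len(f) == len(A) + len(B)
            assert not f.data[f.y_col].isna().any()
            assert not f.data[f.z_col].isna().any()

    def test_hot_deck_values_come_from_observed_donors(self, fused_run):
        A, B, fused, _ = fused_run
        f = fused[0]
        isA = f.data["origin"] == "A"
        imputed_z = set(f.data.loc[isA, f.z_col])
        observed_z = set(B.data["provider_comfort"])
        assert imputed_z <= observed_z
        imputed_y = set(f.data.loc[~isA, f.y_col])
        observed_y = set(A.data["hiv_testing"])
        assert imputed_y <= observed_y

    def test_degenerate_grid_gives_identical_datasets(self):
        A, B, _ = make_gaussian_surveys(300, seed=21)
        grid = sf.RhoGrid(anchor=0.2, values=(0.2,) * 5)
        fused, _ = sf.fuse(A, B, "condoms", "sexual_stigma",
                           sf.REGRESSION_COVARIATES_FULL, grid)
        for f in fused[1:]:
            pd.testing.assert_frame_equal(f.data, fused[0].data)

    def test_deterministic_across_runs(self):
        out = []
        for _ in range(2):
            A, B, truth = make_gaussian_surveys(300, seed=22)
            fused, _ = sf.fuse(A, B, "prep", "community_engagement",
                               sf.REGRESSION_COVARIATES_FULL, sf.rho_grid(0.13))
            out.append(fused[2].data)
        pd.testing.assert_frame_equal(out[0], out[1])

    def test_fused_correlation_monotone_in_rho(self):
        A, B, truth = make_gaussian_surveys(5000, seed=23)
        anchor = truth.true_rho[("provider_comfort", "provider_access")]
        grid = sf.rho_grid(anchor, "absolute")
        fused, _ = sf.fuse(A, B, "provider_access", "provider_comfort",
                           sf.REGRESSION_COVARIATES_FULL, grid)
        corrs = [sf.fused_partial_corr(f, sf.REGRESSION_COVARIATES_FULL) for f in fused]
        diffs = np.diff(corrs)
        assert (diffs > -0.02).all(), corrs

    def test_stochastic_mode_reproducible_and_noisier(self):
        A, B, _ = make_gaussian_surveys(400, seed=24)
        grid = sf.rho_grid(0.2)
        f1, _ = sf.fuse(A, B, "phq4", "sexual_stigma",
                        sf.REGRESSION_COVARIATES_FULL, grid, stochastic=True, seed=9)
        f2, _ = sf.fuse(A, B, "phq4", "sexual_stigma",
                        sf.REGRESSION_COVARIATES_FULL, grid, stochastic=True, seed=9)
        pd.testing.assert_frame_equal(f1[0].data, f2[0].data)
        f3, _ = sf.fuse(A, B, "phq4", "sexual_stigma",
                        sf.REGRESSION_COVARIATES_FULL, grid, stochastic=True, seed=10)
        assert not f3[0].data[f3[0].z_col].equals(f1[0].data[f1[0].z_col])
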