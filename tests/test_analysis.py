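import numpy as np
import pandas as pd
import pytest

import surveyfuse as sf
from surveyfuse.analysis import AnalysisError

from conftest import make_gaussian_surveys


def manual_fused(df, rho=0.1):
    cb = sf.Codebook(variables={
        name: sf.VariableDef(name, "demographic") for name in df.columns
        if name not in ("y", "z", "fusion_weight", "origin")
    })
    cb.variables["y"] = sf.VariableDef("y", "outcome")
    return sf.FusedDataset(data=df, rho=rho, y_col="y", z_col="z", codebook=cb)


def make_estimate(coef, var, exposure="e", outcome="o", covset="full", rho=0.1):
    se = float(np.sqrt(var))
    return sf.CoefficientEstimate(
        exposure=exposure, outcome=outcome, coefficient=coef, se=se,
        ci_low=coef - 1.96 * se, ci_high=coef + 1.96 * se, p_value=0.5,
        covariate_set=covset, rho=rho, n=100,
    )


class TestFitOutcomeModel:
    def test_identity_recovery_zero_noise(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(50)
        df = pd.DataFrame({
            "z": z, "y": z.copy(), "x": rng.standard_normal(50),
            "fusion_weight": np.ones(50), "origin": ["A"] * 50,
        })
        est = sf.fit_outcome_model(manual_fused(df), "y", "z", ["x"])
        assert est.coefficient == pytest.approx(1.0, abs=1e-10)
        assert est.se == pytest.approx(0.0, abs=1e-8)

    def test_three_point_line_slope(self):
        df = pd.DataFrame({
            "z": [0.0, 1.0, 2.0], "y": [1.0, 3.0, 5.0],
            "fusion_weight": [1.0, 1.0, 1.0], "origin": ["A"] * 3,
        })
        est = sf.fit_outcome_model(manual_fused(df), "y", "z", [])
        assert est.coefficient == pytest.approx(2.0, abs=1e-10)

    def test_matches_weighted_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        n = 100
        z = rng.standard_normal(n)
        x = rng.standard_normal(n)
        y = 0.5 * z - x + rng.standard_normal(n)
        w = rng.uniform(0.5, 2.0, n)
        df = pd.DataFrame({"z": z, "x": x, "y": y, "fusion_weight": w,
                           "origin": ["A"] * n})
        est = sf.fit_outcome_model(manual_fused(df), "y", "z", ["x"])
        X = np.column_stack([z, np.ones(n), x])
        oracle = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        assert est.coefficient == pytest.approx(oracle[0], abs=1e-8)
        assert est.ci_low <= est.coefficient <= est.ci_high

    def test_rank_deficiency_rejected(self):
        df = pd.DataFrame({
            "z": [1.0, 2.0, 3.0, 4.0], "x": [1.0, 2.0, 3.0, 4.0],
            "y": [1.0, 2.0, 3.0, 4.0], "fusion_weight": np.ones(4),
            "origin": ["A"] * 4,
        })
        with pytest.raises(AnalysisError, match="rank"):
            sf.fit_outcome_model(manual_fused(df), "y", "z", ["x"])


class TestPoolRubin:
    def test_hand_computed_m3_example(self):
        # coefficients (1.0, 1.2, 1.4), each variance 0.04
        ests = [make_estimate(c, 0.04) for c in (1.0, 1.2, 1.4)]
        pooled = sf.pool_rubin(ests)
        assert pooled.q_bar == pytest.approx(1.2)
        assert pooled.w_bar == pytest.approx(0.04)
        assert pooled.b == pytest.approx(0.04)
        assert pooled.t == pytest.approx(0.04 + (4.0 / 3.0) * 0.04, abs=1e-10)
        assert pooled.t == pytest.approx(0.09333, abs=5e-6)
        # Rubin df = (m-1) * (1 + Wbar / ((1+1/m) B))^2 = 2 * (1 + 0.75)^2
        assert pooled.df == pytest.approx(2 * 1.75**2)

    def test_identical_estimates_degenerate_between_variance(self):
        ests = [make_estimate(0.8, 0.01)] * 5
        pooled = sf.pool_rubin(ests)
        assert pooled.b == 0.0
        assert pooled.t == pytest.approx(pooled.w_bar)
        assert np.isinf(pooled.df)
        # normal-quantile CI
        assert pooled.ci_high - pooled.ci_low == pytest.approx(2 * 1.959964 * 0.1, abs=1e-4)

    def test_scaling_equivariance(self):
        ests = [make_estimate(c, 0.04) for c in (1.0, 1.2, 1.4)]
        scaled = [make_estimate(3 * c, 9 * 0.04) for c in (1.0, 1.2, 1.4)]
        p1, p3 = sf.pool_rubin(ests), sf.pool_rubin(scaled)
        assert p3.q_bar == pytest.approx(3 * p1.q_bar)
        assert p3.t == pytest.approx(9 * p1.t)

    def test_order_invariance(self):
        ests = [make_estimate(c, v) for c, v in [(1.0, 0.04), (1.3, 0.02), (0.9, 0.05)]]
        a = sf.pool_rubin(ests)
        b = sf.pool_rubin(ests[::-1])
        assert (a.q_bar, a.t, a.df) == pytest.approx((b.q_bar, b.t, b.df), rel=1e-12)

    def test_t_at_least_within_variance(self):
        ests = [make_estimate(c, 0.02) for c in (0.5, 0.9, 1.8, -0.3, 0.1)]
        pooled = sf.pool_rubin(ests)
        assert pooled.t >= pooled.w_bar

    def test_mixed_pairs_rejected(self):
        ests = [make_estimate(1.0, 0.1), make_estimate(1.0, 0.1, exposure="other")]
        with pytest.raises(AnalysisError, match="mixed"):
            sf.pool_rubin(ests)


class TestPairAnalysis:
    def test_recovers_positive_effect_with_true_anchor(self):
        A, B, truth = make_gaussian_surveys(3000, seed=30)
        pair = ("provider_comfort", "provider_access")
        pooled = sf.run_pair_analysis(A, B, *pair, truth.true_rho[pair])
        assert pooled.m == 5
        assert pooled.q_bar == pytest.approx(truth.true_beta[pair], rel=0.25)
        assert pooled.q_bar > 0

    def test_sensitivity_unaffected_when_dropped_covariates_irrelevant(self):
        # urbanicity and region carry no signal for this pair, so the
        # reduced regression agrees with the full one within Monte Carlo
        A, B, truth = make_gaussian_surveys(
            3000, seed=31,
            exposure_loading={"sexual_stigma": {"urban": 0.0, "region_south": 0.0}},
            outcome_loading={"condoms": {"urban": 0.0, "region_south": 0.0}},
        )
        pair = ("sexual_stigma", "condoms")
        full, reduced, diff = sf.sensitivity_covariates(
            A, B, *pair, truth.true_rho[pair]
        )
        assert abs(diff) < 2 * np.sqrt(full.t + reduced.t)

    def test_omitted_region_confounding_shifts_reduced_estimate(self):
        # region loads positively on both exposure and outcome; omitting
        # it from the regression biases the estimate upward (the fusion
        # itself still conditions on the full covariate set)
        loadings = {"sexual_stigma": {"region_south": 0.55}}
        out_loadings = {"condoms": {"region_south": 0.55}}
        A, B, truth = make_gaussian_surveys(
            4000, seed=32,
            exposure_loading=loadings, outcome_loading=out_loadings,
        )
        pair = ("sexual_stigma", "condoms")
        full, reduced, diff = sf.sensitivity_covariates(
            A, B, *pair, truth.true_rho[pair]
        )
        assert diff > 0.05


class TestReport:
    def test_report_shape_matches_prevention_table(self):
        pooled = [
            sf.pool_rubin([make_estimate(c + i * 0.01, 0.01, exposure=e, outcome=o)
                           for i in range(5)])
            for c, e in zip((1.1, 0.7, -0.9, -1.0), sf.EXPOSURES)
            for o in ("hiv_testing", "condoms", "prep")
        ]
        report = sf.make_report(pooled)
        assert len(report) == 12
        grid = report.pivot(index="exposure", columns="outcome", values="coefficient")
        assert grid.shape == (4, 3)

    def test_empty_report_header_only(self):
        report = sf.make_report([])
        assert report.empty
        assert "coefficient" in report.columns
        assert sf.format_report(report).strip() == "(no estimates)"

    def test_report_csv_roundtrip(self, tmp_path):
        pooled = [sf.pool_rubin([make_estimate(1.0 + 0.1 * i, 0.02) for i in range(5)])]
        report = sf.make_report(pooled)
        p = tmp_path / "r.csv"
        report.to_csv(p, index=False)
        back = pd.read_csv(p)
        pd.testing.assert_frame_equal(back, report, check_dtype=False)
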