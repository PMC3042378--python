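"""Standardization, joint density, MCMC sampler, EPSR and DIC."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from pthpath.estimate import (
    FitResult,
    McmcConfig,
    PriorSpec,
    StandardizationInfo,
    dic,
    epsr,
    joint_log_density,
    sample_posterior,
    standardize,
    summarize,
)
from pthpath.model import PathEdge, PathModel, VariableSpec
from pthpath.simulate import GeneratorConfig, MarginalSpec, generate_cohort


def _single_linear_model():
    return PathModel.from_specs(
        [
            VariableSpec("x", "continuous", "exogenous"),
            VariableSpec("y", "continuous", "endogenous"),
        ],
        [PathEdge("x", "y")],
        name="one-linear",
    )


def _single_logistic_model():
    return PathModel.from_specs(
        [
            VariableSpec("x", "continuous", "exogenous"),
            VariableSpec("d", "binary", "endogenous"),
        ],
        [PathEdge("x", "d")],
        name="one-logistic",
    )


def _toy_cohort(n, seed, slope=0.5, sigma=0.8, logit_slope=0.9):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    y = slope * x + rng.normal(0, sigma, n)
    d = (rng.random(n) < expit(logit_slope * x)).astype(int)
    return pd.DataFrame({"x": x, "y": y, "d": d, "sex": rng.integers(0, 2, n)})


class TestStandardize:
    def test_reference_moments_map_to_z(self):
        # column with sample mean exactly 5.8 and sample SD exactly 2.3
        cohort = pd.DataFrame({"PTH": [3.5, 5.8, 8.1], "sex": [0, 1, 0]})
        z, info = standardize(cohort)
        assert info.moments["PTH"] == pytest.approx((5.8, 2.3))
        assert z["PTH"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert z["sex"].tolist() == [0, 1, 0]

    def test_result_has_unit_moments_and_idempotence(self, reference_cohort):
        z, info = standardize(reference_cohort)
        for col in ("age", "PTH", "vitD", "calcium"):
            assert z[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert z[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        z2, _ = standardize(z)
        pd.testing.assert_frame_equal(z, z2)

    def test_inverse_transform_round_trip(self, reference_cohort):
        z, info = standardize(reference_cohort)
        back = info.inverse(z["PTH"].to_numpy(), "PTH")
        np.testing.assert_allclose(back, reference_cohort["PTH"].to_numpy(), rtol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(pd.DataFrame({"a": [2.0, 2.0, 2.0]}))

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            standardize(pd.DataFrame({"a": [1.0, np.nan, 3.0]}))


class TestJointLogDensity:
    def test_gaussian_closed_form(self):
        model = _single_linear_model()
        n = 7
        data = pd.DataFrame(
            {"x": np.linspace(-1, 1, n), "y": np.linspace(-0.5, 0.5, n), "sex": 0}
        )
        priors = PriorSpec()
        params = {"y.intercept": 0.0, "y.x": 0.0, "y.residual_sd": 1.0}
        got = joint_log_density(model, data, params, priors)
        expected_lik = float(np.sum(-0.5 * np.log(2 * np.pi) - 0.5 * data["y"] ** 2))
        expected = expected_lik + priors.coef_logpdf(np.zeros(2)) + priors.sigma_logpdf(1.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_logistic_intercept_only_closed_form(self):
        model = PathModel.from_specs(
            [
                VariableSpec("x", "continuous", "exogenous"),
                VariableSpec("d", "binary", "endogenous"),
            ],
            [PathEdge("x", "d")],
        )
        n, c = 11, 0.7
        data = pd.DataFrame({"x": np.linspace(-1, 1, n), "d": np.ones(n, int), "sex": 0})
        priors = PriorSpec()
        params = {"d.intercept": c, "d.x": 0.0}
        got = joint_log_density(model, data, params, priors)
        expected = n * np.log(expit(c)) + priors.coef_logpdf(np.array([c, 0.0]))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_residual_sd_gives_minus_inf(self):
        model = _single_linear_model()
        data = pd.DataFrame({"x": [0.0, 1.0, -1.0], "y": [0.0, 1.0, -1.0], "sex": 0})
        params = {"y.intercept": 0.0, "y.x": 1.0, "y.residual_sd": -0.5}
        assert joint_log_density(model, data, params) == -np.inf

    def test_agreement_with_naive_per_observation_sum(self):
        """Independent oracle: evaluate every observation's density one by
        one with scipy distributions on a 5-subject toy cohort."""
        from scipy import stats

        model = PathModel.from_specs(
            [
                VariableSpec("x", "continuous", "exogenous"),
                VariableSpec("y", "continuous", "endogenous"),
                VariableSpec("d", "binary", "endogenous"),
            ],
            [PathEdge("x", "y"), PathEdge("y", "d"), PathEdge("x", "d")],
        )
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {
                "x": rng.normal(size=5),
                "y": rng.normal(size=5),
                "d": [0, 1, 1, 0, 1],
                "sex": [0, 1, 0, 1, 0],
            }
        )
        priors = PriorSpec()
        params = {
            "y.intercept": 0.2,
            "y.x": -0.7,
            "y.residual_sd": 1.3,
            "d.intercept": -0.1,
            "d.y": 0.5,
            "d.x": 0.9,
        }
        naive = 0.0
        for _, row in data.iterrows():
            mu = params["y.intercept"] + params["y.x"] * row["x"]
            naive += stats.norm.logpdf(row["y"], mu, params["y.residual_sd"])
            eta = params["d.intercept"] + params["d.y"] * row["y"] + params["d.x"] * row["x"]
            naive += stats.bernoulli.logpmf(row["d"], expit(eta))
        naive += priors.coef_logpdf(np.array([0.2, -0.7]))
        naive += priors.coef_logpdf(np.array([-0.1, 0.5, 0.9]))
        naive += priors.sigma_logpdf(1.3)
        got = joint_log_density(model, data, params, priors)
        assert got == pytest.approx(float(naive), rel=1e-10)


class TestEpsr:
    def test_matches_hand_computed_two_chain_example(self):
        """Worked Gelman-Rubin computation on 2 chains x 10 fabricated draws."""
        c1 = np.array([0.1, 0.3, -0.2, 0.5, 0.0, 0.2, -0.1, 0.4, 0.3, 0.1])
        c2 = np.array([0.6, 0.8, 0.5, 0.9, 0.7, 0.4, 0.6, 1.0, 0.8, 0.7])
        arr = np.stack([c1, c2])
        n = 10
        w = (c1.var(ddof=1) + c2.var(ddof=1)) / 2
        b = n * np.var([c1.mean(), c2.mean()], ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b / n) / w)
        got = epsr({"theta": arr})["theta"]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_permuted_chains_near_one(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=500)
        chains = np.stack([rng.permutation(base) for _ in range(3)])
        val = epsr({"p": chains})["p"]
        assert val == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_much_greater_than_one(self):
        rng = np.random.default_rng(4)
        chains = np.stack([rng.normal(0, 1, 200), rng.normal(10, 1, 200)])
        assert epsr({"p": chains})["p"] > 3

    def test_input_contract(self):
        with pytest.raises(ValueError):
            epsr({"p": np.zeros((1, 100))})  # one chain
        with pytest.raises(ValueError):
            epsr({"p": np.zeros((2, 5))})  # too few draws
        with pytest.raises(ValueError):
            epsr({"p": np.ones((2, 50))})  # zero within-chain variance


class TestDic:
    def test_point_mass_draws_have_zero_pd(self):
        model = _single_linear_model()
        cohort = _toy_cohort(60, 1)[["x", "y", "sex"]]
        draws = {
            "y.intercept": np.full((2, 20), 0.1),
            "y.x": np.full((2, 20), 0.4),
            "y.residual_sd": np.full((2, 20), 0.9),
        }
        res = dic(draws, model, cohort)
        assert res["pd"] == pytest.approx(0.0, abs=1e-8)
        assert res["dic"] == pytest.approx(res["dbar"], abs=1e-8)

    def test_identity_and_positive_pd_on_real_fit(self, reference_fit):
        d = reference_fit.dic
        assert d["dic"] == pytest.approx(d["dbar"] + d["pd"], rel=1e-12)
        assert d["pd"] > 0
        for eq in d["per_equation"].values():
            assert eq["dic"] == pytest.approx(eq["dbar"] + eq["pd"], rel=1e-12)

    def test_pd_approximates_parameter_count_large_n(self):
        """A single vague-prior linear equation has pD ~ its parameter count
        (intercept + slope + residual SD = 3) at large n."""
        model = _single_linear_model()
        cohort = _toy_cohort(4000, 7)[["x", "y", "sex"]]
        fit = sample_posterior(
            model, cohort, config=McmcConfig(chains=2, iterations=2000, burnin=500, seed=2)
        )
        assert fit.dic["pd"] == pytest.approx(3.0, abs=0.8)


class TestSamplePosterior:
    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            McmcConfig(chains=1)

    def test_posterior_matches_ols_limit(self):
        """With vague priors the linear-equation posterior mean approaches
        the least-squares estimate (statsmodels as the independent oracle)."""
        model = _single_linear_model()
        cohort = _toy_cohort(971, 11)[["x", "y", "sex"]]
        fit = sample_posterior(
            model, cohort, config=McmcConfig(chains=3, iterations=3000, burnin=1000, seed=3)
        )
        z, _ = standardize(cohort)
        ols = sm.OLS(z["y"], sm.add_constant(z[["x"]])).fit()
        assert fit.posterior_mean("y.x") == pytest.approx(ols.params["x"], abs=0.01)
        assert fit.posterior_mean("y.intercept") == pytest.approx(
            ols.params["const"], abs=0.01
        )

    def test_posterior_matches_logistic_mle_limit(self):
        model = _single_logistic_model()
        cohort = _toy_cohort(2000, 5)[["x", "d", "sex"]]
        fit = sample_posterior(
            model, cohort, config=McmcConfig(chains=3, iterations=4000, burnin=1500, seed=4)
        )
        z, _ = standardize(cohort)
        mle = sm.Logit(z["d"], sm.add_constant(z[["x"]])).fit(disp=0)
        assert fit.posterior_mean("d.x") == pytest.approx(mle.params["x"], abs=0.05)

    def test_reproducible_with_seed(self):
        model = _single_linear_model()
        cohort = _toy_cohort(200, 2)[["x", "y", "sex"]]
        cfg = McmcConfig(chains=2, iterations=400, burnin=100, seed=7)
        a = sample_posterior(model, cohort, config=cfg)
        b = sample_posterior(model, cohort, config=cfg)
        for name in a.parameter_names:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_parameter_names_and_shapes(self, reference_fit, final_model):
        cfg = reference_fit.config
        kept = cfg.kept
        for outcome, parents in final_model.equations().items():
            assert f"{outcome}.intercept" in reference_fit.draws
            for p in parents:
                assert f"{outcome}.{p}" in reference_fit.draws
        for e in final_model.moderated_edges:
            assert f"{e.target}.{e.source}.male_offset" in reference_fit.draws
        for name, arr in reference_fit.draws.items():
            assert arr.shape == (cfg.chains, kept)
            assert np.isfinite(arr).all()
        assert "PTH.residual_sd" in reference_fit.draws
        assert "MS.residual_sd" not in reference_fit.draws

    def test_standardized_fit_rescales_to_raw_slope(self):
        """Natural-unit slope from SD-rescaling of the standardized fit
        agrees with least squares on the raw scale."""
        rng = np.random.default_rng(12)
        x = rng.normal(50, 9, 900)
        y = 0.3 * x + rng.normal(0, 5, 900)
        cohort = pd.DataFrame({"x": x, "y": y, "sex": rng.integers(0, 2, 900)})
        model = _single_linear_model()
        fit = sample_posterior(
            model, cohort, config=McmcConfig(chains=2, iterations=2000, burnin=500, seed=9)
        )
        sd_x = fit.standardization.sd("x")
        sd_y = fit.standardization.sd("y")
        natural = fit.posterior_mean("y.x") * sd_y / sd_x
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert natural == pytest.approx(ols.params[1], abs=0.02)

    def test_summarize_flags_and_interval_logic(self, reference_fit):
        table = summarize(reference_fit)
        assert {"mean", "lower", "upper", "significant", "epsr"} <= set(table.columns)
        for name, row in table.iterrows():
            assert row["lower"] <= row["mean"] <= row["upper"]
            assert row["significant"] == (row["lower"] > 0 or row["upper"] < 0)
        # the dominant diabetes effect is unambiguous in any seeded cohort
        assert table.loc["MS.T2DM", "significant"]

    def test_fit_converges_on_reference_cohort(self, reference_fit):
        assert reference_fit.converged
        assert max(reference_fit.epsr.values()) < 1.1
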