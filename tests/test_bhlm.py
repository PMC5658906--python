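"""Hierarchical model: sampler-vs-closed-form oracle, prior behavior,
summaries, and the per-10-fold rescaling."""

import numpy as np
import pandas as pd
import pytest

from edcmix.bhlm import (
    BHLMSpec,
    FixedHyper,
    build_model,
    conjugate_posterior_fixed_hyper,
    rescale_per_tenfold,
    sample_posterior,
    summarize,
)
from tests.conftest import make_toy_matrix


class TestBuildModel:
    def test_design_layout(self):
        m, _ = make_toy_matrix(n=100, p_hier=6, n_class=2, seed=1)
        model = build_model(m, BHLMSpec(seed=1))
        assert model.p == 1 + 6 + 2
        assert model.names[0] == "intercept"
        assert len(model.class_labels) == 2
        assert len(model.hier_idx) == 6

    def test_five_classes_give_ten_hyperparameters(self):
        m, _ = make_toy_matrix(n=150, p_hier=15, n_class=5, seed=2)
        model = build_model(m, BHLMSpec(seed=2))
        assert len(model.class_labels) == 5  # 5 mu + 5 sigma hyperparameters
        post = sample_posterior(
            model, BHLMSpec(seed=2, iterations=300, warmup=100)
        )
        assert post.mu.shape[1] == 5 and post.sigma.shape[1] == 5

    def test_no_hierarchical_columns_degenerates_to_linear_regression(self):
        import pandas as pd

        from edcmix.preprocess import AnalysisMatrix

        rng = np.random.default_rng(3)
        C = pd.DataFrame({"c1": rng.standard_normal(120)})
        y = 2.0 + 3.0 * C["c1"].to_numpy() + rng.standard_normal(120)
        m = AnalysisMatrix(
            y=y, X=pd.DataFrame(index=C.index), C=C, B=None,
            sd_log10=pd.Series(dtype=float), class_map={},
        )
        model = build_model(m, BHLMSpec(seed=3))
        post = sample_posterior(
            model, BHLMSpec(seed=3, iterations=800, warmup=300)
        )
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(120), C.to_numpy()]), y, rcond=None
        )[0]
        est = post.theta.mean(axis=0)
        assert np.allclose(est, ols, atol=0.2)

    def test_unmapped_column_rejected(self):
        m, _ = make_toy_matrix(n=50, p_hier=4, seed=4)
        del m.class_map["chem_3"]
        with pytest.raises(ValueError, match="class"):
            build_model(m, BHLMSpec(seed=0))

    def test_duplicate_column_names_rejected(self):
        m, _ = make_toy_matrix(n=50, p_hier=4, seed=5)
        m.X.columns = ["a", "a", "b", "c"]
        m.class_map = {"a": "PCB", "b": "PCB", "c": "PCB"}
        with pytest.raises(ValueError, match="duplicate"):
            build_model(m, BHLMSpec(seed=0))


class TestConjugateOracle:
    def test_flat_prior_limit_recovers_ols(self):
        m, _ = make_toy_matrix(n=80, p_hier=4, seed=6)
        model = build_model(m, BHLMSpec(seed=6))
        mean, _, names = conjugate_posterior_fixed_hyper(
            model,
            mu_beta={c: 0.0 for c in model.class_labels},
            sigma_beta={c: 1e8 for c in model.class_labels},
            residual_sd=1.0,
            fixed_coef_prior_var=1e16,
        )
        Z, _ = m.design()
        ols = np.linalg.lstsq(Z, m.y, rcond=None)[0]
        np.testing.assert_allclose(mean, ols, atol=1e-5)

    def test_degenerate_sigma_pins_coefficients_to_class_mean(self):
        m, _ = make_toy_matrix(n=80, p_hier=4, n_class=1, seed=7)
        model = build_model(m, BHLMSpec(seed=7))
        mean, _, _ = conjugate_posterior_fixed_hyper(
            model,
            mu_beta={model.class_labels[0]: 2.5},
            sigma_beta={model.class_labels[0]: 1e-8},
            residual_sd=1.0,
        )
        np.testing.assert_allclose(mean[model.hier_idx], 2.5, atol=1e-4)

    def test_matches_grid_integration_on_small_instance(self):
        """2-parameter model: closed form vs brute-force grid posterior."""
        rng = np.random.default_rng(8)
        n = 50
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=1)
        y = 1.0 + 0.8 * x + rng.normal(0, 0.7, n)

        from edcmix.preprocess import AnalysisMatrix

        m = AnalysisMatrix(
            y=y,
            X=pd.DataFrame({"chem_0": x}),
            C=pd.DataFrame(index=range(n)),
            B=None,
            sd_log10=pd.Series({"chem_0": 0.5}),
            class_map={"chem_0": "PCB"},
        )
        model = build_model(m, BHLMSpec(seed=8))
        mu0, s0, sr = 0.3, 1.5, 0.7
        mean, cov, _ = conjugate_posterior_fixed_hyper(
            model, {"PCB": mu0}, {"PCB": s0}, sr, fixed_coef_prior_var=10.0
        )

        # independent oracle: evaluate the unnormalized posterior on a grid
        b0g = np.linspace(-2, 4, 401)
        b1g = np.linspace(-2, 4, 401)
        B0, B1 = np.meshgrid(b0g, b1g, indexing="ij")
        resid = y[None, None, :] - B0[..., None] - B1[..., None] * x
        loglik = -0.5 * np.sum(resid**2, axis=-1) / sr**2
        logprior = -0.5 * B0**2 / 10.0 - 0.5 * (B1 - mu0) ** 2 / s0**2
        w = np.exp(loglik + logprior - (loglik + logprior).max())
        w /= w.sum()
        grid_mean = np.array([np.sum(w * B0), np.sum(w * B1)])
        grid_var = np.array(
            [np.sum(w * (B0 - grid_mean[0]) ** 2),
             np.sum(w * (B1 - grid_mean[1]) ** 2)]
        )
        np.testing.assert_allclose(mean, grid_mean, atol=2e-3)
        np.testing.assert_allclose(np.diag(cov), grid_var, rtol=5e-3)

    def test_singular_precision_rejected(self):
        m, _ = make_toy_matrix(n=30, p_hier=2, seed=9)
        model = build_model(m, BHLMSpec(seed=9))
        with pytest.raises(ValueError):
            conjugate_posterior_fixed_hyper(
                model, {c: 0.0 for c in model.class_labels},
                {c: 1.0 for c in model.class_labels}, residual_sd=0.0,
            )


class TestSamplePosterior:
    def test_fixed_hyper_matches_conjugate_within_mc_error(self):
        m, _ = make_toy_matrix(n=200, p_hier=10, n_class=2, seed=10)
        model = build_model(m, BHLMSpec(seed=10))
        fh = FixedHyper(
            mu_beta={c: 0.5 for c in model.class_labels},
            sigma_beta={c: 1.0 for c in model.class_labels},
            residual_sd=1.0,
        )
        spec = BHLMSpec(seed=10, iterations=2500, warmup=500)
        post = sample_posterior(model, spec, fixed_hyper=fh)
        mean, cov, _ = conjugate_posterior_fixed_hyper(
            model, fh.mu_beta, fh.sigma_beta, fh.residual_sd
        )
        sd = np.sqrt(np.diag(cov))
        nd = post.n_draws
        # fixed-hyper draws are independent: MC-SE = sd / sqrt(ndraws)
        z_mean = (post.theta.mean(axis=0) - mean) / (sd / np.sqrt(nd))
        assert np.max(np.abs(z_mean)) < 3.0
        z_sd = (post.theta.std(axis=0, ddof=1) - sd) / (sd / np.sqrt(2 * nd))
        assert np.max(np.abs(z_sd)) < 3.0

    def test_prior_only_run_recovers_hyperprior(self):
        """With an uninformative outcome the class mean samples its prior."""
        m, _ = make_toy_matrix(n=60, p_hier=3, n_class=1, seed=11)
        # outcome carrying essentially no information about coefficients
        m.y = np.random.default_rng(11).normal(0.0, 1e6, size=60)
        spec = BHLMSpec(seed=11, iterations=4000, warmup=500,
                        residual_sd_prior_scale=1e8)
        model = build_model(m, spec)
        post = sample_posterior(model, spec)
        mu = post.mu[:, 0]
        assert abs(np.mean(mu)) < 30.0  # prior mean 0, prior SD ~316
        assert np.std(mu) == pytest.approx(np.sqrt(1e5), rel=0.15)

    def test_same_seed_reproduces_draws_exactly(self):
        m, _ = make_toy_matrix(n=100, p_hier=4, seed=12)
        model = build_model(m, BHLMSpec(seed=12))
        spec = BHLMSpec(seed=12, iterations=400, warmup=100)
        p1 = sample_posterior(model, spec)
        p2 = sample_posterior(model, spec)
        np.testing.assert_array_equal(p1.theta, p2.theta)
        np.testing.assert_array_equal(p1.sigma, p2.sigma)

    def test_draw_count_and_positivity(self):
        m, _ = make_toy_matrix(n=100, p_hier=4, seed=13)
        model = build_model(m, BHLMSpec(seed=13))
        spec = BHLMSpec(seed=13, chains=2, iterations=500, warmup=200)
        post = sample_posterior(model, spec)
        assert post.n_draws == 2 * (500 - 200)
        assert np.all(post.sigma > 0) and np.all(post.residual_sd > 0)

    def test_diagnostics_reports_rhat_and_ess(self):
        m, _ = make_toy_matrix(n=150, p_hier=8, n_class=2, seed=14)
        model = build_model(m, BHLMSpec(seed=14))
        post = sample_posterior(model, BHLMSpec(seed=14, iterations=1500,
                                                warmup=500))
        d = post.diagnostics()
        assert {"parameter", "rhat", "ess_bulk"} <= set(d.columns)
        assert d["rhat"].max() < 1.1


class TestSummarize:
    def test_standard_normal_quantiles(self):
        draws = np.random.default_rng(0).standard_normal(1_000_000)
        s = summarize(draws[:, None], names=["z"])
        row = s.iloc[0]
        assert row["ci95_lower"] == pytest.approx(-1.96, abs=0.01)
        assert row["ci95_upper"] == pytest.approx(1.96, abs=0.01)
        assert row["ci50_lower"] == pytest.approx(-0.674, abs=0.01)
        assert not row["excl_zero_95"]

    def test_constant_draws_collapse_intervals(self):
        s = summarize(np.full((200, 1), 3.5), names=["c"])
        row = s.iloc[0]
        assert row["ci95_lower"] == row["ci95_upper"] == 3.5
        assert row["excl_zero_95"] and row["excl_zero_50"]

    def test_interval_nesting(self):
        rng = np.random.default_rng(1)
        draws = pd.DataFrame(rng.standard_normal((5000, 4)),
                             columns=list("abcd"))
        s = summarize(draws)
        assert (s["ci95_lower"] <= s["ci50_lower"]).all()
        assert (s["ci50_upper"] <= s["ci95_upper"]).all()

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            summarize(np.zeros((50, 1)), names=["x"])


class TestRescalePerTenfold:
    def _posterior(self):
        m, _ = make_toy_matrix(n=150, p_hier=4, n_class=2, seed=15)
        model = build_model(m, BHLMSpec(seed=15))
        return sample_posterior(
            model, BHLMSpec(seed=15, iterations=600, warmup=200)
        ), m

    def test_division_by_sd_log10(self):
        post, m = self._posterior()
        chem, _ = rescale_per_tenfold(post)
        per_sd = summarize(post.exposure_draws())
        # sd_log10 = 0.5 everywhere in the toy matrix -> exactly doubled
        np.testing.assert_allclose(
            chem["mean"].to_numpy(), 2 * per_sd["mean"].to_numpy()
        )

    def test_unit_sd_is_identity(self):
        post, m = self._posterior()
        sd1 = pd.Series(1.0, index=m.X.columns)
        chem, _ = rescale_per_tenfold(post, sd_log10=sd1)
        per_sd = summarize(post.exposure_draws())
        np.testing.assert_allclose(
            chem["mean"].to_numpy(), per_sd["mean"].to_numpy()
        )

    def test_rescale_commutes_with_posterior_mean(self):
        post, m = self._posterior()
        chem, _ = rescale_per_tenfold(post)
        direct = post.exposure_draws().mean() / m.sd_log10[m.X.columns]
        np.testing.assert_allclose(
            chem["mean"].to_numpy(), direct.to_numpy(), atol=1e-12
        )

    def test_missing_sd_rejected(self):
        post, m = self._posterior()
        with pytest.raises(ValueError, match="missing"):
            rescale_per_tenfold(post, sd_log10=pd.Series({"chem_0": 0.5}))
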