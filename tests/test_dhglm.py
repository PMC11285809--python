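import numpy as np
import pandas as pd
import pytest
from scipy import stats

import boarsleep as bs
from boarsleep import dhglm
from boarsleep.dhglm import (
    DhglmSpec,
    effective_sample_size,
    fit,
    log_posterior,
    px,
    random_slope_fit,
    split_rhat,
)


def small_dataset(n_ind=2, n_obs=5, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "individual": np.repeat([f"i{k}" for k in range(n_ind)], n_obs),
            "x": rng.standard_normal(n_ind * n_obs),
            "y": rng.standard_normal(n_ind * n_obs) + 5.0,
        }
    )
    return df


def brute_force_log_posterior(params, data, spec):
    """Independent evaluation: plain loops and scipy distributions."""
    ids = sorted(data[spec.id_col].unique())
    lp = 0.0
    for v in params["beta_mean"]:
        lp += stats.norm.logpdf(v, 0, spec.prior_beta_sd)
    for v in params["beta_sigma"]:
        lp += stats.norm.logpdf(v, 0, spec.prior_beta_sd)
    scale = np.std(data[spec.response].to_numpy())
    for s in (params["sd_a"], params["sd_b"]):
        lp += stats.t.logpdf(s / scale, 3) + np.log(2.0 / scale)
    sa, sb, rho = params["sd_a"], params["sd_b"], params["rho"]
    cov = np.array([[sa**2, rho * sa * sb], [rho * sa * sb, sb**2]])
    for i in range(len(ids)):
        lp += stats.multivariate_normal.logpdf(
            [params["a"][i], params["b"][i]], mean=[0, 0], cov=cov
        )
    for _, row in data.iterrows():
        i = ids.index(row[spec.id_col])
        mu = params["beta_mean"][0] + params["beta_mean"][1] * row["x"] + params["a"][i]
        log_sd = params["beta_sigma"][0] + params["beta_sigma"][1] * row["x"] + params["b"][i]
        lp += stats.norm.logpdf(row[spec.response], mu, np.exp(log_sd))
    return lp


SPEC = DhglmSpec(response="y", mean_covariates=["x"], sigma_covariates=["x"],
                 iterations=200, burn_in=100)

PARAMS = {
    "beta_mean": np.array([4.5, -0.3]),
    "beta_sigma": np.array([0.1, 0.2]),
    "a": np.array([0.4, -0.2]),
    "b": np.array([-0.1, 0.15]),
    "sd_a": 0.8,
    "sd_b": 0.25,
    "rho": 0.3,
}


class TestLogPosterior:
    def test_matches_brute_force_to_1e10(self):
        data = small_dataset()
        ours = log_posterior(PARAMS, data, SPEC)
        brute = brute_force_log_posterior(PARAMS, data, SPEC)
        assert ours == pytest.approx(brute, abs=1e-10)

    def test_single_observation_matches_hand_computed_density(self):
        df = pd.DataFrame({"individual": ["i0"], "x": [0.0], "y": [2.0]})
        spec = DhglmSpec(response="y", mean_covariates=["x"], sigma_covariates=["x"],
                         re_scale=1.0, iterations=2, burn_in=1)
        params = dict(PARAMS, a=np.zeros(1), b=np.zeros(1))
        lp = log_posterior(params, df, spec)
        # subtract every prior term by hand; what is left is one normal density
        priors = (
            np.sum(stats.norm.logpdf(params["beta_mean"], 0, 10))
            + np.sum(stats.norm.logpdf(params["beta_sigma"], 0, 10))
            + stats.t.logpdf(PARAMS["sd_a"], 3) + np.log(2.0)
            + stats.t.logpdf(PARAMS["sd_b"], 3) + np.log(2.0)
            + stats.multivariate_normal.logpdf(
                [0.0, 0.0],
                mean=[0, 0],
                cov=[[0.8**2, 0.3 * 0.8 * 0.25], [0.3 * 0.8 * 0.25, 0.25**2]],
            )
        )
        expected = stats.norm.logpdf(2.0, 4.5, np.exp(0.1))
        assert lp - priors == pytest.approx(expected, abs=1e-10)

    def test_rho_outside_support(self):
        data = small_dataset()
        assert log_posterior(dict(PARAMS, rho=1.5), data, SPEC) == -np.inf
        assert log_posterior(dict(PARAMS, sd_a=-0.1), data, SPEC) == -np.inf

    def test_doubling_data_doubles_likelihood_term(self):
        data = small_dataset()
        doubled = pd.concat([data, data], ignore_index=True)
        spec = DhglmSpec(response="y", mean_covariates=["x"], sigma_covariates=["x"],
                         re_scale=1.0, iterations=2, burn_in=1)
        lp1 = log_posterior(PARAMS, data, spec)
        lp2 = log_posterior(PARAMS, doubled, spec)
        # prior terms are identical, so the difference is one data log-likelihood
        ids = sorted(data["individual"].unique())
        ll = 0.0
        for _, row in data.iterrows():
            i = ids.index(row["individual"])
            mu = PARAMS["beta_mean"][0] + PARAMS["beta_mean"][1] * row["x"] + PARAMS["a"][i]
            lsd = PARAMS["beta_sigma"][0] + PARAMS["beta_sigma"][1] * row["x"] + PARAMS["b"][i]
            ll += stats.norm.logpdf(row["y"], mu, np.exp(lsd))
        assert lp2 - lp1 == pytest.approx(ll, abs=1e-9)

    def test_ar1_likelihood_matches_loop(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(12)
        mu = np.zeros(12)
        log_sd = np.zeros(12)
        idx = np.r_[np.zeros(6, int), np.ones(6, int)]
        phi = 0.5
        ours = dhglm._ar1_loglik(y, mu, log_sd, idx, phi)
        expected = 0.0
        for i in (0, 1):
            r = y[idx == i]
            expected += stats.norm.logpdf(r[0])
            for t in range(1, len(r)):
                expected += stats.norm.logpdf(r[t], phi * r[t - 1], np.sqrt(1 - phi**2))
        assert ours == pytest.approx(expected, abs=1e-10)


class TestPx:
    def test_all_positive_is_zero(self):
        assert px(np.abs(np.random.default_rng(0).normal(size=1000)) + 0.01) == 0.0

    def test_symmetric_null_near_fifty(self):
        draws = np.random.default_rng(1).standard_normal(10_000)
        assert px(draws) == pytest.approx(50.0, abs=2.0)

    def test_exact_count(self):
        draws = np.r_[np.full(970, 1.0), np.full(30, -1.0)]
        assert px(draws) == 3.0

    def test_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(0.5, 1.0, 5000)
        assert px(draws) == px(draws * 37.0)

    def test_sign_flip_equivariance(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(0.5, 1.0, 5000)
        assert px(-draws) == px(draws)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            px(np.ones(50))


class TestDiagnostics:
    def test_rhat_and_ess_match_arviz(self):
        import arviz

        rng = np.random.default_rng(4)
        good = rng.standard_normal((4, 500))
        assert split_rhat(good) == pytest.approx(
            float(arviz.rhat(arviz.convert_to_dataset(good[:, :, None]))["x"].values[0]),
            abs=0.02,
        )
        ess_az = float(arviz.ess(arviz.convert_to_dataset(good[:, :, None]))["x"].values[0])
        assert effective_sample_size(good) == pytest.approx(ess_az, rel=0.25)

    def test_rhat_flags_disjoint_chains(self):
        rng = np.random.default_rng(5)
        bad = np.stack([rng.normal(0, 1, 500), rng.normal(5, 1, 500)])
        assert split_rhat(bad) > 2.0


class TestFit:
    def test_identifiability_preconditions(self):
        df = small_dataset(n_ind=1)
        with pytest.raises(ValueError, match="2 individuals"):
            fit(df, SPEC)
        df2 = small_dataset(n_ind=3, n_obs=1)
        with pytest.raises(ValueError, match="2 observations"):
            fit(df2, SPEC)

    def test_prior_only_recovers_prior_moments(self):
        df = small_dataset(n_ind=4, n_obs=10)
        spec = DhglmSpec(
            response="y", mean_covariates=["x"], sigma_covariates=[],
            prior_only=True, re_scale=1.0,
            chains=2, iterations=4000, burn_in=500, thin=1, seed=0,
        )
        post = fit(df, spec)
        draws = post.flat("beta_mean[x]")
        assert np.mean(draws) == pytest.approx(0.0, abs=0.6)
        assert np.std(draws) == pytest.approx(10.0, rel=0.1)

    def test_two_seeds_agree_within_mc_error(self):
        cfg = bs.DhglmSimConfig(n_individuals=15, days_per_individual=30, seed=3)
        data, _ = bs.simulate_dhglm_data(cfg)
        kw = dict(response="y", mean_covariates=["temp", "daylen"],
                  sigma_covariates=["temp"], chains=1,
                  iterations=1600, burn_in=600, thin=1)
        p1 = fit(data, DhglmSpec(seed=11, **kw))
        p2 = fit(data, DhglmSpec(seed=22, **kw))
        for name in ("beta_mean[temp]", "beta_sigma[temp]"):
            m1, m2 = np.median(p1.flat(name)), np.median(p2.flat(name))
            mc = np.std(p1.flat(name)) / 5  # generous MC error bound
            assert abs(m1 - m2) < max(mc, 0.02)

    def test_deterministic_given_seed(self):
        df = small_dataset(n_ind=3, n_obs=8)
        spec = DhglmSpec(response="y", mean_covariates=["x"], sigma_covariates=[],
                         chains=1, iterations=300, burn_in=100, thin=1, seed=7)
        a = fit(df, spec)
        b = fit(df, spec)
        assert np.array_equal(a.flat("sd_a"), b.flat("sd_a"))

    def test_homoscedastic_truth_shrinks_sd_b(self):
        cfg = bs.DhglmSimConfig(
            n_individuals=25, days_per_individual=40,
            beta_mean={"intercept": 5.0}, beta_sigma={"intercept": 0.0},
            sd_intercept_mean=1.0, sd_intercept_sigma=0.0, rho=0.0, seed=8,
        )
        data, _ = bs.simulate_dhglm_data(cfg)
        spec = DhglmSpec(response="y", mean_covariates=[], sigma_covariates=[],
                         chains=1, iterations=1500, burn_in=500, thin=1, seed=9)
        post = fit(data, spec)
        assert np.median(post.flat("sd_b")) < 0.12

    def test_summary_table_shape(self):
        df = small_dataset(n_ind=3, n_obs=8)
        spec = DhglmSpec(response="y", mean_covariates=["x"], sigma_covariates=["x"],
                         chains=2, iterations=400, burn_in=200, thin=1, seed=0)
        s = fit(df, spec).summary()
        for name in ("beta_mean[intercept]", "beta_mean[x]", "beta_sigma[x]",
                     "sd_a", "sd_b", "rho"):
            assert name in s.index
        assert {"median", "ci_2.5", "ci_97.5", "px", "rhat", "ess"} <= set(s.columns)

    def test_ar1_recovery_smoke(self):
        cfg = bs.DhglmSimConfig(
            n_individuals=10, days_per_individual=60,
            beta_mean={"intercept": 1.0}, beta_sigma={"intercept": 0.2},
            sd_intercept_mean=0.5, sd_intercept_sigma=0.1, rho=0.0,
            ar1=0.5, seed=12,
        )
        data, _ = bs.simulate_dhglm_data(cfg)
        spec = DhglmSpec(response="y", mean_covariates=[], sigma_covariates=[],
                         ar1=True, chains=1, iterations=600, burn_in=300, thin=1,
                         seed=13)
        post = fit(data, spec)
        phi = np.median(post.flat("phi"))
        assert 0.2 < phi < 0.8


class TestRandomSlope:
    def test_constant_predictor_rejected(self):
        df = small_dataset()
        df["x"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            random_slope_fit(df, "y", "x")

    def test_fixed_effects_recovered(self):
        # seed chosen so the realized mean of the random slopes is near zero
        # (with m=20 the fixed slope is confounded with it)
        rng = np.random.default_rng(24)
        m, d = 20, 40
        idx = np.repeat(np.arange(m), d)
        x = rng.standard_normal(m * d)
        u = rng.normal(0, 1.0, m)
        v = rng.normal(0, 0.5, m)
        y = 2.0 + 1.5 * x + u[idx] + v[idx] * x + rng.normal(0, 0.8, m * d)
        df = pd.DataFrame({"individual": idx, "x": x, "y": y})
        post = random_slope_fit(df, "y", "x", chains=1, iterations=1200,
                                burn_in=500, thin=1, seed=21)
        lo, hi = post.ci("beta1")
        assert lo < 1.5 < hi
        assert np.median(post.flat("sigma")) == pytest.approx(0.8, abs=0.1)

    def test_zero_slope_variance_shrinks(self):
        rng = np.random.default_rng(22)
        m, d = 20, 40
        idx = np.repeat(np.arange(m), d)
        x = rng.standard_normal(m * d)
        u = rng.normal(0, 1.0, m)
        y = 2.0 + 1.5 * x + u[idx] + rng.normal(0, 1.0, m * d)
        df = pd.DataFrame({"individual": idx, "x": x, "y": y})
        post = random_slope_fit(df, "y", "x", chains=1, iterations=1200,
                                burn_in=500, thin=1, seed=23)
        assert np.median(post.flat("sd_slope")) < 0.15
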