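"""Survival model: standardization, likelihood oracle, MCMC, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import beta as beta_dist

from nestsurv.mcmc import McmcConfig, gelman_rubin, run_mcmc
from nestsurv.model import (
    DailySurvivalModel,
    ModelSpec,
    _fold_random_effects,
    build_design,
    log_posterior,
    standardize,
)

PRIOR_PREC = 0.001


class TestModelSpec:
    def test_female_excludes_nest_age(self):
        assert "nest_age" not in ModelSpec.female().fixed
        with pytest.raises(ValueError):
            ModelSpec(outcome="female", fixed=("nest_age",))

    def test_nest_covariate_order(self):
        assert ModelSpec.nest().fixed == (
            "attempt", "concealment", "distance", "duration", "recesses", "nest_age"
        )


class TestStandardize:
    def test_location_invariance(self, rng):
        df = pd.DataFrame({"x": rng.normal(5, 2, 100)})
        z1, _ = standardize(df, ["x"])
        z2, _ = standardize(df.assign(x=df.x + 123.0), ["x"])
        assert np.allclose(z1.x, z2.x)

    def test_zero_mean_unit_sd(self, rng):
        df = pd.DataFrame({"x": rng.exponential(3, 500)})
        z, scalers = standardize(df, ["x"])
        assert z.x.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.x.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_one_sd_step_is_one_unit(self, rng):
        """A +1.8 hr change in a duration column with SD 1.8 is +1 z-unit."""
        x = rng.normal(2.09, 1.8, 2000)
        x = (x - x.mean()) / x.std(ddof=1) * 1.8 + 2.09  # exact moments
        df = pd.DataFrame({"duration": x})
        z, scalers = standardize(df, ["duration"])
        mu, sd = scalers["duration"]
        assert sd == pytest.approx(1.8)
        assert (x[0] + 1.8 - mu) / sd - z.duration[0] == pytest.approx(1.0)

    def test_zero_sd_error_names_covariate(self):
        df = pd.DataFrame({"flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            standardize(df, ["flat"])


class TestLogPosterior:
    def test_single_day_at_zero(self):
        """All-zero parameters give survival probability one half."""
        lp = log_posterior(np.zeros(1), np.ones((1, 1)), np.ones(1), PRIOR_PREC)
        prior_const = 0.5 * np.log(PRIOR_PREC / (2 * np.pi))
        assert lp == pytest.approx(np.log(0.5) + prior_const)

    def test_doubling_data_doubles_likelihood_part(self, rng):
        X = rng.normal(size=(15, 3))
        y = (rng.random(15) < 0.8).astype(float)
        params = rng.normal(size=3)
        lp1 = log_posterior(params, X, y)
        lp2 = log_posterior(params, np.vstack([X, X]), np.concatenate([y, y]))
        prior = log_posterior(params, np.zeros((0, 3)), np.zeros(0))
        assert lp2 - prior == pytest.approx(2 * (lp1 - prior), rel=1e-12)

    def test_matches_naive_loop_oracle(self, rng):
        """Independently coded per-row loop agrees to 1e-10."""
        for _ in range(5):
            n, p = int(rng.integers(5, 21)), int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            y = (rng.random(n) < 0.7).astype(float)
            params = rng.normal(size=p)
            naive = 0.0
            for i in range(n):
                eta = sum(X[i, j] * params[j] for j in range(p))
                phi = 1.0 / (1.0 + np.exp(-eta))
                naive += y[i] * np.log(phi) + (1 - y[i]) * np.log(1 - phi)
            for j in range(p):
                naive += (
                    0.5 * np.log(PRIOR_PREC / (2 * np.pi))
                    - 0.5 * PRIOR_PREC * params[j] ** 2
                )
            assert log_posterior(params, X, y) == pytest.approx(naive, abs=1e-10)

    def test_nonfinite_covariates_rejected(self):
        X = np.array([[1.0, np.inf]])
        with pytest.raises(ValueError):
            log_posterior(np.zeros(2), X, np.ones(1))


class TestRunMcmc:
    def test_conjugate_beta_oracle(self):
        """Intercept-only posterior of daily survival matches Beta(s+1, f+1)."""
        y = np.concatenate([np.ones(300), np.zeros(20)])
        X = np.ones((320, 1))
        chains = run_mcmc(X, y, McmcConfig.nest_default(seed=5))
        phi = expit(chains.pooled("b0"))
        for q in (0.025, 0.5, 0.975):
            assert np.quantile(phi, q) == pytest.approx(
                beta_dist.ppf(q, 301, 21), abs=0.01
            )

    def test_same_seed_identical_draws(self):
        y = np.concatenate([np.ones(40), np.zeros(5)])
        X = np.ones((45, 1))
        cfg = McmcConfig(n_iter=500, burn_in=100, seed=9)
        a = run_mcmc(X, y, cfg)
        b = run_mcmc(X, y, cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_burn_in_and_thinning_shape(self):
        y = np.ones(20)
        X = np.ones((20, 1))
        cfg = McmcConfig(n_chains=2, n_iter=1000, burn_in=400, thin=3, seed=1)
        chains = run_mcmc(X, y, cfg)
        assert chains.draws.shape == (2, 200, 1)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            run_mcmc(np.empty((0, 1)), np.empty(0), McmcConfig(n_iter=10, burn_in=1))

    def test_complete_separation_stays_proper(self):
        """The proper prior keeps an all-survival dataset sampleable."""
        y = np.ones(50)
        X = np.ones((50, 1))
        chains = run_mcmc(X, y, McmcConfig(n_iter=2000, burn_in=500, seed=3))
        draws = chains.pooled("b0")
        assert np.all(np.isfinite(draws))
        # posterior concentrates on large positive values bounded by the prior
        assert np.median(draws) > 1.0
        assert np.std(draws) < 60.0


class TestGelmanRubin:
    def test_identical_chains_near_one(self, rng):
        one = rng.normal(size=(1, 500, 2))
        chains = np.repeat(one, 3, axis=0)
        assert np.all(gelman_rubin(chains) <= 1.001)

    def test_disjoint_plateaus_diverge(self):
        chains = np.stack([np.zeros((200, 1)), np.full((200, 1), 10.0)])
        chains = chains + np.random.default_rng(0).normal(0, 0.1, chains.shape)
        assert gelman_rubin(chains)[0] > 5.0

    def test_well_mixed_below_threshold(self, rng):
        chains = rng.normal(size=(3, 1000, 4))
        assert np.all(gelman_rubin(chains) < 1.1)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.normal(size=(1, 100, 1)))


def _exposure_frame(rng, n_nests=40, re=True):
    rows = []
    for i in range(n_nests):
        site = f"S{i % 3}"
        year = 2016 + (i % 2)
        for j in range(1, 11):
            rows.append({
                "nest_id": f"N{i}", "site": site, "year": year,
                "attempt": 1 + (i % 2), "concealment": rng.normal(90, 40),
                "distance": rng.gamma(2, 150), "duration": rng.integers(0, 6),
                "recesses": rng.integers(0, 3), "nest_age": j,
                "nest_alive": 1, "female_alive": 1,
            })
    df = pd.DataFrame(rows)
    # sprinkle failures
    idx = rng.choice(len(df), 25, replace=False)
    df.loc[idx, "nest_alive"] = 0
    return df


class TestDailySurvivalModel:
    def test_design_matrix_structure(self, rng):
        df = _exposure_frame(rng)
        model = DailySurvivalModel.from_dataframe(df, outcome="nest")
        names = model.param_names
        assert names[0] == "intercept"
        assert names[1:7] == list(ModelSpec.nest().fixed)
        assert sum(c.startswith("year[") for c in names) == 2
        assert sum(c.startswith("site[") for c in names) == 6
        # site-within-year: indicator columns partition the rows
        site_cols = [j for j, c in enumerate(names) if c.startswith("site[")]
        assert np.allclose(model.exog[:, site_cols].sum(axis=1), 1.0)

    def test_site_labels_permutable_within_year(self, rng):
        """Site levels are (site, year) pairs: permuting site labels within a
        year relabels columns but leaves the likelihood surface invariant."""
        df = _exposure_frame(rng)
        spec = ModelSpec.nest()
        X1, y1, n1 = build_design(df, spec)
        swapped = df.copy()
        mask = swapped.year == 2016
        swapped.loc[mask, "site"] = swapped.loc[mask, "site"].map(
            {"S0": "S1", "S1": "S0", "S2": "S2"}
        )
        X2, y2, n2 = build_design(swapped, spec)
        params = np.random.default_rng(1).normal(size=X1.shape[1])
        perm = [n2.index(c) if c in n2 else None for c in n1]
        # map params of design 1 onto permuted columns of design 2
        mapping = {c: c for c in n1}
        mapping.update({
            "site[S0:2016]": "site[S1:2016]", "site[S1:2016]": "site[S0:2016]"
        })
        params2 = np.empty_like(params)
        for k, c in enumerate(n1):
            params2[n2.index(mapping[c])] = params[k]
        assert log_posterior(params, X1, y1) == pytest.approx(
            log_posterior(params2, X2, y2), rel=1e-12
        )

    def test_fold_random_effects_preserves_linear_predictor(self, rng):
        df = _exposure_frame(rng)
        model = DailySurvivalModel.from_dataframe(df, outcome="nest")
        draws = rng.normal(size=(2, 50, len(model.param_names)))
        folded = _fold_random_effects(draws, model.param_names)
        eta_raw = draws @ model.exog.T
        eta_folded = folded @ model.exog.T
        assert np.allclose(eta_raw, eta_folded, atol=1e-10)

    def test_fit_returns_converged_results(self, rng):
        df = _exposure_frame(rng)
        model = DailySurvivalModel.from_dataframe(df, outcome="nest")
        res = model.fit(McmcConfig(n_chains=2, n_iter=1500, burn_in=500, seed=4))
        table = res.summary()
        assert {"mean", "pd", "rhat"} <= set(table.columns)
        assert "duration" in table.index
        manifest = res.manifest()
        assert manifest["mcmc"]["n_iter"] == 1500
        assert manifest["outcome"] == "nest"

    def test_inference_data_and_curve_plot(self, rng, tmp_path):
        df = _exposure_frame(rng)
        model = DailySurvivalModel.from_dataframe(df, outcome="nest")
        res = model.fit(McmcConfig(n_chains=2, n_iter=800, burn_in=300, seed=8))
        idata = res.to_inference_data()
        assert idata.posterior["duration"].shape == (2, 167)
        # arviz as independent cross-check of our HDI implementation
        import arviz as az
        from nestsurv import posterior as post
        draws = res.draws("duration")
        ours = post.hdi(draws, 0.94)
        theirs = az.hdi(draws, hdi_prob=0.94)
        assert ours[0] == pytest.approx(theirs[0], abs=0.02)
        assert ours[1] == pytest.approx(theirs[1], abs=0.02)
        out = tmp_path / "curves.png"
        res.plot_predicted_period_curves(names=["duration"], path=out)
        assert out.stat().st_size > 0

    def test_intercept_only_period_variant(self, rng):
        df = _exposure_frame(rng)
        model = DailySurvivalModel.intercept_only(df, outcome="nest")
        assert model.param_names == ["intercept"]
        res = model.fit(McmcConfig(n_chains=2, n_iter=1500, burn_in=500, seed=4))
        ps = res.period_survival(n_days=30)
        daily = res.daily_survival_draws()
        assert 0 < ps.mean < 1
        assert ps.mean == pytest.approx(np.mean(daily**30), rel=1e-9)
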