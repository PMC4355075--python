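"""Tests for the sampler, convergence diagnostics, DIC and summaries."""

import numpy as np
import pytest

from lakelevel import (
    McmcSettings,
    PriorSpec,
    SimulationSpec,
    dic,
    fit_model,
    heidelberger_stationarity,
    posterior_summary,
    run_chains,
    simulate_series,
)
from lakelevel.mcmc import PosteriorDraws
from lakelevel.model import ModelParams, log_likelihood


def batch_se(x, n_batches=40):
    """Monte-Carlo standard error of the mean by batch means."""
    x = np.asarray(x)
    m = len(x) // n_batches
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)


def _tiny_series(n=60, seed=0):
    series, _ = simulate_series(SimulationSpec(n_months=n, missing_rate=0.0, seed=seed))
    return series


class TestSampler:
    def test_prior_only_run_recovers_seasonal_period_prior(self):
        """With the likelihood switched off the P1 marginal must be the
        U(6, 18) prior: bounds respected, mean 12 within 3 MC SEs."""
        series = _tiny_series()
        prior = PriorSpec(K=1, n_months=series.n_months)
        settings = McmcSettings(n_iter=30_000, burn_in=5_000, thin=5, n_chains=1, seed=8, escalate=False)
        draws = run_chains(series, prior, settings, use_likelihood=False)[0]
        p1 = draws.params["period1"]
        assert p1.min() >= 6.0 and p1.max() <= 18.0
        assert abs(p1.mean() - 12.0) < 3 * batch_se(p1)

    def test_prior_only_moments_match_known_target(self):
        """Detailed-balance smoke test on a target with known moments:
        unit-variance normal coefficients, uniform AR and period."""
        series = _tiny_series()
        prior = PriorSpec(K=1, n_months=series.n_months, coef_precision=1.0)
        for seed in range(5):
            settings = McmcSettings(n_iter=30_000, burn_in=5_000, thin=5, n_chains=1, seed=seed, escalate=False)
            d = run_chains(series, prior, settings, use_likelihood=False)[0]
            for name, mean, sd in [
                ("beta0", 0.0, 1.0),
                ("beta_ar", 0.0, np.sqrt(1.0 / 3.0)),
                ("period1", 12.0, np.sqrt(12.0)),
            ]:
                x = d.params[name]
                assert abs(x.mean() - mean) < 3 * batch_se(x), (seed, name)
                assert x.std() == pytest.approx(sd, rel=0.25), (seed, name)

    def test_same_seed_identical_draws(self):
        series = _tiny_series()
        prior = PriorSpec(K=1, n_months=series.n_months)
        settings = McmcSettings(n_iter=2_000, burn_in=500, thin=5, n_chains=2, seed=4, escalate=False)
        a = run_chains(series, prior, settings)
        b = run_chains(series, prior, settings)
        for ch_a, ch_b in zip(a, b):
            for nm in ch_a.params:
                np.testing.assert_array_equal(ch_a.params[nm], ch_b.params[nm])

    def test_retained_draws_respect_parameter_supports(self):
        spec = SimulationSpec(n_months=120, seed=21)
        series, _ = simulate_series(spec)
        prior = PriorSpec(K=1, n_months=series.n_months)
        settings = McmcSettings(n_iter=4_000, burn_in=1_000, thin=5, n_chains=1, seed=2, escalate=False)
        d = run_chains(series, prior, settings)[0]
        assert np.all((d.params["beta_ar"] > -1) & (d.params["beta_ar"] < 1))
        assert np.all((d.params["period1"] > 6) & (d.params["period1"] < 18))
        assert np.all(d.params["shape"] > 0)
        assert np.all(d.latent > 0)


class TestImputation:
    def test_latent_months_track_hidden_truth(self):
        """MCAR-deleted months are recovered by their posterior means and
        covered by their 95% intervals at roughly nominal rate."""
        truths, post_means, covered = [], [], []
        for rep in range(12):
            spec = SimulationSpec(n_months=360, missing_rate=0.05, seed=7000 + rep)
            series, _ = simulate_series(spec)
            missing = ~series.observed
            if missing.sum() == 0:
                continue
            settings = McmcSettings(n_iter=8_000, burn_in=2_000, thin=5, n_chains=1, seed=rep, escalate=False)
            prior = PriorSpec(K=1, n_months=series.n_months)
            d = run_chains(series, prior, settings)[0]
            truth = series.hidden_truth[missing]
            lat = d.latent  # (n_retained, n_missing)
            truths.extend(truth)
            post_means.extend(lat.mean(axis=0))
            lo = np.quantile(lat, 0.025, axis=0)
            hi = np.quantile(lat, 0.975, axis=0)
            covered.extend((lo <= truth) & (truth <= hi))
        assert len(truths) >= 150
        r = np.corrcoef(truths, post_means)[0, 1]
        assert r > 0.9
        coverage = 100.0 * np.mean(covered)
        assert 85.0 <= coverage <= 99.0


class TestHeidelbergerWelch:
    def test_type_one_error_on_iid_draws(self):
        passes = 0
        rng = np.random.default_rng(0)
        for _ in range(100):
            if heidelberger_stationarity(rng.standard_normal(5000)).passed:
                passes += 1
        assert passes >= 90

    def test_linear_drift_fails(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 10, 5000) + 0.1 * rng.standard_normal(5000)
        assert not heidelberger_stationarity(x).passed

    def test_constant_sequence_passes_degenerately(self):
        res = heidelberger_stationarity(np.full(500, 3.14))
        assert res.passed

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            heidelberger_stationarity(np.random.default_rng(0).standard_normal(50))


def _constant_draws(series, value_dict, n=200):
    params = {nm: np.full(n, v) for nm, v in value_dict.items()}
    return PosteriorDraws(
        chain=0, params=params, latent=np.empty((n, 0)),
        acceptance={}, n_iter=n, burn_in=0, thin=1,
    )


class TestDic:
    def test_degenerate_chain_has_zero_pd(self):
        series = _tiny_series(n=40)
        vals = {"beta0": 1.0, "beta1": 0.0, "beta_ar": 0.0, "shape": 5.0}
        draws = _constant_draws(series, vals)
        d, p_d = dic([draws], series)
        d_plug, p_d_plug = dic([draws], series, method="plugin")
        assert (d_plug, p_d_plug) == pytest.approx((d, p_d))
        params = ModelParams(beta0=1.0, beta1=0.0, beta_ar=0.0, alphas=[], rhos=[], periods=[], shape=5.0)
        expected = -2.0 * log_likelihood(series, params)
        assert p_d == pytest.approx(0.0, abs=1e-8)
        assert d == pytest.approx(expected)

    def test_agrees_with_brute_force_recomputation(self):
        spec = SimulationSpec(n_months=80, missing_rate=0.0, seed=3)
        series, _ = simulate_series(spec)
        settings = McmcSettings(n_iter=2_000, burn_in=500, thin=10, n_chains=1, seed=5, escalate=False)
        prior = PriorSpec(K=1, n_months=series.n_months)
        draws = run_chains(series, prior, settings)
        d_var, p_var = dic(draws, series)
        d_val, p_d = dic(draws, series, method="plugin")
        # independent recomputation straight from the draw vectors
        devs = []
        ch = draws[0]
        for i in range(ch.n_retained):
            p = ModelParams(
                beta0=ch.params["beta0"][i], beta1=ch.params["beta1"][i],
                beta_ar=ch.params["beta_ar"][i],
                alphas=[ch.params["alpha1"][i]], rhos=[ch.params["rho1"][i]],
                periods=[ch.params["period1"][i]], shape=ch.params["shape"][i],
            )
            devs.append(-2.0 * log_likelihood(series, p, month_mask=series.observed))
        mean_dev = np.mean(devs)
        p_mean = ModelParams(
            beta0=ch.params["beta0"].mean(), beta1=ch.params["beta1"].mean(),
            beta_ar=ch.params["beta_ar"].mean(),
            alphas=[ch.params["alpha1"].mean()], rhos=[ch.params["rho1"].mean()],
            periods=[ch.params["period1"].mean()], shape=ch.params["shape"].mean(),
        )
        d_hat = -2.0 * log_likelihood(series, p_mean, month_mask=series.observed)
        assert d_val == pytest.approx(2 * mean_dev - d_hat, rel=1e-10)
        assert p_d == pytest.approx(mean_dev - d_hat, rel=1e-10)
        assert p_var == pytest.approx(np.var(devs, ddof=1) / 2.0, rel=1e-10)
        assert d_var == pytest.approx(mean_dev + p_var, rel=1e-10)

    def test_seasonal_harmonic_beats_null_by_large_margin(self):
        """On strongly seasonal data the seasonal model's DIC improves on
        the no-harmonic null by far more than the competing threshold."""
        spec = SimulationSpec(n_months=240, seed=31)
        series, _ = simulate_series(spec)
        st = dict(n_iter=6_000, burn_in=1_500, thin=5, n_chains=1, escalate=False)
        f0 = fit_model(series, 0, McmcSettings(seed=1, **st))
        f1 = fit_model(series, 1, McmcSettings(seed=2, **st))
        assert f0.dic - f1.dic > 100.0

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            dic([], _tiny_series(n=40))


class TestPosteriorSummary:
    def test_constant_draws(self):
        d = _constant_draws(None, {"beta0": 2.0, "period1": 12.0})
        summary, modes = posterior_summary([d])
        assert summary["beta0"] == (2.0, 2.0, 2.0)
        assert modes["period1"] == 12.0

    def test_quantiles_match_sorted_draws(self):
        rng = np.random.default_rng(12)
        x = rng.gamma(3.0, 2.0, size=4000)
        d = PosteriorDraws(chain=0, params={"beta0": x}, latent=np.empty((len(x), 0)),
                           acceptance={}, n_iter=0, burn_in=0, thin=1)
        summary, _ = posterior_summary([d])
        mean, lo, hi = summary["beta0"]
        s = np.sort(x)
        assert lo == pytest.approx(np.quantile(s, 0.025))
        assert hi == pytest.approx(np.quantile(s, 0.975))
        assert mean == pytest.approx(x.mean())

    def test_uniform_draws_summary(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(6, 18, size=20_000)
        d = PosteriorDraws(chain=0, params={"period1": x}, latent=np.empty((len(x), 0)),
                           acceptance={}, n_iter=0, burn_in=0, thin=1)
        summary, modes = posterior_summary([d])
        _, lo, hi = summary["period1"]
        assert lo == pytest.approx(6.3, abs=0.1)
        assert hi == pytest.approx(17.7, abs=0.1)
        assert 6.0 <= modes["period1"] <= 18.0
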