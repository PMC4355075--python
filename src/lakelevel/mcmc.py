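"""Metropolis-within-Gibbs sampler for the harmonic regression model.

One sweep updates, in order: the (beta0, beta1) block, beta_ar, each
amplitude pair (alpha_k, rho_k), each period P_k, the gamma shape r, and
every latent missing month.  All proposals are Gaussian random walks;
periods reflect at their prior bounds, and the shape and latent levels
walk on the log scale (with the Jacobian in the acceptance ratio).
Proposal scales adapt toward a 20-40% acceptance rate during burn-in only
and are frozen afterwards, preserving detailed balance for the retained
draws.  Missing months are unknowns of the posterior: their gamma terms
stay in the target and their values feed the AR term of the next month.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import kv, gammaln
from scipy.stats import gaussian_kde

from .model import (
    ModelParams,
    PriorSpec,
    complete_values,
    deterministic_eta,
    log_likelihood,
    log_prior,
)

__all__ = [
    "McmcSettings",
    "PosteriorDraws",
    "FitSummary",
    "HeidelbergerResult",
    "run_chains",
    "fit_model",
    "dic",
    "posterior_summary",
    "heidelberger_stationarity",
]


@dataclass
class McmcSettings:
    """Chain lengths and sampler controls.

    Defaults follow the fitting protocol of the analysis: two chains of
    1e5 iterations, 1e4 burn-in, thinning of 10, escalating once to 10x
    the iterations if the Heidelberger-Welch diagnostic fails.  Tests and
    quick looks pass smaller numbers explicitly.
    """

    n_iter: int = 100_000
    burn_in: int = 10_000
    thin: int = 10
    n_chains: int = 2
    seed: int = 0
    adapt_interval: int = 50
    target_low: float = 0.2
    target_high: float = 0.4
    escalate: bool = True
    escalate_factor: int = 10

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.burn_in < 0 or self.thin <= 0 or self.n_chains <= 0:
            raise ValueError("iteration settings must be positive")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Retained samples of one chain, post burn-in and thinning."""

    chain: int
    params: dict[str, np.ndarray]
    latent: np.ndarray  # (n_retained, n_missing)
    acceptance: dict[str, float]
    n_iter: int
    burn_in: int
    thin: int

    @property
    def n_retained(self) -> int:
        return len(next(iter(self.params.values())))

    def param_names(self) -> list[str]:
        return list(self.params.keys())


@dataclass
class HeidelbergerResult:
    passed: bool
    start_index: int
    pvalue: float


@dataclass
class FitSummary:
    """Per-model fit record: DIC, parameter summaries, convergence flags."""

    K: int
    dic: float
    p_d: float
    mean_deviance: float
    params: dict[str, tuple[float, float, float]]  # mean, 2.5%, 97.5%
    converged: bool
    convergence: dict[str, bool]
    period_modes: dict[str, float]
    n_iter_used: int
    draws: list[PosteriorDraws] = field(repr=False, default_factory=list)


def _param_names(K: int) -> list[str]:
    names = ["beta0", "beta1", "beta_ar"]
    for k in range(1, K + 1):
        names += [f"alpha{k}", f"rho{k}"]
    names += [f"period{k}" for k in range(1, K + 1)]
    names.append("shape")
    return names


# share of period proposals drawn fresh from the uniform prior rather
# than by random walk; enables mode-hopping across multimodal period
# posteriors
PERIOD_JUMP_PROB = 0.25


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a proposal back into (lo, hi) by reflection at the bounds."""
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    if y < 0:
        y += 2.0 * width
    return lo + (y if y <= width else 2.0 * width - y)


class _Block:
    """A Metropolis block with an adaptive scalar scale multiplier."""

    __slots__ = ("name", "scale", "accepts", "attempts", "win_accepts", "win_attempts")

    def __init__(self, name: str, scale: float = 1.0):
        self.name = name
        self.scale = scale
        self.accepts = 0
        self.attempts = 0
        self.win_accepts = 0
        self.win_attempts = 0

    def record(self, accepted: bool, in_window: bool = True) -> None:
        self.attempts += 1
        if accepted:
            self.accepts += 1
        if in_window:
            self.win_attempts += 1
            if accepted:
                self.win_accepts += 1

    def adapt(self, low: float, high: float) -> None:
        if self.win_attempts == 0:
            return
        rate = self.win_accepts / self.win_attempts
        if rate > high:
            self.scale *= 1.4
        elif rate < low:
            self.scale /= 1.4
        self.win_accepts = 0
        self.win_attempts = 0

    @property
    def rate(self) -> float:
        return self.accepts / self.attempts if self.attempts else float("nan")


def _initial_params(prior: PriorSpec, series, chain: int, n_chains: int) -> ModelParams:
    """Starting state: zero coefficients, unit shape, latent months at
    the series median, periods over-dispersed across chains at prior
    quantiles (0.25 / 0.75) to expose multimodal period posteriors."""
    if n_chains == 1:
        q = 0.5
    else:
        q = 0.25 + 0.5 * (chain / (n_chains - 1))
    periods = np.array([lo + q * (hi - lo) for lo, hi in prior.period_bounds])
    n_missing = int((~series.observed).sum())
    med = float(np.median(series.values[series.observed])) if series.observed.any() else 1.0
    return ModelParams(
        beta0=0.0,
        beta1=0.0,
        beta_ar=0.0,
        alphas=np.zeros(prior.K),
        rhos=np.zeros(prior.K),
        periods=periods,
        shape=1.0,
        latent=np.full(n_missing, med),
    )


def _run_single_chain(
    series,
    prior: PriorSpec,
    settings: McmcSettings,
    chain: int,
    use_likelihood: bool = True,
) -> PosteriorDraws:
    rng = np.random.default_rng((settings.seed, chain))
    K = prior.K
    params = _initial_params(prior, series, chain, settings.n_chains)
    missing_idx = np.flatnonzero(~series.observed)
    n_missing = len(missing_idx)
    n = series.n_months

    def loglik(p: ModelParams) -> float:
        return log_likelihood(series, p) if use_likelihood else 0.0

    cur_lp = log_prior(params, prior)
    cur_ll = loglik(params)
    if not np.isfinite(cur_lp + cur_ll):
        raise RuntimeError("could not find a finite-posterior initial state")

    # base proposal standard deviations per block component
    blocks = {"coef": _Block("coef"), "beta_ar": _Block("beta_ar"), "shape": _Block("shape")}
    base = {"coef": np.array([0.05, 2e-4]), "beta_ar": 0.05, "shape": 0.3}
    for k in range(1, K + 1):
        blocks[f"amp{k}"] = _Block(f"amp{k}")
        base[f"amp{k}"] = 0.02
        lo, hi = prior.period_bounds[k - 1]
        blocks[f"period{k}"] = _Block(f"period{k}")
        base[f"period{k}"] = (hi - lo) / 50.0
    if use_likelihood and n_missing:
        blocks["latent"] = _Block("latent")
        base["latent"] = 0.05

    names = _param_names(K)
    n_ret = settings.n_retained
    out = {nm: np.empty(n_ret) for nm in names}
    out_latent = np.empty((n_ret, n_missing))
    ret = 0

    def try_block(block: _Block, mutate, log_jacobian: float = 0.0, adapt_on: bool = True) -> None:
        """Generic Metropolis step: ``mutate`` edits a copy of params."""
        nonlocal params, cur_lp, cur_ll
        prop = params.copy()
        mutate(prop)
        lp = log_prior(prop, prior)
        if not np.isfinite(lp):
            block.record(False, in_window=adapt_on)
            return
        ll = loglik(prop)
        log_ratio = (lp + ll) - (cur_lp + cur_ll) + log_jacobian
        if np.log(rng.random()) < log_ratio:
            params, cur_lp, cur_ll = prop, lp, ll
            block.record(True, in_window=adapt_on)
        else:
            block.record(False, in_window=adapt_on)

    for it in range(1, settings.n_iter + 1):
        b = blocks["coef"]
        step = b.scale * base["coef"] * rng.standard_normal(2)

        def mut_coef(p, step=step):
            p.beta0 += step[0]
            p.beta1 += step[1]

        try_block(b, mut_coef)

        b = blocks["beta_ar"]
        step_ar = b.scale * base["beta_ar"] * rng.standard_normal()
        try_block(b, lambda p, s=step_ar: setattr(p, "beta_ar", p.beta_ar + s))

        for k in range(K):
            b = blocks[f"amp{k + 1}"]
            step2 = b.scale * base[f"amp{k + 1}"] * rng.standard_normal(2)

            def mut_amp(p, k=k, s=step2):
                p.alphas[k] += s[0]
                p.rhos[k] += s[1]

            try_block(b, mut_amp)

            b = blocks[f"period{k + 1}"]
            lo, hi = prior.period_bounds[k]
            # mixture kernel: mostly a reflective random walk, sometimes an
            # independence draw from the uniform prior so the chain can hop
            # between well-separated period modes (both components are
            # symmetric; only the walk feeds the scale adaptation)
            is_jump = rng.random() < PERIOD_JUMP_PROB
            if is_jump:
                newp = lo + (hi - lo) * rng.random()
            else:
                pstep = b.scale * base[f"period{k + 1}"] * rng.standard_normal()
                newp = _reflect(params.periods[k] + pstep, lo, hi)

            def mut_per(p, k=k, v=newp):
                p.periods[k] = v

            try_block(b, mut_per, adapt_on=not is_jump)

        b = blocks["shape"]
        fac = np.exp(np.clip(b.scale * base["shape"] * rng.standard_normal(), -50.0, 50.0))
        try_block(
            b,
            lambda p, f=fac: setattr(p, "shape", p.shape * f),
            log_jacobian=np.log(fac),
        )

        # latent missing months: single-site moves touching only the two
        # gamma terms each latent value enters (its own and the next
        # month's AR feed)
        if use_likelihood and n_missing:
            b = blocks["latent"]
            vals = complete_values(series, params.latent)
            det = np.asarray(deterministic_eta(params, np.arange(1, n + 1)), dtype=float)
            r = params.shape
            bar = params.beta_ar
            lgr = float(gammaln(r))
            log_r = math.log(r)

            def gdens(w: float, log_mu: float) -> float:
                # scalar gamma log density, shape r, mean exp(log_mu)
                return r * (log_r - log_mu) + (r - 1.0) * math.log(w) - r * w * math.exp(-log_mu) - lgr

            for j, i in enumerate(missing_idx):
                w = vals[i]
                w_new = w * math.exp(b.scale * base["latent"] * rng.standard_normal())

                def local(wv: float) -> float:
                    log_mu_i = det[i] + (bar * math.log(vals[i - 1]) if i > 0 else 0.0)
                    t = gdens(wv, log_mu_i)
                    if i + 1 < n:
                        t += gdens(vals[i + 1], det[i + 1] + bar * math.log(wv))
                    return t

                delta = local(w_new) - local(w)
                log_ratio = delta + (math.log(w_new) - math.log(w))
                if np.log(rng.random()) < log_ratio:
                    vals[i] = w_new
                    params.latent[j] = w_new
                    cur_ll += delta  # exact: only these two terms change
                    b.record(True)
                else:
                    b.record(False)

        if it <= settings.burn_in and it % settings.adapt_interval == 0:
            for blk in blocks.values():
                blk.adapt(settings.target_low, settings.target_high)

        if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            vec = [params.beta0, params.beta1, params.beta_ar]
            for k in range(K):
                vec += [params.alphas[k], params.rhos[k]]
            vec += list(params.periods)
            vec.append(params.shape)
            for nm, v in zip(names, vec):
                out[nm][ret] = v
            if n_missing:
                out_latent[ret] = params.latent
            ret += 1

    return PosteriorDraws(
        chain=chain,
        params=out,
        latent=out_latent,
        acceptance={nm: blk.rate for nm, blk in blocks.items()},
        n_iter=settings.n_iter,
        burn_in=settings.burn_in,
        thin=settings.thin,
    )


def run_chains(
    series,
    prior: PriorSpec,
    settings: McmcSettings,
    use_likelihood: bool = True,
) -> list[PosteriorDraws]:
    """Run ``settings.n_chains`` independent chains; deterministic in seed.

    ``use_likelihood=False`` samples the prior alone (latent months are
    then left untouched) — useful for validating the sampler against the
    known prior distributions.
    """
    if not prior.feasible:
        raise ValueError("a period prior band is empty for this series length")
    return [
        _run_single_chain(series, prior, settings, chain, use_likelihood)
        for chain in range(settings.n_chains)
    ]


# ---------------------------------------------------------------------------
# Convergence diagnostics


def _spectrum0_ar(y: np.ndarray) -> float:
    """Spectral density of ``y`` at frequency zero via an AIC-chosen AR fit.

    s(0) = sigma^2 / (1 - sum(phi))^2; order 0 reduces to the sample
    variance.  A near-unit-root fit (sum of AR coefficients >= 0.97)
    means the integrated autocorrelation time is effectively unbounded on
    this window — the estimate is returned as inf, which the
    stationarity test treats as a failure.
    """
    from statsmodels.regression.linear_model import yule_walker

    y = np.asarray(y, dtype=float)
    m = len(y)
    v = float(np.var(y, ddof=1))
    if v == 0.0:
        return 0.0
    max_order = min(int(10.0 * np.log10(m)), m - 2, 30)
    best_aic = m * np.log(v)
    best = v
    yc = y - y.mean()
    for p in range(1, max_order + 1):
        try:
            rho, sigma = yule_walker(yc, order=p, method="mle")
        except Exception:
            break
        sigma2 = float(sigma**2)
        if sigma2 <= 0:
            continue
        aic = m * np.log(sigma2) + 2.0 * p
        if aic < best_aic:
            best_aic = aic
            phi_sum = float(np.sum(rho))
            denom = (1.0 - phi_sum) ** 2
            best = sigma2 / denom if phi_sum < 0.97 else np.inf
    return best


def _pcramer(q: float, eps: float = 1e-5) -> float:
    """CDF of the asymptotic Cramer-von Mises distribution at q."""
    if q <= 0:
        return 0.0
    total = 0.0
    for k in range(4):
        z = gamma_fn(k + 0.5) * np.sqrt(4 * k + 1) / (gamma_fn(k + 1) * np.pi**1.5 * np.sqrt(q))
        u = (4 * k + 1) ** 2 / (16.0 * q)
        if u <= -np.log(eps):
            total += z * np.exp(-u) * kv(0.25, u)
    return float(min(max(total, 0.0), 1.0))


def gamma_fn(x: float) -> float:
    return float(np.exp(gammaln(x)))


def heidelberger_stationarity(
    draws: np.ndarray, alpha: float = 0.05
) -> HeidelbergerResult:
    """Heidelberger-Welch stationarity test for one parameter's chain.

    A Cramer-von Mises statistic on the standardised cumulative-sum
    (Brownian bridge) of the draws, with the spectral density at zero
    estimated from the second half of the chain; the initial 10%, 20%,
    ... up to 50% of draws are discarded in turn until the remaining
    window passes at level ``alpha``.  A constant sequence passes
    trivially (nothing to reject).
    """
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 retained draws")
    if np.ptp(x) == 0.0:
        return HeidelbergerResult(True, 0, 1.0)
    s0 = _spectrum0_ar(x[n // 2 :])
    if s0 == 0.0:
        return HeidelbergerResult(True, 0, 1.0)
    if not np.isfinite(s0):
        # near-unit-root AR fit: the chain is drifting, not stationary
        return HeidelbergerResult(False, n // 2, 0.0)
    pval = 0.0
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        start = int(frac * n)
        y = x[start:]
        m = len(y)
        bridge = np.cumsum(y) - y.mean() * np.arange(1, m + 1)
        cvm = float(np.sum(bridge**2) / (m * m * s0))
        pval = 1.0 - _pcramer(cvm)
        if pval > alpha:
            return HeidelbergerResult(True, start, pval)
    return HeidelbergerResult(False, n // 2, pval)


# ---------------------------------------------------------------------------
# DIC and posterior summaries


def _params_from_draw(draws: PosteriorDraws, idx: int, K: int) -> ModelParams:
    g = draws.params
    return ModelParams(
        beta0=g["beta0"][idx],
        beta1=g["beta1"][idx],
        beta_ar=g["beta_ar"][idx],
        alphas=np.array([g[f"alpha{k}"][idx] for k in range(1, K + 1)]),
        rhos=np.array([g[f"rho{k}"][idx] for k in range(1, K + 1)]),
        periods=np.array([g[f"period{k}"][idx] for k in range(1, K + 1)]),
        shape=g["shape"][idx],
        latent=draws.latent[idx] if draws.latent.size else np.empty(0),
    )


def dic(draws: list[PosteriorDraws], series, method: str = "variance") -> tuple[float, float]:
    """Deviance information criterion and effective parameter count pD.

    D(theta) = -2 * log-likelihood over the *observed* months, with that
    draw's latent values feeding the AR terms.  DIC = mean deviance + pD.

    ``method="variance"`` (default) uses pD = var(D)/2, the half-variance
    estimator; ``method="plugin"`` uses pD = mean deviance - deviance at
    the posterior mean (parameters and latent values plugged in at their
    posterior means).  The plug-in form is classical but ill-behaved when
    a period posterior is multimodal: the posterior mean of the period
    then falls between modes, making D(theta_bar) — and hence pD, which
    can even go negative — an artefact of where that meaningless point
    lands.  The half-variance form only needs the deviance trace and is
    what common Gibbs-sampler front-ends report.
    """
    if not draws or draws[0].n_retained == 0:
        raise ValueError("no retained draws")
    if method not in ("variance", "plugin"):
        raise ValueError("method must be 'variance' or 'plugin'")
    K = sum(1 for nm in draws[0].params if nm.startswith("period"))
    mask = series.observed
    devs = []
    for ch in draws:
        for i in range(ch.n_retained):
            p = _params_from_draw(ch, i, K)
            devs.append(-2.0 * log_likelihood(series, p, month_mask=mask))
    mean_dev = float(np.mean(devs))

    if method == "variance":
        p_d = float(np.var(devs, ddof=1) / 2.0) if len(devs) > 1 else 0.0
        return mean_dev + p_d, p_d

    names = draws[0].param_names()
    pooled = {nm: np.concatenate([ch.params[nm] for ch in draws]) for nm in names}
    lat = (
        np.concatenate([ch.latent for ch in draws], axis=0)
        if draws[0].latent.size
        else np.empty((1, 0))
    )
    mean_params = ModelParams(
        beta0=pooled["beta0"].mean(),
        beta1=pooled["beta1"].mean(),
        beta_ar=pooled["beta_ar"].mean(),
        alphas=np.array([pooled[f"alpha{k}"].mean() for k in range(1, K + 1)]),
        rhos=np.array([pooled[f"rho{k}"].mean() for k in range(1, K + 1)]),
        periods=np.array([pooled[f"period{k}"].mean() for k in range(1, K + 1)]),
        shape=pooled["shape"].mean(),
        latent=lat.mean(axis=0) if lat.size else np.empty(0),
    )
    d_hat = -2.0 * log_likelihood(series, mean_params, month_mask=mask)
    p_d = mean_dev - d_hat
    return mean_dev + p_d, p_d


def posterior_summary(
    draws: list[PosteriorDraws],
) -> tuple[dict[str, tuple[float, float, float]], dict[str, float]]:
    """Pooled posterior mean and central 95% interval per parameter.

    Period marginals are additionally summarised by the mode of a
    Gaussian kernel density (the 'main peak' of the period posterior).
    """
    if not draws or draws[0].n_retained == 0:
        raise ValueError("no retained draws")
    names = draws[0].param_names()
    summary: dict[str, tuple[float, float, float]] = {}
    period_modes: dict[str, float] = {}
    for nm in names:
        pooled = np.concatenate([ch.params[nm] for ch in draws])
        lo, hi = np.quantile(pooled, [0.025, 0.975])
        summary[nm] = (float(pooled.mean()), float(lo), float(hi))
        if nm.startswith("period"):
            if np.ptp(pooled) == 0.0:
                period_modes[nm] = float(pooled[0])
            else:
                kde = gaussian_kde(pooled)
                grid = np.linspace(pooled.min(), pooled.max(), 512)
                period_modes[nm] = float(grid[np.argmax(kde(grid))])
    return summary, period_modes


_MONITORED_PREFIXES = ("beta1", "period", "shape")


def fit_model(
    series,
    K: int,
    settings: McmcSettings,
    coef_prior: str = "precision",
    dic_method: str = "variance",
) -> FitSummary:
    """Fit the K-harmonic model: chains, convergence check, DIC, summary.

    If any monitored parameter (trend, periods, shape) fails the
    Heidelberger-Welch test in any chain, the fit is rerun once at
    ``escalate_factor`` times the iterations (when escalation is
    enabled); the convergence flags of the final run are reported.
    """
    prior = PriorSpec(K=K, n_months=series.n_months, coef_prior=coef_prior)
    settings_used = settings
    for attempt in range(2):
        draws = run_chains(series, prior, settings_used)
        convergence: dict[str, bool] = {}
        for nm in draws[0].param_names():
            if not nm.startswith(_MONITORED_PREFIXES):
                continue
            ok = all(
                heidelberger_stationarity(ch.params[nm]).passed for ch in draws
            )
            convergence[nm] = ok
        converged = all(convergence.values())
        if converged or not settings.escalate or attempt == 1:
            break
        settings_used = McmcSettings(
            n_iter=settings.n_iter * settings.escalate_factor,
            burn_in=settings.burn_in,
            thin=settings.thin,
            n_chains=settings.n_chains,
            seed=settings.seed,
            adapt_interval=settings.adapt_interval,
            escalate=False,
        )
    model_dic, p_d = dic(draws, series, method=dic_method)
    summary, period_modes = posterior_summary(draws)
    return FitSummary(
        K=K,
        dic=model_dic,
        p_d=p_d,
        mean_deviance=model_dic - p_d,
        params=summary,
        converged=converged,
        convergence=convergence,
        period_modes=period_modes,
        n_iter_used=settings_used.n_iter,
        draws=draws,
    )
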