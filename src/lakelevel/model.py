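"""The harmonic regression model as pure functions of parameters and data.

The observation at month t is gamma distributed with mean exp(eta_t),

    eta_t = beta0 + beta1*t + sum_k [alpha_k cos(2 pi t / P_k)
                                     + rho_k sin(2 pi t / P_k)]
            + beta_ar * log(w_{t-1}),

where w_{t-1} is the previous month's (observed or imputed) level.  The
first month has no predecessor, so its AR term is dropped.  The gamma
distribution is parameterised by shape r and rate r/mu so its mean is mu
= exp(eta_t); r controls the (multiplicative) observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ModelParams",
    "PriorSpec",
    "harmonic_term",
    "linear_predictor",
    "deterministic_eta",
    "eta_path",
    "gamma_log_density",
    "log_likelihood",
    "log_prior",
]


@dataclass
class ModelParams:
    """All free quantities of the K-harmonic model.

    Amplitude pairs (alpha_k, rho_k) and periods P_k are stored as arrays
    of length K.  ``latent`` carries the current imputed values of the
    missing months, in series order.
    """

    beta0: float
    beta1: float
    beta_ar: float
    alphas: np.ndarray
    rhos: np.ndarray
    periods: np.ndarray
    shape: float
    latent: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.alphas = np.atleast_1d(np.asarray(self.alphas, dtype=float))
        self.rhos = np.atleast_1d(np.asarray(self.rhos, dtype=float))
        self.periods = np.atleast_1d(np.asarray(self.periods, dtype=float))
        self.latent = np.atleast_1d(np.asarray(self.latent, dtype=float)) if np.size(self.latent) else np.empty(0)
        if not (len(self.alphas) == len(self.rhos) == len(self.periods)):
            raise ValueError("alphas, rhos and periods must have equal length")

    @property
    def n_harmonics(self) -> int:
        return len(self.periods)

    def copy(self) -> "ModelParams":
        # hot path in the sampler: bypass __init__/__post_init__
        new = object.__new__(ModelParams)
        new.beta0 = self.beta0
        new.beta1 = self.beta1
        new.beta_ar = self.beta_ar
        new.alphas = self.alphas.copy()
        new.rhos = self.rhos.copy()
        new.periods = self.periods.copy()
        new.shape = self.shape
        new.latent = self.latent.copy()
        return new


# Period prior bounds per number of harmonics: the seasonal harmonic is
# U(6, 18) months; a single long-term harmonic is open up to the series
# length N; with three harmonics the long-term band splits into a
# disjoint inter-annual U(24, 132) and inter-decadal U(144, N) pair.
_PERIOD_BOUNDS = {
    0: [],
    1: [(6.0, 18.0)],
    2: [(6.0, 18.0), (24.0, None)],
    3: [(6.0, 18.0), (24.0, 132.0), (144.0, None)],
}


@dataclass
class PriorSpec:
    """Priors for a K-harmonic model on a series of N months.

    Regression coefficients (intercept, trend, harmonic amplitudes) get
    vague zero-mean normals with precision ``coef_precision`` (i.e.
    variance 1/precision, 10^6 at the default); ``coef_prior`` may be set
    to ``"variance"`` to read the same number as a variance instead.  The
    AR coefficient is uniform on (-1, 1) for stationarity, each period
    uniform on its band, and the gamma shape has a vague gamma(0.01, 0.01)
    prior.
    """

    K: int
    n_months: int
    coef_precision: float = 1e-6
    coef_prior: str = "precision"
    shape_prior: tuple[float, float] = (0.01, 0.01)
    period_bounds: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.K not in (0, 1, 2, 3):
            raise ValueError("K must be one of 0, 1, 2, 3")
        if self.coef_prior not in ("precision", "variance"):
            raise ValueError("coef_prior must be 'precision' or 'variance'")
        if not self.period_bounds:
            self.period_bounds = [
                (lo, float(self.n_months) if hi is None else hi)
                for lo, hi in _PERIOD_BOUNDS[self.K]
            ]
        for lo, hi in self.period_bounds:
            if lo <= 0:
                raise ValueError(f"period bounds ({lo}, {hi}) must be positive")
            # lo >= hi is representable (e.g. U(144, N) on a short series)
            # but flagged by `feasible` and unusable for sampling

    @property
    def coef_variance(self) -> float:
        if self.coef_prior == "precision":
            return 1.0 / self.coef_precision
        return self.coef_precision

    @property
    def feasible(self) -> bool:
        """Whether every period band is non-empty for this series length."""
        return all(lo < hi for lo, hi in self.period_bounds)


def harmonic_term(alpha: float, rho: float, period: float, t) -> np.ndarray | float:
    """alpha*cos(2*pi*t/period) + rho*sin(2*pi*t/period).

    Bounded in magnitude by sqrt(alpha**2 + rho**2); ``t`` may be a
    scalar or an array of month indices.
    """
    if period <= 0:
        raise ValueError("harmonic period must be positive")
    w = 2.0 * np.pi * np.asarray(t, dtype=float) / period
    out = alpha * np.cos(w) + rho * np.sin(w)
    return float(out) if np.isscalar(t) else out


def deterministic_eta(params: ModelParams, t) -> np.ndarray | float:
    """Trend plus harmonic part of the linear predictor (no AR term)."""
    tv = np.asarray(t, dtype=float)
    eta = params.beta0 + params.beta1 * tv
    for a, r, p in zip(params.alphas, params.rhos, params.periods):
        if p <= 0:
            raise ValueError("harmonic period must be positive")
        w = (2.0 * np.pi / p) * tv
        eta = eta + a * np.cos(w) + r * np.sin(w)
    return float(eta) if np.isscalar(t) else eta


def linear_predictor(params: ModelParams, t: int, prev_level: float | None = None) -> float:
    """eta_t for a single month; the AR term is dropped at t = 1."""
    if t < 1:
        raise ValueError("month index t is 1-based")
    eta = deterministic_eta(params, t)
    if t >= 2:
        if prev_level is None or prev_level <= 0:
            raise ValueError("prev_level must be positive for t >= 2")
        eta += params.beta_ar * np.log(prev_level)
    return float(eta)


def eta_path(params: ModelParams, levels: np.ndarray) -> np.ndarray:
    """Linear predictor for every month given the complete level vector.

    ``levels`` must have latent months filled in; entry t-1 feeds the AR
    term of month t.  Shared by the simulator and the likelihood so the
    generative and inferential model cannot drift apart.
    """
    levels = np.asarray(levels, dtype=float)
    n = len(levels)
    eta = np.asarray(deterministic_eta(params, np.arange(1, n + 1)), dtype=float)
    if n > 1:
        eta[1:] = eta[1:] + params.beta_ar * np.log(levels[:-1])
    return eta


def gamma_log_density(w, shape: float, mean) -> np.ndarray:
    """Log density of a gamma with given shape r and mean mu (rate r/mu)."""
    w = np.asarray(w, dtype=float)
    mean = np.asarray(mean, dtype=float)
    return (
        shape * (np.log(shape) - np.log(mean))
        + (shape - 1.0) * np.log(w)
        - shape * w / mean
        - gammaln(shape)
    )


def complete_values(series, latent: np.ndarray) -> np.ndarray:
    """Series values with the latent draws substituted for missing months."""
    latent = np.asarray(latent, dtype=float)
    n_missing = int((~series.observed).sum())
    if len(latent) != n_missing:
        raise ValueError(f"expected {n_missing} latent values, got {len(latent)}")
    vals = series.values.copy()
    vals[~series.observed] = latent
    return vals


def log_likelihood(series, params: ModelParams, month_mask: np.ndarray | None = None) -> float:
    """Joint log density of the level vector under the model.

    Missing months are filled from ``params.latent`` and contribute their
    own gamma terms (they are unknowns of the posterior, not dropped).
    ``month_mask`` restricts the sum to a subset of months — the DIC
    deviance uses the observed mask.  Non-positive levels yield -inf
    rather than raising, so an invalid proposed state is simply rejected.
    """
    if params.shape <= 0:
        return -np.inf
    vals = complete_values(series, params.latent)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        return -np.inf
    eta = eta_path(params, vals)
    terms = gamma_log_density(vals, params.shape, np.exp(eta))
    if month_mask is not None:
        terms = terms[np.asarray(month_mask, dtype=bool)]
    total = float(terms.sum())
    return total if np.isfinite(total) else -np.inf


def _normal_logpdf(x: float, var: float) -> float:
    return -0.5 * (np.log(2.0 * np.pi * var) + x * x / var)


def log_prior(params: ModelParams, prior: PriorSpec) -> float:
    """Sum of log prior densities; -inf outside any support."""
    if params.n_harmonics != prior.K:
        raise ValueError("params harmonic count does not match prior K")
    if not -1.0 < params.beta_ar < 1.0:
        return -np.inf
    if params.shape <= 0:
        return -np.inf
    var = prior.coef_variance
    lp = _normal_logpdf(params.beta0, var) + _normal_logpdf(params.beta1, var)
    lp -= np.log(2.0)  # uniform(-1, 1) for beta_ar
    for k in range(prior.K):
        lo, hi = prior.period_bounds[k]
        if not lo < params.periods[k] < hi:
            return -np.inf
        lp += _normal_logpdf(params.alphas[k], var)
        lp += _normal_logpdf(params.rhos[k], var)
        lp -= np.log(hi - lo)
    a0, b0 = prior.shape_prior
    lp += a0 * np.log(b0) + (a0 - 1.0) * np.log(params.shape) - b0 * params.shape - gammaln(a0)
    return float(lp)
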