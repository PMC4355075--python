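# Methods

## The model

A lake's monthly mean water level `w_t` (t = 1..N, in months) is treated
as gamma distributed with mean `mu_t = exp(Y_t)` and shape `r`
(rate `r/mu_t`), so levels are strictly positive and the noise is
multiplicative with coefficient of variation `1/sqrt(r)`.  The linear
predictor is

    Y_t = beta0 + beta1*t + sum_{k=1..K} [ alpha_k cos(2*pi*t/P_k)
                                         + rho_k  sin(2*pi*t/P_k) ]
          + beta_AR * log(w_{t-1})

with `K in {0, 1, 2, 3}` harmonics of *unknown* period `P_k`.  `beta1`
is the long-term trend per month on the log scale; the AR term operates
on the log of the previous month's (observed or imputed) level, so the
predictor is a proper first-order autoregression on the scale implied by
the log link.  The observation noise of the gamma distribution is the
model's only stochastic error term.  At t = 1 there is no predecessor
and the AR term is dropped — the simplest well-defined choice, and
negligible at N ≈ 300–450.

Priors: zero-mean normals with precision 1e-6 (variance 1e6) on
`beta0`, `beta1` and every amplitude; uniform(−1, 1) on `beta_AR`
(stationarity); vague gamma(0.01, 0.01) on `r`; and uniform period
priors per alternative — K=1: `P1 ~ U(6, 18)` months (annual
seasonality); K=2 adds `P2 ~ U(24, N)`; K=3 uses the disjoint pair
`P2 ~ U(24, 132)` (inter-annual) and `P3 ~ U(144, N)` (inter-decadal).
The disjointness guarantees label separation between the two long-term
harmonics.  The precision-1e-6 reading of the coefficient prior is the
standard vague-prior idiom of precision-parameterised Gibbs software; a
literal variance of 1e-6 would pin every coefficient to zero and is
inconsistent with any non-trivial fitted trend.  Both readings are
selectable (`coef_prior="precision" | "variance"`); precision is the
default.

Missing months are unknowns of the posterior: each contributes its own
gamma term and feeds the AR term of the following month, so imputation
happens inside the sampler rather than by any a-priori fill-in.

## Sampling

A Metropolis-within-Gibbs sweep updates blocks `(beta0, beta1)`,
`beta_AR`, each `(alpha_k, rho_k)`, each `P_k`, `r`, and every latent
missing month.  All proposals are Gaussian random walks; the shape and
the latent levels walk on the log scale (with the Jacobian in the
acceptance ratio), and period proposals reflect at their prior bounds so
the hard edges are handled without wasted rejections.  Because period
posteriors are commonly multimodal, each period update is a mixture
kernel: with probability 0.25 an independence draw from the uniform
period prior (a symmetric proposal that lets the chain hop between
well-separated modes), otherwise the reflective walk.  Without the
hopping component a walk settles into one periodogram peak and the
posterior-average deviance is biased low.  Proposal scales
adapt toward a 20–40% acceptance rate in windows of 50 iterations during
burn-in only and are then frozen, preserving detailed balance for every
retained draw.  Latent-month updates touch only the two likelihood terms
the value enters, so their cost is independent of N.

Initial values: coefficients at 0, `r` at 1, latent months at the series
median, and periods over-dispersed across chains at the 0.25/0.75 prior
quantiles — a heuristic (not a guarantee) for exposing the multimodal
period posteriors that long-term harmonics commonly show.

Default protocol: two chains, 1e5 iterations, 1e4 burn-in, thinning 10.
Stationarity of the monitored parameters (`beta1`, periods, `r`) is
tested per chain with the Heidelberger–Welch statistic — a Cramér–von
Mises test on the standardised cumulative-sum bridge, with the spectral
density at zero estimated from the second half of the chain by an
AIC-chosen AR fit (an effectively unit-root fit is reported as
nonstationary).  On failure the fit escalates once to 10x the
iterations.

DIC is computed from the deviance over *observed* months only,
conditional on that draw's latent values.  The effective parameter count
uses Gelman's half-variance estimator `pD = var(D)/2` by default: the
classical plug-in form `pD = mean D − D(posterior mean)` is ill-defined
when a period posterior is multimodal (the posterior-mean period falls
between modes, and pD can even go negative), whereas the half-variance
form needs only the deviance trace and matches what common
Gibbs-sampler front-ends report.  The plug-in form remains available
(`dic(..., method="plugin")`).  DIC with latent variables is ambiguous
in general; both choices condition on the imputed months and are
recorded here.  Model selection: alternatives within
4 DIC of the best are "competing", and the competitor with the most
harmonics is selected; an exact tie at 4 counts as not competing.  A fit
failing the stationarity test after escalation is excluded from
selection.

## Synthetic data

The generator draws series from exactly the model above — the simulator
and the likelihood share one linear-predictor code path, so the
generative and inferential model cannot drift apart.  Defaults emulate
the study lakes: 360 months (30 years), `beta0 = 1` (levels around
e ≈ 2.7 m), `beta1 = −2e-4` per month (≈ −0.24% per year),
`beta_AR = 0.3`, one annual harmonic of amplitude ≈ 0.2 log-units,
`r = 400` (5% CV observation noise), and 2.7% of months missing
completely at random (the gauge network's empirical missing rate; the
mechanism is not documented, so MCAR is assumed).  Two-harmonic test
cohorts add a 6-year cycle of amplitude 0.14 log-units whose phase
rotates across lakes, emulating lakes whose long-term cycles are not
phase-locked; their true trends span the range observed across the study
cohort (−4.6 to +4.0 ×10⁻⁴ per month), because cross-lake regressions of
one fit's trend estimates on another's are only meaningful when the
trends genuinely vary between lakes.

What the generator does *not* emulate: weather forcing, abrupt regime
shifts, datum changes, heteroscedastic gauge error, or missingness that
clusters in time.  Tests passing on this synthetic cohort therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness of the model on arbitrary real gauge
records.

## Daily-to-monthly preparation

A calendar month's mean uses all its available daily values but is
flagged missing unless the month contains at least one complete week of
daily data, read as ≥ 7 *consecutive* days (the contiguity reading is
consistent with justifying the rule by strong 30-day serial correlation;
`require_consecutive=False` selects the ≥ 7-days-total reading).  The
lagged Durbin–Watson statistic `d = Σ(e_t − e_{t−lag})² / Σe_t²` is
computed on OLS-detrended daily levels with a normal approximation
`d ~ N(2, 4/n)` for the p-value — adequate at thousands of daily
observations, so the exact Imhof distribution is not implemented.

## Cross-lake statistics

`beta1` converts to annual percent change by the exact log-link form
`100*(exp(12*beta1) − 1)`; the linear approximation `1200*beta1` differs
by < 0.01 at gauge-series magnitudes and is available as an option.  A
trend is "significant" when its central 95% credible interval excludes
zero; an endpoint exactly at zero is conservatively not significant.
Single- vs multi-harmonic comparisons use the paired Wilcoxon
signed-rank test (exact null distribution for n ≤ 25, zeros dropped;
the all-zero case reported as statistic 0, p = 1) on the trend
coefficients and on the absolute magnitudes of their credible intervals,
plus an OLS regression of multi-harmonic on seasonal-only estimates with
a t test of the slope against 1 on n − 2 df.  The abstraction
correlation is the Pearson product–moment correlation of annual
abstraction volume with the trend coefficient.  Moran's I uses
row-standardised inverse great-circle-distance weights by default (the
weighting scheme for the published value is not documented, so only the
direction and non-significance are meaningful for comparison); its
p-value uses the normality approximation with `E[I] = −1/(n−1)`.

Two quantities in the packaged summary tables are reported but not
closely reproducible from printed precision: the cohort minimum annual
percent change (printed coefficients are rounded to one digit × 1e-4)
and the abstraction correlation (same rounding; the recomputed r is 0.11
against a published 0.13).  The cohort mean percent change and maximum
are robust to that rounding.

## Problem sizes in the test suite

The acceptance-style tests fit 20 synthetic lakes per cohort at 1e4
MCMC iterations (2.5e3 burn-in, thinning 5, single chain, escalation at
3x) — the package's reduced test protocol.  At the strong seasonal
signal of the study conditions the seasonal-period posterior has
standard deviation well under 0.05 months, so the reduced protocol
leaves the ±0.3-month recovery margin dominated by model error, not
Monte-Carlo error.  The full 1e5/1e6 protocol remains the library
default for real analyses.

## Known limitations

- Random-walk Metropolis mixes slowly across widely separated period
  modes; over-dispersed initialisation mitigates but does not guarantee
  full exploration of multimodal period posteriors.
- DIC's plug-in posterior mean is a poor summary for multimodal period
  marginals; competing-set comparisons inherit that caveat.
- The Durbin–Watson p-value and Moran's I p-value both rely on
  large-sample normal approximations.
- The gamma observation model requires strictly positive levels;
  relative gauge series containing zeros or negatives need a datum
  offset applied by the user before fitting.
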