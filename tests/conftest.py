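"""Shared fixtures: synthetic lake cohorts fitted once per session.

The cohort fixtures run the full MCMC at a reduced scale (10^4 iterations,
single chain) so the whole suite stays within a routine CI budget; the
generating conditions themselves (series length, amplitudes, trend, noise,
missingness) are the package defaults that emulate the study lakes.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from lakelevel import McmcSettings, SimulationSpec, fit_all, fit_model, simulate_series

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

N_LAKES = 20
TRUE_BETA1 = -2e-4
TEST_SETTINGS = dict(n_iter=10_000, burn_in=2_500, thin=5, n_chains=1,
                     escalate=True, escalate_factor=3)


def make_seasonal_spec(i: int) -> SimulationSpec:
    """True K=1 lake: annual cycle only, weak negative trend."""
    return SimulationSpec(
        n_months=360,
        beta0=1.0,
        beta1=TRUE_BETA1,
        beta_ar=0.3,
        harmonics=[(0.2, 0.05, 12.0)],
        gamma_shape=400.0,
        missing_rate=0.027,
        seed=100 + 17 * i,
        lake_id=f"sim{i:02d}",
    )


def make_two_harmonic_spec(i: int) -> SimulationSpec:
    """True K=2 lake: annual plus 6-year cycle, phase rotating per lake.

    True trends span the range observed across the study cohort
    (-4.6e-4 to +4.0e-4 per month) so that cross-lake regressions of one
    fit's trend estimates on another's have real signal variance."""
    angle = 2.0 * np.pi * i / N_LAKES
    amp = 0.14
    beta1 = (-4.6 + 8.6 * i / (N_LAKES - 1)) * 1e-4
    return SimulationSpec(
        n_months=360,
        beta0=1.0,
        beta1=beta1,
        beta_ar=0.3,
        harmonics=[(0.2, 0.05, 12.0), (amp * np.cos(angle), amp * np.sin(angle), 72.0)],
        gamma_shape=400.0,
        missing_rate=0.027,
        seed=500 + 13 * i,
        lake_id=f"sim2h{i:02d}",
    )


@pytest.fixture(scope="session")
def seasonal_cohort_fits():
    """20 true-K=1 lakes fitted with all four model alternatives."""
    out = []
    for i in range(N_LAKES):
        spec = make_seasonal_spec(i)
        series, _ = simulate_series(spec)
        settings = McmcSettings(seed=1000 + i, **TEST_SETTINGS)
        fits = fit_all(series, settings)
        out.append((spec, series, fits))
    return out


@pytest.fixture(scope="session")
def two_harmonic_cohort_fits():
    """20 true-K=2 lakes fitted with the K=1 and K=2 alternatives."""
    out = []
    for i in range(N_LAKES):
        spec = make_two_harmonic_spec(i)
        series, _ = simulate_series(spec)
        k1 = fit_model(series, 1, McmcSettings(seed=3000 + i, **TEST_SETTINGS))
        k2 = fit_model(series, 2, McmcSettings(seed=4000 + i, **TEST_SETTINGS))
        out.append((spec, series, {1: k1, 2: k2}))
    return out
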