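"""Fitting the K = 0..3 model alternatives and choosing among them by DIC.

Models within 4 DIC units of the best are "competing"; among competitors
the model with the most harmonics is selected, reflecting an a-priori
interest in long-term cyclic structure.  A fit that fails the convergence
diagnostics even after escalation is excluded from selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .mcmc import FitSummary, McmcSettings, fit_model
from .model import PriorSpec

__all__ = ["SelectionResult", "fit_all", "select_model"]

log = logging.getLogger(__name__)

DEFAULT_COMPETING_THRESHOLD = 4.0


@dataclass
class SelectionResult:
    """Outcome of DIC-based selection across the fitted alternatives."""

    fits: dict[int, FitSummary]
    chosen_k: int
    competing: list[int]
    lowest_dic_k: int
    delta_dic_null: float | None = None
    excluded: list[int] = field(default_factory=list)

    @property
    def chosen(self) -> FitSummary:
        return self.fits[self.chosen_k]


def fit_all(
    series,
    settings: McmcSettings,
    ks: tuple[int, ...] = (0, 1, 2, 3),
    coef_prior: str = "precision",
) -> dict[int, FitSummary]:
    """Fit every requested alternative whose period priors are satisfiable.

    A K whose period band is empty at this series length (e.g. the
    inter-decadal U(144, N) band when N <= 144) is skipped with a
    warning rather than crashing the lake.
    """
    if series.n_months < 24:
        raise ValueError("series must span at least 24 months for fitting")
    fits: dict[int, FitSummary] = {}
    for k in ks:
        prior = PriorSpec(K=k, n_months=series.n_months)
        if not prior.feasible:
            log.warning(
                "lake %s: skipping K=%d (empty period prior at N=%d)",
                series.lake_id,
                k,
                series.n_months,
            )
            continue
        child = McmcSettings(
            n_iter=settings.n_iter,
            burn_in=settings.burn_in,
            thin=settings.thin,
            n_chains=settings.n_chains,
            seed=settings.seed + 1000 * k,
            adapt_interval=settings.adapt_interval,
            escalate=settings.escalate,
            escalate_factor=settings.escalate_factor,
        )
        fits[k] = fit_model(series, k, child, coef_prior=coef_prior)
    return fits


def select_model(
    fits: dict[int, FitSummary],
    threshold: float = DEFAULT_COMPETING_THRESHOLD,
    require_convergence: bool = True,
) -> SelectionResult:
    """Apply the selection rule to a set of per-K fits.

    Competing set: fits with DIC strictly within ``threshold`` of the
    minimum (an exact tie at the threshold does not compete).  The
    selected model is the competitor with the largest K.  Non-converged
    fits are excluded up front; ``delta_dic_null`` reports DIC(null) -
    DIC(chosen) when the K=0 fit is available.
    """
    if not fits:
        raise ValueError("no fits to select among")
    excluded = []
    usable = {}
    for k, f in fits.items():
        if require_convergence and not f.converged:
            excluded.append(k)
            log.warning("K=%d excluded from selection (convergence failure)", k)
        else:
            usable[k] = f
    if not usable:
        raise ValueError("every fit failed convergence; nothing to select")
    best_dic = min(f.dic for f in usable.values())
    competing = sorted(k for k, f in usable.items() if f.dic - best_dic < threshold)
    chosen_k = max(competing)
    lowest_dic_k = min(usable, key=lambda k: usable[k].dic)
    delta_null = None
    if 0 in usable:
        delta_null = usable[0].dic - usable[chosen_k].dic
    return SelectionResult(
        fits=fits,
        chosen_k=chosen_k,
        competing=competing,
        lowest_dic_k=lowest_dic_k,
        delta_dic_null=delta_null,
        excluded=excluded,
    )
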