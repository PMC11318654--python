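"""Cell-type adaptation of parameter priors from the best-fitting variants.

The top decile of the ensemble (by total cumulative quality score) defines an
empirical distribution for each independently sampled parameter.  A one-sample
Kolmogorov-Smirnov test in ln space compares it against the originally sampled
Normal(mu, sigma); Bonferroni correction over the number of testable
parameters controls the family-wise error rate.  Where the test rejects, the
prior is re-fitted (maximum-likelihood log-normal on the selected values,
width floored) so subsequent sampling favours the enriched value ranges; a
binned enrichment profile in log space is retained for inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .priors import (
    SIGMA_MIN,
    Ensemble,
    ParameterPrior,
    WeightedValue,
    fit_weighted_lognormal,
)
from .scoring import ScoreTable

__all__ = [
    "AdaptationResult",
    "select_top_models",
    "ks_adapt",
    "enrichment_profile",
    "adapt_ensemble",
]

DEFAULT_ALPHA = 0.01  # family-wise error rate
ENRICHMENT_PSEUDOCOUNT = 0.5


@dataclass
class AdaptationResult:
    parameter: str
    ks_statistic: float
    p_value: float
    significant: bool
    alpha: float
    n_hypotheses: int
    n_top: int
    prior: ParameterPrior
    adjusted_prior: ParameterPrior | None
    enrichment: pd.DataFrame | None = None

    @property
    def effective_prior(self) -> ParameterPrior:
        return self.adjusted_prior if self.significant else self.prior


def select_top_models(table: ScoreTable, fraction: float = 0.1) -> list[int]:
    """Indices of the best-fitting ceil(fraction * n) variants.

    "Best" means highest (least negative) total cumulative score; ties break
    towards the lower variant index so selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    totals = table.variant_totals()
    if totals.empty:
        raise ValueError("select_top_models: empty score table")
    k = math.ceil(fraction * len(totals))
    ranked = totals.sort_values(["total", "variant"], ascending=[False, True])
    return ranked["variant"].head(k).astype(int).tolist()


def ks_adapt(
    top_values: Sequence[float] | np.ndarray,
    prior: ParameterPrior,
    alpha: float = DEFAULT_ALPHA,
    n_hypotheses: int = 1,
    sigma_min: float = SIGMA_MIN,
    enrichment_bins: int = 20,
) -> AdaptationResult:
    """One-sample KS test of selected parameter values against their prior.

    ``top_values`` are the (linear-scale) parameter values of the selected
    variants; the test runs on their logs against Normal(mu, sigma).  The
    corrected level is ``alpha / n_hypotheses``.  On rejection the adjusted
    prior is the log-normal refit of the selected values.
    """
    vals = np.asarray(top_values, dtype=float)
    if vals.size < 5:
        raise ValueError("ks_adapt: need at least 5 selected values")
    if np.any(vals <= 0):
        raise ValueError("ks_adapt: parameter values must be positive")
    if prior.dependent:
        raise ValueError(
            f"prior {prior.name!r} is dependent; only sampled parameters are testable"
        )
    if n_hypotheses < 1:
        raise ValueError("n_hypotheses must be >= 1")

    logs = np.log(vals)
    ks = stats.kstest(logs, "norm", args=(prior.mu, prior.sigma))
    significant = bool(ks.pvalue < alpha / n_hypotheses)

    adjusted = None
    if significant:
        refit = fit_weighted_lognormal(
            [WeightedValue(v) for v in vals],
            name=prior.name, kind=prior.kind, sigma_min=sigma_min,
        )
        adjusted = refit

    enr = enrichment_profile(vals, prior, bins=enrichment_bins)
    return AdaptationResult(
        parameter=prior.name,
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        significant=significant,
        alpha=alpha,
        n_hypotheses=n_hypotheses,
        n_top=int(vals.size),
        prior=prior,
        adjusted_prior=adjusted,
        enrichment=enr,
    )


def enrichment_profile(
    top_values: Sequence[float] | np.ndarray,
    prior: ParameterPrior,
    bins: int = 20,
    pseudocount: float = ENRICHMENT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-bin log-ratio of observed vs prior-expected counts (log space).

    Bin edges span the prior's central 99.9% mass; expected counts are
    ``n_top * prior mass in bin``; the log-ratio uses a pseudocount so empty
    bins stay finite.
    """
    if bins < 2:
        raise ValueError("enrichment_profile: bins must be >= 2")
    if prior.sigma <= 0:
        raise ValueError("enrichment_profile: degenerate prior")
    vals = np.asarray(top_values, dtype=float)
    logs = np.log(vals)
    z = stats.norm.ppf(0.9995)
    lo, hi = prior.mu - z * prior.sigma, prior.mu + z * prior.sigma
    edges = np.linspace(lo, hi, bins + 1)
    observed, _ = np.histogram(logs, bins=edges)
    cdf = stats.norm.cdf(edges, prior.mu, prior.sigma)
    expected = vals.size * np.diff(cdf)
    log_ratio = np.log((observed + pseudocount) / (expected + pseudocount))
    return pd.DataFrame({
        "ln_lo": edges[:-1], "ln_hi": edges[1:],
        "observed": observed, "expected": expected, "log_ratio": log_ratio,
    })


def adapt_ensemble(
    ens: Ensemble,
    table: ScoreTable,
    priors: Mapping[str, ParameterPrior],
    parameters: Sequence[str] | None = None,
    fraction: float = 0.1,
    alpha: float = DEFAULT_ALPHA,
    n_hypotheses: int | None = None,
) -> dict[str, AdaptationResult]:
    """Adapt a set of priors from the top-scoring fraction of one ensemble.

    ``parameters`` defaults to the catalyst starting concentrations (the
    quantities a cell type is expected to shift); ``n_hypotheses`` defaults to
    the count of all independently sampled parameters in the ensemble, so the
    correction stays honest about the full testing family.
    """
    top = select_top_models(table, fraction)
    if parameters is None:
        parameters = [nm for nm in ens.prior_names if nm.startswith("enzyme_conc_0_")]
    if n_hypotheses is None:
        n_hypotheses = len(ens.prior_names)

    scored = set(int(v) for v in table.variants)
    results: dict[str, AdaptationResult] = {}
    for nm in parameters:
        prior = priors[nm]
        vals = [
            ens.variants[i].assignment[nm] for i in top if i in scored
        ]
        results[nm] = ks_adapt(
            vals, prior, alpha=alpha, n_hypotheses=n_hypotheses
        )
    return results


def results_table(results: Mapping[str, AdaptationResult]) -> pd.DataFrame:
    rows = []
    for nm, r in results.items():
        adj = r.adjusted_prior
        rows.append({
            "parameter": nm,
            "ks_statistic": r.ks_statistic,
            "p_value": r.p_value,
            "significant": r.significant,
            "n_hypotheses": r.n_hypotheses,
            "n_top": r.n_top,
            "prior_mu": r.prior.mu,
            "prior_sigma": r.prior.sigma,
            "adjusted_mu": adj.mu if adj else np.nan,
            "adjusted_sigma": adj.sigma if adj else np.nan,
        })
    return pd.DataFrame(rows)
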