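"""Log-normal parameter priors and thermodynamically consistent sampling.

Every kinetic parameter and catalyst starting concentration is represented by a
log-normal prior, fitted from weighted literature values when those are
available.  Within each reaction the reverse-direction parameter is *dependent*:
it is never sampled marginally but derived from the forward parameters and the
equilibrium constant so that every sampled quadruplet (k_cat, K_ms, K_mp, K_eq)
or triplet (k_f, k_r, K_eq) is thermodynamically consistent (Haldane
constraint).  An :class:`Ensemble` is a seeded, reproducible collection of such
complete parameter assignments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .network import (
    Network,
    ReactionSpec,
    enzyme_conc_name,
    parse_ref,
    transporter_kcat_name,
)

__all__ = [
    "SIGMA_MIN",
    "WeightedValue",
    "ParameterPrior",
    "ModelVariant",
    "Ensemble",
    "fit_weighted_lognormal",
    "derive_dependent",
    "sample_ensemble",
    "variant_from_modes",
    "thermodynamic_residuals",
    "parameter_census",
    "save_priors",
    "load_priors",
]

#: floor on the ln-space width of any prior; a single literature value would
#: otherwise collapse the prior to a point mass
SIGMA_MIN = 0.25

#: parameter kinds that are always derived, never sampled marginally
DEPENDENT_KINDS = frozenset({"K_mp", "k_r"})


@dataclass(frozen=True)
class WeightedValue:
    """One literature observation with its likelihood weight."""

    value: float
    weight: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"WeightedValue: value must be > 0, got {self.value}")
        if not self.weight > 0:
            raise ValueError(f"WeightedValue: weight must be > 0, got {self.weight}")


@dataclass(frozen=True)
class ParameterPrior:
    """Log-normal prior: ln(value) ~ Normal(mu, sigma)."""

    name: str
    kind: str
    mu: float
    sigma: float
    dependent: bool = False
    sources: tuple[WeightedValue, ...] = ()

    def __post_init__(self) -> None:
        if not self.dependent and self.sigma < SIGMA_MIN - 1e-12:
            raise ValueError(
                f"prior {self.name!r}: sigma {self.sigma} below floor {SIGMA_MIN}"
            )

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dependent:
            raise ValueError(f"dependent prior {self.name!r} is never sampled marginally")
        return np.exp(rng.normal(self.mu, self.sigma, size=n))

    def interval(self, mass: float = 0.999) -> tuple[float, float]:
        """Central probability interval on the natural (linear) scale."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + mass / 2.0)
        return math.exp(self.mu - z * self.sigma), math.exp(self.mu + z * self.sigma)


def fit_weighted_lognormal(
    values: Sequence[WeightedValue],
    name: str = "",
    kind: str = "",
    sigma_min: float = SIGMA_MIN,
) -> ParameterPrior:
    """Fit a log-normal prior by weighted moments of ln(value).

    mu is the weighted mean of the log-values, sigma the weighted (population)
    standard deviation floored at ``sigma_min``; weights are normalised
    internally so only their ratios matter.
    """
    if not values:
        raise ValueError("fit_weighted_lognormal: need at least one value")
    logs = np.array([math.log(v.value) for v in values])
    w = np.array([v.weight for v in values], dtype=float)
    w = w / w.sum()
    mu = float(np.sum(w * logs))
    var = float(np.sum(w * (logs - mu) ** 2))
    sigma = max(math.sqrt(var), sigma_min)
    return ParameterPrior(name=name, kind=kind, mu=mu, sigma=sigma,
                          sources=tuple(values))


def derive_dependent(forward: float, K_ms: float | None, K_eq: float,
                     kind: str) -> float:
    """Derive the thermodynamically consistent dependent parameter.

    * non-enzymatic triplet (``kind='k_r'``): k_r = k_f / K_eq, so that
      K_eq = k_f / k_r holds exactly;
    * enzymatic quadruplet (``kind='K_mp'``): K_mp = K_eq * K_ms, the Haldane
      relation of the reversible uni-uni rate law under the equal
      forward/reverse turnover convention used throughout the model.
    """
    if not forward > 0 or not K_eq > 0:
        raise ValueError("derive_dependent: inputs must be positive")
    if kind == "k_r":
        return forward / K_eq
    if kind == "K_mp":
        if K_ms is None or not K_ms > 0:
            raise ValueError("derive_dependent: K_ms must be positive for K_mp")
        return K_eq * K_ms
    raise ValueError(f"derive_dependent: unknown dependent kind {kind!r}")


# ---------------------------------------------------------------------------
# ensembles


@dataclass(frozen=True)
class ModelVariant:
    """One complete numeric parameter assignment."""

    index: int
    assignment: Mapping[str, float]

    def __getitem__(self, name: str) -> float:
        return self.assignment[name]


@dataclass
class Ensemble:
    variants: list[ModelVariant]
    seed: int
    network_name: str
    prior_names: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return len(self.variants)

    def values(self, name: str) -> np.ndarray:
        """Sampled/derived values of one parameter across all variants."""
        return np.array([v.assignment[name] for v in self.variants])


def _independent_names(net: Network, priors: Mapping[str, ParameterPrior]) -> list[str]:
    """Independently sampled prior names the network requires, in stable order."""
    names = []
    for nm in net.required_parameter_names(include_disabled=True):
        prior = priors.get(nm)
        if prior is not None and prior.dependent:
            continue
        names.append(nm)
    return names


def parameter_census(net: Network, priors: Mapping[str, ParameterPrior]) -> int:
    """Count of independently sampled parameters (the KS-testable ones)."""
    missing = [nm for nm in _independent_names(net, priors) if nm not in priors]
    if missing:
        raise KeyError(f"network references priors with no definition: {missing[:5]}")
    return len(_independent_names(net, priors))


def _reaction_param_names(rxn: ReactionSpec) -> dict[str, str]:
    names = {kind: rxn.parameter_name(kind) for kind in rxn.parameters}
    if rxn.rtype == "transport" and rxn.catalyst is not None:
        names["k_cat"] = transporter_kcat_name(parse_ref(rxn.catalyst)[0])
    return names


def _complete_assignment(
    net: Network, draw: dict[str, float]
) -> dict[str, float]:
    """Fill in the dependent parameters of every quadruplet/triplet."""
    out = dict(draw)
    for rxn in net.sorted_reactions():
        names = _reaction_param_names(rxn)
        if rxn.rtype == "enzymatic":
            out[names["K_mp"]] = derive_dependent(
                out[names["k_cat"]], out[names["K_ms"]], out[names["K_eq"]], "K_mp"
            )
        elif rxn.rtype == "non_enzymatic":
            out[names["k_r"]] = derive_dependent(
                out[names["k_f"]], None, out[names["K_eq"]], "k_r"
            )
    return out


def sample_ensemble(
    net: Network,
    priors: Mapping[str, ParameterPrior],
    n: int,
    seed: int,
) -> Ensemble:
    """Draw ``n`` thermodynamically consistent model variants.

    Independent parameters are drawn from their log-normal priors in sorted
    name order (so the ensemble is a pure function of the seed); dependent
    parameters are derived per variant via :func:`derive_dependent`.
    """
    if n < 1:
        raise ValueError("sample_ensemble: n must be >= 1")
    indep = _independent_names(net, priors)
    for rxn in net.enabled_reactions():
        for kind, nm in _reaction_param_names(rxn).items():
            if kind in DEPENDENT_KINDS:
                continue
            if nm not in priors:
                raise KeyError(
                    f"reaction {rxn.number}: no prior for parameter {kind} ({nm})"
                )
    missing = [nm for nm in indep if nm not in priors]
    if missing:
        raise KeyError(f"missing priors: {missing[:5]}")

    rng = np.random.default_rng(seed)
    draws = {nm: priors[nm].sample(rng, n) for nm in sorted(indep)}
    variants = []
    for i in range(n):
        draw = {nm: float(draws[nm][i]) for nm in indep}
        variants.append(ModelVariant(index=i, assignment=_complete_assignment(net, draw)))
    return Ensemble(variants=variants, seed=seed, network_name=net.name,
                    prior_names=tuple(indep))


def variant_from_modes(
    net: Network,
    priors: Mapping[str, ParameterPrior],
    overrides: Mapping[str, float] | None = None,
    index: int = -1,
) -> ModelVariant:
    """Deterministic variant at every prior's median, with optional overrides.

    Overrides apply to independent parameters before the dependent ones are
    derived, so the result is always thermodynamically consistent.
    """
    draw = {nm: priors[nm].median for nm in _independent_names(net, priors)}
    if overrides:
        unknown = set(overrides) - set(draw)
        if unknown:
            raise KeyError(f"overrides for unknown/dependent parameters: {sorted(unknown)}")
        draw.update(overrides)
    return ModelVariant(index=index, assignment=_complete_assignment(net, draw))


def thermodynamic_residuals(net: Network, variant: ModelVariant) -> dict[int, float]:
    """Relative Haldane residual per reversible reaction (should be ~0)."""
    res: dict[int, float] = {}
    a = variant.assignment
    for rxn in net.sorted_reactions():
        names = _reaction_param_names(rxn)
        if rxn.rtype == "enzymatic":
            implied = a[names["K_mp"]] / a[names["K_ms"]]
            res[rxn.number] = abs(implied / a[names["K_eq"]] - 1.0)
        elif rxn.rtype == "non_enzymatic":
            implied = a[names["k_f"]] / a[names["k_r"]]
            res[rxn.number] = abs(implied / a[names["K_eq"]] - 1.0)
    return res


# ---------------------------------------------------------------------------
# serialisation

def save_priors(priors: Mapping[str, ParameterPrior], path: str | Path) -> Path:
    path = Path(path)
    payload = []
    for nm in sorted(priors):
        p = priors[nm]
        payload.append({
            "name": p.name,
            "kind": p.kind,
            "mu": p.mu,
            "sigma": p.sigma,
            "dependent": p.dependent,
            "sources": [
                {"value": s.value, "weight": s.weight, "source": s.source}
                for s in p.sources
            ],
        })
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_priors(path: str | Path) -> dict[str, ParameterPrior]:
    payload = json.loads(Path(path).read_text())
    out: dict[str, ParameterPrior] = {}
    for row in payload:
        out[row["name"]] = ParameterPrior(
            name=row["name"],
            kind=row["kind"],
            mu=float(row["mu"]),
            sigma=float(row["sigma"]),
            dependent=bool(row["dependent"]),
            sources=tuple(
                WeightedValue(s["value"], s["weight"], s.get("source", ""))
                for s in row.get("sources", ())
            ),
        )
    return out
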