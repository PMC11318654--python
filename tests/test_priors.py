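"""Weighted log-normal fitting, Haldane dependencies, ensemble sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aacascade import (
    WeightedValue,
    derive_dependent,
    fit_weighted_lognormal,
    load_priors,
    sample_ensemble,
    save_priors,
    thermodynamic_residuals,
    variant_from_modes,
)
from aacascade.priors import SIGMA_MIN, ParameterPrior


class TestWeightedFit:
    def test_single_value_pins_mu_and_floors_sigma(self):
        p = fit_weighted_lognormal([WeightedValue(2.0)])
        assert p.mu == pytest.approx(math.log(2.0))
        assert p.sigma == SIGMA_MIN

    def test_equal_weight_midpoint_in_log_space(self):
        p = fit_weighted_lognormal([WeightedValue(1.0), WeightedValue(math.e**2)])
        assert p.mu == pytest.approx(1.0)

    def test_matches_direct_weighted_moments(self):
        vals = [0.5, 1.0, 2.0, 4.0, 8.0]
        weights = [1.0, 2.0, 1.0, 0.5, 1.5]
        # independent arithmetic oracle on ln values
        logs = [math.log(v) for v in vals]
        wsum = sum(weights)
        mu = sum(w * x for w, x in zip(weights, logs)) / wsum
        var = sum(w * (x - mu) ** 2 for w, x in zip(weights, logs)) / wsum
        p = fit_weighted_lognormal(
            [WeightedValue(v, w) for v, w in zip(vals, weights)]
        )
        assert p.mu == pytest.approx(mu)
        assert p.sigma == pytest.approx(max(math.sqrt(var), SIGMA_MIN))

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            fit_weighted_lognormal([])
        with pytest.raises(ValueError):
            WeightedValue(-1.0)
        with pytest.raises(ValueError):
            WeightedValue(1.0, weight=0.0)

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=1, max_size=8),
        st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_weight_scaling_invariance(self, vals, scale):
        """Only weight ratios matter; mu lies within the log-value hull."""
        a = fit_weighted_lognormal([WeightedValue(v, 1.0) for v in vals])
        b = fit_weighted_lognormal([WeightedValue(v, scale) for v in vals])
        assert a.mu == pytest.approx(b.mu)
        assert a.sigma == pytest.approx(b.sigma)
        logs = [math.log(v) for v in vals]
        assert min(logs) - 1e-9 <= a.mu <= max(logs) + 1e-9


class TestDependentParameters:
    def test_triplet_reverse_rate(self):
        assert derive_dependent(2.0, None, 4.0, "k_r") == pytest.approx(0.5)

    def test_symmetric_equilibrium(self):
        assert derive_dependent(3.7, None, 1.0, "k_r") == pytest.approx(3.7)

    def test_quadruplet_haldane(self):
        assert derive_dependent(5.0, 2e-3, 1e4, "K_mp") == pytest.approx(20.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            derive_dependent(-1.0, None, 2.0, "k_r")
        with pytest.raises(ValueError):
            derive_dependent(1.0, 0.0, 2.0, "K_mp")


class TestEnsembleSampling:
    def test_seed_determinism(self, cascade_net, cascade_priors):
        a = sample_ensemble(cascade_net, cascade_priors, 5, seed=7)
        b = sample_ensemble(cascade_net, cascade_priors, 5, seed=7)
        c = sample_ensemble(cascade_net, cascade_priors, 5, seed=8)
        for va, vb in zip(a.variants, b.variants):
            assert va.assignment == vb.assignment
        assert any(
            a.variants[i].assignment != c.variants[i].assignment for i in range(5)
        )

    def test_every_variant_thermodynamically_consistent(
        self, cascade_net, cascade_priors
    ):
        ens = sample_ensemble(cascade_net, cascade_priors, 20, seed=3)
        for v in ens.variants:
            worst = max(thermodynamic_residuals(cascade_net, v).values())
            assert worst < 1e-9

    def test_missing_prior_names_reaction_and_symbol(
        self, cascade_net, cascade_priors
    ):
        broken = dict(cascade_priors)
        del broken["k_cat_r2"]
        with pytest.raises(KeyError, match="reaction 2.*k_cat"):
            sample_ensemble(cascade_net, broken, 2, seed=0)

    def test_degenerate_width_prior_concentrates_at_median(
        self, cascade_net, cascade_priors
    ):
        narrow = {
            nm: (
                p if p.dependent else ParameterPrior(
                    p.name, p.kind, p.mu, SIGMA_MIN, sources=p.sources
                )
            )
            for nm, p in cascade_priors.items()
        }
        ens = sample_ensemble(cascade_net, narrow, 1, seed=11)
        v = ens.variants[0]
        for nm in ens.prior_names:
            lo = math.log(v.assignment[nm]) - narrow[nm].mu
            assert abs(lo) < 4 * SIGMA_MIN

    def test_marginal_sampling_moments(self):
        prior = ParameterPrior("p", "k_cat", mu=1.3, sigma=0.6)
        rng = np.random.default_rng(5)
        draws = np.log(prior.sample(rng, 100_000))
        se_mean = prior.sigma / math.sqrt(draws.size)
        assert abs(draws.mean() - prior.mu) < 3 * se_mean
        se_sd = prior.sigma / math.sqrt(2 * draws.size)
        assert abs(draws.std() - prior.sigma) < 3 * se_sd

    def test_variant_from_modes_applies_overrides_consistently(
        self, cascade_net, cascade_priors
    ):
        v = variant_from_modes(
            cascade_net, cascade_priors, overrides={"K_eq_r2": 123.0}
        )
        assert v.assignment["K_eq_r2"] == 123.0
        # dependent K_mp must follow the override
        assert v.assignment["K_mp_r2"] == pytest.approx(
            123.0 * v.assignment["K_ms_r2"]
        )

    def test_rejects_bad_n(self, cascade_net, cascade_priors):
        with pytest.raises(ValueError):
            sample_ensemble(cascade_net, cascade_priors, 0, seed=0)


def test_priors_json_round_trip(cascade_priors, tmp_path):
    path = save_priors(cascade_priors, tmp_path / "priors.json")
    again = load_priors(path)
    assert set(again) == set(cascade_priors)
    for nm, p in cascade_priors.items():
        q = again[nm]
        assert (q.mu, q.sigma, q.kind, q.dependent) == (
            p.mu, p.sigma, p.kind, p.dependent
        )
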