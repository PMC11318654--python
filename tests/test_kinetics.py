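"""Rate-law contracts: limits, signs, continuity, release/induction shapes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aacascade import (
    InductionSchedule,
    ReleaseProfile,
    cumulative_release,
    degradation_rate,
    enzymatic_rate,
    induction_level,
    non_enzymatic_rate,
    release_concentration,
    release_rate,
    transport_rate,
)
from aacascade.synthetic import make_release_scenarios

pos = st.floats(1e-6, 1e3)
conc = st.floats(0.0, 1e3)


class TestRelease:
    def test_monotone_rise_to_asymptote(self):
        prof = ReleaseProfile(max_conc_6h=0.2, doubling_time=0.5)
        ts = np.linspace(0, 48, 400)
        vals = [release_concentration(t, prof) for t in ts]
        assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(0.2, rel=1e-10)

    def test_decay_halves_per_half_life(self):
        prof = ReleaseProfile(
            max_conc_6h=1.0, doubling_time=0.05,
            decay_switch=True, peak_time=1.0, half_life=0.7,
        )
        peak = release_concentration(1.0, prof)
        assert release_concentration(1.7, prof) == pytest.approx(0.5 * peak)
        assert release_concentration(2.4, prof) == pytest.approx(0.25 * peak)

    def test_continuity_across_schedule_boundary(self):
        prof = ReleaseProfile(
            max_conc_6h=0.01, doubling_time=0.25,
            schedule=((3.0, {"max_conc_6h": 0.1}),),
        )
        before = release_concentration(3.0 - 1e-9, prof)
        after = release_concentration(3.0 + 1e-9, prof)
        assert after == pytest.approx(before, rel=1e-5)

    def test_negative_time_rejected(self):
        prof = ReleaseProfile(max_conc_6h=1.0)
        with pytest.raises(ValueError):
            release_concentration(-0.1, prof)
        with pytest.raises(ValueError):
            release_rate(-0.1, prof)

    def test_minimal_delayed_splits_release_10_90(self):
        prof = make_release_scenarios(total_aa_mM=1.0)["minimal_delayed"]
        frac_3h = cumulative_release(3.0, prof) / cumulative_release(6.0, prof)
        assert frac_3h == pytest.approx(0.10, abs=0.002)

    def test_constant_scenario_is_time_invariant(self):
        prof = make_release_scenarios()["constant"]
        vals = [release_concentration(t, prof) for t in (0.5, 1, 3, 6)]
        assert max(vals) - min(vals) < 1e-12 * max(vals)

    def test_delayed_scenario_holds_zero_then_releases(self):
        prof = make_release_scenarios(total_aa_mM=1.0)["delayed"]
        assert release_concentration(2.9, prof) == pytest.approx(0.0, abs=1e-12)
        assert release_concentration(6.0, prof) > 0.9

    def test_decaying_scenario_strictly_decreasing_after_peak(self):
        prof = make_release_scenarios()["decaying"]
        ts = np.linspace(0.6, 6.0, 50)
        vals = [release_concentration(t, prof) for t in ts]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestInduction:
    def test_empty_schedule_holds_baseline(self):
        sched = InductionSchedule("COX-2")
        assert induction_level(4.2, sched, baseline=1e-4) == 1e-4

    def test_step_semantics_right_continuous(self):
        sched = InductionSchedule("COX-2", steps=((3.0, 2e-4),))
        assert induction_level(2.9, sched, 1e-4) == 1e-4
        assert induction_level(3.0, sched, 1e-4) == 2e-4

    def test_rise_then_fall_profile(self):
        sched = InductionSchedule("COX-2", steps=((1.0, 3e-4), (3.0, 5e-4), (4.0, 2e-4)))
        levels = [induction_level(t, sched, 1e-4) for t in (0.5, 2.0, 3.5, 5.0)]
        assert levels == [1e-4, 3e-4, 5e-4, 2e-4]
        peak = max(levels)
        assert levels.index(peak) not in (0, len(levels) - 1)


class TestEnzymaticRate:
    def test_no_catalyst_no_flux(self):
        assert enzymatic_rate(1.0, 0.1, 0.0, 10, 1e-3, 1.0, 1e3) == 0.0

    def test_equilibrium_zero(self):
        v = enzymatic_rate(2.0, 2.0 * 50.0, 1e-3, 10, 1e-3, 0.05, 50.0)
        assert v == pytest.approx(0.0, abs=1e-18)

    def test_saturation_approaches_kcat_e(self):
        v = enzymatic_rate(100 * 1e-3, 0.0, 2e-5, 10, 1e-3, 1.0, 1e6)
        assert v == pytest.approx(10 * 2e-5, rel=0.011)

    def test_competitor_strictly_reduces_magnitude(self):
        base = enzymatic_rate(1e-3, 0.0, 1e-5, 10, 1e-3, 1.0, 1e6)
        inhib = enzymatic_rate(
            1e-3, 0.0, 1e-5, 10, 1e-3, 1.0, 1e6, competitors=[(1e-3, 1e-3)]
        )
        assert 0 < inhib < base

    @given(S=conc, P=conc, E=pos, k_cat=pos, K_ms=pos, K_eq=pos)
    @settings(max_examples=200, deadline=None)
    def test_sign_matches_thermodynamic_drive(self, S, P, E, k_cat, K_ms, K_eq):
        K_mp = K_eq * K_ms
        v = enzymatic_rate(S, P, E, k_cat, K_ms, K_mp, K_eq)
        drive = S - P / K_eq
        if drive > 1e-12 * max(S, P, 1.0):
            assert v > 0
        elif drive < -1e-12 * max(S, P, 1.0):
            assert v < 0

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            enzymatic_rate(-1.0, 0.0, 1.0, 1, 1, 1, 1)


class TestSimpleRates:
    def test_non_enzymatic_arithmetic(self):
        assert non_enzymatic_rate(3.0, 1.0, 2.0, 0.5) == pytest.approx(5.5)

    def test_non_enzymatic_equilibrium_ratio(self):
        assert non_enzymatic_rate(1.0, 4.0, 2.0, 0.5) == pytest.approx(0.0)
        assert non_enzymatic_rate(0.0, 0.0, 2.0, 0.5) == 0.0

    def test_transport_half_saturation(self):
        v = transport_rate((1e-3, 1e-3), [], T=1e-5, k_cat=10)
        assert v == pytest.approx(0.5 * 10 * 1e-5)

    def test_transport_competition_arithmetic(self):
        v = transport_rate((1.0, 1.0), [(2.0, 0.5)], T=1.0, k_cat=1.0)
        assert v == pytest.approx(1.0 / 6.0)

    def test_transport_zero_competitors_match_absent(self):
        with_zero = transport_rate((1.0, 1.0), [(0.0, 0.5)], T=1.0, k_cat=1.0)
        without = transport_rate((1.0, 1.0), [], T=1.0, k_cat=1.0)
        assert with_zero == pytest.approx(without)

    def test_degradation(self):
        assert degradation_rate(2.0, 0.1) == pytest.approx(0.2)
        assert degradation_rate(0.0, 0.1) == 0.0
        assert degradation_rate(2.0, 0.0) == 0.0
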