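"""ODE assembly and protocol integration against analytic expectations."""

import math

import numpy as np
import pytest

from aacascade import (
    ReleaseProfile,
    SimulationProtocol,
    assemble_odes,
    run_variant,
    variant_from_modes,
)
from aacascade.kinetics import InductionSchedule
from aacascade.priors import ModelVariant


def ab_variant(k_f=1.0, K_eq=1.0):
    return ModelVariant(0, {
        "k_f_r1": k_f, "K_eq_r1": K_eq, "k_r_r1": k_f / K_eq,
    })


def transport_variant():
    return ModelVariant(0, {
        "K_ms_r1": 1e-3,
        "k_cat_T": 5.0,
        "enzyme_conc_0_T": 1e-5,
        "k_f_r2": 1e-3, "K_eq_r2": 2.0, "k_r_r2": 5e-4,
    })


class TestAssembly:
    def test_reversible_pair_rhs_is_antisymmetric(self, ab_network):
        rhs, states, y0 = assemble_odes(ab_network, ab_variant(k_f=2.0, K_eq=4.0))
        dy = rhs(0.0, np.array([1.0, 0.5]))
        # dA/dt = -k_f A + k_r B; dB/dt = +k_f A - k_r B
        expected = -2.0 * 1.0 + 0.5 * 0.5
        assert dy[states.index("A@intracellular")] == pytest.approx(expected)
        assert dy.sum() == pytest.approx(0.0, abs=1e-15)

    def test_transport_conserves_amount_in_rhs(self, transport_network):
        rhs, states, y0 = assemble_odes(transport_network, transport_variant())
        vols = {"intracellular": 1e-12, "extracellular": 1e-9}
        y = np.array([0.3 if s == "X@intracellular" else 0.05 for s in states])
        dy = rhs(0.0, y)
        d_amount = sum(
            dy[i] * vols[s.rsplit("@", 1)[1]] for i, s in enumerate(states)
        )
        assert d_amount == pytest.approx(0.0, abs=1e-28)

    def test_all_reactions_disabled_gives_zero_rhs(self, ab_network):
        net = ab_network.with_reaction_enabled(1, False)
        rhs, states, _ = assemble_odes(net, ab_variant())
        assert np.allclose(rhs(0.0, np.array([1.0, 2.0])), 0.0)


class TestProtocolIntegration:
    def test_linear_reversible_matches_closed_form(self, ab_network):
        protocol = SimulationProtocol(
            equilibration_h=0.0, post_stimulus_h=2.0 / 3600.0,
            report_times_h=(0.5 / 3600.0, 1.0 / 3600.0, 2.0 / 3600.0),
            rtol=1e-10, atol=1e-14,
        )
        traj = run_variant(ab_network, ab_variant(k_f=1.0, K_eq=1.0), protocol)
        assert traj.success
        for t_s in (0.5, 1.0, 2.0):
            expected = 0.5 + 0.5 * math.exp(-2.0 * t_s)
            got = traj.value("A", "intracellular", t_s / 3600.0)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_unstimulated_fixture_stays_at_floor(self, cascade_net, cascade_priors):
        protocol = SimulationProtocol(release=None, rtol=1e-8)
        v = variant_from_modes(cascade_net, cascade_priors)
        traj = run_variant(cascade_net, v, protocol)
        assert traj.success
        assert np.nanmax(traj.conc) < 10 * 1e-28

    def test_stimulus_drives_aa_and_downstream_products(
        self, cascade_net, cascade_priors, stimulus_protocol
    ):
        v = variant_from_modes(cascade_net, cascade_priors)
        traj = run_variant(cascade_net, v, stimulus_protocol)
        assert traj.success
        aa = traj.series("AA", "intracellular")
        pre = traj.value("AA", "intracellular", -0.5)
        assert aa.max() > 1e6 * max(pre, 1e-28)
        for sid in ("PGE2", "12-HETE"):
            assert traj.value(sid, "extracellular", 6.0) > 1e-12

    def test_solver_tolerance_convergence(self, ab_network):
        kwargs = dict(
            equilibration_h=0.0, post_stimulus_h=1.0 / 3600.0,
            report_times_h=(1.0 / 3600.0,),
        )
        loose = run_variant(
            ab_network, ab_variant(), SimulationProtocol(rtol=1e-8, atol=1e-12, **kwargs)
        )
        tight = run_variant(
            ab_network, ab_variant(), SimulationProtocol(rtol=1e-9, atol=1e-13, **kwargs)
        )
        a, b = (t.value("A", "intracellular", 1.0 / 3600.0) for t in (loose, tight))
        assert abs(a - b) / b < 1e-3

    def test_induction_raises_downstream_product(
        self, cascade_net, cascade_priors
    ):
        v = variant_from_modes(cascade_net, cascade_priors)
        release = ReleaseProfile(max_conc_6h=0.1, doubling_time=0.25)
        base = run_variant(
            cascade_net, v, SimulationProtocol(release=release, rtol=1e-6)
        )
        baseline_conc = v.assignment["enzyme_conc_0_COX-2"]
        induced = run_variant(
            cascade_net, v, SimulationProtocol(
                release=release, rtol=1e-6,
                induction=(InductionSchedule("COX-2", ((1.0, 10 * baseline_conc),)),),
            ),
        )
        assert induced.value("PGE2", "extracellular", 6.0) > \
            base.value("PGE2", "extracellular", 6.0)

    def test_report_time_outside_window_rejected(self):
        with pytest.raises(ValueError, match="report time"):
            SimulationProtocol(report_times_h=(7.5,))

    def test_grid_contains_report_times(self, cascade_net, cascade_priors,
                                         stimulus_protocol):
        v = variant_from_modes(cascade_net, cascade_priors)
        traj = run_variant(cascade_net, v, stimulus_protocol)
        for t in stimulus_protocol.report_times_h:
            assert np.isclose(traj.times_h, t).any()
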