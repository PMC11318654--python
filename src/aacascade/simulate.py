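"""ODE assembly and the equilibration-then-stimulus simulation protocol.

One model variant defines a stiff ODE system over the metabolite pools of both
compartments (catalyst concentrations are parameters, held constant except by
induction schedules).  The protocol integrates an equilibration hour, switches
the substrate-release profile on at its end ("the stimulus"), and continues
for the post-stimulus window, reporting concentrations on a dense grid that
contains the experimental report times.  Stimulus, release re-assignments and
induction steps are implemented by stopping and restarting the integrator at
event times, never by a discontinuous right-hand side.

Internal time unit is seconds (all rate constants are s^-1); every public
interface speaks hours relative to the stimulus (equilibration is negative
time).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import LN2, InductionSchedule, ReleaseProfile, induction_level
from .network import Network, parse_ref, transporter_kcat_name, enzyme_conc_name
from .priors import ModelVariant

__all__ = ["SimulationProtocol", "Trajectory", "assemble_odes", "run_variant"]

log = logging.getLogger(__name__)

H = 3600.0  # seconds per hour


@dataclass(frozen=True)
class SimulationProtocol:
    """Equilibrate, stimulate, report."""

    equilibration_h: float = 1.0
    post_stimulus_h: float = 6.0
    release: ReleaseProfile | None = None
    induction: tuple[InductionSchedule, ...] = ()
    report_times_h: tuple[float, ...] = (0.5, 1.0, 3.0, 6.0)
    rtol: float = 1e-8
    atol: float = 1e-30  # mM; must resolve the 1e-28 mM metabolite floor
    grid_per_hour: int = 20

    def __post_init__(self) -> None:
        if self.equilibration_h < 0 or self.post_stimulus_h <= 0:
            raise ValueError("invalid protocol window")
        for t in self.report_times_h:
            if not (0 < t <= self.post_stimulus_h):
                raise ValueError(
                    f"report time {t} h outside (0, {self.post_stimulus_h}] h window"
                )

    @property
    def total_h(self) -> float:
        return self.equilibration_h + self.post_stimulus_h


@dataclass
class Trajectory:
    """Solver output for one variant.

    ``times_h`` runs from ``-equilibration`` to ``post_stimulus`` with the
    stimulus at t = 0; ``conc`` is (n_states, n_times) in mM; ``states`` are
    the qualified species refs in row order.
    """

    variant_index: int
    times_h: np.ndarray
    conc: np.ndarray
    states: tuple[str, ...]
    status: str = "ok"
    message: str = ""

    @property
    def success(self) -> bool:
        return self.status == "ok"

    def _row(self, species_id: str, compartment: str) -> int:
        ref = f"{species_id}@{compartment}"
        try:
            return self.states.index(ref)
        except ValueError:
            raise KeyError(f"no state {ref!r} in trajectory") from None

    def value(self, species_id: str, compartment: str, time_h: float) -> float:
        """Concentration (mM) at one time, linearly interpolated."""
        row = self._row(species_id, compartment)
        return float(np.interp(time_h, self.times_h, self.conc[row]))

    def series(self, species_id: str, compartment: str,
               times_h: Sequence[float] | None = None) -> np.ndarray:
        row = self._row(species_id, compartment)
        if times_h is None:
            return self.conc[row].copy()
        return np.interp(np.asarray(times_h, dtype=float), self.times_h, self.conc[row])


# ---------------------------------------------------------------------------
# compiled right-hand side


class _CompiledSystem:
    """Vectorised RHS for one (network, variant) pair.

    Reactions are grouped by type into index arrays; the stoichiometry matrix
    carries the donor/acceptor volume ratio on cross-compartment rows so that
    the transport term conserves amount (concentration x volume) exactly.
    """

    def __init__(self, net: Network, variant: ModelVariant):
        self.net = net
        self.variant = variant
        a = variant.assignment

        states = sorted(
            sp.ref for sp in net.species.values() if sp.role == "metabolite"
        )
        self.states: tuple[str, ...] = tuple(states)
        self.index = {ref: i for i, ref in enumerate(states)}
        self.n = len(states)
        self.y0 = np.array(
            [net.species[ref].initial_concentration for ref in states]
        )
        vol = {cid: c.volume_l for cid, c in net.compartments.items()}

        # catalyst concentrations, overridable per segment (induction)
        self.catalysts = sorted({
            parse_ref(r.catalyst)[0]
            for r in net.enabled_reactions() if r.catalyst is not None
        })
        self.cat_index = {cid: i for i, cid in enumerate(self.catalysts)}
        self.baseline_conc = np.array([
            a[enzyme_conc_name(cid)] for cid in self.catalysts
        ])
        self.cat_conc = self.baseline_conc.copy()

        # K_m lookup for competition terms: (catalyst id, substrate ref) -> K_m
        km_of: dict[tuple[str, str], float] = {}
        for rxn in net.enabled_reactions():
            if rxn.rtype in ("enzymatic", "transport") and rxn.catalyst:
                cid = parse_ref(rxn.catalyst)[0]
                for ref, _ in rxn.substrates:
                    km_of.setdefault((cid, ref), a[rxn.parameter_name("K_ms")])

        enz, nonenz, trans, deg = [], [], [], []
        self.release_idx: list[int] = []
        rxn_order: list[tuple[int, int]] = []  # (column, reaction number)
        cols: list[dict] = []

        for rxn in net.enabled_reactions():
            subs = [(s, st) for s, st in rxn.substrates
                    if net.species[s].role == "metabolite"]
            prods = [(s, st) for s, st in rxn.products
                     if net.species[s].role == "metabolite"]
            donor_comp = (
                parse_ref(rxn.substrates[0][0])[1] if rxn.substrates else None
            )
            col = {"subs": subs, "prods": prods, "donor": donor_comp,
                   "number": rxn.number}
            if rxn.rtype == "enzymatic":
                cid = parse_ref(rxn.catalyst)[0]
                comp_terms = [
                    (self.index[c], km_of[(cid, c)])
                    for c in rxn.competitors if (cid, c) in km_of
                ]
                enz.append({
                    "si": self.index[subs[0][0]],
                    "pi": self.index[prods[0][0]],
                    "kcat": a[rxn.parameter_name("k_cat")],
                    "cat": self.cat_index[cid],
                    "Kms": a[rxn.parameter_name("K_ms")],
                    "Kmp": a[rxn.parameter_name("K_mp")],
                    "Keq": a[rxn.parameter_name("K_eq")],
                    "comp": comp_terms,
                })
                col["group"], col["gi"] = "enz", len(enz) - 1
            elif rxn.rtype == "non_enzymatic":
                nonenz.append({
                    "si": self.index[subs[0][0]],
                    "pi": self.index[prods[0][0]],
                    "kf": a[rxn.parameter_name("k_f")],
                    "kr": a[rxn.parameter_name("k_r")],
                })
                col["group"], col["gi"] = "nonenz", len(nonenz) - 1
            elif rxn.rtype == "transport":
                cid = parse_ref(rxn.catalyst)[0]
                comp_terms = [
                    (self.index[c], km_of[(cid, c)])
                    for c in rxn.competitors if (cid, c) in km_of
                ]
                # donor-basis velocity scales with the volume ratio between the
                # transporter's home compartment and the donor compartment: the
                # same carrier pool moves the same amount per second whichever
                # direction it works, so the concentration change it produces
                # in the 1000x larger extracellular donor is 1000x smaller
                cat_comp = parse_ref(rxn.catalyst)[1]
                trans.append({
                    "si": self.index[subs[0][0]],
                    "pi": self.index[prods[0][0]],
                    "kcat": a[transporter_kcat_name(cid)]
                    * vol[cat_comp] / vol[donor_comp],
                    "cat": self.cat_index[cid],
                    "Km": a[rxn.parameter_name("K_ms")],
                    "comp": comp_terms,
                })
                col["group"], col["gi"] = "trans", len(trans) - 1
            elif rxn.rtype == "degradation":
                deg.append({
                    "si": self.index[subs[0][0]],
                    "kdeg": a[rxn.parameter_name("k_deg")],
                })
                col["group"], col["gi"] = "deg", len(deg) - 1
            elif rxn.rtype == "substrate_release":
                if prods:
                    self.release_idx.append(self.index[prods[0][0]])
                col["group"], col["gi"] = "release", None
            else:  # protein_induction rows carry no flux; schedules drive them
                col["group"], col["gi"] = "none", None
            cols.append(col)
            rxn_order.append((len(cols) - 1, rxn.number))

        def pack(group: list[dict], keys: list[str]):
            return {k: np.array([g[k] for g in group]) for k in keys} if group else None

        self.enz = pack(enz, ["si", "pi", "kcat", "cat", "Kms", "Kmp", "Keq"])
        self.nonenz = pack(nonenz, ["si", "pi", "kf", "kr"])
        self.trans = pack(trans, ["si", "pi", "kcat", "cat", "Km"])
        self.deg = pack(deg, ["si", "kdeg"])

        # sparse competition matrices as dense (small system)
        self.enz_comp = np.zeros((len(enz), self.n)) if enz else None
        for i, g in enumerate(enz):
            for j, km in g["comp"]:
                self.enz_comp[i, j] += 1.0 / km
        self.trans_comp = np.zeros((len(trans), self.n)) if trans else None
        for i, g in enumerate(trans):
            for j, km in g["comp"]:
                self.trans_comp[i, j] += 1.0 / km

        # stoichiometry with volume scaling, one column per flux group member
        n_flux = len(enz) + len(nonenz) + len(trans) + len(deg)
        self.N = np.zeros((self.n, n_flux))
        offs = {"enz": 0, "nonenz": len(enz), "trans": len(enz) + len(nonenz),
                "deg": len(enz) + len(nonenz) + len(trans)}
        for col in cols:
            if col["group"] not in offs or col["gi"] is None:
                continue
            j = offs[col["group"]] + col["gi"]
            vd = vol[col["donor"]] if col["donor"] else None
            for ref, st in col["subs"]:
                self.N[self.index[ref], j] -= st
            for ref, st in col["prods"]:
                scale = 1.0
                if vd is not None:
                    scale = vd / vol[parse_ref(ref)[1]]
                self.N[self.index[ref], j] += st * scale

        self._n_enz, self._n_nonenz = len(enz), len(nonenz)
        self._n_trans, self._n_deg = len(trans), len(deg)

        # release segment context (seconds); inactive until configured
        self.release_active = False
        self.seg_t0_s = 0.0
        self.seg_a0 = 0.0
        self.seg_target = 0.0
        self.seg_tau_s = 1.0

    # -- segment context ---------------------------------------------------
    def set_release_segment(self, t0_s: float, a0: float, target: float,
                            tau_h: float) -> None:
        self.release_active = True
        self.seg_t0_s = t0_s
        self.seg_a0 = a0
        self.seg_target = target
        self.seg_tau_s = tau_h * H

    def clear_release(self) -> None:
        self.release_active = False

    def set_catalyst_conc(self, conc: dict[str, float]) -> None:
        self.cat_conc = self.baseline_conc.copy()
        for cid, c in conc.items():
            self.cat_conc[self.cat_index[cid]] = c

    # -- RHS ----------------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        yc = np.maximum(y, 0.0)
        v = np.empty(self._n_enz + self._n_nonenz + self._n_trans + self._n_deg)
        o = 0
        if self.enz is not None:
            g = self.enz
            S, P = yc[g["si"]], yc[g["pi"]]
            den = 1.0 + S / g["Kms"] + P / g["Kmp"] + self.enz_comp @ yc
            E = self.cat_conc[g["cat"]]
            v[o:o + self._n_enz] = (
                g["kcat"] * E * (S / g["Kms"] - P / (g["Kms"] * g["Keq"])) / den
            )
            o += self._n_enz
        if self.nonenz is not None:
            g = self.nonenz
            v[o:o + self._n_nonenz] = g["kf"] * yc[g["si"]] - g["kr"] * yc[g["pi"]]
            o += self._n_nonenz
        if self.trans is not None:
            g = self.trans
            S = yc[g["si"]]
            den = 1.0 + S / g["Km"] + self.trans_comp @ yc
            T = self.cat_conc[g["cat"]]
            v[o:o + self._n_trans] = g["kcat"] * T * (S / g["Km"]) / den
            o += self._n_trans
        if self.deg is not None:
            g = self.deg
            v[o:o + self._n_deg] = g["kdeg"] * yc[g["si"]]

        dy = self.N @ v
        if self.release_active and self.release_idx:
            A = self.seg_target + (self.seg_a0 - self.seg_target) * math.exp(
                -LN2 * (t - self.seg_t0_s) / self.seg_tau_s
            )
            raw = (LN2 / self.seg_tau_s) * (self.seg_target - A)  # mM/s
            for i in self.release_idx:
                flux = raw if raw >= 0 else raw * (yc[i] / (yc[i] + 1e-9))
                dy[i] += flux
        return dy


def assemble_odes(
    net: Network,
    variant: ModelVariant,
    release: ReleaseProfile | None = None,
) -> tuple[Callable[[float, np.ndarray], np.ndarray], tuple[str, ...], np.ndarray]:
    """Build the RHS f(t_seconds, y) for one variant.

    Returns ``(rhs, state refs, y0)``.  If a release profile is given it is
    active from t = 0 using its first segment only; :func:`run_variant` is the
    protocol-aware driver that walks all segments.
    """
    sys_ = _CompiledSystem(net, variant)
    if release is not None:
        seg = release.segments(t_end=1e9)[0]
        sys_.set_release_segment(seg.t0 * H, seg.a0, seg.target, seg.tau)
    return sys_.rhs, sys_.states, sys_.y0


def run_variant(
    net: Network,
    variant: ModelVariant,
    protocol: SimulationProtocol,
) -> Trajectory:
    """Integrate one variant through equilibration and the stimulated window.

    Integration failures are captured in the trajectory status; this function
    never raises for numerical trouble, so ensembles survive pathological
    parameter draws.
    """
    try:
        system = _CompiledSystem(net, variant)
    except KeyError as exc:
        raise KeyError(f"variant {variant.index}: missing parameter {exc}") from None

    # segment boundaries in hours post-stimulus
    bounds: set[float] = set()
    release_segs = []
    if protocol.release is not None:
        release_segs = protocol.release.segments(protocol.post_stimulus_h)
        bounds.update(seg.t0 for seg in release_segs)
    for sched in protocol.induction:
        bounds.update(t for t, _ in sched.steps)
    bounds = sorted(b for b in bounds if 0 < b < protocol.post_stimulus_h)
    edges_h = [0.0] + bounds + [protocol.post_stimulus_h]

    times: list[np.ndarray] = []
    concs: list[np.ndarray] = []
    y = system.y0.copy()

    def integrate(t0_s: float, t1_s: float, y0: np.ndarray,
                  extra_pts: Sequence[float]) -> np.ndarray | None:
        n_grid = max(5, int(round((t1_s - t0_s) / H * protocol.grid_per_hour)))
        t_eval = np.unique(np.concatenate([
            np.linspace(t0_s, t1_s, n_grid),
            np.asarray(sorted(extra_pts)),
        ]))
        sol = solve_ivp(
            system.rhs, (t0_s, t1_s), y0, method="LSODA",
            t_eval=t_eval, rtol=protocol.rtol, atol=protocol.atol,
        )
        if not sol.success:
            return None
        times.append(sol.t)
        concs.append(sol.y)
        return sol.y[:, -1]

    try:
        # equilibration: release inactive
        if protocol.equilibration_h > 0:
            system.clear_release()
            y = integrate(-protocol.equilibration_h * H, 0.0, y, [])
            if y is None:
                return _failed(variant, system, "equilibration failed")

        for t0_h, t1_h in zip(edges_h, edges_h[1:]):
            if protocol.release is not None:
                seg = next(
                    s for s in release_segs
                    if s.t0 <= t0_h and (t0_h < s.t1 or s is release_segs[-1])
                )
                system.set_release_segment(
                    seg.t0 * H, seg.a0, seg.target, seg.tau
                )
            else:
                system.clear_release()
            if protocol.induction:
                conc = {}
                for sched in protocol.induction:
                    base = system.baseline_conc[system.cat_index[sched.enzyme]]
                    conc[sched.enzyme] = induction_level(t0_h, sched, base)
                system.set_catalyst_conc(conc)
            report_s = [t * H for t in protocol.report_times_h if t0_h < t <= t1_h]
            y = integrate(t0_h * H, t1_h * H, y, report_s)
            if y is None:
                return _failed(variant, system, f"segment [{t0_h}, {t1_h}] h failed")
    except Exception as exc:  # pragma: no cover - defensive
        return _failed(variant, system, f"{type(exc).__name__}: {exc}")

    t_all = np.concatenate(times)
    c_all = np.concatenate(concs, axis=1)
    t_all, keep = np.unique(np.round(t_all, 9), return_index=True)
    return Trajectory(
        variant_index=variant.index,
        times_h=t_all / H,
        conc=c_all[:, keep],
        states=system.states,
    )


def _failed(variant: ModelVariant, system: _CompiledSystem, msg: str) -> Trajectory:
    log.warning("variant %d integration failed: %s", variant.index, msg)
    return Trajectory(
        variant_index=variant.index,
        times_h=np.array([]),
        conc=np.empty((len(system.states), 0)),
        states=system.states,
        status="failed",
        message=msg,
    )
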