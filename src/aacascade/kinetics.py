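"""Rate laws: substrate release, induction, enzymatic/non-enzymatic/transport
kinetics and first-order degradation.

All rate functions are pure, continuous on the non-negative orthant and keep
the thermodynamic sign convention sign(v) = sign(S - P/K_eq) for reversible
laws.  Concentrations are mM, rate constants s^-1, velocities mM s^-1;
interfaces that speak about protocol time use hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ReleaseProfile",
    "InductionSchedule",
    "release_concentration",
    "release_rate",
    "cumulative_release",
    "induction_level",
    "enzymatic_rate",
    "non_enzymatic_rate",
    "transport_rate",
    "degradation_rate",
]

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# substrate release (available-AA profile)


@dataclass(frozen=True)
class ReleaseProfile:
    """Time course of substrate (AA) made available after the stimulus.

    The profile is piecewise: in each segment the available concentration
    relaxes exponentially from its current level towards a target with the
    segment's doubling time, ``A(t) = target + (A0 - target) * 2^(-(t-t0)/tau)``.
    The default single segment rises from zero towards ``max_conc_6h``.  With
    ``decay_switch`` set, an automatic segment starting at ``peak_time``
    targets zero with ``tau = half_life``, so the available concentration
    halves every half-life after the peak.  ``schedule`` entries re-assign
    ``max_conc_6h`` and/or ``doubling_time`` at set times (hours after the
    stimulus), which is how the delayed / pulsed release dynamics are built.
    """

    max_conc_6h: float  # mM, level the release relaxes towards
    doubling_time: float = 0.25  # h
    half_life: float = 1.0  # h
    decay_switch: bool = False
    peak_time: float | None = None  # h; start of the decay segment
    schedule: tuple[tuple[float, dict], ...] = ()

    def __post_init__(self) -> None:
        if self.max_conc_6h < 0:
            raise ValueError("max_conc_6h must be >= 0")
        if not self.doubling_time > 0:
            raise ValueError("doubling_time must be > 0")
        if not self.half_life > 0:
            raise ValueError("half_life must be > 0")
        if self.decay_switch and self.peak_time is None:
            raise ValueError("decay_switch requires peak_time")
        times = [t for t, _ in self.schedule]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")
        if any(t < 0 for t in times):
            raise ValueError("schedule times must be >= 0")

    def segments(self, t_end: float) -> list["_Segment"]:
        """Resolve the piecewise description into concrete segments."""
        events: list[tuple[float, dict | None]] = [(t, dict(upd)) for t, upd in self.schedule]
        if self.decay_switch:
            events.append((float(self.peak_time), None))  # None marks decay onset
        events.sort(key=lambda e: e[0])

        segs: list[_Segment] = []
        target = self.max_conc_6h
        tau = self.doubling_time
        a0, t0 = 0.0, 0.0
        for t_ev, upd in events:
            if t_ev > t0:
                segs.append(_Segment(t0, t_ev, a0, target, tau))
                a0 = segs[-1].value(t_ev)
                t0 = t_ev
            if upd is None:  # decay onset
                target, tau = 0.0, self.half_life
            else:
                target = float(upd.get("max_conc_6h", target))
                tau = float(upd.get("doubling_time", tau))
        segs.append(_Segment(t0, max(t_end, t0), a0, target, tau))
        return segs


@dataclass(frozen=True)
class _Segment:
    t0: float
    t1: float
    a0: float
    target: float
    tau: float  # h

    def value(self, t: float) -> float:
        return self.target + (self.a0 - self.target) * 2.0 ** (-(t - self.t0) / self.tau)

    def rate(self, t: float) -> float:
        """dA/dt in mM per hour."""
        return (LN2 / self.tau) * (self.target - self.value(t))


def _segment_at(profile: ReleaseProfile, t: float) -> _Segment:
    segs = profile.segments(t_end=t)
    for seg in segs:
        if t < seg.t1 or seg is segs[-1]:
            return seg
    return segs[-1]


def release_concentration(t: float, profile: ReleaseProfile) -> float:
    """Available substrate concentration (mM) at ``t`` hours post-stimulus."""
    if t < 0:
        raise ValueError("release_concentration: t must be >= 0")
    return _segment_at(profile, t).value(t)


def release_rate(t: float, profile: ReleaseProfile) -> float:
    """dA/dt (mM per hour) at ``t`` hours post-stimulus."""
    if t < 0:
        raise ValueError("release_rate: t must be >= 0")
    return _segment_at(profile, t).rate(t)


def cumulative_release(t: float, profile: ReleaseProfile) -> float:
    """Total substrate released (mM) on [0, t]: the integral of max(dA/dt, 0).

    Within each segment the available concentration approaches its target
    monotonically, so the positive-flux integral is the segment's net rise
    (exact closed form; withdrawal during decay segments is not counted).
    For monotone profiles this equals ``release_concentration(t)``.
    """
    if t <= 0:
        return 0.0
    total = 0.0
    for seg in profile.segments(t_end=t):
        t1 = min(seg.t1, t)
        if t1 <= seg.t0:
            break
        total += max(seg.value(t1) - seg.a0, 0.0)
    return total


# ---------------------------------------------------------------------------
# protein induction


@dataclass(frozen=True)
class InductionSchedule:
    """Piecewise-constant enzyme-concentration programme.

    ``steps`` are ``(time h post-stimulus, target concentration mM)``; the
    enzyme sits at its sampled baseline before the first step and jumps to the
    most recent target at each step time (right-continuous).
    """

    enzyme: str  # species id
    steps: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        times = [t for t, _ in self.steps]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("induction step times must be strictly increasing")
        if any(c < 0 for _, c in self.steps):
            raise ValueError("induction targets must be >= 0")


def induction_level(t: float, schedule: InductionSchedule, baseline: float) -> float:
    """Enzyme concentration (mM) at ``t`` hours post-stimulus."""
    level = baseline
    for t_step, target in schedule.steps:
        if t >= t_step:
            level = target
        else:
            break
    return level


# ---------------------------------------------------------------------------
# reaction rate laws


def _check_nonneg(**conc: float) -> None:
    for name, c in conc.items():
        if c < 0:
            raise ValueError(f"negative concentration {name}={c}")


def enzymatic_rate(
    S: float,
    P: float,
    E: float,
    k_cat: float,
    K_ms: float,
    K_mp: float,
    K_eq: float,
    competitors: Sequence[tuple[float, float]] = (),
) -> float:
    """Reversible uni-uni Michaelis-Menten velocity with competitive binding.

    v = k_cat E (S/K_ms - P/(K_ms K_eq)) / (1 + S/K_ms + P/K_mp + sum C_j/K_mj)

    Competitors are ``(concentration, K_m)`` pairs of other species binding the
    same enzyme; they scale the magnitude of v but never flip its sign.
    """
    _check_nonneg(S=S, P=P, E=E)
    for c, _ in competitors:
        _check_nonneg(competitor=c)
    if min(k_cat, K_ms, K_mp, K_eq) <= 0 or any(km <= 0 for _, km in competitors):
        raise ValueError("kinetic parameters must be > 0")
    num = k_cat * E * (S / K_ms - P / (K_ms * K_eq))
    den = 1.0 + S / K_ms + P / K_mp + sum(c / km for c, km in competitors)
    return num / den


def non_enzymatic_rate(S: float, P: float, k_f: float, k_r: float) -> float:
    """Reversible first-order velocity v = k_f S - k_r P."""
    _check_nonneg(S=S, P=P)
    if k_f <= 0 or k_r <= 0:
        raise ValueError("rate constants must be > 0")
    return k_f * S - k_r * P


def transport_rate(
    substrate: tuple[float, float],
    co_transported: Sequence[tuple[float, float]],
    T: float,
    k_cat: float,
) -> float:
    """Saturable carrier flux with competition, donor-compartment basis.

    v = k_cat T (S/K_m) / (1 + S/K_m + sum S_j/K_mj); with no co-transported
    species this is plain Michaelis-Menten.
    """
    S, K_m = substrate
    _check_nonneg(S=S, T=T)
    for c, _ in co_transported:
        _check_nonneg(co_transported=c)
    if K_m <= 0 or k_cat <= 0 or any(km <= 0 for _, km in co_transported):
        raise ValueError("transport parameters must be > 0")
    den = 1.0 + S / K_m + sum(c / km for c, km in co_transported)
    return k_cat * T * (S / K_m) / den


def degradation_rate(S: float, k_deg: float) -> float:
    """First-order removal v = k_deg S."""
    _check_nonneg(S=S)
    if k_deg < 0:
        raise ValueError("k_deg must be >= 0")
    return k_deg * S
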