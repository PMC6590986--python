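"""Closed-form model of periodic inhibitory synaptic conductance and follower
burst-onset phase.

The follower neuron (modeled after the pyloric LP neuron) is assumed to be
silenced whenever the synaptic conductance ``g_syn`` exceeds a threshold
``g*`` and to fire as soon as ``g_syn`` falls below it.  The conductance obeys
a two-phase linear ODE within each cycle of period ``P``::

    dg/dt = (g_max - g)/tau_r   for 0 <= t (mod P) < t_peak   (rise)
    dg/dt = -g/tau_s            for t_peak <= t (mod P) < P   (decay)

The periodic fixed point has a closed form, as does the threshold-crossing
delay ``Δt`` and hence the burst-onset phase ``φ = Δt/P``.  Two stimulation
regimes are distinguished: constant duration (C-Dur, fixed active time
``T_act``) and constant duty cycle (C-DC, ``T_act = DC·P``).

Units package-wide: time in ms, conductance in µS, current in nA, voltage
in mV.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "Mode",
    "SynapseSchedule",
    "PhaseModelParams",
    "PeriodicSolution",
    "solve_periodic_conductance",
    "burst_delay",
    "phase_simplified",
    "phase_full",
    "triangle_burst_delay",
]


class Mode(str, enum.Enum):
    """Stimulation regime of the periodic synaptic input."""

    C_DUR = "C_DUR"  #: constant active duration T_act across periods
    C_DC = "C_DC"    #: constant duty cycle, T_act = DC * P


@dataclass(frozen=True)
class SynapseSchedule:
    """One periodic synaptic input.

    Parameters
    ----------
    P : float
        Cycle period, ms.
    mode : Mode
        C_DUR (fixed ``T_act``) or C_DC (fixed duty cycle ``DC``).
    g_max : float
        Peak conductance, µS.
    delta_peak : float
        Phase of the conductance peak within the active window, in [0, 1].
    T_act : float, optional
        Active duration, ms (required in C_DUR mode).
    DC : float, optional
        Duty cycle in (0, 1) (required in C_DC mode).
    """

    P: float
    mode: Mode
    g_max: float
    delta_peak: float
    T_act: float | None = None
    DC: float | None = None

    def __post_init__(self) -> None:
        mode = Mode(self.mode)
        object.__setattr__(self, "mode", mode)
        if not (self.P > 0):
            raise ValueError(f"P must be positive, got {self.P}")
        if not (0.0 <= self.delta_peak <= 1.0):
            raise ValueError(f"delta_peak must lie in [0, 1], got {self.delta_peak}")
        if not (self.g_max > 0):
            raise ValueError(f"g_max must be positive, got {self.g_max}")
        if mode is Mode.C_DUR:
            if self.T_act is None:
                raise ValueError("C_DUR schedule requires T_act")
            if not (0 < self.T_act <= self.P):
                raise ValueError(f"T_act must satisfy 0 < T_act <= P, got {self.T_act}")
        else:
            if self.DC is None:
                raise ValueError("C_DC schedule requires DC")
            if not (0 < self.DC < 1):
                raise ValueError(f"DC must lie in (0, 1), got {self.DC}")
        if not (0.0 <= self.t_peak < self.P):
            raise ValueError(
                f"derived t_peak={self.t_peak} must lie in [0, P={self.P})"
            )

    @property
    def active_duration(self) -> float:
        """Active duration T_act in ms, whichever mode."""
        if self.mode is Mode.C_DUR:
            return float(self.T_act)
        return float(self.DC * self.P)

    @property
    def duty_cycle(self) -> float:
        """T_act / P."""
        return self.active_duration / self.P

    @property
    def t_peak(self) -> float:
        """Time of the conductance peak from conductance onset, ms."""
        return self.delta_peak * self.active_duration


@dataclass(frozen=True)
class PhaseModelParams:
    """Kinetic and threshold parameters of the phase model.

    tau_r : synaptic rise time constant, ms (small in the simplified model)
    tau_s : synaptic decay time constant, ms
    g_star : conductance threshold below which the follower fires, µS
    """

    tau_r: float
    tau_s: float
    g_star: float

    def __post_init__(self) -> None:
        if not (self.tau_r > 0 and self.tau_s > 0 and self.g_star > 0):
            raise ValueError("tau_r, tau_s and g_star must all be positive")


#: Fit to the biological dynamic-clamp data with realistic waveforms:
#: tau_s = 26.0 ms, g* = 0.021 µS (lumped peak-phase term 0.43 handled
#: separately).  tau_r is nominally instantaneous.
DEFAULT_PARAMS = PhaseModelParams(tau_r=0.1, tau_s=26.0, g_star=0.021)


@dataclass(frozen=True)
class PeriodicSolution:
    """Steady-state summary of one periodic cycle.

    g_lo / g_peak are the cycle minimum / maximum of the conductance (µS),
    dt the burst-onset delay from conductance onset (ms) and phi = dt/P the
    burst-onset phase.  ``subthreshold`` marks inputs that never exceed
    ``g*`` (the follower fires immediately, phi = 0); ``not_entrained`` marks
    delays of a full period or more (phi >= 1 is reported unwrapped).
    """

    g_lo: float
    g_peak: float
    dt: float
    phi: float
    subthreshold: bool = False
    not_entrained: bool = False


def solve_periodic_conductance(
    schedule: SynapseSchedule, params: PhaseModelParams
) -> PeriodicSolution:
    """Closed-form periodic fixed point of the rise/decay conductance ODE.

    With ``E_r = exp(-t_peak/tau_r)`` and ``E_s = exp(-(P - t_peak)/tau_s)``,
    periodicity (g(0) = g(P) = g_lo) gives

        g_peak = g_max (1 - E_r) / (1 - E_r E_s),   g_lo = g_peak E_s.

    The burst delay is then obtained from the decay branch via
    :func:`burst_delay`.
    """
    t_peak = schedule.t_peak
    P = schedule.P
    if t_peak >= P:
        raise ValueError("t_peak must be strictly less than P")
    E_r = math.exp(-t_peak / params.tau_r)
    E_s = math.exp(-(P - t_peak) / params.tau_s)
    g_peak = schedule.g_max * (1.0 - E_r) / (1.0 - E_r * E_s)
    g_lo = g_peak * E_s
    dt, subthreshold = burst_delay(g_peak, t_peak, params)
    phi = dt / P
    return PeriodicSolution(
        g_lo=g_lo,
        g_peak=g_peak,
        dt=dt,
        phi=phi,
        subthreshold=subthreshold,
        not_entrained=bool(dt >= P),
    )


def burst_delay(
    g_peak: float, t_peak: float, params: PhaseModelParams
) -> tuple[float, bool]:
    """Delay from conductance onset to the threshold crossing g_syn = g*.

    On the decay branch g_syn(t) = g_peak exp(-(t - t_peak)/tau_s), so the
    crossing occurs at ``Δt = tau_s ln(g_peak/g*) + t_peak``.  Returns
    ``(dt, subthreshold)``; a peak at or below threshold yields dt = 0 with
    the subthreshold flag set (the follower is never silenced).
    """
    if g_peak < 0:
        raise ValueError("g_peak must be non-negative")
    if g_peak <= params.g_star:
        return 0.0, True
    return params.tau_s * math.log(g_peak / params.g_star) + t_peak, False


def phase_simplified(
    schedule: SynapseSchedule, params: PhaseModelParams
) -> PeriodicSolution:
    """Instantaneous-rise closed form for the burst-onset phase.

    Assumes g_syn jumps to g_max at onset, holds it until t_peak, then decays
    with tau_s.  C-Dur:  φ = (tau_s ln(g_max/g*) + Δ_peak T_act) / P.
    C-DC:   φ = (tau_s/P) ln(g_max/g*) + Δ_peak DC, which tends to
    Δ_peak·DC as P → ∞ (the C-Dur form tends to 0).
    """
    t_peak = schedule.t_peak
    dt, subthreshold = burst_delay(schedule.g_max, t_peak, params)
    phi = dt / schedule.P
    return PeriodicSolution(
        g_lo=0.0,
        g_peak=schedule.g_max,
        dt=dt,
        phi=phi,
        subthreshold=subthreshold,
        not_entrained=bool(dt >= schedule.P),
    )


def phase_full(
    schedule: SynapseSchedule, params: PhaseModelParams
) -> PeriodicSolution:
    """Burst-onset phase from the full periodic fixed point.

    φ = (tau_s ln(g_peak/g*) + t_peak) / P with g_peak from
    :func:`solve_periodic_conductance`.  Reduces to :func:`phase_simplified`
    in the tau_r → 0, P → ∞ limit.
    """
    return solve_periodic_conductance(schedule, params)


def triangle_burst_delay(
    schedule: SynapseSchedule, g_star: float
) -> tuple[float, bool]:
    """Threshold crossing of the triangular conductance waveform itself.

    The dynamic-clamp experiments inject a triangle: linear rise 0 → g_max
    over [0, t_peak], linear fall g_max → 0 over [t_peak, T_act].  The
    downward crossing of ``g_star`` is exact geometry:

        Δt = t_peak + (1 - g*/g_max) (T_act - t_peak)

    This is the reference the simulator bridge is compared against; the
    exponential-decay closed forms are surrogates for it.
    """
    if g_star <= 0:
        raise ValueError("g_star must be positive")
    if schedule.g_max <= g_star:
        return 0.0, True
    t_peak = schedule.t_peak
    T_act = schedule.active_duration
    dt = t_peak + (1.0 - g_star / schedule.g_max) * (T_act - t_peak)
    return dt, False
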