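"""Synthetic dynamic-clamp data generator.

Emulates the experimental protocols on a simulated follower neuron so the
whole analysis pipeline runs without recordings:

* triangular and realistic periodic synaptic conductance waveforms,
* Ornstein–Uhlenbeck noise current with a DC offset,
* a leaky integrate-and-fire (LIF) follower that fires tonically when
  uninhibited and is silenced while the synaptic conductance is high,
* grid protocols sweeping (P, g_max, Δ_peak) in the constant-duration and
  constant-duty-cycle regimes, yielding long-format burst-onset phase
  surfaces.

The LIF membrane obeys

    C_m dV/dt = -g_L (V - E_L) - g_syn (V - E_syn) + I_drive + I_ext

with threshold/reset/refractory spiking (Euler integration, linear
interpolation of threshold-crossing times).  For a constant conductance the
silence/fire boundary of this neuron is the effective threshold

    g* = (I_drive - g_L (V_th - E_L)) / (V_th - E_syn)

which bridges the simulator to the closed-form phase model's ``g*``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .core_model import Mode, SynapseSchedule

__all__ = [
    "SampledTrace",
    "OUParams",
    "FollowerNeuronParams",
    "RealisticTemplate",
    "ClampProtocol",
    "DEFAULT_NEURON",
    "noise_protocol_neuron",
    "triangle_waveform",
    "realistic_waveform",
    "ou_current",
    "simulate_follower",
    "effective_threshold",
    "run_clamp_grid",
]


@dataclass
class SampledTrace:
    """Uniformly sampled trace (conductance µS, current nA or voltage mV)."""

    dt: float
    values: np.ndarray
    kind: str = "conductance"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("trace must be a non-empty 1-D array")
        if self.kind == "conductance" and np.any(self.values < 0):
            raise ValueError("conductance traces must be non-negative")

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)


@dataclass(frozen=True)
class OUParams:
    """Ornstein–Uhlenbeck noise current: dX = -X/tau dt + sigma-scaled dW.

    ``sigma`` is the *stationary standard deviation* of the process in nA
    (0.2 nA = 200 pA by default); ``I_DC`` is the DC offset in nA.
    """

    tau: float = 15.0
    sigma: float = 0.2
    I_DC: float = -0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class FollowerNeuronParams:
    """LIF stand-in for the follower (LP-like) neuron.

    C_m nF, g_L µS, voltages mV, times ms, currents nA.  ``I_drive`` is the
    tonic depolarizing drive standing in for the neuron's intrinsic
    excitability (it fires tonically in the absence of inhibition).
    """

    C_m: float = 5.0
    g_L: float = 0.1
    E_L: float = -60.0
    V_th: float = -45.0
    V_reset: float = -55.0
    t_ref: float = 2.0
    I_drive: float = 2.235
    E_syn: float = -80.0

    def __post_init__(self) -> None:
        if not (self.V_reset < self.V_th):
            raise ValueError("V_reset must be below V_th")
        if not (self.g_L > 0 and self.C_m > 0):
            raise ValueError("g_L and C_m must be positive")
        if not (self.E_syn < self.V_reset):
            raise ValueError("E_syn must be below V_reset")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m/g_L, ms."""
        return self.C_m / self.g_L


#: Dynamic-clamp configuration: I_drive sets the effective threshold to
#: 0.021 µS (the scale fitted to the biological data) and tau_m = 50 ms
#: gives the follower a post-release rebound latency of tens of ms, which
#: extends the burst phase beyond the synaptic envelope the way the real
#: follower's recovery dynamics do.  Model-bridge checks use a fast-membrane
#: variant (C_m = 0.2 nF, tau_m = 2 ms) in which that latency is negligible.
DEFAULT_NEURON = FollowerNeuronParams()


def noise_protocol_neuron() -> FollowerNeuronParams:
    """Follower configuration for the noise-current protocol.

    The biological follower in synaptic blockers integrates its input over
    slow intrinsic currents, so noise drive produces irregular bursts
    separated by silent periods of hundreds of ms.  A fast LIF cannot do
    this, so the noise protocol uses a slow-integrator variant
    (tau_m = 1 s, an effective constant standing in for the neuron's slow
    envelope dynamics, not a biophysical membrane value) with a depolarized
    reset just below threshold (plateau-like, so bursts of several spikes
    persist while the integrated drive stays high).  A deep noise
    excursion then leaves a charge deficit that takes hundreds of ms to
    reclaim, producing inter-burst intervals that span the 300–900 ms
    analysis bins with deeper average inhibition before longer intervals.
    """
    return FollowerNeuronParams(
        C_m=100.0, g_L=0.1, I_drive=1.7, t_ref=5.0, V_reset=-45.5
    )


def triangle_waveform(
    schedule: SynapseSchedule, dt: float, n_cycles: int
) -> SampledTrace:
    """Periodic triangular conductance: linear rise 0→g_max over
    [0, t_peak], linear fall g_max→0 over [t_peak, T_act], zero elsewhere.

    Δ_peak = 0 or 1 give one-sided ramps (instant rise or instant drop).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    n = int(round(n_cycles * schedule.P / dt))
    t = np.arange(n) * dt
    tau = np.mod(t, schedule.P)
    t_peak = schedule.t_peak
    T_act = schedule.active_duration
    g = np.zeros(n)
    if t_peak > 0:
        rising = tau < t_peak
        g[rising] = schedule.g_max * tau[rising] / t_peak
    if T_act > t_peak:
        falling = (tau >= t_peak) & (tau < T_act)
        g[falling] = schedule.g_max * (T_act - tau[falling]) / (T_act - t_peak)
    elif t_peak > 0:
        # delta_peak == 1: instant drop at T_act; peak sample included above
        pass
    if t_peak == 0:
        # instant rise: decay occupies the whole active window
        falling = tau < T_act
        g[falling] = schedule.g_max * (T_act - tau[falling]) / T_act
    return SampledTrace(dt=dt, values=g, kind="conductance")


@dataclass(frozen=True)
class RealisticTemplate:
    """Smooth synthetic stand-in for a recorded pyloric IPSC waveform.

    Sum of two raised-cosine bumps spanning one normalized cycle: an early
    smaller bump (follower PY input) and a late dominant bump (pacemaker
    AB/PD input).  ``kink_phase`` marks the pacemaker-onset reference (the
    'kink') as a fraction of the cycle span; burst latency in the realistic
    protocol is measured from it.
    """

    py_center: float = 0.30
    py_width: float = 0.25
    py_amp: float = 0.6
    pm_center: float = 0.70
    pm_width: float = 0.15
    pm_amp: float = 1.0
    kink_phase: float = 0.55  # pacemaker onset = pm_center - pm_width

    def unit_shape(self, x: np.ndarray) -> np.ndarray:
        """Unit-amplitude waveform on normalized time x ∈ [0, 1)."""

        def bump(c: float, w: float, a: float) -> np.ndarray:
            y = np.zeros_like(x)
            m = np.abs(x - c) < w
            y[m] = a * 0.5 * (1.0 + np.cos(np.pi * (x[m] - c) / w))
            return y

        y = bump(self.py_center, self.py_width, self.py_amp) + bump(
            self.pm_center, self.pm_width, self.pm_amp
        )
        return y / y.max() if y.max() > 0 else y


def realistic_waveform(
    P: float,
    g_max: float,
    template: RealisticTemplate | None = None,
    *,
    dt: float,
    n_cycles: int,
) -> tuple[SampledTrace, float]:
    """Realistic IPSC conductance scaled to period P and amplitude g_max.

    Pure time scaling: doubling P doubles every feature time.  Returns the
    trace and the kink time (pacemaker onset reference) within each cycle.
    """
    if template is None:
        template = RealisticTemplate()
    n = int(round(n_cycles * P / dt))
    t = np.arange(n) * dt
    x = np.mod(t, P) / P
    # evaluate the unit shape once per sample grid of one cycle for speed
    g = g_max * template.unit_shape(x)
    kink_time = template.kink_phase * P
    return SampledTrace(dt=dt, values=g, kind="conductance"), kink_time


@njit(cache=True)
def _ou_fill(noise, a, b, x0):  # pragma: no cover - numba kernel
    n = noise.size
    out = np.empty(n)
    x = x0
    for i in range(n):
        x = a * x + b * noise[i]
        out[i] = x
    return out


def ou_current(params: OUParams, duration: float, dt: float) -> SampledTrace:
    """Exact-discretization OU noise current with DC offset.

    X_{k+1} = X_k e^{-dt/tau} + sigma sqrt(1 - e^{-2 dt/tau}) N(0,1); the
    output is I_DC + X with X started from its stationary distribution.
    Reproducible for a fixed seed.
    """
    if duration < dt:
        raise ValueError("duration must be at least dt")
    n = int(round(duration / dt))
    rng = np.random.default_rng(params.seed)
    a = math.exp(-dt / params.tau)
    b = params.sigma * math.sqrt(1.0 - a * a)
    noise = rng.standard_normal(n + 1)
    x = _ou_fill(noise[1:], a, b, params.sigma * noise[0])
    return SampledTrace(dt=dt, values=params.I_DC + x, kind="current")


@njit(cache=True)
def _lif_core(
    n,
    dt,
    g_syn,
    I_ext,
    C_m,
    g_L,
    E_L,
    V_th,
    V_reset,
    t_ref,
    I_drive,
    E_syn,
    V0,
    store_v,
):  # pragma: no cover - numba kernel
    has_g = g_syn.size > 0
    has_i = I_ext.size > 0
    V = np.empty(n if store_v else 1)
    cap = n + 2
    if t_ref > dt:
        cap = int(n * dt / t_ref) + 2
    spikes = np.empty(cap)
    n_sp = 0
    v = V0
    release = -1.0e30
    if store_v:
        V[0] = v
    for i in range(1, n):
        t_prev = (i - 1) * dt
        if t_prev < release:
            v = V_reset
        else:
            g = g_syn[i - 1] if has_g else 0.0
            I = I_ext[i - 1] if has_i else 0.0
            dv = (
                -g_L * (v - E_L) - g * (v - E_syn) + I_drive + I
            ) * dt / C_m
            v_new = v + dv
            if v_new >= V_th:
                frac = (V_th - v) / (v_new - v) if v_new > v else 1.0
                t_sp = t_prev + frac * dt
                spikes[n_sp] = t_sp
                n_sp += 1
                release = t_sp + t_ref
                v_new = V_reset
            v = v_new
        if store_v:
            V[i] = v
    return V, spikes[:n_sp]


def simulate_follower(
    neuron: FollowerNeuronParams,
    g_syn: SampledTrace | None = None,
    I_ext: SampledTrace | None = None,
    duration: float | None = None,
    *,
    dt: float | None = None,
    V0: float | None = None,
    store_voltage: bool = True,
) -> tuple[SampledTrace | None, np.ndarray]:
    """Integrate the LIF follower under synaptic conductance and/or current.

    Returns ``(voltage_trace, spike_times)``; the voltage trace is ``None``
    when ``store_voltage`` is False (long noise runs).  Inputs must share
    ``dt``; non-finite samples are rejected.
    """
    if g_syn is None and I_ext is None:
        if duration is None or dt is None:
            raise ValueError("need duration and dt when no input traces given")
        n = int(round(duration / dt))
    else:
        dts = {tr.dt for tr in (g_syn, I_ext) if tr is not None}
        if len(dts) > 1:
            raise ValueError("g_syn and I_ext must share dt")
        trace_dt = dts.pop()
        if dt is not None and not math.isclose(dt, trace_dt):
            raise ValueError("dt argument conflicts with trace dt")
        dt = trace_dt
        n = min(tr.values.size for tr in (g_syn, I_ext) if tr is not None)
        if duration is not None:
            n = min(n, int(round(duration / dt)))
    g_arr = g_syn.values[:n] if g_syn is not None else np.empty(0)
    i_arr = I_ext.values[:n] if I_ext is not None else np.empty(0)
    for arr, name in ((g_arr, "g_syn"), (i_arr, "I_ext")):
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite samples")
    v0 = neuron.E_L if V0 is None else float(V0)
    V, spikes = _lif_core(
        n,
        dt,
        np.ascontiguousarray(g_arr, dtype=np.float64),
        np.ascontiguousarray(i_arr, dtype=np.float64),
        neuron.C_m,
        neuron.g_L,
        neuron.E_L,
        neuron.V_th,
        neuron.V_reset,
        neuron.t_ref,
        neuron.I_drive,
        neuron.E_syn,
        v0,
        store_voltage,
    )
    vt = SampledTrace(dt=dt, values=V, kind="voltage") if store_voltage else None
    return vt, spikes


def effective_threshold(neuron: FollowerNeuronParams) -> float:
    """Conductance at which constant inhibition just silences the neuron.

    Setting the steady-state voltage equal to V_th under constant g_syn:

        g* = (I_drive - g_L (V_th - E_L)) / (V_th - E_syn)

    Below-rheobase neurons return 0 (they never fire, so any inhibition
    silences them).
    """
    g = (neuron.I_drive - neuron.g_L * (neuron.V_th - neuron.E_L)) / (
        neuron.V_th - neuron.E_syn
    )
    return max(g, 0.0)


@dataclass(frozen=True)
class ClampProtocol:
    """Grid protocol for the dynamic-clamp sweeps.

    The triangular protocol covers both regimes on the experimental grids
    (P = 500–2000 ms, g_max = 0.1/0.2/0.4 µS, Δ_peak = 0…1, T_act = 300 ms
    or DC = 0.3); the realistic protocol sweeps P = 500–2000 ms and
    g_max = 0.1–0.8 µS with latency referenced to the waveform kink.
    Of ``n_cycles`` cycles per run the last ``n_keep`` are averaged.
    """

    waveform: str = "triangle"
    P_values: tuple = (500.0, 750.0, 1000.0, 1500.0, 2000.0)
    g_max_values: tuple = (0.1, 0.2, 0.4)
    delta_peak_values: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    modes: tuple = (Mode.C_DUR, Mode.C_DC)
    T_act: float = 300.0
    DC: float = 0.3
    n_cycles: int = 30
    n_keep: int = 5
    dt: float = 0.05
    n_replicates: int = 1
    jitter: float = 0.05
    seed: int = 0
    template: RealisticTemplate = field(default_factory=RealisticTemplate)

    @classmethod
    def realistic(cls, **kw) -> "ClampProtocol":
        kw.setdefault("waveform", "realistic")
        kw.setdefault("P_values", (500.0, 750.0, 1000.0, 1250.0, 1500.0, 2000.0))
        kw.setdefault("g_max_values", (0.1, 0.2, 0.4, 0.6, 0.8))
        kw.setdefault("delta_peak_values", (np.nan,))
        kw.setdefault("modes", (Mode.C_DC,))
        return cls(**kw)


def _replicate_neurons(
    neuron: FollowerNeuronParams, protocol: ClampProtocol
) -> list[FollowerNeuronParams]:
    """Per-replicate neurons: tonic drive jittered to emulate inter-animal
    variability in excitability (and hence in the effective threshold)."""
    rng = np.random.default_rng(protocol.seed)
    out = []
    for _ in range(protocol.n_replicates):
        factor = 1.0 + protocol.jitter * rng.standard_normal()
        out.append(replace(neuron, I_drive=neuron.I_drive * max(factor, 0.1)))
    return out


def _cycle_onsets_delays(
    spikes: np.ndarray,
    P: float,
    search_ref: float,
    delay_ref: float,
    n_cycles: int,
    n_keep: int,
) -> tuple[float, str]:
    """Mean burst-onset delay over the retained cycles.

    The burst onset in cycle k is the first spike at or after the
    within-cycle search reference (the conductance peak): the follower fires
    tonically until inhibition takes hold, so spikes earlier in the cycle
    belong to the previous burst, not to the release from this cycle's
    inhibition.  The delay is reported relative to ``delay_ref`` (the
    conductance onset for triangles, the pacemaker kink for realistic
    waveforms).
    """
    delays = []
    for k in range(n_cycles - n_keep, n_cycles):
        ref = k * P + search_ref
        i = np.searchsorted(spikes, ref)
        if i >= spikes.size or spikes[i] >= (k + 1) * P + search_ref:
            return math.nan, "no_spike"
        delays.append(spikes[i] - (k * P + delay_ref))
    return float(np.mean(delays)), ""


def run_clamp_grid(
    neuron: FollowerNeuronParams,
    protocol: ClampProtocol,
) -> pd.DataFrame:
    """Run the full grid protocol; returns a long-format phase surface.

    Columns: ``replicate, mode, P_ms, g_max_uS, delta_peak, dt_ms, phi,
    flag``.  ``dt_ms`` is the burst-onset delay from the conductance onset
    (triangle) or from the kink (realistic); ``phi = dt_ms / P``.  Cycles
    with no spike are flagged rather than dropped.
    """
    rows = []
    neurons = _replicate_neurons(neuron, protocol)
    for mode in protocol.modes:
        mode = Mode(mode)
        for P in protocol.P_values:
            for g_max in protocol.g_max_values:
                if protocol.waveform == "triangle":
                    dpk_list = protocol.delta_peak_values
                else:
                    dpk_list = (math.nan,)
                for dpk in dpk_list:
                    if protocol.waveform == "triangle":
                        schedule = SynapseSchedule(
                            P=P,
                            mode=mode,
                            g_max=g_max,
                            delta_peak=dpk,
                            T_act=protocol.T_act if mode is Mode.C_DUR else None,
                            DC=protocol.DC if mode is Mode.C_DC else None,
                        )
                        trace = triangle_waveform(
                            schedule, protocol.dt, protocol.n_cycles
                        )
                        search_ref = schedule.t_peak
                        delay_ref = 0.0
                    else:
                        trace, kink = realistic_waveform(
                            P,
                            g_max,
                            protocol.template,
                            dt=protocol.dt,
                            n_cycles=protocol.n_cycles,
                        )
                        search_ref = protocol.template.pm_center * P
                        delay_ref = kink
                    for r, nrn in enumerate(neurons):
                        _, spikes = simulate_follower(
                            nrn, g_syn=trace, store_voltage=False
                        )
                        delay, flag = _cycle_onsets_delays(
                            spikes,
                            P,
                            search_ref,
                            delay_ref,
                            protocol.n_cycles,
                            protocol.n_keep,
                        )
                        phi = delay / P if flag == "" else math.nan
                        rows.append(
                            (
                                r,
                                mode.value,
                                P,
                                g_max,
                                dpk,
                                delay,
                                phi,
                                flag,
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "replicate",
            "mode",
            "P_ms",
            "g_max_uS",
            "delta_peak",
            "dt_ms",
            "phi",
            "flag",
        ],
    )
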