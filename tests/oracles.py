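"""Independent oracles used by the test suite.

These deliberately avoid the closed forms under test: the conductance and
availability ODEs are integrated numerically to their periodic steady state,
threshold crossings are root-found on dense solutions, and period ranges are
recovered by brute-force parameter scans.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq


def integrate_conductance_cycles(
    P, t_peak, g_max, tau_r, tau_s, n_cycles=60, rtol=1e-10
):
    """Integrate the rise/decay conductance ODE cycle by cycle to steady
    state; returns (g_lo, g_peak, decay_solution) of the final cycle."""

    def rise(t, y):
        return [(g_max - y[0]) / tau_r]

    def decay(t, y):
        return [-y[0] / tau_s]

    g0 = 0.0
    sol_decay = None
    for _ in range(n_cycles):
        if t_peak > 0:
            r = solve_ivp(rise, (0, t_peak), [g0], rtol=rtol, atol=1e-14,
                          dense_output=True)
            g_pk = r.y[0, -1]
        else:
            g_pk = g0
        d = solve_ivp(decay, (t_peak, P), [g_pk], rtol=rtol, atol=1e-14,
                      dense_output=True)
        g_new = d.y[0, -1]
        if abs(g_new - g0) < 1e-13 * max(g_new, 1e-30):
            g0 = g_new
            sol_decay = d
            break
        g0 = g_new
        sol_decay = d
    return g0, sol_decay.y[0, 0], sol_decay


def crossing_delay_ode(P, t_peak, g_max, tau_r, tau_s, g_star, **kw):
    """Burst delay from dense ODE integration: root of g(t) = g* on the
    decay branch of the periodic steady-state cycle."""
    g_lo, g_pk, d = integrate_conductance_cycles(P, t_peak, g_max, tau_r,
                                                 tau_s, **kw)
    if g_pk <= g_star:
        return 0.0, True, g_lo, g_pk
    f = lambda t: d.sol(t)[0] - g_star
    if f(P) > 0:  # never decays below threshold within the cycle
        return np.inf, False, g_lo, g_pk
    t_cross = brentq(f, t_peak, P, xtol=1e-10)
    return t_cross, False, g_lo, g_pk


def decay_crossing(g_peak, t_peak, tau_s, g_star, t_max):
    """Root-find g(t) = g* on a dense ODE solution of the decay branch."""
    d = solve_ivp(lambda t, y: [-y[0] / tau_s], (t_peak, t_max), [g_peak],
                  rtol=1e-12, atol=1e-16, dense_output=True)
    return brentq(lambda t: d.sol(t)[0] - g_star, t_peak, t_max, xtol=1e-9)


def s_max_ode(P, DC, tau_alpha, tau_beta, n_cycles=4000):
    """Cycle maximum of the depression variable from exact piecewise-
    exponential stepping of the s_d ODE to periodic steady state."""
    T_act = DC * P
    s = 1.0
    for _ in range(n_cycles):
        s_end_act = s * np.exp(-T_act / tau_beta)
        s_new = 1.0 + (s_end_act - 1.0) * np.exp(-(P - T_act) / tau_alpha)
        if abs(s_new - s) < 1e-15:
            s = s_new
            break
        s = s_new
    return s  # maximum occurs at the start of the active window


def period_range_scan(phi_c, g_max, tau_s, g_star, mode, DC=None, T_act=None,
                      n=10_000):
    """Brute-force period range: for each Δ_peak on a dense grid solve the
    simplified phase equation for P and collect admissible periods."""
    L = tau_s * np.log(g_max / g_star)
    dpk = np.linspace(0.0, 1.0, n)
    if mode == "C_DC":
        denom = phi_c - dpk * DC
        P = np.where(denom > 0, L / denom, np.inf)
        P = P[denom > 0] if np.any(denom > 0) else np.array([])
        P_all = np.concatenate([P, [np.inf]]) if np.any(denom <= 0) else P
        return (float(np.min(P_all)), float(np.max(P_all))) if P_all.size else None
    P = (L + dpk * T_act) / phi_c
    return float(np.min(P)), float(np.max(P))


def lif_isi(neuron):
    """Closed-form interspike interval of the tonically firing LIF."""
    Vinf = neuron.E_L + neuron.I_drive / neuron.g_L
    return neuron.t_ref + neuron.tau_m * np.log(
        (Vinf - neuron.V_reset) / (Vinf - neuron.V_th)
    )
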