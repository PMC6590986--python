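"""Short-term synaptic depression: steady-state availability and the
period-dependent synaptic strength it imposes.

A single availability variable ``s_d`` ∈ (0, 1) depresses during the active
window (time constant ``tau_beta``) and recovers during the silent phase
(``tau_alpha``)::

    ds/dt = -s/tau_beta        for t (mod P) <= T_act
    ds/dt = (1 - s)/tau_alpha  for T_act < t (mod P) < P

At the periodic steady state the cycle maximum — reached at the start of the
active window — is

    s_max(P) = (1 - e^{-P(1-DC)/tau_alpha})
               / (1 - e^{-P(1-DC)/tau_alpha} e^{-DC·P/tau_beta})

which increases monotonically with P and approaches 1: a depressing synapse
recovers more at longer cycle periods and is therefore effectively stronger,
g_max(P) = ḡ_max · s_max(P).  Default time constants (recovery 1000 ms,
depression 200 ms) make recovery slow relative to one pyloric cycle, so
depression accumulates over several cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import PhaseModelParams
from .phase_constancy import levelset_dpeak

__all__ = [
    "DepressionParams",
    "s_max",
    "depressing_gmax",
    "calibrate_gbar",
    "depressing_levelset",
]


@dataclass(frozen=True)
class DepressionParams:
    """Depression kinetics and undepressed strength.

    tau_alpha : recovery time constant, ms
    tau_beta  : depression time constant, ms
    gbar_max  : undepressed maximal conductance ḡ_max, µS
    """

    tau_alpha: float = 1000.0
    tau_beta: float = 200.0
    gbar_max: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_alpha > 0 and self.tau_beta > 0 and self.gbar_max > 0):
            raise ValueError("all depression parameters must be positive")


def s_max(P: float, DC: float, params: DepressionParams) -> float:
    """Steady-state cycle maximum of the availability variable.

    Strictly increasing in P, tends to 1 as P → ∞ and to
    a/(a+b) with a = (1-DC)/tau_alpha, b = DC/tau_beta as P → 0.
    """
    if P <= 0:
        raise ValueError("P must be positive")
    if not (0 < DC < 1):
        raise ValueError("DC must lie in (0, 1)")
    E_a = math.exp(-P * (1.0 - DC) / params.tau_alpha)
    E_b = math.exp(-DC * P / params.tau_beta)
    return (1.0 - E_a) / (1.0 - E_a * E_b)


def depressing_gmax(P: float, DC: float, params: DepressionParams) -> float:
    """Effective synaptic strength ḡ_max · s_max(P), µS."""
    return params.gbar_max * s_max(P, DC, params)


def calibrate_gbar(
    P_ref: float, g_ref: float, DC: float, params: DepressionParams
) -> DepressionParams:
    """Return params with ḡ_max chosen so that g_max(P_ref) = g_ref.

    Standard calibration: anchor the depressing synapse's strength at a
    reference period (e.g. 0.335 µS at P = 1 s).
    """
    gbar = g_ref / s_max(P_ref, DC, params)
    return DepressionParams(
        tau_alpha=params.tau_alpha, tau_beta=params.tau_beta, gbar_max=gbar
    )


def depressing_levelset(
    phi_c: float,
    params: DepressionParams,
    model_params: PhaseModelParams,
    DC: float,
    P_grid,
) -> pd.DataFrame:
    """Phase-constancy curve when depression dictates g_max(P).

    For each period the synaptic strength follows the depression rule and the
    compensating peak phase comes from the C-DC level set.  Rows are flagged
    admissible when g_max exceeds g* and Δ_peak lands in [0, 1]; the
    admissible span of P is the range over which a depressing synapse can
    hold the phase at φ_c, and exceeds the span of any fixed-g_max synapse
    matched at a reference period.

    Returns columns ``P_ms, g_max_uS, delta_peak, admissible``.
    """
    rows = []
    for P in np.atleast_1d(np.asarray(P_grid, dtype=float)):
        g = depressing_gmax(P, DC, params)
        if g <= model_params.g_star:
            rows.append((P, g, math.nan, False))
            continue
        dpk, valid = levelset_dpeak(P, g, phi_c, model_params, DC)
        rows.append((P, g, dpk, valid))
    return pd.DataFrame(
        rows, columns=["P_ms", "g_max_uS", "delta_peak", "admissible"]
    )
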