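"""Level sets of constant burst-onset phase and achievable period ranges.

For the instantaneous-rise phase model the C-DC phase equation

    φ = (tau_s / P) ln(g_max / g*) + Δ_peak · DC

can be inverted analytically for either ``g_max`` or ``Δ_peak``, giving the
locus of inputs that hold the follower phase at a target value ``φ_c``.
Requiring the compensating ``Δ_peak`` to stay within [0, 1] bounds the range
of periods over which phase constancy is achievable; the constant-duty-cycle
and constant-duration regimes share the same lower period bound but differ
in the upper one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import Mode, PhaseModelParams

__all__ = [
    "PeriodRange",
    "levelset_gmax",
    "levelset_dpeak",
    "period_range",
    "cdc_wider_than_cdur",
    "delta_p_curve",
]


@dataclass(frozen=True)
class PeriodRange:
    """Interval of periods over which some Δ_peak ∈ [0, 1] achieves φ_c.

    ``P_max`` may be ``math.inf`` (C-DC with φ_c ≤ DC).  An empty range is
    encoded as P_min == P_max.
    """

    P_min: float
    P_max: float
    phi_c: float
    mode: Mode

    def __post_init__(self) -> None:
        if self.P_min > self.P_max:
            raise ValueError("P_min must not exceed P_max")

    @property
    def width(self) -> float:
        """ΔP = P_max - P_min (may be inf)."""
        return self.P_max - self.P_min

    @property
    def empty(self) -> bool:
        return self.P_max <= self.P_min


def levelset_gmax(
    P: float,
    delta_peak: float,
    phi_c: float,
    params: PhaseModelParams,
    DC: float,
) -> tuple[float, bool]:
    """Peak conductance holding phase at φ_c for given P and Δ_peak (C-DC).

    Algebraic inverse of the C-DC phase equation:

        g_max = g* · exp( (P/tau_s) (φ_c - Δ_peak·DC) )

    Returns ``(g_max, valid)``; the value is invalid (g_max < g*) when
    φ_c < Δ_peak·DC, i.e. the requested phase precedes the earliest phase an
    above-threshold synapse can impose.
    """
    g_max = params.g_star * math.exp(P / params.tau_s * (phi_c - delta_peak * DC))
    return g_max, bool(g_max >= params.g_star)


def levelset_dpeak(
    P: float,
    g_max: float,
    phi_c: float,
    params: PhaseModelParams,
    DC: float,
) -> tuple[float, bool]:
    """Peak phase holding phase at φ_c for given P and g_max (C-DC).

        Δ_peak = φ_c/DC - (tau_s / (DC·P)) ln(g_max/g*)

    Returns ``(delta_peak, valid)`` where validity means the value lies in
    [0, 1] (equivalently, P lies inside the achievable period range).
    """
    if g_max <= params.g_star:
        raise ValueError("levelset_dpeak requires g_max > g_star")
    delta_peak = phi_c / DC - params.tau_s / (DC * P) * math.log(
        g_max / params.g_star
    )
    return delta_peak, bool(0.0 <= delta_peak <= 1.0)


def period_range(
    phi_c: float,
    g_max: float,
    params: PhaseModelParams,
    mode: Mode,
    *,
    DC: float | None = None,
    T_act: float | None = None,
) -> PeriodRange:
    """Range of periods over which Δ_peak ∈ [0, 1] can hold phase at φ_c.

    Solving 0 ≤ Δ_peak ≤ 1 in the respective level-set equations gives

        C-DC :  tau_s L / φ_c  <  P  <  tau_s L / (φ_c - DC)
        C-Dur:  tau_s L / φ_c  <  P  <  (T_act + tau_s L) / φ_c

    with L = ln(g_max/g*).  The lower limits coincide; the C-DC upper limit
    is +∞ when φ_c ≤ DC.  Boundary values Δ_peak ∈ {0, 1} are included.
    """
    if phi_c <= 0:
        raise ValueError("phi_c must be positive")
    if g_max <= params.g_star:
        raise ValueError("period_range requires g_max > g_star")
    mode = Mode(mode)
    L = params.tau_s * math.log(g_max / params.g_star)
    P_lo = L / phi_c
    if mode is Mode.C_DC:
        if DC is None:
            raise ValueError("C_DC period range requires DC")
        P_hi = math.inf if phi_c <= DC else L / (phi_c - DC)
    else:
        if T_act is None:
            raise ValueError("C_DUR period range requires T_act")
        # Lower limit is shared with C-DC by construction (Δ_peak = 0 in
        # both); P < T_act additionally violates the schedule itself, which
        # callers must enforce separately.
        P_hi = (T_act + L) / phi_c
    if P_hi < P_lo:
        P_hi = P_lo
    return PeriodRange(P_min=P_lo, P_max=P_hi, phi_c=phi_c, mode=mode)


def cdc_wider_than_cdur(
    phi_c: float,
    g_max: float,
    params: PhaseModelParams,
    DC: float,
    T_act: float,
) -> bool:
    """True iff the C-DC period range is strictly wider than the C-Dur one.

    Equivalent to the closed-form criterion

        φ_c < DC (1 + (tau_s / T_act) ln(g_max/g*))

    (with the C-DC width infinite whenever φ_c ≤ DC).
    """
    L = params.tau_s * math.log(g_max / params.g_star)
    return phi_c < DC * (1.0 + L / T_act)


def delta_p_curve(
    phi_c_grid,
    params: PhaseModelParams,
    mode: Mode,
    *,
    g_max: float | None = None,
    DC: float | None = None,
    T_act: float | None = None,
    depression=None,
    P_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """ΔP(φ_c): achievable period-range width per target phase.

    With fixed ``g_max`` the width comes from :func:`period_range`
    analytically (0 when the level set is empty or g_max ≤ g*).  When a
    ``depression`` rule is given (a callable P ↦ g_max(P), e.g. a calibrated
    depressing synapse), no closed form exists and the admissible set is
    found by scanning ``P_grid`` (default 2000 log-spaced points over
    100 ms – 20 s) for points where the compensating Δ_peak lies in [0, 1].

    Returns a DataFrame with columns ``phi_c, P_min_ms, P_max_ms, dP_ms``.
    """
    mode = Mode(mode)
    rows = []
    if depression is None:
        if g_max is None:
            raise ValueError("delta_p_curve requires g_max or a depression rule")
        for phi_c in np.atleast_1d(phi_c_grid):
            phi_c = float(phi_c)
            if g_max <= params.g_star:
                rows.append((phi_c, math.nan, math.nan, 0.0))
                continue
            try:
                pr = period_range(
                    phi_c, g_max, params, mode, DC=DC, T_act=T_act
                )
            except ValueError:
                rows.append((phi_c, math.nan, math.nan, 0.0))
                continue
            rows.append((phi_c, pr.P_min, pr.P_max, pr.width))
    else:
        if mode is not Mode.C_DC:
            raise NotImplementedError(
                "depression-coupled ranges are defined for the C-DC regime"
            )
        if DC is None:
            raise ValueError("C_DC delta_p_curve requires DC")
        if P_grid is None:
            P_grid = np.logspace(2, math.log10(20_000.0), 2000)
        P_grid = np.asarray(P_grid, dtype=float)
        g_of_P = np.asarray([depression(P) for P in P_grid], dtype=float)
        for phi_c in np.atleast_1d(phi_c_grid):
            phi_c = float(phi_c)
            ok = np.zeros(P_grid.shape, dtype=bool)
            for i, (P, g) in enumerate(zip(P_grid, g_of_P)):
                if g <= params.g_star:
                    continue
                _, valid = levelset_dpeak(P, g, phi_c, params, DC)
                ok[i] = valid
            if ok.any():
                P_ok = P_grid[ok]
                rows.append(
                    (phi_c, float(P_ok.min()), float(P_ok.max()),
                     float(P_ok.max() - P_ok.min()))
                )
            else:
                rows.append((phi_c, math.nan, math.nan, 0.0))
    return pd.DataFrame(rows, columns=["phi_c", "P_min_ms", "P_max_ms", "dP_ms"])
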