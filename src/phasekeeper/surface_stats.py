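"""Statistical layer over burst-onset phase surfaces.

* least-squares fit of the constant-duty-cycle phase equation
  φ = (tau_s/P) ln(g_max/g*) + c to a measured surface,
* sensitivity of φ to g_max and Δ_peak along cardinal directions of the
  (g_max, Δ_peak) grid,
* Friedman test (repeated-measures ANOVA on ranks) and repeated-measures
  ANOVA,
* empirical level-set extraction (the period at which an interpolated
  surface attains a target phase, per grid node),
* tolerant readers for the published source-data spreadsheets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "TestResult",
    "fit_phase_model",
    "sensitivity_grid",
    "friedman_test",
    "rm_anova",
    "empirical_levelset",
    "levelset_range_curve",
    "load_numeric_sheets",
]


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters of φ = (tau_s/P) ln(g_max/g*) + c.

    ``c`` is the lumped constant Δ_peak·DC of the constant-duty-cycle
    equation.  Residual norm is the RMS residual of the converged fit.
    """

    tau_s: float
    g_star: float
    c: float
    residual_norm: float
    converged: bool


@dataclass(frozen=True)
class TestResult:
    """One test statistic (χ² or F) with degrees of freedom and p-value."""

    name: str
    statistic: float
    df: tuple
    p_value: float


def _phase_cdc(P, g_max, tau_s, g_star, c):
    return tau_s / P * np.log(g_max / g_star) + c


def fit_phase_model(
    surface: pd.DataFrame,
    *,
    tau_s_max: float = 500.0,
    n_starts: int = 5,
) -> FitResult:
    """Fit the C-DC phase equation to (P, g_max, φ) data.

    Bounded nonlinear least squares with multi-start over ``g_star``
    (log-spaced below the smallest g_max) to step off the flat
    ln(g_max/g*) ridge; on noiseless model-generated data the generating
    parameters are recovered.  Requires columns ``P_ms, g_max_uS, phi``
    with ≥ 3 distinct periods and ≥ 2 distinct conductances.
    """
    df = surface.dropna(subset=["phi"])
    P = df["P_ms"].to_numpy(float)
    g = df["g_max_uS"].to_numpy(float)
    phi = df["phi"].to_numpy(float)
    if np.unique(P).size < 3 or np.unique(g).size < 2:
        raise ValueError("fit requires >= 3 distinct P and >= 2 distinct g_max")
    g_min = g.min()

    def resid(theta):
        tau_s, log_gstar, c = theta
        return _phase_cdc(P, g, tau_s, math.exp(log_gstar), c) - phi

    lo = [1e-6, math.log(1e-6), 0.0]
    hi = [tau_s_max, math.log(g_min) - 1e-9, 1.0 - 1e-12]
    best = None
    for g0 in np.logspace(math.log10(g_min) - 3, math.log10(g_min) - 0.05, n_starts):
        x0 = [30.0, math.log(g0), float(np.clip(np.median(phi), 0.01, 0.9))]
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lo, hi))
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult(math.nan, math.nan, math.nan, math.nan, False)
    tau_s, log_gstar, c = best.x
    rms = math.sqrt(2.0 * best.cost / P.size)
    return FitResult(
        tau_s=float(tau_s),
        g_star=float(math.exp(log_gstar)),
        c=float(c),
        residual_norm=rms,
        converged=bool(best.success),
    )


_G_FULL = (0.1, 0.2, 0.3, 0.4)
_D_FULL = (0.0, 0.25, 0.5, 0.75, 1.0)
_CARDINAL = ("g_max", "delta_peak", "g_max+delta_peak", "g_max-delta_peak")


def _phase_matrix(sub: pd.DataFrame, g_grid, d_grid) -> np.ndarray | None:
    """4×5 φ matrix over (g_max, Δ_peak), interpolating g_max = 0.3 µS."""
    pivot = sub.pivot_table(index="g_max_uS", columns="delta_peak", values="phi")
    try:
        pivot = pivot.reindex(columns=list(d_grid))
    except KeyError:
        return None
    if pivot.isna().any().any():
        return None
    rows = []
    for gv in g_grid:
        if gv in pivot.index:
            rows.append(pivot.loc[gv].to_numpy(float))
        elif math.isclose(gv, 0.3) and 0.2 in pivot.index and 0.4 in pivot.index:
            rows.append(
                0.5 * (pivot.loc[0.2].to_numpy(float) + pivot.loc[0.4].to_numpy(float))
            )
        else:
            return None
    return np.vstack(rows)


def sensitivity_grid(
    surface: pd.DataFrame,
    P_values=None,
    g_grid=_G_FULL,
    d_grid=_D_FULL,
) -> pd.DataFrame:
    """Directional sensitivities of φ on the (g_max, Δ_peak) grid.

    Per replicate and period the 4×5 φ matrix (g_max = 0.3 µS linearly
    interpolated from 0.2 and 0.4) is differenced along eight directions;
    each step's Δφ is divided by the normalized increment (g_max steps
    normalized by 0.4 µS, Δ_peak steps raw, diagonal steps by the common
    normalized increment 0.25).  Opposite directions are averaged into four
    cardinal directions and cell-averaged, giving one sensitivity per
    (replicate, P, direction).  Cells whose neighbors are missing are
    skipped; a ``n_missing`` count is attached as a DataFrame attribute.
    """
    if P_values is None:
        P_values = sorted(surface["P_ms"].unique())
    g_step = (g_grid[1] - g_grid[0]) / max(g_grid)  # normalized: 0.25
    d_step = d_grid[1] - d_grid[0]  # 0.25
    if not math.isclose(g_step, d_step):
        raise ValueError("grid steps must share the normalized increment")
    h = g_step
    rows = []
    n_missing = 0
    for rep, sub_r in surface.groupby("replicate"):
        for P in P_values:
            sub = sub_r[sub_r["P_ms"] == P]
            M = _phase_matrix(sub, g_grid, d_grid)
            if M is None:
                n_missing += 1
                continue
            ng, nd = M.shape
            acc = {d: [] for d in _CARDINAL}
            for i in range(ng):
                for j in range(nd):
                    # aligned pairs: forward and backward differences
                    if i + 1 < ng:
                        acc["g_max"].append((M[i + 1, j] - M[i, j]) / h)
                    if i - 1 >= 0:
                        acc["g_max"].append((M[i, j] - M[i - 1, j]) / h)
                    if j + 1 < nd:
                        acc["delta_peak"].append((M[i, j + 1] - M[i, j]) / h)
                    if j - 1 >= 0:
                        acc["delta_peak"].append((M[i, j] - M[i, j - 1]) / h)
                    if i + 1 < ng and j + 1 < nd:
                        acc["g_max+delta_peak"].append(
                            (M[i + 1, j + 1] - M[i, j]) / h
                        )
                    if i - 1 >= 0 and j - 1 >= 0:
                        acc["g_max+delta_peak"].append(
                            (M[i, j] - M[i - 1, j - 1]) / h
                        )
                    if i + 1 < ng and j - 1 >= 0:
                        acc["g_max-delta_peak"].append(
                            (M[i + 1, j - 1] - M[i, j]) / h
                        )
                    if i - 1 >= 0 and j + 1 < nd:
                        acc["g_max-delta_peak"].append(
                            (M[i, j] - M[i - 1, j + 1]) / h
                        )
            for d in _CARDINAL:
                rows.append((rep, P, d, float(np.mean(acc[d]))))
    out = pd.DataFrame(
        rows, columns=["replicate", "P_ms", "direction", "sensitivity"]
    )
    out.attrs["n_missing"] = n_missing
    return out


def friedman_test(matrix: np.ndarray, name: str = "friedman") -> TestResult:
    """Friedman χ² (repeated-measures ANOVA on ranks) with tie correction.

    ``matrix`` is replicates × conditions.  Values are mid-ranked within
    each replicate; the statistic

        χ² = [ (12 / (N k (k+1))) Σ_j R_j² - 3 N (k+1) ] / C

    with the standard tie factor C = 1 - Σ(t³ - t) / (N (k³ - k)) is
    compared to χ² with k-1 degrees of freedom.  Bounded above by N(k-1).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 replicates and >= 2 conditions")
    N, k = X.shape
    ranks = np.vstack([stats.rankdata(row) for row in X])
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (N * k * (k + 1)) * np.sum(R**2) - 3.0 * N * (k + 1)
    ties = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    C = 1.0 - ties / (N * (k**3 - k))
    if C > 0:
        chi2 /= C
    p = float(stats.chi2.sf(chi2, k - 1))
    return TestResult(name=name, statistic=float(chi2), df=(k - 1,), p_value=p)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str] | str,
    subject: str,
) -> list[TestResult]:
    """Repeated-measures ANOVA with one or two within-subject factors.

    Thin wrapper over statsmodels' ``AnovaRM`` (balanced designs only;
    unbalanced input raises with a clear message).  Returns one
    :class:`TestResult` per within factor (and the interaction for two
    factors).
    """
    from statsmodels.stats.anova import AnovaRM

    if isinstance(within, str):
        within = [within]
    counts = data.groupby([subject, *within]).size()
    if counts.max() != counts.min() or (counts != 1).any():
        raise ValueError(
            "rm_anova requires a balanced design with exactly one observation "
            "per subject and factor-level combination"
        )
    res = AnovaRM(data, depvar=dv, subject=subject, within=within).fit()
    tbl = res.anova_table
    out = []
    for effect, row in tbl.iterrows():
        F = float(row["F Value"])
        p = float(row["Pr > F"])
        if F < 0:  # 0/0 rounding for a factor with no within-subject variance
            F, p = 0.0, 1.0
        out.append(
            TestResult(
                name=str(effect),
                statistic=F,
                df=(float(row["Num DF"]), float(row["Den DF"])),
                p_value=p,
            )
        )
    return out


def _node_levelset_P(P_vals: np.ndarray, phi_vals: np.ndarray, phi_c: float):
    """Solve φ(P) = φ_c on a piecewise-linear interpolant (φ decreasing)."""
    order = np.argsort(P_vals)
    P_vals, phi_vals = P_vals[order], phi_vals[order]
    for a in range(len(P_vals) - 1):
        y0, y1 = phi_vals[a], phi_vals[a + 1]
        if (y0 - phi_c) * (y1 - phi_c) <= 0 and y0 != y1:
            return float(
                P_vals[a] + (phi_c - y0) / (y1 - y0) * (P_vals[a + 1] - P_vals[a])
            )
    return math.nan


def empirical_levelset(
    surface: pd.DataFrame, phi_c: float, mode: str | None = None
) -> pd.DataFrame:
    """Per-node period at which the measured surface attains φ_c.

    The surface (mean φ across replicates per (g_max, Δ_peak, P) node) is
    interpolated piecewise-linearly in P and the crossing φ(P) = φ_c is
    solved per (g_max, Δ_peak) node; nodes without a crossing are empty
    (NaN).  The attribute ``dP`` on the returned frame is the max - min of
    the crossing periods over non-empty nodes (0 when fewer than one).
    """
    df = surface
    if mode is not None:
        df = df[df["mode"] == str(getattr(mode, "value", mode))]
    mean = (
        df.dropna(subset=["phi"])
        .groupby(["g_max_uS", "delta_peak", "P_ms"], as_index=False)["phi"]
        .mean()
    )
    rows = []
    for (gv, dv), sub in mean.groupby(["g_max_uS", "delta_peak"]):
        P_star = _node_levelset_P(
            sub["P_ms"].to_numpy(float), sub["phi"].to_numpy(float), phi_c
        )
        rows.append((gv, dv, P_star))
    out = pd.DataFrame(rows, columns=["g_max_uS", "delta_peak", "P_ms"])
    found = out["P_ms"].dropna()
    out.attrs["dP"] = float(found.max() - found.min()) if len(found) else 0.0
    out.attrs["phi_c"] = phi_c
    return out


def levelset_range_curve(
    surface: pd.DataFrame, phi_c_grid, mode: str | None = None
) -> pd.DataFrame:
    """ΔP(φ_c) over a sweep of target phases, from the measured surface."""
    rows = []
    for phi_c in np.atleast_1d(phi_c_grid):
        ls = empirical_levelset(surface, float(phi_c), mode=mode)
        n_found = int(ls["P_ms"].notna().sum())
        rows.append((float(phi_c), ls.attrs["dP"], n_found))
    return pd.DataFrame(rows, columns=["phi_c", "dP_ms", "n_nodes"])


def load_numeric_sheets(path, min_cols: int = 2) -> dict[str, pd.DataFrame]:
    """Tolerant reader for published source-data spreadsheets.

    Loads every sheet of an XLSX file and extracts its largest contiguous
    all-numeric column block (dropping label columns and header junk), so
    the same statistics can run on published tables and on the synthetic
    tables this package writes.
    """
    sheets = pd.read_excel(path, sheet_name=None, header=None)
    out = {}
    for name, raw in sheets.items():
        num = raw.apply(pd.to_numeric, errors="coerce")
        good_cols = [c for c in num.columns if num[c].notna().sum() >= 2]
        if len(good_cols) < min_cols:
            continue
        block = num[good_cols].dropna(axis=0, how="any")
        if block.shape[0] >= 2:
            out[name] = block.reset_index(drop=True)
    return out
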