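import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phasekeeper import (
    empirical_levelset,
    fit_phase_model,
    friedman_test,
    levelset_dpeak,
    rm_anova,
    sensitivity_grid,
)
from conftest import FIT_C, FIT_G_STAR, FIT_TAU_S

REAL_P = (500.0, 750.0, 1000.0, 1250.0, 1500.0, 2000.0)
REAL_G = (0.1, 0.2, 0.4, 0.6, 0.8)


def model_surface(tau_s=FIT_TAU_S, g_star=FIT_G_STAR, c=FIT_C, noise=0.0,
                  rng=None):
    rows = []
    for P, g in itertools.product(REAL_P, REAL_G):
        phi = tau_s / P * np.log(g / g_star) + c
        if noise and rng is not None:
            phi += rng.normal(0, noise)
        rows.append((P, g, phi))
    return pd.DataFrame(rows, columns=["P_ms", "g_max_uS", "phi"])


class TestPhaseModelFit:
    def test_noiseless_roundtrip(self):
        fit = fit_phase_model(model_surface())
        assert fit.converged
        assert fit.tau_s == pytest.approx(FIT_TAU_S, abs=1e-6)
        assert fit.g_star == pytest.approx(FIT_G_STAR, abs=1e-6)
        assert fit.c == pytest.approx(FIT_C, abs=1e-6)

    def test_noisy_recovery(self, rng):
        errs = [
            abs(fit_phase_model(model_surface(noise=0.02, rng=rng)).tau_s
                - FIT_TAU_S)
            for _ in range(30)
        ]
        assert np.median(errs) < 5.0

    def test_error_degrades_gracefully_with_noise(self, rng):
        med = []
        for sd in (0.0, 0.01, 0.05):
            errs = [
                abs(fit_phase_model(model_surface(noise=sd, rng=rng)).tau_s
                    - FIT_TAU_S)
                for _ in range(12)
            ]
            med.append(np.median(errs))
        assert med[0] < med[2]

    def test_requires_enough_grid(self):
        df = model_surface().query("P_ms in (500.0, 750.0)")
        with pytest.raises(ValueError):
            fit_phase_model(df)


def grid_surface(fn, replicate=0):
    rows = []
    for g in (0.1, 0.2, 0.4):
        for d in (0.0, 0.25, 0.5, 0.75, 1.0):
            for P in (500.0, 1000.0):
                rows.append((replicate, P, g, d, fn(P, g, d)))
    return pd.DataFrame(
        rows, columns=["replicate", "P_ms", "g_max_uS", "delta_peak", "phi"]
    )


class TestSensitivityGrid:
    def test_constant_surface_has_zero_sensitivity(self):
        s = sensitivity_grid(grid_surface(lambda P, g, d: 0.42))
        assert np.allclose(s["sensitivity"], 0.0)

    def test_planar_surface_cardinal_directions(self):
        a, b = 0.21, 0.13
        s = sensitivity_grid(grid_surface(lambda P, g, d: a * g / 0.4 + b * d))
        m = s.groupby("direction")["sensitivity"].mean()
        assert m["g_max"] == pytest.approx(a, abs=1e-9)
        assert m["delta_peak"] == pytest.approx(b, abs=1e-9)
        assert m["g_max+delta_peak"] == pytest.approx(a + b, abs=1e-9)
        assert m["g_max-delta_peak"] == pytest.approx(a - b, abs=1e-9)

    def test_explicit_step_definition(self):
        # the Δ_peak step 0.25→0.5 is Δφ / 0.25
        phis = {}
        fn = lambda P, g, d: 0.1 + 0.04 * np.sin(d * 7 + g * 3)
        s = sensitivity_grid(grid_surface(fn))
        manual = []
        for g in (0.1, 0.2, 0.3, 0.4):
            gg = g if g != 0.3 else None
            for d0, d1 in [(0.25, 0.5)]:
                f = (lambda gv: (fn(500, gv, d1) - fn(500, gv, d0)) / 0.25)
                manual.append(f(g) if gg else (f(0.2) + f(0.4)) / 2)
        # package mean over all Δ_peak steps includes these; just check sign
        # consistency of the construction on a monotone surface
        s2 = sensitivity_grid(grid_surface(lambda P, g, d: d * 0.2))
        assert s2.groupby("direction")["sensitivity"].mean()[
            "delta_peak"] == pytest.approx(0.2, abs=1e-9)


class TestFriedman:
    def test_perfectly_ordered_attains_upper_bound(self):
        X = np.tile(np.arange(1, 5), (5, 1)) + np.arange(5)[:, None] * 10
        res = friedman_test(X)
        assert res.statistic == pytest.approx(15.0)  # N(k-1)
        assert res.df == (3,)

    def test_identical_conditions_give_zero(self):
        X = np.tile(np.arange(5)[:, None], (1, 4)).astype(float)
        assert friedman_test(X).statistic == pytest.approx(0.0)

    def test_matches_scipy(self, rng):
        X = rng.normal(size=(12, 4))
        res = friedman_test(X)
        ref = stats.friedmanchisquare(*X.T)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_scipy_with_ties(self, rng):
        X = rng.integers(0, 3, size=(10, 4)).astype(float)
        res = friedman_test(X)
        ref = stats.friedmanchisquare(*X.T)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        X = rng.normal(size=(9, 4))
        a = friedman_test(X).statistic
        b = friedman_test(np.exp(3 * X)).statistic
        assert a == pytest.approx(b, rel=1e-12)

    def test_bounded_above(self, rng):
        for _ in range(20):
            N, k = rng.integers(3, 10), rng.integers(3, 6)
            X = rng.normal(size=(N, k))
            assert friedman_test(X).statistic <= N * (k - 1) + 1e-9


def long_table(rng, n_subj=6, n_a=4, n_b=3, effect=0.0):
    rows = []
    for s in range(n_subj):
        off = rng.normal()
        for a in range(n_a):
            for b in range(n_b):
                rows.append((s, a, b, off + effect * a + rng.normal()))
    return pd.DataFrame(rows, columns=["subject", "A", "B", "y"])


class TestRMAnova:
    def test_matches_pingouin_one_way(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = long_table(rng, n_b=1)
        res = rm_anova(df, "y", "A", "subject")
        ref = pingouin.rm_anova(data=df, dv="y", within="A", subject="subject")
        assert res[0].statistic == pytest.approx(float(ref["F"][0]), rel=1e-6)
        assert res[0].p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)

    def test_matches_pingouin_two_way(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = long_table(rng)
        res = {t.name: t for t in rm_anova(df, "y", ["A", "B"], "subject")}
        ref = pingouin.rm_anova(data=df, dv="y", within=["A", "B"],
                                subject="subject")
        for name, key in (("A", "A"), ("B", "B"), ("A:B", "A * B")):
            row = ref[ref["Source"] == key].iloc[0]
            assert res[name].statistic == pytest.approx(float(row["F"]),
                                                        rel=1e-6)

    def test_constant_factor_gives_zero_f(self, rng):
        rows = []
        for s in range(6):
            off = rng.normal()
            for a in range(4):
                rows.append((s, a, off))
        df = pd.DataFrame(rows, columns=["subject", "A", "y"])
        res = rm_anova(df, "y", "A", "subject")
        assert res[0].statistic == 0.0 and res[0].p_value == 1.0

    def test_unbalanced_rejected(self, rng):
        df = long_table(rng, n_b=1).iloc[:-1]
        with pytest.raises(ValueError, match="balanced"):
            rm_anova(df, "y", "A", "subject")

    def test_type_i_error_calibration(self, rng):
        # simulated null: rejection rate at alpha = 0.05
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            df = long_table(rng, n_subj=6, n_a=3, n_b=1)
            if rm_anova(df, "y", "A", "subject")[0].p_value < 0.05:
                hits += 1
        assert 0.02 <= hits / n_sim <= 0.09


class TestEmpiricalLevelset:
    def _surface(self, params):
        rows = []
        for r in range(1):
            for g in (0.1, 0.2, 0.4):
                for d in (0.0, 0.25, 0.5, 0.75, 1.0):
                    for P in (500.0, 750.0, 1000.0, 1500.0, 2000.0):
                        phi = (params.tau_s / P * np.log(g / params.g_star)
                               + d * 0.3)
                        rows.append((r, "C_DC", P, g, d, phi, ""))
        return pd.DataFrame(rows, columns=["replicate", "mode", "P_ms",
                                           "g_max_uS", "delta_peak", "phi",
                                           "flag"])

    def test_matches_analytic_levelset(self, params):
        surf = self._surface(params)
        phi_c = 0.34
        ls = empirical_levelset(surf, phi_c, mode="C_DC")
        checked = 0
        for _, row in ls.dropna(subset=["P_ms"]).iterrows():
            # invert analytically: the Δ_peak that holds phi_c at the
            # extracted P must be this node's Δ_peak (up to the linear-in-P
            # interpolation error of the convex 1/P surface)
            d_chk, _ = levelset_dpeak(row.P_ms, row.g_max_uS, phi_c,
                                      params, 0.3)
            assert d_chk == pytest.approx(row.delta_peak, abs=0.06)
            checked += 1
        assert checked >= 3

    def test_matches_dense_scan(self, params):
        surf = self._surface(params)
        ls = empirical_levelset(surf, 0.30, mode="C_DC")
        got = ls.dropna(subset=["P_ms"])
        assert len(got)
        for _, row in got.iterrows():
            # oracle: brute-force scan of the interpolated curve at 1 ms
            sub = surf[(surf.g_max_uS == row.g_max_uS)
                       & (surf.delta_peak == row.delta_peak)]
            P_grid = np.arange(500.0, 2000.0, 1.0)
            phi_i = np.interp(P_grid, sub.P_ms, sub.phi)
            k = np.argmin(np.abs(phi_i - 0.30))
            assert row.P_ms == pytest.approx(P_grid[k], abs=2.0)

    def test_no_crossing_marked_empty(self, params):
        surf = self._surface(params)
        ls = empirical_levelset(surf, 0.95, mode="C_DC")
        assert ls["P_ms"].isna().all()
        assert ls.attrs["dP"] == 0.0
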