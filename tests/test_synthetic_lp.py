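import dataclasses
import math

import numpy as np
import pytest

from phasekeeper import (
    DEFAULT_NEURON,
    ClampProtocol,
    FollowerNeuronParams,
    Mode,
    OUParams,
    SynapseSchedule,
    effective_threshold,
    ou_current,
    realistic_waveform,
    run_clamp_grid,
    simulate_follower,
    triangle_waveform,
)
from phasekeeper.core_model import triangle_burst_delay
from phasekeeper.synthetic_lp import SampledTrace
from oracles import lif_isi


def tri_sched(P=1000.0, g_max=0.4, dpk=0.5, T_act=300.0):
    return SynapseSchedule(P=P, mode=Mode.C_DUR, g_max=g_max,
                           delta_peak=dpk, T_act=T_act)


class TestTriangleWaveform:
    def test_peak_and_silent_window(self):
        tr = triangle_waveform(tri_sched(), 0.1, 2)
        i_peak = int(round(150.0 / 0.1))
        assert tr.values[i_peak] == pytest.approx(0.4, abs=1e-3)
        assert np.all(tr.values[int(300 / 0.1) + 1 : int(1000 / 0.1)] == 0)
        assert tr.values.max() <= 0.4 + 1e-12

    def test_area_matches_triangle_geometry(self):
        tr = triangle_waveform(tri_sched(), 0.1, 1)
        area = tr.values.sum() * 0.1
        assert area == pytest.approx(0.4 * 300 / 2, rel=1e-3)

    @pytest.mark.parametrize("dpk", [0.0, 1.0])
    def test_one_sided_ramps(self, dpk):
        tr = triangle_waveform(tri_sched(dpk=dpk), 0.1, 1)
        active = tr.values[: int(300 / 0.1)]
        diffs = np.diff(active)
        if dpk == 0.0:  # instant rise, pure falling ramp
            assert np.all(diffs[: len(diffs) // 2] < 0)
            assert active[0] == pytest.approx(0.4, rel=1e-3)
        else:  # pure rising ramp with instant drop at T_act
            assert np.all(diffs > 0)
            assert tr.values[int(300 / 0.1) + 1] == 0.0


class TestRealisticWaveform:
    def test_peak_equals_gmax(self):
        tr, kink = realistic_waveform(1000.0, 0.4, dt=0.1, n_cycles=1)
        assert tr.values.max() == pytest.approx(0.4, rel=1e-6)

    def test_pure_time_scaling(self):
        tr1, k1 = realistic_waveform(500.0, 0.4, dt=0.1, n_cycles=1)
        tr2, k2 = realistic_waveform(1000.0, 0.4, dt=0.2, n_cycles=1)
        assert k2 == pytest.approx(2 * k1)
        assert np.allclose(tr1.values, tr2.values, atol=1e-9)

    def test_kink_phase_parameter(self):
        _, kink = realistic_waveform(2000.0, 0.1, dt=0.1, n_cycles=1)
        assert kink == pytest.approx(0.55 * 2000.0)


class TestOUCurrent:
    def test_zero_sigma_converges_to_offset(self):
        tr = ou_current(OUParams(sigma=0.0, I_DC=-0.15, seed=0), 1000.0, 0.1)
        assert np.allclose(tr.values, -0.15)

    def test_stationary_standard_deviation(self):
        tr = ou_current(OUParams(tau=15.0, sigma=0.2, I_DC=-0.15, seed=7),
                        60_000.0, 0.2)
        assert tr.values.std() == pytest.approx(0.2, rel=0.05)
        assert tr.values.mean() == pytest.approx(-0.15, abs=0.02)

    def test_lag_autocorrelation(self):
        tr = ou_current(OUParams(tau=15.0, sigma=0.2, I_DC=0.0, seed=3),
                        120_000.0, 0.2)
        x = tr.values
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(math.exp(-0.2 / 15.0), abs=0.005)

    def test_seed_reproducibility(self):
        p = OUParams(seed=11)
        a = ou_current(p, 5000.0, 0.1)
        b = ou_current(p, 5000.0, 0.1)
        assert np.array_equal(a.values, b.values)


class TestFollowerSimulation:
    def test_tonic_isi_matches_closed_form(self):
        _, spikes = simulate_follower(DEFAULT_NEURON, duration=5000.0, dt=0.01)
        isi = np.diff(spikes)
        assert np.mean(isi[5:]) == pytest.approx(lif_isi(DEFAULT_NEURON),
                                                 abs=0.05)

    def test_suprathreshold_inhibition_silences(self):
        g = SampledTrace(dt=0.05, values=np.full(100_000, 0.05))
        _, spikes = simulate_follower(DEFAULT_NEURON, g_syn=g)
        assert spikes.size == 0

    def test_release_latency_matches_triangle_crossing(self, fast_neuron):
        # fast membrane: first spike after the peak tracks the conductance
        # downslope crossing of the effective threshold within 5 ms
        s = tri_sched(P=1000.0, g_max=0.4, dpk=0.5)
        tr = triangle_waveform(s, 0.05, 3)
        _, spikes = simulate_follower(fast_neuron, g_syn=tr)
        g_star = effective_threshold(fast_neuron)
        dt_model, _ = triangle_burst_delay(s, g_star)
        cyc = spikes[(spikes >= 2000.0 + s.t_peak) & (spikes < 3000.0)]
        assert cyc.size and cyc[0] - 2000.0 == pytest.approx(dt_model, abs=5.0)

    def test_rejects_nonfinite_input(self):
        bad = SampledTrace(dt=0.1, values=np.array([0.0, np.nan]), kind="current")
        with pytest.raises(ValueError):
            simulate_follower(DEFAULT_NEURON, I_ext=bad)

    def test_rejects_mismatched_dt(self):
        g = SampledTrace(dt=0.1, values=np.zeros(10))
        i = SampledTrace(dt=0.2, values=np.zeros(10), kind="current")
        with pytest.raises(ValueError):
            simulate_follower(DEFAULT_NEURON, g_syn=g, I_ext=i)


class TestEffectiveThreshold:
    def test_reference_value(self):
        assert effective_threshold(DEFAULT_NEURON) == pytest.approx(0.021,
                                                                    abs=1e-6)

    def test_rheobase_neuron_has_zero_threshold(self):
        n = dataclasses.replace(DEFAULT_NEURON, I_drive=1.5)  # = g_L(V_th-E_L)
        assert effective_threshold(n) == 0.0

    def test_increasing_in_drive(self):
        gs = [effective_threshold(dataclasses.replace(DEFAULT_NEURON, I_drive=i))
              for i in np.linspace(1.6, 3.0, 8)]
        assert np.all(np.diff(gs) > 0)

    def test_simulated_silence_boundary_brackets_threshold(self):
        g_star = effective_threshold(DEFAULT_NEURON)
        for factor, should_fire in ((0.95, True), (1.05, False)):
            g = SampledTrace(dt=0.05, values=np.full(200_000, g_star * factor))
            _, spikes = simulate_follower(DEFAULT_NEURON, g_syn=g)
            assert (spikes.size > 0) == should_fire


class TestClampGrid:
    def test_triangular_grid_shape(self, triangular_surface):
        surf = triangular_surface
        assert len(surf) == 2 * 5 * 3 * 5  # modes x P x g_max x delta_peak
        ok = surf[surf["flag"] == ""]
        assert (ok["phi"] > 0).all() and np.isfinite(ok["phi"]).all()

    def test_surface_reproduces_trend_signs(self, triangular_surface):
        surf = triangular_surface
        for mode in ("C_DC", "C_DUR"):
            s = surf[surf["mode"] == mode]
            slope = lambda d, x: np.polyfit(d[x], d["phi"], 1)[0]
            dP = s.groupby(["g_max_uS", "delta_peak"]).apply(
                slope, "P_ms", include_groups=False)
            dg = s.groupby(["P_ms", "delta_peak"]).apply(
                slope, "g_max_uS", include_groups=False)
            dd = s.groupby(["P_ms", "g_max_uS"]).apply(
                slope, "delta_peak", include_groups=False)
            assert (dP < 0).all() and (dg > 0).all() and (dd > 0).all()

    def test_seed_determinism(self):
        proto = ClampProtocol(
            P_values=(500.0,), g_max_values=(0.4,),
            delta_peak_values=(0.5,), n_cycles=6, n_keep=2,
            n_replicates=2, seed=5,
        )
        a = run_clamp_grid(DEFAULT_NEURON, proto)
        b = run_clamp_grid(DEFAULT_NEURON, proto)
        assert a.equals(b)

    def test_realistic_grid_latency_referenced_to_kink(self):
        proto = ClampProtocol.realistic(
            P_values=(500.0, 1000.0), g_max_values=(0.4,),
            n_cycles=6, n_keep=2, n_replicates=1, jitter=0.0, seed=0,
        )
        surf = run_clamp_grid(DEFAULT_NEURON, proto)
        assert len(surf) == 2
        ok = surf[surf["flag"] == ""]
        # burst follows the pacemaker component: small positive phase
        assert (ok["phi"] > 0).all() and (ok["phi"] < 0.6).all()
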