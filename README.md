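# phasekeeper

How does a neuron that is driven by rhythmic inhibition keep firing at the
same *phase* of the cycle when the rhythm speeds up or slows down? In
central pattern generators such as the crustacean pyloric circuit, a
follower neuron's burst-onset phase φ = Δt/P is nearly constant over a
severalfold range of periods P, which means the synaptic input's duration,
strength (g_max) and peak phase (Δ_peak) must change with P in a
coordinated way. `phasekeeper` implements, as a tested Python library plus
analysis pipeline:

* a **closed-form phase model**: for a periodic conductance that rises to
  g_max and decays with time constant τ_s, silencing the follower while it
  exceeds a threshold g\*, the burst phase is
  φ = (τ_s ln(g_max/g\*) + Δ_peak·T_act)/P for constant-duration (C-Dur)
  input, and φ = (τ_s/P) ln(g_max/g\*) + Δ_peak·DC for constant-duty-cycle
  (C-DC) input;
* **phase-constancy level sets** — the g_max(P) or Δ_peak(P) that holds
  φ at a target φ_c — and the period ranges ΔP over which they stay
  admissible, in both regimes;
* a **short-term synaptic depression** extension,
  g_max(P) = ḡ_max·s_max(P), under which g_max and Δ_peak covary with P
  and the phase-constancy range widens;
* a **synthetic dynamic-clamp pipeline**: a leaky integrate-and-fire
  follower driven by triangular or realistic inhibitory conductance
  waveforms or by Ornstein–Uhlenbeck noise current, with burst detection,
  IBI-binned burst-triggered averaging, surface fitting, sensitivity
  grids, Friedman and repeated-measures statistics.

The intended audience is computational neuroscientists studying phase
maintenance in oscillatory circuits, and anyone who wants a worked,
reproducible pipeline from model equations to the statistics run on
dynamic-clamp-style data.

## Worked example

```python
from phasekeeper import (Mode, PhaseModelParams, SynapseSchedule,
                         phase_simplified, period_range, calibrate_gbar,
                         DepressionParams, depressing_levelset)

# parameters fitted to biological realistic-waveform data
params = PhaseModelParams(tau_r=0.1, tau_s=26.0, g_star=0.021)

s = SynapseSchedule(P=1000, mode=Mode.C_DC, g_max=0.4, delta_peak=0.5, DC=0.3)
print(round(phase_simplified(s, params).phi, 3))

pr = period_range(0.34, 0.4, params, Mode.C_DC, DC=0.3)
print(round(pr.P_min, 1), round(pr.P_max, 1))

dep = calibrate_gbar(1000, 0.335, 0.3, DepressionParams())
curve = depressing_levelset(0.34, dep, params, 0.3, [1000.0])
print(round(float(curve["delta_peak"].iloc[0]), 3))
```

prints

```
0.227
225.4 1915.5
0.893
```

— a 0.4 µS constant-duty-cycle synapse at P = 1 s puts the follower's
burst at phase 0.227; phase can be held at φ_c = 0.34 for periods between
225 and 1916 ms by moving Δ_peak across [0, 1]; and a depressing synapse
calibrated to 0.335 µS at 1 s needs its peak at 0.893 of the active window
to hold that phase at P = 1 s.

## Analysis pipeline

The numbered drivers under `analysis/` run the full study on synthetic
data and write their tables to `results/`:

```sh
cd analysis
python 01_noise_bta.py          # noise-driven bursts, I_BTA shape metrics
python 02_clamp_grids.py        # triangular + realistic phase surfaces
python 03_fit_phase_equation.py # fit of the C-DC phase equation
python 04_sensitivity.py        # directional sensitivities + RM-ANOVA
python 05_phase_constancy.py    # level sets, ΔP(φ_c), depression curves
```

The same stages are scriptable through the `phasekeeper` command
(`phasekeeper run --config configs/demo.yaml`), and every stage is
seed-deterministic: identical config + seed yields byte-identical
artifacts.

If the published source-data spreadsheets for the burst-triggered-average
metrics and the sensitivity tables are available, place them under
`data/published/` as `fig2_source_data_1.xlsx` and
`fig7_source_data_1.xlsx`; the statistics layer then runs on them through
the same code paths (see `tests/test_acceptance.py`).

## Layout

```
src/phasekeeper/     core_model, phase_constancy, depression, synthetic_lp,
                     burst_analysis, surface_stats, workbench, cli
analysis/            numbered narrative drivers (write to results/)
scripts/acceptance.py
tests/               pytest suite incl. ODE/brute-force oracles
docs/methods.md      model, assumptions, parameter choices, limitations
```
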