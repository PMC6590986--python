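# Methods

## The problem

In rhythmic circuits such as the crustacean pyloric network, follower
neurons (here modeled after the lateral pyloric, LP, neuron) fire at a
roughly constant *phase* of the cycle — burst-onset latency divided by
period, φ = Δt/P — even as the period P varies severalfold. The follower's
timing is set almost entirely by the rhythmic inhibition it receives, so
phase constancy constrains how the synaptic input's duration, strength
(g_max) and peak phase (Δ_peak) must covary with P. This package implements
a closed-form model of that relationship, the level-set analysis of phase
constancy it permits, a short-term-depression extension, and a fully
synthetic dynamic-clamp pipeline on which the whole analysis chain runs.

## The phase model

Within each cycle the synaptic conductance rises toward g_max with time
constant τ_r until the peak time t_peak, then decays with τ_s:

    dg/dt = (g_max − g)/τ_r   for 0 ≤ t (mod P) < t_peak
    dg/dt = −g/τ_s            for t_peak ≤ t (mod P) < P

The follower is silenced whenever g exceeds a threshold g\* and fires as
soon as g falls below it. The periodic fixed point is closed-form: with
E_r = e^(−t_peak/τ_r) and E_s = e^(−(P−t_peak)/τ_s),

    g_peak = g_max (1 − E_r) / (1 − E_r E_s),   g_lo = g_peak E_s,

and the burst-onset delay is Δt = τ_s ln(g_peak/g\*) + t_peak. In the
instantaneous-rise limit (τ_r → 0) this reduces to two regime-specific
phase equations:

* constant duration (C-Dur, T_act fixed):
  φ = (τ_s ln(g_max/g\*) + Δ_peak·T_act) / P → 0 as P → ∞;
* constant duty cycle (C-DC, T_act = DC·P):
  φ = (τ_s/P) ln(g_max/g\*) + Δ_peak·DC → Δ_peak·DC as P → ∞.

Degenerate inputs are flagged rather than raised: a synapse whose peak
never exceeds g\* returns φ = 0 with a `subthreshold` flag (the follower
fires immediately), and Δt ≥ P is returned unwrapped with a
`not_entrained` flag. With a finite τ_r, t_peak = 0 leaves no time for the
conductance to rise at all; the closed form then returns the degenerate
g_peak = g_lo, and the instantaneous-rise equations are the appropriate
description of a step-onset input.

Units are fixed package-wide: time in ms, conductance in µS, current in
nA, voltage in mV.

## Level sets and period ranges

Holding φ at a target φ_c and inverting the C-DC equation for either
parameter gives the phase-constancy level sets

    g_max = g\* exp((P/τ_s)(φ_c − Δ_peak·DC)),
    Δ_peak = φ_c/DC − (τ_s/(DC·P)) ln(g_max/g\*),

and requiring Δ_peak ∈ [0, 1] bounds the periods over which a fixed-g_max
synapse can hold phase:

    τ_s L/φ_c < P < τ_s L/(φ_c − DC)          (C-DC; ∞ when φ_c ≤ DC)
    τ_s L/φ_c < P < (T_act + τ_s L)/φ_c       (C-Dur)

with L = ln(g_max/g\*). The lower limits coincide; the C-DC range is wider
exactly when φ_c < DC(1 + τ_s L/T_act). Boundary values Δ_peak ∈ {0, 1}
are included in the admissible set (the measure-zero difference from the
strict inequalities buys numerical robustness), and infinite upper bounds
are represented as true infinities that serialize as `inf`. The C-Dur
inequalities are used exactly as derived; periods below T_act additionally
violate the schedule itself (T_act ≤ P) and are the caller's concern, so
that the two regimes' lower limits remain algebraically identical.

Default model constants, used wherever nothing else is specified, are the
values fitted to biological realistic-waveform data: τ_s = 26.0 ms,
g\* = 0.021 µS, lumped constant Δ_peak·DC = 0.43, with τ_r = 0.1 ms
standing in for "instantaneous".

## Short-term depression

A single availability variable s_d depresses during the active window
(τ_β, default 200 ms) and recovers during the silent phase (τ_α, default
1000 ms). Its steady-state cycle maximum,

    s_max(P) = (1 − e^(−P(1−DC)/τ_α)) / (1 − e^(−P(1−DC)/τ_α) e^(−DC·P/τ_β)),

rises monotonically to 1 with P, so the effective strength
g_max(P) = ḡ_max·s_max(P) grows with period. The defaults make recovery
slower than one typical cycle, so depression accumulates over several
cycles; ḡ_max is calibrated so that g_max = 0.335 µS at P = 1 s. When this
rule sets g_max and the Δ_peak level set compensates per period, the
admissible period span at φ_c = 0.34 exceeds the span of the matched
fixed-strength synapse (1810 vs 1588 ms with the defaults). The widening
holds below a crossover near φ_c ≈ 0.39; above it both interval endpoints
fall below the calibration period, where the depressing synapse is weaker
than the fixed one, and the ordering reverses — the depressing synapse is
then operating outside its dynamic range. No closed form exists for the
depression-coupled range, so it is computed by scanning P on a log-spaced
grid (2000 points, 100 ms – 20 s).

## The synthetic dynamic-clamp pipeline

All data in this package are generated by a leaky integrate-and-fire (LIF)
follower,

    C_m dV/dt = −g_L(V − E_L) − g_syn(V − E_syn) + I_drive + I_ext,

with threshold −45 mV, reset, refractory period, and E_syn = −80 mV
(Euler at dt = 0.05 ms, threshold crossings located by linear
interpolation). Under constant inhibition its silence/fire boundary is the
effective threshold g\* = (I_drive − g_L(V_th − E_L))/(V_th − E_syn),
which bridges the simulator to the model's g\*; the default drive
(2.235 nA) puts it at 0.021 µS, matching the fitted scale.

Two configurations are used:

* **Dynamic-clamp follower** (default): τ_m = C_m/g_L = 50 ms. The slow
  membrane gives the follower a post-release rebound latency of tens of
  ms that grows with inhibition depth, which is what lets the
  constant-duty-cycle surface reach phases above the geometric cap
  Δt ≤ T_act of the injected triangle — the same role the biological
  follower's recovery dynamics play. Model-bridge checks use a fast
  variant (C_m = 0.2 nF, τ_m = 2 ms) in which this latency is negligible,
  and there the simulated phase tracks the triangle's own downslope
  crossing of g\* within 0.006 over the full grid.
* **Noise-protocol follower**: an effective slow integrator (τ_m = 1 s —
  an envelope time constant, not a biophysical membrane value) with a
  depolarized, plateau-like reset 0.5 mV below threshold and tonic drive
  near rheobase. A deep noise excursion then leaves a charge deficit that
  takes hundreds of ms to reclaim, producing irregular bursts whose
  preceding silent intervals span the 300–900 ms analysis bins.

The injected waveforms are (a) a triangle — linear rise over
[0, t_peak], linear fall over [t_peak, T_act], silent until P — swept over
the experimental grids (P ∈ {500, 750, 1000, 1500, 2000} ms, g_max ∈
{0.1, 0.2, 0.4} µS, Δ_peak ∈ {0, 0.25, 0.5, 0.75, 1}, both regimes with
T_act = 300 ms or DC = 0.3), and (b) a smooth synthetic stand-in for a
recorded pyloric IPSC: two raised-cosine bumps, a smaller early one (the
PY component) and a dominant later one (the pacemaker component) whose
onset at 0.55 of the cycle span is the marked "kink" from which burst
latency is measured; the realistic grid uses P ∈ {500…2000} ms and g_max ∈
{0.1…0.8} µS. The template leaves a genuinely low-conductance window after
the pacemaker bump, as the real waveform does; without it the follower
never fires.

Burst onset in a clamp run is the first spike at or after the conductance
peak of each cycle (the pacemaker peak for the realistic waveform), with
the delay reported from conductance onset (or kink). Searching from the
peak rather than from onset matters because a tonically firing
integrate-and-fire neuron keeps spiking through the sub-threshold early
rise of the input; those spikes belong to the previous burst. Each run
simulates 30 cycles and averages the last 5 (the input is deterministic,
so steady state is reached within 2–3 cycles; the default mirrors the
usual experimental averaging habit). Replicate "preparations" jitter
I_drive by 5% (one standard deviation), which varies the effective
threshold across replicates the way excitability varies across animals.

The noise current is an exactly discretized Ornstein–Uhlenbeck process,
X ← X e^(−dt/τ) + σ√(1 − e^(−2dt/τ)) N(0,1), output I_DC + X, with
τ = 15 ms, σ = 200 pA and I_DC = −150 pA by default. σ is interpreted as
the *stationary standard deviation* of the process: quoting the SDE
coefficient instead would leave the printed value without consistent
units, and the stationary SD is what one measures from a recording.

## Burst-triggered averaging

Bursts are runs of ≥ 2 spikes with consecutive inter-spike intervals
< 300 ms following a silent gap ≥ 300 ms; the preceding inter-burst
interval (IBI) is the gap from the previous spike of any kind to burst
onset (the first run of a recording, with no earlier spike, counts its
gap as infinite and is excluded from binning). Bursts are binned at
300/500/700/900 ms with ±100 ms half-width; because the averaging window
[onset − bin, onset] must itself be spike-free, a burst qualifies for a
bin only when its IBI is at least the bin's window length, so the
effective bins are [bin, bin + 100) ms. Mean traces are normalized by the
magnitude of the 300 ms bin's negative peak and summarized by four shape
metrics on normalized axes: trough amplitude I_peak, trough phase
Δ_peak_bta (earliest minimum under ties), and two-point slopes from
window start to trough and trough to window end. The two-point slope
estimator is a deliberate, documented choice; a line-fit variant would be
a drop-in replacement.

On the synthetic noise data, I_peak grows monotonically with IBI (about
twofold from the 300 to the 900 ms bin, Friedman p < 0.001 across
replicates) — longer silences require deeper average inhibition. The
trough *position* carries no systematic IBI trend in this emulation: for
a threshold neuron without slow rebound conductances, the mean input
conditioned on a long silence is flat-bottomed, so its minimum's location
is uninformative. In the biological preparation the trough moves earlier
with IBI, a signature of slow rebound currents (I_A, I_h) that are
deliberately outside this neuron model's scope. Passing tests on the
synthetic data therefore validate the amplitude directionality and the
full analysis chain, not the rebound-driven peak-phase effect.

## Surface statistics

* **Fit.** φ = (τ_s/P) ln(g_max/g\*) + c is fitted by bounded nonlinear
  least squares with five starts log-spaced in g\* (the objective is flat
  along a (τ_s, g\*) ridge; multi-start steps off it). Noiseless
  model-generated surfaces are recovered to 1e−6; at Gaussian noise of
  SD 0.02 the median τ_s error is well under 5 ms.
* **Sensitivities.** Per replicate and period, a 4×5 matrix of mean φ over
  g_max ∈ {0.1, 0.2, 0.3, 0.4} µS (0.3 interpolated linearly from 0.2 and
  0.4) × Δ_peak ∈ {0…1} is differenced along eight directions; g_max
  steps are normalized by 0.4 µS so every step has the common normalized
  increment 0.25, and diagonal steps are divided by that same increment —
  on a planar surface φ = a·(g_max/0.4) + b·Δ_peak the four cardinal
  directions read exactly a, b, a+b, a−b. Opposite directions are
  averaged, then cells, giving one value per (replicate, P, direction).
* **Rank and repeated-measures tests.** The Friedman χ² (mid-ranks, the
  standard tie correction, k−1 degrees of freedom, bounded by N(k−1)) is
  implemented directly and agrees with scipy's to machine precision; the
  repeated-measures ANOVA wraps statsmodels' AnovaRM (balanced designs
  only) and is cross-checked against pingouin. Because published analyses
  of the sensitivity tables are ambiguous between a one-way (direction)
  and a two-way (direction × P) structure, both are computed and
  reported. A factor with no within-subject variance yields a 0/0 F
  statistic; it is reported as F = 0, p = 1.
* **Empirical level sets.** Per (g_max, Δ_peak) node the mean φ(P) is
  interpolated piecewise-linearly in P and φ(P) = φ_c solved on the
  monotone segments; ΔP is the span of crossing periods over non-empty
  nodes, and sweeping φ_c ∈ [0.2, 0.8] yields the range-vs-phase curves.
  On the simulated surfaces the C-DC regime has no solutions below
  φ_c ≈ DC (the follower cannot fire during the inhibitory window), a
  much wider ΔP than C-Dur at mid-range phases, and loses to C-Dur at
  high phases — with constant duty cycle, arbitrarily large follower
  phases are unreachable.
* **Published tables.** A tolerant XLSX reader extracts each sheet's
  largest numeric block so the same statistics run unchanged on published
  source-data spreadsheets (placed under `data/published/`) and on the
  synthetic tables this package writes. None are bundled; the relevant
  tests activate when the files are present.

## What the synthetic data do and do not establish

The generator reproduces the structure the analyses need: phase surfaces
with the experimental trend signs (φ falls with P, rises with g_max and
Δ_peak, in both regimes), sensitivity ordering (combined direction
largest, opposed smallest), level-set geometry including the C-DC floor at
DC, realistic-waveform phases in the biological range (mean ≈ 0.33), and
IBI-dependent inhibition depth. It does not reproduce effects that depend
on conductances outside the LIF: rebound-current timing (the I_BTA
peak-phase shift), spike-shape or intra-burst structure, and the specific
numbers of any biological fit. Green tests on synthetic data certify the
mathematics and the pipeline, not the biology.

## Reproducibility and problem sizes

Every stochastic stage derives an independent substream from one global
seed; identical config + seed gives byte-identical artifacts, and mixing
artifacts from different configurations in one output directory is
refused via a config hash in the manifest. The bundled analysis drivers
use 12 noise replicates × 30 min and 4 clamp replicates × 12 cycles; the
acceptance script uses 8 × 20 min and 4 replicates × 30 cycles; the test
suite uses smaller variants. These sizes were chosen so each run fills
every IBI bin and resolves the grid trends cleanly; the statistics are
insensitive to making them larger.
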