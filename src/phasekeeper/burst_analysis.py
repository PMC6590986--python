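"""Burst detection, inter-burst-interval binning, and burst-triggered
averaging of the driving input current.

Bursts are groups of at least ``min_spikes`` action potentials whose
consecutive inter-spike intervals are below ``max_isi``, following a silent
gap of at least ``min_gap`` (defaults 300 ms throughout, the convention used
for noise-driven pyloric follower recordings).  For each burst the preceding
inter-burst interval (IBI) — the gap from the previous spike of any kind to
the burst onset — classifies it into IBI bins (300/500/700/900 ms); the
input current over the ``[onset - bin, onset]`` window is averaged per bin
(the burst-triggered average, I_BTA) and summarized by four shape metrics:
peak (trough) amplitude, trough phase, and the rising and falling slopes on
normalized axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .synthetic_lp import SampledTrace

__all__ = [
    "Burst",
    "BurstSet",
    "BTAResult",
    "detect_bursts",
    "burst_triggered_average",
    "bta_metrics",
]

DEFAULT_BINS = (300.0, 500.0, 700.0, 900.0)


@dataclass(frozen=True)
class Burst:
    """One detected burst with its preceding silent gap."""

    onset: float
    offset: float
    spike_times: np.ndarray
    preceding_ibi: float  # math.inf when no earlier spike exists

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class BurstSet:
    """Ordered, non-overlapping bursts detected from one spike train."""

    bursts: list[Burst] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self):
        return iter(self.bursts)

    def onsets(self) -> np.ndarray:
        return np.array([b.onset for b in self.bursts])


def detect_bursts(
    spikes: np.ndarray,
    max_isi: float = 300.0,
    min_spikes: int = 2,
    min_gap: float = 300.0,
) -> BurstSet:
    """Detect bursts as maximal runs of spikes with ISIs below ``max_isi``.

    Runs with fewer than ``min_spikes`` spikes are discarded, as are runs
    whose preceding silent gap is shorter than ``min_gap``.  The first run
    of a recording has no earlier spike; its gap counts as infinite (kept).
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size and (np.any(np.diff(spikes) <= 0) or not np.all(
        np.isfinite(spikes)
    )):
        raise ValueError("spike times must be finite and strictly increasing")
    out = BurstSet()
    if spikes.size == 0:
        return out
    # split into maximal runs at ISIs >= max_isi
    breaks = np.nonzero(np.diff(spikes) >= max_isi)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [spikes.size - 1]))
    for s, e in zip(starts, ends):
        if e - s + 1 < min_spikes:
            continue
        gap = spikes[s] - spikes[s - 1] if s > 0 else math.inf
        if gap < min_gap:
            continue
        out.bursts.append(
            Burst(
                onset=float(spikes[s]),
                offset=float(spikes[e]),
                spike_times=spikes[s : e + 1].copy(),
                preceding_ibi=float(gap),
            )
        )
    return out


@dataclass
class BTAResult:
    """Burst-triggered average of the input current for one IBI bin.

    ``trace`` is the sample-wise mean of the current over the
    ``[onset - bin, onset]`` windows of the contributing bursts, amplitude-
    normalized across bins by the magnitude of the 300 ms bin's negative
    peak; its time axis is normalized to [0, 1].
    """

    bin_ms: float
    trace: np.ndarray | None
    n: int
    dt: float
    i_peak: float = math.nan
    delta_peak: float = math.nan
    slope_up: float = math.nan
    slope_down: float = math.nan


def burst_triggered_average(
    current: SampledTrace,
    bursts: BurstSet,
    bins=DEFAULT_BINS,
    bin_halfwidth: float = 100.0,
) -> list[BTAResult]:
    """Per-IBI-bin burst-triggered average of the input current.

    A burst contributes to bin ``b`` when its preceding IBI lies within
    ``b ± bin_halfwidth`` (half-open: ``[b - hw, b + hw)``) and the
    ``[onset - b, onset]`` window is fully covered by the current trace.
    All bins' mean traces are divided by the magnitude of the smallest
    (300 ms) bin's negative peak, so that bin's trough is exactly -1; shape
    metrics are then computed on the normalized traces.
    """
    bins = sorted(float(b) for b in bins)
    raw: list[BTAResult] = []
    t_lo = current.t0
    t_hi = current.t0 + current.duration
    for b in bins:
        n_samples = int(round(b / current.dt)) + 1
        segs = []
        for burst in bursts:
            ibi = burst.preceding_ibi
            if not (b - bin_halfwidth <= ibi < b + bin_halfwidth):
                continue
            # the averaging window must be spike-free: a burst whose gap is
            # shorter than the window length has the previous spike inside it
            if ibi < b:
                continue
            start = burst.onset - b
            if start < t_lo or burst.onset > t_hi:
                continue
            i0 = int(round((start - current.t0) / current.dt))
            if i0 < 0 or i0 + n_samples > current.values.size:
                continue
            segs.append(current.values[i0 : i0 + n_samples])
        if segs:
            mean = np.mean(segs, axis=0)
            raw.append(BTAResult(bin_ms=b, trace=mean, n=len(segs), dt=current.dt))
        else:
            raw.append(BTAResult(bin_ms=b, trace=None, n=0, dt=current.dt))
    # amplitude normalization by the first (smallest-IBI) bin's trough
    ref = raw[0]
    if ref.n > 0:
        scale = abs(float(ref.trace.min()))
        if scale > 0:
            for r in raw:
                if r.n > 0:
                    r.trace = r.trace / scale
    for r in raw:
        if r.n > 0:
            bta_metrics(r)
    return raw


def bta_metrics(result: BTAResult) -> BTAResult:
    """Fill the four shape metrics of one BTA trace (in place).

    On normalized axes (time mapped to [0, 1]):

    * ``i_peak``      = |minimum of the mean trace|
    * ``delta_peak``  = position of the (earliest) minimum / window length
    * ``slope_up``    = (trace(min) - trace(0)) / delta_peak
    * ``slope_down``  = (trace(end) - trace(min)) / (1 - delta_peak)

    Flat traces take the earliest minimum; degenerate end positions yield
    zero slopes.
    """
    if result.n < 1 or result.trace is None:
        raise ValueError("metrics require a non-empty BTA")
    y = result.trace
    k = int(np.argmin(y))  # ties -> earliest
    L = y.size - 1
    dpk = k / L if L > 0 else 0.0
    result.i_peak = abs(float(y[k]))
    result.delta_peak = dpk
    result.slope_up = (float(y[k]) - float(y[0])) / dpk if dpk > 0 else 0.0
    result.slope_down = (
        (float(y[-1]) - float(y[k])) / (1.0 - dpk) if dpk < 1.0 else 0.0
    )
    return result
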