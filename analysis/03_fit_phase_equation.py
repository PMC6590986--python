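"""Fit the constant-duty-cycle phase equation to the realistic surface.

phi = (tau_s / P) ln(g_max / g*) + c, with c the lumped peak-phase x
duty-cycle constant. Writes results/fit.json and prints the recovered
parameters next to the long-period limit they imply.
"""

import json

from common import RESULTS, config
from phasekeeper.workbench import run_pipeline


def main() -> None:
    run_pipeline(config(), "fit")
    fit = json.loads((RESULTS / "fit.json").read_text())
    print("fit of phi = (tau_s/P) ln(g_max/g*) + c to the simulated "
          "realistic-waveform surface:")
    print(f"  tau_s = {fit['tau_s']:.1f} ms, g* = {fit['g_star']:.4f} uS, "
          f"c = {fit['c']:.3f} (rms residual {fit['residual_norm']:.4f})")
    print(f"  implied P->inf phase limit: {fit['c']:.3f}")
    print("  (biological reference fit: tau_s = 26.0 ms, g* = 0.021 uS, "
          "c = 0.43)")


if __name__ == "__main__":
    main()
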