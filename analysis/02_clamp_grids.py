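"""Sweep the dynamic-clamp grids on the simulated follower.

Runs the triangular-conductance protocol (both constant-duration and
constant-duty-cycle regimes, P x g_max x delta_peak) and the realistic-
waveform protocol, producing long-format burst-onset phase surfaces.

Writes results/phase_surface.csv and results/realistic_surface.csv.
"""

import pandas as pd

from common import RESULTS, config
from phasekeeper.workbench import run_pipeline


def main() -> None:
    run_pipeline(config(), "clamp_grid")
    surf = pd.read_csv(RESULTS / "phase_surface.csv")
    ok = surf[surf["flag"].isna() | (surf["flag"] == "")]
    print(f"triangular surface: {len(surf)} runs, {len(ok)} with bursts")
    for mode in ("C_DC", "C_DUR"):
        s = ok[ok["mode"] == mode]
        by_P = s.groupby("P_ms")["phi"].mean()
        print(f"  {mode}: phi falls from {by_P.iloc[0]:.3f} (P={by_P.index[0]:.0f}) "
              f"to {by_P.iloc[-1]:.3f} (P={by_P.index[-1]:.0f})")
    real = pd.read_csv(RESULTS / "realistic_surface.csv")
    m = real.dropna(subset=["phi"])["phi"]
    print(f"realistic surface: mean phi = {m.mean():.3f} "
          f"(range {m.min():.3f}-{m.max():.3f})")


if __name__ == "__main__":
    main()
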