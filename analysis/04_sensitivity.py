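"""Directional sensitivity of burst phase to g_max and delta_peak.

From the triangular surface, differences phi along the eight grid
directions, averages them into four cardinal directions and tests the
direction and period effects with repeated-measures ANOVA.

Writes results/sensitivity.csv and results/sensitivity_tests.json.
"""

import json

import pandas as pd

from common import RESULTS, config
from phasekeeper.workbench import run_pipeline


def main() -> None:
    run_pipeline(config(), "sensitivity")
    sens = pd.read_csv(RESULTS / "sensitivity.csv")
    tests = json.loads((RESULTS / "sensitivity_tests.json").read_text())
    for mode in ("C_DC", "C_DUR"):
        m = (sens[sens["mode"] == mode]
             .groupby("direction")["sensitivity"].mean())
        print(f"{mode}: mean sensitivities "
              + ", ".join(f"{k} = {v:.3f}" for k, v in m.items()))
        t = tests.get(mode, {})
        print(f"  direction effect: one-way F = "
              f"{t.get('one_way_direction_F', float('nan')):.2f} "
              f"(p = {t.get('one_way_direction_p', float('nan')):.2g})")
    print("\nvarying g_max and delta_peak together moves phase most; "
          "in opposition, least.")


if __name__ == "__main__":
    main()
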