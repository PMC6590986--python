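"""Shared configuration for the numbered analysis drivers.

All drivers write into ``results/`` with one seed so their artifacts form a
single coherent dataset (the manifest refuses mixed configurations).
"""

from pathlib import Path

from phasekeeper.workbench import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

CONFIG = {
    "seed": 20190610,
    "outdir": str(RESULTS),
    # noise protocol: 12 preparations x 30 min keeps the full run under a
    # couple of minutes while filling every IBI bin
    "noise": {"n_replicates": 12, "duration_min": 30},
    # dynamic clamp: 4 jittered preparations, 12 cycles with the last 5
    # averaged (the deterministic runs reach steady state within 2 cycles)
    "protocol": {"n_replicates": 4, "n_cycles": 12, "n_keep": 5},
}


def config() -> RunConfig:
    return RunConfig.from_dict(CONFIG)
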