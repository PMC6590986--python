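"""Configuration, orchestration and I/O for the end-to-end pipelines.

A single :class:`RunConfig` (YAML- or dict-backed, unknown keys rejected)
drives the reproduction stages:

``noise_bta``          noise-driven follower runs → burst-triggered-average
                       metrics table and Friedman statistics
``clamp_grid``         triangular and realistic dynamic-clamp grids →
                       long-format phase surfaces
``fit``                constant-duty-cycle phase-equation fit to the
                       realistic-waveform surface
``levelsets``          empirical level sets and ΔP(φ_c) curves from the
                       measured surface
``sensitivity``        directional sensitivity grids and repeated-measures
                       statistics
``depression_curves``  fixed-g_max vs depressing-synapse phase-constancy
                       ranges

Every stage derives its own random substream from the global seed, writes
CSV/JSON artifacts into the output directory and registers them in a
manifest carrying the config hash, so identical config + seed reproduce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import depression as depr
from . import phase_constancy as pc
from . import surface_stats as ss
from .burst_analysis import burst_triggered_average, detect_bursts
from .core_model import Mode, PhaseModelParams
from .synthetic_lp import (
    DEFAULT_NEURON,
    ClampProtocol,
    FollowerNeuronParams,
    OUParams,
    noise_protocol_neuron,
    ou_current,
    run_clamp_grid,
    simulate_follower,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "roundtrip_tables",
    "write_table",
    "read_table",
    "load_schedules",
]

STAGES = (
    "noise_bta",
    "clamp_grid",
    "fit",
    "levelsets",
    "sensitivity",
    "depression_curves",
)

_DEFAULTS: dict = {
    "seed": None,
    "outdir": "artifacts",
    "model": {"tau_r_ms": 0.1, "tau_s_ms": 26.0, "g_star_uS": 0.021},
    "depression": {
        "tau_alpha_ms": 1000.0,
        "tau_beta_ms": 200.0,
        "P_ref_ms": 1000.0,
        "g_ref_uS": 0.335,
    },
    "neuron": {},
    "noise": {
        "tau_ms": 15.0,
        "sigma_nA": 0.2,
        "I_DC_nA": -0.15,
        "duration_min": 60.0,
        "dt_ms": 0.1,
        "n_replicates": 23,
    },
    "protocol": {
        "n_cycles": 30,
        "n_keep": 5,
        "dt_ms": 0.05,
        "n_replicates": 9,
        "jitter": 0.05,
    },
    "stats": {"phi_c": 0.34, "phi_c_grid": [0.2, 0.8, 31]},
}


def _merge_strict(defaults: dict, given: dict, path: str = "") -> dict:
    out = {}
    for k, v in defaults.items():
        if isinstance(v, dict):
            out[k] = _merge_strict(v, given.get(k, {}) or {}, f"{path}{k}.")
        else:
            out[k] = given.get(k, v)
    unknown = set(given) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(path + u for u in unknown)}")
    return out


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration; ``seed`` is mandatory."""

    data: dict

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        merged = _merge_strict(_DEFAULTS, d)
        if merged["seed"] is None:
            raise ValueError("config requires an integer seed")
        merged["seed"] = int(merged["seed"])
        return cls(merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def seed(self) -> int:
        return self.data["seed"]

    @property
    def outdir(self) -> Path:
        return Path(self.data["outdir"])

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream root (stable across re-runs)."""
        idx = STAGES.index(stage)
        return int(
            np.random.SeedSequence([self.seed, idx]).generate_state(1)[0]
            & 0x7FFFFFFF
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def model_params(self) -> PhaseModelParams:
        m = self.data["model"]
        return PhaseModelParams(
            tau_r=m["tau_r_ms"], tau_s=m["tau_s_ms"], g_star=m["g_star_uS"]
        )

    def clamp_neuron(self) -> FollowerNeuronParams:
        return dataclasses.replace(DEFAULT_NEURON, **self.data["neuron"])

    def depression_params(self, DC: float = 0.3) -> depr.DepressionParams:
        d = self.data["depression"]
        base = depr.DepressionParams(
            tau_alpha=d["tau_alpha_ms"], tau_beta=d["tau_beta_ms"]
        )
        return depr.calibrate_gbar(d["P_ref_ms"], d["g_ref_uS"], DC, base)


def load_schedules(path) -> list:
    """Read synapse schedules from CSV.

    Columns: ``P_ms, mode, T_act_ms, DC, delta_peak, g_max_uS``; T_act_ms
    applies to C_DUR rows and DC to C_DC rows (the other may be blank).
    """
    from .core_model import Mode, SynapseSchedule

    df = pd.read_csv(path)
    required = {"P_ms", "mode", "delta_peak", "g_max_uS"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"schedule CSV missing column(s) {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        mode = Mode(r["mode"])
        out.append(
            SynapseSchedule(
                P=float(r["P_ms"]),
                mode=mode,
                g_max=float(r["g_max_uS"]),
                delta_peak=float(r["delta_peak"]),
                T_act=float(r["T_act_ms"]) if mode is Mode.C_DUR else None,
                DC=float(r["DC"]) if mode is Mode.C_DC else None,
            )
        )
    return out


def write_table(obj, path: Path) -> None:
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    raise TypeError(f"cannot serialize {type(x)}")


def read_table(path: Path):
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    with open(path) as fh:
        return json.load(fh)


def roundtrip_tables(path: Path):
    """Read an artifact table; raises a named-column error on bad schemas."""
    obj = read_table(path)
    if isinstance(obj, pd.DataFrame) and any(
        str(c).startswith("Unnamed") for c in obj.columns
    ):
        bad = [c for c in obj.columns if str(c).startswith("Unnamed")]
        raise ValueError(f"malformed header in {path}: unnamed column(s) {bad}")
    return obj


# ---------------------------------------------------------------------------
# stages

_BTA_METRICS = ("i_peak", "delta_peak", "slope_up", "slope_down")


def _stage_noise_bta(cfg: RunConfig, out: Path) -> list[str]:
    nz = cfg.data["noise"]
    neuron = noise_protocol_neuron()
    root = cfg.stage_seed("noise_bta")
    rows = []
    trace_acc: dict[float, list[np.ndarray]] = {}
    for rep in range(int(nz["n_replicates"])):
        ou = ou_current(
            OUParams(
                tau=nz["tau_ms"],
                sigma=nz["sigma_nA"],
                I_DC=nz["I_DC_nA"],
                seed=(root + rep) & 0x7FFFFFFF,
            ),
            nz["duration_min"] * 60_000.0,
            nz["dt_ms"],
        )
        _, spikes = simulate_follower(neuron, I_ext=ou, store_voltage=False)
        bursts = detect_bursts(spikes)
        for r in burst_triggered_average(ou, bursts):
            rows.append(
                (
                    rep,
                    r.bin_ms,
                    r.n,
                    r.i_peak,
                    r.delta_peak,
                    r.slope_up,
                    r.slope_down,
                )
            )
            if r.n:
                x = np.linspace(0.0, 1.0, 101)
                y = np.interp(x, np.linspace(0, 1, r.trace.size), r.trace)
                trace_acc.setdefault(r.bin_ms, []).append(y)
    metrics = pd.DataFrame(
        rows, columns=["replicate", "bin_ms", "n_bursts", *_BTA_METRICS]
    )
    write_table(metrics, out / "bta_metrics.csv")
    tr_rows = []
    for b, tl in sorted(trace_acc.items()):
        m = np.mean(tl, axis=0)
        for i, v in enumerate(m):
            tr_rows.append((b, i / (m.size - 1), v))
    write_table(
        pd.DataFrame(tr_rows, columns=["bin_ms", "time_norm", "i_bta"]),
        out / "bta_traces.csv",
    )
    tests = {}
    wide_all = metrics.pivot(index="replicate", columns="bin_ms", values="n_bursts")
    complete = wide_all.index[(wide_all > 0).all(axis=1)]
    for m in _BTA_METRICS:
        wide = metrics.pivot(index="replicate", columns="bin_ms", values=m)
        wide = wide.loc[complete].dropna()
        if wide.shape[0] >= 2:
            res = ss.friedman_test(wide.to_numpy(), name=m)
            tests[m] = {
                "chi2": res.statistic,
                "df": res.df[0],
                "p": res.p_value,
                "n_replicates": wide.shape[0],
            }
    write_table(tests, out / "bta_friedman.json")
    return ["bta_metrics.csv", "bta_traces.csv", "bta_friedman.json"]


def _stage_clamp_grid(cfg: RunConfig, out: Path) -> list[str]:
    pr = cfg.data["protocol"]
    neuron = cfg.clamp_neuron()
    common = dict(
        n_cycles=int(pr["n_cycles"]),
        n_keep=int(pr["n_keep"]),
        dt=pr["dt_ms"],
        n_replicates=int(pr["n_replicates"]),
        jitter=pr["jitter"],
        seed=cfg.stage_seed("clamp_grid"),
    )
    tri = run_clamp_grid(neuron, ClampProtocol(**common))
    write_table(tri, out / "phase_surface.csv")
    real = run_clamp_grid(neuron, ClampProtocol.realistic(**common))
    write_table(real, out / "realistic_surface.csv")
    return ["phase_surface.csv", "realistic_surface.csv"]


def _require(out: Path, name: str, stage: str) -> pd.DataFrame:
    p = out / name
    if not p.exists():
        raise FileNotFoundError(
            f"stage '{stage}' requires artifact {p}; run 'clamp_grid' first"
        )
    return roundtrip_tables(p)


def _stage_fit(cfg: RunConfig, out: Path) -> list[str]:
    real = _require(out, "realistic_surface.csv", "fit")
    mean = (
        real.dropna(subset=["phi"])
        .groupby(["P_ms", "g_max_uS"], as_index=False)["phi"]
        .mean()
    )
    fit = ss.fit_phase_model(mean)
    write_table(dataclasses.asdict(fit), out / "fit.json")
    return ["fit.json"]


def _stage_levelsets(cfg: RunConfig, out: Path) -> list[str]:
    surf = _require(out, "phase_surface.csv", "levelsets")
    st = cfg.data["stats"]
    phi_c = st["phi_c"]
    lo, hi, n = st["phi_c_grid"]
    grid = np.linspace(lo, hi, int(n))
    arts = []
    maps = []
    curves = []
    for mode in ("C_DC", "C_DUR"):
        ls = ss.empirical_levelset(surf, phi_c, mode=mode)
        ls.insert(0, "mode", mode)
        ls["dP_ms"] = ls.attrs["dP"]
        maps.append(ls)
        cur = ss.levelset_range_curve(surf, grid, mode=mode)
        cur.insert(0, "mode", mode)
        curves.append(cur)
    write_table(pd.concat(maps, ignore_index=True), out / "empirical_levelsets.csv")
    write_table(pd.concat(curves, ignore_index=True), out / "levelset_ranges.csv")
    arts += ["empirical_levelsets.csv", "levelset_ranges.csv"]
    return arts


def _stage_sensitivity(cfg: RunConfig, out: Path) -> list[str]:
    surf = _require(out, "phase_surface.csv", "sensitivity")
    frames = []
    tests = {}
    for mode in ("C_DC", "C_DUR"):
        sens = ss.sensitivity_grid(surf[surf["mode"] == mode])
        sens.insert(0, "mode", mode)
        frames.append(sens)
        if sens["replicate"].nunique() >= 2:
            per = {"mode": mode}
            one = ss.rm_anova(
                sens.groupby(["replicate", "direction"], as_index=False)[
                    "sensitivity"
                ].mean(),
                "sensitivity",
                "direction",
                "replicate",
            )
            per["one_way_direction_F"] = one[0].statistic
            per["one_way_direction_p"] = one[0].p_value
            two = ss.rm_anova(
                sens, "sensitivity", ["direction", "P_ms"], "replicate"
            )
            for t in two:
                key = t.name.replace(":", "_x_")
                per[f"two_way_{key}_F"] = t.statistic
                per[f"two_way_{key}_p"] = t.p_value
            tests[mode] = per
    write_table(pd.concat(frames, ignore_index=True), out / "sensitivity.csv")
    write_table(tests, out / "sensitivity_tests.json")
    return ["sensitivity.csv", "sensitivity_tests.json"]


def _stage_depression_curves(cfg: RunConfig, out: Path) -> list[str]:
    st = cfg.data["stats"]
    params = cfg.model_params()
    DC = 0.3
    dp = cfg.depression_params(DC)
    lo, hi, n = st["phi_c_grid"]
    grid = np.linspace(lo, hi, int(n))
    g_fixed = cfg.data["depression"]["g_ref_uS"]
    fixed = pc.delta_p_curve(grid, params, Mode.C_DC, g_max=g_fixed, DC=DC)
    fixed.insert(0, "g_max_rule", "fixed")
    dep = pc.delta_p_curve(
        grid,
        params,
        Mode.C_DC,
        DC=DC,
        depression=lambda P: depr.depressing_gmax(P, DC, dp),
    )
    dep.insert(0, "g_max_rule", "depressing")
    write_table(pd.concat([fixed, dep], ignore_index=True), out / "depression_curves.csv")
    P_grid = np.logspace(2, math.log10(20_000.0), 400)
    ls = depr.depressing_levelset(st["phi_c"], dp, params, DC, P_grid)
    write_table(ls, out / "depressing_levelset.csv")
    return ["depression_curves.csv", "depressing_levelset.csv"]


_STAGE_FN = {
    "noise_bta": _stage_noise_bta,
    "clamp_grid": _stage_clamp_grid,
    "fit": _stage_fit,
    "levelsets": _stage_levelsets,
    "sensitivity": _stage_sensitivity,
    "depression_curves": _stage_depression_curves,
}


def run_pipeline(config: RunConfig, stage: str = "all") -> dict:
    """Execute one stage (or ``all`` in dependency order); returns the
    manifest (also written to ``manifest.json``)."""
    stages = list(STAGES) if stage == "all" else [stage]
    for s in stages:
        if s not in _STAGE_FN:
            raise ValueError(f"unknown stage '{s}'; choose from {STAGES} or 'all'")
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") != config.config_hash():
            raise ValueError(
                "output directory contains artifacts from a different config "
                f"(hash {manifest.get('config_hash')}); use a fresh outdir"
            )
    else:
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "artifacts": {},
        }
    for s in stages:
        arts = _STAGE_FN[s](config, out)
        manifest["artifacts"][s] = {"files": arts, "stage_seed": config.stage_seed(s)}
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
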