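"""End-to-end reproducible runs: cohort generation, per-cell analysis,
group statistics, and neuron-simulation scenarios from one config.

The run is fully determined by (config, seed): per-cohort seeds are
derived from the master seed, and the manifest records the config hash,
seed and package versions needed to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import TAU_REPORT_GRID, analyze_cell, metrics_table
from .phenotypes import default_phenotype
from .protocols import protocol_preset, PROTOCOL_KINDS
from .stats import interaction_anova, log10_tau_table, per_voltage_tests
from .synth import generate_cell_suite, simulate_protocol
from .traceio import write_traceset
from .neuron import (SimTrace, build_neuron, firing_rate_curve,
                     inactivation_only_variant, lq_variant,
                     persistent_firing_test, persistent_only_variant,
                     ramp_block_test, rheobase, stimulus_preset,
                     test_pulse_peak_current, wt_variant)

__all__ = ["RunConfig", "run_pipeline", "generate_fixtures",
           "write_simtrace", "DEFAULT_CONFIG"]

log = logging.getLogger("navkit.pipeline")

VARIANT_BUILDERS = {
    "WT": wt_variant,
    "L1624Q": lq_variant,
    "persistent_only": persistent_only_variant,
    "inactivation_only": inactivation_only_variant,
}

# Cohort sizes mirror the current-density experiment (the largest per
# condition in the study design: 28/28 at 22 degC, 28/41 at 37 degC).
DEFAULT_CONFIG: dict = {
    "cohorts": [
        {"genotype": "WT", "temperature": 22, "n": 28},
        {"genotype": "L1624Q", "temperature": 22, "n": 28},
        {"genotype": "WT", "temperature": 37, "n": 28},
        {"genotype": "L1624Q", "temperature": 37, "n": 41},
    ],
    "cell_variability": 0.15,
    "noise_sd": 0.0,
    "capacitance_mean": 15.0,
    "protocols": list(PROTOCOL_KINDS),
    "variants": ["WT", "L1624Q"],
    "scenarios": ["test_pulse", "rheobase", "persistent_firing"],
    "write_traces": False,
}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration."""
    seed: int
    outdir: Path
    cohorts: List[dict]
    cell_variability: float = 0.15
    noise_sd: float = 0.0
    capacitance_mean: float = 15.0
    protocols: List[str] = dataclasses.field(
        default_factory=lambda: list(PROTOCOL_KINDS))
    variants: List[str] = dataclasses.field(
        default_factory=lambda: ["WT", "L1624Q"])
    scenarios: List[str] = dataclasses.field(
        default_factory=lambda: ["test_pulse", "rheobase",
                                 "persistent_firing"])
    write_traces: bool = False

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None,
                  outdir: Optional[Path] = None) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_dict(raw, seed=seed, outdir=outdir)

    @classmethod
    def from_dict(cls, raw: dict, seed: Optional[int] = None,
                  outdir: Optional[Path] = None) -> "RunConfig":
        merged = {**DEFAULT_CONFIG, **raw}
        seed = seed if seed is not None else merged.get("seed")
        if seed is None:
            raise ValueError("a seed is required (stochastic stages enabled)")
        outdir = Path(outdir if outdir is not None
                      else merged.get("outdir", "navkit_out"))
        for p in merged["protocols"]:
            if p not in PROTOCOL_KINDS:
                raise KeyError(f"unknown protocol preset {p!r}")
        for v in merged["variants"]:
            if v not in VARIANT_BUILDERS:
                raise KeyError(f"unknown variant {v!r}; "
                               f"available: {sorted(VARIANT_BUILDERS)}")
        known = {"test_pulse", "rheobase", "persistent_firing",
                 "firing_rates", "ramp_rest", "ramp_prestim"}
        for s in merged["scenarios"]:
            if s not in known:
                raise KeyError(f"unknown scenario {s!r}; available: "
                               f"{sorted(known)}")
        return cls(seed=int(seed), outdir=outdir,
                   cohorts=merged["cohorts"],
                   cell_variability=float(merged["cell_variability"]),
                   noise_sd=float(merged["noise_sd"]),
                   capacitance_mean=float(merged["capacitance_mean"]),
                   protocols=list(merged["protocols"]),
                   variants=list(merged["variants"]),
                   scenarios=list(merged["scenarios"]),
                   write_traces=bool(merged["write_traces"]))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        return d


def _cohort_seed(master: int, index: int) -> int:
    ss = np.random.SeedSequence([master, index])
    return int(ss.generate_state(1)[0] % (2**31))


def write_simtrace(trace: SimTrace, path, stride: int = 10) -> Path:
    """Write a SimTrace as a time/voltage/stimulus table (decimated by
    `stride`) plus a JSON summary sidecar with spike times and metrics."""
    path = Path(path)
    body = np.column_stack([trace.time[::stride], trace.v_m[::stride],
                            trace.stimulus[::stride]])
    with open(path, "w") as f:
        f.write("time_ms\tv_m_mV\tstimulus_pA\n")
        np.savetxt(f, body, fmt="%.9g", delimiter="\t")
    summary = {
        "n_spikes": int(trace.spike_times.size),
        "spike_times_ms": [round(float(t), 4) for t in trace.spike_times],
        "fired_after_offset": trace.fired_after_offset,
        "block_onset_current_pA": trace.block_onset_current,
        "dt_ms": trace.dt,
    }
    path.with_suffix(path.suffix + ".summary.json").write_text(
        json.dumps(summary, indent=1))
    return path


def generate_cohorts(config: RunConfig) -> Dict[tuple, list]:
    """Generate every cohort of the config: condition -> list of per-cell
    protocol-suite dicts."""
    protos = {name: protocol_preset(name) for name in config.protocols}
    out = {}
    for i, spec in enumerate(config.cohorts):
        phen = default_phenotype(spec["genotype"], spec["temperature"])
        suite = generate_cell_suite(
            phen, protos, n_cells=int(spec["n"]),
            cell_variability=float(spec.get("variability",
                                            config.cell_variability)),
            noise_sd=float(spec.get("noise_sd", config.noise_sd)),
            seed=_cohort_seed(config.seed, i),
            capacitance_mean=config.capacitance_mean)
        out[(spec["genotype"], spec["temperature"])] = suite
        log.info("generated cohort %s/%s degC: %d cells",
                 spec["genotype"], spec["temperature"], len(suite))
    return out


def analyze_cohorts(cohorts: Dict[tuple, list]) -> pd.DataFrame:
    """Per-cell metrics table over all cohorts."""
    frames = []
    for (gen, temp), suite in cohorts.items():
        cells = [analyze_cell(cell) for cell in suite]
        df = metrics_table(cells)
        frames.append(df)
        log.info("analyzed cohort %s/%s degC", gen, temp)
    table = pd.concat(frames, ignore_index=True)
    table["cell_id"] = range(len(table))
    return table


def stats_stage(metrics: pd.DataFrame) -> dict:
    """Interaction ANOVAs on density and persistent fraction, plus
    per-voltage genotype contrasts on log10 tau at each temperature."""
    out = {"anova": {}, "per_voltage": {}}
    for response in ("density_pA_pF", "persistent_pct"):
        res = interaction_anova(
            metrics.rename(columns={"temperature_C": "temperature"}),
            response)
        out["anova"][response] = res
    tau_cols = [c for c in metrics.columns if c.startswith("tau_ms_at_")]
    long = metrics.melt(
        id_vars=["cell_id", "genotype", "temperature_C"],
        value_vars=tau_cols, var_name="voltage", value_name="tau_ms")
    long["voltage"] = long["voltage"].str.removeprefix("tau_ms_at_").astype(float)
    long = log10_tau_table(long.dropna(subset=["tau_ms"]), "tau_ms")
    for temp in sorted(long["temperature_C"].unique()):
        sub = long[long["temperature_C"] == temp]
        out["per_voltage"][float(temp)] = per_voltage_tests(
            sub, response="log10_tau_ms")
    return out


def simulate_stage(config: RunConfig, outdir: Optional[Path] = None) -> dict:
    """Run the configured neuron scenarios for every configured variant."""
    params = {name: build_neuron(VARIANT_BUILDERS[name]())
              for name in config.variants}
    summary: dict = {}
    if "test_pulse" in config.scenarios:
        peaks = {n: test_pulse_peak_current(p) for n, p in params.items()}
        summary["test_pulse_peak_uA_cm2"] = peaks
        if "WT" in peaks and "L1624Q" in peaks:
            summary["peak_reduction_pct"] = 100.0 * (
                1.0 - peaks["L1624Q"] / peaks["WT"])
    if "rheobase" in config.scenarios:
        summary["rheobase_pA"] = {n: rheobase(p) for n, p in params.items()}
    if "persistent_firing" in config.scenarios:
        res = {}
        for n, p in params.items():
            fired, n_post, trace = persistent_firing_test(p)
            res[n] = {"fired_after_offset": bool(fired),
                      "spikes_after_offset": n_post}
            if config.write_traces and outdir is not None:
                write_simtrace(trace, outdir / f"persistent_firing_{n}.tsv")
        summary["persistent_firing"] = res
    if "firing_rates" in config.scenarios:
        amps = [1.0, 2.0, 5.0, 10.0, 20.0, 40.0]
        summary["firing_rates_hz"] = {
            n: firing_rate_curve(p, amps) for n, p in params.items()}
    for scen in ("ramp_rest", "ramp_prestim"):
        if scen in config.scenarios:
            ramp = stimulus_preset(scen)
            summary.setdefault("block_onset_pA", {}).setdefault(scen, {})
            for n, p in params.items():
                summary["block_onset_pA"][scen][n] = ramp_block_test(p, ramp)
    log.info("simulation scenarios done: %s", sorted(summary))
    return summary


def _manifest(config: RunConfig, files: List[Path]) -> dict:
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    entries = {}
    for f in files:
        entries[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    return {
        "navkit_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config.to_dict(),
        "outputs_sha256": entries,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute generate -> analyze -> stats -> simulate and write the
    report files under ``config.outdir``.  Returns the report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: List[Path] = []

    cohorts = generate_cohorts(config)
    if config.write_traces:
        tracedir = outdir / "traces"
        tracedir.mkdir(exist_ok=True)
        for (gen, temp), suite in cohorts.items():
            for i, cell in enumerate(suite):
                for pname, ts in cell.items():
                    fp = write_traceset(
                        ts, tracedir / f"{gen}_{temp}C_cell{i:03d}_{pname}.tsv")
                    files.append(fp)

    metrics = analyze_cohorts(cohorts)
    mpath = outdir / "cell_metrics.tsv"
    metrics.to_csv(mpath, sep="\t", index=False, float_format="%.10g")
    files.append(mpath)

    stats = stats_stage(metrics)
    effects = pd.concat(
        [res.to_frame().assign(response=name)
         for name, res in stats["anova"].items()], ignore_index=True)
    epath = outdir / "effects.tsv"
    effects.to_csv(epath, sep="\t", index=False, float_format="%.6g")
    files.append(epath)
    pv_rows = [{"temperature_C": temp, "voltage_mV": v, "p": p}
               for temp, pairs in stats["per_voltage"].items()
               for v, p in pairs]
    pvpath = outdir / "per_voltage_tests.tsv"
    pd.DataFrame(pv_rows).to_csv(pvpath, sep="\t", index=False,
                                 float_format="%.6g")
    files.append(pvpath)

    sim = simulate_stage(config, outdir)
    spath = outdir / "simulation_summary.json"
    spath.write_text(json.dumps(sim, indent=1, sort_keys=True))
    files.append(spath)

    report = {
        "metrics_rows": len(metrics),
        "anova_stepdown": {name: res.stepdown_applied
                           for name, res in stats["anova"].items()},
        "simulation": sim,
        "files": [str(f) for f in files],
    }
    manifest = _manifest(config, files)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report


def generate_fixtures(seed: int, outdir, noisy: bool = False,
                      n_noisy_cells: int = 5,
                      sample_interval: float = 0.05) -> List[Path]:
    """Write small TraceSet fixture files: one noise-free set per
    protocol x genotype x temperature (16 files), plus optional noisy
    cohorts.  Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    protos = {name: protocol_preset(name, sample_interval=sample_interval)
              for name in PROTOCOL_KINDS}
    for gen in ("WT", "L1624Q"):
        for temp in (22, 37):
            phen = default_phenotype(gen, temp)
            for pname, proto in protos.items():
                ts = simulate_protocol(phen, proto, capacitance=15.0)
                fp = write_traceset(
                    ts, outdir / f"{gen}_{temp}C_{pname}_clean.tsv")
                written.append(fp)
            if noisy:
                suite = generate_cell_suite(
                    phen, protos, n_cells=n_noisy_cells,
                    cell_variability=0.15, noise_sd=10.0,
                    seed=_cohort_seed(seed, hash((gen, temp)) % 1000))
                for i, cell in enumerate(suite):
                    for pname, ts in cell.items():
                        fp = write_traceset(
                            ts,
                            outdir / f"{gen}_{temp}C_noisy{i}_{pname}.tsv")
                        written.append(fp)
    return written
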