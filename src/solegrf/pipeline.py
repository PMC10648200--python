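"""End-to-end orchestration: simulate → preprocess → fit → evaluate → report.

A run is a pure function of its :class:`RunConfig` (including the master
seed): the generator, per-fold GP restarts and summary tables are all
seeded deterministically, so rerunning the same config file reproduces
byte-identical summary CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as trial_io
from .evaluation import (FoldResult, interval_coverage, loocv, summarize,
                         variability_summary)
from .gpr import GPRConfig
from .preprocessing import assemble_dataset, preprocess_trials
from .synthetic import (GeneratorConfig, WaveformParams, generate_dataset)

DIRECTIONS = ("x", "y", "z")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cutoff_hz: float = 50.0
    sensor_threshold_n: float = 15.0
    plate_threshold_n: float = 50.0
    interpolation: str = "linear"
    p_enter: float = 0.05
    p_remove: float = 0.10
    gpr: GPRConfig = field(default_factory=GPRConfig)
    gpr_k: int = 12
    models: tuple[str, ...] = ("mlr", "gpr")
    groupings: tuple[str, ...] = ("per-movement", "all")
    master_seed: int = 0

    def __post_init__(self) -> None:
        # one seed to rule the run: generator and GP restarts both derive from it
        self.generator = dataclasses.replace(self.generator,
                                             master_seed=self.master_seed)
        self.gpr = dataclasses.replace(self.gpr, seed=self.master_seed)

    def to_dict(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return {
            "generator": encode(self.generator),
            "preprocessing": {"cutoff_hz": self.cutoff_hz,
                              "sensor_threshold_n": self.sensor_threshold_n,
                              "plate_threshold_n": self.plate_threshold_n,
                              "interpolation": self.interpolation},
            "mlr": {"p_enter": self.p_enter, "p_remove": self.p_remove},
            "gpr": encode(self.gpr),
            "evaluation": {"gpr_k": self.gpr_k,
                           "models": list(self.models),
                           "groupings": list(self.groupings)},
            "master_seed": self.master_seed,
        }

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen_raw = dict(raw.get("generator", {}))
        wf = WaveformParams(**{k: tuple(map(tuple, v)) if isinstance(v, list)
                               and v and isinstance(v[0], list) else
                               (tuple(v) if isinstance(v, list) else v)
                               for k, v in gen_raw.pop("waveform", {}).items()})
        if "movements" in gen_raw:
            gen_raw["movements"] = tuple(gen_raw["movements"])
        if "mass_bounds" in gen_raw:
            gen_raw["mass_bounds"] = tuple(gen_raw["mass_bounds"])
        gen = GeneratorConfig(waveform=wf, **gen_raw)
        pre = raw.get("preprocessing", {})
        mlr_raw = raw.get("mlr", {})
        gpr_raw = dict(raw.get("gpr", {}))
        ev = raw.get("evaluation", {})
        return cls(
            generator=gen,
            cutoff_hz=pre.get("cutoff_hz", 50.0),
            sensor_threshold_n=pre.get("sensor_threshold_n", 15.0),
            plate_threshold_n=pre.get("plate_threshold_n", 50.0),
            interpolation=pre.get("interpolation", "linear"),
            p_enter=mlr_raw.get("p_enter", 0.05),
            p_remove=mlr_raw.get("p_remove", 0.10),
            gpr=GPRConfig(**gpr_raw),
            gpr_k=ev.get("gpr_k", 12),
            models=tuple(ev.get("models", ("mlr", "gpr"))),
            groupings=tuple(ev.get("groupings", ("per-movement", "all"))),
            master_seed=raw.get("master_seed", 0),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class RunResult:
    """In-memory results of one end-to-end run."""

    config: RunConfig
    steps: list
    summaries: dict[tuple[str, str], pd.DataFrame]  # (grouping, model) -> table
    folds: dict[tuple[str, str], list[FoldResult]]  # (dataset name, model)
    variability: pd.DataFrame
    log: list[dict]

    def summary_frame(self) -> pd.DataFrame:
        frames = []
        for (grouping, model), table in sorted(self.summaries.items()):
            t = table.copy()
            t.insert(0, "grouping", grouping)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def execute(config: RunConfig) -> RunResult:
    """Run the whole analysis in memory (no files written)."""
    log: list[dict] = []

    def stage(name: str, t_start: float, **extra) -> None:
        log.append({"stage": name, "seconds": round(time.time() - t_start, 3),
                    **extra})

    t = time.time()
    trials = generate_dataset(config.generator)
    stage("simulate", t, n_trials=len(trials))

    t = time.time()
    steps = preprocess_trials(
        trials, cutoff=config.cutoff_hz,
        sensor_threshold=config.sensor_threshold_n,
        plate_threshold=config.plate_threshold_n,
        interpolation=config.interpolation)
    stage("preprocess", t, n_steps=len(steps))

    movements = list(dict.fromkeys(st.movement.label for st in steps))
    datasets: dict[str, list] = {}
    if "per-movement" in config.groupings:
        for mov in movements:
            datasets[mov] = [st for st in steps if st.movement.label == mov]
    if "all" in config.groupings and len(movements) > 1:
        datasets["all"] = list(steps)

    summaries: dict[tuple[str, str], pd.DataFrame] = {}
    folds_by: dict[tuple[str, str], list[FoldResult]] = {}
    for name, group_steps in datasets.items():
        ds = assemble_dataset(group_steps)
        for model in config.models:
            t = time.time()
            folds = loocv(ds, model, gpr_config=config.gpr,
                          p_enter=config.p_enter, p_remove=config.p_remove,
                          gpr_k=config.gpr_k)
            folds_by[(name, model)] = folds
            grouping = "all" if name == "all" else "per-movement"
            table = summarize(folds, grouping)
            summaries[(name, model)] = table
            extra = {}
            if model == "gpr":
                extra["coverage_95"] = round(interval_coverage(folds), 4)
            stage(f"loocv[{name}/{model}]", t, n_folds=len(folds), **extra)

    t = time.time()
    variability = variability_summary(steps)
    stage("variability", t)

    return RunResult(config=config, steps=steps, summaries=summaries,
                     folds=folds_by, variability=variability, log=log)


def run_experiment(config: RunConfig, out_dir: str | Path,
                   write_trials: bool = False) -> Path:
    """Execute a run and persist its outputs under ``out_dir``.

    Writes: the echoed config (YAML), aligned steps CSV, per-fold JSONL,
    per-(dataset, model) and combined summary CSVs, the variability table,
    and a run log with seeds, timings and the config hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(out / "config.yaml")

    result = execute(config)
    if write_trials:
        trials = generate_dataset(config.generator)
        trial_io.write_trials(trials, out / "trials")
    trial_io.write_aligned_steps(result.steps, out / "aligned_steps.csv")

    with open(out / "folds.jsonl", "w") as fh:
        for (name, model), folds in sorted(result.folds.items()):
            for f in folds:
                fh.write(json.dumps({
                    "dataset": name, "model": model,
                    "step": list(map(str, f.step_key)),
                    "movement": f.movement,
                    "metrics": {d: {"mae": f.metrics[d].mae,
                                    "pct_rmse": f.metrics[d].pct_rmse,
                                    "adj_r2": f.metrics[d].adj_r2}
                                for d in DIRECTIONS},
                    "config_hash": chash,
                }) + "\n")

    combined = result.summary_frame()
    combined["config_hash"] = chash
    combined.to_csv(out / "summary.csv", index=False, float_format="%.6g")
    result.variability.assign(config_hash=chash).to_csv(
        out / "variability.csv", index=False, float_format="%.6g")
    (out / "run_log.json").write_text(json.dumps({
        "config_hash": chash, "master_seed": config.master_seed,
        "stages": result.log}, indent=1))
    return out


def plot_data_frame(result: RunResult, dataset: str, model: str) -> pd.DataFrame:
    """Long-format per-step curves (measured, predicted, CI) for plotting."""
    rows = []
    for f in result.folds[(dataset, model)]:
        for d_idx, d in enumerate(DIRECTIONS):
            for pct in range(f.measured.shape[0]):
                rows.append({
                    "step": "/".join(map(str, f.step_key)), "direction": d,
                    "pct": pct,
                    "measured": f.measured[pct, d_idx],
                    "predicted": f.predicted[pct, d_idx],
                    "ci_low": None if f.ci95_low is None else f.ci95_low[pct, d_idx],
                    "ci_high": None if f.ci95_high is None else f.ci95_high[pct, d_idx],
                })
    return pd.DataFrame(rows)
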