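"""On-disk interchange formats.

A trial is a directory of three CSVs plus ``meta.json``::

    trial_000/
      sensor.csv      time,fx1,...,fx4,fy1,...,fy4,fz1,...,fz4   (870 Hz)
      forceplate.csv  time,FX,FY,FZ                              (1000 Hz)
      markers.csv     time,heelX,heelY,toeX,toeY                 (200 Hz)
      meta.json       participant, mass, movement, heading, seed, rates

Aligned steps (the interchange format between preprocessing and the
regression stages) are a single CSV with one 101-row block per step:
``participant,movement,step,pct,fx1..fz4,Fx,Fy,Fz``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (FEATURE_COLUMNS, MOVEMENTS, TARGET_COLUMNS,
                        ParticipantProfile, TrialRecording)

FLOAT_FMT = "%.9g"

_SENSOR_HEADER = ["time", *FEATURE_COLUMNS]
_PLATE_HEADER = ["time", "FX", "FY", "FZ"]
_MARKER_HEADER = ["time", "heelX", "heelY", "toeX", "toeY"]


def _write_csv(path: Path, header: list[str], t: np.ndarray, data: np.ndarray) -> None:
    arr = np.column_stack([t, data])
    np.savetxt(path, arr, delimiter=",", header=",".join(header),
               comments="", fmt=FLOAT_FMT)


def write_trial(trial: TrialRecording, directory: str | Path) -> Path:
    """Write one trial to ``directory`` (created if needed)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, header, data, fs in (
            ("sensor.csv", _SENSOR_HEADER, trial.sensor, trial.sensor_fs),
            ("forceplate.csv", _PLATE_HEADER, trial.forceplate, trial.plate_fs),
            ("markers.csv", _MARKER_HEADER, trial.markers, trial.marker_fs)):
        t = np.arange(data.shape[0]) / fs
        _write_csv(d / name, header, t, data)
    meta = {
        "participant_id": trial.participant.participant_id,
        "body_mass_kg": trial.participant.body_mass,
        "movement": trial.movement.label,
        "heading_angle_deg": trial.movement.heading_angle,
        "seed": trial.seed,
        "step_index": trial.step_index,
        "sampling_rates_hz": {"sensor": trial.sensor_fs,
                              "forceplate": trial.plate_fs,
                              "markers": trial.marker_fs},
        "truth": {"heading_deg": trial.truth_heading_deg,
                  "stance_start_s": trial.truth_stance_start,
                  "stance_duration_s": trial.truth_stance_duration,
                  "amplitude_scale": list(trial.truth_scale)},
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    return d


def read_trial(directory: str | Path) -> TrialRecording:
    """Read a trial directory written by :func:`write_trial`."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    sensor = pd.read_csv(d / "sensor.csv")
    plate = pd.read_csv(d / "forceplate.csv")
    markers = pd.read_csv(d / "markers.csv")
    profile = ParticipantProfile(
        participant_id=meta["participant_id"],
        body_mass=meta["body_mass_kg"],
        amplitude_effect=(0.0, 0.0, 0.0),  # not serialized; not needed downstream
    )
    truth = meta.get("truth", {})
    return TrialRecording(
        sensor=sensor[list(FEATURE_COLUMNS)].to_numpy(),
        forceplate=plate[["FX", "FY", "FZ"]].to_numpy(),
        markers=markers[["heelX", "heelY", "toeX", "toeY"]].to_numpy(),
        participant=profile,
        movement=MOVEMENTS[meta["movement"]],
        seed=meta["seed"],
        step_index=meta.get("step_index", 0),
        sensor_fs=meta["sampling_rates_hz"]["sensor"],
        plate_fs=meta["sampling_rates_hz"]["forceplate"],
        marker_fs=meta["sampling_rates_hz"]["markers"],
        truth_heading_deg=truth.get("heading_deg", 0.0),
        truth_stance_start=truth.get("stance_start_s", 0.0),
        truth_stance_duration=truth.get("stance_duration_s", 0.0),
        truth_scale=tuple(truth.get("amplitude_scale", (1.0, 1.0, 1.0))),
    )


def write_trials(trials: list[TrialRecording], directory: str | Path) -> list[Path]:
    """Write a cohort as ``trial_000``, ``trial_001``, ... subdirectories."""
    root = Path(directory)
    paths = []
    for i, trial in enumerate(trials):
        paths.append(write_trial(trial, root / f"trial_{i:03d}"))
    return paths


def read_trials(directory: str | Path) -> list[TrialRecording]:
    root = Path(directory)
    return [read_trial(p) for p in sorted(root.glob("trial_*"))]


def write_aligned_steps(steps, path: str | Path) -> Path:
    """Write aligned steps to the interchange CSV (101 rows per step)."""
    frames = []
    for st in steps:
        df = pd.DataFrame(st.features, columns=list(FEATURE_COLUMNS))
        for j, col in enumerate(TARGET_COLUMNS):
            df[col] = st.targets[:, j]
        df.insert(0, "pct", np.arange(101))
        df.insert(0, "step", st.step_id)
        df.insert(0, "movement", st.movement.label)
        df.insert(0, "participant", st.participant_id)
        df["body_mass"] = st.body_mass
        df["heading_deg"] = st.heading_angle_used
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    out.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def read_aligned_steps(path: str | Path):
    """Read the aligned-steps CSV back into AlignedStep objects."""
    from .preprocessing import AlignedStep  # local import to avoid a cycle

    df = pd.read_csv(path)
    steps = []
    for (part, mov, step), grp in df.groupby(["participant", "movement", "step"],
                                             sort=True):
        grp = grp.sort_values("pct")
        steps.append(AlignedStep(
            features=grp[list(FEATURE_COLUMNS)].to_numpy(),
            targets=grp[list(TARGET_COLUMNS)].to_numpy(),
            body_mass=float(grp["body_mass"].iloc[0]),
            movement=MOVEMENTS[mov],
            participant_id=str(part),
            step_id=int(step),
            heading_angle_used=float(grp["heading_deg"].iloc[0]),
        ))
    return steps
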