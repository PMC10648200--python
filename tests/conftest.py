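"""Shared fixtures.

The expensive end-to-end results (full default run, five-seed sweep) are
session-scoped so the acceptance-level tests share one computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import solegrf as sg
import solegrf.preprocessing as pp
import solegrf.synthetic as sy
from solegrf.evaluation import loocv


@pytest.fixture(scope="session")
def default_run() -> sg.RunResult:
    """Full default experiment (3 participants × 4 steps × 3 movements, seed 1)."""
    return sg.execute(sg.RunConfig(master_seed=1))


@pytest.fixture(scope="session")
def xtrend_sweep() -> list[dict]:
    """Mediolateral %RMSE of GPR and MLR across five master seeds.

    Per seed: per-movement and pooled LOOCV, x direction, both models.
    Used for the cross-seed trend checks (model ranking and the per-movement
    vs pooled-model contrast in the mediolateral direction).
    """
    rows = []
    for seed in (1, 2, 3, 4, 5):
        cfg = sg.RunConfig(master_seed=seed)
        steps = pp.preprocess_trials(sy.generate_dataset(cfg.generator))
        rec = {"seed": seed}
        for model in ("gpr", "mlr"):
            per = []
            for mov in ("straight", "side_step", "cross_step"):
                ds = pp.assemble_dataset(
                    [s for s in steps if s.movement.label == mov])
                folds = loocv(ds, model, gpr_config=cfg.gpr)
                per.extend(f.metrics["x"].pct_rmse for f in folds)
            ds_all = pp.assemble_dataset(steps)
            folds_all = loocv(ds_all, model, gpr_config=cfg.gpr)
            rec[f"{model}_per_x"] = float(np.mean(per))
            rec[f"{model}_all_x"] = float(
                np.mean([f.metrics["x"].pct_rmse for f in folds_all]))
        rows.append(rec)
    return rows


@pytest.fixture(scope="session")
def noise_free_trials() -> list[sy.TrialRecording]:
    """A noise-free cohort (sensor noise and heading noise off)."""
    cfg = sy.GeneratorConfig(master_seed=3, sensor_noise_sd=0.0,
                             heading_noise_sd=0.0)
    return sy.generate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_wellspecified_config(seed: int = 1) -> sy.GeneratorConfig:
    """Cohort whose steps differ only by sensor noise and stance timing —
    the regime in which the GP's iid-noise assumption actually holds."""
    return dataclasses.replace(
        sy.GeneratorConfig(master_seed=seed),
        x_variability_scale=0.0, within_amplitude_sd_yz=0.0,
        between_amplitude_sd_yz=0.0, n_participants=3, steps_per_movement=3)
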