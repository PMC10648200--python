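"""Leave-one-step-out cross-validation and the three accuracy metrics.

The evaluation unit is the step: all 101 resampled samples of one stance
phase leave the training set together, the model (including stepwise
selection or GP hyperparameter fitting) is refit on the remaining steps,
and the held-out step's curves are predicted.  Per held-out step and GRF
direction three metrics are computed:

* MAE of the body-mass-normalized force, N/kg;
* %RMSE — RMSE as a percentage of the measured step's max−min range;
* adjusted R² with the (n−1)/(n−k−1) degree-of-freedom penalty (may be
  negative for poor fits).

Summaries report mean ± sample SD of each metric across folds, grouped per
movement or pooled over all movements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gpr import GPRConfig, fit_gpr, predict_gpr
from .mlr import fit_mlr, predict_mlr
from .preprocessing import AlignedStep, RegressionDataset
from .synthetic import DomainError

DIRECTIONS = ("x", "y", "z")
GPR_K_DEFAULT = 12  # predictor count charged to the GP in adjusted R²


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def mae(measured: np.ndarray, predicted: np.ndarray, body_mass: float) -> float:
    """Mean absolute error of the mass-normalized force, N/kg."""
    measured = np.asarray(measured, float).ravel()
    predicted = np.asarray(predicted, float).ravel()
    if measured.size != predicted.size:
        raise DomainError("measured and predicted lengths differ")
    if body_mass <= 0:
        raise DomainError("body mass must be positive")
    return float(np.mean(np.abs(measured - predicted)) / body_mass)


def pct_rmse(measured: np.ndarray, predicted: np.ndarray) -> float:
    """RMSE as a percentage of the measured series' max−min range."""
    measured = np.asarray(measured, float).ravel()
    predicted = np.asarray(predicted, float).ravel()
    if measured.size != predicted.size:
        raise DomainError("measured and predicted lengths differ")
    rng = float(measured.max() - measured.min())
    if rng <= 0:
        raise DomainError("measured series has zero range")
    rmse = float(np.sqrt(np.mean((measured - predicted) ** 2)))
    return 100.0 * rmse / rng


def adj_r2(measured: np.ndarray, predicted: np.ndarray, k: int) -> float:
    """Degree-of-freedom-adjusted coefficient of determination."""
    measured = np.asarray(measured, float).ravel()
    predicted = np.asarray(predicted, float).ravel()
    n = measured.size
    if n <= k + 1:
        raise DomainError(f"need n > k+1 (n={n}, k={k})")
    ss_res = float(np.sum((measured - predicted) ** 2))
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    if ss_tot <= 0:
        raise DomainError("measured series is constant; R² undefined")
    return 1.0 - (ss_res / ss_tot) * ((n - 1) / (n - k - 1))


@dataclass
class MetricsRecord:
    """The three metrics for one held-out step and direction."""

    direction: str
    mae: float
    pct_rmse: float
    adj_r2: float


@dataclass
class FoldResult:
    """Everything recorded for one LOOCV fold."""

    step_key: tuple            # (participant, movement, step)
    model_type: str            # "mlr" or "gpr"
    predicted: np.ndarray      # 101×3
    measured: np.ndarray       # 101×3
    body_mass: float
    movement: str
    k_per_direction: dict[str, int]
    ci95_low: np.ndarray | None = None   # GPR only
    ci95_high: np.ndarray | None = None
    metrics: dict[str, MetricsRecord] = field(default_factory=dict)

    def compute_metrics(self) -> None:
        for d_idx, d in enumerate(DIRECTIONS):
            self.metrics[d] = MetricsRecord(
                direction=d,
                mae=mae(self.measured[:, d_idx], self.predicted[:, d_idx],
                        self.body_mass),
                pct_rmse=pct_rmse(self.measured[:, d_idx], self.predicted[:, d_idx]),
                adj_r2=adj_r2(self.measured[:, d_idx], self.predicted[:, d_idx],
                              self.k_per_direction[d]),
            )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def loocv(dataset: RegressionDataset, model_type: str,
          gpr_config: GPRConfig | None = None,
          p_enter: float = 0.05, p_remove: float = 0.10,
          gpr_k: int = GPR_K_DEFAULT) -> list[FoldResult]:
    """Leave-one-step-out CV: one fold per step, retraining in every fold.

    For MLR the adjusted-R² predictor count k is the fold's per-direction
    stepwise selection size; for GPR all 12 channels enter the kernel, so
    k = ``gpr_k`` in every direction.
    """
    keys = dataset.step_keys
    if len(keys) < 3:
        raise DomainError("need at least 3 steps for leave-one-step-out CV")
    folds: list[FoldResult] = []
    all_rows = np.arange(dataset.n)
    for key in keys:
        test_rows = dataset.step_rows(key)
        train_rows = np.setdiff1d(all_rows, test_rows)
        train = dataset.subset(train_rows)
        test = dataset.subset(test_rows)
        mass = float(test.row_metadata["body_mass"].iloc[0])
        try:
            if model_type == "mlr":
                model = fit_mlr(train, p_enter, p_remove)
                pred = predict_mlr(model, test.f)
                kpd = {d: len(model.directions[d].selected) for d in DIRECTIONS}
                ci_lo = ci_hi = None
            elif model_type == "gpr":
                pred = np.empty((test.n, 3))
                ci_lo = np.empty((test.n, 3))
                ci_hi = np.empty((test.n, 3))
                for d_idx, d in enumerate(DIRECTIONS):
                    gm = fit_gpr(train, d, gpr_config)
                    dist = predict_gpr(gm, test.f)
                    pred[:, d_idx] = dist.mean
                    ci_lo[:, d_idx] = dist.ci95_low
                    ci_hi[:, d_idx] = dist.ci95_high
                kpd = {d: gpr_k for d in DIRECTIONS}
            else:
                raise DomainError(f"unknown model_type {model_type!r}")
        except Exception as exc:
            raise type(exc)(f"fold {key}: {exc}") from exc
        fold = FoldResult(step_key=key, model_type=model_type,
                          predicted=pred, measured=test.F, body_mass=mass,
                          movement=str(test.row_metadata["movement"].iloc[0]),
                          k_per_direction=kpd, ci95_low=ci_lo, ci95_high=ci_hi)
        fold.compute_metrics()
        folds.append(fold)
    return folds


def summarize(folds: list[FoldResult], grouping: str = "per-movement"
              ) -> pd.DataFrame:
    """Mean ± sample SD of each metric across folds, per group and direction.

    ``grouping`` is "per-movement" (one group per movement label) or "all"
    (a single pooled group).  Groups with fewer than 2 folds are omitted.
    """
    rows = []
    if grouping == "per-movement":
        group_of = lambda f: f.movement
    elif grouping == "all":
        group_of = lambda f: "all"
    else:
        raise DomainError(f"unknown grouping {grouping!r}")
    groups: dict[str, list[FoldResult]] = {}
    for f in folds:
        groups.setdefault(group_of(f), []).append(f)
    for gname in sorted(groups):
        members = groups[gname]
        if len(members) < 2:
            import warnings
            warnings.warn(f"group {gname!r} has < 2 folds; omitted")
            continue
        for d in DIRECTIONS:
            vals = {m: np.array([f.metrics[d].__dict__[m] for f in members])
                    for m in ("mae", "pct_rmse", "adj_r2")}
            rows.append({
                "gait": gname,
                "model": members[0].model_type,
                "direction": d,
                "n_folds": len(members),
                "mae_mean": vals["mae"].mean(), "mae_sd": vals["mae"].std(ddof=1),
                "pct_rmse_mean": vals["pct_rmse"].mean(),
                "pct_rmse_sd": vals["pct_rmse"].std(ddof=1),
                "adj_r2_mean": vals["adj_r2"].mean(),
                "adj_r2_sd": vals["adj_r2"].std(ddof=1),
            })
    return pd.DataFrame(rows)


def format_summary(table: pd.DataFrame) -> str:
    """Aligned-text rendering of a summary table (mean ± SD)."""
    lines = [f"{'gait':<12} {'model':<5} {'dir':<3} "
             f"{'MAE (N/kg)':<16} {'%RMSE':<15} {'adj R²':<15}"]
    for _, r in table.iterrows():
        lines.append(
            f"{r['gait']:<12} {r['model']:<5} {r['direction']:<3} "
            f"{r['mae_mean']:.3f} ± {r['mae_sd']:.3f}    "
            f"{r['pct_rmse_mean']:5.1f} ± {r['pct_rmse_sd']:4.1f}   "
            f"{r['adj_r2_mean']:6.3f} ± {r['adj_r2_sd']:5.3f}")
    return "\n".join(lines)


def interval_coverage(folds: list[FoldResult]) -> float:
    """Pooled fraction of measured samples inside the GPR 95% band."""
    hits = total = 0
    for f in folds:
        if f.ci95_low is None:
            raise DomainError("coverage requires GPR folds with intervals")
        inside = (f.measured >= f.ci95_low) & (f.measured <= f.ci95_high)
        hits += int(inside.sum())
        total += inside.size
    return hits / total


# ---------------------------------------------------------------------------
# Cohort variability
# ---------------------------------------------------------------------------

def variability_summary(steps: list[AlignedStep]) -> pd.DataFrame:
    """Between- and within-participant SD of mass-normalized GRF per movement.

    Convention (stated explicitly because the estimator has free choices):
    within-participant SD = the SD across one participant's steps at each
    stance percent, averaged over percents and then over participants;
    between-participant SD = the SD across participant-mean curves at each
    stance percent, averaged over percents.
    """
    rows = []
    by_movement: dict[str, list[AlignedStep]] = {}
    for st in steps:
        by_movement.setdefault(st.movement.label, []).append(st)
    for mov, group in sorted(by_movement.items()):
        by_part: dict[str, list[np.ndarray]] = {}
        for st in group:
            by_part.setdefault(st.participant_id, []).append(
                st.targets / st.body_mass)
        if len(by_part) < 2 or any(len(v) < 2 for v in by_part.values()):
            raise DomainError(
                f"movement {mov!r}: need >= 2 participants with >= 2 steps each")
        for d_idx, d in enumerate(DIRECTIONS):
            curves = {p: np.stack([c[:, d_idx] for c in cs])
                      for p, cs in by_part.items()}  # p -> (steps, 101)
            within = float(np.mean([c.std(axis=0, ddof=1).mean()
                                    for c in curves.values()]))
            part_means = np.stack([c.mean(axis=0) for c in curves.values()])
            between = float(part_means.std(axis=0, ddof=1).mean())
            rows.append({"movement": mov, "direction": d,
                         "between_sd": between, "within_sd": within,
                         "n_participants": len(by_part),
                         "steps_per_participant": min(len(v) for v in by_part.values())})
    return pd.DataFrame(rows)
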