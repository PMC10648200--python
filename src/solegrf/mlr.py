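"""Multiple linear regression with classical stepwise predictor selection.

Each GRF direction is modeled independently as an affine function of the 12
instantaneous sensor channels: F̂ = f·k + b.  Predictors enter and leave by
forward–backward stepwise selection on partial-F p-values (enter < 0.05,
remove > 0.10 by default); coefficients come from ordinary least squares via
a numerically stable orthogonal decomposition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .preprocessing import RegressionDataset
from .synthetic import FEATURE_COLUMNS, DomainError

DIRECTIONS = ("x", "y", "z")
P_ENTER_DEFAULT = 0.05
P_REMOVE_DEFAULT = 0.10


class RankDeficientError(np.linalg.LinAlgError):
    """Predictor matrix is exactly collinear."""


@dataclass
class DirectionModel:
    """Selected predictors, coefficients and intercept for one direction."""

    selected: list[int]           # column indices into the 12-channel layout
    coefficients: np.ndarray      # aligned with ``selected``
    intercept: float
    training_n: int

    @property
    def selected_names(self) -> list[str]:
        return [FEATURE_COLUMNS[j] for j in self.selected]


@dataclass
class MLRModel:
    """Per-direction linear models sharing one 12-column feature layout."""

    directions: dict[str, DirectionModel]
    p_enter: float = P_ENTER_DEFAULT
    p_remove: float = P_REMOVE_DEFAULT

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "p_enter": self.p_enter,
            "p_remove": self.p_remove,
            "directions": {
                d: {
                    "selected_columns": m.selected_names,
                    "selected_indices": m.selected,
                    "coefficients": list(map(float, m.coefficients)),
                    "intercept": m.intercept,
                    "training_n": m.training_n,
                } for d, m in self.directions.items()
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MLRModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        dirs = {}
        for d, m in payload["directions"].items():
            dirs[d] = DirectionModel(
                selected=list(m["selected_indices"]),
                coefficients=np.asarray(m["coefficients"], dtype=float),
                intercept=float(m["intercept"]),
                training_n=int(m["training_n"]),
            )
        return cls(directions=dirs, p_enter=payload["p_enter"],
                   p_remove=payload["p_remove"])


def fit_ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit of y on X with an intercept.

    Returns (coefficients, intercept).  Solved through the QR-based
    ``lstsq`` driver; raises :class:`RankDeficientError` naming the exactly
    collinear columns when the design is rank-deficient.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise DomainError("X and y row counts differ")
    n, p = X.shape
    if n <= p + 1:
        raise DomainError(f"need n > p+1 rows (got n={n}, p={p})")
    design = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p + 1:
        # identify offending columns via pivoted QR on the centered design
        from scipy.linalg import qr
        _, R, piv = qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = sorted(piv[j] - 1 for j in range(len(diag)) if diag[j] < tol
                     and piv[j] > 0)
        names = [FEATURE_COLUMNS[j] if j < len(FEATURE_COLUMNS) else str(j)
                 for j in bad]
        raise RankDeficientError(f"rank-deficient design; dependent columns: {names}")
    return beta[1:], float(beta[0])


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of the OLS fit with intercept."""
    n = y.size
    design = np.column_stack([np.ones(n), X]) if X.shape[1] else np.ones((n, 1))
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    r = y - design @ beta
    return float(r @ r)


def stepwise_select(y: np.ndarray, X: np.ndarray,
                    p_enter: float = P_ENTER_DEFAULT,
                    p_remove: float = P_REMOVE_DEFAULT) -> list[int]:
    """Forward–backward stepwise selection on partial-F p-values.

    Starting from the intercept-only model, repeatedly add the candidate
    with the smallest partial-F p-value if it is below ``p_enter``, then
    drop any included predictor whose p-value exceeds ``p_remove``.  Ties
    break toward the lower column index; revisiting a previous subset
    terminates the loop (cycle guard).  May return an empty list.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p + 2:
        raise DomainError("too few rows for stepwise selection")

    selected: list[int] = []
    visited = {frozenset()}
    rss_cur = _rss(y, X[:, []])
    while True:
        changed = False
        # forward step
        candidates = [j for j in range(p) if j not in selected]
        best_j, best_p, best_rss = None, np.inf, None
        dof = n - len(selected) - 2
        for j in candidates:
            rss_j = _rss(y, X[:, selected + [j]])
            if rss_j <= 0:
                pval, rss_j = 0.0, max(rss_j, 0.0)
            else:
                F = (rss_cur - rss_j) / (rss_j / dof)
                pval = float(stats.f.sf(max(F, 0.0), 1, dof))
            if pval < best_p - 1e-15:  # strict improvement; ties keep lower index
                best_j, best_p, best_rss = j, pval, rss_j
        if best_j is not None and best_p < p_enter:
            trial = frozenset(selected + [best_j])
            if trial not in visited:
                selected.append(best_j)
                selected.sort()
                visited.add(trial)
                rss_cur = _rss(y, X[:, selected])
                changed = True
        # backward step
        while True:
            worst_k, worst_p = None, -np.inf
            dof = n - len(selected) - 1
            for k in selected:
                rest = [j for j in selected if j != k]
                rss_minus = _rss(y, X[:, rest])
                F = (rss_minus - rss_cur) / (rss_cur / dof) if rss_cur > 0 else np.inf
                pval = float(stats.f.sf(max(F, 0.0), 1, dof)) if np.isfinite(F) else 0.0
                if pval > worst_p + 1e-15:
                    worst_k, worst_p = k, pval
            if worst_k is not None and worst_p > p_remove:
                trial = frozenset(j for j in selected if j != worst_k)
                if trial in visited:
                    break
                selected.remove(worst_k)
                visited.add(trial)
                rss_cur = _rss(y, X[:, selected])
                changed = True
            else:
                break
        if not changed:
            return selected


def fit_mlr(dataset: RegressionDataset,
            p_enter: float = P_ENTER_DEFAULT,
            p_remove: float = P_REMOVE_DEFAULT) -> MLRModel:
    """Fit one stepwise-selected linear model per GRF direction."""
    directions = {}
    for d_idx, d in enumerate(DIRECTIONS):
        y = dataset.F[:, d_idx]
        selected = stepwise_select(y, dataset.f, p_enter, p_remove)
        if selected:
            coef, intercept = fit_ols(y, dataset.f[:, selected])
        else:
            coef, intercept = np.zeros(0), float(y.mean())
        directions[d] = DirectionModel(selected=selected, coefficients=coef,
                                       intercept=intercept, training_n=dataset.n)
    return MLRModel(directions=directions, p_enter=p_enter, p_remove=p_remove)


def predict_mlr(model: MLRModel, f_test: np.ndarray) -> np.ndarray:
    """Predict the (m, 3) GRF matrix for an (m, 12) feature matrix."""
    f_test = np.atleast_2d(np.asarray(f_test, dtype=float))
    if f_test.shape[1] != 12:
        raise DomainError("f_test must have 12 columns in the training layout")
    out = np.empty((f_test.shape[0], 3))
    for d_idx, d in enumerate(DIRECTIONS):
        m = model.directions[d]
        out[:, d_idx] = f_test[:, m.selected] @ m.coefficients + m.intercept
    return out
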