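"""Time-dependent prediction-error measures for survival models.

The workhorse is the inverse-probability-of-censoring-weighted (IPCW) Brier
score (Graf estimator): at evaluation time t, a subject who had the event by
t contributes ``S_hat(t|x)^2 / G_hat(t_i-)``, a subject still at risk
contributes ``(1 - S_hat(t|x))^2 / G_hat(t)``, and a subject censored before
t contributes nothing.  ``G_hat`` is the Kaplan-Meier estimate of the
censoring distribution (event indicator flipped), estimated on training data.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import StepFunction, SurvivalDataset, TimeGrid, km_estimate

__all__ = ["LossCurve", "censoring_distribution", "brier_curve",
           "integrated_brier"]


@dataclass(frozen=True)
class LossCurve:
    """A loss evaluated on a time grid, with optional per-subject detail."""

    grid: TimeGrid
    values: np.ndarray
    per_observation: np.ndarray | None = None
    loss_name: str = "brier"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.grid),):
            raise ValueError("one loss value per grid time required")
        if self.per_observation is not None:
            po = np.asarray(self.per_observation, dtype=float)
            object.__setattr__(self, "per_observation", po)
            if po.shape[1] != len(self.grid):
                raise ValueError("per_observation columns must match the grid")
            if not np.allclose(po.mean(axis=0), values, atol=1e-10):
                raise ValueError("values must be column means of per_observation")

    def integrated(self, lower: float | None = None,
                   upper: float | None = None) -> float:
        return integrated_brier(self, lower, upper)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time": np.asarray(self.grid), "value": self.values}).to_csv(
            path, index=False
        )
        summary = {"loss": self.loss_name, "integrated": self.integrated(),
                   "range": [float(self.grid[0]), float(self.grid[-1])]}
        Path(path).with_suffix(".json").write_text(json.dumps(summary))


def censoring_distribution(train: SurvivalDataset) -> StepFunction:
    """Kaplan-Meier estimate of the censoring survival G(t) (flipped events)."""
    flipped = SurvivalDataset(train.features, train.times, 1 - train.events)
    return km_estimate(flipped)


def brier_curve(test: SurvivalDataset, predictions: np.ndarray, grid: TimeGrid,
                censoring_km: StepFunction) -> LossCurve:
    """IPCW (Graf) Brier score curve.

    Parameters
    ----------
    test : SurvivalDataset
        Evaluation data; rows aligned with ``predictions``.
    predictions : ndarray, shape (n, len(grid))
        Predicted survival probabilities.
    censoring_km : StepFunction
        Censoring survival G estimated on training data
        (see :func:`censoring_distribution`).
    """
    predictions = np.asarray(predictions, dtype=float)
    grid_arr = np.asarray(grid, dtype=float)
    if predictions.shape != (test.n, grid_arr.size):
        raise ValueError("predictions must be n x len(grid), row-aligned with test")
    t_i = test.times[:, None]
    delta = test.events[:, None].astype(bool)
    S = predictions

    # G just before each subject's own time (left limit), and G at grid times
    G_at_ti_minus = censoring_km(np.nextafter(test.times, 0.0))[:, None]
    G_at_t = censoring_km(grid_arr)[None, :]

    had_event = (t_i <= grid_arr[None, :]) & delta
    at_risk = t_i > grid_arr[None, :]

    for name, G, mask in (("G(t_i-)", G_at_ti_minus, had_event),
                          ("G(t)", G_at_t, at_risk)):
        bad = mask & (np.broadcast_to(G, mask.shape) <= 0)
        if bad.any():
            o, k = np.argwhere(bad)[0]
            raise ValueError(
                f"censoring survival {name} is zero where a weight is needed "
                f"(subject {o}, evaluation time {grid_arr[k]:g})"
            )

    contrib = np.zeros_like(S)
    contrib = np.where(had_event, S**2 / np.where(G_at_ti_minus > 0, G_at_ti_minus, 1.0),
                       contrib)
    contrib = np.where(at_risk, (1.0 - S) ** 2 / np.where(G_at_t > 0, G_at_t, 1.0),
                       contrib)
    return LossCurve(grid, contrib.mean(axis=0), per_observation=contrib)


def integrated_brier(loss: LossCurve, lower: float | None = None,
                     upper: float | None = None) -> float:
    """Time-normalized trapezoidal integral of a loss curve.

    Defaults to the full span of the evaluation grid; the result is divided
    by the interval length, so a constant curve integrates to its own value.
    """
    t = np.asarray(loss.grid, dtype=float)
    lower = float(t[0]) if lower is None else float(lower)
    upper = float(t[-1]) if upper is None else float(upper)
    if not (t[0] <= lower < upper <= t[-1]):
        raise ValueError("integration interval must be non-degenerate and "
                         "inside the grid span")
    fine = np.union1d(t[(t >= lower) & (t <= upper)], [lower, upper])
    vals = np.interp(fine, t, loss.values)
    return float(np.trapezoid(vals, fine) / (upper - lower))
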