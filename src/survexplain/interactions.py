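"""Friedman's H-statistics for survival models.

The two-way statistic asks how much of the variance of the joint partial
dependence of two features is not explained by the sum of their individual
partial dependences; the total statistic compares the full prediction with
the sum of a feature's partial dependence and that of all remaining
features.  Both are computed per timepoint on the survival scale and
averaged over time for a scalar summary.

All partial-dependence functions are evaluated at the observed feature
values of a (seeded) subsample of m observations, with the double sums over
that same subsample, and are mean-centered per timepoint before entering
numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SurvivalDataset, SurvivalModel, TimeGrid

__all__ = ["HStatisticResult", "h_two_way", "h_total"]

DEFAULT_SAMPLE_SIZE = 300


@dataclass(frozen=True)
class HStatisticResult:
    """Interaction strength over time for one feature pair (or one feature
    against all others).  Timepoints where the statistic is 0/0 are NaN and
    excluded from the time marginal."""

    identifier: tuple[str, str]
    time_grid: TimeGrid
    h_squared: np.ndarray
    sample_size: int
    seed: int

    @property
    def time_marginal(self) -> float:
        vals = self.h_squared[~np.isnan(self.h_squared)]
        return float(vals.mean()) if vals.size else float("nan")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"pair": ["/".join(self.identifier)] * len(self.time_grid),
                      "time": np.asarray(self.time_grid),
                      "h_squared": self.h_squared}).to_csv(path, index=False)
        Path(path).with_suffix(".json").write_text(json.dumps({
            "identifier": list(self.identifier),
            "time_marginal": self.time_marginal,
            "sample_size": self.sample_size, "seed": self.seed}))


def _subsample(data: SurvivalDataset, sample_size: int | None,
               seed: int) -> pd.DataFrame:
    m = min(data.n, DEFAULT_SAMPLE_SIZE if sample_size is None else sample_size)
    if m < data.n:
        rng = np.random.default_rng(seed)
        idx = rng.choice(data.n, size=m, replace=False)
    else:
        idx = np.arange(data.n)
    return data.features.iloc[idx].reset_index(drop=True)


def _pd_at_observed(model: SurvivalModel, base: pd.DataFrame,
                    fixed: list[str], time_grid: TimeGrid) -> np.ndarray:
    """PD of the ``fixed`` feature set evaluated at each row's own values.

    PD_S(x_S_i; t) = (1/m) sum_j f(x_S_i, x_{-S}_j; t), estimated over the
    same m rows that index i runs over.  Returns (m, T).
    """
    m = len(base)
    big = base.iloc[np.tile(np.arange(m), m)].reset_index(drop=True)
    for col in fixed:
        big[col] = np.repeat(base[col].to_numpy(), m)
    preds = model.predict_survival(big, time_grid)
    return preds.reshape(m, m, len(time_grid)).mean(axis=1)


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _ratio(num_parts: np.ndarray, denom_parts: np.ndarray) -> np.ndarray:
    num = (num_parts**2).sum(axis=0)
    denom = (denom_parts**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(denom > 0, num / denom, np.nan)
    return h2


def h_two_way(model: SurvivalModel, data: SurvivalDataset, feature_a: str,
              feature_b: str, time_grid: TimeGrid | None = None,
              sample_size: int | None = None, seed: int = 0) -> HStatisticResult:
    """Two-way interaction strength between two features, per timepoint.

    Zero when the joint partial dependence decomposes additively; near one
    when only the interaction moves the prediction.  Values can exceed one
    in rare cases where the interaction variance exceeds the joint-PD
    variance.
    """
    if feature_a == feature_b:
        raise ValueError("two-way H needs two distinct features")
    for f in (feature_a, feature_b):
        if f not in data.feature_names:
            raise ValueError(f"unknown feature {f!r}")
    if time_grid is None:
        time_grid = TimeGrid.from_dataset(data)
    base = _subsample(data, sample_size, seed)
    pd_ab = _center(_pd_at_observed(model, base, [feature_a, feature_b], time_grid))
    pd_a = _center(_pd_at_observed(model, base, [feature_a], time_grid))
    pd_b = _center(_pd_at_observed(model, base, [feature_b], time_grid))
    h2 = _ratio(pd_ab - pd_a - pd_b, pd_ab)
    return HStatisticResult((feature_a, feature_b), time_grid, h2, len(base), seed)


def h_total(model: SurvivalModel, data: SurvivalDataset, feature_a: str,
            time_grid: TimeGrid | None = None,
            sample_size: int | None = None, seed: int = 0) -> HStatisticResult:
    """Total interaction strength of one feature against all others.

    Compares the model's own predictions at the sampled rows against the sum
    of the feature's partial dependence and the complement's partial
    dependence; zero when the prediction is additively separable in the
    feature.
    """
    if feature_a not in data.feature_names:
        raise ValueError(f"unknown feature {feature_a!r}")
    if len(data.feature_names) < 2:
        raise ValueError("total interaction needs at least two features")
    if time_grid is None:
        time_grid = TimeGrid.from_dataset(data)
    base = _subsample(data, sample_size, seed)
    rest = [c for c in base.columns if c != feature_a]
    full = _center(model.predict_survival(base, time_grid))
    pd_a = _center(_pd_at_observed(model, base, [feature_a], time_grid))
    pd_rest = _center(_pd_at_observed(model, base, rest, time_grid))
    h2 = _ratio(full - pd_a - pd_rest, full)
    return HStatisticResult((feature_a, "rest"), time_grid, h2, len(base), seed)
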