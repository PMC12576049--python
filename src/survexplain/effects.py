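"""Time-dependent feature-effect curves: ICE, PDP, M-plots and ALE.

All estimators share one geometry: a feature grid (values of the feature of
interest), a time grid, and survival-probability values indexed by
(observation x) grid value x time.  Individual conditional expectation (ICE)
curves keep the per-observation dimension; partial dependence (PDP) averages
it out; M-plots average only over observations whose true feature value lies
near the grid value; accumulated local effects (ALE) accumulate interval-wise
averaged finite differences and are unbiased under correlated features where
the PDP is not.

Centering subtracts each observation's prediction at a reference feature
value, removing level effects; time-marginalized ("-T") variants average the
curves over the time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .data import SurvivalDataset, SurvivalModel, TimeGrid

__all__ = ["FeatureGridSpec", "EffectCurves", "ice", "center_curves",
           "aggregate_pdp", "pdp", "marginalize_time", "mplot", "ale",
           "order_categorical_levels"]


@dataclass(frozen=True)
class FeatureGridSpec:
    """How to pick the grid of feature values.

    ``quantile`` (default, g=25) approximately preserves the feature's
    marginal distribution; ``equidistant`` spans the observed range evenly;
    ``levels`` enumerates observed values and is mandatory for binary and
    categorical features.
    """

    strategy: str = "quantile"
    g: int = 25

    def __post_init__(self) -> None:
        if self.strategy not in ("quantile", "equidistant", "levels"):
            raise ValueError("strategy must be quantile, equidistant or levels")
        if self.strategy != "levels" and self.g < 2:
            raise ValueError("numeric grids need at least 2 points")

    def build(self, data: SurvivalDataset, feature: str) -> np.ndarray:
        col = data.features[feature]
        kind = data.column_kind(feature)
        if kind in ("binary", "categorical") or self.strategy == "levels":
            levels = col.unique()
            try:
                return np.sort(levels)
            except TypeError:
                return np.asarray(levels)
        x = col.to_numpy(dtype=float)
        if self.strategy == "quantile":
            return np.unique(np.quantile(x, np.linspace(0, 1, self.g)))
        return np.linspace(x.min(), x.max(), self.g)


def default_grid_spec(data: SurvivalDataset, feature: str) -> FeatureGridSpec:
    if data.column_kind(feature) != "numeric":
        return FeatureGridSpec("levels")
    return FeatureGridSpec("quantile", 25)


@dataclass(frozen=True)
class EffectCurves:
    """Feature-effect values on a (grid value, time) lattice.

    ``values`` has shape (n_obs, n_grid, n_times) for per-observation
    estimators (ICE) and (n_grid, n_times) for aggregated ones (PDP, M-plot,
    ALE).  If ``time_marginalized``, the trailing time axis is dropped.
    """

    feature: str
    grid_values: np.ndarray
    time_grid: TimeGrid
    values: np.ndarray
    estimator: str
    centered_at: object | None = None
    time_marginalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_values", np.asarray(self.grid_values))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        g = len(self.grid_values)
        expect_tail = (g,) if self.time_marginalized else (g, len(self.time_grid))
        if self.values.shape[-len(expect_tail):] != expect_tail:
            raise ValueError(f"values shape {self.values.shape} inconsistent "
                             f"with grid/time dimensions {expect_tail}")

    @property
    def per_observation(self) -> bool:
        return self.values.ndim == (2 if self.time_marginalized else 3)

    def _grid_index(self, value) -> int:
        matches = np.flatnonzero(self.grid_values == value)
        if matches.size == 0:
            raise ValueError(
                f"value {value!r} is not on the feature grid; include it in "
                "the grid when computing the curves"
            )
        return int(matches[0])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (observation?, grid_value, time?, value)."""
        vals = self.values
        cols: dict[str, np.ndarray] = {}
        if self.time_marginalized:
            if self.per_observation:
                n, g = vals.shape
                cols["observation"] = np.repeat(np.arange(n), g)
                cols["grid_value"] = np.tile(self.grid_values, n)
            else:
                cols["grid_value"] = self.grid_values
        else:
            t = np.asarray(self.time_grid)
            if self.per_observation:
                n, g, T = vals.shape
                cols["observation"] = np.repeat(np.arange(n), g * T)
                cols["grid_value"] = np.tile(np.repeat(self.grid_values, T), n)
                cols["time"] = np.tile(t, n * g)
            else:
                g, T = vals.shape
                cols["grid_value"] = np.repeat(self.grid_values, T)
                cols["time"] = np.tile(t, g)
        cols["value"] = vals.ravel()
        return pd.DataFrame(cols)

    def plot(self, ax=None):
        """Minimal line plot: one line per grid value over time (or the
        marginalized curve against the feature grid).  Returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vals = self.values.mean(axis=0) if self.per_observation else self.values
        if self.time_marginalized:
            ax.plot(self.grid_values, vals, marker="o")
            ax.set_xlabel(self.feature)
        else:
            for k, v in enumerate(self.grid_values):
                ax.plot(np.asarray(self.time_grid), vals[k], label=str(v))
            ax.set_xlabel("time")
            if len(self.grid_values) <= 6:
                ax.legend(title=self.feature)
        ax.set_ylabel(f"{self.estimator} value")
        return ax

    def to_csv(self, path: str | Path, **meta) -> None:
        self.to_frame().to_csv(path, index=False)
        info = {"feature": self.feature, "estimator": self.estimator,
                "centered_at": None if self.centered_at is None else self.centered_at,
                "time_marginalized": self.time_marginalized, **meta}
        Path(path).with_suffix(".json").write_text(json.dumps(info, default=str))


# ---------------------------------------------------------------------------
# ICE / PDP
# ---------------------------------------------------------------------------


def _predict_on_grid(model: SurvivalModel, data: SurvivalDataset, feature: str,
                     grid_values: np.ndarray, time_grid: TimeGrid) -> np.ndarray:
    """Predictions with the feature forced to each grid value.

    Returns shape (n_obs, n_grid, n_times).  All (grid value, observation)
    combinations are sent to the model in one call so adapters can batch.
    """
    n, g = data.n, len(grid_values)
    frames = []
    for v in grid_values:
        Xv = data.features.copy()
        Xv[feature] = v
        frames.append(Xv)
    stacked = pd.concat(frames, ignore_index=True)
    preds = model.predict_survival(stacked, time_grid)
    return preds.reshape(g, n, len(time_grid)).transpose(1, 0, 2)


def ice(model: SurvivalModel, data: SurvivalDataset, feature: str,
        grid_spec: FeatureGridSpec | None = None,
        time_grid: TimeGrid | None = None,
        center_at=None) -> EffectCurves:
    """Individual conditional expectation curves.

    For every observation i, grid value k and time t, the model's predicted
    survival probability with the feature of interest set to the grid value
    and all remaining features at their observed values.  ``center_at``
    optionally adds the reference value to the grid and centers the curves.
    """
    if feature not in data.feature_names:
        raise ValueError(f"unknown feature {feature!r}")
    if grid_spec is None:
        grid_spec = default_grid_spec(data, feature)
    if time_grid is None:
        time_grid = TimeGrid.from_dataset(data)
    grid_values = grid_spec.build(data, feature)
    if center_at is not None and center_at not in grid_values:
        grid_values = np.sort(np.append(grid_values, center_at))
    if len(grid_values) == 0:
        raise ValueError("empty feature grid")
    values = _predict_on_grid(model, data, feature, grid_values, time_grid)
    curves = EffectCurves(feature, grid_values, time_grid, values, "ice")
    if center_at is not None:
        curves = center_curves(curves, center_at)
    return curves


def center_curves(curves: EffectCurves, reference_value) -> EffectCurves:
    """Subtract the prediction at the reference grid value per observation
    and time, so centered curves are exactly zero at the reference."""
    k = curves._grid_index(reference_value)
    vals = curves.values
    axis = 1 if curves.per_observation else 0
    ref = np.take(vals, k, axis=axis)
    centered = vals - np.expand_dims(ref, axis=axis)
    return replace(curves, values=centered, centered_at=reference_value)


def aggregate_pdp(ice_curves: EffectCurves) -> EffectCurves:
    """Partial dependence: the mean of the ICE curves over observations."""
    if not ice_curves.per_observation:
        raise ValueError("aggregate_pdp needs per-observation (ICE) curves")
    return replace(ice_curves, values=ice_curves.values.mean(axis=0),
                   estimator="pdp")


def pdp(model: SurvivalModel, data: SurvivalDataset, feature: str,
        grid_spec: FeatureGridSpec | None = None,
        time_grid: TimeGrid | None = None,
        center_at=None) -> EffectCurves:
    """Partial dependence curves; identical to averaging :func:`ice`."""
    return aggregate_pdp(ice(model, data, feature, grid_spec, time_grid,
                             center_at=center_at))


def marginalize_time(curves: EffectCurves,
                     weights: np.ndarray | None = None) -> EffectCurves:
    """Average the curves over the time grid ("-T" variants).

    ``weights`` (optional) are normalized internally; the default is the
    unweighted mean over the grid times.
    """
    if curves.time_marginalized:
        raise ValueError("curves are already time-marginalized")
    if weights is None:
        vals = curves.values.mean(axis=-1)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(curves.time_grid),):
            raise ValueError("weights must match the time grid length")
        vals = curves.values @ (w / w.sum())
    return replace(curves, values=vals, time_marginalized=True)


# ---------------------------------------------------------------------------
# M-plots
# ---------------------------------------------------------------------------


def mplot(model: SurvivalModel, data: SurvivalDataset, feature: str,
          grid_spec: FeatureGridSpec | None = None,
          time_grid: TimeGrid | None = None,
          neighborhood: float | None = None) -> EffectCurves:
    """Marginal plot: conditional-density analogue of the PDP.

    At each grid value the average runs only over observations whose observed
    feature value lies in a neighborhood of the grid value.  ``neighborhood``
    is a half-width; if omitted, the window holds the ceil(n/g) nearest
    observations by feature value (ties broken by row order).  Grid values
    with an empty neighborhood get NaN, never a fabricated value.
    """
    if data.column_kind(feature) != "numeric":
        raise ValueError("M-plots require a numeric feature")
    if grid_spec is None:
        grid_spec = default_grid_spec(data, feature)
    if time_grid is None:
        time_grid = TimeGrid.from_dataset(data)
    grid_values = grid_spec.build(data, feature).astype(float)
    x = data.features[feature].to_numpy(dtype=float)
    g = len(grid_values)
    k_nearest = int(np.ceil(data.n / g))

    out = np.full((g, len(time_grid)), np.nan)
    for j, v in enumerate(grid_values):
        dist = np.abs(x - v)
        if neighborhood is not None:
            idx = np.flatnonzero(dist <= neighborhood)
        else:
            idx = np.argsort(dist, kind="stable")[:k_nearest]
        if idx.size == 0:
            continue
        Xv = data.features.iloc[idx].copy()
        Xv[feature] = v
        out[j] = model.predict_survival(Xv, time_grid).mean(axis=0)
    return EffectCurves(feature, grid_values, time_grid, out, "mplot")


# ---------------------------------------------------------------------------
# ALE
# ---------------------------------------------------------------------------


def _ale_partition(x: np.ndarray, n_intervals: int):
    """Quantile interval bounds q_0 < ... < q_g with q_0 just below min(x).

    Duplicate quantile edges are collapsed (empty intervals thereby merge
    rightward) and the effective number of intervals may shrink.
    """
    qs = np.quantile(x, np.linspace(0, 1, n_intervals + 1))
    edges = np.unique(qs)
    if edges.size < 2:
        raise ValueError("feature is constant; ALE is undefined")
    edges[0] = np.nextafter(edges[0], -np.inf)
    # interval index per observation: x in (q_{k-1}, q_k] -> k-1 (0-based)
    idx = np.clip(np.searchsorted(edges, x, side="left") - 1, 0, edges.size - 2)
    return edges, idx


def ale(model: SurvivalModel, data: SurvivalDataset, feature: str,
        n_intervals: int = 25, time_grid: TimeGrid | None = None,
        centered: bool = True) -> EffectCurves:
    """First-order accumulated local effects over time.

    The feature range is partitioned into quantile intervals; within each
    interval the finite differences of predictions at the interval's upper
    and lower bound (other features at observed values) are averaged, and
    the per-interval effects accumulated across the range.  If ``centered``,
    the observation-weighted mean of the accumulated curve is subtracted, so
    the effect has mean zero over the data.
    """
    if data.column_kind(feature) == "categorical":
        raise ValueError("order the levels first and encode them as ordinals; "
                         "see order_categorical_levels")
    if n_intervals < 1:
        raise ValueError("need at least one interval")
    if time_grid is None:
        time_grid = TimeGrid.from_dataset(data)
    x = data.features[feature].to_numpy(dtype=float)
    edges, interval_of = _ale_partition(x, n_intervals)
    g = edges.size - 1

    # predictions at the lower and upper bound of each observation's interval
    lo = data.features.copy()
    lo[feature] = edges[interval_of]
    hi = data.features.copy()
    hi[feature] = edges[interval_of + 1]
    stacked = pd.concat([lo, hi], ignore_index=True)
    preds = model.predict_survival(stacked, time_grid)
    diffs = preds[data.n:] - preds[: data.n]          # (n, T)

    T = len(time_grid)
    counts = np.bincount(interval_of, minlength=g).astype(float)
    sums = np.zeros((g, T))
    np.add.at(sums, interval_of, diffs)
    with np.errstate(invalid="ignore"):
        local = np.where(counts[:, None] > 0, sums / counts[:, None], 0.0)
    accumulated = np.vstack([np.zeros((1, T)), np.cumsum(local, axis=0)])  # at q_0..q_g

    if centered:
        weighted_mean = (counts @ accumulated[1:]) / data.n
        accumulated = accumulated - weighted_mean
    return EffectCurves(feature, edges, time_grid, accumulated, "ale",
                        centered_at="mean" if centered else None)


# ---------------------------------------------------------------------------
# Categorical level ordering for ALE
# ---------------------------------------------------------------------------


def _tv_distance(a: pd.Series, b: pd.Series) -> float:
    pa = a.value_counts(normalize=True)
    pb = b.value_counts(normalize=True)
    keys = pa.index.union(pb.index)
    return 0.5 * float(np.abs(pa.reindex(keys, fill_value=0.0)
                              - pb.reindex(keys, fill_value=0.0)).sum())


def order_categorical_levels(data: SurvivalDataset, feature: str) -> list:
    """Give an unordered categorical feature an order for ALE accumulation.

    Levels are compared through the distributions of the *other* features
    within each level: two-sample Kolmogorov-Smirnov distance for numeric
    columns, total-variation distance of relative frequency tables for
    categorical ones, summed across columns.  The summed distance matrix is
    embedded in one dimension by classical multidimensional scaling and the
    levels are returned sorted along the embedding.  Orientation is
    canonical: the level appearing first in the data maps to the
    non-positive side, so the result is deterministic up to that convention.
    """
    col = data.features[feature]
    levels = list(pd.unique(col))
    m = len(levels)
    if m == 1:
        return levels
    others = [c for c in data.feature_names if c != feature]
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            mask_i, mask_j = col == levels[i], col == levels[j]
            d = 0.0
            for c in others:
                if data.column_kind(c) == "numeric":
                    d += ks_2samp(data.features.loc[mask_i, c],
                                  data.features.loc[mask_j, c]).statistic
                else:
                    d += _tv_distance(data.features.loc[mask_i, c],
                                      data.features.loc[mask_j, c])
            D[i, j] = D[j, i] = d
    # classical MDS to one dimension
    J = np.eye(m) - np.full((m, m), 1.0 / m)
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    coord = V[:, -1] * np.sqrt(max(w[-1], 0.0))
    if coord[0] > 0:
        coord = -coord
    order = np.argsort(coord, kind="stable")
    return [levels[i] for i in order]
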