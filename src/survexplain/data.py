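"""Core survival data structures and nonparametric estimators.

Right-censored survival data are triplets ``(x_i, t_i, delta_i)``: a feature
vector, an observed time (event or censoring, whichever came first) and an
event indicator (1 = event observed, 0 = censored).  Survival curves and
cumulative hazard functions (CHFs) are represented as right-continuous step
functions over time, related through ``S(t) = exp(-Lambda(t))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable
import json

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "TimeGrid",
    "StepFunction",
    "SurvivalModel",
    "km_estimate",
    "nelson_aalen",
    "convert",
    "SURVIVAL_FLOOR",
]

#: floor applied to survival probabilities before taking logs, so that
#: ``-log(S)`` stays finite when a curve reaches zero
SURVIVAL_FLOOR = 1e-12

RESERVED_COLUMNS = ("time", "event")


def _infer_kind(col: pd.Series) -> str:
    if col.nunique(dropna=False) <= 2:
        return "binary"
    if not pd.api.types.is_numeric_dtype(col):
        return "categorical"
    return "numeric"


@dataclass(frozen=True)
class SurvivalDataset:
    """Features plus observed times and event indicators.

    Parameters
    ----------
    features : pandas.DataFrame
        n rows by p named columns; numeric, binary or categorical.
    times : ndarray
        Positive observed times, one per row.
    events : ndarray
        Event indicators, 1 = event observed, 0 = censored.
    """

    features: pd.DataFrame
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        feats = self.features.reset_index(drop=True)
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=int)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        n = len(feats)
        if n < 2:
            raise ValueError("a survival dataset needs at least two subjects")
        if times.shape != (n,) or events.shape != (n,):
            raise ValueError("times/events must align with the feature rows")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("all observed times must be positive and finite")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("event indicators must be 0 (censored) or 1 (event)")
        if feats.isna().any().any():
            raise ValueError("missing feature values are not supported")
        if feats.columns.duplicated().any():
            raise ValueError("feature column names must be unique")
        if any(c in RESERVED_COLUMNS for c in feats.columns):
            raise ValueError(f"column names {RESERVED_COLUMNS} are reserved")

    # -- basic introspection -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def column_kind(self, name: str) -> str:
        """'numeric', 'binary' or 'categorical', inferred from the column."""
        return _infer_kind(self.features[name])

    def event_times(self) -> np.ndarray:
        """Ordered unique observed event times (``delta_i = 1`` only)."""
        return np.unique(self.times[self.events == 1])

    def subset(self, idx: Sequence[int] | np.ndarray) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(
            self.features.iloc[idx], self.times[idx], self.events[idx]
        )

    def drop_feature(self, name: str) -> "SurvivalDataset":
        return SurvivalDataset(
            self.features.drop(columns=[name]), self.times, self.events
        )

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        out = self.features.copy()
        out["time"] = self.times
        out["event"] = self.events
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurvivalDataset":
        if not {"time", "event"}.issubset(frame.columns):
            raise ValueError("expected reserved columns 'time' and 'event'")
        feats = frame.drop(columns=["time", "event"])
        return cls(feats, frame["time"].to_numpy(), frame["event"].to_numpy())

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurvivalDataset":
        return cls.from_frame(pd.read_csv(path))

    def to_structured(self) -> np.ndarray:
        """Structured array (event, time) as used by scikit-survival."""
        y = np.empty(self.n, dtype=[("event", "?"), ("time", "f8")])
        y["event"] = self.events.astype(bool)
        y["time"] = self.times
        return y


class TimeGrid(np.ndarray):
    """Strictly increasing positive evaluation times.

    Subclasses ndarray so it can be used directly in arithmetic; construction
    validates sortedness, uniqueness and positivity.
    """

    def __new__(cls, times: Iterable[float]) -> "TimeGrid":
        arr = np.asarray(list(times) if not isinstance(times, np.ndarray) else times,
                         dtype=float).view(cls)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("a time grid must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(arr)) or arr[0] <= 0:
            raise ValueError("grid times must be positive and finite")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("grid times must be strictly increasing")
        return arr

    @classmethod
    def from_dataset(cls, dataset: SurvivalDataset, max_points: int | None = 50,
                     events_only: bool = True) -> "TimeGrid":
        """Default grid: ordered unique observed (event) times, optionally
        thinned to at most ``max_points`` quantile-spaced values."""
        times = dataset.event_times() if events_only else np.unique(dataset.times)
        if times.size == 0:
            times = np.unique(dataset.times)
        if max_points is not None and times.size > max_points:
            times = np.unique(np.quantile(times, np.linspace(0, 1, max_points)))
        return cls(times)


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous piecewise-constant curve over time.

    ``kind='survival'`` curves start at 1 and are non-increasing in [0, 1];
    ``kind='chf'`` curves start at 0 and are non-decreasing.  Evaluation at
    ``t`` returns the value at the largest knot <= t, or the initial value
    before the first knot.
    """

    knots: TimeGrid
    values: np.ndarray
    kind: str = "survival"
    initial_value: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        knots = self.knots if isinstance(self.knots, TimeGrid) else TimeGrid(self.knots)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", values)
        if self.kind not in ("survival", "chf"):
            raise ValueError("kind must be 'survival' or 'chf'")
        if values.shape != (len(knots),):
            raise ValueError("one value per knot required")
        init = self.initial_value
        if init is None:
            init = 1.0 if self.kind == "survival" else 0.0
        object.__setattr__(self, "initial_value", float(init))
        tol = 1e-10
        if self.kind == "survival":
            if np.any(values < -tol) or np.any(values > 1 + tol):
                raise ValueError("survival values must lie in [0, 1]")
            if np.any(np.diff(values) > tol):
                raise ValueError("survival curves must be non-increasing")
        else:
            if np.any(values < -tol):
                raise ValueError("cumulative hazards must be non-negative")
            if np.any(np.diff(values) < -tol):
                raise ValueError("cumulative hazards must be non-decreasing")

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(np.asarray(self.knots), t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.initial_value)
        return float(out) if out.ndim == 0 else out

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV (time, value) plus a JSON sidecar with metadata."""
        pd.DataFrame({"time": np.asarray(self.knots), "value": self.values}).to_csv(
            path, index=False
        )
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps({"kind": self.kind, "initial_value": self.initial_value})
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "StepFunction":
        frame = pd.read_csv(path)
        meta = json.loads(Path(path).with_suffix(".json").read_text())
        return cls(TimeGrid(frame["time"].to_numpy()), frame["value"].to_numpy(),
                   kind=meta["kind"], initial_value=meta["initial_value"])


@runtime_checkable
class SurvivalModel(Protocol):
    """Adapter contract for any fitted survival learner.

    ``predict_survival`` maps feature rows and a time grid to an
    ``n x len(grid)`` matrix of survival probabilities; each row must lie in
    [0, 1] and be non-increasing along the grid.
    """

    def predict_survival(self, X: pd.DataFrame, grid: TimeGrid) -> np.ndarray: ...


def predict_chf(model: SurvivalModel, X: pd.DataFrame, grid: TimeGrid) -> np.ndarray:
    """Cumulative hazards from a model, via the adapter's own ``predict_chf``
    when present, else ``-log`` of floored survival probabilities."""
    fn = getattr(model, "predict_chf", None)
    if fn is not None:
        return np.asarray(fn(X, grid), dtype=float)
    S = model.predict_survival(X, grid)
    return -np.log(np.clip(S, SURVIVAL_FLOOR, None))


# ---------------------------------------------------------------------------
# Nonparametric estimators
# ---------------------------------------------------------------------------


def _risk_table(times: np.ndarray, events: np.ndarray):
    """Unique event times with event counts d_o and numbers at risk n_o.

    Ties between events and censorings at the same time are resolved with
    events first: a subject censored at t is still at risk for an event at t.
    """
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return event_times, np.array([]), np.array([])
    d = np.array([np.sum((t == u) & (e == 1)) for u in event_times])
    n_at_risk = np.array([np.sum(t >= u) for u in event_times])
    return event_times, d, n_at_risk


def km_estimate(dataset: SurvivalDataset) -> StepFunction:
    """Kaplan-Meier product-limit estimate of the survival function.

    Knots sit at the unique observed event times; ties are pooled so that a
    time with d_o events among n_o subjects at risk contributes the factor
    ``1 - d_o / n_o``.
    """
    event_times, d, n_at_risk = _risk_table(dataset.times, dataset.events)
    if event_times.size == 0:
        # no events: S(t) = 1 everywhere; keep a knot for evaluability
        t_max = float(np.max(dataset.times))
        return StepFunction(TimeGrid([t_max]), np.array([1.0]), kind="survival")
    surv = np.cumprod(1.0 - d / n_at_risk)
    return StepFunction(TimeGrid(event_times), surv, kind="survival")


def nelson_aalen(dataset: SurvivalDataset) -> StepFunction:
    """Nelson-Aalen estimate of the cumulative hazard: the running sum of
    ``d_o / n_o`` over the unique event times."""
    event_times, d, n_at_risk = _risk_table(dataset.times, dataset.events)
    if event_times.size == 0:
        t_max = float(np.max(dataset.times))
        return StepFunction(TimeGrid([t_max]), np.array([0.0]), kind="chf")
    chf = np.cumsum(d / n_at_risk)
    return StepFunction(TimeGrid(event_times), chf, kind="chf")


def convert(curve: StepFunction) -> StepFunction:
    """Convert between survival and CHF representations.

    survival -> chf uses ``Lambda = -log(max(S, floor))``; chf -> survival uses
    ``S = exp(-Lambda)``.  The round trip is the identity wherever S exceeds
    the floor.
    """
    if curve.kind == "survival":
        vals = -np.log(np.clip(curve.values, SURVIVAL_FLOOR, None))
        return StepFunction(curve.knots, vals, kind="chf")
    vals = np.exp(-curve.values)
    return StepFunction(curve.knots, vals, kind="survival")
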