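"""Survival-model adapters.

The explainers in this package treat a fitted survival model as a black box
exposing ``predict_survival(X, grid) -> n x len(grid)`` matrix of survival
probabilities.  Two adapters are shipped — Cox proportional hazards and a
random survival forest, both thin wrappers over scikit-survival — plus an
adapter for arbitrary analytic survival functions, used as exact oracles.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxPHSurvivalAnalysis

from .data import SURVIVAL_FLOOR, StepFunction, SurvivalDataset, TimeGrid

__all__ = [
    "CoxModel",
    "RandomSurvivalForestModel",
    "AnalyticModel",
    "KaplanMeierModel",
    "make_model",
]


def _sanitize(S: np.ndarray) -> np.ndarray:
    """Clip to [0, 1] and enforce monotone non-increase along the grid."""
    S = np.clip(S, 0.0, 1.0)
    return np.minimum.accumulate(S, axis=1)


def _encode(X: pd.DataFrame, categories: dict[str, list]) -> np.ndarray:
    """One-hot encode categorical columns with fixed category lists."""
    parts = []
    for col in X.columns:
        if col in categories:
            cats = categories[col]
            vals = X[col].to_numpy()
            parts.append(np.column_stack([(vals == c).astype(float) for c in cats[1:]]))
        else:
            parts.append(X[col].to_numpy(dtype=float)[:, None])
    return np.hstack(parts)


class _SksurvAdapter:
    """Shared plumbing for scikit-survival estimators."""

    def __init__(self) -> None:
        self._est = None
        self._categories: dict[str, list] = {}
        self.feature_names_: list[str] | None = None

    def _build(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, dataset: SurvivalDataset):
        self.feature_names_ = dataset.feature_names
        # one-hot targets: categoricals plus binary columns with
        # non-numeric labels (e.g. yes/no)
        self._categories = {
            c: sorted(dataset.features[c].unique().tolist())
            for c in dataset.feature_names
            if dataset.column_kind(c) == "categorical"
            or not pd.api.types.is_numeric_dtype(dataset.features[c])
        }
        X = _encode(dataset.features, self._categories)
        self._est = self._build()
        self._est.fit(X, self._fit_target(dataset))
        self._train_times = np.asarray(self._est.unique_times_, dtype=float)
        return self

    def _fit_target(self, dataset: SurvivalDataset) -> np.ndarray:
        return dataset.to_structured()

    def predict_survival(self, X: pd.DataFrame, grid: TimeGrid,
                         chunk: int = 8192) -> np.ndarray:
        if self._est is None:
            raise RuntimeError("model is not fitted")
        Xe = _encode(X[self.feature_names_], self._categories)
        grid_arr = np.asarray(grid, dtype=float)
        # right-continuous lookup into the estimator's native time grid;
        # times before the first training time get survival 1
        idx = np.searchsorted(self._train_times, grid_arr, side="right") - 1
        out = np.empty((len(Xe), grid_arr.size))
        for s in range(0, len(Xe), chunk):
            arr = self._est.predict_survival_function(Xe[s : s + chunk],
                                                      return_array=True)
            block = np.where(idx[None, :] >= 0,
                             arr[:, np.clip(idx, 0, None)], 1.0)
            out[s : s + chunk] = block
        return _sanitize(out)

    def predict_chf(self, X: pd.DataFrame, grid: TimeGrid) -> np.ndarray:
        S = self.predict_survival(X, grid)
        return -np.log(np.clip(S, SURVIVAL_FLOOR, None))


class CoxModel(_SksurvAdapter):
    """Cox proportional hazards with Breslow baseline hazard."""

    def __init__(self, alpha: float = 1e-4) -> None:
        super().__init__()
        self.alpha = alpha

    def _build(self):
        return CoxPHSurvivalAnalysis(alpha=self.alpha)

    @property
    def coef_(self) -> np.ndarray:
        return self._est.coef_

    def baseline_chf(self) -> StepFunction:
        """Breslow baseline cumulative hazard of the fitted model."""
        fn = self._est.cum_baseline_hazard_
        t = np.asarray(fn.x, dtype=float)
        keep = t > 0
        return StepFunction(TimeGrid(t[keep]), np.asarray(fn.y)[keep], kind="chf")

    def refit(self, dataset: SurvivalDataset) -> "CoxModel":
        return CoxModel(alpha=self.alpha).fit(dataset)


class RandomSurvivalForestModel(_SksurvAdapter):
    """Random survival forest (log-rank splitting, Nelson-Aalen leaves).

    ``max_unique_times`` coarsens observed times onto that many quantile bins
    before fitting; the ensemble's per-tree risk tables scale with the number
    of unique times, and ~250 bins keeps predictions cheap with negligible
    change to the fitted curves.
    """

    def __init__(self, n_estimators: int = 100, min_samples_leaf: int = 50,
                 max_features: str | float = "sqrt", random_state: int = 0,
                 max_unique_times: int = 250) -> None:
        super().__init__()
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.random_state = random_state
        self.max_unique_times = max_unique_times

    def _build(self):
        return RandomSurvivalForest(
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            random_state=self.random_state,
            n_jobs=1,
        )

    def _fit_target(self, dataset: SurvivalDataset) -> np.ndarray:
        y = dataset.to_structured()
        t = y["time"]
        uniq = np.unique(t)
        if uniq.size > self.max_unique_times:
            edges = np.unique(np.quantile(uniq, np.linspace(0, 1, self.max_unique_times)))
            # snap each time up to the nearest edge so no event moves later
            # than its bin boundary's right end
            pos = np.clip(np.searchsorted(edges, t, side="left"), 0, edges.size - 1)
            y = y.copy()
            y["time"] = edges[pos]
        return y

    def refit(self, dataset: SurvivalDataset) -> "RandomSurvivalForestModel":
        return RandomSurvivalForestModel(
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            random_state=self.random_state,
            max_unique_times=self.max_unique_times,
        ).fit(dataset)


class AnalyticModel:
    """Wrap a closed-form survival function ``S(t, X) -> n x |grid|``.

    Used for exact oracles: the callable receives the grid as a 1-d array and
    the feature frame, and returns survival probabilities.
    """

    def __init__(self, fn: Callable[[np.ndarray, pd.DataFrame], np.ndarray]) -> None:
        self._fn = fn

    def predict_survival(self, X: pd.DataFrame, grid: TimeGrid) -> np.ndarray:
        return _sanitize(np.asarray(self._fn(np.asarray(grid, dtype=float), X),
                                    dtype=float))


class KaplanMeierModel:
    """Featureless predictor: the training Kaplan-Meier curve for every row."""

    def fit(self, dataset: SurvivalDataset) -> "KaplanMeierModel":
        from .data import km_estimate

        self._km = km_estimate(dataset)
        return self

    def predict_survival(self, X: pd.DataFrame, grid: TimeGrid) -> np.ndarray:
        vals = self._km(np.asarray(grid, dtype=float))
        return np.tile(vals, (len(X), 1))

    def refit(self, dataset: SurvivalDataset) -> "KaplanMeierModel":
        return KaplanMeierModel().fit(dataset)


_REGISTRY = {
    "cox": CoxModel,
    "rsf": RandomSurvivalForestModel,
    "km": KaplanMeierModel,
}


def make_model(name: str, **kwargs):
    """Instantiate a registered adapter by name ('cox', 'rsf', 'km')."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown model adapter {name!r}; "
                         f"available: {sorted(_REGISTRY)}") from None
    return cls(**kwargs)
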