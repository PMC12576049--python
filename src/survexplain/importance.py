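"""Time-dependent feature importance: PFI, CPI and LOCO.

All three follow the same template: evaluate a time-dependent loss (IPCW
Brier by default) on intact predictions, perturb the information carried by
one feature, re-evaluate, and report the per-time increase in loss
(difference form ``FI_d``; the quotient form ``FI_q`` is kept alongside).

* PFI permutes the feature column — a marginal perturbation that breaks the
  feature's joint distribution with its correlates.
* CPI replaces the column with a model-X knockoff, preserving the covariate
  structure, and supports one-sided paired t-tests on per-subject loss
  differences.
* LOCO refits the model without the feature and compares losses on held-out
  data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
import json
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .data import SurvivalDataset, SurvivalModel, TimeGrid
from .metrics import LossCurve, brier_curve, censoring_distribution

__all__ = ["ImportanceResult", "KnockoffMatrix", "brier_loss", "pfi",
           "sample_knockoffs", "cpi", "loco", "importance_inference",
           "holm_adjust"]

LossFn = Callable[[SurvivalDataset, np.ndarray, TimeGrid], LossCurve]


def brier_loss(train: SurvivalDataset) -> LossFn:
    """IPCW Brier loss with the censoring distribution estimated on
    training data (flipped event indicators)."""
    G = censoring_distribution(train)

    def loss(test: SurvivalDataset, predictions: np.ndarray,
             grid: TimeGrid) -> LossCurve:
        return brier_curve(test, predictions, grid, G)

    return loss


@dataclass
class ImportanceResult:
    """Per-time importance of one feature.

    ``fi_d`` is perturbed-minus-baseline loss (positive = important),
    ``fi_q`` the corresponding ratio.  ``per_observation_diff`` holds the
    time-averaged per-subject loss differences that back the paired tests.
    """

    feature: str
    time_grid: TimeGrid
    fi_d: np.ndarray
    fi_q: np.ndarray
    per_repeat: np.ndarray          # (repeats, T) difference-form curves
    baseline_loss: LossCurve
    method: str
    per_observation_diff: np.ndarray | None = None
    p_value: float | None = None
    seed: int | None = None

    @property
    def repeats(self) -> int:
        return self.per_repeat.shape[0]

    @property
    def time_average(self) -> float:
        return float(self.fi_d.mean())

    def to_frame(self) -> pd.DataFrame:
        R, T = self.per_repeat.shape
        base = self.baseline_loss.values
        return pd.DataFrame({
            "feature": self.feature,
            "time": np.tile(np.asarray(self.time_grid), R),
            "repeat": np.repeat(np.arange(R), T),
            "fi_d": self.per_repeat.ravel(),
            "fi_q": ((self.per_repeat + base) / np.where(base > 0, base, np.nan)).ravel(),
        })


def save_importances(results: list[ImportanceResult], path: str | Path) -> None:
    pd.concat([r.to_frame() for r in results], ignore_index=True).to_csv(
        path, index=False)
    meta = {r.feature: {"p_value": r.p_value, "seed": r.seed,
                        "method": r.method,
                        "loss": r.baseline_loss.loss_name}
            for r in results}
    Path(path).with_suffix(".json").write_text(json.dumps(meta))


def _evaluate(model: SurvivalModel, data: SurvivalDataset, features: pd.DataFrame,
              loss: LossFn, grid: TimeGrid) -> LossCurve:
    preds = model.predict_survival(features, grid)
    return loss(data, preds, grid)


def _result(feature: str, grid: TimeGrid, repeats_fi: np.ndarray,
            baseline: LossCurve, method: str, seed: int | None,
            per_obs_diff: np.ndarray | None = None) -> ImportanceResult:
    fi_d = repeats_fi.mean(axis=0)
    base = baseline.values
    with np.errstate(invalid="ignore", divide="ignore"):
        fi_q = np.where(base > 0, (fi_d + base) / base, np.nan)
    return ImportanceResult(feature, grid, fi_d, fi_q, repeats_fi, baseline,
                            method, per_observation_diff=per_obs_diff, seed=seed)


# ---------------------------------------------------------------------------
# PFI
# ---------------------------------------------------------------------------


def pfi(model: SurvivalModel, data: SurvivalDataset, loss: LossFn,
        n_repeats: int | str = 10, seed: int = 0,
        time_grid: TimeGrid | None = None,
        features: list[str] | None = None) -> list[ImportanceResult]:
    """Permutation feature importance, sorted by descending time-averaged
    importance.

    ``n_repeats='all'`` enumerates every permutation of the column (only
    sensible for tiny n); otherwise ``n_repeats`` seeded random permutations
    are averaged.
    """
    if time_grid is None:
        time_grid = TimeGrid.from_dataset(data)
    if isinstance(n_repeats, int) and n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    baseline = _evaluate(model, data, data.features, loss, time_grid)
    rng = np.random.default_rng(seed)
    results = []
    for feat in features or data.feature_names:
        if n_repeats == "all":
            if data.n > 7:
                raise ValueError("exhaustive mode is limited to n <= 7")
            perms = [np.asarray(p) for p in permutations(range(data.n))]
        else:
            perms = [rng.permutation(data.n) for _ in range(n_repeats)]
        fi = np.empty((len(perms), len(time_grid)))
        for r, perm in enumerate(perms):
            Xp = data.features.copy()
            Xp[feat] = Xp[feat].to_numpy()[perm]
            fi[r] = _evaluate(model, data, Xp, loss, time_grid).values - baseline.values
        results.append(_result(feat, time_grid, fi, baseline, "pfi", seed))
    results.sort(key=lambda r: -r.time_average)
    return results


# ---------------------------------------------------------------------------
# Knockoffs and CPI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KnockoffMatrix:
    """Second-order Gaussian knockoff copy of a feature table."""

    values: pd.DataFrame
    generator: str
    seed: int
    s: np.ndarray = field(default=None)  # type: ignore[assignment]


def sample_knockoffs(features: pd.DataFrame, seed: int = 0,
                     ridge: float = 1e-6) -> KnockoffMatrix:
    """Second-order Gaussian knockoffs with the equicorrelated construction.

    The knockoff X~ matches the first two moments of X and satisfies the
    exchangeability structure cov(X_j, X~_j) = Sigma_jj - s_j with
    s = min(1, 2 lambda_min(R)) on the correlation scale.  Sampled jointly
    Gaussian conditional on X; a singular correlation matrix is
    ridge-regularized with a warning.
    """
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant columns cannot be knockoff-sampled")
    Z = (X - mu) / sd
    R = np.corrcoef(Z, rowvar=False).reshape(p, p)
    lam_min = float(np.linalg.eigvalsh(R).min())
    if lam_min < 1e-8:
        import warnings

        warnings.warn("near-singular feature correlation; ridge-regularizing",
                      stacklevel=2)
        R = R + ridge * np.eye(p)
        lam_min = float(np.linalg.eigvalsh(R).min())
    s = np.full(p, min(1.0, 2.0 * lam_min))
    s_mat = np.diag(s)
    Rinv_s = np.linalg.solve(R, s_mat)
    cond_mean = Z - Z @ Rinv_s
    cond_cov = 2.0 * s_mat - s_mat @ Rinv_s
    # symmetrize and factor; clip tiny negative eigenvalues from round-off
    cond_cov = (cond_cov + cond_cov.T) / 2.0
    w, V = np.linalg.eigh(cond_cov)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.default_rng(seed)
    Zk = cond_mean + rng.standard_normal((n, p)) @ L.T
    Xk = Zk * sd + mu
    return KnockoffMatrix(pd.DataFrame(Xk, columns=features.columns),
                          "gaussian_second_order", seed, s)


def _conditional_categorical(features: pd.DataFrame, col: str,
                             seed: int) -> np.ndarray:
    """Conditional resample of a binary/categorical column given the rest,
    via a seeded random-forest classifier's predicted class probabilities."""
    from sklearn.ensemble import RandomForestClassifier

    rest = features.drop(columns=[col])
    rest_num = pd.get_dummies(rest, drop_first=True).to_numpy(dtype=float)
    y = features[col].to_numpy()
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size == 1:
        return y.copy()
    clf = RandomForestClassifier(n_estimators=50, min_samples_leaf=20,
                                 random_state=seed)
    clf.fit(rest_num, y_idx)
    proba = clf.predict_proba(rest_num)
    rng = np.random.default_rng(seed + 1)
    draws = np.array([rng.choice(classes.size, p=p) for p in proba])
    return classes[draws]


def cpi(model: SurvivalModel, data: SurvivalDataset, loss: LossFn,
        seed: int = 0, time_grid: TimeGrid | None = None,
        features: list[str] | None = None,
        knockoffs: KnockoffMatrix | None = None) -> list[ImportanceResult]:
    """Conditional predictive impact: knockoff-based importance with
    one-sided paired t-tests (Holm-adjusted across features).

    Numeric columns are replaced by Gaussian knockoffs; binary/categorical
    columns are conditionally resampled from a classifier fitted on the
    remaining columns.
    """
    if time_grid is None:
        time_grid = TimeGrid.from_dataset(data)
    baseline = _evaluate(model, data, data.features, loss, time_grid)
    if baseline.per_observation is None:
        raise ValueError("CPI needs per-observation losses; use a metrics-"
                         "module loss that retains them (e.g. brier_loss)")
    numeric = [c for c in data.feature_names if data.column_kind(c) == "numeric"]
    if knockoffs is None and len(numeric) >= 1:
        knockoffs = sample_knockoffs(data.features[numeric], seed=seed)
    results = []
    for feat in features or data.feature_names:
        Xk = data.features.copy()
        if feat in numeric:
            Xk[feat] = knockoffs.values[feat].to_numpy()
        else:
            Xk[feat] = _conditional_categorical(data.features, feat, seed)
        perturbed = _evaluate(model, data, Xk, loss, time_grid)
        fi = (perturbed.values - baseline.values)[None, :]
        diffs = (perturbed.per_observation - baseline.per_observation).mean(axis=1)
        res = _result(feat, time_grid, fi, baseline, "cpi", seed,
                      per_obs_diff=diffs)
        res.p_value = importance_inference(res)
        results.append(res)
    _apply_holm(results)
    results.sort(key=lambda r: -r.time_average)
    return results


# ---------------------------------------------------------------------------
# LOCO
# ---------------------------------------------------------------------------


def loco(model: SurvivalModel, train: SurvivalDataset, test: SurvivalDataset,
         loss: LossFn, time_grid: TimeGrid | None = None,
         features: list[str] | None = None,
         test_kind: str = "wilcoxon") -> list[ImportanceResult]:
    """Leave-one-covariate-out importance by refitting.

    The adapter must expose ``refit``; the full model's loss on test data is
    compared with that of a model refitted on training data without the
    feature.  Hyperparameters are reused unchanged.
    """
    if not hasattr(model, "refit"):
        raise TypeError("LOCO requires a model adapter exposing refit(dataset)")
    if time_grid is None:
        time_grid = TimeGrid.from_dataset(test)
    baseline = _evaluate(model, test, test.features, loss, time_grid)
    results = []
    for feat in features or train.feature_names:
        reduced = model.refit(train.drop_feature(feat))
        preds = reduced.predict_survival(test.features.drop(columns=[feat]),
                                         time_grid)
        red_loss = loss(test, preds, time_grid)
        fi = (red_loss.values - baseline.values)[None, :]
        diffs = None
        if baseline.per_observation is not None and red_loss.per_observation is not None:
            diffs = (red_loss.per_observation - baseline.per_observation).mean(axis=1)
        res = _result(feat, time_grid, fi, baseline, "loco", None,
                      per_obs_diff=diffs)
        if diffs is not None:
            res.p_value = importance_inference(res, kind=test_kind)
        results.append(res)
    _apply_holm(results)
    results.sort(key=lambda r: -r.time_average)
    return results


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def importance_inference(result: ImportanceResult, kind: str = "t") -> float:
    """One-sided test of H0: FI <= 0 against H1: FI > 0.

    ``t``: paired t-test on per-subject loss differences (CPI default);
    ``wilcoxon``: signed-rank alternative for median-based LOCO inference.
    Returns 1.0 when every difference is exactly zero.
    """
    d = result.per_observation_diff
    if d is None or d.size < 2:
        raise ValueError("inference needs at least two paired per-observation "
                         "loss differences")
    if np.all(d == 0):
        return 1.0
    if kind == "t":
        stat = stats.ttest_1samp(d, 0.0, alternative="greater")
        return float(stat.pvalue)
    if kind == "wilcoxon":
        nz = d[d != 0]
        return float(stats.wilcoxon(nz, alternative="greater").pvalue)
    raise ValueError("kind must be 't' or 'wilcoxon'")


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (assumption-free FWER control)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _apply_holm(results: list[ImportanceResult]) -> None:
    tested = [r for r in results if r.p_value is not None]
    if len(tested) > 1:
        adj = holm_adjust(np.array([r.p_value for r in tested]))
        for r, a in zip(tested, adj):
            r.p_value = float(a)
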