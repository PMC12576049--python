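"""Per-observation explanations for survival models.

* SurvLIME fits a local Cox surrogate: perturb the explained point, predict
  black-box cumulative hazards, and solve a weighted least-squares problem
  on the log-CHF scale so that ``log L(t|x_k) ~ log L0(t) + b' x_k``.  The
  coefficient vector b is the explanation.
* SurvSHAP(t) attributes the predicted survival curve to features with
  time-dependent Shapley values, by permutation sampling or by
  Shapley-kernel weighted regression; both are exact under full enumeration
  and satisfy local accuracy per timepoint.
* Counterfactuals search for a nearby feature vector whose restricted mean
  survival time (RMST) exceeds the original's by a requested margin, via a
  hinge loss plus a Euclidean proximity penalty, optimized with a seeded
  particle swarm.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb

import numpy as np
import pandas as pd

from .data import (SURVIVAL_FLOOR, StepFunction, SurvivalDataset,
                   SurvivalModel, TimeGrid, nelson_aalen, predict_chf)

__all__ = ["SurvLIMEResult", "SurvSHAPResult", "CounterfactualResult",
           "survlime", "survshap_sampling", "survshap_kernel", "rmst",
           "counterfactual"]


# ---------------------------------------------------------------------------
# SurvLIME
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvLIMEResult:
    """Local Cox-surrogate explanation of one observation."""

    coefficients: pd.Series           # b per (expanded) feature
    neighborhood: pd.DataFrame        # perturbed points x_k
    weights: np.ndarray               # kernel weights w_k >= 0
    baseline_chf: StepFunction
    time_grid: TimeGrid
    surrogate_chf: np.ndarray         # Lambda0(t) * exp(b'x) at the explained point
    fidelity: float                   # weighted RMS gap between CHFs
    seed: int

    @property
    def local_importance(self) -> pd.Series:
        """|b_j * x_j| at the explained point, sorted descending."""
        x = self.neighborhood.iloc[0]  # first neighborhood point is x itself
        imp = (self.coefficients * x).abs()
        return imp.sort_values(ascending=False)


def _expand_onehot(X: pd.DataFrame, categories: dict[str, list]) -> pd.DataFrame:
    out = {}
    for col in X.columns:
        if col in categories:
            for lev in categories[col]:
                out[f"{col}={lev}"] = (X[col] == lev).astype(float)
        else:
            out[col] = X[col].astype(float)
    return pd.DataFrame(out)


def survlime(model: SurvivalModel, train: SurvivalDataset, x: pd.Series | pd.DataFrame,
             g: int = 1000, kernel_width: float = 0.5, seed: int = 0,
             time_grid: TimeGrid | None = None,
             baseline: StepFunction | None = None,
             perturbation_scale: float = 0.1) -> SurvLIMEResult:
    """Explain one observation with a local Cox surrogate.

    Parameters
    ----------
    g : int
        Neighborhood size (the explained point is included).
    kernel_width : float
        Radius r of the Epanechnikov kernel ``w_k = 1 - d_k^2 / r`` on
        standardized distances; negative weights are clipped to zero.
    baseline : StepFunction, optional
        Baseline cumulative hazard L0; defaults to the Nelson-Aalen
        estimate on the training data.
    """
    if isinstance(x, pd.DataFrame):
        x = x.iloc[0]
    x = x[train.feature_names]
    if time_grid is None:
        time_grid = TimeGrid.from_dataset(train)
    if baseline is None:
        baseline = nelson_aalen(train)
    categories = {c: sorted(train.features[c].unique().tolist())
                  for c in train.feature_names
                  if train.column_kind(c) == "categorical"}

    Xe_train = _expand_onehot(train.features, categories)
    xe = _expand_onehot(x.to_frame().T, categories).iloc[0]
    sd = Xe_train.std(axis=0, ddof=1).replace(0.0, 1.0)

    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=perturbation_scale, size=(g, len(xe))) * sd.to_numpy()
    pts = xe.to_numpy() + noise
    pts[0] = xe.to_numpy()  # include the explained point itself
    neigh = pd.DataFrame(pts, columns=Xe_train.columns)
    # snap perturbed one-hot blocks back to a valid single level
    for col, levels in categories.items():
        block = [f"{col}={lev}" for lev in levels]
        arg = neigh[block].to_numpy().argmax(axis=1)
        onehot = np.zeros((g, len(block)))
        onehot[np.arange(g), arg] = 1.0
        neigh[block] = onehot

    # map expanded points back to original feature space for prediction
    orig = {}
    for col in train.feature_names:
        if col in categories:
            block = [f"{col}={lev}" for lev in categories[col]]
            arg = neigh[block].to_numpy().argmax(axis=1)
            orig[col] = np.asarray(categories[col])[arg]
        else:
            orig[col] = neigh[col].to_numpy()
    X_orig = pd.DataFrame(orig)

    dist2 = (((neigh - xe.to_numpy()) / sd.to_numpy()) ** 2).sum(axis=1).to_numpy()
    w = np.clip(1.0 - dist2 / kernel_width, 0.0, None)

    chf = predict_chf(model, X_orig, time_grid)          # (g, T)
    lam0 = baseline(np.asarray(time_grid))
    valid_t = lam0 > 0
    if not valid_t.any():
        raise ValueError("baseline cumulative hazard is zero on the whole grid")
    pointwise = chf[:, valid_t]
    keep = (pointwise > 0).any(axis=1)
    if not keep.any():
        raise ValueError("every neighborhood point has an all-zero CHF")
    if not keep.all():
        import warnings

        warnings.warn(f"dropping {int((~keep).sum())} neighborhood points "
                      "with all-zero CHFs", stacklevel=2)

    Z = neigh.to_numpy()[keep]
    wk = w[keep]
    lam = pointwise[keep]
    with np.errstate(divide="ignore"):
        y = np.log(np.clip(lam, SURVIVAL_FLOOR, None)) - np.log(lam0[valid_t])
    # zero CHFs have no log; CHFs at the survival floor are numerically
    # saturated -- both get zero weight instead of a fabricated value
    saturated = lam >= 0.999 * (-np.log(SURVIVAL_FLOOR))
    v = np.where((lam > 0) & ~saturated, lam, 0.0)       # per-(point,time) weights
    row_w = wk[:, None] * v                              # (g', T')
    # intercept column absorbs any time-constant offset between the black
    # box and the supplied baseline, so a featureless model yields b = 0
    Zi = np.column_stack([np.ones(len(Z)), Z])
    W_tot = row_w.sum(axis=1)                            # per-point total weight
    A = (Zi * W_tot[:, None]).T @ Zi
    rhs = Zi.T @ (row_w * y).sum(axis=1)
    b_full = np.linalg.lstsq(A, rhs, rcond=None)[0]
    b = b_full[1:]

    b0 = float(b_full[0])
    surrogate = np.asarray(baseline(np.asarray(time_grid))) * np.exp(
        b0 + float(xe.to_numpy() @ b))
    full_chf = chf
    surr_all = lam0[None, :] * np.exp(b0 + neigh.to_numpy() @ b)[:, None]
    gaps = np.sqrt(np.mean((full_chf[:, valid_t][keep] - surr_all[:, valid_t][keep]) ** 2,
                           axis=1))
    fidelity = float(np.average(gaps, weights=np.where(wk.sum() > 0, wk, 1.0)))
    return SurvLIMEResult(pd.Series(b, index=neigh.columns), neigh, w,
                          baseline, time_grid, surrogate, fidelity, seed)


# ---------------------------------------------------------------------------
# SurvSHAP(t)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvSHAPResult:
    """Time-dependent Shapley attributions for one observation."""

    phi: pd.DataFrame                 # features x time
    baseline: np.ndarray              # average predicted survival over background
    prediction: np.ndarray            # model prediction for x
    time_grid: TimeGrid
    estimator: str
    n_samples: int                    # permutations or coalitions used
    seed: int

    @property
    def reconstruction_error(self) -> float:
        recon = self.phi.to_numpy().sum(axis=0) + self.baseline
        return float(np.max(np.abs(recon - self.prediction)))


class _CoalitionValues:
    """Cache of v(S)(t): background-marginalized predictions with the
    explained point's values on coalition S."""

    def __init__(self, model: SurvivalModel, background: pd.DataFrame,
                 x: pd.Series, grid: TimeGrid) -> None:
        self.model = model
        self.background = background.reset_index(drop=True)
        self.x = x
        self.grid = grid
        self.p = len(x)
        self.names = list(background.columns)
        self._cache: dict[frozenset, np.ndarray] = {}

    def compute(self, coalitions: list[frozenset]) -> None:
        todo = [S for S in dict.fromkeys(coalitions) if S not in self._cache]
        if not todo:
            return
        B = len(self.background)
        frames = []
        for S in todo:
            Xb = self.background.copy()
            for j in S:
                Xb[self.names[j]] = self.x[self.names[j]]
            frames.append(Xb)
        preds = self.model.predict_survival(pd.concat(frames, ignore_index=True),
                                            self.grid)
        preds = preds.reshape(len(todo), B, len(self.grid)).mean(axis=1)
        for S, row in zip(todo, preds):
            self._cache[S] = row

    def __getitem__(self, S: frozenset) -> np.ndarray:
        if S not in self._cache:
            self.compute([S])
        return self._cache[S]


def _prepare(model, background, x, time_grid):
    if isinstance(background, SurvivalDataset):
        bg = background.features
    else:
        bg = background
    if len(bg) == 0:
        raise ValueError("empty background set")
    if isinstance(x, pd.DataFrame):
        x = x.iloc[0]
    x = x[list(bg.columns)]
    if time_grid is None:
        raise ValueError("a time grid is required")
    return _CoalitionValues(model, bg, x, time_grid), x


def survshap_sampling(model: SurvivalModel, background, x,
                      n_permutations: int | str = 50, seed: int = 0,
                      time_grid: TimeGrid | None = None) -> SurvSHAPResult:
    """SurvSHAP(t) by permutation sampling.

    Averages marginal contributions over sampled feature orderings; with
    ``n_permutations='all'`` every ordering is used and the estimator is
    exact.  Out-of-coalition features are marginalized by substituting
    background rows (interventional estimation).
    """
    vals, x = _prepare(model, background, x, time_grid)
    p = vals.p
    if n_permutations == "all":
        perms = list(permutations(range(p)))
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be at least 1")
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(p)) for _ in range(n_permutations)]
    needed = set()
    for pi in perms:
        S: frozenset = frozenset()
        needed.add(S)
        for j in pi:
            S = S | {j}
            needed.add(S)
    vals.compute(list(needed))
    T = len(time_grid)
    phi = np.zeros((p, T))
    for pi in perms:
        S: frozenset = frozenset()
        for j in pi:
            Sj = S | {j}
            phi[j] += vals[Sj] - vals[S]
            S = Sj
    phi /= len(perms)
    return SurvSHAPResult(pd.DataFrame(phi, index=vals.names), vals[frozenset()],
                          vals[frozenset(range(p))], time_grid, "sampling",
                          len(perms), seed)


def _shapley_kernel_weight(p: int, s: int) -> float:
    return (p - 1) / (comb(p, s) * s * (p - s))


def survshap_kernel(model: SurvivalModel, background, x,
                    n_coalitions: int | str = "all", seed: int = 0,
                    time_grid: TimeGrid | None = None,
                    ridge: float = 1e-10) -> SurvSHAPResult:
    """SurvSHAP(t) by Shapley-kernel weighted regression (KernelSHAP).

    One weighted least-squares solve per timepoint with a shared design
    matrix of binary coalition vectors; the efficiency constraint
    ``sum_j phi_j(t) = f(x)(t) - baseline(t)`` is enforced exactly by
    eliminating one feature.  ``n_coalitions='all'`` enumerates every
    non-trivial coalition, which reproduces exact Shapley values.
    """
    vals, x = _prepare(model, background, x, time_grid)
    p = vals.p
    all_nontrivial = [frozenset(c) for s in range(1, p)
                      for c in combinations(range(p), s)]
    if n_coalitions == "all":
        coalitions = all_nontrivial
    else:
        if n_coalitions < p + 2:
            raise ValueError("need at least p + 2 sampled coalitions")
        rng = np.random.default_rng(seed)
        sizes = np.arange(1, p)
        w_sizes = np.array([_shapley_kernel_weight(p, s) * comb(p, s)
                            for s in sizes])
        w_sizes /= w_sizes.sum()
        coalitions = []
        for _ in range(min(n_coalitions, len(all_nontrivial) * 4)):
            s = rng.choice(sizes, p=w_sizes)
            coalitions.append(frozenset(rng.choice(p, size=s, replace=False)
                                        .tolist()))
        coalitions = list(dict.fromkeys(coalitions))
    empty, full = frozenset(), frozenset(range(p))
    vals.compute(coalitions + [empty, full])

    Z = np.array([[1.0 if j in S else 0.0 for j in range(p)] for S in coalitions])
    W = np.array([_shapley_kernel_weight(p, int(z.sum())) for z in Z])
    base = vals[empty]
    total = vals[full] - base                             # (T,)
    Y = np.array([vals[S] for S in coalitions]) - base    # (m, T)
    # eliminate feature p-1 to enforce the efficiency constraint exactly
    Zr = Z[:, :-1] - Z[:, -1:][:, [0] * (p - 1)]
    Yr = Y - np.outer(Z[:, -1], total)
    A = (Zr * W[:, None]).T @ Zr
    if np.linalg.cond(A) > 1e12:
        A = A + ridge * np.eye(p - 1)
    phi_r = np.linalg.solve(A, (Zr * W[:, None]).T @ Yr)  # (p-1, T)
    phi = np.vstack([phi_r, total - phi_r.sum(axis=0)])
    return SurvSHAPResult(pd.DataFrame(phi, index=vals.names), base,
                          vals[full], time_grid, "kernel", len(coalitions), seed)


# ---------------------------------------------------------------------------
# RMST and counterfactuals
# ---------------------------------------------------------------------------


def rmst(curve: StepFunction, horizon: float) -> float:
    """Restricted mean survival time: area under a step survival curve on
    [0, horizon].  Exact for step functions."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if curve.kind != "survival":
        raise ValueError("rmst expects a survival curve")
    knots = np.asarray(curve.knots, dtype=float)
    edges = np.concatenate([[0.0], knots, [np.inf]])
    vals = np.concatenate([[curve.initial_value], curve.values])
    widths = np.clip(np.minimum(edges[1:], horizon) - np.minimum(edges[:-1], horizon),
                     0.0, None)
    return float(np.sum(widths * vals))


def _rmst_rows(model: SurvivalModel, X: pd.DataFrame, grid: TimeGrid) -> np.ndarray:
    """RMST of each predicted curve, truncated at the grid's last time."""
    S = model.predict_survival(X, grid)
    t = np.asarray(grid, dtype=float)
    edges = np.concatenate([[0.0], t])
    vals = np.concatenate([np.ones((len(X), 1)), S[:, :-1]], axis=1)
    return vals @ np.diff(edges)


@dataclass(frozen=True)
class CounterfactualResult:
    """Outcome of the counterfactual search for one observation."""

    counterfactual: pd.Series
    hinge: float
    distance: float
    rmst_original: float
    rmst_counterfactual: float
    target_gap: float
    regularization: float
    converged: bool
    loss_history: np.ndarray

    @property
    def loss(self) -> float:
        return self.hinge + self.regularization * self.distance


def counterfactual(model: SurvivalModel, x: pd.Series | pd.DataFrame, r: float,
                   C: float, feature_bounds: dict[str, tuple[float, float]],
                   seed: int = 0, time_grid: TimeGrid | None = None,
                   n_particles: int = 50, n_iterations: int = 200) -> CounterfactualResult:
    """Hinge-loss counterfactual explanation.

    Minimizes ``max(0, r - (E(c) - E(x))) + C * ||c - x||_2`` over feature
    vectors c within per-feature bounds, where E is the RMST truncated at
    the last grid time.  Optimized with a seeded particle swarm (inertia
    0.7, cognitive/social weights 1.5); the explained point is seeded into
    the swarm, so the loss of the reported solution never exceeds the
    trivial one, and the best-so-far loss is non-increasing by elitism.
    """
    if r < 0 or C <= 0:
        raise ValueError("need r >= 0 and C > 0")
    if isinstance(x, pd.DataFrame):
        x = x.iloc[0]
    names = list(feature_bounds)
    if set(names) != set(x.index):
        raise ValueError("feature_bounds must cover exactly the features of x")
    if time_grid is None:
        raise ValueError("a time grid is required")
    lo = np.array([feature_bounds[f][0] for f in names], dtype=float)
    hi = np.array([feature_bounds[f][1] for f in names], dtype=float)
    if np.any(lo > hi):
        raise ValueError("infeasible bounds")
    x0 = x[names].to_numpy(dtype=float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("the explained point must satisfy the bounds")

    E_x = float(_rmst_rows(model, pd.DataFrame([dict(zip(names, x0))]), time_grid)[0])

    def losses(P: np.ndarray) -> np.ndarray:
        E = _rmst_rows(model, pd.DataFrame(P, columns=names), time_grid)
        hinge = np.clip(r - (E - E_x), 0.0, None)
        dist = np.linalg.norm(P - x0, axis=1)
        return hinge + C * dist

    rng = np.random.default_rng(seed)
    span = np.where(hi > lo, hi - lo, 1.0)
    P = lo + rng.uniform(size=(n_particles, len(names))) * (hi - lo)
    P[0] = x0
    V = rng.normal(scale=0.1, size=P.shape) * span
    pbest, pbest_loss = P.copy(), losses(P)
    g_idx = int(np.argmin(pbest_loss))
    gbest, gbest_loss = pbest[g_idx].copy(), float(pbest_loss[g_idx])
    history = [gbest_loss]
    inertia, cog, soc = 0.7, 1.5, 1.5
    for _ in range(n_iterations):
        r1 = rng.uniform(size=P.shape)
        r2 = rng.uniform(size=P.shape)
        V = inertia * V + cog * r1 * (pbest - P) + soc * r2 * (gbest - P)
        P = np.clip(P + V, lo, hi)
        cur = losses(P)
        improved = cur < pbest_loss
        pbest[improved], pbest_loss[improved] = P[improved], cur[improved]
        i = int(np.argmin(pbest_loss))
        if pbest_loss[i] < gbest_loss:
            gbest, gbest_loss = pbest[i].copy(), float(pbest_loss[i])
        history.append(gbest_loss)
    history = np.asarray(history)
    tail = history[-max(2, n_iterations // 4):]
    converged = bool(tail[0] - tail[-1] <= 1e-9)
    E_c = float(_rmst_rows(model, pd.DataFrame([dict(zip(names, gbest))]),
                           time_grid)[0])
    return CounterfactualResult(
        counterfactual=pd.Series(gbest, index=names),
        hinge=float(max(0.0, r - (E_c - E_x))),
        distance=float(np.linalg.norm(gbest - x0)),
        rmst_original=E_x, rmst_counterfactual=E_c,
        target_gap=r, regularization=C, converged=converged,
        loss_history=history,
    )
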