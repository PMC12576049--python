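"""End-to-end experiment orchestration.

An experiment = simulate (or load) a cohort, split it, fit a model adapter,
run a list of explainers, and write every result as CSV/JSON together with
a manifest recording seeds, shapes and timings.  Re-running the same config
reproduces all artifacts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import effects, importance, interactions, local
from .data import SurvivalDataset, TimeGrid
from .importance import brier_loss
from .metrics import censoring_distribution, brier_curve
from .models import make_model
from .simulate import SimulationConfig, simulate

__all__ = ["ExperimentConfig", "run_experiment", "train_test_split"]

log = logging.getLogger("survexplain")

KNOWN_EXPLAINERS = ("ice", "pdp", "mplot", "ale", "h_two_way", "h_total",
                    "pfi", "cpi", "loco", "survlime", "survshap",
                    "counterfactual", "brier")


@dataclass
class ExperimentConfig:
    design: str
    model: str = "rsf"
    n: int = 3000
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    model_params: dict = field(default_factory=dict)
    explainers: list[dict] = field(default_factory=list)
    test_fraction: float = 0.3
    out_dir: str = "results"

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds: one spawn of the experiment seed per
    stochastic stage, mapped into [0, 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def train_test_split(dataset: SurvivalDataset, test_fraction: float,
                     seed: int) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Seeded split, stratified by the event indicator."""
    rng = np.random.default_rng(seed)
    test_idx = []
    for value in (0, 1):
        idx = np.flatnonzero(dataset.events == value)
        rng.shuffle(idx)
        test_idx.append(idx[: int(round(test_fraction * idx.size))])
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(dataset.n), test_idx)
    return dataset.subset(train_idx), dataset.subset(test_idx)


def _validate(config: ExperimentConfig, model) -> None:
    for spec in config.explainers:
        method = spec.get("method")
        if method not in KNOWN_EXPLAINERS:
            raise ValueError(f"unknown explainer {method!r}; "
                             f"known: {KNOWN_EXPLAINERS}")
        if method == "loco" and not hasattr(model, "refit"):
            raise TypeError("config requests LOCO but the model adapter has "
                            "no refit capability")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one experiment; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    seeds = child_seeds(config.seed, 4 + len(config.explainers))
    sim_cfg = SimulationConfig.for_design(config.design, n=config.n,
                                          seed=seeds[0], **config.simulation)
    dataset = simulate(sim_cfg)
    train, test = train_test_split(dataset, config.test_fraction, seeds[1])
    model = make_model(config.model, **config.model_params)
    _validate(config, model)     # fail on capability mismatch before compute
    out.mkdir(parents=True, exist_ok=True)
    dataset.to_csv(out / "data.csv")

    t0 = time.time()
    model.fit(train)
    log.info("fitted %s on train n=%d p=%d", config.model, train.n,
             len(train.feature_names))
    grid = TimeGrid.from_dataset(test)
    loss = brier_loss(train)
    manifest = {"config": {**config.__dict__}, "seeds": seeds,
                "train_n": train.n, "test_n": test.n, "stages": []}

    for spec, stage_seed in zip(config.explainers, seeds[4:]):
        spec = dict(spec)
        method = spec.pop("method")
        t1 = time.time()
        name = method + ("_" + spec["feature"] if "feature" in spec else "")
        path = out / f"{name}.csv"
        if method in ("ice", "pdp", "mplot", "ale"):
            feat = spec.pop("feature")
            center = spec.pop("center", None)
            marginal = spec.pop("time_marginal", False)
            if method == "ale":
                curves = effects.ale(model, test, feat, time_grid=grid, **spec)
            elif method == "mplot":
                curves = effects.mplot(model, test, feat, time_grid=grid, **spec)
            else:
                fn = effects.ice if method == "ice" else effects.pdp
                curves = fn(model, test, feat, time_grid=grid,
                            center_at=center, **spec)
            if marginal:
                curves = effects.marginalize_time(curves)
            curves.to_csv(path, seed=stage_seed)
        elif method == "h_two_way":
            res = interactions.h_two_way(model, test, spec.pop("feature"),
                                         spec.pop("with_feature"),
                                         time_grid=grid, seed=stage_seed, **spec)
            res.to_csv(path)
        elif method == "h_total":
            res = interactions.h_total(model, test, spec.pop("feature"),
                                       time_grid=grid, seed=stage_seed, **spec)
            res.to_csv(path)
        elif method == "pfi":
            res = importance.pfi(model, test, loss, seed=stage_seed,
                                 time_grid=grid, **spec)
            importance.save_importances(res, path)
        elif method == "cpi":
            res = importance.cpi(model, test, loss, seed=stage_seed,
                                 time_grid=grid, **spec)
            importance.save_importances(res, path)
        elif method == "loco":
            res = importance.loco(model, train, test, loss, time_grid=grid,
                                  **spec)
            importance.save_importances(res, path)
        elif method == "survlime":
            row = spec.pop("row", 0)
            res = local.survlime(model, train, test.features.iloc[row],
                                 seed=stage_seed, time_grid=grid, **spec)
            path.with_suffix(".json").write_text(json.dumps({
                "coefficients": res.coefficients.to_dict(),
                "fidelity": res.fidelity, "seed": res.seed}))
        elif method == "survshap":
            row = spec.pop("row", 0)
            bg = train.features.iloc[:spec.pop("background_size", 100)]
            res = local.survshap_kernel(model, bg, test.features.iloc[row],
                                        seed=stage_seed, time_grid=grid, **spec)
            res.phi.assign(feature=res.phi.index).to_csv(path, index=False)
        elif method == "counterfactual":
            row = spec.pop("row", 0)
            bounds = spec.pop("feature_bounds", None) or {
                f: (float(train.features[f].min()), float(train.features[f].max()))
                for f in train.feature_names}
            res = local.counterfactual(model, test.features.iloc[row],
                                       spec.pop("r", 0.5), spec.pop("C", 0.1),
                                       bounds, seed=stage_seed, time_grid=grid,
                                       **spec)
            path.with_suffix(".json").write_text(json.dumps({
                "counterfactual": res.counterfactual.to_dict(),
                "hinge": res.hinge, "distance": res.distance,
                "rmst_original": res.rmst_original,
                "rmst_counterfactual": res.rmst_counterfactual,
                "converged": res.converged}))
        elif method == "brier":
            preds = model.predict_survival(test.features, grid)
            brier_curve(test, preds, grid, censoring_distribution(train)).to_csv(path)
        dt = time.time() - t1
        log.info("stage %s done in %.1fs (seed %d)", name, dt, stage_seed)
        manifest["stages"].append({"method": method, "artifact": str(path),
                                   "seed": stage_seed, "seconds": dt})
    manifest["total_seconds"] = time.time() - t0
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
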