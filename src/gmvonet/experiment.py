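"""Reproducible multi-run experiment orchestration.

One experiment = preprocess -> train with a chosen optimizer -> evaluate
on the held-out split, repeated ``R`` times with per-run seeds
``master_seed + i``, then summarized (mean/best/worst/std) and compared
pairwise with a Wilcoxon rank-sum test on accuracy.  A data-fraction
scaling mode re-runs the full cycle on stratified subsamples.

Optimizer registry: ``mvo`` and ``gmvo`` train the network by population
search over its flattened weights; ``sgdm`` and ``adam`` are the
mini-batch gradient baselines.  Third-party trainers (e.g. other
gradient-metaheuristic hybrids) can be plugged in via
:func:`register_optimizer`.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .data import (
    Dataset,
    SyntheticConfig,
    generate_synthetic,
    load_uci,
    minmax_fit_apply,
    preprocess,
    split_train_test,
)
from .gradients import GradientTrainerConfig, train_gradient
from .metrics import compute_metrics, rank_sum_test, summarize_runs
from .network import NetworkSpec, predict, train_population
from .optimizer import OptimizerConfig

__all__ = [
    "ExperimentConfig",
    "register_optimizer",
    "available_optimizers",
    "spec_for_features",
    "run_single",
    "run_comparison",
    "run_fraction_scaling",
]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a comparison experiment."""

    source: str = "synthetic"  # "synthetic" | "wbcd" | "wdbc"
    data_path: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    optimizers: tuple[str, ...] = ("gmvo",)
    repeats: int = 20
    data_fraction: float = 1.0
    train_fraction: float = 0.7
    seed: int = 0
    outdir: str | None = None
    resplit_each_run: bool = True
    population: OptimizerConfig = field(
        default_factory=lambda: OptimizerConfig(lb=-10.0, ub=10.0, n=50,
                                                max_iter=1000)
    )
    gradient: GradientTrainerConfig = field(default_factory=GradientTrainerConfig)
    history_checkpoints: int = 6

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not (0.0 < self.data_fraction <= 1.0):
            raise ValueError("data_fraction must lie in (0, 1]")


def _train_mvo(spec, train: Dataset, run_seed: int, cfg: ExperimentConfig):
    pop_cfg = replace(cfg.population, alpha=0.0, seed=run_seed)
    weights, result = train_population(spec, train.X, train.y, pop_cfg)
    return weights, list(result.history)


def _train_gmvo(spec, train: Dataset, run_seed: int, cfg: ExperimentConfig):
    pop_cfg = replace(cfg.population, seed=run_seed)
    if pop_cfg.alpha <= 0.0:
        pop_cfg = replace(pop_cfg, alpha=0.7)
    weights, result = train_population(spec, train.X, train.y, pop_cfg)
    return weights, list(result.history)


def _train_sgdm(spec, train: Dataset, run_seed: int, cfg: ExperimentConfig):
    gcfg = replace(cfg.gradient, seed=run_seed)
    weights, history = train_gradient(spec, train.X, train.y, gcfg, optimizer="sgdm")
    return weights, history["loss"]


def _train_adam(spec, train: Dataset, run_seed: int, cfg: ExperimentConfig):
    gcfg = replace(cfg.gradient, seed=run_seed)
    weights, history = train_gradient(spec, train.X, train.y, gcfg, optimizer="adam")
    return weights, history["loss"]


_REGISTRY = {
    "mvo": _train_mvo,
    "gmvo": _train_gmvo,
    "sgdm": _train_sgdm,
    "adam": _train_adam,
}


def register_optimizer(name: str, trainer) -> None:
    """Register a trainer ``f(spec, train_dataset, run_seed, cfg) ->
    (flat_weights, loss_history)`` under ``name``."""
    _REGISTRY[name] = trainer


def available_optimizers() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def spec_for_features(d_in: int) -> NetworkSpec:
    """Architecture rule: 5-3-2 hidden units for narrow (cytology-like)
    tables, 8-4-2 for wide (FNA-image-like) ones."""
    hidden = (5, 3, 2) if d_in <= 12 else (8, 4, 2)
    return NetworkSpec((d_in, *hidden, 1))


def load_experiment_dataset(cfg: ExperimentConfig) -> Dataset:
    """Materialize the experiment's dataset from its configured source."""
    if cfg.source == "synthetic":
        syn = cfg.synthetic
        if syn.seed is None:
            syn = replace(syn, seed=cfg.seed)
        return generate_synthetic(syn)
    if cfg.source in ("wbcd", "wdbc"):
        if cfg.data_path is None:
            raise ValueError(f"source {cfg.source!r} requires data_path")
        return preprocess(load_uci(cfg.data_path, cfg.source))
    raise ValueError(f"unknown source {cfg.source!r}")


def _checkpoints(history, k: int):
    if len(history) == 0:
        return []
    idx = np.linspace(0, len(history) - 1, num=min(k, len(history)), dtype=int)
    return [float(history[i]) for i in idx]


def run_single(dataset: Dataset, optimizer: str, run_seed: int,
               cfg: ExperimentConfig) -> dict:
    """One seeded train/evaluate cycle; returns a per-run record."""
    if optimizer not in _REGISTRY:
        raise ValueError(
            f"unknown optimizer {optimizer!r}; valid names: "
            f"{', '.join(available_optimizers())}"
        )
    split_seed = run_seed if cfg.resplit_each_run else cfg.seed
    train, test = split_train_test(dataset, cfg.train_fraction, seed=split_seed)
    train_n, [test_n], stats = minmax_fit_apply(train, [test])

    spec = spec_for_features(train_n.X.shape[1])
    t0 = time.perf_counter()
    weights, history = _REGISTRY[optimizer](spec, train_n, run_seed, cfg)
    elapsed = time.perf_counter() - t0

    y_pred = predict(spec, weights, test_n.X)
    counts, report = compute_metrics(test_n.y, y_pred)
    record = report.as_dict()
    record.update(
        seed=run_seed,
        optimizer=optimizer,
        time=elapsed,
        confusion={"tp": counts.tp, "tn": counts.tn,
                   "fp": counts.fp, "fn": counts.fn},
        loss_checkpoints=_checkpoints(history, cfg.history_checkpoints),
        n_train=len(train_n),
        n_test=len(test_n),
        feature_min=stats["min"].tolist(),
        feature_max=stats["max"].tolist(),
    )
    return record


def _subsample(dataset: Dataset, fraction: float, seed: int) -> Dataset:
    if fraction >= 1.0:
        return dataset
    idx = np.arange(len(dataset))
    keep, _ = train_test_split(idx, train_size=fraction, random_state=seed,
                               stratify=dataset.y, shuffle=True)
    sub = dataset.subset(keep)
    if len(np.unique(sub.y)) < 2:
        raise ValueError(f"fraction {fraction} leaves a single class")
    return sub


def run_comparison(cfg: ExperimentConfig) -> dict:
    """Execute ``R`` seeded runs per optimizer and summarize.

    The bundle maps each optimizer to its per-run records and a
    mean/best/worst/std summary, and holds rank-sum comparisons of the
    accuracy vectors of the first optimizer against every other one.
    Fully reproducible from the config.
    """
    dataset = _subsample(load_experiment_dataset(cfg), cfg.data_fraction, cfg.seed)
    bundle: dict = {
        "config": _config_to_jsonable(cfg),
        "n_samples": len(dataset),
        "results": {},
        "rank_sum": {},
    }
    for name in cfg.optimizers:
        runs = [run_single(dataset, name, cfg.seed + i, cfg)
                for i in range(cfg.repeats)]
        bundle["results"][name] = {
            "runs": runs,
            "summary": summarize_runs(runs, times=[r["time"] for r in runs]),
        }
    first = cfg.optimizers[0]
    for other in cfg.optimizers[1:]:
        acc_first = [r["acc"] for r in bundle["results"][first]["runs"]]
        acc_other = [r["acc"] for r in bundle["results"][other]["runs"]]
        res = rank_sum_test(acc_other, acc_first)
        bundle["rank_sum"][f"{other}_vs_{first}"] = dataclasses.asdict(res)

    if cfg.outdir is not None:
        _write_bundle(bundle, cfg)
    return bundle


def run_fraction_scaling(cfg: ExperimentConfig, fractions) -> pd.DataFrame:
    """Full train/evaluate cycle per data fraction per optimizer.

    Returns one row of the six metrics per (optimizer, fraction); a
    fraction of 1.0 reproduces the first run of :func:`run_comparison`
    under the same seed.
    """
    fractions = list(fractions)
    if any(not (0.0 < f <= 1.0) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    dataset = load_experiment_dataset(cfg)
    rows = []
    for name in cfg.optimizers:
        for frac in fractions:
            sub = _subsample(dataset, frac, cfg.seed)
            rec = run_single(sub, name, cfg.seed, cfg)
            rows.append({
                "optimizer": name,
                "fraction": frac,
                "n_samples": len(sub),
                **{k: rec[k] for k in ("acc", "ppv", "spc", "sen", "f1", "mcc")},
            })
    table = pd.DataFrame(rows)
    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "fraction_scaling.csv", index=False)
    return table


def _config_to_jsonable(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key in ("population", "gradient", "synthetic"):
        d[key] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                  for k, v in d[key].items()}
    return d


def _write_bundle(bundle: dict, cfg: ExperimentConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "comparison.json", "w") as fh:
        json.dump(bundle, fh, indent=1, default=float)
    rows = []
    for name, block in bundle["results"].items():
        for r in block["runs"]:
            rows.append({
                "optimizer": name, "seed": r["seed"],
                **{k: r[k] for k in ("acc", "ppv", "spc", "sen", "f1", "mcc")},
                "time": r["time"],
            })
    pd.DataFrame(rows).to_csv(out / "per_run_metrics.csv", index=False)
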