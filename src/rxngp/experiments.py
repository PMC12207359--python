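"""End-to-end experiment drivers.

Two entry points live here:

* :func:`run_experiment` — the full factorial protocol (methods x
  support sizes x repeats) over a split manifest, producing the
  per-repeat and aggregated results tables;
* :func:`few_shot_benchmark` — a self-contained benchmark on the
  synthetic task suite: per replicate seed it generates a suite, trains
  the four meta-learners, and meta-tests them across support sizes.
  This is the basis for the support-size monotonicity and
  few-shot-advantage analyses.

The benchmark runs at a reduced scale chosen for a single CPU (see
``BENCHMARK_SCALE``): 32 binary feature columns, six training tasks of
256 reactions each, meta-training episodes of 64 support / 32 query.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (ADKFClassifier, ADKFPriorClassifier, DKTClassifier,
                         PrototypicalNetworkClassifier, meta_test)
from .evaluate import aggregate_table, results_table
from .synthetic import SyntheticSpec, generate_tasks

__all__ = [
    "BENCHMARK_SCALE",
    "benchmark_spec",
    "train_all_methods",
    "few_shot_benchmark",
    "support_size_monotonicity",
    "paired_sign_test",
    "run_experiment",
]

_SEED_MAX = 2**31 - 1

#: reduced study scale for the single-CPU synthetic benchmark: tasks are
#: related but substantially distinct (large latent shift) and differ in
#: label reliability (per-task noise multiplier), the regime the
#: adaptive deep kernel methods are designed for
BENCHMARK_SCALE = {
    "n_tasks": 10,             # 6 train + 1 valid + 3 test
    "n_train_tasks": 6,
    "n_valid_tasks": 1,
    "n_per_task": 256,
    "dim": 32,
    "latent_dim": 8,
    "task_shift_scale": 1.5,
    "noise_scale": 0.5,
    "noise_heterogeneity": 0.5,
    "positive_prevalence": 0.65,
    "model": {
        "hidden_sizes": (32, 16),
        "latent_dim": 8,
        "n_iter": 60,
        "task_batch_size": 5,
        "train_support_size": 64,
        "train_query_size": 32,
        "inner_steps": 15,
        "learning_rate": 0.02,
        "val_every": 1000,      # model selection off in the benchmark
    },
}


def benchmark_spec(seed: int) -> SyntheticSpec:
    s = BENCHMARK_SCALE
    return SyntheticSpec(n_tasks=s["n_tasks"], n_per_task=s["n_per_task"],
                         dim=s["dim"], latent_dim=s["latent_dim"],
                         task_shift_scale=s["task_shift_scale"],
                         noise_scale=s["noise_scale"],
                         noise_heterogeneity=s["noise_heterogeneity"],
                         positive_prevalence=s["positive_prevalence"],
                         seed=seed)


METHODS = {
    "dkt": DKTClassifier,
    "adkf": ADKFClassifier,
    "adkf_prior": ADKFPriorClassifier,
    "protonet": PrototypicalNetworkClassifier,
}


def train_all_methods(X, y, train_tasks, valid_tasks, seed: int,
                      model_config: dict | None = None,
                      methods=tuple(METHODS)) -> dict:
    """Fit every requested meta-learner on one task suite."""
    cfg = dict(BENCHMARK_SCALE["model"])
    cfg.update(model_config or {})
    out = {}
    for name in methods:
        model = METHODS[name](random_state=seed, **cfg)
        model.fit(X, y, train_tasks, valid_tasks=valid_tasks)
        out[name] = model
    return out


def few_shot_benchmark(n_seeds: int = 20, base_seed: int = 0,
                       support_sizes=(8, 16, 32, 64, 128),
                       small_support_sizes=(5,), query_size: int = 128,
                       n_repeats: int = 2, n_small_repeats: int = 16,
                       methods=tuple(METHODS),
                       model_config: dict | None = None) -> pd.DataFrame:
    """Synthetic-suite benchmark over independent replicate seeds.

    For each replicate: generate a task suite, meta-train each method on
    the training tasks, then meta-test on each of the held-out test
    tasks at every support size (``n_repeats`` episodes per test task),
    averaging AUPRC over all episodes.  ``small_support_sizes`` are
    evaluated with more repeats for the Bayesian methods only — they are
    the basis of the ADKF-prior vs ADKF low-data comparison.

    Returns a tidy frame (method, seed, support_size, auprc), one row
    per replicate with the episode-averaged score.
    """
    s = BENCHMARK_SCALE
    n_train, n_valid = s["n_train_tasks"], s["n_valid_tasks"]
    root = np.random.SeedSequence(base_seed)
    rows = []
    for rep, child in enumerate(root.spawn(n_seeds)):
        seed = int(child.generate_state(1)[0] % _SEED_MAX)
        X, y, tasks, _ = generate_tasks(benchmark_spec(seed))
        train_tasks = tasks[:n_train]
        valid_tasks = tasks[n_train:n_train + n_valid]
        test_tasks = tasks[n_train + n_valid:]
        models = train_all_methods(X, y, train_tasks, valid_tasks, seed,
                                   model_config, methods=methods)
        for name, model in models.items():
            for sz in support_sizes:
                sc = [meta_test(model, X, y, tt, sz, query_size, n_repeats,
                                seed=seed + 1 + k)
                      for k, tt in enumerate(test_tasks)]
                rows.append((name, rep, int(sz), float(np.mean(sc))))
            for sz in small_support_sizes:
                if name not in ("adkf", "adkf_prior"):
                    continue
                sc = [meta_test(model, X, y, tt, sz, query_size,
                                n_small_repeats, seed=seed + 101 + k)
                      for k, tt in enumerate(test_tasks)]
                rows.append((name, rep, int(sz), float(np.mean(sc))))
    return pd.DataFrame(rows, columns=["method", "seed", "support_size",
                                       "auprc"])


def support_size_monotonicity(bench: pd.DataFrame, method: str,
                              support_sizes=(8, 16, 32, 64, 128)):
    """Spearman correlation of mean AUPRC with support size for a method."""
    sub = bench[(bench.method == method)
                & bench.support_size.isin(support_sizes)]
    curve = sub.groupby("support_size")["auprc"].mean()
    curve = curve.loc[list(support_sizes)]
    rho, p = stats.spearmanr(np.asarray(support_sizes), curve.to_numpy())
    return float(rho), float(p), curve


def paired_sign_test(bench: pd.DataFrame, method_a: str, method_b: str,
                     support_size: int):
    """One-sided sign test that method_a beats method_b per seed."""
    a = (bench[(bench.method == method_a)
               & (bench.support_size == support_size)]
         .set_index("seed")["auprc"])
    b = (bench[(bench.method == method_b)
               & (bench.support_size == support_size)]
         .set_index("seed")["auprc"])
    diff = (a - b).dropna()
    wins = int((diff > 0).sum())
    losses = int((diff < 0).sum())
    n = wins + losses
    if n == 0:
        return wins, losses, 1.0
    p = stats.binomtest(wins, n, 0.5, alternative="greater").pvalue
    return wins, losses, float(p)


def run_experiment(X, y, split: dict, methods=tuple(METHODS),
                   support_sizes=(8, 16, 32, 64, 128), query_size: int = 128,
                   n_repeats: int = 10, seed: int = 0, split_mode="random",
                   dispersion_kind="sd", model_config: dict | None = None):
    """Full factorial evaluation over methods x support sizes x repeats.

    ``split`` maps 'train'/'valid'/'test' to task lists (a single test
    Task is accepted).  Returns the per-repeat and aggregated tables.
    """
    train_tasks = split["train"]
    valid_tasks = split.get("valid") or None
    test_tasks = split["test"]
    if not isinstance(test_tasks, (list, tuple)):
        test_tasks = [test_tasks]
    models = train_all_methods(X, y, train_tasks, valid_tasks, seed,
                               model_config, methods=methods)
    rows = []
    for name, model in models.items():
        for combo, test_task in enumerate(test_tasks):
            for s in support_sizes:
                usable = len(test_task) - s
                q = min(query_size, usable)
                if q < 1:
                    continue
                scores = meta_test(model, X, y, test_task, s, q,
                                   n_repeats, seed=seed + 17)
                for r, sc in enumerate(scores):
                    rows.append((name, split_mode, combo, int(s), r, float(sc)))
    per_repeat = results_table(rows)
    return per_repeat, aggregate_table(per_repeat, dispersion_kind)
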