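"""Repeated k-fold cross-validation and the GA architecture search.

Model performance is summarized under an 8-fold cross-validation plan with
10 repeats (80 train/test splits).  Pooled test metrics are computed on the
concatenation of all out-of-fold predictions in original units, pooled
training metrics on the concatenated in-fold predictions.

Folds are assigned at the row (replicate) level to mirror the source study's
row counts.  Replicates of one substrate are near-twins, so row-level folds
carry an optimistic bias; ``group_by_substrate=True`` instead keeps all rows
of a substrate in the same fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .ga import GAConfig, run_ga
from .mlp import FitMetrics, compute_metrics

__all__ = ["CVPlan", "CVResult", "make_folds", "cross_validate", "search_hidden_neurons"]


class SupportsPredict(Protocol):
    def predict(self, X: np.ndarray) -> np.ndarray: ...


#: A model factory trains on (X, y) in original units and returns a predictor.
ModelFactory = Callable[[np.ndarray, np.ndarray], SupportsPredict]


@dataclass(frozen=True)
class CVPlan:
    """k folds × repeats, shuffled deterministically per seed."""

    k: int = 8
    repeats: int = 10
    seed: int = 0
    group_by_substrate: bool = False

    def __post_init__(self) -> None:
        if self.k < 2 or self.repeats < 1:
            raise ValueError("need k >= 2 and repeats >= 1")


@dataclass(frozen=True)
class CVResult:
    """All per-split metrics plus pooled train/test metrics."""

    split_train: list[FitMetrics]
    split_test: list[FitMetrics]
    pooled_train: FitMetrics
    pooled_test: FitMetrics
    n_splits: int
    factory_name: str = ""


def make_folds(n_rows: int, plan: CVPlan, groups: np.ndarray | None = None) -> np.ndarray:
    """Fold labels, shape (repeats, n_rows), each repeat an exact partition.

    Fold sizes differ by at most one.  With ``groups`` (one label per row) all
    rows sharing a label land in the same fold.
    """
    if n_rows < plan.k:
        raise ValueError(f"cannot split {n_rows} rows into {plan.k} folds")
    rng = np.random.default_rng(plan.seed)
    out = np.empty((plan.repeats, n_rows), dtype=int)
    for rep in range(plan.repeats):
        if groups is None:
            perm = rng.permutation(n_rows)
            fold = np.empty(n_rows, dtype=int)
            fold[perm] = np.arange(n_rows) % plan.k
            out[rep] = fold
        else:
            uniq = np.unique(groups)
            gperm = rng.permutation(len(uniq))
            gfold = {g: i % plan.k for i, g in enumerate(uniq[gperm])}
            out[rep] = np.array([gfold[g] for g in groups])
    return out


def cross_validate(
    model_factory: ModelFactory,
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    groups: np.ndarray | None = None,
    factory_name: str = "",
) -> CVResult:
    """Fit the factory on every training split; pool predictions across splits."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    folds = make_folds(len(y), plan, groups=groups)
    split_train, split_test = [], []
    pool_true_te, pool_pred_te = [], []
    pool_true_tr, pool_pred_tr = [], []
    for rep in range(plan.repeats):
        for fold in range(plan.k):
            test = folds[rep] == fold
            train = ~test
            try:
                model = model_factory(X[train], y[train])
            except Exception as exc:
                raise RuntimeError(f"training failed on repeat {rep}, fold {fold}: {exc}") from exc
            pred_tr = np.asarray(model.predict(X[train]), dtype=float)
            pred_te = np.asarray(model.predict(X[test]), dtype=float)
            split_train.append(compute_metrics(y[train], pred_tr))
            split_test.append(compute_metrics(y[test], pred_te))
            pool_true_te.append(y[test]); pool_pred_te.append(pred_te)
            pool_true_tr.append(y[train]); pool_pred_tr.append(pred_tr)
    return CVResult(
        split_train=split_train,
        split_test=split_test,
        pooled_train=compute_metrics(np.concatenate(pool_true_tr), np.concatenate(pool_pred_tr)),
        pooled_test=compute_metrics(np.concatenate(pool_true_te), np.concatenate(pool_pred_te)),
        n_splits=plan.k * plan.repeats,
        factory_name=factory_name,
    )


def search_hidden_neurons(
    X: np.ndarray,
    y: np.ndarray,
    factory_for_width: Callable[[int], ModelFactory],
    plan: CVPlan,
    gene_range: tuple[int, int] = (1, 25),
    ga_config: GAConfig | None = None,
) -> tuple[int, dict[int, float], "object"]:
    """GA (integer encoding) over the hidden-layer width.

    Fitness of a width is the negative pooled cross-validated test RMSE under
    ``plan``; each distinct width is evaluated once and cached, so at most
    ``gene_range`` span full CV evaluations occur no matter how many
    generations run.  Returns (best width, cache of −RMSE per width, GA outcome).
    """
    if ga_config is None:
        ga_config = GAConfig(bounds=(gene_range,), encoding="integer")
    elif ga_config.encoding != "integer":
        raise ValueError("architecture search requires integer encoding")
    cache: dict[int, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        n_hidden = int(round(chrom[0]))
        if n_hidden not in cache:
            res = cross_validate(factory_for_width(n_hidden), X, y, plan)
            cache[n_hidden] = -res.pooled_test.rmse
        return cache[n_hidden]

    outcome = run_ga(fitness, ga_config)
    best = max(cache, key=cache.get)
    return best, cache, outcome
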