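"""Ablation-based input importance: variable sensitivity error and ratio.

For each input variable, the surrogate is retrained from the same seed and
with the same hidden-layer width but *without* that input; the retrained
model's RMSE over the whole dataset is the variable sensitivity error (VSE).
The variable sensitivity ratio (VSR) is VSE divided by the full model's
RMSE, then min-max rescaled to [0, 1]; inputs are ranked by rescaled VSR,
largest (most load-bearing) first.

A cheaper mean-ablation variant — no retraining, the input is frozen at its
dataset mean — is available for comparison via ``method="mean_ablate"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mlp import MLPModel, TrainConfig, fit_surrogate

__all__ = ["VSRReport", "compute_vsr"]


@dataclass(frozen=True)
class VSRReport:
    """Per-input ablation importance; ranking is descending by rescaled VSR."""

    feature_names: tuple[str, ...]
    rmse_full: float
    vse: dict[str, float]
    vsr_raw: dict[str, float]
    vsr_rescaled: dict[str, float]
    ranking: tuple[str, ...]
    method: str
    seed: int


def _rmse(model: MLPModel, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean((model.predict(X) - y) ** 2)))


def compute_vsr(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    n_hidden: int,
    cfg: TrainConfig,
    method: str = "retrain",
    boxcox_offset: float = 1.0,
) -> VSRReport:
    """Rank input importance by retrain-without-input (or mean-ablation) RMSE."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    names = tuple(feature_names)
    if X.shape[1] != len(names) or len(names) < 2:
        raise ValueError("need >= 2 named inputs matching the columns of X")
    if method not in ("retrain", "mean_ablate"):
        raise ValueError(f"unknown method {method!r}")

    full = fit_surrogate(X, y, n_hidden, cfg, feature_names=names, boxcox_offset=boxcox_offset)
    rmse_full = _rmse(full, X, y)

    vse: dict[str, float] = {}
    for i, name in enumerate(names):
        if method == "retrain":
            keep = [j for j in range(len(names)) if j != i]
            try:
                reduced = fit_surrogate(
                    X[:, keep], y, n_hidden, cfg,
                    feature_names=tuple(names[j] for j in keep),
                    boxcox_offset=boxcox_offset,
                )
            except Exception as exc:
                raise RuntimeError(f"retraining without input {name!r} failed: {exc}") from exc
            vse[name] = _rmse(reduced, X[:, keep], y)
        else:
            Xa = X.copy()
            Xa[:, i] = X[:, i].mean()
            vse[name] = float(np.sqrt(np.mean((full.predict(Xa) - y) ** 2)))

    vsr_raw = {k: v / rmse_full for k, v in vse.items()}
    vals = np.array([vsr_raw[k] for k in names])
    span = vals.max() - vals.min()
    rescaled = (vals - vals.min()) / span if span > 0 else np.zeros_like(vals)
    vsr_rescaled = dict(zip(names, rescaled.tolist()))
    ranking = tuple(sorted(names, key=lambda k: -vsr_rescaled[k]))
    return VSRReport(
        feature_names=names,
        rmse_full=rmse_full,
        vse=vse,
        vsr_raw=vsr_raw,
        vsr_rescaled=vsr_rescaled,
        ranking=ranking,
        method=method,
        seed=cfg.seed,
    )
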