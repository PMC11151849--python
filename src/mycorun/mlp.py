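"""The three-layer perceptron surrogate.

One hidden layer of tanh ("tansig") units and a linear output unit:

    y = w2 · tanh(W1 x + b1) + b2

The network is trained by full-batch gradient descent with an adaptive
moment-estimation update on the mean-squared error, with early stopping on a
held-out validation split.  Training happens in transformed space — inputs
min-max scaled to [-1, 1], response Box–Cox normalized — and predictions are
mapped back to original units (cm, cm d⁻¹) through the attached transforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .preprocess import (
    BoxCoxTransform,
    FeatureScaler,
    boxcox_forward,
    boxcox_inverse,
    fit_boxcox,
    fit_feature_scaler,
)

__all__ = [
    "MLPModel",
    "TrainConfig",
    "FitMetrics",
    "TrainingDivergence",
    "init_mlp",
    "mlp_forward",
    "train_mlp",
    "fit_surrogate",
    "compute_metrics",
    "save_model",
    "load_model",
]


class TrainingDivergence(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class MLPModel:
    """A 1-hidden-layer tanh network plus its input/output transforms."""

    n_inputs: int
    n_hidden: int
    W1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    feature_names: tuple[str, ...] = ()
    x_scaler: Optional[FeatureScaler] = None
    y_transform: Optional[BoxCoxTransform] = None
    train_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.W1.shape != (self.n_hidden, self.n_inputs) or self.b1.shape != (self.n_hidden,) or self.w2.shape != (self.n_hidden,):
            raise ValueError("weight array shapes inconsistent with (n_inputs, n_hidden, 1)")
        for arr in (self.W1, self.b1, self.w2):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite network weights")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict in original response units for inputs in original units."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.x_scaler is not None:
            X = self.x_scaler.apply(X)
        y = mlp_forward(self, X)
        if self.y_transform is not None:
            y = boxcox_inverse(self.y_transform, y, clip=True)
        return y


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-training settings (the study names no optimizer; these are ours)."""

    seed: int = 0
    max_epochs: int = 1500
    learning_rate: float = 0.02
    lr_decay: float = 1.0  # multiplicative per-epoch decay of the step size
    patience: int = 150  # early-stop patience on validation MSE
    val_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.max_epochs < 0 or self.learning_rate <= 0 or self.patience <= 0:
            raise ValueError("max_epochs >= 0, learning_rate > 0, patience > 0 required")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction in [0, 1) required")


@dataclass(frozen=True)
class FitMetrics:
    """Goodness-of-fit summary: R², RMSE, MAE, and MAPE over nonzero targets."""

    r2: float
    rmse: float
    mae: float
    mape: float


def init_mlp(n_inputs: int, n_hidden: int, seed: int) -> MLPModel:
    """Xavier-uniform initialization; deterministic per seed."""
    if n_inputs < 1 or n_hidden < 1:
        raise ValueError("n_inputs and n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    lim1 = np.sqrt(6.0 / (n_inputs + n_hidden))
    lim2 = np.sqrt(6.0 / (n_hidden + 1))
    return MLPModel(
        n_inputs=n_inputs,
        n_hidden=n_hidden,
        W1=rng.uniform(-lim1, lim1, size=(n_hidden, n_inputs)),
        b1=np.zeros(n_hidden),
        w2=rng.uniform(-lim2, lim2, size=n_hidden),
        b2=0.0,
        train_seed=seed,
    )


def mlp_forward(model: MLPModel, X_scaled: np.ndarray) -> np.ndarray:
    """Network output in transformed space for pre-scaled inputs."""
    X = np.atleast_2d(np.asarray(X_scaled, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} input columns, got {X.shape[1]}")
    H = np.tanh(X @ model.W1.T + model.b1)
    return H @ model.w2 + model.b2


def _mse(model_params, X, y):
    W1, b1, w2, b2 = model_params
    H = np.tanh(X @ W1.T + b1)
    r = H @ w2 + b2 - y
    return float(r @ r) / len(y)


def train_mlp(model: MLPModel, X: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> tuple[MLPModel, list[float]]:
    """Train on (scaled X, transformed y); returns the model and the loss history.

    The returned weights are the best-validation snapshot (best-training when
    ``val_fraction`` is 0), so the final training MSE never exceeds the
    initial one.  ``max_epochs=0`` returns the model unchanged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(X) != len(y) or len(y) < 10:
        raise ValueError("need matched X, y with at least 10 rows")
    if cfg.max_epochs == 0:
        return model, []

    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    n_val = int(round(cfg.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = (X[val_idx], y[val_idx]) if n_val else (Xtr, ytr)

    W1, b1 = model.W1.copy(), model.b1.copy()
    w2, b2 = model.w2.copy(), float(model.b2)
    params = [W1, b1, w2, np.array([b2])]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = cfg.learning_rate

    best_val = np.inf
    best = [p.copy() for p in params]
    stall = 0
    history: list[float] = []
    ntr = len(ytr)

    for epoch in range(1, cfg.max_epochs + 1):
        A = Xtr @ params[0].T + params[1]
        H = np.tanh(A)
        pred = H @ params[2] + params[3][0]
        resid = pred - ytr
        loss = float(resid @ resid) / ntr
        if not np.isfinite(loss):
            raise TrainingDivergence(f"non-finite training loss at epoch {epoch}")
        history.append(loss)

        g_out = 2.0 * resid / ntr
        g_hidden = (g_out[:, None] * params[2]) * (1.0 - H * H)  # (n, h)
        grads = [
            g_hidden.T @ Xtr,  # dW1
            g_hidden.sum(axis=0),  # db1
            H.T @ g_out,  # dw2
            np.array([g_out.sum()]),  # db2
        ]
        for i, (p, g) in enumerate(zip(params, grads)):
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g * g
            mhat = m[i] / (1 - beta1**epoch)
            vhat = v[i] / (1 - beta2**epoch)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        lr *= cfg.lr_decay

        val_loss = _mse(( params[0], params[1], params[2], params[3][0]), Xval, yval)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best = [p.copy() for p in params]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    trained = replace(
        model,
        W1=best[0], b1=best[1], w2=best[2], b2=float(best[3][0]),
        train_seed=cfg.seed,
    )
    return trained, history


def fit_surrogate(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    cfg: TrainConfig,
    feature_names: Sequence[str] = (),
    boxcox_offset: float = 1.0,
    boxcox_lmbda: Optional[float] = None,
) -> MLPModel:
    """End-to-end fit in original units: scale X, Box–Cox y, train the network.

    ``boxcox_lmbda`` fixes the power (e.g. one estimated on the full dataset);
    when None it is profile-likelihood estimated on the training response.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    scaler = fit_feature_scaler(X, mode="minmax")
    if boxcox_lmbda is None:
        bc = fit_boxcox(y, offset=boxcox_offset)
    else:
        bc = BoxCoxTransform(lmbda=boxcox_lmbda, offset=boxcox_offset)
    model = init_mlp(X.shape[1], n_hidden, seed=cfg.seed)
    model = replace(model, feature_names=tuple(feature_names), x_scaler=scaler, y_transform=bc)
    trained, _ = train_mlp(model, scaler.apply(X), boxcox_forward(bc, y), cfg)
    return trained


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> FitMetrics:
    """R², RMSE, MAE; MAPE averaged over rows with nonzero truth."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or len(y_true) < 2:
        raise ValueError("y_true and y_pred must have equal length >= 2")
    resid = y_true - y_pred
    ss_res = float(resid @ resid)
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    nz = y_true != 0
    mape = float(np.mean(np.abs(resid[nz] / y_true[nz]))) if nz.any() else 0.0
    return FitMetrics(
        r2=r2,
        rmse=float(np.sqrt(ss_res / len(y_true))),
        mae=float(np.abs(resid).mean()),
        mape=mape,
    )


def _scaler_to_dict(s: Optional[FeatureScaler]):
    if s is None:
        return None
    return {"mode": s.mode, "center": s.center.tolist(), "scale": s.scale.tolist()}


def save_model(model: MLPModel, path) -> None:
    """Serialize to JSON; floats survive the round trip bit-exactly."""
    doc = {
        "n_inputs": model.n_inputs,
        "n_hidden": model.n_hidden,
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2,
        "feature_names": list(model.feature_names),
        "x_scaler": _scaler_to_dict(model.x_scaler),
        "y_transform": None if model.y_transform is None else {"lmbda": model.y_transform.lmbda, "offset": model.y_transform.offset},
        "train_seed": model.train_seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> MLPModel:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    scaler = doc["x_scaler"]
    bc = doc["y_transform"]
    return MLPModel(
        n_inputs=doc["n_inputs"],
        n_hidden=doc["n_hidden"],
        W1=np.array(doc["W1"], dtype=float),
        b1=np.array(doc["b1"], dtype=float),
        w2=np.array(doc["w2"], dtype=float),
        b2=float(doc["b2"]),
        feature_names=tuple(doc["feature_names"]),
        x_scaler=None if scaler is None else FeatureScaler(scaler["mode"], np.array(scaler["center"]), np.array(scaler["scale"])),
        y_transform=None if bc is None else BoxCoxTransform(lmbda=bc["lmbda"], offset=bc["offset"]),
        train_seed=doc["train_seed"],
    )
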