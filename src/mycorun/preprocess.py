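"""Response normalization, feature scaling, and the PCA outlier screen.

The response variables (running length / running rate) are Box–Cox
normalized before model fitting; an additive offset of 1 is applied first
because the no-growth control contributes exact zeros, which the plain power
transform cannot accept.  Inputs are designed factor levels and are only
min-max scaled (to [-1, 1], where the tanh hidden layer is well conditioned),
never power-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "BoxCoxTransform",
    "FeatureScaler",
    "fit_boxcox",
    "boxcox_forward",
    "boxcox_inverse",
    "fit_feature_scaler",
    "pca_outlier_screen",
]


@dataclass(frozen=True)
class BoxCoxTransform:
    """Box–Cox power transform y = ((x + offset)^lambda - 1) / lambda (log at 0)."""

    lmbda: float
    offset: float = 0.0


def fit_boxcox(values: np.ndarray, offset: float = 0.0) -> BoxCoxTransform:
    """Estimate the Box–Cox power by profile maximum likelihood.

    All shifted values must be strictly positive; a constant vector has no
    information about the power and is rejected.
    """
    x = np.asarray(values, dtype=float) + offset
    if np.any(x <= 0):
        raise ValueError(
            "Box-Cox requires strictly positive shifted values; increase the offset "
            f"(min shifted value = {x.min():.6g})"
        )
    if np.ptp(x) == 0:
        raise ValueError("constant vector: Box-Cox power is unidentifiable (zero variance)")
    # Profile-likelihood maximization on a bracketed interval (scipy Brent).
    lmbda = float(stats.boxcox_normmax(x, brack=(-2.0, 2.0), method="mle"))
    return BoxCoxTransform(lmbda=lmbda, offset=offset)


def boxcox_forward(t: BoxCoxTransform, x: np.ndarray) -> np.ndarray:
    """Apply the transform; strictly increasing in x for any lambda."""
    shifted = np.asarray(x, dtype=float) + t.offset
    if np.any(shifted <= 0):
        raise ValueError("input + offset must be strictly positive")
    if t.lmbda == 0:
        return np.log(shifted)
    # expm1 formulation stays accurate as lambda -> 0
    return np.expm1(t.lmbda * np.log(shifted)) / t.lmbda


def boxcox_inverse(t: BoxCoxTransform, y: np.ndarray, clip: bool = False) -> np.ndarray:
    """Invert the transform back to original units.

    With ``clip=True``, transformed values outside the image of the forward
    map (possible for model extrapolations when lambda != 0) are clipped to
    the boundary instead of raising.
    """
    y = np.asarray(y, dtype=float)
    if t.lmbda == 0:
        return np.exp(y) - t.offset
    z = t.lmbda * y
    if np.any(z <= -1.0):
        if not clip:
            raise ValueError("value outside the range of the forward transform")
        z = np.maximum(z, -1.0 + 1e-12)
    return np.exp(np.log1p(z) / t.lmbda) - t.offset


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature affine scaler; 'minmax' maps training range to [-1, 1]."""

    mode: str  # 'minmax' or 'zscore'
    center: np.ndarray  # min (minmax) or mean (zscore)
    scale: np.ndarray  # range (minmax) or sd (zscore)

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.mode == "minmax":
            return 2.0 * (X - self.center) / self.scale - 1.0
        return (X - self.center) / self.scale

    def invert(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.asarray(Xs, dtype=float)
        if self.mode == "minmax":
            return (Xs + 1.0) / 2.0 * self.scale + self.center
        return Xs * self.scale + self.center


def fit_feature_scaler(X: np.ndarray, mode: str = "minmax") -> FeatureScaler:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if mode not in ("minmax", "zscore"):
        raise ValueError(f"unknown scaler mode {mode!r}")
    spread = np.ptp(X, axis=0)
    constant = np.flatnonzero(spread == 0)
    if constant.size:
        raise ValueError(f"constant feature(s) at column index {constant.tolist()}: cannot scale")
    if mode == "minmax":
        return FeatureScaler(mode, center=X.min(axis=0), scale=spread)
    return FeatureScaler(mode, center=X.mean(axis=0), scale=X.std(axis=0, ddof=1))


def pca_outlier_screen(X: np.ndarray, sd_threshold: float = 3.0, retained_variance: float = 0.90) -> np.ndarray:
    """Flag multivariate outliers by score distance on leading components.

    Columns are standardized, components retained up to ``retained_variance``
    explained variance, and each row's whitened score distance is compared
    against ``sd_threshold`` robust standard deviations (median + MAD scale)
    of the score-distance distribution.  Returns the flagged row indices
    (empty when no outliers are present).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than features ({p})")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0) or np.linalg.matrix_rank(np.cov(X, rowvar=False)) < p:
        raise ValueError("degenerate covariance: remove constant/duplicated columns or rows")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=min(n - 1, p), svd_solver="full")
    scores = pca.fit_transform(Z)
    k = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), retained_variance) + 1)
    k = min(k, scores.shape[1])
    whitened = scores[:, :k] / np.sqrt(pca.explained_variance_[:k])
    dist = np.linalg.norm(whitened, axis=1)
    med = np.median(dist)
    mad = np.median(np.abs(dist - med)) * 1.4826
    if mad == 0:
        mad = dist.std(ddof=1) or 1.0
    return np.flatnonzero((dist - med) / mad > sd_threshold)
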