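"""Linear-regression comparators: MLR, stepwise, OLSR, PCR, PLSR.

All five fit an affine predictor of the Box–Cox-transformed response on the
raw inputs (component percentages, and running time for the length model),
so their cross-validated metrics are directly comparable with the network
surrogate's.  Predictions are inverse-transformed back to original units.

"MLR" and "OLSR" are the same least-squares estimator reported under both of
the source study's labels; they carry distinct method tags and identical
predictions.  PCR standardizes features before extracting components —
otherwise the large-variance composition axes (0–100) would crowd out the
time axis (5–40) in the retained-variance cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import statsmodels.api as sm
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .preprocess import BoxCoxTransform, boxcox_forward, boxcox_inverse, fit_boxcox

__all__ = ["LinearModelFit", "fit_mlr", "fit_olsr", "fit_stepwise", "fit_pcr", "fit_plsr", "baseline_factory", "BASELINE_METHODS"]

BASELINE_METHODS = ("mlr", "stepwise", "olsr", "pcr", "plsr")


@dataclass(frozen=True)
class LinearModelFit:
    """An affine predictor in original feature order, on the transformed response."""

    method: str
    coef: np.ndarray  # one coefficient per original feature (zeros for dropped terms)
    intercept: float
    y_transform: Optional[BoxCoxTransform] = None
    n_components: Optional[int] = None
    selected: Optional[tuple[int, ...]] = None  # stepwise: retained feature indices

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coef)) or not np.isfinite(self.intercept):
            raise ValueError("non-finite coefficients")

    def predict_transformed(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict in original response units."""
        z = self.predict_transformed(X)
        if self.y_transform is None:
            return z
        return boxcox_inverse(self.y_transform, z, clip=True)


def _lstsq_fit(X: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, float]:
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 rows (n={n}, p={p})")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < p + 1:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(A, z, rcond=None)
    return beta[1:], float(beta[0])


def _prepare(X, y, y_transform, boxcox_offset):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if y_transform is None:
        y_transform = fit_boxcox(y, offset=boxcox_offset)
    z = boxcox_forward(y_transform, y)
    return X, z, y_transform


def fit_mlr(X, y, y_transform: Optional[BoxCoxTransform] = None, boxcox_offset: float = 1.0, method: str = "mlr") -> LinearModelFit:
    """Multiple linear regression by least squares (QR-based solve)."""
    X, z, t = _prepare(X, y, y_transform, boxcox_offset)
    coef, intercept = _lstsq_fit(X, z)
    return LinearModelFit(method=method, coef=coef, intercept=intercept, y_transform=t)


def fit_olsr(X, y, y_transform: Optional[BoxCoxTransform] = None, boxcox_offset: float = 1.0) -> LinearModelFit:
    """Ordinary least squares: the same estimator as MLR under its own tag."""
    return fit_mlr(X, y, y_transform=y_transform, boxcox_offset=boxcox_offset, method="olsr")


def fit_stepwise(
    X,
    y,
    y_transform: Optional[BoxCoxTransform] = None,
    boxcox_offset: float = 1.0,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> LinearModelFit:
    """Bidirectional stepwise selection by partial-F p-values from the empty model.

    Ties break toward the lowest p-value then the lowest feature index; an
    intercept-only model is a legitimate result.
    """
    X, z, t = _prepare(X, y, y_transform, boxcox_offset)
    n, p = X.shape
    selected: list[int] = []

    def pvalues(cols: list[int]) -> np.ndarray:
        A = sm.add_constant(X[:, cols], has_constant="add")
        fit = sm.OLS(z, A).fit()
        return fit.pvalues[1:]

    changed, steps = True, 0
    while changed and steps < 4 * p * p + 8:  # cycle guard for enter/remove thrashing
        steps += 1
        changed = False
        # forward step: best candidate by its partial-F (== coefficient t-test) p-value
        candidates = [j for j in range(p) if j not in selected]
        best_j, best_p = None, np.inf
        for j in candidates:
            pv = pvalues(selected + [j])[-1]
            if pv < best_p - 1e-15 or (abs(pv - best_p) <= 1e-15 and (best_j is None or j < best_j)):
                best_j, best_p = j, pv
        if best_j is not None and best_p < alpha_enter:
            selected.append(best_j)
            changed = True
        # backward step: drop the worst retained term if it no longer earns its place
        if selected:
            pv = pvalues(selected)
            worst = int(np.argmax(pv))
            if pv[worst] > alpha_remove and len(selected) > 0:
                if not (changed and selected[worst] == best_j):  # never drop the term just added
                    del selected[worst]
                    changed = True

    coef = np.zeros(p)
    if selected:
        sub_coef, intercept = _lstsq_fit(X[:, selected], z)
        coef[selected] = sub_coef
    else:
        intercept = float(z.mean())
    return LinearModelFit(method="stepwise", coef=coef, intercept=intercept, y_transform=t, selected=tuple(sorted(selected)))


def fit_pcr(X, y, n_components: Optional[int] = None, y_transform: Optional[BoxCoxTransform] = None, boxcox_offset: float = 1.0) -> LinearModelFit:
    """Principal-component regression on standardized features.

    Default component count: the smallest number explaining >= 95% of the
    (standardized) feature variance.  Coefficients are mapped back to the
    original feature space, so the fit is an ordinary affine predictor.
    """
    X, z, t = _prepare(X, y, y_transform, boxcox_offset)
    n, p = X.shape
    if n_components is not None and n_components > p:
        raise ValueError(f"n_components={n_components} exceeds {p} features")
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant feature: cannot standardize for PCR")
    Z = (X - mu) / sd
    pca = PCA(n_components=p, svd_solver="full")
    scores = pca.fit_transform(Z)
    if n_components is None:
        n_components = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), 0.95) + 1)
        n_components = min(n_components, p)
    S = scores[:, :n_components]
    gamma, intercept_s = _lstsq_fit(S, z)
    # fold standardization and rotation back into original-feature coefficients
    coef = (pca.components_[:n_components].T @ gamma) / sd
    intercept = intercept_s - float(mu @ coef)
    return LinearModelFit(method="pcr", coef=coef, intercept=intercept, y_transform=t, n_components=n_components)


def _pls_cv_components(X: np.ndarray, z: np.ndarray, max_components: int, k: int = 5) -> int:
    """Pick the component count by deterministic k-fold CV on the training data."""
    n = len(z)
    fold = np.arange(n) % k
    best_c, best_mse = 1, np.inf
    for c in range(1, max_components + 1):
        errs = []
        for f in range(k):
            tr, te = fold != f, fold == f
            pls = PLSRegression(n_components=c, scale=True)
            pls.fit(X[tr], z[tr])
            errs.append(np.mean((pls.predict(X[te]).ravel() - z[te]) ** 2))
        mse = float(np.mean(errs))
        if mse < best_mse - 1e-12:
            best_c, best_mse = c, mse
    return best_c


def fit_plsr(X, y, n_components: Optional[int] = None, y_transform: Optional[BoxCoxTransform] = None, boxcox_offset: float = 1.0) -> LinearModelFit:
    """Partial least squares (NIPALS) regression.

    Latent directions maximize covariance with the response; the fitted map
    is affine, so it is stored as coefficients in the original feature space.
    Default component count is chosen by 5-fold CV within the training data.
    """
    X, z, t = _prepare(X, y, y_transform, boxcox_offset)
    p = X.shape[1]
    if np.ptp(z) == 0:
        raise ValueError("zero-variance response")
    if n_components is None:
        n_components = _pls_cv_components(X, z, max_components=p)
    if n_components > p:
        raise ValueError(f"n_components={n_components} exceeds {p} features")
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X, z.reshape(-1, 1))
    coef = pls.coef_.ravel()  # already in original (unscaled) feature units
    intercept = float(pls.intercept_.ravel()[0] - pls._x_mean @ coef)
    return LinearModelFit(method="plsr", coef=coef, intercept=intercept, y_transform=t, n_components=n_components)


def baseline_factory(method: str, y_transform: Optional[BoxCoxTransform] = None, boxcox_offset: float = 1.0):
    """A model factory (X, y) -> fitted LinearModelFit for cross-validation."""
    fitters = {
        "mlr": fit_mlr,
        "olsr": fit_olsr,
        "stepwise": fit_stepwise,
        "pcr": fit_pcr,
        "plsr": fit_plsr,
    }
    if method not in fitters:
        raise ValueError(f"unknown baseline {method!r}; choose from {BASELINE_METHODS}")
    fitter = fitters[method]

    def factory(X, y):
        return fitter(X, y, y_transform=y_transform, boxcox_offset=boxcox_offset)

    return factory
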