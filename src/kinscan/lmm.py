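"""EMMA-style mixed-model kinship correction.

The polygenic model puts a random effect with covariance proportional to the
kinship matrix K on each phenotype, so that the residual covariance is
σ²·(h·K + (1−h)·I) for a mixing parameter h ∈ [0, 1).  Factoring
K = V·Λ·Vᵀ once, the model becomes a weighted least-squares problem in the
rotated basis Vᵀ, with weights 1/(h·λᵢ + 1−h); the fixed effects and σ² are
then available in closed form for each h, and h itself is profiled on a
one-dimensional grid.  Downstream scans run ordinary least squares on the
rotated, weighted data, so every scan statistic keeps its usual form.

Full maximum likelihood is the default; REML is available via
``method="reml"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinship import KinshipMatrix, PSD_TOL

__all__ = [
    "KinshipEigen",
    "LMMFit",
    "eigen_kinship",
    "fit_mixing_parameter",
    "rotate",
    "default_grid",
]


def default_grid(step: float = 0.01) -> np.ndarray:
    """The default profile grid for h: {0, step, ..., < 1}."""
    return np.arange(0.0, 1.0, step)


@dataclass
class KinshipEigen:
    """Spectral decomposition of a kinship matrix, eigenvalues nonincreasing."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # orthonormal columns

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    def reconstruct(self) -> np.ndarray:
        return (self.eigenvectors * self.eigenvalues[None, :]) @ self.eigenvectors.T


@dataclass
class LMMFit:
    """A profiled mixing-parameter fit for one phenotype × kinship matrix."""

    h: float
    grid: np.ndarray
    log_likelihood: np.ndarray  # profile over the grid
    weights: np.ndarray  # 1/(h·λᵢ + 1−h), strictly positive
    eigen: KinshipEigen
    sigma2: float
    beta: np.ndarray  # fixed effects of the null model at ĥ
    method: str = "ml"


def eigen_kinship(K: KinshipMatrix | np.ndarray) -> KinshipEigen:
    """Eigendecompose a symmetric PSD kinship matrix.

    Eigenvalues in (−1e−8, 0) are clipped to zero; anything more negative
    indicates upstream corruption and is fatal.
    """
    values = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("kinship matrix is not symmetric")
    vals, vecs = np.linalg.eigh(values)
    if vals.min() < -PSD_TOL * max(1.0, abs(vals.max())):
        raise ValueError(
            f"kinship matrix is not PSD (min eigenvalue {vals.min():.3e})"
        )
    vals = np.clip(vals, 0.0, None)
    order = np.argsort(vals)[::-1]
    return KinshipEigen(vals[order], vecs[:, order])


def _profile_loglik(
    yr: np.ndarray, Xr: np.ndarray, lam: np.ndarray, h: float, method: str
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Closed-form fixed effects and variance at a given h, plus the
    (restricted) log-likelihood; all in the rotated basis."""
    n, p = Xr.shape
    d = h * lam + (1.0 - h)
    w = 1.0 / d
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    XtWy = Xw.T @ yr
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular rotated design in mixed-model fit") from err
    resid = yr - Xr @ beta
    rss = float(np.sum(w * resid**2))
    if method == "reml":
        df = n - p
        sigma2 = rss / df
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            df * np.log(2 * np.pi * sigma2)
            + np.sum(np.log(d))
            + logdet_xwx
            + df
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + np.sum(np.log(d)) + n)
    return ll, beta, sigma2, w


def fit_mixing_parameter(
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    eigen: KinshipEigen,
    grid: np.ndarray | None = None,
    method: str = "ml",
) -> LMMFit:
    """Profile the variance mixing parameter h on a grid.

    The null design is an intercept plus the given covariate columns.  For
    each grid point the fixed effects and σ² are solved in closed form in
    the rotated basis; the returned fit maximizes the profile, ties broken
    toward smaller h.
    """
    y = np.asarray(phenotype, float).ravel()
    n = eigen.n
    if y.shape[0] != n:
        raise ValueError("phenotype length does not match kinship dimension")
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values; drop them upstream")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, float)
    if grid.min() < 0 or grid.max() >= 1:
        raise ValueError("grid must lie in [0, 1)")
    X = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        X = np.column_stack([X, np.asarray(covariates, float)])
    V = eigen.eigenvectors
    yr = V.T @ y
    Xr = V.T @ X

    lls = np.empty(len(grid))
    best = None
    for k, h in enumerate(grid):
        ll, beta, sigma2, w = _profile_loglik(yr, Xr, eigen.eigenvalues, h, method)
        lls[k] = ll
        if best is None or ll > best[0] + 1e-12:
            best = (ll, float(h), beta, sigma2, w)
    _, h_hat, beta, sigma2, w = best
    return LMMFit(
        h=h_hat,
        grid=grid,
        log_likelihood=lls,
        weights=w,
        eigen=eigen,
        sigma2=sigma2,
        beta=beta,
        method=method,
    )


def rotate(
    phenotype: np.ndarray,
    design_columns: np.ndarray,
    fit: LMMFit,
) -> tuple[np.ndarray, np.ndarray]:
    """Transform phenotype and design columns into the whitened basis.

    Returns (y*, X*) with y* = W^{1/2}·Vᵀ·y and likewise per design column;
    OLS on the transformed data is the GLS fit under the mixed model.  At
    h = 0 the map is an orthonormal change of basis, so all OLS statistics
    are unchanged.
    """
    y = np.asarray(phenotype, float)
    X = np.asarray(design_columns, float)
    if X.ndim == 1:
        X = X[:, None]
    n = fit.eigen.n
    if y.shape[0] != n or X.shape[0] != n:
        raise ValueError("dimension mismatch with the fitted kinship rotation")
    sw = np.sqrt(fit.weights)
    Vt = fit.eigen.eigenvectors.T
    return sw * (Vt @ y), sw[:, None] * (Vt @ X)
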