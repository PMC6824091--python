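"""Ordination of Procrustes coordinates: PCA, hypothetical shapes along PC
axes, and multivariate shape-on-size regression with optional residual PCA.

PCA is covariance-based on the flattened coordinates (the universal
geometric-morphometrics convention) with eigenvalue divisor n − 1, so the
"PC1 %" figures match conventional morphometrics software. Axes are 0-based
in code and reported 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .superimposition import AlignedSample
from .types import Configuration, MorphovarError

__all__ = [
    "PCAModel",
    "RegressionModel",
    "pca",
    "hypothetical_configuration",
    "shape_size_regression",
]


@dataclass
class PCAModel:
    """Principal components of a coordinate matrix.

    ``eigenvectors`` has one orthonormal axis per column, descending
    eigenvalue; components that are numerically zero (below ``1e-12`` of the
    leading eigenvalue) are dropped. Sign convention: the largest-magnitude
    loading of each axis is positive, which makes the output invariant to
    specimen order.
    """

    mean: np.ndarray            # (3L,)
    eigenvectors: np.ndarray    # (3L, k)
    eigenvalues: np.ndarray     # (k,) descending
    scores: np.ndarray          # (n, k)
    var_explained: np.ndarray   # (k,) sums to 1
    n_landmarks: int

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def project(self, coords: np.ndarray) -> np.ndarray:
        """Scores of one configuration (``(L, 3)`` or flat) on all axes."""
        flat = np.asarray(coords, float).reshape(-1)
        if flat.size != self.mean.size:
            raise MorphovarError(
                f"configuration has {flat.size} coordinates, model expects {self.mean.size}"
            )
        return (flat - self.mean) @ self.eigenvectors


def _as_matrix(data) -> tuple[np.ndarray, int]:
    if isinstance(data, AlignedSample):
        return data.flat, data.n_landmarks
    arr = np.asarray(data, float)
    if arr.ndim == 3:
        return arr.reshape(arr.shape[0], -1), arr.shape[1]
    if arr.ndim == 2:
        if arr.shape[1] % 3:
            raise MorphovarError("flattened coordinate matrix width must be 3L")
        return arr, arr.shape[1] // 3
    raise MorphovarError("expected AlignedSample, (n, L, 3) or (n, 3L) array")


def pca(data: AlignedSample | np.ndarray) -> PCAModel:
    """Covariance PCA of (aligned) coordinates; requires n >= 3 specimens."""
    X, L = _as_matrix(data)
    n = X.shape[0]
    if n < 3:
        raise MorphovarError(f"PCA needs at least 3 specimens, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    if eig[0] <= 0:
        # degenerate sample (all specimens identical): keep one zero component
        # so downstream code can see the zero total variance explicitly
        V = np.zeros((X.shape[1], 1))
        V[0, 0] = 1.0
        return PCAModel(
            mean=mean,
            eigenvectors=V,
            eigenvalues=np.zeros(1),
            scores=np.zeros((n, 1)),
            var_explained=np.zeros(1),
            n_landmarks=L,
        )
    keep = eig > eig[0] * 1e-12
    eig, vt = eig[keep], vt[keep]
    V = vt.T
    # deterministic sign: largest-|loading| entry of each axis positive
    for j in range(V.shape[1]):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    scores = Xc @ V
    return PCAModel(
        mean=mean,
        eigenvectors=V,
        eigenvalues=eig,
        scores=scores,
        var_explained=eig / eig.sum(),
        n_landmarks=L,
    )


def hypothetical_configuration(model: PCAModel, axis: int, score: float) -> Configuration:
    """Reconstructed shape ``mean + score * eigenvector(axis)``.

    ``axis`` is 0-based (axis 0 = PC1). ``score = 0`` returns the consensus.
    """
    if not 0 <= axis < model.n_components:
        raise MorphovarError(
            f"axis {axis} out of range (model has {model.n_components} components)"
        )
    flat = model.mean + float(score) * model.eigenvectors[:, axis]
    return Configuration(
        f"hypothetical_pc{axis + 1}@{score:.6g}", flat.reshape(model.n_landmarks, 3)
    )


@dataclass
class RegressionModel:
    """Multivariate OLS of shape on a covariate.

    For a scalar covariate, ``coefficients`` is the 3L shape change per unit
    covariate and ``regression_scores`` is the projection of centred shapes
    onto the normalized coefficient vector (the x-axis of conventional
    allometry plots). ``fitted + residuals`` reconstructs the data exactly.
    """

    coefficients: np.ndarray | None   # (3L,) scalar covariate only
    fitted: np.ndarray                # (n, 3L) including the mean
    residuals: np.ndarray             # (n, 3L)
    regression_scores: np.ndarray | None
    r_squared: float
    covariate: np.ndarray
    mean: np.ndarray

    @property
    def residual_coords(self) -> np.ndarray:
        """Residuals re-centred on the mean shape, as (n, 3L)."""
        return self.residuals + self.mean


def shape_size_regression(
    aligned: AlignedSample | np.ndarray,
    covariate,
    residual_pca: bool = False,
) -> RegressionModel | tuple[RegressionModel, PCAModel]:
    """OLS of every Procrustes coordinate on a covariate (allometry fit).

    A numeric covariate is used as-is (centred); a non-numeric covariate is
    treated as a factor and dummy-coded. With ``residual_pca=True`` a PCA of
    the residual coordinates is returned alongside (size-free morphospace).
    """
    X, _ = _as_matrix(aligned)
    n = X.shape[0]
    cov = np.asarray(covariate)
    if cov.shape[0] != n:
        raise MorphovarError(f"covariate length {cov.shape[0]} != n specimens {n}")
    mean = X.mean(axis=0)
    Xc = X - mean

    if cov.dtype.kind in "fiu":
        x = cov.astype(float)
        xc = x - x.mean()
        ss_x = float(xc @ xc)
        if ss_x == 0.0:
            raise MorphovarError("constant covariate: regression undefined")
        b = (Xc.T @ xc) / ss_x
        fitted_c = np.outer(xc, b)
        coefficients = b
        scores = Xc @ (b / np.linalg.norm(b)) if np.linalg.norm(b) > 0 else np.zeros(n)
    else:
        levels, codes = np.unique(cov, return_inverse=True)
        if levels.size < 2:
            raise MorphovarError("constant covariate: regression undefined")
        D = np.eye(levels.size)[codes][:, 1:]  # reference-coded dummies
        Dc = D - D.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Dc, Xc, rcond=None)
        fitted_c = Dc @ beta
        coefficients = None
        scores = None

    residuals = Xc - fitted_c
    ss_tot = float((Xc**2).sum())
    r2 = float((fitted_c**2).sum() / ss_tot) if ss_tot > 0 else 0.0
    model = RegressionModel(
        coefficients=coefficients,
        fitted=fitted_c + mean,
        residuals=residuals,
        regression_scores=scores,
        r_squared=r2,
        covariate=cov,
        mean=mean,
    )
    if residual_pca:
        return model, pca(model.residual_coords)
    return model
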