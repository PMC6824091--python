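"""Generalized Procrustes analysis (GPA), centroid size, Procrustes distances.

The fit is partial Procrustes: configurations are centred, scaled to unit
centroid size (when scaling is on) and rotated — reflections excluded — to
the running consensus until the consensus stops moving. Because Procrustes
coordinates are defined only up to a global rotation, the converged sample is
re-oriented to the principal axes of the consensus (largest-variance axis
first, deterministic sign convention) so that repeated runs and permuted
input orders produce identical coordinates up to that canonical frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Configuration, MorphovarError, Sample

__all__ = [
    "AlignedSample",
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "optimal_rotation",
]


def centroid_size(config: Configuration | np.ndarray) -> float:
    """Square root of summed squared landmark distances from their centroid."""
    coords = config.coords if isinstance(config, Configuration) else np.asarray(config, float)
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise MorphovarError("degenerate shape: all landmarks coincide")
    return cs


def optimal_rotation(b: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Rotation ``R`` (3x3, det +1) minimizing ``||b @ R - a||`` over rotations.

    Reflections are excluded: the smallest singular direction is sign-flipped
    when the unconstrained orthogonal solution would be improper.
    """
    m = b.T @ a
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    return u @ np.diag([1.0, 1.0, d]) @ vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the flattened coordinate difference.

    Both inputs must already live in a common Procrustes frame; no
    re-alignment is performed.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise MorphovarError(f"mismatched configurations: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


@dataclass
class AlignedSample:
    """A GPA-superimposed sample.

    Attributes
    ----------
    aligned:
        ``(n, L, 3)`` Procrustes coordinates (dimensionless when scaled).
    centroid_sizes:
        ``(n,)`` original centroid sizes (length units).
    consensus:
        Mean shape as a :class:`Configuration`; exactly the arithmetic mean
        of ``aligned``.
    objective_history:
        Sum of squared distances to the consensus after each iteration;
        non-increasing.
    """

    aligned: np.ndarray
    centroid_sizes: np.ndarray
    consensus: Configuration
    iterations: int
    converged: bool
    objective_history: np.ndarray
    specimen_ids: list[str]
    landmark_ids: list[str]
    metadata: pd.DataFrame
    scaled: bool = True

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    @property
    def flat(self) -> np.ndarray:
        """``(n, 3L)`` flattened coordinates (landmark-major: x1,y1,z1,x2,...)."""
        return self.aligned.reshape(self.n_specimens, -1)

    def configuration(self, i: int) -> Configuration:
        return Configuration(self.specimen_ids[i], self.aligned[i], self.landmark_ids)

    def to_sample(self) -> Sample:
        """Aligned coordinates as a Sample (for export via write_landmarks)."""
        configs = [self.configuration(i) for i in range(self.n_specimens)]
        return Sample(configs, self.metadata.reset_index(drop=True))

    def distances_to_consensus(self) -> np.ndarray:
        diff = self.aligned - self.consensus.coords
        return np.sqrt((diff**2).sum(axis=(1, 2)))


def _canonical_orientation(mean_shape: np.ndarray) -> np.ndarray:
    """Rotation taking the consensus to its principal axes (det +1).

    Axes are ordered by decreasing variance; each axis is flipped so that
    its largest-magnitude component is positive (first occurrence on ties),
    then the third axis is flipped if needed to keep the frame right-handed.
    """
    c = mean_shape - mean_shape.mean(axis=0)
    cov = c.T @ c
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending variance
    for j in range(3):
        k = int(np.argmax(np.abs(v[:, j])))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def gpa(
    sample: Sample,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedSample:
    """Generalized Procrustes superimposition of a landmark sample.

    Each configuration is centred, scaled to unit centroid size (if
    ``scale``), and rotated to the consensus by orthogonal least squares with
    reflections disallowed; the consensus is the arithmetic mean, recomputed
    until it moves by less than ``tol`` (Frobenius norm).

    Raises on fewer than 2 specimens, rank-deficient (collinear)
    configurations, and non-convergence within ``max_iter``.
    """
    if sample.n_specimens < 2:
        raise MorphovarError("GPA needs at least 2 specimens")
    X = sample.coords.astype(float)
    n, L, _ = X.shape
    sizes = np.empty(n)
    for i in range(n):
        X[i] -= X[i].mean(axis=0)
        sizes[i] = float(np.sqrt((X[i] ** 2).sum()))
        if sizes[i] == 0.0:
            raise MorphovarError(
                f"specimen {sample.specimen_ids[i]!r}: all landmarks coincide"
            )
        if np.linalg.matrix_rank(X[i], tol=1e-10 * sizes[i]) < 2:
            raise MorphovarError(
                f"specimen {sample.specimen_ids[i]!r}: landmarks are collinear; "
                "the rotation fit is degenerate"
            )
        if scale:
            X[i] /= sizes[i]

    mean = X[0].copy()
    objective = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            X[i] = X[i] @ optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        objective.append(float(((X - new_mean) ** 2).sum()))
        shift = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        if it > 1 and shift < tol:
            converged = True
            break
    if not converged:
        raise MorphovarError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus shift {shift:.3e})"
        )

    rot = _canonical_orientation(mean)
    X = X @ rot
    mean = mean @ rot

    consensus = Configuration("consensus", mean, sample.landmark_ids)
    return AlignedSample(
        aligned=X,
        centroid_sizes=sizes,
        consensus=consensus,
        iterations=it,
        converged=converged,
        objective_history=np.asarray(objective),
        specimen_ids=sample.specimen_ids,
        landmark_ids=sample.landmark_ids,
        metadata=sample.metadata.copy(),
        scaled=scale,
    )
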