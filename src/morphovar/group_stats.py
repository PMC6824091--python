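"""Group-level shape statistics: disparity (Procrustes variance), Procrustes
ANOVA with permutation p-values, replicate repeatability, two-block partial
least squares, and score correlations.

Conventions match the standard morphometrics software family: Procrustes
variance uses divisor n_g (so published disparity tables are comparable),
ANOVA p-values come from residual randomization of the reduced model, and
r-PLS is the Pearson correlation of the first pair of block scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .superimposition import AlignedSample
from .types import MorphovarError

__all__ = [
    "DisparityResult",
    "ProcrustesAnovaResult",
    "PLSResult",
    "procrustes_variance_test",
    "procrustes_anova",
    "repeatability",
    "two_block_pls",
    "correlate_scores",
]


def _flat(data) -> np.ndarray:
    if isinstance(data, AlignedSample):
        return data.flat
    arr = np.asarray(data, float)
    if arr.ndim == 3:
        return arr.reshape(arr.shape[0], -1)
    return arr


# --- Disparity ---------------------------------------------------------


@dataclass
class DisparityResult:
    groups: list[str]
    procrustes_variance: dict[str, float]
    pairwise_diff: pd.DataFrame   # |PV_i - PV_j|
    pairwise_p: pd.DataFrame      # permutation p-values, symmetric
    n_perm: int

    def table(self) -> pd.DataFrame:
        """Square table: PV on the diagonal, p-values off-diagonal."""
        t = self.pairwise_p.copy()
        for g in self.groups:
            t.loc[g, g] = self.procrustes_variance[g]
        return t


def _group_pv(X: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Procrustes variance per group: mean squared distance from the group
    mean (divisor n_g, the disparity convention)."""
    pv = np.empty(n_groups)
    for g in range(n_groups):
        sub = X[codes == g]
        pv[g] = ((sub - sub.mean(axis=0)) ** 2).sum() / sub.shape[0]
    return pv


def procrustes_variance_test(
    aligned: AlignedSample | np.ndarray,
    groups,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> DisparityResult:
    """Per-group Procrustes variance with pairwise permutation tests.

    For each group pair the null permutes the pooled specimens' group labels
    and recomputes ``|PV_i − PV_j|``; p-values use the pseudo-count
    estimator and are reported unadjusted.
    """
    X = _flat(aligned)
    labels = np.asarray(groups)
    if labels.size != X.shape[0]:
        raise MorphovarError(f"{labels.size} labels for {X.shape[0]} specimens")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise MorphovarError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise MorphovarError(
            f"singleton group {uniq[int(np.argmin(counts))]!r}: "
            "Procrustes variance needs >= 2 specimens per group"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pv = _group_pv(X, codes, uniq.size)
    names = [str(u) for u in uniq]
    diff = pd.DataFrame(np.abs(pv[:, None] - pv[None, :]), index=names, columns=names)
    pmat = pd.DataFrame(np.full((uniq.size, uniq.size), np.nan), index=names, columns=names)
    for a in range(uniq.size):
        for b in range(a + 1, uniq.size):
            mask = (codes == a) | (codes == b)
            sub = X[mask]
            sub_codes = (codes[mask] == b).astype(int)
            opv = _group_pv(sub, sub_codes, 2)
            obs = abs(opv[0] - opv[1])
            ge = 0
            for _ in range(n_perm):
                perm = rng.permutation(sub_codes)
                ppv = _group_pv(sub, perm, 2)
                if abs(ppv[0] - ppv[1]) >= obs:
                    ge += 1
            p = (ge + 1) / (n_perm + 1)
            pmat.iloc[a, b] = pmat.iloc[b, a] = p
    return DisparityResult(
        groups=names,
        procrustes_variance={names[g]: float(pv[g]) for g in range(uniq.size)},
        pairwise_diff=diff,
        pairwise_p=pmat,
        n_perm=n_perm,
    )


# --- Procrustes ANOVA --------------------------------------------------


@dataclass
class ProcrustesAnovaResult:
    ss_effect: float
    ss_residual: float
    ss_total: float
    df_effect: int
    df_residual: int
    r_squared: float
    f_statistic: float
    p_value: float
    n_perm: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_effect, self.df_residual, self.df_effect + self.df_residual],
                "SS": [self.ss_effect, self.ss_residual, self.ss_total],
                "MS": [
                    self.ss_effect / self.df_effect,
                    self.ss_residual / self.df_residual,
                    np.nan,
                ],
                "Rsq": [self.r_squared, np.nan, np.nan],
                "F": [self.f_statistic, np.nan, np.nan],
                "p": [self.p_value, np.nan, np.nan],
            },
            index=["effect", "residual", "total"],
        )


def _design(covariate, n: int) -> tuple[np.ndarray, int]:
    cov = np.asarray(covariate)
    if cov.shape[0] != n:
        raise MorphovarError(f"covariate length {cov.shape[0]} != n specimens {n}")
    if cov.ndim == 1 and cov.dtype.kind in "fiu":
        x = cov.astype(float)
        if np.ptp(x) == 0:
            raise MorphovarError("constant covariate")
        xc = (x - x.mean())[:, None]
        return xc, 1
    levels, codes = np.unique(cov, return_inverse=True)
    if levels.size < 2:
        raise MorphovarError("constant covariate")
    if np.bincount(codes).min() < 2:
        raise MorphovarError("each factor level needs >= 2 specimens")
    D = np.eye(levels.size)[codes][:, 1:]
    return D - D.mean(axis=0), levels.size - 1


def _anova_ss(Yc: np.ndarray, Xc: np.ndarray) -> tuple[float, float]:
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    ss_e = float((fitted**2).sum())
    ss_r = float(((Yc - fitted) ** 2).sum())
    return ss_e, ss_r


def procrustes_anova(
    aligned: AlignedSample | np.ndarray,
    covariate,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    permute: str = "residual",
) -> ProcrustesAnovaResult:
    """Procrustes ANOVA: sums of squares of the multivariate OLS of (flat)
    coordinates on a scalar covariate or a factor.

    ``F = (SS_effect / df_e) / (SS_residual / df_r)``; the p-value permutes
    reduced-model residuals (here: the centred data, the reduced model being
    the intercept) ``n_perm`` times, or raw rows with ``permute="labels"``
    (equivalent for a single-term model, kept as an explicit option).

    Works equally on a univariate response (e.g. centroid size against sex):
    pass a 1-column matrix or 1-D array as ``aligned``.
    """
    Y = _flat(aligned)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    Xc, df_e = _design(covariate, n)
    df_r = n - 1 - df_e
    if df_r < 1:
        raise MorphovarError("not enough specimens for the design")
    if permute not in ("residual", "labels"):
        raise MorphovarError(f"unknown permutation scheme {permute!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Yc = Y - Y.mean(axis=0)
    ss_tot = float((Yc**2).sum())
    if ss_tot == 0:
        raise MorphovarError("zero total variance in the response")
    ss_e, ss_r = _anova_ss(Yc, Xc)
    f_obs = (ss_e / df_e) / (ss_r / df_r) if ss_r > 0 else np.inf

    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pe, pr = _anova_ss(Yc[perm], Xc)
        f_perm = (pe / df_e) / (pr / df_r) if pr > 0 else np.inf
        if f_perm >= f_obs:
            ge += 1
    p = (ge + 1) / (n_perm + 1)
    return ProcrustesAnovaResult(
        ss_effect=ss_e,
        ss_residual=ss_r,
        ss_total=ss_tot,
        df_effect=df_e,
        df_residual=df_r,
        r_squared=ss_e / ss_tot,
        f_statistic=f_obs,
        p_value=p,
        n_perm=n_perm,
    )


def repeatability(
    aligned: AlignedSample | np.ndarray,
    specimen_factor,
    replicates: int = 2,
) -> float:
    """Digitization repeatability from replicated landmarking.

    A Procrustes ANOVA on the specimen factor yields among- and
    within-specimen mean squares; ``R = s²_among / (s²_among + s²_within)``
    with ``s²_among = (MS_among − MS_within) / replicates``, clamped to
    [0, 1]. Requires balanced replication (every specimen digitized exactly
    ``replicates`` times).
    """
    Y = _flat(aligned)
    labels = np.asarray(specimen_factor)
    if labels.size != Y.shape[0]:
        raise MorphovarError(f"{labels.size} labels for {Y.shape[0]} rows")
    uniq, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    if not np.all(counts == replicates):
        bad = uniq[int(np.argmax(counts != replicates))]
        raise MorphovarError(
            f"unbalanced replication: specimen {bad!r} appears "
            f"{int(counts[counts != replicates][0])} times, expected {replicates}"
        )
    n_spec = uniq.size
    Yc = Y - Y.mean(axis=0)
    group_means = np.zeros((n_spec, Y.shape[1]))
    np.add.at(group_means, codes, Yc)
    group_means /= replicates
    ss_among = float(replicates * (group_means**2).sum())
    ss_within = float(((Yc - group_means[codes]) ** 2).sum())
    ms_among = ss_among / (n_spec - 1)
    ms_within = ss_within / (n_spec * (replicates - 1))
    s2_among = (ms_among - ms_within) / replicates
    if s2_among <= 0:
        return 0.0
    return float(min(1.0, s2_among / (s2_among + ms_within)))


# --- Two-block PLS -----------------------------------------------------


@dataclass
class PLSResult:
    axis_a: np.ndarray     # first singular axis, block A (unit norm)
    axis_b: np.ndarray
    scores_a: np.ndarray   # per-specimen PLS1 scores
    scores_b: np.ndarray
    r_pls: float
    p_value: float
    n_perm: int
    singular_value: float


def two_block_pls(
    block_a: AlignedSample | np.ndarray,
    block_b: AlignedSample | np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PLSResult:
    """Two-block partial least squares: the pair of axes (one per block)
    with maximal between-block covariance.

    The first singular vectors of the cross-covariance matrix give the
    axes; PLS1 scores are the centred blocks projected on them; ``r_pls``
    is the Pearson correlation of the score pair. The p-value permutes the
    specimen rows of block B, breaking the association, and counts
    permuted ``r_pls`` ≥ observed.
    """
    A = _flat(block_a)
    B = _flat(block_b)
    if A.shape[0] != B.shape[0]:
        raise MorphovarError(
            f"blocks have different specimen counts: {A.shape[0]} vs {B.shape[0]}"
        )
    if isinstance(block_a, AlignedSample) and isinstance(block_b, AlignedSample):
        if block_a.specimen_ids != block_b.specimen_ids:
            raise MorphovarError("blocks must contain the same specimens in the same order")
    n = A.shape[0]
    if n < 3:
        raise MorphovarError("two-block PLS needs at least 3 specimens")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)

    def first_pair(bmat):
        C = Ac.T @ bmat / (n - 1)
        u, s, vt = np.linalg.svd(C, full_matrices=False)
        return u[:, 0], vt[0], s[0]

    u1, v1, s1 = first_pair(Bc)
    # deterministic sign: largest-|loading| of the A axis positive
    k = int(np.argmax(np.abs(u1)))
    if u1[k] < 0:
        u1, v1 = -u1, -v1
    sa = Ac @ u1
    sb = Bc @ v1
    r_obs = float(np.corrcoef(sa, sb)[0, 1])

    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pu, pv, _ = first_pair(Bc[perm])
        r = abs(float(np.corrcoef(Ac @ pu, Bc[perm] @ pv)[0, 1]))
        if r >= abs(r_obs):
            ge += 1
    p = (ge + 1) / (n_perm + 1)
    return PLSResult(
        axis_a=u1, axis_b=v1, scores_a=sa, scores_b=sb,
        r_pls=r_obs, p_value=p, n_perm=n_perm, singular_value=float(s1),
    )


def correlate_scores(x, y) -> tuple[float, float, float]:
    """Pearson correlation with its t statistic and two-sided p-value.

    ``t = r √(n − 2) / √(1 − r²)``; for |r| = 1 the t statistic is infinite
    and the p-value is reported as 0.0 (the minimum attainable).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise MorphovarError("score vectors differ in length")
    n = x.size
    if n < 3:
        raise MorphovarError("correlation test needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise MorphovarError("non-finite score")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MorphovarError("zero variance in a score vector")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), float(np.sign(r) * np.inf), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, float(t), p
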