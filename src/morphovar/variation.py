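"""The landmark-position variation test.

Given two superimposed configurations (extreme specimens, hypothetical PC1
extremes, or group mean shapes), the per-landmark displacement magnitudes
are compared between a named partition (a morphological hypothesis region,
e.g. "zygomatic arch") and the structure as a whole. Two statistics are
evaluated against a permutation null of same-sized random landmark subsets:

* the total displacement in the partition (does the region move more — or
  less — than a random region of the same size?), tested on both tails;
* the Bhattacharyya coefficient between the partition's magnitude
  distribution and the all-landmark magnitude distribution (is the region's
  displacement *distribution* distinguishable from the whole?), tested on
  the lower tail — less overlap means more distinguishable.

p-values use the pseudo-count estimator (b + 1) / (m + 1) and can therefore
never be zero. A result is classified as ``none`` (no magnitude signal),
``magnitude_only`` (magnitude significant but the distribution
indistinguishable from the whole) or ``magnitude_and_distribution`` (both
significant). Optional rarefaction repeats the whole test on random
sub-partitions of a fixed smaller size, to control for unequal partition
sizes, and summarizes by median p-values and majority classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ordination import PCAModel, hypothetical_configuration, pca
from .superimposition import AlignedSample
from .types import Configuration, MorphovarError, Partition

__all__ = [
    "DisplacementField",
    "VariationTestResult",
    "RarefiedSummary",
    "PairSelection",
    "displacement_field",
    "select_pair",
    "bhattacharyya_coefficient",
    "variation_test",
    "run_battery",
    "displacement_table",
]

logger = logging.getLogger(__name__)

PAIR_MODES = ("hypothetical_pc1", "pc1_extremes", "procrustes_extremes", "group_means")
CLASSIFICATIONS = ("none", "magnitude_only", "magnitude_and_distribution")


@dataclass
class DisplacementField:
    """Per-landmark displacement between two configurations (B − A)."""

    vectors: np.ndarray      # (L, 3)
    magnitudes: np.ndarray   # (L,)
    pair_ids: tuple[str, str]
    mode: str = "explicit"

    @property
    def n_landmarks(self) -> int:
        return self.magnitudes.size


def displacement_field(
    a: Configuration | np.ndarray,
    b: Configuration | np.ndarray,
    mode: str = "explicit",
) -> DisplacementField:
    """Displacement vectors and Euclidean magnitudes between two
    configurations that share a Procrustes frame."""
    id_a, ca = (a.specimen_id, a.coords) if isinstance(a, Configuration) else ("A", np.asarray(a, float))
    id_b, cb = (b.specimen_id, b.coords) if isinstance(b, Configuration) else ("B", np.asarray(b, float))
    if ca.shape != cb.shape:
        raise MorphovarError(f"mismatched configurations: {ca.shape} vs {cb.shape}")
    vectors = cb - ca
    magnitudes = np.linalg.norm(vectors, axis=1)
    return DisplacementField(vectors, magnitudes, (id_a, id_b), mode)


@dataclass
class PairSelection:
    """The two configurations chosen for a comparison, with provenance."""

    config_a: Configuration
    config_b: Configuration
    mode: str
    ci: float = 1.0

    def field(self) -> DisplacementField:
        return displacement_field(self.config_a, self.config_b, self.mode)


def _ci_keep(values: np.ndarray, ci: float) -> np.ndarray:
    """Boolean mask keeping values inside the two-sided empirical ci band."""
    if not 0 < ci <= 1:
        raise MorphovarError(f"ci must be in (0, 1], got {ci}")
    if ci == 1.0:
        return np.ones(values.size, dtype=bool)
    lo, hi = np.percentile(values, [50 * (1 - ci), 100 - 50 * (1 - ci)])
    return (values >= lo) & (values <= hi)


def select_pair(
    aligned: AlignedSample,
    model: PCAModel | None = None,
    mode: str = "pc1_extremes",
    ci: float = 1.0,
    groups: Sequence[str] | None = None,
) -> PairSelection:
    """Choose the two configurations to compare.

    Modes
    -----
    ``hypothetical_pc1``
        Reconstructed shapes at the (ci-trimmed) min and max PC1 scores.
    ``pc1_extremes``
        The actual specimens with the lowest and highest PC1 score.
    ``procrustes_extremes``
        The two specimens farthest from the consensus (ci-trimmed on the
        distance distribution), ordered by PC1 score for determinism.
    ``group_means``
        Mean aligned configuration of each of exactly two groups
        (``groups`` required; ordered by sorted group label).
    """
    if mode not in PAIR_MODES:
        raise MorphovarError(f"unknown pair mode {mode!r}; expected one of {PAIR_MODES}")
    n = aligned.n_specimens
    if n < 2:
        raise MorphovarError("pair selection needs at least 2 specimens")

    if mode == "group_means":
        if groups is None:
            raise MorphovarError("group_means mode requires group labels")
        labels = np.asarray(groups)
        if labels.size != n:
            raise MorphovarError(f"{labels.size} group labels for {n} specimens")
        uniq = sorted(set(labels.tolist()))
        if len(uniq) != 2:
            raise MorphovarError(
                f"group_means needs exactly 2 groups, got {len(uniq)}: {uniq}"
            )
        means = []
        for g in uniq:
            means.append(
                Configuration(
                    f"mean:{g}",
                    aligned.aligned[labels == g].mean(axis=0),
                    aligned.landmark_ids,
                )
            )
        return PairSelection(means[0], means[1], mode, 1.0)

    if model is None:
        model = pca(aligned)
    if model.eigenvalues[0] <= 0:
        raise MorphovarError("degenerate sample: zero-variance PC1")
    pc1 = model.scores[:, 0]

    if mode == "hypothetical_pc1":
        keep = _ci_keep(pc1, ci)
        lo, hi = float(pc1[keep].min()), float(pc1[keep].max())
        return PairSelection(
            hypothetical_configuration(model, 0, lo),
            hypothetical_configuration(model, 0, hi),
            mode,
            ci,
        )
    if mode == "pc1_extremes":
        keep = _ci_keep(pc1, ci)
        cand = np.flatnonzero(keep)
        i = cand[np.argmin(pc1[cand])]
        j = cand[np.argmax(pc1[cand])]
        if i == j:
            raise MorphovarError("ci trimming left fewer than 2 distinct specimens")
        return PairSelection(aligned.configuration(i), aligned.configuration(j), mode, ci)

    # procrustes_extremes: the two specimens most distant from the consensus
    d = aligned.distances_to_consensus()
    keep = _ci_keep(d, ci)
    cand = np.flatnonzero(keep)
    if cand.size < 2:
        raise MorphovarError("ci trimming left fewer than 2 specimens")
    top = cand[np.argsort(d[cand])[-2:]]
    i, j = sorted(top, key=lambda k: pc1[k])
    return PairSelection(aligned.configuration(i), aligned.configuration(j), mode, ci)


# --- Bhattacharyya coefficient -----------------------------------------


def _auto_bins(nx: int, ny: int) -> int:
    return max(2, math.ceil(math.sqrt(min(nx, ny))))


def bhattacharyya_coefficient(x, y, bins: int | str = "auto") -> float:
    """Histogram-overlap Bhattacharyya coefficient of two scalar samples.

    A shared histogram over the pooled range ``[min(x ∪ y), max(x ∪ y)]``
    with ``B`` bins gives per-sample bin probabilities p, q; the coefficient
    is ``Σ √(p_i q_i)`` ∈ [0, 1] (1 = identical binned distributions, 0 =
    disjoint). ``bins="auto"`` uses ``⌈√(min(|x|, |y|))⌉`` with a floor of 2.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size == 0 or y.size == 0:
        raise MorphovarError("Bhattacharyya coefficient needs non-empty samples")
    if bins == "auto":
        bins = _auto_bins(x.size, y.size)
    bins = int(bins)
    if bins < 1:
        raise MorphovarError("bins must be >= 1")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if lo == hi:
        return 1.0  # all values identical across both samples
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(x, bins=edges)
    q, _ = np.histogram(y, bins=edges)
    bc = float(np.sqrt((p / x.size) * (q / y.size)).sum())
    return min(bc, 1.0)


# --- Permutation test --------------------------------------------------


@dataclass
class RarefiedSummary:
    """Median p-values and majority classification over rarefied re-tests."""

    rarefy_to: int
    n_rarefactions: int
    p_high: float
    p_low: float
    p_bc: float
    classification: str
    direction: str
    n_significant: int


@dataclass
class VariationTestResult:
    partition_name: str
    partition_size: int
    observed_total: float
    observed_mean: float
    effect: float
    p_high: float
    p_low: float
    bc_observed: float
    p_bc: float
    classification: str
    direction: str
    n_perm: int
    alpha: float
    null_totals: np.ndarray = field(repr=False)
    null_bc: np.ndarray = field(repr=False)
    seed: int | None = None
    rarefied: RarefiedSummary | None = None

    @property
    def significant(self) -> bool:
        return self.classification != "none"


def _null_subsets(L: int, k: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, k) uniform random k-subsets of range(L), no replacement
    within a draw."""
    u = rng.random((n_perm, L))
    return np.argpartition(u, k - 1, axis=1)[:, :k]


def _subset_bc_null(
    magnitudes: np.ndarray, subsets: np.ndarray, bins: int
) -> np.ndarray:
    """Vectorized BC of each subset's magnitudes against all magnitudes.

    The pooled range of (subset ∪ all) is always the range of all
    magnitudes, so the bin edges — and the full-distribution bin
    probabilities — are shared across subsets.
    """
    L = magnitudes.size
    n_perm, k = subsets.shape
    lo, hi = float(magnitudes.min()), float(magnitudes.max())
    if lo == hi:
        return np.ones(n_perm)
    edges = np.linspace(lo, hi, bins + 1)
    # np.histogram semantics: half-open bins, last bin closed
    lm_bin = np.clip(np.searchsorted(edges, magnitudes, side="right") - 1, 0, bins - 1)
    q = np.bincount(lm_bin, minlength=bins) / L
    rows = np.repeat(np.arange(n_perm), k)
    flat = rows * bins + lm_bin[subsets].ravel()
    counts = np.bincount(flat, minlength=n_perm * bins).reshape(n_perm, bins)
    return np.minimum(np.sqrt((counts / k) * q).sum(axis=1), 1.0)


def _classify(p_high: float, p_low: float, p_bc: float, alpha: float) -> str:
    if min(p_high, p_low) > alpha:
        return "none"
    return "magnitude_and_distribution" if p_bc <= alpha else "magnitude_only"


def variation_test(
    field_: DisplacementField,
    partition: Partition,
    n_perm: int = 1000,
    alpha: float = 0.001,
    rarefy_to: int | None = None,
    n_rarefactions: int = 100,
    seed: int | np.random.Generator | None = None,
    null_from_complement: bool = False,
    bins: int | str = "auto",
) -> VariationTestResult:
    """Permutation test of a landmark partition's displacement against
    same-sized random landmark subsets.

    The null draws ``n_perm`` uniform random subsets of size ``|partition|``
    from all L landmarks (or from the complement of the partition when
    ``null_from_complement``, for sensitivity analysis) and computes each
    subset's total displacement and its Bhattacharyya coefficient against
    the full magnitude distribution. One-sided p-values use
    ``(b + 1) / (n_perm + 1)``; ``alpha`` defaults to 0.001, compensating for
    the large number of cells in a typical battery. With ``rarefy_to`` the
    whole test is repeated ``n_rarefactions`` times on random
    sub-partitions of that size (median p, majority classification).
    """
    L = field_.n_landmarks
    partition.validate_against(L)
    k = len(partition)
    if rarefy_to is not None and not 1 <= rarefy_to <= k:
        raise MorphovarError(f"rarefy_to must be in [1, {k}], got {rarefy_to}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, int) else None

    mags = field_.magnitudes
    observed_total = float(mags[partition.indices].sum())
    observed_mean = observed_total / k
    if bins == "auto":
        bins_ = _auto_bins(k, L)
    else:
        bins_ = int(bins)
    bc_obs = bhattacharyya_coefficient(mags[partition.indices], mags, bins_)

    if k == L:
        # strict subsetting impossible: every "random subset" is the whole
        # structure, so both statistics sit exactly at their null
        null_totals = np.full(n_perm, observed_total)
        null_bc = np.full(n_perm, bc_obs)
        return VariationTestResult(
            partition_name=partition.name, partition_size=k,
            observed_total=observed_total, observed_mean=observed_mean,
            effect=0.0, p_high=1.0, p_low=1.0, bc_observed=bc_obs, p_bc=1.0,
            classification="none", direction="smaller", n_perm=n_perm,
            alpha=alpha, null_totals=null_totals, null_bc=null_bc,
            seed=seed_val, rarefied=None,
        )

    if null_from_complement:
        pool = np.setdiff1d(np.arange(L), partition.indices)
        if pool.size < k:
            raise MorphovarError(
                f"complement ({pool.size}) smaller than partition ({k}); "
                "cannot draw complement-only null subsets"
            )
        subsets = pool[_null_subsets(pool.size, k, n_perm, rng)]
    else:
        subsets = _null_subsets(L, k, n_perm, rng)

    null_totals = mags[subsets].sum(axis=1)
    null_bc = _subset_bc_null(mags, subsets, bins_)

    p_high = (1 + int((null_totals >= observed_total).sum())) / (n_perm + 1)
    p_low = (1 + int((null_totals <= observed_total).sum())) / (n_perm + 1)
    p_bc = (1 + int((null_bc <= bc_obs).sum())) / (n_perm + 1)
    effect = observed_mean - float(np.median(null_totals / k))
    classification = _classify(p_high, p_low, p_bc, alpha)
    direction = "larger" if effect > 0 else "smaller"

    rarefied = None
    if rarefy_to is not None and rarefy_to < k:
        ph, pl, pb, cls, dirs = [], [], [], [], []
        for _ in range(n_rarefactions):
            sub_idx = rng.choice(partition.indices, size=rarefy_to, replace=False)
            sub = Partition(f"{partition.name}[rarefied]", sub_idx)
            r = variation_test(
                field_, sub, n_perm=n_perm, alpha=alpha, seed=rng,
                null_from_complement=null_from_complement, bins=bins,
            )
            ph.append(r.p_high)
            pl.append(r.p_low)
            pb.append(r.p_bc)
            cls.append(r.classification)
            dirs.append(r.direction)
        maj = max(CLASSIFICATIONS, key=lambda c: cls.count(c))
        maj_dir = max(("larger", "smaller"), key=lambda d: dirs.count(d))
        rarefied = RarefiedSummary(
            rarefy_to=rarefy_to,
            n_rarefactions=n_rarefactions,
            p_high=float(np.median(ph)),
            p_low=float(np.median(pl)),
            p_bc=float(np.median(pb)),
            classification=maj,
            direction=maj_dir,
            n_significant=sum(c != "none" for c in cls),
        )
    elif rarefy_to == k:
        rarefied = RarefiedSummary(
            rarefy_to=k, n_rarefactions=1, p_high=p_high, p_low=p_low,
            p_bc=p_bc, classification=classification, direction=direction,
            n_significant=int(classification != "none"),
        )

    return VariationTestResult(
        partition_name=partition.name,
        partition_size=k,
        observed_total=observed_total,
        observed_mean=observed_mean,
        effect=effect,
        p_high=p_high,
        p_low=p_low,
        bc_observed=bc_obs,
        p_bc=p_bc,
        classification=classification,
        direction=direction,
        n_perm=n_perm,
        alpha=alpha,
        null_totals=null_totals,
        null_bc=null_bc,
        seed=seed_val,
        rarefied=rarefied,
    )


# --- Battery -----------------------------------------------------------


def _result_row(group, part, mode, ci, res: VariationTestResult,
                hypotheses: Mapping[str, str] | None) -> dict:
    row = {
        "group": group,
        "partition": part,
        "partition_size": res.partition_size,
        "mode": mode,
        "ci": ci,
        "observed_total": res.observed_total,
        "observed_mean": res.observed_mean,
        "effect": res.effect,
        "p_high": res.p_high,
        "p_low": res.p_low,
        "bc_observed": res.bc_observed,
        "p_bc": res.p_bc,
        "classification": res.classification,
        "direction": res.direction,
        "error": "",
    }
    if res.rarefied is not None:
        row["rarefied_p_high"] = res.rarefied.p_high
        row["rarefied_p_low"] = res.rarefied.p_low
        row["rarefied_p_bc"] = res.rarefied.p_bc
        row["rarefied_classification"] = res.rarefied.classification
        row["rarefaction_robust"] = (
            res.significant
            and res.rarefied.classification != "none"
            and res.rarefied.direction == res.direction
        )
    if hypotheses and part in hypotheses:
        row["hypothesis"] = hypotheses[part]
        row["opposite_direction"] = bool(
            res.significant and res.direction != hypotheses[part]
        )
    return row


def run_battery(
    aligned_by_group: Mapping[str, AlignedSample],
    partitions: Sequence[Partition],
    modes: Sequence[str] = ("hypothetical_pc1", "pc1_extremes", "procrustes_extremes"),
    ci_levels: Sequence[float] = (1.0, 0.95),
    n_perm: int = 1000,
    alpha: float = 0.001,
    seed: int | None = None,
    rarefy_to: int | None = None,
    n_rarefactions: int = 100,
    hypotheses: Mapping[str, str] | None = None,
    joint: tuple[AlignedSample, Sequence[str]] | None = None,
    null_from_complement: bool = False,
) -> pd.DataFrame:
    """Run the variation test over group × partition × pair-mode × CI.

    ``aligned_by_group`` maps group name to its (separately superimposed)
    sample; within-group modes run per group. If ``joint`` (a joint
    alignment plus its group labels) is given and ``"group_means"`` is in
    ``modes``, mean-shape comparisons are added for every unordered group
    pair (at ci = 1.0). ``hypotheses`` maps partition name to the expected
    direction ("larger"/"smaller"); significant results contradicting it are
    flagged (``opposite_direction``). Per-cell failures are logged and
    recorded in the ``error`` column, not fatal. ``rarefy_to`` defaults to
    the smallest partition when set; pass None to skip rarefaction.

    The run is bit-reproducible for a fixed ``seed``: every cell draws from
    an independent child stream of one seed sequence.
    """
    for m in modes:
        if m not in PAIR_MODES:
            raise MorphovarError(f"unknown pair mode {m!r}")
    within_modes = [m for m in modes if m != "group_means"]
    ss = np.random.SeedSequence(seed)
    rows: list[dict] = []

    def run_cell(group_label, fld, part, mode, ci):
        rng = np.random.default_rng(ss.spawn(1)[0])
        try:
            part.validate_against(fld.n_landmarks) if fld is not None else None
            res = variation_test(
                fld, part, n_perm=n_perm, alpha=alpha,
                rarefy_to=rarefy_to, n_rarefactions=n_rarefactions,
                seed=rng, null_from_complement=null_from_complement,
            )
            rows.append(_result_row(group_label, part.name, mode, ci, res, hypotheses))
        except MorphovarError as e:
            logger.warning("cell (%s, %s, %s, %s) failed: %s", group_label, part.name, mode, ci, e)
            rows.append({
                "group": group_label, "partition": part.name,
                "partition_size": len(part), "mode": mode, "ci": ci,
                "error": str(e),
            })

    for group, aligned in aligned_by_group.items():
        model = pca(aligned) if within_modes else None
        for mode in within_modes:
            for ci in ci_levels:
                try:
                    fld = select_pair(aligned, model, mode, ci).field()
                except MorphovarError as e:
                    for part in partitions:
                        logger.warning("pair (%s, %s, %s) failed: %s", group, mode, ci, e)
                        rows.append({
                            "group": group, "partition": part.name,
                            "partition_size": len(part), "mode": mode, "ci": ci,
                            "error": str(e),
                        })
                    continue
                for part in partitions:
                    run_cell(group, fld, part, mode, ci)

    if "group_means" in modes:
        if joint is None:
            raise MorphovarError(
                "group_means mode requires joint=(AlignedSample, group_labels)"
            )
        j_aligned, j_labels = joint
        labels = np.asarray(j_labels)
        uniq = sorted(set(labels.tolist()))
        for a_i in range(len(uniq)):
            for b_i in range(a_i + 1, len(uniq)):
                ga, gb = uniq[a_i], uniq[b_i]
                mask = (labels == ga) | (labels == gb)
                sub = AlignedSample(
                    aligned=j_aligned.aligned[mask],
                    centroid_sizes=j_aligned.centroid_sizes[mask],
                    consensus=j_aligned.consensus,
                    iterations=j_aligned.iterations,
                    converged=j_aligned.converged,
                    objective_history=j_aligned.objective_history,
                    specimen_ids=[s for s, m in zip(j_aligned.specimen_ids, mask) if m],
                    landmark_ids=j_aligned.landmark_ids,
                    metadata=j_aligned.metadata.loc[mask],
                    scaled=j_aligned.scaled,
                )
                fld = select_pair(sub, None, "group_means", groups=labels[mask]).field()
                for part in partitions:
                    run_cell(f"{ga}|{gb}", fld, part, "group_means", 1.0)

    return pd.DataFrame(rows)


def displacement_table(
    field_: DisplacementField,
    config_a: Configuration | None = None,
    config_b: Configuration | None = None,
) -> pd.DataFrame:
    """Per-landmark export (1-based ids) for external 3D heat-map rendering."""
    L = field_.n_landmarks
    out = {"landmark": np.arange(1, L + 1)}
    if config_a is not None:
        out.update({"ax": config_a.coords[:, 0], "ay": config_a.coords[:, 1],
                    "az": config_a.coords[:, 2]})
    if config_b is not None:
        out.update({"bx": config_b.coords[:, 0], "by": config_b.coords[:, 1],
                    "bz": config_b.coords[:, 2]})
    out.update({"dx": field_.vectors[:, 0], "dy": field_.vectors[:, 1],
                "dz": field_.vectors[:, 2], "magnitude": field_.magnitudes})
    return pd.DataFrame(out)
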