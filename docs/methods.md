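# Methods

This note documents the statistical procedures implemented in `morphovar`,
their assumptions, the tunable parameters that matter, and the design choices
made where several defensible options existed. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Superimposition

Generalized Procrustes analysis uses the partial (unit-size) fit: every
configuration is centred, scaled to unit centroid size (scaling can be
disabled), and rotated to the running consensus by orthogonal least squares.
The rotation comes from the SVD of the cross-covariance matrix with the
smallest singular direction sign-corrected, so reflections are never matched:
a mirrored copy of a chiral shape keeps a non-zero residual, as it should for
biological structures. The consensus is the arithmetic mean of the aligned
coordinates, recomputed until it moves by less than `tol` (Frobenius norm);
because each rotation step and each consensus update minimizes the summed
squared distance to the consensus, the GPA objective is non-increasing, which
the test suite asserts on every run via the recorded `objective_history`.

Defaults: `tol = 1e-10`, `max_iter = 100`, scaling on. These are
conservative; typical samples converge in well under ten iterations.
Degenerate inputs (coincident or collinear landmarks, a single specimen)
raise immediately rather than returning an ill-conditioned fit.

Procrustes coordinates are defined only up to a global rotation, so the
converged sample is re-oriented to the principal axes of the consensus:
axes ordered by decreasing variance, each axis flipped so its
largest-magnitude component is positive (first occurrence on ties), the third
axis flipped if needed to keep a right-handed frame. This makes output
coordinates reproducible run-to-run and invariant to specimen input order up
to floating-point noise; pairwise Procrustes distances are invariant to the
frame choice altogether and are what downstream statistics consume.

## Ordination

PCA is covariance-based on the flattened coordinates (never
correlation-based — the coordinates share units), with eigenvalue divisor
n − 1 so the "PC1 %" values match conventional morphometrics software.
Numerically zero eigenvalues (below 1e−12 of the leading one) are dropped;
an all-identical sample yields a single explicit zero component rather than
an error, because a residual PCA after a perfect fit legitimately has zero
total variance. Eigenvector signs follow the largest-|loading|-positive
convention, making scores bit-stable under specimen permutation.

Hypothetical configurations along an axis are `mean + score · eigenvector`,
the standard reconstruction; projecting such a shape back returns exactly
that score on the chosen axis and zero elsewhere (orthonormality), which is
asserted to 1e−10.

Shape-on-size regression is multivariate OLS of each Procrustes coordinate on
the centred covariate. Centroid size is used raw, not log-transformed — the
adult within-species size ranges this targets are narrow, where the two are
nearly affine; callers who want log-size can pass it. The regression score is
the projection of the centred shapes onto the unit coefficient vector (the
x-axis of conventional allometry plots); it is defined only for a scalar
covariate, while factors go through a dummy design for R² and residuals.

## The landmark variation test

The test asks whether a named landmark partition displaces more (or less)
between two configurations than random regions of the same size, and whether
its displacement-magnitude *distribution* is distinguishable from that of the
whole structure.

Null model: `n_perm` uniform random subsets of size k drawn from all L
landmarks (without replacement within a draw). Drawing from all landmarks —
rather than from the complement of the tested partition — treats the
partition as one region among equals; complement-only sampling is available
as an option (`null_from_complement`) for sensitivity analysis and is the
more conservative variant when a partition dominates the structure.

Statistics. The displacement statistic is the summed partition magnitude
(equivalent to the mean for fixed subset size), with one-sided p-values on
both tails and a signed effect `observed_mean − median(null means)`, so
positive effects read "varies more than the structure at large". The
distributional statistic is the Bhattacharyya coefficient between the
partition's magnitudes and all magnitudes, computed on a shared histogram
over the pooled range with `⌈√min(|x|,|y|)⌉` bins (floor 2). The bin rule is
deliberately exposed as a parameter: histogram-overlap coefficients are
bin-sensitive and no single rule is canonical. BC is tested lower-tail only —
*less* overlap than random subsets means the region is distinguishable.

p-values use `(b + 1)/(m + 1)` and can never be zero; with the default
`n_perm = 1000` the minimum attainable p is ≈ 0.000999, which is why the
default threshold α = 0.001 is exactly attainable and no smaller. The strict
default α compensates for the many cells of a typical battery. The
classification is: `none` if neither displacement tail reaches α;
`magnitude_only` if displacement is significant but BC is not;
`magnitude_and_distribution` if both are.

Degenerate cases are defined, not errors: a partition equal to the whole
structure returns p = 1 for both statistics (no strict subsetting is
possible), and a zero-range magnitude vector gives BC = 1.

Pair selection supports four modes: hypothetical shapes at the extreme PC1
scores, the actual specimens with extreme PC1 scores, the two specimens
farthest from the consensus ("Procrustes extremes", defined as distance from
the mean shape, not maximal pairwise distance — the two largest-distance
specimens are taken, ordered by PC1 score for determinism), and group mean
shapes. Confidence-interval trimming (e.g. 95%) removes observations outside
the two-sided [2.5, 97.5] empirical percentiles of the relevant score or
distance distribution before the extremes are taken; the trim is applied
two-sided even to the one-sided distance distribution, for symmetry across
modes.

Rarefaction re-runs the entire test on `n_rarefactions = 100` random
sub-partitions of a fixed smaller size (typically the smallest partition in
the battery) and reports median p-values and the majority classification.
The count 100 balances the granularity of a median p against runtime; the
median rather than the mean resists the heavy right tail of p-values under
weak signal. A battery result is "rarefaction-robust" when the full-size and
rarefied classifications agree in significance and direction.

The battery (`run_battery`) crosses groups × partitions × pair modes × CI
levels, draws every cell's permutations from an independent child stream of
one seed sequence (bit-reproducible for a fixed seed), records per-cell
errors instead of aborting, and flags cells whose significant direction
contradicts a declared hypothesis.

## Group statistics

*Disparity.* Procrustes variance per group is the mean squared Procrustes
distance from the group mean with divisor n_g (not n_g − 1), matching the
disparity convention of the standard morphometrics software family so values
are comparable with published tables. Pairwise tests permute group labels
within each pair and compare |ΔPV|; p-values are reported unadjusted.

*Procrustes ANOVA.* Sums of squares come from the trace form of the
multivariate OLS fit; `F = (SS_e/df_e)/(SS_r/df_r)`. The permutation scheme
is residual randomization of the reduced model — for a single-term model the
reduced model is the intercept, so this permutes the centred response rows;
raw-label permutation is available as an explicit option and coincides for
this design. The same routine accepts a univariate response (centroid size
against a factor) for size-dimorphism tests.

*Repeatability.* From a balanced replicate design, the specimen-factor ANOVA
yields `R = s²_among / (s²_among + MS_within)` with
`s²_among = (MS_among − MS_within)/r`, clamped to [0, 1]. Negative
variance-component estimates (replicates effectively independent of specimen
identity) clamp to 0.

*Two-block PLS.* First singular pair of the between-block cross-covariance;
r-PLS is the Pearson correlation of the first score pair; significance by
permuting the specimen rows of one block (on |r|). The r-PLS is invariant to
a common rotation applied to one block after alignment, which the suite
asserts.

*Score correlations.* Pearson r with `t = r√(n−2)/√(1−r²)` against the
t(n−2) reference distribution; |r| = 1 reports an infinite t and the minimum
p rather than NaN.

## Synthetic data

The generator emulates a Procrustes-scale landmark study: a deterministic
template (Fibonacci-spiral ellipsoid, axes 1 : 0.7 : 0.55, or a cube
lattice; centred, unit centroid size), isotropic per-landmark Gaussian noise
(`base_sd = 0.01` Procrustes units by default — digitizing-plus-individual
variation at roughly 1% of structure size), optional partition-localized
noise inflation (multiplicative sd factors ≥ 1; the signal the variation
test detects), optional allometry, and per-group mean offsets. Specimens are
emitted randomly rotated, translated, and scaled (sizes uniform, ±10% by
default), so every analysis exercises superimposition rather than starting
from aligned coordinates.

Allometric and group-offset directions are drawn in the similarity tangent
space of the template — orthogonal to the three translation modes, the three
infinitesimal rotations, and the radial scaling mode — so planted effects are
not absorbed by GPA and parameter-recovery experiments measure the
statistics, not leakage through the alignment. Inflation is isotropic per
landmark; anisotropic noise, correlated (integrated) noise between
neighbouring landmarks, and semilandmark sliding artefacts are *not*
emulated. Passing tests therefore demonstrate correctness of the statistical
machinery under exchangeable-noise conditions, not robustness to the spatial
correlation structure of real semilandmark data — on real data the test
inherits the usual caveats of Procrustes least-squares fitting (variance
spreading), mitigated by dense, even landmark coverage.

Every sample is reproducible from its seed; the returned truth record stores
all generating parameters (including the realized direction vectors) and is
sufficient to re-create the sample exactly.

## Validation problem sizes

The statistical validation suite runs at sizes chosen to make its bounds
sharp yet quick: exhaustive-enumeration comparisons on L ≤ 12 toys
(C(12, 4) = 495 subsets) against 10,000-draw Monte-Carlo p-values; type-I
rates over 2,000 exchangeable fields of 100 landmarks with a 20-landmark
partition at α = 0.001 (bound 0.005, ≈ 2.5× the two-tailed expectation);
power over 100 replicates of the 3×-inflation condition (n = 30, base sd
0.01) requiring ≥ 90% green classifications. `scripts/acceptance.py` repeats
these measurements from scratch together with a three-species study
(24 specimens per species, 120 landmarks, two inflated partitions, weak
allometry) and reports every number it computes.

## Known limitations

- Missing landmarks are rejected outright; there is no estimation of
  missing data.
- Semilandmark sliding is assumed done upstream; the package consumes
  already-slid coordinates.
- The Bhattacharyya coefficient depends on the bin rule; compare like with
  like when changing `bins`.
- Permutation tests have coarse resolution for very small partitions
  (k ≲ 5): few distinct subsets exist, and the attainable p-values are
  coarse. Rarefaction to very small sizes inherits this.
- Between-group PCA, phylogenetically corrected variants, and displacement
  *direction* statistics are out of scope.
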