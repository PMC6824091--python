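"""Displacement fields, pair selection, Bhattacharyya overlap, and the
partition permutation test with rarefaction and battery orchestration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphovar import (
    Configuration,
    MorphovarError,
    Partition,
    bhattacharyya_coefficient,
    displacement_field,
    displacement_table,
    gpa,
    pca,
    run_battery,
    select_pair,
    variation_test,
)
from morphovar.synthetic import SimulationSpec, simulate_sample

from conftest import synthetic_aligned


class TestDisplacementField:
    def test_identical_configs_zero(self, rng):
        a = rng.standard_normal((6, 3))
        fld = displacement_field(a, a)
        np.testing.assert_array_equal(fld.magnitudes, 0.0)

    def test_uniform_translation(self, rng):
        a = rng.standard_normal((6, 3))
        t = np.array([1.0, -2.0, 2.0])
        fld = displacement_field(a, a + t)
        np.testing.assert_allclose(fld.magnitudes, 3.0)

    def test_single_landmark_move(self, rng):
        a = rng.standard_normal((6, 3))
        b = a.copy()
        b[4] += [1, 2, 2]
        fld = displacement_field(a, b)
        assert fld.magnitudes[4] == pytest.approx(3.0)
        assert np.all(np.delete(fld.magnitudes, 4) == 0.0)

    def test_magnitude_matches_vector_norm(self, rng):
        fld = displacement_field(rng.standard_normal((8, 3)), rng.standard_normal((8, 3)))
        np.testing.assert_allclose(
            fld.magnitudes, np.linalg.norm(fld.vectors, axis=1), atol=1e-12
        )

    def test_mismatched_landmark_counts(self, rng):
        with pytest.raises(MorphovarError):
            displacement_field(rng.standard_normal((5, 3)), rng.standard_normal((6, 3)))

    def test_displacement_table_layout(self, rng):
        a = Configuration("a", rng.standard_normal((5, 3)))
        b = Configuration("b", rng.standard_normal((5, 3)))
        tbl = displacement_table(displacement_field(a, b), a, b)
        assert list(tbl["landmark"]) == [1, 2, 3, 4, 5]  # 1-based in reports
        assert {"ax", "bx", "dx", "magnitude"} <= set(tbl.columns)


def _line_aligned(scores, L=5, rng=None):
    """Aligned sample whose PC1 scores are exactly `scores` (centered)."""
    rng = rng or np.random.default_rng(5)
    mean = rng.standard_normal((L, 3))
    v = rng.standard_normal(3 * L)
    v /= np.linalg.norm(v)
    coords = np.stack([mean + (s * v).reshape(L, 3) for s in scores])
    return synthetic_aligned(coords)


class TestSelectPair:
    def test_pc1_extremes_brute_force(self):
        scores = np.array([-2.0, -1.0, 0.0, 3.0])
        al = _line_aligned(scores)
        model = pca(al)
        pair = select_pair(al, model, "pc1_extremes")
        got = {pair.config_a.specimen_id, pair.config_b.specimen_id}
        # brute force: specimens holding min and max score
        expect = {al.specimen_ids[int(np.argmin(scores))], al.specimen_ids[int(np.argmax(scores))]}
        assert got == expect

    def test_ci_trimming_excludes_beyond_percentiles(self):
        scores = np.arange(1.0, 101.0)
        al = _line_aligned(scores, L=6)
        model = pca(al)
        pair = select_pair(al, model, "pc1_extremes", ci=0.95)
        lo, hi = np.percentile(model.scores[:, 0], [2.5, 97.5])
        s = np.sort(model.scores[:, 0])
        kept = s[(s >= lo) & (s <= hi)]
        got = sorted(
            [model.project(pair.config_a.coords)[0], model.project(pair.config_b.coords)[0]]
        )
        assert got[0] == pytest.approx(kept.min(), abs=1e-9)
        assert got[1] == pytest.approx(kept.max(), abs=1e-9)

    def test_hypothetical_pc1_scores_at_extremes(self):
        scores = np.array([-1.5, 0.2, 0.4, 2.0, -0.3])
        al = _line_aligned(scores)
        model = pca(al)
        pair = select_pair(al, model, "hypothetical_pc1")
        pa = model.project(pair.config_a.coords)
        pb = model.project(pair.config_b.coords)
        assert pa[0] == pytest.approx(model.scores[:, 0].min(), abs=1e-10)
        assert pb[0] == pytest.approx(model.scores[:, 0].max(), abs=1e-10)
        np.testing.assert_allclose(pa[1:], 0.0, atol=1e-10)

    def test_procrustes_extremes_most_distant_from_consensus(self, rng):
        coords = rng.standard_normal((8, 6, 3)) * 0.1
        coords[3] += 2.0  # uniform offset: far from consensus
        coords[6] -= 1.5
        al = synthetic_aligned(coords)
        pair = select_pair(al, None, "procrustes_extremes")
        d = al.distances_to_consensus()
        expect = {al.specimen_ids[i] for i in np.argsort(d)[-2:]}
        assert {pair.config_a.specimen_id, pair.config_b.specimen_id} == expect

    def test_group_means_pair(self, rng):
        coords = rng.standard_normal((6, 5, 3))
        al = synthetic_aligned(coords)
        labels = ["x", "x", "x", "y", "y", "y"]
        pair = select_pair(al, None, "group_means", groups=labels)
        np.testing.assert_allclose(pair.config_a.coords, coords[:3].mean(axis=0))
        np.testing.assert_allclose(pair.config_b.coords, coords[3:].mean(axis=0))

    def test_degenerate_zero_variance_pc1(self, rng):
        coords = np.repeat(rng.standard_normal((1, 5, 3)), 4, axis=0)
        al = synthetic_aligned(coords)
        with pytest.raises(MorphovarError, match="zero-variance"):
            select_pair(al, None, "hypothetical_pc1")

    def test_invalid_ci(self, rng):
        al = _line_aligned(np.arange(5.0))
        with pytest.raises(MorphovarError, match="ci"):
            select_pair(al, None, "pc1_extremes", ci=1.5)


class TestBhattacharyya:
    def test_identical_samples(self, rng):
        x = rng.standard_normal(30)
        assert bhattacharyya_coefficient(x, x.copy()) == pytest.approx(1.0)

    def test_disjoint_across_bin_boundary(self):
        assert bhattacharyya_coefficient([0.0, 0.1, 0.2], [0.8, 0.9, 1.0], bins=2) == 0.0

    def test_hand_computed_two_bin_case(self):
        # p = (1/2, 1/2), q = (1/4, 3/4): sum of sqrt(pq) = 0.96593
        bc = bhattacharyya_coefficient([1, 1, 2, 2], [1, 2, 2, 2], bins=2)
        assert bc == pytest.approx(math.sqrt(0.5 * 0.25) + math.sqrt(0.5 * 0.75), abs=1e-12)
        assert bc == pytest.approx(0.9659, abs=1e-4)

    def test_constant_identical_values(self):
        assert bhattacharyya_coefficient([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(MorphovarError):
            bhattacharyya_coefficient([], [1.0])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_bounded(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(r.integers(1, 20))
        y = r.standard_normal(r.integers(1, 20))
        b1 = bhattacharyya_coefficient(x, y, bins=4)
        b2 = bhattacharyya_coefficient(y, x, bins=4)
        assert 0.0 <= b1 <= 1.0
        assert b1 == pytest.approx(b2, abs=1e-12)


def _exact_test(magnitudes, indices):
    """Exhaustive-enumeration oracle for the permutation p-values."""
    L = len(magnitudes)
    k = len(indices)
    obs_total = magnitudes[indices].sum()
    bins = max(2, math.ceil(math.sqrt(k)))
    obs_bc = bhattacharyya_coefficient(magnitudes[indices], magnitudes, bins)
    totals, bcs = [], []
    for sub in itertools.combinations(range(L), k):
        sub = np.asarray(sub)
        totals.append(magnitudes[sub].sum())
        bcs.append(bhattacharyya_coefficient(magnitudes[sub], magnitudes, bins))
    totals = np.asarray(totals)
    bcs = np.asarray(bcs)
    return (
        (totals >= obs_total - 1e-12).mean(),
        (totals <= obs_total + 1e-12).mean(),
        (bcs <= obs_bc + 1e-12).mean(),
    )


class TestVariationTest:
    def test_equal_magnitudes_exchangeable(self):
        a = np.zeros((10, 3))
        b = np.column_stack([np.zeros((10, 2)), np.ones(10)])  # all magnitudes exactly 1
        fld = displacement_field(a, b)
        res = variation_test(fld, Partition("p", [0, 1, 2]), n_perm=200, seed=1)
        assert res.p_high == 1.0 and res.p_low == 1.0 and res.p_bc == 1.0
        assert res.effect == pytest.approx(0.0, abs=1e-12)
        assert res.classification == "none"

    def test_full_partition_degenerate(self, rng):
        a = rng.standard_normal((8, 3))
        fld = displacement_field(a, a + rng.standard_normal((8, 3)))
        res = variation_test(fld, Partition("all", np.arange(8)), n_perm=100, seed=2)
        assert res.p_high == 1.0 and res.p_low == 1.0

    def test_pseudo_count_p_formula_and_determinism(self, rng):
        a = rng.standard_normal((12, 3))
        fld = displacement_field(a, a + 0.1 * rng.standard_normal((12, 3)))
        part = Partition("p", [0, 3, 7])
        r1 = variation_test(fld, part, n_perm=99, seed=7)
        r2 = variation_test(fld, part, n_perm=99, seed=7)
        for p in (r1.p_high, r1.p_low, r1.p_bc):
            assert 0 < p <= 1.0
            assert round(p * 100) == pytest.approx(p * 100)  # multiples of 1/(m+1)
        assert r1.p_high == r2.p_high and r1.p_bc == r2.p_bc
        np.testing.assert_array_equal(r1.null_totals, r2.null_totals)

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        mags = rng.gamma(2.0, 1.0, size=8)
        a = np.zeros((8, 3))
        b = np.column_stack([mags, np.zeros(8), np.zeros(8)])
        fld = displacement_field(a, b)
        part = Partition("p", [0, 2, 5])
        n_perm = 4000
        res = variation_test(fld, part, n_perm=n_perm, seed=11)
        e_high, e_low, e_bc = _exact_test(mags, part.indices)
        for p_mc, p_ex in [(res.p_high, e_high), (res.p_low, e_low), (res.p_bc, e_bc)]:
            se = math.sqrt(p_ex * (1 - p_ex) / n_perm)
            assert abs(p_mc - p_ex) <= 3 * se + 2 / n_perm

    def test_inflated_partition_detected(self, rng):
        mags = np.concatenate([5 * rng.rayleigh(1.0, 20), rng.rayleigh(1.0, 80)])
        fld = displacement_field(
            np.zeros((100, 3)), np.column_stack([mags, np.zeros((100, 2))])
        )
        res = variation_test(fld, Partition("hot", np.arange(20)), n_perm=1000, seed=3)
        assert res.classification == "magnitude_and_distribution"
        assert res.direction == "larger"
        assert res.p_high <= 0.001

    def test_complement_null_option(self, rng):
        mags = rng.rayleigh(1.0, 30)
        fld = displacement_field(
            np.zeros((30, 3)), np.column_stack([mags, np.zeros((30, 2))])
        )
        part = Partition("p", np.arange(10))
        res = variation_test(fld, part, n_perm=200, seed=4, null_from_complement=True)
        # no drawn subset may touch the partition
        assert res.p_high > 0
        big = Partition("big", np.arange(20))
        with pytest.raises(MorphovarError, match="complement"):
            variation_test(fld, big, n_perm=10, seed=0, null_from_complement=True)

    def test_rarefaction_summary(self, rng):
        mags = np.concatenate([6 * rng.rayleigh(1.0, 30), rng.rayleigh(1.0, 70)])
        fld = displacement_field(
            np.zeros((100, 3)), np.column_stack([mags, np.zeros((100, 2))])
        )
        res = variation_test(
            fld, Partition("hot", np.arange(30)), n_perm=200, seed=5,
            rarefy_to=10, n_rarefactions=20,
        )
        assert res.rarefied is not None
        assert res.rarefied.rarefy_to == 10
        assert res.rarefied.classification in (
            "none", "magnitude_only", "magnitude_and_distribution"
        )
        assert 0 < res.rarefied.p_high <= 1

    def test_rarefy_larger_than_partition_rejected(self, rng):
        fld = displacement_field(np.zeros((10, 3)), rng.standard_normal((10, 3)))
        with pytest.raises(MorphovarError, match="rarefy_to"):
            variation_test(fld, Partition("p", [0, 1]), rarefy_to=5, seed=0)


class TestBattery:
    @pytest.fixture()
    def species_samples(self):
        groups = {}
        for i, name in enumerate(["vu", "ll", "lk"]):
            spec = SimulationSpec(n=12, L=30, base_sd=0.01, seed=100 + i)
            sample, _ = simulate_sample(spec)
            groups[name] = gpa(sample)
        return groups

    def test_cardinality(self, species_samples):
        parts = [
            Partition("a", np.arange(8)),
            Partition("b", np.arange(8, 16)),
            Partition("c", np.arange(16, 30)),
        ]
        table = run_battery(
            species_samples, parts,
            modes=("hypothetical_pc1", "pc1_extremes", "procrustes_extremes"),
            ci_levels=(1.0, 0.95), n_perm=100, seed=0,
        )
        assert len(table) == 3 * 3 * 3 * 2  # 54 cells
        assert (table["error"] == "").all()

    def test_bit_reproducible_with_fixed_seed(self, species_samples):
        parts = [Partition("a", np.arange(8))]
        t1 = run_battery(species_samples, parts, ci_levels=(1.0,), n_perm=100, seed=9)
        t2 = run_battery(species_samples, parts, ci_levels=(1.0,), n_perm=100, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_hypothesis_and_group_mean_flags(self, rng):
        hot = Partition("hot", np.arange(10))
        spec = SimulationSpec(
            n=24, L=50, base_sd=0.01, inflation={hot: 4.0},
            groups=["A"] * 12 + ["B"] * 12,
            group_offsets={"A": np.zeros(150), "B": np.zeros(150)},
            seed=77,
        )
        sample, _ = simulate_sample(spec)
        joint = gpa(sample)
        labels = sample.metadata["species"].to_numpy()
        groups = {}
        for g in ("A", "B"):
            idx = labels == g
            sub_sample = type(sample)(
                [c for c, m in zip(sample.configurations, idx) if m]
            )
            groups[g] = gpa(sub_sample)
        table = run_battery(
            groups, [hot, hot.complement(50)],
            modes=("procrustes_extremes", "group_means"),
            ci_levels=(1.0,), n_perm=200, seed=1,
            hypotheses={"hot": "smaller"},  # deliberately contrary
            joint=(joint, labels),
        )
        assert set(table["mode"]) == {"procrustes_extremes", "group_means"}
        assert (table.loc[table["mode"] == "group_means", "group"] == "A|B").all()
        hot_rows = table[(table["partition"] == "hot") & (table["mode"] == "procrustes_extremes")]
        sig = hot_rows[hot_rows["classification"] != "none"]
        assert (sig["opposite_direction"]).all()  # inflated region moves MORE
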