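"""Dice maps, entropy/MI, exact expected MI, and AMI."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import parcstd as ps
from parcstd import ContingencyTable, contingency_from_arrays
from parcstd.errors import ConsistencyError, ParameterError

from conftest import parc


def table(counts):
    counts = np.asarray(counts)
    return ContingencyTable(
        row_labels=np.arange(1, counts.shape[0] + 1),
        col_labels=np.arange(1, counts.shape[1] + 1),
        counts=counts,
    )


# brute-force reference formulas, independent of the implementation paths
def mi_brute(counts):
    counts = np.asarray(counts, dtype=float)
    N = counts.sum()
    a = counts.sum(axis=1)
    b = counts.sum(axis=0)
    out = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            h = counts[i, j]
            if h > 0:
                out += h / N * math.log(N * h / (a[i] * b[j]))
    return out


class TestDice:
    def test_identical_single_region(self):
        dm = ps.dice_map(table([[5]]))
        np.testing.assert_allclose(dm.values, [[1.0]])

    def test_hand_built_eight_voxel_pair(self):
        # A: region 1 on the first 4 voxels; B: region 1 overlaps 2 of them
        la = [1, 1, 1, 1, 2, 2, 2, 2]
        lb = [1, 1, 2, 2, 1, 1, 2, 2]
        t = contingency_from_arrays(la, lb)
        dm = ps.dice_map(t)
        np.testing.assert_allclose(dm.values, 2 * 2 / (4 + 4) * np.ones((2, 2)))

    def test_disjoint_regions_zero(self):
        dm = ps.dice_map(table([[0, 3], [3, 0]]))
        assert dm.values[0, 0] == 0.0 and dm.values[1, 1] == 0.0
        np.testing.assert_allclose(dm.values[0, 1], 1.0)

    def test_symmetry_under_transpose(self, small_voronoi):
        other = ps.refine_parcellation(small_voronoi, 2, seed=1)
        t_ab = ps.contingency(small_voronoi, other)
        t_ba = ps.contingency(other, small_voronoi)
        np.testing.assert_allclose(
            ps.dice_map(t_ab).values, ps.dice_map(t_ba).values.T
        )

    def test_entries_in_unit_interval(self, small_voronoi):
        other = ps.permute_labels(small_voronoi, seed=9)
        v = ps.dice_map(ps.contingency(small_voronoi, other)).values
        assert v.min() >= 0.0 and v.max() <= 1.0 + 1e-12

    def test_nested_region_has_single_nonzero_row(self, small_voronoi):
        child = ps.refine_parcellation(small_voronoi, 3, seed=5)
        dm = ps.dice_map(ps.contingency(child, small_voronoi))
        nonzero_per_row = (dm.values > 0).sum(axis=1)
        assert np.all(nonzero_per_row == 1)


class TestEntropyMI:
    def test_single_region_entropy_zero(self):
        assert ps.entropy([10], 10) == 0.0

    def test_uniform_entropy_closed_form(self):
        assert ps.entropy([3, 3, 3, 3], 12) == pytest.approx(math.log(4), abs=1e-12)

    def test_skewed_entropy_value(self):
        expected = -(0.25 * math.log(0.25) + 0.75 * math.log(0.75))
        assert ps.entropy([1, 3], 4) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.562335, abs=1e-6)

    def test_entropy_zero_total_raises(self):
        with pytest.raises(ParameterError):
            ps.entropy([0], 0)

    def test_mi_zero_under_exact_independence(self):
        # h_ij = a_i b_j / N exactly
        t = table([[1, 1], [1, 1]])
        assert ps.mutual_information(t) == pytest.approx(0.0, abs=1e-12)

    def test_mi_equals_entropy_for_identical_partitions(self):
        t = table([[3, 0, 0], [0, 2, 0], [0, 0, 5]])
        assert ps.mutual_information(t) == pytest.approx(
            ps.entropy([3, 2, 5], 10), abs=1e-12
        )

    def test_mi_matches_brute_force_on_four_voxel_table(self):
        counts = [[1, 1], [0, 2]]
        assert ps.mutual_information(table(counts)) == pytest.approx(
            mi_brute(counts), abs=1e-14
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_mi_nonnegative_and_bounded_by_entropies(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 6, size=(4, 3))
        counts[0, 0] += 1  # never empty
        counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
        t = table(counts)
        mi = ps.mutual_information(t)
        assert mi >= -1e-12
        h = min(ps.entropy(t.row_marginals, t.total), ps.entropy(t.col_marginals, t.total))
        assert mi <= h + 1e-9


class TestExpectedMI:
    def test_single_region_side_is_zero(self):
        assert ps.expected_mi([8], [3, 5], 8) == pytest.approx(0.0, abs=1e-12)

    def test_matches_full_enumeration_2x2(self):
        exact = ps.expected_mi([2, 2], [2, 2], 4)
        oracle = ps.emi_exhaustive([2, 2], [2, 2], 4)
        assert exact == pytest.approx(oracle, abs=1e-12)

    def test_bounded_by_min_entropy(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.integers(1, 20, size=5)
            b = rng.multinomial(a.sum(), np.ones(4) / 4) + 1
            n = a.sum() + 4
            a = np.append(a, 4)
            emi = ps.expected_mi(a, b, n)
            assert emi <= min(ps.entropy(a, n), ps.entropy(b, n)) + 1e-9

    def test_inconsistent_marginals_raise(self):
        with pytest.raises(ConsistencyError):
            ps.expected_mi([2, 2], [3, 3], 4)

    def test_monte_carlo_agrees_with_exact(self):
        a, b, n = [5, 7, 4], [6, 6, 4], 16
        exact = ps.expected_mi(a, b, n)
        mean, se = ps.emi_monte_carlo(a, b, n, reps=2000, seed=11)
        assert abs(mean - exact) <= 3 * se + 1e-12

    def test_monte_carlo_single_region_degenerate(self):
        mean, se = ps.emi_monte_carlo([9], [4, 5], 9, reps=100, seed=0)
        assert mean == pytest.approx(0.0, abs=1e-12) and se == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_reproducible(self):
        r1 = ps.emi_monte_carlo([3, 5], [4, 4], 8, reps=200, seed=7)
        r2 = ps.emi_monte_carlo([3, 5], [4, 4], 8, reps=200, seed=7)
        assert r1 == r2

    def test_monte_carlo_rejects_tiny_reps(self):
        with pytest.raises(ParameterError):
            ps.emi_monte_carlo([3, 5], [4, 4], 8, reps=10, seed=0)

    def test_large_n_remains_finite(self):
        rng = np.random.default_rng(1)
        a = rng.multinomial(10**7, np.ones(100) / 100)
        b = rng.multinomial(10**7, np.ones(80) / 80)
        emi = ps.expected_mi(a, b, 10**7)
        assert np.isfinite(emi) and emi >= 0.0


class TestAmi:
    def test_self_agreement(self, small_voronoi):
        r = ps.ami(ps.contingency(small_voronoi, small_voronoi))
        assert r.ami == pytest.approx(1.0, abs=1e-9)

    def test_relabeling_invariance(self, small_voronoi):
        q = ps.permute_labels(small_voronoi, seed=5)
        r = ps.ami(ps.contingency(small_voronoi, q))
        assert r.ami == pytest.approx(1.0, abs=1e-9)

    def test_single_region_both_sides_degenerate_identical(self):
        r = ps.ami(table([[6]]))
        assert r.ami == 1.0

    def test_perfect_vs_uninformative_two_by_two(self):
        perfect = ps.ami(table([[2, 0], [0, 2]]))
        assert perfect.ami == pytest.approx(1.0, abs=1e-9)
        flat = ps.ami(table([[1, 1], [1, 1]]))
        # MI = 0 here, so AMI = -EMI / (H - EMI) <= 0
        assert flat.ami <= 1e-9

    def test_components_recorded(self):
        r = ps.ami(table([[1, 1], [0, 2]]))
        assert r.n_voxels == 4
        assert r.mi == pytest.approx(mi_brute([[1, 1], [0, 2]]), abs=1e-12)
        assert r.entropy_a == pytest.approx(ps.entropy([2, 2], 4), abs=1e-12)
        assert r.emi == pytest.approx(ps.emi_exhaustive([2, 2], [1, 3], 4), abs=1e-12)

    def test_agrees_with_sklearn_reference(self):
        """Cross-check against scikit-learn's AMI (arithmetic mean)."""
        from sklearn.metrics import adjusted_mutual_info_score

        rng = np.random.default_rng(12)
        for _ in range(10):
            la = rng.integers(0, rng.integers(2, 8), size=400)
            lb = rng.integers(0, rng.integers(2, 8), size=400)
            mine = ps.ami(contingency_from_arrays(la, lb)).ami
            ref = adjusted_mutual_info_score(la, lb, average_method="arithmetic")
            assert mine == pytest.approx(ref, abs=1e-6)

    def test_refinement_scores_above_independent(self, small_voronoi):
        child = ps.refine_parcellation(small_voronoi, 2, seed=2)
        k = len(ps.list_labels(child))
        indep = ps.voronoi_parcellation(
            ps.SynthSpec(shape=(24, 24, 24), n_regions=k, seed=77,
                         semi_axes=(10.5, 10.5, 10.5))
        )
        ami_child = ps.ami(ps.contingency(small_voronoi, child)).ami
        ami_indep = ps.ami(ps.contingency(small_voronoi, indep)).ami
        assert ami_child > ami_indep

    def test_refinement_ami_decreases_with_split_count(self, small_voronoi):
        scores = []
        for splits in (2, 4, 8):
            child = ps.refine_parcellation(small_voronoi, splits, seed=3)
            scores.append(ps.ami(ps.contingency(small_voronoi, child)).ami)
        assert scores[0] > scores[1] > scores[2]


class TestPairwiseAmi:
    def test_single_atlas(self, small_voronoi):
        names, mat = ps.pairwise_ami([small_voronoi])
        np.testing.assert_allclose(mat, [[1.0]])
        assert names == [small_voronoi.name]

    def test_permuted_pair_and_symmetry(self, small_voronoi):
        q = ps.permute_labels(small_voronoi, seed=1)
        child = ps.refine_parcellation(small_voronoi, 2, seed=1)
        _, mat = ps.pairwise_ami([small_voronoi, q, child])
        np.testing.assert_allclose(mat, mat.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(mat), 1.0, atol=1e-9)
        assert mat[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert 0 < mat[0, 2] < 1

    def test_grid_mismatch_raises(self, small_voronoi):
        other = parc(np.ones((4, 4, 4), dtype=np.int64))
        with pytest.raises(ps.GridMismatchError):
            ps.pairwise_ami([small_voronoi, other])
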