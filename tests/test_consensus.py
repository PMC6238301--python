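"""Consensus procedure: confusion matrices, linear-assignment cluster
matching, frequency filtering, row association and heatmap ordering."""

import itertools

import numpy as np
import pytest

from promclust import consensus as cs
from promclust.bicluster import Bicluster, BiclusterSolution


def solution(col_sets, n_cols, n_rows=4, row_sets=None):
    bcs = []
    for i, cols in enumerate(col_sets):
        rows = row_sets[i] if row_sets else (0,)
        bcs.append(Bicluster(tuple(rows), tuple(cols), 1.0))
    return BiclusterSolution(bcs, n_rows, n_cols)


class TestConfusionMatrix:
    def test_identical_solutions_are_diagonal(self):
        a = solution([range(5), range(5, 12)], 12)
        np.testing.assert_array_equal(cs.confusion_matrix(a, a),
                                      [[5, 0], [0, 7]])

    def test_split_cluster(self):
        a = solution([[0, 1, 2, 3]], 4)
        b = solution([[0, 1], [2, 3]], 4)
        np.testing.assert_array_equal(cs.confusion_matrix(a, b), [[2, 2]])

    def test_matches_set_intersection_oracle(self, rng):
        n = 30
        for _ in range(20):
            la = rng.integers(-1, 3, n)
            lb = rng.integers(-1, 4, n)
            a = solution([np.flatnonzero(la == k) for k in range(3)
                          if (la == k).any()], n)
            b = solution([np.flatnonzero(lb == k) for k in range(4)
                          if (lb == k).any()], n)
            got = cs.confusion_matrix(a, b)
            for i, bca in enumerate(a.biclusters):
                for j, bcb in enumerate(b.biclusters):
                    assert got[i, j] == len(set(bca.cols) & set(bcb.cols))

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            cs.confusion_matrix(solution([[0]], 3), solution([[0]], 4))


def brute_force_lap(grid):
    """Oracle: maximum assignment over all permutations."""
    ns, nt = grid.shape
    dim = max(ns, nt)
    padded = np.zeros((dim, dim))
    padded[:ns, :nt] = grid
    return max(sum(padded[i, p[i]] for i in range(dim))
               for p in itertools.permutations(range(dim)))


class TestAssignClusters:
    def test_identity(self):
        m = cs.assign_clusters(np.array([[5, 0], [0, 7]]))
        assert m.assignment == {0: 0, 1: 1} and m.total_overlap == 12

    def test_swap(self):
        m = cs.assign_clusters(np.array([[0, 5], [7, 0]]))
        assert m.assignment == {0: 1, 1: 0} and m.total_overlap == 12

    def test_rectangular_surplus_unmapped(self):
        m = cs.assign_clusters(np.array([[9, 0], [0, 8], [1, 1]]))
        assert set(m.assignment) <= {0, 1, 2} and len(m.assignment) == 2

    def test_matches_permutation_oracle(self, rng):
        for _ in range(100):
            grid = rng.integers(0, 20, (4, 4))
            got = cs.assign_clusters(grid).total_overlap
            assert got == brute_force_lap(grid)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cs.assign_clusters(np.array([[-1, 0], [0, 1]]))


@pytest.fixture(scope="module")
def noise_free_consensus():
    x = np.zeros((10, 30))
    x[:3, :12] = 1.0
    x[5:8, 15:25] = 0.9
    return x, cs.consensus_biclust(x, engine="ssvd", n_runs=5, seed=42)


class TestConsensusBiclust:
    def test_deterministic_engine_gives_frequency_one(self, noise_free_consensus):
        _, sol = noise_free_consensus
        for j, k in sol.retained_cols.items():
            assert sol.column_frequency[j, k] == 1.0

    def test_noise_free_equals_single_run(self, noise_free_consensus):
        x, sol = noise_free_consensus
        from promclust.bicluster import run_ssvd
        single = run_ssvd(x, seed=0)
        expected = {tuple(sorted(b.cols)) for b in single.biclusters}
        got = {tuple(sol.cluster_columns(k)) for k in range(sol.n_clusters)
               if sol.cluster_columns(k)}
        assert got == expected

    def test_frequencies_sum_to_at_most_one(self, noise_free_consensus):
        _, sol = noise_free_consensus
        assert (sol.column_frequency.sum(axis=1) <= 1.0 + 1e-12).all()

    def test_low_frequency_columns_dropped(self):
        # engine stub: column 5 lands in the target cluster in only 2
        # of 5 runs (frequency 0.4 < 0.5) and must be dropped
        calls = itertools.count()

        def engine(matrix, seed, **kw):
            cols = (0, 1, 2, 5) if next(calls) < 2 else (0, 1, 2)
            return BiclusterSolution([Bicluster((0,), cols, 1.0)], 2, 8)

        sol = cs.consensus_biclust(np.zeros((2, 8)), engine=engine,
                                   n_runs=5, seed=0,
                                   compute_row_tests=False)
        freqs = sol.column_frequency[5]
        assert freqs.max() <= 0.5 and 5 not in sol.retained_cols
        assert 0 in sol.retained_cols

    def test_same_seed_fully_reproducible(self, planted):
        mat, _ = planted
        a = cs.consensus_biclust(mat.values, n_runs=6, seed=9)
        b = cs.consensus_biclust(mat.values, n_runs=6, seed=9)
        assert a.retained_cols == b.retained_cols
        assert a.retained_rows == b.retained_rows
        np.testing.assert_array_equal(a.column_frequency, b.column_frequency)

    def test_min_freq_monotonicity(self, planted):
        mat, _ = planted
        sol = cs.consensus_biclust(mat.values, n_runs=6, seed=9,
                                   compute_row_tests=False)
        kept = {}
        for f in (0.3, 0.5, 0.7):
            kept[f] = {j for j in range(mat.values.shape[1])
                       if sol.column_frequency[j].max() > f}
        assert kept[0.7] <= kept[0.5] <= kept[0.3]

    def test_engine_with_no_clusters_gives_empty_solution(self):
        sol = cs.consensus_biclust(np.zeros((4, 6)), engine="ssvd",
                                   n_runs=3, seed=0)
        assert sol.n_clusters == 0 and sol.retained_cols == {}


class TestRowClusterTTest:
    def test_closed_form_value(self):
        # inside values [1,2,3], outside [4,5,6]: t = -3 / sqrt(1/3 + 1/3)
        x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        t, p, bar = cs.row_cluster_ttest(x, [0, 1, 2], 0)
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert bar == pytest.approx(-np.log10(p))

    def test_identical_constants_give_zero_bar(self):
        x = np.full((1, 8), 2.5)
        t, p, bar = cs.row_cluster_ttest(x, [0, 1, 2, 3], 0)
        assert t == 0.0 and p == 1.0 and bar == 0.0

    def test_bar_is_neglog10(self):
        assert cs.row_cluster_ttest(
            np.array([[0.0, 0, 0, 1, 1, 1.01]]), [0, 1, 2], 0
        )[2] == pytest.approx(-np.log10(cs.row_cluster_ttest(
            np.array([[0.0, 0, 0, 1, 1, 1.01]]), [0, 1, 2], 0)[1]))

    def test_improper_cluster_rejected(self):
        with pytest.raises(ValueError):
            cs.row_cluster_ttest(np.zeros((1, 4)), [0, 1, 2, 3], 0)


class TestOrderHeatmap:
    def test_two_block_boundaries(self, noise_free_consensus):
        x, sol = noise_free_consensus
        row_order, col_order, col_b, row_b = cs.order_heatmap(x, sol)
        assert col_b[0] == 12  # larger planted block first
        assert set(col_order[:12]) == set(range(12))
        assert set(col_order[12:22]) == set(range(15, 25))
        assert set(row_order[:3]) == {0, 1, 2}

    def test_solution_serializes_to_json(self, noise_free_consensus):
        import json
        _, sol = noise_free_consensus
        out = json.dumps(sol.to_dict())
        assert json.loads(out)["n_runs"] == 5

    def test_orders_are_permutations(self, noise_free_consensus):
        x, sol = noise_free_consensus
        row_order, col_order, _, _ = cs.order_heatmap(x, sol)
        assert sorted(row_order) == list(range(x.shape[0]))
        assert sorted(col_order) == list(range(x.shape[1]))
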