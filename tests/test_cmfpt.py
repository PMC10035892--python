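import numpy as np
import pytest

from clonefpt.cmfpt import (WalkConfig, estimate_cmfpt, exact_cmfpt,
                            normalized_cmfpt, null_cmfpt, walk_graph)
from clonefpt.patterns import (EMPTY, RED, YELLOW, BinnedPattern, ClassGrid,
                               downsample, generate_clusters, generate_column)
from tests.conftest import random_two_class

CFG = WalkConfig(walks_per_start=2000, seed=11, null_reps=4)


def swap_colours(grid):
    labels = grid.labels.copy()
    labels[grid.labels == RED] = YELLOW
    labels[grid.labels == YELLOW] = RED
    return ClassGrid(labels)


class TestWalkGraph:
    def test_path_graph_of_three(self, ryr_row):
        graph = walk_graph(downsample(ryr_row))
        assert graph.n_nodes == 3
        assert list(graph.degrees) == [1, 2, 1]

    def test_empty_bins_excluded(self):
        labels = np.array([[RED, EMPTY, YELLOW],
                           [RED, EMPTY, YELLOW]], dtype=np.int8)
        with pytest.warns(UserWarning, match="components"):
            graph = walk_graph(downsample(ClassGrid(labels)))
        assert graph.n_nodes == 4

    def test_fractional_bin_class_probability(self):
        # (f_red, f_yellow, f_empty) = (0.3, 0.3, 0.4): renormalised to 1/2
        b = BinnedPattern(
            f_red=np.array([[0.3, 1.0]]), f_yellow=np.array([[0.3, 0.0]]),
            f_empty=np.array([[0.4, 0.0]]), n_sites=np.array([[10.0, 10.0]]))
        graph = walk_graph(b)
        assert graph.p_red[0] == pytest.approx(0.5)


class TestExactOracle:
    def test_ryr_hand_solution(self, ryr_row):
        tau = exact_cmfpt(downsample(ryr_row))
        # middle node's both neighbours are red; ends' only neighbour yellow
        np.testing.assert_allclose(tau, [[2.0, 1.0], [1.0, 2.0]])

    def test_two_node_forced_alternation(self):
        grid = ClassGrid(np.array([[RED, YELLOW]], dtype=np.int8))
        tau = exact_cmfpt(downsample(grid))
        np.testing.assert_allclose(tau, [[2.0, 1.0], [1.0, 2.0]])

    def test_uniform_fraction_bins_are_geometric(self):
        # every bin half red / half yellow: absorption is a fair coin on
        # each arrival, so every tau entry is exactly 2
        b = BinnedPattern(
            f_red=np.full((12, 12), 0.5), f_yellow=np.full((12, 12), 0.5),
            f_empty=np.zeros((12, 12)), n_sites=np.full((12, 12), 4.0))
        np.testing.assert_allclose(exact_cmfpt(b), np.full((2, 2), 2.0))

    def test_colour_swap_duality_exact(self):
        grid = random_two_class((9, 9), 0.4, seed=2)
        tau = exact_cmfpt(downsample(grid))
        tau_sw = exact_cmfpt(downsample(swap_colours(grid)))
        np.testing.assert_allclose(tau_sw, tau[::-1, ::-1], rtol=1e-10)

    def test_unreachable_class_errors(self):
        labels = np.array([[RED, EMPTY, YELLOW],
                           [RED, EMPTY, YELLOW]], dtype=np.int8)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="unreachable"):
                exact_cmfpt(downsample(ClassGrid(labels)))


class TestMonteCarloEstimator:
    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_oracle_on_random_patterns(self, seed):
        grid = random_two_class((8, 8), 0.5 if seed % 2 else 0.3, seed=seed)
        binned = downsample(grid)
        expect = exact_cmfpt(binned)
        est = estimate_cmfpt(binned, WalkConfig(walks_per_start=2000,
                                                seed=100 + seed))
        for a in range(2):
            for b in range(2):
                tol = 3 * est.se[a, b] + 1e-9
                assert abs(est.tau[a, b] - expect[a, b]) < tol

    def test_agrees_with_oracle_on_fractional_bins(self):
        grid = random_two_class((16, 16), 0.4, seed=10)
        binned = downsample(grid, target_bins=64)  # 2x2 fractional bins
        expect = exact_cmfpt(binned)
        est = estimate_cmfpt(binned, WalkConfig(walks_per_start=4000, seed=3))
        assert (np.abs(est.tau - expect) < 3 * est.se + 1e-9).all()

    def test_tau_at_least_one(self, iid_30x30):
        est = estimate_cmfpt(downsample(iid_30x30),
                             WalkConfig(walks_per_start=200, seed=0))
        assert (est.tau >= 1.0).all()

    def test_entry_selection_matches_full_run(self, ryr_row):
        binned = downsample(ryr_row)
        full = estimate_cmfpt(binned, CFG)
        ry = estimate_cmfpt(binned, CFG, entries=("ry",))
        assert np.isnan(ry.tau[1, 1])
        assert ry.tau[0, 1] == pytest.approx(full.tau[0, 1], rel=0.05)

    def test_one_class_absent_errors(self):
        grid = ClassGrid(np.full((4, 4), RED, dtype=np.int8))
        with pytest.raises(ValueError):
            estimate_cmfpt(downsample(grid), CFG)

    def test_reproducible(self, iid_30x30):
        binned = downsample(iid_30x30)
        a = estimate_cmfpt(binned, WalkConfig(walks_per_start=300, seed=5))
        b = estimate_cmfpt(binned, WalkConfig(walks_per_start=300, seed=5))
        np.testing.assert_array_equal(a.tau, b.tau)


class TestNullModel:
    def test_null_invariant_under_label_permutation(self, iid_30x30):
        binned = downsample(iid_30x30)
        shuffled = iid_30x30.labels.ravel().copy()
        np.random.default_rng(0).shuffle(shuffled)
        binned_perm = downsample(ClassGrid(shuffled.reshape(30, 30)))
        a = null_cmfpt(binned, CFG)
        b = null_cmfpt(binned_perm, CFG)
        np.testing.assert_array_equal(a.tau, b.tau)

    def test_null_preserves_abundances_in_expectation(self, iid_30x30):
        # null tau_ry for phi = 0.5 iid pattern stays near the raw value
        binned = downsample(iid_30x30)
        raw = estimate_cmfpt(binned, CFG)
        null = null_cmfpt(binned, CFG)
        assert null.tau[0, 1] == pytest.approx(raw.tau[0, 1], rel=0.1)


class TestNormalized:
    def test_iid_pattern_sits_at_unit_coordinates(self):
        grid = random_two_class((40, 40), 0.5, seed=21)
        res = normalized_cmfpt(downsample(grid),
                               WalkConfig(walks_per_start=1500, seed=2,
                                          null_reps=6))
        assert res.tau_ry_tilde == pytest.approx(1.0, abs=0.08)
        assert res.coords[1] == pytest.approx(1.0, abs=0.08)

    def test_column_mirror_symmetry(self):
        grid = generate_column(30, 30, 0.5)
        res = normalized_cmfpt(downsample(grid),
                               WalkConfig(walks_per_start=1500, seed=4,
                                          null_reps=6))
        assert res.tau_ry_tilde == pytest.approx(res.tau_yr_tilde, rel=0.1)

    def test_segregation_orders_column_above_clusters(self):
        cfg = WalkConfig(walks_per_start=800, seed=9, null_reps=4)
        col = normalized_cmfpt(downsample(generate_column(54, 54, 0.5)),
                               cfg, entries=("ry",))
        clu = normalized_cmfpt(
            downsample(generate_clusters(54, 54, 0.5, 3, seed=1)),
            cfg, entries=("ry",))
        assert col.tau_ry_tilde > clu.tau_ry_tilde
        assert col.tau_ry_tilde > 1.5  # strongly segregated

    def test_scale_normalization_under_tiling(self):
        grid = generate_clusters(24, 24, 0.3, 3, seed=6)
        tiled = ClassGrid(np.tile(grid.labels, (2, 2)))
        cfg = WalkConfig(walks_per_start=1000, seed=13, null_reps=6)
        a = normalized_cmfpt(downsample(grid), cfg, entries=("ry",))
        b = normalized_cmfpt(downsample(tiled), cfg, entries=("ry",))
        assert a.tau_ry_tilde == pytest.approx(b.tau_ry_tilde, rel=0.15)
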