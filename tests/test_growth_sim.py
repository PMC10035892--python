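import numpy as np
import pytest
from scipy import ndimage, stats

from clonefpt.growth_sim import (SimParams, TumourState, attempt_division,
                                 choose_push_path, simulate_tumour, slice_3d)
from clonefpt.patterns import EMPTY, RED, YELLOW, ClassGrid, class_ratio


def block_state(side, block, seed=0):
    """Square grid with a central block of WT cells, elsewhere empty."""
    labels = np.zeros((side, side), dtype=np.int8)
    lo = (side - block) // 2
    labels[lo:lo + block, lo:lo + block] = YELLOW
    return TumourState.from_grid(ClassGrid(labels), seed=seed)


class TestPushPath:
    def test_adjacent_empty_gives_empty_chain(self):
        state = block_state(5, 1)
        path = choose_push_path(state, (2, 2), q=0)
        assert path.chain == []
        assert abs(path.empty_site[0] - 2) + abs(path.empty_site[1] - 2) == 1

    def test_unique_minimal_chain_row(self):
        # divider at the corner; every depth-1 neighbour occupied and the
        # only reachable empty within a chain of 1 is along the top row
        labels = np.full((3, 3), EMPTY, dtype=np.int8)
        for site in ((0, 0), (0, 1), (1, 0), (1, 1), (2, 0)):
            labels[site] = YELLOW
        state = TumourState.from_grid(ClassGrid(labels))
        path = choose_push_path(state, (0, 0), q=1)
        assert path.chain == [(0, 1)]
        assert path.empty_site == (0, 2)

    def test_centre_of_3x3_block_needs_one_push(self):
        state = block_state(7, 3)
        assert choose_push_path(state, (3, 3), q=0) is None
        path = choose_push_path(state, (3, 3), q=1)
        assert path is not None and len(path.chain) == 1

    @pytest.mark.parametrize("q", [0, 1, 2, 3])
    def test_block_too_thick_for_push_limit(self, q):
        # centre of a (2q+3)-square block: nearest empty needs q+1 pushes
        side = 2 * q + 3 + 4
        state = block_state(side, 2 * q + 3)
        centre = (side // 2, side // 2)
        assert choose_push_path(state, centre, q=q) is None
        assert choose_push_path(state, centre, q=q + 1) is not None

    def test_straight_chain_preferred_over_turning(self):
        # divider at (0,0); straight chain right of length 1, and an equally
        # short turning chain down-then-right; the straight one must win
        labels = np.full((4, 4), EMPTY, dtype=np.int8)
        labels[0, 0] = labels[0, 1] = labels[1, 0] = YELLOW
        for seed in range(20):
            state = TumourState.from_grid(ClassGrid(labels), seed=seed)
            path = choose_push_path(state, (0, 0), q=1)
            # never the turning chain into (1, 1)
            assert (path.chain, path.empty_site) in (
                ([(0, 1)], (0, 2)), ([(1, 0)], (2, 0)))

    def test_empty_divider_site_rejected(self):
        state = block_state(5, 1)
        with pytest.raises(ValueError):
            choose_push_path(state, (0, 0), q=0)


class TestAttemptDivision:
    def test_success_places_same_genotype_daughter(self):
        labels = np.zeros((5, 5), dtype=np.int8)
        labels[2, 2] = RED
        state = TumourState.from_grid(ClassGrid(labels))
        assert attempt_division(state, (2, 2), q=0)
        grid = state.to_grid()
        assert (grid.labels == RED).sum() == 2

    def test_failure_leaves_state_unchanged(self):
        state = block_state(9, 5)
        before = state.to_grid()
        assert not attempt_division(state, (4, 4), q=0)
        assert state.to_grid() == before

    def test_push_conserves_cells(self):
        state = block_state(9, 3)
        n0 = state.n_cells
        assert attempt_division(state, (4, 4), q=1)
        grid = state.to_grid()
        assert (grid.labels != EMPTY).sum() == n0 + 1


class TestSimulateTumour:
    def test_bookkeeping_small_run(self):
        params = SimParams(s=0.0, n_mut=0.5, q=0, n_max=200, seed=1)
        grid, rec = simulate_tumour(params)
        assert rec.pop_at_mutation == 100
        assert rec.final_n_wt + rec.final_n_mut == 200
        assert (grid.labels != EMPTY).sum() == 200
        assert 0 < rec.final_phi < 1
        assert rec.final_phi == pytest.approx(class_ratio(grid))

    def test_no_deaths_when_psi_zero(self):
        params = SimParams(s=0.5, n_mut=0.25, q=2, n_max=400, psi=0.0, seed=2)
        _, rec = simulate_tumour(params)
        assert rec.n_deaths == 0
        assert rec.final_n_wt + rec.final_n_mut == 400

    def test_reproducible(self):
        params = SimParams(s=1.0, n_mut=0.1, q=3, n_max=500, seed=9)
        g1, r1 = simulate_tumour(params)
        g2, r2 = simulate_tumour(params)
        assert g1 == g2
        assert r1 == r2

    def test_death_fraction_matches_psi(self):
        params = SimParams(s=0.5, n_mut=0.1, q=5, n_max=20_000, seed=4)
        _, rec = simulate_tumour(params)
        frac = rec.n_deaths / rec.n_firings
        se = np.sqrt(0.3 * 0.7 / rec.n_firings)
        assert rec.n_firings > 1e4
        assert abs(frac - 0.3) < 3 * se

    def test_mutant_firing_rate_is_1_plus_s_fold(self):
        # chi-squared on the event log against the expected mutant share
        params = SimParams(s=3.0, n_mut=0.1, q=5, n_max=10_000, seed=5)
        _, rec = simulate_tumour(params)
        exp_mut = rec.expected_mut_firings
        exp_wt = rec.n_firings - exp_mut
        chi2 = ((rec.n_mut_firings - exp_mut) ** 2 / exp_mut
                + (rec.n_wt_firings - exp_wt) ** 2 / exp_wt)
        assert stats.chi2.sf(chi2, df=1) > 1e-4

    def test_surface_growth_colony_is_compact(self):
        # q = 0 and psi = 0: growth only at the boundary; the colony is one
        # connected blob and can trap at most a few tiny empty pockets
        # where two advancing arms seal a concavity
        params = SimParams(s=0.0, n_mut=0.5, q=0, n_max=2_000, psi=0.0,
                           seed=6)
        grid, _ = simulate_tumour(params, crop=False)
        occ = grid.labels != EMPTY
        _, n_occ = ndimage.label(occ)
        labels_bg, n_bg = ndimage.label(~occ)
        assert n_occ == 1
        # all background components except the outside are trapped pockets
        outside = labels_bg[0, 0]
        pocket = (~occ) & (labels_bg != outside)
        assert pocket.sum() < 0.01 * occ.sum()

    def test_restart_budget_error_mentions_params(self):
        with pytest.raises(Exception, match="n_mut=0.5"):
            # single attempts essentially never all survive mutant drift
            for s in range(50):
                simulate_tumour(SimParams(s=0.0, n_mut=0.5, q=0, n_max=500,
                                          seed=s, max_restarts=1))

    @pytest.mark.parametrize("bad", [
        dict(s=-0.1, n_mut=0.1, q=0, n_max=100),
        dict(s=0.0, n_mut=0.0, q=0, n_max=100),
        dict(s=0.0, n_mut=0.1, q=-1, n_max=100),
        dict(s=0.0, n_mut=0.1, q=0, n_max=100, psi=1.5),
        dict(s=0.0, n_mut=0.001, q=0, n_max=100),  # n_intro < 1
    ])
    def test_invalid_params(self, bad):
        with pytest.raises(ValueError):
            SimParams(**bad)


class TestThreeDimensions:
    def test_3d_run_and_slicing_conserve_classes(self):
        params = SimParams(s=1.0, n_mut=0.2, q=2, n_max=2_000, dims=3, seed=8)
        grid, rec = simulate_tumour(params)
        assert grid.labels.ndim == 3
        assert (grid.labels != EMPTY).sum() == 2_000
        # restacking all z-slices reproduces the volume
        stack = np.stack([slice_3d(grid, "z", i).labels
                          for i in range(grid.depth)])
        assert np.array_equal(stack, grid.labels)
        # class totals over slices of one axis equal the volume totals
        reds = sum((slice_3d(grid, "x", i).labels == RED).sum()
                   for i in range(grid.width))
        assert reds == rec.final_n_mut

    def test_uniform_cube_slice(self):
        cube = ClassGrid(np.full((4, 4, 4), RED, dtype=np.int8))
        assert (slice_3d(cube, "y", 2).labels == RED).all()
        with pytest.raises(IndexError):
            slice_3d(cube, "z", 4)
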