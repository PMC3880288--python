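"""Tip migration, branching hotpoints, vessel maturation and pruning."""

import numpy as np
import pytest

import tumorsim as ts
from tumorsim import (AngioParams, NECROTIC, SimulationConfig, init_state,
                      branching_probability, prune_vessels, radius_map,
                      age_and_radius_update, VesselNetwork,
                      vessel_growth_rate)
from tumorsim.angiogenesis import (apply_branching, sample_branching_hotpoints,
                                   step_angiogenesis, tip_migration_step)

PARAMS = AngioParams()


class TestGrowthRate:
    def test_baseline_floor_at_zero_head(self):
        assert vessel_growth_rate(0.0, PARAMS) == PARAMS.g1_normal
        assert vessel_growth_rate(-10.0, PARAMS) == PARAMS.g1_normal

    def test_strictly_increasing_for_positive_head(self):
        r1 = vessel_growth_rate(5.0, PARAMS)
        r2 = vessel_growth_rate(20.0, PARAMS)
        assert PARAMS.g1_normal < r1 < r2

    def test_in_tumor_baseline_is_higher(self):
        assert (vessel_growth_rate(0.0, PARAMS, in_tumor=True)
                > vessel_growth_rate(0.0, PARAMS))

    def test_full_head_regression(self):
        # rate at delta_p = p_v doubles the baseline (g2 = g1 by default)
        assert vessel_growth_rate(PARAMS.p_v, PARAMS) == pytest.approx(
            2 * PARAMS.g1_normal)


class TestBranchingProbability:
    def test_zero_taf_zero_probability(self):
        assert branching_probability(0.0, PARAMS) == 0.0

    def test_unit_taf_equals_kbh(self):
        assert branching_probability(1.0, PARAMS) == pytest.approx(0.3e-3)

    def test_monotone_and_capped(self):
        c = np.linspace(0, 2000, 50)
        p = branching_probability(c, PARAMS)
        assert np.all(np.diff(p) >= 0)
        assert np.all(p <= 1.0)


class TestRadiusAndAge:
    def test_radius_monotone_saturating(self):
        ages = np.array([0.0, 1.0, 10.0, 100.0, 1e4, 1e7])
        r = radius_map(ages, PARAMS)
        assert np.all(np.diff(r) >= 0)
        assert r[0] == 0.0
        assert r[-1] == pytest.approx(PARAMS.k_AR1 * PARAMS.R_max, rel=1e-3)

    def test_half_saturation_at_kar2(self):
        assert radius_map(PARAMS.k_AR2, PARAMS) == pytest.approx(
            0.5 * PARAMS.k_AR1 * PARAMS.R_max)

    def test_stalled_tip_ages_backwards(self):
        net = VesselNetwork()
        a = net.add_segment((0, 0, 0), age=5.0, is_tip=True)
        b = net.add_segment((5, 5, 5), age=5.0, is_tip=True)
        net.segments[a].stall = PARAMS.stall_limit + 1
        age_and_radius_update(net, PARAMS)
        assert net.segments[a].age == 4.0
        assert net.segments[b].age == 6.0


class TestPruning:
    def test_no_zero_age_is_identity(self):
        net = VesselNetwork()
        net.add_segment((0, 0, 0), age=3.0)
        net.add_segment((1, 0, 0), parent=0, age=2.0)
        before = net.copy()
        assert prune_vessels(net) == before

    def test_root_pruned_removes_tree(self):
        net = VesselNetwork()
        root = net.add_segment((0, 0, 0), age=0.0)
        net.add_segment((1, 0, 0), parent=root, age=5.0)
        net.add_segment((2, 0, 0), parent=1, age=5.0)
        prune_vessels(net)
        assert len(net) == 0

    def test_midbranch_prune_removes_distal_subtree(self):
        net = VesselNetwork()
        ids = [net.add_segment((x, 0, 0), parent=(x - 1 if x else -1), age=5.0)
               for x in range(5)]
        net.segments[ids[2]].age = 0.0
        prune_vessels(net)
        assert set(net.segments) == {ids[0], ids[1]}
        assert net.is_forest()


def _angio_state(taf_gradient_axis=None):
    config = SimulationConfig(grid_points_per_axis=16, domain_edge=0.0008,
                              c_init=0.0)
    state = init_state(config)
    if taf_gradient_axis is not None:
        coords = np.arange(16, dtype=float) / 16.0
        shape = [1, 1, 1]
        shape[taf_gradient_axis] = 16
        state.fields["taf"].values[:] = coords.reshape(shape)
    return state


class TestTipMigration:
    def test_moves_up_unique_gradient(self):
        state = _angio_state(taf_gradient_axis=0)
        tip = state.vessels.add_segment((8, 8, 8), age=10.0, is_tip=True)
        child = tip_migration_step(state, tip, u=0.5)
        assert state.vessels.segments[child].pos == (9, 8, 8)
        assert not state.vessels.segments[tip].is_tip

    def test_uniform_taf_falls_back_to_uniform_choice(self):
        positions = set()
        for u in np.linspace(0, 0.999, 12):
            state = _angio_state()
            tip = state.vessels.add_segment((8, 8, 8), age=10.0, is_tip=True)
            child = tip_migration_step(state, tip, u=float(u))
            positions.add(state.vessels.segments[child].pos)
        assert len(positions) == 6

    def test_surrounded_by_necrotic_stalls(self):
        state = _angio_state()
        state.lattice = ts.CellLattice(state.grid.shape)
        tip = state.vessels.add_segment((8, 8, 8), age=10.0, is_tip=True)
        for nb in ts.neighborhood((8, 8, 8), (16, 16, 16), "faces6"):
            state.lattice.add_cell(nb, NECROTIC)
        assert tip_migration_step(state, tip, u=0.3) is None
        assert state.vessels.segments[tip].stall == 1


class TestBranchingSampling:
    def test_zero_taf_no_hotpoints(self):
        state = _angio_state()
        state.vessels.add_segment((8, 8, 8), age=10.0)
        u = np.full((16, 16, 16), 0.5)
        assert sample_branching_hotpoints(state, u) == []

    def test_forced_branch_spawns_one_tip(self):
        state = _angio_state()
        seg = state.vessels.add_segment((8, 8, 8), age=10.0)
        state.fields["taf"].values[:] = 1.0
        u = np.ones((16, 16, 16))  # no draw succeeds ...
        u[9, 8, 8] = 0.0           # ... except this forced voxel
        hp = sample_branching_hotpoints(state, u)
        assert hp == [(seg, (9, 8, 8))]
        assert apply_branching(state, hp) == 1
        new = state.vessels.segment_at((9, 8, 8))
        assert new is not None and new.is_tip

    def test_deterministic_given_state_and_step(self):
        results = []
        for _ in range(2):
            state = _angio_state()
            state.fields["taf"].values[:] = 0.8
            state.vessels.add_segment((8, 8, 8), age=10.0)
            from tumorsim import rng as tsrng
            u = tsrng.uniform_grid(state.config.rng_seed, 5, tsrng.BRANCH,
                                   state.lattice.shape)
            results.append(sample_branching_hotpoints(state, u))
        assert results[0] == results[1]


class TestNetworkInvariants:
    def test_forest_preserved_over_random_stepping(self):
        config = SimulationConfig(grid_points_per_axis=16, domain_edge=0.0008,
                                  c_init=0.0, parent_vessel="single_axis",
                                  parent_vessel_offset=3, rng_seed=11)
        state = init_state(config)
        # strong artificial TAF gradient toward the tumor to force activity
        state.fields["taf"].values[:] = np.linspace(1, 0, 16)[None, :, None]
        for _ in range(60):
            ts.step_simulation(state)
        assert state.vessels.is_forest()
        # no vessel on a necrotic voxel
        for seg in state.vessels.segments.values():
            assert state.lattice.phenotype[seg.pos] != NECROTIC
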