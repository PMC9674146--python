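"""Particle grid construction, visual field extraction, movement/consumption."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnus.config import RewardParams
from somnus.environment import (ALL_ORIENTATIONS, DIRECTIONS, TASK1, TASK2,
                                AgentState, EnvironmentDensityError,
                                Orientation, RewardKind, get_visual_field,
                                init_environment, move_agent)


def make_agent(grid, r=5, c=5):
    return AgentState(position=(r, c))


class TestInitEnvironment:
    def test_default_density_gives_250_cells_125_particles(self, rng):
        grid = init_environment(50, 50, 0.10, ALL_ORIENTATIONS, rng)
        assert grid.n_particles == 125
        assert np.sum(grid.cells >= 0) == 250
        counts = sorted(grid.orientation_counts.values())
        assert counts in ([31, 31, 31, 32],)
        grid.check_invariants()

    def test_zero_density_empty_grid(self, rng):
        grid = init_environment(50, 50, 0.0, ALL_ORIENTATIONS, rng)
        assert grid.n_particles == 0
        assert np.all(grid.cells < 0)

    def test_two_orientation_task_environment(self, rng):
        grid = init_environment(50, 50, 0.10, TASK1.orientations, rng)
        present = {o for o, _ in grid.particles.values()}
        assert present == {Orientation.HORIZONTAL, Orientation.NEG_DIAGONAL}
        counts = sorted(grid.orientation_counts.values())
        assert counts == [62, 63]

    def test_particle_count_density_semantics(self, rng):
        grid = init_environment(20, 20, 0.05, ALL_ORIENTATIONS, rng,
                                density_semantics="particle_fraction")
        assert grid.n_particles == 20

    def test_overdense_request_fails(self, rng):
        # 30% cell occupancy with the 8-neighbourhood exclusion zone is
        # geometrically infeasible on a small grid.
        with pytest.raises(EnvironmentDensityError):
            init_environment(10, 10, 0.30, ALL_ORIENTATIONS, rng)

    def test_adjacency_invariant_exhaustive_small_grid(self, rng):
        for seed in range(5):
            g = init_environment(15, 15, 0.10, ALL_ORIENTATIONS,
                                 np.random.default_rng(seed))
            g.check_invariants()


class TestVisualField:
    def test_empty_grid_all_zero(self, rng):
        grid = init_environment(20, 20, 0.0, ALL_ORIENTATIONS, rng)
        vf = get_visual_field(grid, make_agent(grid))
        assert vf.shape == (7, 7)
        assert vf.sum() == 0

    def test_single_particle_mapped_to_egocentric_offsets(self, rng):
        grid = init_environment(20, 20, 0.0, ALL_ORIENTATIONS, rng)
        # horizontal particle anchored 2 up, 2 left of the agent at (5,5)
        grid._place(Orientation.HORIZONTAL, (3, 3))
        vf = get_visual_field(grid, make_agent(grid))
        assert vf.sum() == 2
        assert vf[1, 1] == 1 and vf[1, 2] == 1

    def test_window_matches_brute_force_scan(self, rng):
        grid = init_environment(30, 30, 0.10, ALL_ORIENTATIONS, rng)
        agent = make_agent(grid, 2, 28)    # near the edge: exercises wrap
        vf = get_visual_field(grid, agent)
        for i in range(7):
            for j in range(7):
                rr, cc = grid.wrap(agent.position[0] + i - 3,
                                   agent.position[1] + j - 3)
                assert vf[i, j] == (grid.cells[rr, cc] >= 0)


class TestMoveAgent:
    def test_empty_cell_small_punishment(self, rng):
        grid = init_environment(20, 20, 0.0, ALL_ORIENTATIONS, rng)
        agent = make_agent(grid)
        _, event = move_agent(grid, agent, (0, 1), TASK1)
        assert event.kind == RewardKind.EMPTY_CELL
        assert event.s_rp == -0.0001
        assert agent.position == (5, 6)

    def test_rewarded_consumption_conserves_particles(self, rng):
        grid = init_environment(20, 20, 0.10, TASK1.orientations, rng)
        agent = make_agent(grid)
        rewards = RewardParams()
        for _ in range(300):
            before = dict(grid.orientation_counts)
            _, event = move_agent(grid, agent, DIRECTIONS[rng.integers(8)],
                                  TASK1, rewards)
            assert grid.orientation_counts == before   # respawn restores
            if event.kind == RewardKind.REWARDED_PARTICLE:
                assert event.s_rp == 1.0
                assert event.orientation == Orientation.HORIZONTAL
            elif event.kind == RewardKind.PUNISHED_PARTICLE:
                assert event.s_rp == -0.001
                assert event.orientation == Orientation.NEG_DIAGONAL
        grid.check_invariants()

    def test_whole_particle_removed_when_either_pixel_stepped_on(self, rng):
        grid = init_environment(20, 20, 0.0, ALL_ORIENTATIONS, rng)
        pid = grid._place(Orientation.HORIZONTAL, (5, 6))
        agent = make_agent(grid)   # at (5,5); second pixel at (5,7)
        _, event = move_agent(grid, agent, (0, 1), TASK1)
        assert event.kind == RewardKind.REWARDED_PARTICLE
        assert pid not in grid.particles
        # both pixels cleared, exactly one respawned particle elsewhere
        assert grid.n_particles == 1
        grid.check_invariants()


class TestExplorationBookkeeping:
    def test_increment_and_reset(self):
        agent = AgentState(position=(0, 0))
        for _ in range(20):
            agent.register_move(acquired=False)
        assert agent.explore_prob == pytest.approx(0.21)
        agent.register_move(acquired=True)
        assert agent.explore_prob == 0.01

    def test_probability_saturates_at_one(self):
        agent = AgentState(position=(0, 0))
        for _ in range(300):
            agent.register_move(acquired=False)
        assert agent.explore_prob == 1.0


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000), n_moves=st.integers(1, 60))
def test_property_invariants_hold_under_random_moves(seed, n_moves):
    rng = np.random.default_rng(seed)
    grid = init_environment(14, 14, 0.08, ALL_ORIENTATIONS, rng)
    agent = AgentState(position=(7, 7))
    per_orientation = dict(grid.orientation_counts)
    for _ in range(n_moves):
        move_agent(grid, agent, DIRECTIONS[rng.integers(8)], TASK2)
    assert grid.orientation_counts == per_orientation
    grid.check_invariants()


def test_random_policy_chance_consumption_is_balanced(rng):
    """With equal rewarded/punished densities a random walker consumes both
    kinds in equal proportion (binomial tolerance)."""
    grid = init_environment(40, 40, 0.10, TASK1.orientations, rng)
    agent = AgentState(position=(20, 20))
    rewarded = punished = 0
    while rewarded + punished < 400:
        _, ev = move_agent(grid, agent, DIRECTIONS[rng.integers(8)], TASK1)
        rewarded += ev.kind == RewardKind.REWARDED_PARTICLE
        punished += ev.kind == RewardKind.PUNISHED_PARTICLE
    frac = rewarded / (rewarded + punished)
    assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(400)
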