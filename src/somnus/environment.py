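"""Procedural foraging world.

A toroidal ``height x width`` grid is populated with two-pixel "food"
particles in four orientations.  The agent sees a square egocentric window
(the visual field), moves to one of the eight neighbouring cells each epoch,
and consumes any particle it steps on; consumed particles respawn at a
random admissible location so density is conserved.  No two particles may
ever occupy directly adjacent cells (8-neighbourhood).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .config import EnvParams, RewardParams


class Orientation(str, Enum):
    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"
    POS_DIAGONAL = "pos_diagonal"
    NEG_DIAGONAL = "neg_diagonal"


#: (row, col) offset of a particle's second pixel relative to its anchor.
ORIENTATION_OFFSETS: dict[Orientation, tuple[int, int]] = {
    Orientation.HORIZONTAL: (0, 1),
    Orientation.VERTICAL: (1, 0),
    Orientation.POS_DIAGONAL: (-1, 1),   # visually up-right
    Orientation.NEG_DIAGONAL: (1, 1),    # visually down-right
}

ALL_ORIENTATIONS: tuple[Orientation, ...] = tuple(Orientation)

#: The eight movement directions in row-major order of a 3x3 grid with the
#: center removed; index i corresponds to decision neuron i.
DIRECTIONS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

STAY: tuple[int, int] = (0, 0)


class EnvironmentDensityError(RuntimeError):
    """Requested density cannot be met under the adjacency constraint."""


class RewardKind(str, Enum):
    REWARDED_PARTICLE = "rewarded_particle"
    PUNISHED_PARTICLE = "punished_particle"
    EMPTY_CELL = "empty_cell"


@dataclass(frozen=True)
class RewardEvent:
    """Outcome of a single move: what was stepped on and its reward scalar."""

    kind: RewardKind
    s_rp: float
    orientation: Orientation | None = None


@dataclass(frozen=True)
class TaskSpec:
    """Maps particle orientations to reward classes for one task."""

    name: str
    rewarded: Orientation
    punished: Orientation

    @property
    def orientations(self) -> tuple[Orientation, Orientation]:
        return (self.rewarded, self.punished)


TASK1 = TaskSpec("Task1", Orientation.HORIZONTAL, Orientation.NEG_DIAGONAL)
TASK2 = TaskSpec("Task2", Orientation.VERTICAL, Orientation.POS_DIAGONAL)


@dataclass
class AgentState:
    """Agent position and exploration bookkeeping.

    ``explore_prob`` starts at the policy floor, grows by a fixed increment
    on every move that does not acquire a particle, and resets to the floor
    on acquisition (the only reading under which it does not saturate).
    """

    position: tuple[int, int]
    last_direction: int | None = None      # index into DIRECTIONS
    explore_prob: float = 0.01

    def register_move(self, acquired: bool, base: float = 0.01,
                      increment: float = 0.01) -> None:
        if acquired:
            self.explore_prob = base
        else:
            self.explore_prob = min(1.0, self.explore_prob + increment)


@dataclass
class ParticleGrid:
    """Occupancy grid plus particle bookkeeping.

    ``cells[r, c]`` holds the particle id occupying that cell, or -1.
    """

    width: int
    height: int
    density: float
    cells: np.ndarray
    particles: dict[int, tuple[Orientation, tuple[int, int]]]
    rng: np.random.Generator
    next_id: int = 0
    orientation_counts: dict[Orientation, int] = field(default_factory=dict)

    # -- geometry helpers -------------------------------------------------

    def wrap(self, r: int, c: int) -> tuple[int, int]:
        return r % self.height, c % self.width

    def particle_pixels(self, pid: int) -> tuple[tuple[int, int], tuple[int, int]]:
        orientation, (r, c) = self.particles[pid]
        dr, dc = ORIENTATION_OFFSETS[orientation]
        return (r, c), self.wrap(r + dr, c + dc)

    def _pixels_for(self, orientation: Orientation,
                    anchor: tuple[int, int]) -> tuple[tuple[int, int], tuple[int, int]]:
        dr, dc = ORIENTATION_OFFSETS[orientation]
        return anchor, self.wrap(anchor[0] + dr, anchor[1] + dc)

    def _admissible(self, pixels, forbidden: tuple[int, int] | None = None) -> bool:
        """True if both pixels and their full 8-neighbourhoods are free."""
        for (r, c) in pixels:
            if forbidden is not None and (r, c) == forbidden:
                return False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = self.wrap(r + dr, c + dc)
                    if self.cells[rr, cc] >= 0:
                        return False
        return True

    # -- mutation ---------------------------------------------------------

    def _place(self, orientation: Orientation, anchor: tuple[int, int]) -> int:
        pid = self.next_id
        self.next_id += 1
        for (r, c) in self._pixels_for(orientation, anchor):
            self.cells[r, c] = pid
        self.particles[pid] = (orientation, anchor)
        self.orientation_counts[orientation] = (
            self.orientation_counts.get(orientation, 0) + 1
        )
        return pid

    def _remove(self, pid: int) -> Orientation:
        orientation, _ = self.particles[pid]
        for (r, c) in self.particle_pixels(pid):
            self.cells[r, c] = -1
        del self.particles[pid]
        self.orientation_counts[orientation] -= 1
        return orientation

    def spawn_particle(self, orientation: Orientation,
                       forbidden: tuple[int, int] | None = None,
                       max_tries: int = 20000) -> int:
        """Place one particle at a random admissible location."""
        for _ in range(max_tries):
            r = int(self.rng.integers(self.height))
            c = int(self.rng.integers(self.width))
            pixels = self._pixels_for(orientation, (r, c))
            if self._admissible(pixels, forbidden):
                return self._place(orientation, (r, c))
        raise EnvironmentDensityError(
            f"could not place a {orientation.value} particle after "
            f"{max_tries} tries; grid too dense for the adjacency constraint"
        )

    # -- queries ----------------------------------------------------------

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def occupied_fraction(self) -> float:
        return 2 * self.n_particles / (self.width * self.height)

    def check_invariants(self) -> None:
        """Exhaustively verify pixel consistency and the adjacency rule."""
        occupied = {}
        for pid in self.particles:
            for px in self.particle_pixels(pid):
                assert px not in occupied, "overlapping particles"
                occupied[px] = pid
        assert np.sum(self.cells >= 0) == 2 * len(self.particles)
        for (r, c), pid in occupied.items():
            assert self.cells[r, c] == pid
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = self.wrap(r + dr, c + dc)
                    other = self.cells[rr, cc]
                    assert other < 0 or other == pid, (
                        f"particles {pid} and {other} are adjacent"
                    )

    def snapshot_table(self) -> list[tuple[int, int, int, str]]:
        """(row, col, particle_id, orientation) rows for CSV export."""
        rows = []
        for pid in sorted(self.particles):
            orientation, _ = self.particles[pid]
            for (r, c) in self.particle_pixels(pid):
                rows.append((r, c, pid, orientation.value))
        return rows


def init_environment(width: int, height: int, density: float,
                     orientations=ALL_ORIENTATIONS,
                     rng: np.random.Generator | None = None,
                     density_semantics: str = "cell_fraction") -> ParticleGrid:
    """Build a particle grid meeting the density and adjacency constraints.

    Parameters
    ----------
    density
        Under ``"cell_fraction"`` semantics (default), the fraction of grid
        cells occupied by particle pixels; each particle covers two cells.
        Under ``"particle_fraction"``, the number of particles is
        ``round(density * cells)``.
    orientations
        Non-empty subset of the four orientations; counts are split equally
        (±1 where the total does not divide evenly).
    """
    if rng is None:
        rng = np.random.default_rng()
    orientations = tuple(Orientation(o) for o in orientations)
    if density > 0 and not orientations:
        raise ValueError("need at least one orientation")
    if not (0 <= density <= 0.3):
        raise ValueError("density must lie in [0, 0.3]")

    n_cells = width * height
    if density_semantics == "cell_fraction":
        n_particles = int(round(density * n_cells / 2))
    elif density_semantics == "particle_fraction":
        n_particles = int(round(density * n_cells))
    else:
        raise ValueError(f"unknown density_semantics: {density_semantics!r}")

    grid = ParticleGrid(
        width=width, height=height, density=density,
        cells=np.full((height, width), -1, dtype=np.int64),
        particles={}, rng=rng,
    )
    if n_particles == 0:
        return grid

    k = len(orientations)
    base, extra = divmod(n_particles, k)
    counts = [base + (1 if i < extra else 0) for i in range(k)]
    # Interleave placements so no orientation is systematically squeezed.
    order = []
    for i in range(max(counts)):
        for j, orientation in enumerate(orientations):
            if i < counts[j]:
                order.append(orientation)
    for orientation in order:
        grid.spawn_particle(orientation)
    return grid


def init_environment_from_params(env: EnvParams, task_orientations=ALL_ORIENTATIONS,
                                 rng: np.random.Generator | None = None) -> ParticleGrid:
    return init_environment(env.width, env.height, env.density,
                            task_orientations, rng, env.density_semantics)


def get_visual_field(grid: ParticleGrid, agent: AgentState,
                     fov: int = 7) -> np.ndarray:
    """Egocentric binary occupancy window centred on the agent.

    The centre cell corresponds to the agent's own location; the grid wraps
    toroidally, so every window cell maps onto a real grid cell.
    """
    half = fov // 2
    r0, c0 = agent.position
    vf = np.zeros((fov, fov), dtype=np.int8)
    for i in range(fov):
        for j in range(fov):
            rr, cc = grid.wrap(r0 + i - half, c0 + j - half)
            if grid.cells[rr, cc] >= 0:
                vf[i, j] = 1
    return vf


def classify_consumption(orientation: Orientation, task: TaskSpec | None,
                         reward: RewardParams) -> RewardEvent:
    """Map a consumed particle's orientation to a reward event under a task.

    Outside task phases (``task is None``) consumption carries the rewarded
    scalar, but no rewarded plasticity runs then, so the value is inert.
    """
    if task is None or orientation == task.rewarded:
        kind = RewardKind.REWARDED_PARTICLE
        s_rp = reward.s_rp_rewarded
    else:
        kind = RewardKind.PUNISHED_PARTICLE
        s_rp = reward.s_rp_punished
    return RewardEvent(kind, s_rp, orientation)


def move_agent(grid: ParticleGrid, agent: AgentState,
               direction: tuple[int, int], task: TaskSpec | None = None,
               reward: RewardParams | None = None) -> tuple[AgentState, RewardEvent]:
    """Move the agent one cell and resolve consumption.

    Stepping onto either pixel of a particle removes the whole particle,
    emits the matching :class:`RewardEvent`, and respawns one particle of
    the same orientation at a random admissible location, so the per-
    orientation particle count is conserved.  Stepping onto an empty cell
    emits the small empty-cell punishment.
    """
    if reward is None:
        reward = RewardParams()
    dr, dc = direction
    r, c = grid.wrap(agent.position[0] + dr, agent.position[1] + dc)
    agent.position = (r, c)
    pid = int(grid.cells[r, c])
    if pid >= 0:
        orientation = grid._remove(pid)
        grid.spawn_particle(orientation, forbidden=(r, c))
        event = classify_consumption(orientation, task, reward)
    else:
        event = RewardEvent(RewardKind.EMPTY_CELL, reward.s_rp_empty)
    return agent, event
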