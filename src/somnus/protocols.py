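"""Experiment schedules and the performance metric.

A schedule is an ordered list of phases: an unsupervised developmental
period (the only time input->hidden plasticity is on), rewarded task
training, frozen-weight testing, task-interleaved training, sleep-
interleaved training, or sleep alone.  Performance is pattern
discriminability -- the fraction of consumed particles that were rewarded
-- with 0.5 as chance.  Time is counted in movement cycles (epochs) and
aeons (100 epochs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .environment import (ALL_ORIENTATIONS, DIRECTIONS, TASK1, TASK2,
                          AgentState, ParticleGrid, RewardKind, TaskSpec,
                          get_visual_field, init_environment_from_params,
                          move_agent)
from .network import Network, build_network, decide_move
from .plasticity import (apply_rewarded_update, heterosynaptic_rescale,
                         homeostatic_scale, inhibitory_balance)
from .rng import spawn_streams
from .sleep import SleepDriver, record_target_rates, run_sleep_interval

EPOCHS_PER_AEON = 100

PHASE_KINDS = (
    "unsupervised", "train_T1", "train_T2", "test_T1", "test_T2",
    "interleaved_T1T2", "interleaved_S_T1", "interleaved_S_T2", "sleep_only",
)

_TASK_OF = {"T1": TASK1, "T2": TASK2}


class ScheduleError(ValueError):
    """Raised for schedules that violate the phase-ordering invariants."""


@dataclass(frozen=True)
class Phase:
    kind: str
    aeons: int
    label: str | None = None

    def __post_init__(self):
        if self.kind not in PHASE_KINDS:
            raise ScheduleError(f"unknown phase kind: {self.kind!r}")
        if self.aeons < 0:
            raise ScheduleError("phase duration must be nonnegative")


@dataclass
class PhaseSchedule:
    """Validated ordered list of phases.

    Invariants: at most one unsupervised phase and it must come first;
    any task-driven phase requires a preceding unsupervised phase (the
    input->hidden pathway must have been shaped before task learning).
    """

    phases: list[Phase]

    def __post_init__(self):
        kinds = [p.kind for p in self.phases]
        if "unsupervised" in kinds:
            if kinds.index("unsupervised") != 0 or kinds.count("unsupervised") > 1:
                raise ScheduleError(
                    "exactly one unsupervised phase is allowed and it must be first")
        task_like = [k for k in kinds if k != "unsupervised"]
        if task_like and "unsupervised" not in kinds:
            raise ScheduleError("task phases require a preceding unsupervised phase")

    def __iter__(self):
        return iter(self.phases)

    def __len__(self):
        return len(self.phases)


@dataclass
class PhaseRecord:
    """Everything recorded about one executed phase."""

    label: str
    kind: str
    start_epoch: int
    n_epochs: int = 0
    rewarded: np.ndarray | None = None    # per-aeon consumption counts
    punished: np.ndarray | None = None
    empty: np.ndarray | None = None
    hidden_rate_mean: np.ndarray | None = None
    snap_aeons: list[int] = field(default_factory=list)
    snap_weights: list[np.ndarray] = field(default_factory=list)
    block_labels: list[str] = field(default_factory=list)
    input_spikes: int = 0
    output_spikes: int = 0

    def performance(self) -> float:
        """Pooled discriminability over the phase; NaN if nothing consumed."""
        if self.rewarded is None:
            return float("nan")
        r = int(self.rewarded.sum())
        p = int(self.punished.sum())
        if r + p == 0:
            return float("nan")
        return r / (r + p)

    def performance_per_aeon(self) -> np.ndarray:
        r = self.rewarded.astype(float)
        p = self.punished.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(r + p > 0, r / (r + p), np.nan)


@dataclass
class RunRecord:
    """Time series and snapshots of one trial, phase by phase."""

    seed: int
    trial: int = 0
    phases: list[PhaseRecord] = field(default_factory=list)
    config: SimConfig | None = None
    final_state: dict | None = None       # wiring + weights at run end

    def phase(self, label: str) -> PhaseRecord:
        for ph in self.phases:
            if ph.label == label:
                return ph
        raise KeyError(label)

    def performance_frame(self) -> pd.DataFrame:
        """Tidy per-aeon performance: (trial, phase, kind, aeon, value)."""
        rows = []
        for ph in self.phases:
            if ph.rewarded is None:
                continue
            for a, v in enumerate(ph.performance_per_aeon()):
                rows.append({"trial": self.trial, "phase": ph.label,
                             "kind": ph.kind,
                             "aeon": ph.start_epoch // EPOCHS_PER_AEON + a,
                             "value": v})
        return pd.DataFrame(rows)

    def snapshots(self, labels=None):
        """Flattened weight snapshots with (phase, aeon) labels."""
        out = []
        for ph in self.phases:
            if labels is not None and ph.label not in labels:
                continue
            for a, w in zip(ph.snap_aeons, ph.snap_weights):
                out.append((ph.label, a, w))
        return out


def performance(rewarded: int, punished: int) -> float:
    """Discriminability over a consumption window: rewarded/(rewarded+punished).

    Undefined (NaN) when nothing was consumed; callers flag rather than
    impute such windows.
    """
    if rewarded + punished == 0:
        return float("nan")
    return rewarded / (rewarded + punished)


class Session:
    """One trial: a network, an agent, and the machinery to run phases."""

    def __init__(self, config: SimConfig | None = None, seed: int = 0,
                 trial: int = 0):
        self.config = config or SimConfig()
        self.seed = int(seed)
        self.streams = spawn_streams(self.seed)
        self.net: Network = build_network(
            self.config,
            wiring_rng=self.streams["wiring"],
            weights_rng=self.streams["weights"],
            release_rng=self.streams["release"],
            ties_rng=self.streams["ties"],
        )
        env = self.config.env
        self.agent = AgentState(position=(env.height // 2, env.width // 2),
                                explore_prob=self.config.policy.explore_base)
        self.record = RunRecord(seed=self.seed, trial=trial, config=self.config)
        self._phase_counter: dict[str, int] = {}

    # -- helpers ----------------------------------------------------------

    def _label(self, kind: str) -> str:
        n = self._phase_counter.get(kind, 0)
        self._phase_counter[kind] = n + 1
        return kind if n == 0 else f"{kind}#{n + 1}"

    def _new_env(self, orientations) -> ParticleGrid:
        return init_environment_from_params(
            self.config.env, orientations, self.streams["environment"])

    def _awake_cycle(self, env: ParticleGrid, task: TaskSpec | None,
                     plasticity: str, dropout_mask=None):
        """One movement cycle: sense, simulate, move, learn."""
        cfg = self.config
        vf = get_visual_field(env, self.agent, cfg.network.input_shape[0])
        res = self.net.run_epoch(
            vf,
            ih_plasticity=(plasticity == "unsupervised"),
            ho_traces=(plasticity == "rewarded"),
            hidden_dropout_mask=dropout_mask,
        )
        direction = decide_move(res.direction, self.agent,
                                self.streams["exploration"], cfg.policy)
        self.agent.last_direction = direction
        _, event = move_agent(env, self.agent, DIRECTIONS[direction],
                              task, cfg.reward)
        acquired = event.kind != RewardKind.EMPTY_CELL
        self.agent.register_move(acquired, cfg.policy.explore_base,
                                 cfg.policy.explore_increment)
        if plasticity == "rewarded":
            self.net.avg_tr = apply_rewarded_update(
                self.net.weights, self.net.trace_buffer, event.s_rp,
                res.epoch, self.net.avg_tr, cfg.stdp)
            heterosynaptic_rescale(self.net.weights)
            inhibitory_balance(self.net.weights)
            homeostatic_scale(self.net.weights, res.output_counts,
                              cfg.homeostasis)
        return res, event

    def _run_block(self, rec: PhaseRecord, env, task, plasticity, n_cycles,
                   counters, hidden_accum, dropout_mask=None):
        """Run awake cycles, accumulating per-aeon consumption counts."""
        for _ in range(n_cycles):
            res, event = self._awake_cycle(env, task, plasticity, dropout_mask)
            aeon = rec.n_epochs // EPOCHS_PER_AEON
            if event.kind == RewardKind.REWARDED_PARTICLE:
                counters["rewarded"][aeon] += 1
            elif event.kind == RewardKind.PUNISHED_PARTICLE:
                counters["punished"][aeon] += 1
            else:
                counters["empty"][aeon] += 1
            hidden_accum += res.hidden_counts
            rec.input_spikes += int(res.input_counts.sum())
            rec.output_spikes += int(res.output_counts.sum())
            rec.n_epochs += 1

    def _snapshot(self, rec: PhaseRecord) -> None:
        rec.snap_aeons.append(self.net.epoch // EPOCHS_PER_AEON)
        rec.snap_weights.append(
            self.net.weights.w_ho.astype(np.float32).ravel().copy())

    # -- phases -----------------------------------------------------------

    def run_phase(self, phase: Phase) -> PhaseRecord:
        cfg = self.config
        kind = phase.kind
        label = phase.label or self._label(kind)
        n_cycles = phase.aeons * EPOCHS_PER_AEON
        n_aeons = max(phase.aeons, 1)
        rec = PhaseRecord(label=label, kind=kind, start_epoch=self.net.epoch)
        counters = {k: np.zeros(n_aeons, dtype=np.int64)
                    for k in ("rewarded", "punished", "empty")}
        hidden_accum = np.zeros(cfg.network.n_hidden, dtype=np.float64)
        snap_every = cfg.protocol.snapshot_every_aeons * EPOCHS_PER_AEON
        block = cfg.protocol.block_cycles

        if n_cycles > 0:
            self._snapshot(rec)

        if kind == "unsupervised":
            env = self._new_env(ALL_ORIENTATIONS)
            done = 0
            while done < n_cycles:
                chunk = min(snap_every, n_cycles - done)
                self._run_block(rec, env, None, "unsupervised", chunk,
                                counters, hidden_accum)
                done += chunk
                self._snapshot(rec)
        elif kind in ("train_T1", "train_T2", "test_T1", "test_T2"):
            task = _TASK_OF[kind[-2:]]
            plast = "rewarded" if kind.startswith("train") else (
                "rewarded" if cfg.protocol.plasticity_during_test else "off")
            env = self._new_env(task.orientations)
            done = 0
            while done < n_cycles:
                chunk = min(snap_every, n_cycles - done)
                self._run_block(rec, env, task, plast, chunk,
                                counters, hidden_accum)
                done += chunk
                self._snapshot(rec)
        elif kind == "interleaved_T1T2":
            env1 = self._new_env(TASK1.orientations)
            env2 = self._new_env(TASK2.orientations)
            done = 0
            use_t1 = True
            since_snap = 0
            while done < n_cycles:
                chunk = min(block, n_cycles - done)
                env, task = (env1, TASK1) if use_t1 else (env2, TASK2)
                rec.block_labels.append(task.name)
                self._run_block(rec, env, task, "rewarded", chunk,
                                counters, hidden_accum)
                done += chunk
                since_snap += chunk
                use_t1 = not use_t1
                if since_snap >= snap_every:
                    self._snapshot(rec)
                    since_snap = 0
            if n_cycles > 0:
                self._snapshot(rec)
        elif kind in ("interleaved_S_T1", "interleaved_S_T2", "sleep_only"):
            task = None if kind == "sleep_only" else _TASK_OF[kind[-2:]]
            driver = self._sleep_driver()
            env = self._new_env(task.orientations) if task else None
            done = 0
            train_turn = task is not None
            since_snap = 0
            while done < n_cycles:
                chunk = min(block, n_cycles - done)
                if train_turn:
                    rec.block_labels.append(task.name)
                    self._run_block(rec, env, task, "rewarded", chunk,
                                    counters, hidden_accum)
                else:
                    rec.block_labels.append("sleep")
                    pos_before = self.agent.position
                    h_counts, in_spk, out_spk = run_sleep_interval(
                        self.net, driver, chunk)
                    assert self.agent.position == pos_before
                    hidden_accum += h_counts
                    rec.input_spikes += in_spk
                    rec.output_spikes += out_spk
                    rec.n_epochs += chunk
                done += chunk
                since_snap += chunk
                if task is not None:
                    train_turn = not train_turn
                if since_snap >= snap_every:
                    self._snapshot(rec)
                    since_snap = 0
            if n_cycles > 0:
                self._snapshot(rec)
        else:  # pragma: no cover
            raise ScheduleError(f"unhandled phase kind {kind!r}")

        rec.rewarded = counters["rewarded"][:n_aeons]
        rec.punished = counters["punished"][:n_aeons]
        rec.empty = counters["empty"][:n_aeons]
        if rec.n_epochs > 0:
            rec.hidden_rate_mean = hidden_accum / rec.n_epochs
        self.record.phases.append(rec)
        return rec

    def _sleep_driver(self) -> SleepDriver:
        """Target rates from all preceding task-training phases."""
        labels = [ph.label for ph in self.record.phases
                  if ph.kind in ("train_T1", "train_T2")]
        if not labels:
            raise ScheduleError(
                "sleep requires at least one preceding training phase "
                "to set hidden-layer target rates")
        targets = record_target_rates(self.record, labels)
        return SleepDriver.for_targets(self.config.sleep, targets,
                                       self.config.network.n_hidden)

    def finalize(self) -> RunRecord:
        w = self.net.weights
        self.record.final_state = {
            "wiring": self.net.arch.wiring.copy(),
            "w_ih": w.w_ih.copy(), "w_ho": w.w_ho.copy(),
            "wi_ho": w.wi_ho.copy(), "w_j0": w.w_j0.copy(),
            "w_i0": w.w_i0.copy(),
        }
        return self.record

    def run_schedule(self, schedule: PhaseSchedule) -> RunRecord:
        for phase in schedule:
            self.run_phase(phase)
        return self.finalize()


def run_schedule(schedule: PhaseSchedule, config: SimConfig | None = None,
                 seed: int = 0, n_trials: int = 1) -> list[RunRecord]:
    """Execute a schedule for ``n_trials`` independently seeded trials."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not isinstance(schedule, PhaseSchedule):
        schedule = PhaseSchedule(list(schedule))
    trial_seeds = np.random.SeedSequence(seed).generate_state(n_trials) % (2**31)
    records = []
    for t, ts in enumerate(trial_seeds):
        session = Session(config, seed=int(ts), trial=t)
        records.append(session.run_schedule(schedule))
    return records


def interleaved_tasks(session: Session, aeons: int) -> PhaseRecord:
    """Strictly alternating Task 1 / Task 2 blocks (both environments kept)."""
    return session.run_phase(Phase("interleaved_T1T2", aeons))


def random_policy_baseline(config: SimConfig | None = None, seed: int = 0,
                           task: TaskSpec = TASK1,
                           min_acquisitions: int = 2000,
                           max_moves: int = 500_000) -> tuple[float, int]:
    """Chance-level control: a uniformly random walker, no network.

    Runs in a symmetric two-orientation environment until at least
    ``min_acquisitions`` particles are consumed; returns (discriminability,
    acquisitions).  Expected value is 0.5 within binomial error.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    env = init_environment_from_params(config.env, task.orientations, rng)
    agent = AgentState(position=(config.env.height // 2, config.env.width // 2))
    rewarded = punished = 0
    moves = 0
    while rewarded + punished < min_acquisitions and moves < max_moves:
        d = DIRECTIONS[rng.integers(len(DIRECTIONS))]
        _, event = move_agent(env, agent, d, task, config.reward)
        if event.kind == RewardKind.REWARDED_PARTICLE:
            rewarded += 1
        elif event.kind == RewardKind.PUNISHED_PARTICLE:
            punished += 1
        moves += 1
    return performance(rewarded, punished), rewarded + punished


def dropout_test(session: Session, removal_fractions, task: TaskSpec,
                 aeons_per_fraction: int = 2) -> pd.DataFrame:
    """Progressively silence random hidden neurons and measure performance.

    Plasticity is off throughout.  Removal is cumulative along a single
    random permutation, so each larger fraction extends the previous one.
    Returns a frame with (fraction, performance, rewarded, punished).
    """
    cfg = session.config
    n_h = cfg.network.n_hidden
    order = session.streams["analysis"].permutation(n_h)
    env = session._new_env(task.orientations)
    rows = []
    for frac in removal_fractions:
        n_remove = int(round(frac * n_h))
        mask = np.zeros(n_h, dtype=bool)
        mask[order[:n_remove]] = True
        rewarded = punished = 0
        for _ in range(aeons_per_fraction * EPOCHS_PER_AEON):
            _, event = session._awake_cycle(env, task, "off", mask)
            if event.kind == RewardKind.REWARDED_PARTICLE:
                rewarded += 1
            elif event.kind == RewardKind.PUNISHED_PARTICLE:
                punished += 1
        rows.append({"fraction": frac, "performance":
                     performance(rewarded, punished),
                     "rewarded": rewarded, "punished": punished})
    return pd.DataFrame(rows)


# Canonical schedules -------------------------------------------------------


def sequential_schedule(cfg: SimConfig) -> PhaseSchedule:
    """Unsupervised -> T1 -> test -> T2 -> test (catastrophic forgetting)."""
    p = cfg.protocol
    return PhaseSchedule([
        Phase("unsupervised", p.unsupervised_aeons),
        Phase("train_T1", p.train_aeons),
        Phase("test_T1", p.test_aeons, "test_T1_postT1"),
        Phase("test_T2", p.test_aeons, "test_T2_postT1"),
        Phase("train_T2", p.train_aeons),
        Phase("test_T1", p.test_aeons, "test_T1_postT2"),
        Phase("test_T2", p.test_aeons, "test_T2_postT2"),
    ])


def sleep_interleaved_schedule(cfg: SimConfig) -> PhaseSchedule:
    """Unsupervised -> T1 -> tests -> Interleaved_S,T2 -> tests."""
    p = cfg.protocol
    return PhaseSchedule([
        Phase("unsupervised", p.unsupervised_aeons),
        Phase("train_T1", p.train_aeons),
        Phase("test_T1", p.test_aeons, "test_T1_postT1"),
        Phase("test_T2", p.test_aeons, "test_T2_postT1"),
        Phase("interleaved_S_T2", p.train_aeons),
        Phase("test_T1", p.test_aeons, "test_T1_postSleep"),
        Phase("test_T2", p.test_aeons, "test_T2_postSleep"),
    ])
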