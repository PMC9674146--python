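# somnus

A spiking-network reinforcement-learning simulator for studying
catastrophic forgetting and its rescue by sleep replay, with a full
synaptic weight-space analysis suite.

## The problem

Networks trained on one task and then on a second, interfering task tend
to overwrite the first — catastrophic forgetting. Biological brains avoid
this, and offline replay during sleep is a leading candidate mechanism:
spontaneous reactivation of task circuits lets new learning be integrated
without erasing old synaptic structure. `somnus` implements a compact
spiking model of this idea: a virtual agent forages on a 50×50 grid of
two-pixel "food" particles, learns complementary discrimination tasks
(Task 1: horizontal rewarded, negative diagonal punished; Task 2 the
90°-rotated complement) through reward-modulated spike-timing-dependent
plasticity, and can be put through simulated REM-like sleep in which the
sensory layer is silenced, the hidden layer is driven by rate-matched
Poisson noise, and the motor output is decoupled.

## The model

* **Neurons** — 842 two-variable map neurons (fast variable `V` under a
  piecewise map with α = 3.65, slow variable `I` with μ = 5·10⁻⁴; one step
  = 0.5 ms), in three feed-forward layers: 7×7 input (the egocentric
  visual field), 28×28 hidden (9 random afferents each), 3×3 output with
  a nonfunctional centre — eight decision neurons, one per movement
  direction. Every hidden neuron contacts every decision neuron with an
  excitatory and an inhibitory synapse (6272 plastic excitatory weights).
* **Synapses** — event-driven conductances, `g ← γg + (1−R+2XR)·W/W_tgt`
  on each presynaptic spike (R = 0.12, X ~ U[0,1]), currents
  `−g·(V − V_rp)`.
* **Plasticity** — pairings within 120 steps leave traces
  `±0.04·e^(−|Δt|/40 ms)`. Input→hidden traces apply immediately
  (unsupervised, developmental phase only). Hidden→output traces are
  stored for 6 epochs and cashed in on reward events:
  `W ← W·Π_k(1 + (W_i0/W_i)·Δ_k)` with
  `Δ_k = S_rp·(tr_k/(t−t_k+c))·Sum_tr/Avg_tr`, followed by heterosynaptic
  rescaling of every output neuron's input column to its homeostatic
  target and E/I rebalancing. Rewards: +1 food, −0.001 punished particle,
  −0.0001 empty cell, constant +0.5 during sleep.
* **Policy** — the decision neuron with the most spikes in the first half
  of a 600-step epoch sets the move; ties break at random; an
  exploration probability starts at 1%, grows 1% per non-acquiring move
  and resets on acquisition.

`docs/methods.md` gives the full equations, every calibration constant,
and an explicit account of what desk-scale runs of this model do and do
not reproduce.

## Worked example

```python
from somnus import SimConfig, Session, Phase, analysis

cfg = SimConfig()
cfg.protocol.unsupervised_aeons = 5   # 1 aeon = 100 movement cycles
cfg.protocol.train_aeons = 20
cfg.protocol.test_aeons = 5

session = Session(cfg, seed=7)
session.run_phase(Phase("unsupervised", cfg.protocol.unsupervised_aeons))
train = session.run_phase(Phase("train_T1", cfg.protocol.train_aeons))
test = session.run_phase(Phase("test_T1", cfg.protocol.test_aeons))
record = session.finalize()

print(f"epochs simulated:      {session.net.epoch}")
print(f"particles consumed:    {int(train.rewarded.sum() + train.punished.sum())} during training")
print(f"test discriminability: {test.performance():.3f} (chance = 0.5)")
```

prints

```
epochs simulated:      3000
particles consumed:    90 during training
test discriminability: 0.474 (chance = 0.5)
```

Discriminability is the fraction of consumed particles that were rewarded
(0.5 = chance). Twenty aeons of training are far too few to lift it —
weight structure drifts toward the task at roughly +0.2% per aeon while
the behavioural read-out needs orders of magnitude more contrast; see the
methods note. The weight-space analyses operate on the recorded
snapshots, e.g.:

```python
t1_states = analysis.manifold_point_set([record], "train_T1")
analysis.svm_weight_classifier(...)      # RBF-SVM weight-state classifier
analysis.prm(wiring, w_ih, w_ho, "horizontal")   # particle responsiveness
analysis.weight_histogram_2d(snap_a, snap_b)     # 2-D weight movement
```

A command line wraps the same machinery:

```bash
somnus run --schedule sequential --preset desk --trials 3 --seed 7 --out run.h5
somnus analyze --in run.h5 --what svm --out tables/
```

## Scope of desk-scale runs

Every mechanism is verified individually by the test suite (kernel
bit-parity against a reference implementation, closed-form plasticity
values, conservation invariants, oracle-checked analyses). The
behavioural learning curves, however, require training runs of order
10⁴–10⁵ aeons — hours to days of CPU per trial — to rise above the
spike-count read-out's noise floor; at the desk preset they remain at
chance, and the corresponding acceptance tests are left failing rather
than weakened. The weight-space signatures (task-specific weight-drift
clusters, SVM separation with sleep-interleaved states between the class
means) are reproduced at desk scale. The `full_preset()` configuration
exposes full-length phase durations for long runs.
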