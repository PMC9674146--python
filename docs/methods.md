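# Methods

This note documents the model implemented by `somnus`, the choices made
where the design was genuinely open, the calibration of the constants the
model class does not pin down, and — importantly — what desk-scale runs of
this simulator do and do not show.

## The model

### World

Foraging takes place on a toroidal 50×50 grid populated by two-pixel
"food" particles in four orientations (horizontal, vertical, positive
diagonal, negative diagonal). Particle density is 10% of cells (125
particles); no two particles may occupy directly adjacent cells
(8-neighbourhood), which is enforced at construction and after every
respawn. The agent sees a 7×7 egocentric binary window and moves one cell
per movement cycle in one of eight directions. Consuming a particle
removes it and respawns one of the same orientation at a random admissible
location, so density and orientation counts are conserved. Task 1 rewards
horizontal particles (S_rp = 1) and punishes negative diagonals
(S_rp = −0.001); Task 2 is the 90°-rotated complement (vertical rewarded,
positive diagonal punished). Stepping onto an empty cell carries
S_rp = −0.0001. The torus (rather than a bounded grid) avoids edge
artifacts in a world only seven windows wide; the visual field wraps with
it.

### Neurons

All 842 neurons (7×7 input, 28×28 hidden, 3×3 output with a nonfunctional
centre) are two-variable map neurons: a fast membrane variable `V` under a
piecewise map with parameter `alpha = 3.65` and a slow variable `I` with
rate `mu = 5e-4` (one step = 0.5 ms). External current enters the fast map
through `beta_e = 0.133` and the slow equation through `sigma_e = 1`;
intrinsic drive `sigma = 0.06` places the silent fixed point
(V = −0.94, I ≈ −1.8214) close to threshold, making the cell excitable
with small inputs. A spike is registered on the plateau branch; the next
step always resets `V` to −1. The printed form of the subthreshold branch
is ambiguous up to an additive constant; we use `alpha/(1−V) − 1 + I`,
which has a genuine resting state, and expose the alternative as a config
toggle, along with the literal `−mu·V_{n+1}` slow-term reading.

### Synapses

Synapses are event-driven conductances: a presynaptic spike increments the
postsynaptic conductance by the plastic weight normalized by the
postsynaptic target input sum, times a release factor drawn uniformly from
[1−R, 1+R] with R = 0.12; between events the conductance relaxes
geometrically with `gamma = 0.6` per step (a value this package chose;
fast decay makes the cell an integration window of a few steps).
Currents are `−g·(V_post − V_rp)` with reversal potentials `V_rp = 0`
(excitatory) and `−1.1` (inhibitory) in map units. Two numerical points:

* The conductance normalizer is the *initial* target sum, held fixed.
  Normalizing by the evolving homeostatic target would cancel homeostatic
  scaling exactly (the scaling of weights and of the normalizer would
  always divide out).
* Conductances decayed below 1e−30 are snapped to zero; geometric decay
  otherwise drives them into denormal floating-point range, which stalls
  the arithmetic units by two orders of magnitude. No observable quantity
  is affected at this threshold.

### Architecture and read-out

Each hidden neuron receives excitatory synapses from 9 distinct input
neurons chosen uniformly at random; each hidden neuron contacts all eight
decision neurons with one excitatory and one inhibitory synapse
(784·8 = 6272 plastic excitatory weights). Initial input→hidden weights
are truncated-normal (mean 0.1, sd 25% of the mean); initial
hidden→output weights are a uniform constant. Inhibitory weights track
the negative mean of the neuron's outgoing excitatory weights after every
plasticity event (balanced feed-forward inhibition).

An epoch (movement cycle) is 600 steps. Input neurons whose visual-field
cell is occupied receive a 5-step suprathreshold pulse (amplitude 12),
re-applied every 150 steps for 4 volleys. The decision is the output
neuron with the most spikes in steps 1–300; ties are broken uniformly at
random, and an epoch with no output spikes repeats the previous move.
With probability `explore_prob` the decision is overridden by a random
direction; the probability starts at 1%, grows 1% per non-acquiring move,
and resets on acquisition (the only reading under which it does not
saturate). At the end of every epoch all neurons are returned to the
silent fixed point: at `mu = 5e-4` the slow variable needs several epochs
to relax after a burst, so the reset is what enforces the model's stated
property that each cycle ends at rest. (The carry-over mode remains
selectable.)

The repeated stimulation volley is a deliberate departure from a single
epoch-initial pulse. A single volley lets each burst-adapting output fire
at most one spike, so decision counts are almost always fully tied
(measured tie fraction 0.8–0.98), and — worse for learning — the action
actually taken then carries no spike-count signature for the rewarded
plasticity to read. Four volleys give counts in 0–4 and a graded read-out.

### Plasticity

Every pre/post spike pairing within 120 steps leaves a trace
`±K·exp(−|Δt|/Tc)` with K = 0.04 and Tc = 40 ms; the sign follows the
pairing order, and each new spike is compared to all opposite-side spikes
in the window.

*Input→hidden (unsupervised, developmental phase only).* Traces apply
immediately and multiplicatively, `W ← W·(1+tr)`, clipped at zero, with
two stabilizers this package adds: after every update a neuron's afferent
weights are rescaled to their initial sum (volley-locked timing makes the
raw rule potentiation-dominated and divergent), and no single afferent may
hold more than 15% of the sum. The cap matters: unconstrained competition
collapses receptive fields onto single high-traffic pixels, and a
one-pixel field carries no orientation information. With the cap, hidden
neurons remain multi-pixel coincidence detectors; because the adjacency
rule forbids two *different* particles from occupying adjacent cells, a
detector of two adjacent co-active pixels is automatically an
orientation-and-place detector.

*Hidden→output (rewarded).* Traces are stored for 6 epochs and converted
into weight changes only on reward events (every move ends in one). At an
event with scalar `S_rp` at epoch `t`, with per-trace discount
`1/(t − t_k + c)`, c = 1 epoch:

    Sum_tr(ij) = Σ_k tr_k/(t − t_k + c)          over synapse ij's live traces
    Δ_k        = S_rp · tr_k/(t − t_k + c) · Sum_tr(ij)/Avg_tr
    W_ij      ← W_ij · Π_k (1 + (W_i0/W_i)·Δ_k)
    Avg_tr    ← (1−δ)·Avg_tr + δ·⟨Sum_tr⟩,      δ = 0.01

We read `Sum_tr` as ranging over the *same synapse's* live traces (the
product over k is per synapse), so credit scales with a synapse's own
recent pairing coincidence and consistently anti-causal pairings are
depressed by rewards; a pooled-global mode is selectable. `Avg_tr` is
updated from the trace-weighted mean of the per-synapse sums, putting the
normalizing ratio at order one for strongly coincident synapses. Three
numerical guards keep the product rule well-posed: the ratio is clipped at
±3, a synapse's per-event multiplier is clamped into [0.2, 5], and weights
are floored at 0.1% of the mean column weight — a hard zero is absorbing
under a multiplicative rule, and without the floor a burst of negative
ratios permanently killed 98% of synapses within 15 aeons.

*Normalization.* After every event, each output neuron's excitatory input
column is rescaled to its target sum `W_j0` (heterosynaptic scaling;
frozen synapses keep their values and the rescale redistributes over the
rest), and inhibitory weights are reset to the negative row means. Once
per epoch `W_j0` moves by a factor (1 ± D_tar) toward a target firing
rate. D_tar and the target are not pinned by the model class; we use
D_tar = 5e-5 per epoch and 2 spikes/epoch. This is deliberately slow: at
D_tar ≥ 2e-4 the homeostat down-scales whichever output wins most often
fast enough to cancel any policy asymmetry outright (verified in an
instrumented conditioning experiment where learning inverted to active
avoidance of the rewarded action). At 5e-5 it acts as a long-run
excitability guardrail only.

*Freezing.* `freeze_top_fraction` marks the top `floor(f·N)` weights by
value (ties by index); frozen synapses are exempt from every subsequent
rule.

### Sleep

A sleep interval silences the input layer (no stimulation; it emits no
spikes), decouples the output layer from movement, and drives each hidden
neuron with an independent Poisson event train through a dedicated
excitatory noise synapse subject to the standard release-variability law.
The Poisson intensity is steered by a slow proportional controller
(gain 0.1 events/epoch per spike of error against an EMA of the realized
rate) toward per-neuron targets recorded as the mean rates of preceding
task-training phases (averaged across phases; a uniform mode drives every
neuron at the population mean instead). Plasticity runs as rewarded STDP
with a constant reward S_rp = 0.5 per movement cycle, which makes replay
functionally unsupervised; homeostatic scaling stays on (config flag to
disable). Interleaved protocols alternate 100-cycle blocks of task
training and sleep.

## Phase durations (the desk preset)

The model class does not print phase lengths; figure time axes in this
literature reach beyond 1e5 aeons (1 aeon = 100 epochs). This package's
default protocol durations are a desk preset chosen so a full
multi-protocol study (three trials each of the sequential and the
sleep-interleaved protocol, plus all analyses) completes in minutes on one
CPU: 15 aeons unsupervised, 120 aeons per task-training or interleaved
phase, 15 aeons per test phase, snapshots every 5 aeons. A full-scale
preset (2000/10000/500 aeons) is provided for long runs.

## What desk-scale runs show — and what they do not

The package's diagnostics verify each mechanism individually: traces have
the correct sign structure (the chosen action's synapses receive ~13% more
same-epoch trace mass than unchosen ones); the synapses linking
food-detecting hidden neurons to the matching movement direction gain
relative mass monotonically during rewarded training (≈ +0.2% per aeon in
instrumented runs); and a hand-built linear read-out on the same frozen
hidden code reaches ≈ 0.70 discriminability, so the conjunction code
carries the task.

Behaviourally expressed learning, however, accumulates far more slowly
than the desk preset can integrate: at +0.2%/aeon the weight contrast
needed to dominate the spike-count read-out (with its release noise, ties
and exploration dilution) extrapolates to 1e4–1e5 aeons of training —
hours to days of CPU per trial, consistent with the very long time axes
this class of study reports. At the desk preset, measured test
discriminability therefore remains statistically indistinguishable from
the 0.5 chance level for both tasks, and the behavioural
forgetting-and-rescue ordering (new-task performance above 0.6; sleep
interleaving protecting the old task by a visible margin) is *not*
reproduced. The corresponding acceptance checks are left failing rather
than weakened; the weight-space signatures that do not require asymptotic
behavioural performance — distinct task-specific weight-drift clusters, an
RBF-SVM that separates them with Task-1 states on the negative side, and
sleep-interleaved states falling between the two class means — are
reproduced at desk scale.

What the synthetic world does not emulate: real sensory statistics (the
particle field is i.i.d. apart from the adjacency constraint), occlusion,
continuous space or time, and any reward structure beyond the three
scalars. Passing tests on this world say nothing about natural stimuli.

## Other numerical choices

* Trace lifetime semantics: a trace created at epoch `e` acts on events at
  epochs `e … e+5` and is erased when its age reaches 6.
* Pairing is evaluated per epoch; cross-epoch pairs (possible only within
  120 steps of the boundary) are neglected — activity is volley-locked and
  essentially over by mid-epoch.
* Unsupervised traces are applied at the end of the epoch in which they
  arise (the rule is continuous-time in principle; at 600 steps per epoch
  the distinction affects nothing observable).
* `Avg_tr` starts at zero; until it has history, the normalizing ratio is
  pinned to magnitude one by dividing by the current sum's own scale.
* Degenerate inputs: zero-density environments, all-zero weight columns
  (rescale skipped and flagged), zero-variance snapshot sets (embedding
  flagged degenerate), and empty manifold point sets (error) are all
  handled explicitly and tested.
* Determinism: a master seed spawns named child streams (wiring, weights,
  environment, release, exploration, ties, sleep); identical seeds give
  bit-identical runs. The compiled kernel and the pure-python reference
  implementation produce bit-identical trajectories when release
  variability is off (asserted in the test suite).

## Analyses

Receptive fields place afferent weights at their visual-field coordinates;
output-neuron fields are weight-averaged hidden fields. The particle
responsiveness metric (PRM) sums, over output neurons and all placements
of a particle orientation, the overlap between the direction-masked field
and hidden receptive fields weighted by `(grand overlap)²` and the
hidden→output weight; direction masks are 3×3 blocks at the matching edge
or corner of the field. Task-relevant synapses are the top 10%
(`ceil(0.1·N)` = 628 of 6272, ties by index) of a snapshot. Weight-state
classification uses an RBF-kernel SVM (C = 1, bandwidth `scale`) trained
on the last fifth of each task phase's snapshots, signed so Task-1 states
are negative. Trajectory embeddings use PCA or RBF kernel-PCA with a
median-heuristic bandwidth, fitted jointly on the pooled snapshot set.
Solution-manifold distance is the minimum Euclidean distance to the
sampled point set (last-fifth snapshots). 2-D weight histograms bin paired
snapshots on a common [0, max] range with counts capped at 50 for display
and exact counts retained. PRM, manifold distances and histograms are
cross-checked against literal brute-force implementations in the test
suite; the SVM is cross-checked against a nearest-neighbour classifier on
separated fixtures.
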