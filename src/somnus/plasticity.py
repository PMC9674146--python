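"""STDP traces, rewarded weight updates, homeostatic and heterosynaptic rules.

Two plasticity systems coexist:

* **Unsupervised STDP** on input->hidden synapses: every pre/post spike
  pairing within the pairing window produces a signed trace
  ``±K * exp(-|dt|/Tc)`` that is applied to the synapse immediately
  (multiplicatively, ``W <- W * (1 + tr)``, clipped at zero).

* **Rewarded STDP** on hidden->output synapses: pairing traces are stored
  in a buffer for a fixed number of epochs and converted into weight
  changes only when a reward or punishment arrives.  On an event with
  scalar ``S_rp`` at epoch ``t``::

      Sum_tr = sum_k  tr_k / (t - t_k + c)              (all live traces)
      Delta_k = S_rp * tr_k / (t - t_k + c) * Sum_tr / Avg_tr
      W_ij   <- W_ij * prod_k (1 + (W_i0 / W_i) * Delta_k)
      Avg_tr <- (1 - delta) * Avg_tr + delta * Sum_tr

  where ``W_i`` is hidden neuron *i*'s total output weight and ``W_i0`` its
  initial target, so neurons with depleted output budgets potentiate more
  easily.

Around every event, heterosynaptic rescaling pins each output neuron's
total excitatory input to its homeostatic target ``W_j0`` (itself nudged
every epoch toward a target firing rate), and each hidden neuron's
outgoing inhibitory weights track the negative mean of its outgoing
excitatory weights.  Frozen synapses are exempt from every rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import HomeostasisParams, StdpParams

__all__ = [
    "StdpParams", "TraceBuffer", "WeightState", "compute_trace",
    "pairing_traces", "apply_unsupervised_stdp", "apply_rewarded_update",
    "homeostatic_scale", "heterosynaptic_rescale", "inhibitory_balance",
    "freeze_top_fraction",
]


def compute_trace(t_pre: float, t_post: float, params: StdpParams) -> float:
    """Signed trace value for one spike pairing; times in milliseconds.

    Positive (potentiating) when the presynaptic spike leads
    (``t_post >= t_pre``), negative when it lags.
    """
    dt = t_post - t_pre
    magnitude = params.k * np.exp(-abs(dt) / params.tc)
    return float(magnitude if dt >= 0 else -magnitude)


def pairing_traces(pre_steps: np.ndarray, post_steps: np.ndarray,
                   params: StdpParams, dt_ms: float) -> np.ndarray:
    """Vectorized traces for the cross product of spike-time arrays (in steps).

    Returns a ``(len(pre), len(post))`` array; pairs outside the pairing
    window get trace 0.  Every new spike is compared to *all* opposite-side
    spikes within the window (no nearest-neighbour restriction).
    """
    pre = np.asarray(pre_steps, dtype=np.int64)[:, None]
    post = np.asarray(post_steps, dtype=np.int64)[None, :]
    dsteps = post - pre
    inside = np.abs(dsteps) <= params.pairing_window
    mag = params.k * np.exp(-np.abs(dsteps) * dt_ms / params.tc)
    return np.where(inside, np.where(dsteps >= 0, mag, -mag), 0.0)


@dataclass
class TraceBuffer:
    """Stored rewarded-STDP traces: (flat synapse id, value, creation epoch)."""

    syn: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    val: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    epoch: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return self.syn.size

    def add(self, syn: np.ndarray, val: np.ndarray, epoch: int) -> None:
        if len(syn) == 0:
            return
        syn = np.asarray(syn, dtype=np.int64)
        self.syn = np.concatenate([self.syn, syn])
        self.val = np.concatenate([self.val, np.asarray(val, dtype=np.float64)])
        self.epoch = np.concatenate(
            [self.epoch, np.full(len(syn), epoch, dtype=np.int64)])

    def prune(self, now: int, lifetime: int) -> None:
        """Drop traces whose age has reached ``lifetime`` epochs."""
        keep = (now - self.epoch) < lifetime
        if not np.all(keep):
            self.syn = self.syn[keep]
            self.val = self.val[keep]
            self.epoch = self.epoch[keep]


@dataclass
class WeightState:
    """All plastic weights plus homeostatic targets and the freeze mask.

    ``w_ih``: nonnegative input->hidden weights, one row of ``n_afferents``
    entries per hidden neuron (column k pairs with wiring column k).
    ``w_ho`` / ``wi_ho``: dense hidden->output excitatory (>= 0) and
    inhibitory (<= 0) matrices.  ``w_j0`` is each output neuron's target
    input sum; ``w_i0`` each hidden neuron's initial total output weight;
    ``w_ih_target`` each hidden neuron's initial input sum (the conductance
    normalizer for input->hidden synapses).
    """

    w_ih: np.ndarray
    w_ho: np.ndarray
    wi_ho: np.ndarray
    w_j0: np.ndarray
    w_i0: np.ndarray
    w_ih_target: np.ndarray
    frozen_mask: np.ndarray    # bool, same shape as w_ho
    # Fixed conductance normalizer for hidden->output synapses (the
    # initial target sum).  The homeostatic target w_j0 evolves; dividing
    # the drive by the evolving target would cancel homeostasis exactly,
    # so the normalizer stays pinned at its initial value.
    w_j0_ref: np.ndarray | None = None

    def __post_init__(self):
        if self.w_j0_ref is None:
            self.w_j0_ref = self.w_j0.copy()

    @property
    def n_hidden(self) -> int:
        return self.w_ho.shape[0]

    @property
    def n_output(self) -> int:
        return self.w_ho.shape[1]

    def copy(self) -> "WeightState":
        return WeightState(
            w_ih=self.w_ih.copy(), w_ho=self.w_ho.copy(),
            wi_ho=self.wi_ho.copy(), w_j0=self.w_j0.copy(),
            w_i0=self.w_i0.copy(), w_ih_target=self.w_ih_target.copy(),
            frozen_mask=self.frozen_mask.copy(),
            w_j0_ref=self.w_j0_ref.copy(),
        )


def apply_unsupervised_stdp(w_ih: np.ndarray, hidden_idx: np.ndarray,
                            aff_idx: np.ndarray, traces: np.ndarray,
                            params: StdpParams) -> None:
    """Apply traces to input->hidden synapses in place.

    Multiplicative by default (``W <- W * prod(1 + tr)`` over that
    synapse's traces), clipped at zero.
    """
    if len(traces) == 0:
        return
    if params.unsupervised_mode == "multiplicative":
        factors = np.ones_like(w_ih)
        np.multiply.at(factors, (hidden_idx, aff_idx), 1.0 + traces)
        w_ih *= factors
    else:
        np.add.at(w_ih, (hidden_idx, aff_idx), traces)
    np.clip(w_ih, 0.0, None, out=w_ih)


def apply_rewarded_update(weights: WeightState, buffer: TraceBuffer,
                          s_rp: float, t_now: int, avg_tr: float,
                          params: StdpParams) -> float:
    """Convert live stored traces into hidden->output weight changes.

    Mutates ``weights.w_ho`` (frozen entries excepted) and returns the
    updated running trace average ``Avg_tr``.  ``Sum_tr``/``Avg_tr`` are
    global (network-wide) quantities; the per-trace discount divides by the
    trace age in epochs plus the softening constant ``c``.
    """
    buffer.prune(t_now, params.trace_lifetime)
    if len(buffer) == 0:
        return (1.0 - params.delta) * avg_tr

    discounted = buffer.val / (t_now - buffer.epoch + params.c)
    if params.sum_scope == "per_synapse":
        # Sum_tr of the synapse each trace belongs to: credit scales with
        # that synapse's own recent pairing coincidence, so consistently
        # causal pairs are amplified and anti-causal ones depressed.
        active_syn, inverse = np.unique(buffer.syn, return_inverse=True)
        syn_sums = np.zeros(active_syn.size)
        np.add.at(syn_sums, inverse, discounted)
        sum_of_trace = syn_sums[inverse]
        # Scalar fed to the Avg_tr running average: trace-weighted mean of
        # the per-synapse sums, so the normalizer sits on the scale of the
        # strongly coincident (multi-trace) synapses and per-event weight
        # factors stay O(1).
        sum_tr = float(np.mean(sum_of_trace))
    else:
        sum_tr = float(np.sum(discounted))
        sum_of_trace = np.full(discounted.size, sum_tr)
    # Until Avg_tr has accumulated history (start of a rewarded phase) the
    # normalization ratio is pinned to magnitude ~1 by dividing by the
    # current |Sum_tr| scale; afterwards the floor only guards degeneracy.
    if avg_tr > params.avg_tr_floor:
        denom = avg_tr
    else:
        denom = max(abs(sum_tr), params.avg_tr_floor)
    if params.ratio_order == "sum_over_avg":
        ratio = sum_of_trace / denom
    else:
        ratio = denom / np.maximum(sum_of_trace, params.avg_tr_floor)
    np.clip(ratio, -params.ratio_clip, params.ratio_clip, out=ratio)
    delta_k = s_rp * discounted * ratio

    if s_rp != 0.0:
        w_i = weights.w_ho.sum(axis=1)
        budget = weights.w_i0 / np.maximum(w_i, 1e-9)
        hidden_of_trace = buffer.syn // weights.n_output
        factors_flat = np.ones(weights.w_ho.size)
        np.multiply.at(factors_flat, buffer.syn,
                       np.maximum(1.0 + budget[hidden_of_trace] * delta_k, 0.0))
        np.clip(factors_flat, params.factor_clip_low, params.factor_clip_high,
                out=factors_flat)
        factors = factors_flat.reshape(weights.w_ho.shape)
        factors[weights.frozen_mask] = 1.0
        weights.w_ho *= factors
        floor = params.w_floor_frac * weights.w_j0 / weights.n_hidden
        free = ~weights.frozen_mask
        weights.w_ho[free] = np.maximum(weights.w_ho[free],
                                        np.broadcast_to(floor, weights.w_ho.shape)[free])

    return (1.0 - params.delta) * avg_tr + params.delta * sum_tr


def heterosynaptic_rescale(weights: WeightState) -> list[int]:
    """Pin every output neuron's excitatory input sum to its target ``W_j0``.

    Frozen synapses keep their values; the remaining (unfrozen) entries of
    a column are scaled so the full column sums to ``W_j0`` exactly.
    Returns the indices of columns skipped because their unfrozen mass is
    zero (nothing to rescale).
    """
    skipped: list[int] = []
    frozen = weights.frozen_mask
    w = weights.w_ho
    for j in range(weights.n_output):
        col = w[:, j]
        frozen_j = frozen[:, j]
        frozen_sum = float(col[frozen_j].sum())
        free_sum = float(col[~frozen_j].sum())
        target_free = weights.w_j0[j] - frozen_sum
        if free_sum <= 0.0 or target_free <= 0.0:
            skipped.append(j)
            continue
        col[~frozen_j] *= target_free / free_sum
    return skipped


def inhibitory_balance(weights: WeightState) -> None:
    """Set each hidden neuron's outgoing inhibition to minus its mean
    outgoing excitatory weight (feed-forward E/I balance)."""
    row_mean = weights.w_ho.mean(axis=1)
    weights.wi_ho[:, :] = -row_mean[:, None]


def homeostatic_scale(weights: WeightState, rates: np.ndarray,
                      params: HomeostasisParams) -> list[int]:
    """Per-epoch homeostatic update of the output targets ``W_j0``.

    A neuron firing below (above) the target rate grows (shrinks) its
    target input sum by the factor ``1 ± D_tar``; equality leaves it
    untouched.  Incoming excitatory weights are then rescaled so column
    sums match the new targets.  Returns skipped (all-zero) columns.
    """
    rates = np.asarray(rates, dtype=float)
    low = rates < params.target_rate
    high = rates > params.target_rate
    weights.w_j0[low] *= (1.0 + params.d_tar)
    weights.w_j0[high] *= (1.0 - params.d_tar)
    # Keep the slow target within a sane band of its initial value so a
    # persistently silent (or saturated) unit cannot run it away.
    np.clip(weights.w_j0, 0.01 * weights.w_j0_ref, 10.0 * weights.w_j0_ref,
            out=weights.w_j0)
    return heterosynaptic_rescale(weights)


def freeze_top_fraction(w_ho: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean mask marking the top ``floor(fraction * N)`` weights by value.

    Ties at the threshold are broken by flat synapse index (stable sort).
    Masked synapses are exempt from all subsequent updates.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    flat = w_ho.ravel()
    n_freeze = int(np.floor(fraction * flat.size))
    mask = np.zeros(flat.size, dtype=bool)
    if n_freeze > 0:
        order = np.argsort(-flat, kind="stable")
        mask[order[:n_freeze]] = True
    return mask.reshape(w_ho.shape)
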