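"""Architecture construction and the per-epoch simulation loop.

The network is three feed-forward layers of map neurons: a 7x7 input layer
(one neuron per visual-field cell), a 28x28 hidden layer, and a 3x3 output
layer whose center neuron is nonfunctional, leaving eight decision neurons
that map one-to-one onto the eight movement directions.  Each hidden
neuron receives excitatory synapses from 9 randomly selected input
neurons; every hidden neuron connects to every decision neuron with one
excitatory and one inhibitory synapse (6272 excitatory weights for the
default sizes).

An epoch is 600 time steps: occupied visual-field cells get a brief
suprathreshold stimulation pulse at the start, dynamics run the full
epoch, and the decision neuron with the most spikes in the first half
determines the movement direction (ties broken at random; no output
spikes repeats the previous move).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .config import NetworkParams, SimConfig
from .environment import DIRECTIONS, AgentState
from .map_neuron import MapNeuronState, resting_state, step_neuron
from .plasticity import (TraceBuffer, WeightState, apply_unsupervised_stdp,
                         pairing_traces)
from .rng import kernel_seed


@dataclass
class NetworkArchitecture:
    """Wiring and layer geometry; fixed for the lifetime of a network."""

    params: NetworkParams
    wiring: np.ndarray            # (n_hidden, n_afferents) input ids
    in_ptr: np.ndarray            # CSR over input ids -> (hidden, slot)
    in_h: np.ndarray
    in_k: np.ndarray
    slot_of: np.ndarray           # (n_input, n_hidden) afferent slot or -1
    output_directions: tuple = DIRECTIONS

    @property
    def n_neurons(self) -> int:
        p = self.params
        return p.n_input + p.n_hidden + (p.output_shape[0] * p.output_shape[1])

    @property
    def n_ho_synapses(self) -> int:
        return self.params.n_hidden * self.params.n_output


@dataclass
class EpochResult:
    """Summary of one movement cycle's network activity."""

    direction: int | None                 # index into DIRECTIONS, or None
    output_counts_half: np.ndarray        # decision-window spikes per output
    output_counts: np.ndarray             # full-epoch spikes per output
    hidden_counts: np.ndarray             # full-epoch spikes per hidden neuron
    input_counts: np.ndarray
    n_traces_created: int = 0
    epoch: int = 0
    overflow: bool = False
    events: dict | None = None            # optional (layer -> (ids, steps))

    @property
    def aeon(self) -> int:
        return self.epoch // 100


def _build_wiring(params: NetworkParams, rng: np.random.Generator):
    wiring = np.empty((params.n_hidden, params.n_afferents), dtype=np.int64)
    for h in range(params.n_hidden):
        wiring[h] = rng.choice(params.n_input, size=params.n_afferents,
                               replace=False)
    # CSR: for each input neuron, the (hidden, slot) pairs it feeds.
    order = np.argsort(wiring.ravel(), kind="stable")
    flat_h, flat_k = np.divmod(order, params.n_afferents)
    srcs = wiring.ravel()[order]
    in_ptr = np.zeros(params.n_input + 1, dtype=np.int64)
    np.add.at(in_ptr, srcs + 1, 1)
    in_ptr = np.cumsum(in_ptr)
    slot_of = np.full((params.n_input, params.n_hidden), -1, dtype=np.int16)
    slot_of[wiring.ravel(), np.repeat(np.arange(params.n_hidden),
                                      params.n_afferents)] = \
        np.tile(np.arange(params.n_afferents, dtype=np.int16), params.n_hidden)
    return wiring, in_ptr.astype(np.int64), flat_h.astype(np.int64), \
        flat_k.astype(np.int64), slot_of


def _initial_weights(params: NetworkParams, rng: np.random.Generator) -> WeightState:
    n_h, n_aff, n_out = params.n_hidden, params.n_afferents, params.n_output
    w_ih = rng.normal(params.w_ih_mean, params.w_ih_sd_frac * params.w_ih_mean,
                      size=(n_h, n_aff))
    np.clip(w_ih, 0.0, None, out=w_ih)
    w_ho = np.full((n_h, n_out), params.w_ho_init, dtype=np.float64)
    wi_ho = np.full((n_h, n_out), -params.w_ho_init, dtype=np.float64)
    return WeightState(
        w_ih=w_ih,
        w_ho=w_ho,
        wi_ho=wi_ho,
        w_j0=w_ho.sum(axis=0),
        w_i0=w_ho.sum(axis=1),
        w_ih_target=np.maximum(w_ih.sum(axis=1), 1e-9),
        frozen_mask=np.zeros((n_h, n_out), dtype=bool),
    )


class Network:
    """Mutable simulation state: wiring, weights, neuron and synapse state.

    The heavy per-step dynamics run in a compiled kernel; this class owns
    the epoch-level bookkeeping (stimulation, decision read-out, trace
    creation, weight updates are orchestrated by the protocol layer).
    """

    def __init__(self, config: SimConfig, arch: NetworkArchitecture,
                 weights: WeightState, release_rng: np.random.Generator,
                 ties_rng: np.random.Generator):
        self.config = config
        self.arch = arch
        self.weights = weights
        self.release_rng = release_rng
        self.ties_rng = ties_rng
        p = config.network
        rest = resting_state(config.map)
        self.V_i = np.full(p.n_input, rest.V)
        self.I_i = np.full(p.n_input, rest.I)
        self.Vp_i = np.full(p.n_input, rest.V_prev)
        self.V_h = np.full(p.n_hidden, rest.V)
        self.I_h = np.full(p.n_hidden, rest.I)
        self.Vp_h = np.full(p.n_hidden, rest.V_prev)
        self.V_o = np.full(p.n_output, rest.V)
        self.I_o = np.full(p.n_output, rest.I)
        self.Vp_o = np.full(p.n_output, rest.V_prev)
        self.G_ih = np.zeros(p.n_hidden)
        self.G_noise = np.zeros(p.n_hidden)
        self.G_oe = np.zeros(p.n_output)
        self.G_oi = np.zeros(p.n_output)
        self.trace_buffer = TraceBuffer()
        self.avg_tr = 0.0
        self.epoch = 0
        self._rest = rest
        # Event buffers, reused across epochs.
        self._ev_in = (np.empty(p.n_input * 8, np.int64),
                       np.empty(p.n_input * 8, np.int64))
        self._ev_h = (np.empty(p.n_hidden * 24, np.int64),
                      np.empty(p.n_hidden * 24, np.int64))
        self._ev_o = (np.empty(max(p.n_output * 64, 512), np.int64),
                      np.empty(max(p.n_output * 64, 512), np.int64))

    # -- state management -------------------------------------------------

    def reset_dynamic_state(self) -> None:
        """Return every neuron to the silent fixed point and clear g."""
        rest = self._rest
        for V, I, Vp in ((self.V_i, self.I_i, self.Vp_i),
                         (self.V_h, self.I_h, self.Vp_h),
                         (self.V_o, self.I_o, self.Vp_o)):
            V.fill(rest.V)
            I.fill(rest.I)
            Vp.fill(rest.V_prev)
        for G in (self.G_ih, self.G_noise, self.G_oe, self.G_oi):
            G.fill(0.0)

    def _normalized_weights(self):
        p = self.config.network
        w = self.weights
        if self.config.synapse.normalization == "target_sum":
            wih = p.gain_ih * w.w_ih / w.w_ih_target[:, None]
            whoe = p.gain_ho_exc * w.w_ho / w.w_j0_ref[None, :]
            whoi = p.gain_ho_inh * np.abs(w.wi_ho) / w.w_j0_ref[None, :]
        else:
            wih = p.gain_ih * w.w_ih
            whoe = p.gain_ho_exc * w.w_ho
            whoi = p.gain_ho_inh * np.abs(w.wi_ho)
        return np.ascontiguousarray(wih), np.ascontiguousarray(whoe), \
            np.ascontiguousarray(whoi)

    # -- one movement cycle ----------------------------------------------

    def run_epoch(self, visual_field: np.ndarray, ih_plasticity: bool = False,
                  ho_traces: bool = False,
                  noise_prob: np.ndarray | None = None,
                  stimulate_input: bool = True,
                  hidden_dropout_mask: np.ndarray | None = None,
                  collect_events: bool = False) -> EpochResult:
        """Simulate one epoch and return its activity summary.

        Input neurons whose visual-field cell is occupied receive the
        stimulation pulse (unless ``stimulate_input`` is off, as during
        sleep).  ``noise_prob`` is the per-step Poisson drive probability
        per hidden neuron (sleep only).  ``hidden_dropout_mask`` silences
        the marked hidden neurons by zeroing their afferent drive.
        """
        cfg = self.config
        p = cfg.network
        vf = np.asarray(visual_field).reshape(-1)
        if vf.size != p.n_input:
            raise ValueError("visual field size does not match input layer")
        input_mask = (vf > 0) if stimulate_input else np.zeros(p.n_input, bool)

        wih, whoe, whoi = self._normalized_weights()
        if hidden_dropout_mask is not None:
            wih = wih.copy()
            whoe = whoe.copy()
            whoi = whoi.copy()
            wih[hidden_dropout_mask] = 0.0
            whoe[hidden_dropout_mask] = 0.0
            whoi[hidden_dropout_mask] = 0.0
        if noise_prob is None:
            noise_prob = np.zeros(p.n_hidden)
            noise_amp = 0.0
        else:
            noise_amp = cfg.sleep.noise_amp
            if hidden_dropout_mask is not None:
                noise_prob = np.where(hidden_dropout_mask, 0.0, noise_prob)

        hidden_counts = np.zeros(p.n_hidden, np.int64)
        output_counts = np.zeros(p.n_output, np.int64)
        output_counts_half = np.zeros(p.n_output, np.int64)
        input_counts = np.zeros(p.n_input, np.int64)
        mp, sp = cfg.map, cfg.synapse

        n_in_ev, n_h_ev, n_o_ev, overflow = _kernels.run_epoch_kernel(
            self.V_i, self.I_i, self.Vp_i,
            self.V_h, self.I_h, self.Vp_h,
            self.V_o, self.I_o, self.Vp_o,
            self.G_ih, self.G_noise, self.G_oe, self.G_oi,
            wih, whoe, whoi,
            self.arch.in_ptr, self.arch.in_h, self.arch.in_k,
            input_mask, p.pulse_amp, p.pulse_steps, p.pulse_every,
            min(p.pulse_repeats * p.pulse_every, p.epoch_steps),
            np.ascontiguousarray(noise_prob, dtype=np.float64), noise_amp,
            p.epoch_steps, p.decision_steps,
            mp.alpha, mp.mu, mp.sigma, mp.beta_e, mp.sigma_e,
            1.0 if mp.branch1_minus_one else 0.0, mp.literal_slow_term,
            sp.gamma, sp.release_variability, sp.v_rp_exc, sp.v_rp_inh,
            kernel_seed(self.release_rng),
            self._ev_in[0], self._ev_in[1],
            self._ev_h[0], self._ev_h[1],
            self._ev_o[0], self._ev_o[1],
            hidden_counts, output_counts, output_counts_half, input_counts,
        )

        in_ids = self._ev_in[0][:n_in_ev]
        in_ts = self._ev_in[1][:n_in_ev]
        h_ids = self._ev_h[0][:n_h_ev]
        h_ts = self._ev_h[1][:n_h_ev]
        o_ids = self._ev_o[0][:n_o_ev]
        o_ts = self._ev_o[1][:n_o_ev]

        n_traces = 0
        if ih_plasticity and n_in_ev and n_h_ev:
            n_traces += self._unsupervised_pairing(in_ids, in_ts, h_ids, h_ts)
        if ho_traces and n_h_ev and n_o_ev:
            n_traces += self._rewarded_pairing(h_ids, h_ts, o_ids, o_ts)

        direction = self._decide_direction(output_counts_half)
        events = None
        if collect_events:
            events = {"input": (in_ids.copy(), in_ts.copy()),
                      "hidden": (h_ids.copy(), h_ts.copy()),
                      "output": (o_ids.copy(), o_ts.copy())}
        result = EpochResult(
            direction=direction,
            output_counts_half=output_counts_half,
            output_counts=output_counts,
            hidden_counts=hidden_counts,
            input_counts=input_counts,
            n_traces_created=n_traces,
            epoch=self.epoch,
            overflow=overflow,
            events=events,
        )
        self.epoch += 1
        if p.reset_state_each_epoch:
            self.reset_dynamic_state()
        return result

    def _decide_direction(self, counts_half: np.ndarray) -> int | None:
        total = counts_half.sum()
        if total == 0:
            return None
        best = counts_half.max()
        tied = np.flatnonzero(counts_half == best)
        if tied.size == 1:
            return int(tied[0])
        return int(self.ties_rng.choice(tied))

    def _unsupervised_pairing(self, in_ids, in_ts, h_ids, h_ts) -> int:
        stdp = self.config.stdp
        traces = pairing_traces(in_ts, h_ts, stdp, self.config.map.dt)
        slots = self.arch.slot_of[in_ids[:, None], h_ids[None, :]]
        mask = (slots >= 0) & (traces != 0.0)
        if not mask.any():
            return 0
        rows, cols = np.nonzero(mask)
        apply_unsupervised_stdp(
            self.weights.w_ih, h_ids[cols], slots[rows, cols].astype(np.int64),
            traces[rows, cols], stdp)
        if stdp.ih_input_scaling:
            touched = np.unique(h_ids[cols])
            w = self.weights.w_ih
            tgt = self.weights.w_ih_target[touched]
            sums = w[touched].sum(axis=1)
            ok = sums > 0
            w[touched[ok]] *= (tgt[ok] / sums[ok])[:, None]
            if stdp.ih_share_cap < 1.0:
                # Clip dominant afferents and hand the excess back to the
                # rest of the row (repeated once; adequate in practice).
                for _ in range(2):
                    rows_w = w[touched]
                    cap = stdp.ih_share_cap * tgt[:, None]
                    over = rows_w > cap
                    if not over.any():
                        break
                    clipped = np.where(over, cap, rows_w)
                    free = clipped.sum(axis=1) - (over * cap).sum(axis=1)
                    deficit = tgt - clipped.sum(axis=1)
                    scale = np.where(free > 0, 1.0 + deficit / np.maximum(free, 1e-12), 1.0)
                    w[touched] = np.where(over, cap, clipped * scale[:, None])
        return int(rows.size)

    def _rewarded_pairing(self, h_ids, h_ts, o_ids, o_ts) -> int:
        stdp = self.config.stdp
        traces = pairing_traces(h_ts, o_ts, stdp, self.config.map.dt)
        mask = traces != 0.0
        if not mask.any():
            return 0
        rows, cols = np.nonzero(mask)
        syn = h_ids[rows] * self.config.network.n_output + o_ids[cols]
        self.trace_buffer.add(syn, traces[rows, cols], self.epoch)
        return int(rows.size)


def build_network(config: SimConfig | None = None,
                  rng_seed: int | np.random.SeedSequence | None = None,
                  wiring_rng: np.random.Generator | None = None,
                  weights_rng: np.random.Generator | None = None,
                  release_rng: np.random.Generator | None = None,
                  ties_rng: np.random.Generator | None = None) -> Network:
    """Construct a network with random wiring and initial weights.

    Either pass ``rng_seed`` (all streams derived from it) or explicit
    generators per concern.  Two builds from the same seed are identical.
    """
    config = config or SimConfig()
    if wiring_rng is None:
        ss = np.random.SeedSequence(rng_seed)
        c1, c2, c3, c4 = ss.spawn(4)
        wiring_rng = np.random.default_rng(c1)
        weights_rng = np.random.default_rng(c2)
        release_rng = np.random.default_rng(c3)
        ties_rng = np.random.default_rng(c4)
    wiring, in_ptr, in_h, in_k, slot_of = _build_wiring(config.network, wiring_rng)
    arch = NetworkArchitecture(params=config.network, wiring=wiring,
                               in_ptr=in_ptr, in_h=in_h, in_k=in_k,
                               slot_of=slot_of)
    weights = _initial_weights(config.network, weights_rng)
    return Network(config, arch, weights, release_rng, ties_rng)


def decide_move(direction: int | None, agent: AgentState,
                rng: np.random.Generator, policy) -> int:
    """Apply the exploration policy to the network's chosen direction.

    With probability ``agent.explore_prob`` a uniformly random direction
    overrides the network's choice.  When the network produced no output
    spikes (``direction is None``) the previous direction is repeated (a
    random one if there is no previous move yet).
    """
    if rng.random() < agent.explore_prob:
        return int(rng.integers(len(DIRECTIONS)))
    if direction is None:
        if agent.last_direction is None:
            return int(rng.integers(len(DIRECTIONS)))
        return agent.last_direction
    return direction


# ----------------------------------------------------------------------
# Pure-python reference epoch (used by the test suite to validate the
# compiled kernel; runs the identical update order through the reference
# map-neuron step).


def reference_epoch(net: Network, input_mask: np.ndarray, n_steps: int):
    """Mirror of the kernel's update order built on ``step_neuron``.

    Only valid with release variability R = 0 and no sleep noise (the two
    paths then share no random draws).  Returns per-layer V trajectories
    and spike rasters without touching the network's real state.
    """
    cfg = net.config
    assert cfg.synapse.release_variability == 0.0
    wih, whoe, whoi = net._normalized_weights()
    mp, sp = cfg.map, cfg.synapse
    p = cfg.network

    state_i = MapNeuronState(net.V_i.copy(), net.I_i.copy(), net.Vp_i.copy())
    state_h = MapNeuronState(net.V_h.copy(), net.I_h.copy(), net.Vp_h.copy())
    state_o = MapNeuronState(net.V_o.copy(), net.I_o.copy(), net.Vp_o.copy())
    G_ih = net.G_ih.copy()
    G_oe = net.G_oe.copy()
    G_oi = net.G_oi.copy()
    spk_i = np.zeros(p.n_input, bool)
    spk_h = np.zeros(p.n_hidden, bool)

    traj = {"V_i": [], "V_h": [], "V_o": [],
            "spk_i": [], "spk_h": [], "spk_o": []}
    for n in range(n_steps):
        G_ih *= sp.gamma
        G_oe *= sp.gamma
        G_oi *= sp.gamma
        for G in (G_ih, G_oe, G_oi):     # same flush-to-zero as the kernel
            G[G <= _kernels.G_FLUSH] = 0.0
        for i in np.flatnonzero(spk_i):
            sel = slice(net.arch.in_ptr[i], net.arch.in_ptr[i + 1])
            np.add.at(G_ih, net.arch.in_h[sel],
                      wih[net.arch.in_h[sel], net.arch.in_k[sel]])
        for h in np.flatnonzero(spk_h):
            G_oe += whoe[h]
            G_oi += whoi[h]

        pulse_until = min(p.pulse_repeats * p.pulse_every, p.epoch_steps)
        ext_i = np.where(
            input_mask & (n < pulse_until) & (n % p.pulse_every < p.pulse_steps),
            p.pulse_amp, 0.0)
        ext_h = G_ih * (sp.v_rp_exc - state_h.V)
        ext_o = G_oe * (sp.v_rp_exc - state_o.V) + G_oi * (sp.v_rp_inh - state_o.V)

        state_i = step_neuron(state_i, mp, ext_i)
        state_h = step_neuron(state_h, mp, ext_h)
        state_o = step_neuron(state_o, mp, ext_o)
        spk_i = state_i.spiked
        spk_h = state_h.spiked
        traj["V_i"].append(state_i.V.copy())
        traj["V_h"].append(state_h.V.copy())
        traj["V_o"].append(state_o.V.copy())
        traj["spk_i"].append(spk_i.copy())
        traj["spk_h"].append(spk_h.copy())
        traj["spk_o"].append(state_o.spiked.copy())
    return {k: np.asarray(v) for k, v in traj.items()}
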