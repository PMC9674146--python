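"""Compiled inner loop: one epoch of network dynamics.

The arithmetic here mirrors ``map_neuron.step_neuron`` and
``synapse_dynamics.step_synapse`` exactly (the test suite cross-checks the
two paths step by step).  Conductances are tracked as per-postsynaptic-
neuron sums: with a shared decay ratio the summed conductance obeys the
same difference equation as the individual synapses, and only the sums
enter the membrane currents.

A presynaptic spike at step ``n`` increments the postsynaptic conductance
used from step ``n+1`` on (one-step synaptic delay), matching
``g_{n+1} = gamma * g_n + spike_n``.

``fastmath`` is restricted to reassociation-free flags so results stay
bit-identical with the pure-python reference path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Conductances decayed below this are treated as exactly zero.
G_FLUSH = 1e-30


@njit(cache=True, inline="always")
def _map_step(V, I, Vp, ext, alpha, mu, sigma, beta_e, sigma_e,
              branch1_offset, literal_slow):
    i_star = I + beta_e * ext
    spiked = False
    if V <= 0.0:
        v_next = alpha / (1.0 - V) - branch1_offset + i_star
    elif V < alpha + i_star and Vp <= 0.0:
        v_next = alpha + i_star
        spiked = True
    else:
        v_next = -1.0
    if literal_slow:
        i_next = I - mu * v_next + mu * sigma + mu * sigma_e * ext
    else:
        i_next = I - mu * (V + 1.0) + mu * sigma + mu * sigma_e * ext
    return v_next, i_next, V, spiked


@njit(cache=True)
def run_epoch_kernel(
    V_i, I_i, Vp_i,
    V_h, I_h, Vp_h,
    V_o, I_o, Vp_o,
    G_ih, G_noise, G_oe, G_oi,
    wih_norm, whoe_norm, whoi_norm,
    in_ptr, in_h, in_k,
    input_mask, pulse_amp, pulse_steps, pulse_every, pulse_until,
    noise_prob, noise_amp,
    n_steps, decision_steps,
    alpha, mu, sigma, beta_e, sigma_e, branch1_offset, literal_slow,
    gamma, R, vrp_e, vrp_i,
    seed,
    ev_in_id, ev_in_t,
    ev_h_id, ev_h_t,
    ev_o_id, ev_o_t,
    hidden_counts, output_counts, output_counts_half, input_counts,
):
    """Advance the whole network ``n_steps`` steps.

    Mutates neuron/conductance state and fills the event buffers; returns
    ``(n_in_events, n_h_events, n_o_events, overflow)`` where ``overflow``
    flags that an event buffer filled up (recording stops, dynamics
    continue).
    """
    np.random.seed(seed)
    n_in = V_i.shape[0]
    n_hid = V_h.shape[0]
    n_out = V_o.shape[0]

    # Spiking neuron ids from the previous step (event lists).
    prev_in = np.empty(n_in, dtype=np.int64)
    prev_h = np.empty(n_hid, dtype=np.int64)
    n_prev_in = 0
    n_prev_h = 0

    c_in = 0
    c_h = 0
    c_o = 0
    overflow = False
    noise_on = noise_amp > 0.0

    for n in range(n_steps):
        # Decay, then increments from spikes at step n-1, so that
        # g_{n+1} = gamma * g_n + increment.  Conductances below G_FLUSH
        # are snapped to zero: geometric decay otherwise drives them into
        # denormal floats, which stall the arithmetic units.
        for o in range(n_out):
            g = G_oe[o] * gamma
            G_oe[o] = g if g > G_FLUSH else 0.0
            g = G_oi[o] * gamma
            G_oi[o] = g if g > G_FLUSH else 0.0
        for h in range(n_hid):
            g = G_ih[h] * gamma
            G_ih[h] = g if g > G_FLUSH else 0.0
        if noise_on:
            for h in range(n_hid):
                gn = G_noise[h] * gamma
                if gn <= G_FLUSH:
                    gn = 0.0
                if noise_prob[h] > 0.0 and np.random.random() < noise_prob[h]:
                    rel = 1.0 - R + 2.0 * np.random.random() * R
                    gn += rel * noise_amp
                G_noise[h] = gn
        for q in range(n_prev_in):
            i = prev_in[q]
            for p in range(in_ptr[i], in_ptr[i + 1]):
                rel = 1.0 - R + 2.0 * np.random.random() * R
                G_ih[in_h[p]] += rel * wih_norm[in_h[p], in_k[p]]
        for q in range(n_prev_h):
            h = prev_h[q]
            for o in range(n_out):
                rel = 1.0 - R + 2.0 * np.random.random() * R
                G_oe[o] += rel * whoe_norm[h, o]
                rel = 1.0 - R + 2.0 * np.random.random() * R
                G_oi[o] += rel * whoi_norm[h, o]

        # Input layer: driven only by the stimulation pulses (repeated
        # every pulse_every steps while n < pulse_until).
        n_prev_in = 0
        if n < pulse_until and n % pulse_every < pulse_steps:
            for i in range(n_in):
                ext = pulse_amp if input_mask[i] else 0.0
                v, islow, vp, spiked = _map_step(
                    V_i[i], I_i[i], Vp_i[i], ext, alpha, mu, sigma,
                    beta_e, sigma_e, branch1_offset, literal_slow)
                V_i[i] = v
                I_i[i] = islow
                Vp_i[i] = vp
                if spiked:
                    prev_in[n_prev_in] = i
                    n_prev_in += 1
                    input_counts[i] += 1
                    if c_in < ev_in_id.shape[0]:
                        ev_in_id[c_in] = i
                        ev_in_t[c_in] = n
                        c_in += 1
                    else:
                        overflow = True
        else:
            for i in range(n_in):
                v, islow, vp, spiked = _map_step(
                    V_i[i], I_i[i], Vp_i[i], 0.0, alpha, mu, sigma,
                    beta_e, sigma_e, branch1_offset, literal_slow)
                V_i[i] = v
                I_i[i] = islow
                Vp_i[i] = vp
                if spiked:
                    prev_in[n_prev_in] = i
                    n_prev_in += 1
                    input_counts[i] += 1
                    if c_in < ev_in_id.shape[0]:
                        ev_in_id[c_in] = i
                        ev_in_t[c_in] = n
                        c_in += 1
                    else:
                        overflow = True

        # Hidden layer: input-afferent plus noise conductance, excitatory.
        n_prev_h = 0
        for h in range(n_hid):
            g = G_ih[h]
            if noise_on:
                g = g + G_noise[h]
            ext = g * (vrp_e - V_h[h])
            v, islow, vp, spiked = _map_step(
                V_h[h], I_h[h], Vp_h[h], ext, alpha, mu, sigma,
                beta_e, sigma_e, branch1_offset, literal_slow)
            V_h[h] = v
            I_h[h] = islow
            Vp_h[h] = vp
            if spiked:
                prev_h[n_prev_h] = h
                n_prev_h += 1
                hidden_counts[h] += 1
                if c_h < ev_h_id.shape[0]:
                    ev_h_id[c_h] = h
                    ev_h_t[c_h] = n
                    c_h += 1
                else:
                    overflow = True

        # Output layer: excitatory and inhibitory drive from hidden spikes.
        for o in range(n_out):
            ext = G_oe[o] * (vrp_e - V_o[o]) + G_oi[o] * (vrp_i - V_o[o])
            v, islow, vp, spiked = _map_step(
                V_o[o], I_o[o], Vp_o[o], ext, alpha, mu, sigma,
                beta_e, sigma_e, branch1_offset, literal_slow)
            V_o[o] = v
            I_o[o] = islow
            Vp_o[o] = vp
            if spiked:
                output_counts[o] += 1
                if n < decision_steps:
                    output_counts_half[o] += 1
                if c_o < ev_o_id.shape[0]:
                    ev_o_id[c_o] = o
                    ev_o_t[c_o] = n
                    c_o += 1
                else:
                    overflow = True

    return c_in, c_h, c_o, overflow
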