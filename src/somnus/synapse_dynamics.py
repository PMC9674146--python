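"""Event-driven synaptic conductance with stochastic release amplitude.

On each presynaptic spike the conductance jumps by the synaptic weight
(normalized by the postsynaptic target sum) scaled by a release factor
drawn uniformly from ``[1-R, 1+R]``; between spikes it relaxes
geometrically with ratio ``gamma``:

    g_{n+1} = gamma * g_n + (1 - R + 2*X*R) * W_ij / W_j_target   [on spike]
    I_syn   = -g_n * (V_post - V_rp)

``V_rp`` is the reversal potential and fixes the synapse's sign: an
excitatory synapse (``V_rp`` above rest) depolarizes, an inhibitory one
(``V_rp`` below rest) hyperpolarizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SynapseParams

__all__ = ["SynapseParams", "SynapticState", "step_synapse", "release_factor"]


@dataclass
class SynapticState:
    """Conductance of one (pre, post) synapse; decays to zero absent input."""

    g: float = 0.0


def release_factor(R: float, X: float) -> float:
    """Stochastic release amplitude ``1 - R + 2*X*R`` for ``X ~ U[0, 1]``."""
    return 1.0 - R + 2.0 * X * R


def step_synapse(state: SynapticState, params: SynapseParams,
                 pre_spiked: bool, W_ij: float, W_j_target: float,
                 X: float, V_post: float,
                 excitatory: bool = True) -> tuple[SynapticState, float]:
    """Advance one synapse a single step and return its postsynaptic current.

    Parameters
    ----------
    X
        Uniform[0, 1] draw from the caller's seeded stream; consumed only
        when ``pre_spiked``.
    W_j_target
        Postsynaptic normalization (the homeostatic target input sum under
        the default normalization mode); must be positive.
    """
    if W_j_target <= 0:
        raise ValueError("W_j_target must be positive (degenerate normalization)")
    g = params.gamma * state.g
    if pre_spiked:
        if params.normalization == "target_sum":
            increment = W_ij / W_j_target
        else:                       # "fixed": raw coupling strength
            increment = W_ij
        g += release_factor(params.release_variability, X) * increment
    v_rp = params.v_rp_exc if excitatory else params.v_rp_inh
    i_syn = -g * (V_post - v_rp)
    return SynapticState(g=g), i_syn
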