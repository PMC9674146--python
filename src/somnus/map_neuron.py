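"""Two-variable map-based (Rulkov-type) spiking neuron.

The membrane variable ``V`` evolves under a piecewise fast map and the slow
variable ``I`` integrates activity on a ``1/mu`` timescale:

    V_{n+1} = f_alpha(V_n, I_n + beta_e * I_ext)
    I_{n+1} = I_n - mu * (V_n + 1) + mu * sigma + mu * sigma_e * I_ext

with the fast map

    f_alpha(V, I*) = alpha / (1 - V) - 1 + I*        if V <= 0
                   = alpha + I*                       if 0 < V < alpha + I*
                                                        and V_prev <= 0
                   = -1                               otherwise.

A spike is registered on the plateau step (second branch), giving exactly
one spike per upstroke/peak/reset cycle; the step after a spike always
resets ``V`` to -1 exactly.  This module is the scalar/vector reference
implementation; the simulation loop uses a compiled kernel with identical
arithmetic (cross-checked in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import MapParams

__all__ = ["MapParams", "MapNeuronState", "step_neuron", "resting_state",
           "iterate"]


@dataclass
class MapNeuronState:
    """State of one map neuron (or an array of them)."""

    V: float | np.ndarray
    I: float | np.ndarray
    V_prev: float | np.ndarray
    spiked: bool | np.ndarray = False


def resting_state(params: MapParams) -> MapNeuronState:
    """Silent fixed point of the map with zero external input.

    The slow variable equilibrates where the mean of ``V`` equals
    ``sigma - 1``; substituting into the subthreshold branch gives the
    resting ``I``.  Returned values solve both equations exactly.
    """
    v = params.sigma - 1.0
    offset = 1.0 if params.branch1_minus_one else 0.0
    i = v + offset - params.alpha / (1.0 - v)
    return MapNeuronState(V=v, I=i, V_prev=v, spiked=False)


def step_neuron(state: MapNeuronState, params: MapParams,
                I_ext: float | np.ndarray = 0.0) -> MapNeuronState:
    """Advance the neuron one time step under external current ``I_ext``.

    Works on scalars or numpy arrays elementwise.  Raises on non-finite
    state, which signals numerical blow-up upstream.
    """
    V = np.asarray(state.V, dtype=float)
    I = np.asarray(state.I, dtype=float)
    Vp = np.asarray(state.V_prev, dtype=float)
    ext = np.asarray(I_ext, dtype=float)
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(I))):
        raise FloatingPointError("non-finite neuron state")

    i_star = I + params.beta_e * ext
    offset = 1.0 if params.branch1_minus_one else 0.0

    sub = V <= 0.0
    plateau = (~sub) & (V < params.alpha + i_star) & (Vp <= 0.0)

    v_next = np.where(
        sub,
        params.alpha / (1.0 - V) - offset + i_star,
        np.where(plateau, params.alpha + i_star, -1.0),
    )
    if params.literal_slow_term:
        i_next = I - params.mu * v_next + params.mu * params.sigma \
            + params.mu * params.sigma_e * ext
    else:
        i_next = I - params.mu * (V + 1.0) + params.mu * params.sigma \
            + params.mu * params.sigma_e * ext

    if v_next.ndim == 0:
        return MapNeuronState(V=float(v_next), I=float(i_next),
                              V_prev=float(V), spiked=bool(plateau))
    return MapNeuronState(V=v_next, I=i_next, V_prev=V, spiked=plateau)


def iterate(state: MapNeuronState, params: MapParams,
            I_ext_series) -> tuple[MapNeuronState, np.ndarray, np.ndarray]:
    """Run the map over a drive series; return (state, V trace, spike flags)."""
    vs, spikes = [], []
    for ext in I_ext_series:
        state = step_neuron(state, params, ext)
        vs.append(state.V)
        spikes.append(state.spiked)
    return state, np.asarray(vs), np.asarray(spikes, dtype=bool)
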