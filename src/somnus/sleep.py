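"""Simulated REM-like sleep: input silenced, hidden layer driven by noise.

During a sleep interval the sensory input layer receives no stimulation
and stays silent, the output layer spikes but no longer moves the agent,
and each hidden neuron is driven by an independent Poisson spike train
delivered through a dedicated excitatory noise synapse (standard release
variability).  The Poisson intensity is adjusted by a slow proportional
controller so each neuron's realized rate tracks a target -- the mean rate
that neuron showed during preceding awake task training -- conserving
spiking statistics across wake and sleep.  Hidden-to-output plasticity
stays on with a constant reward of ``S_rp = 0.5`` per movement cycle,
which makes the rewarded rule functionally unsupervised replay.

The ``uniform_rate`` variant drives every hidden neuron at the population
mean rate instead of its private rate history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimConfig, SleepParams
from .network import Network
from .plasticity import (apply_rewarded_update, heterosynaptic_rescale,
                         homeostatic_scale, inhibitory_balance)

__all__ = ["SleepParams", "SleepDriver", "record_target_rates",
           "run_sleep_interval", "interleave"]


def record_target_rates(run_record, phase_labels) -> np.ndarray:
    """Per-hidden-neuron target rates: average of per-phase mean rates.

    ``phase_labels`` names training phases of the run record; each phase
    contributes its per-neuron mean spikes/epoch, and targets are the
    across-phase average.  Raises if a named phase is missing or empty.
    """
    labels = [phase_labels] if isinstance(phase_labels, str) else list(phase_labels)
    if not labels:
        raise ValueError("no phases named for target-rate recording")
    by_label = {ph.label: ph for ph in run_record.phases}
    rates = []
    for label in labels:
        if label not in by_label:
            raise ValueError(f"phase {label!r} not found in run record")
        ph = by_label[label]
        if ph.n_epochs == 0 or ph.hidden_rate_mean is None:
            raise ValueError(f"phase {label!r} has no recorded hidden activity")
        rates.append(ph.hidden_rate_mean)
    return np.mean(rates, axis=0)


@dataclass
class SleepDriver:
    """Closed-loop Poisson drive for one network's hidden layer.

    ``lam`` holds the per-neuron Poisson intensity in events/epoch; the
    controller nudges it after every sleep epoch by
    ``controller_gain * (target - realized)`` where ``realized`` is an
    exponential moving average of the neuron's spikes/epoch.
    """

    params: SleepParams
    target_rates: np.ndarray
    lam: np.ndarray
    ema_rates: np.ndarray

    @classmethod
    def for_targets(cls, params: SleepParams, target_rates: np.ndarray,
                    n_hidden: int) -> "SleepDriver":
        targets = np.asarray(target_rates, dtype=float)
        if params.mode == "uniform_rate":
            targets = np.full(n_hidden, float(targets.mean()))
        lam = np.clip(params.lambda_init_scale * targets, 0.05, params.lambda_max)
        return cls(params=params, target_rates=targets, lam=lam,
                   ema_rates=targets.copy())

    def noise_prob(self, epoch_steps: int) -> np.ndarray:
        """Per-step event probability for the kernel."""
        return np.clip(self.lam / epoch_steps, 0.0, 1.0)

    def update(self, realized_counts: np.ndarray) -> None:
        a = self.params.rate_ema
        self.ema_rates = (1 - a) * self.ema_rates + a * realized_counts
        self.lam += self.params.controller_gain * (self.target_rates - self.ema_rates)
        np.clip(self.lam, 0.0, self.params.lambda_max, out=self.lam)


def run_sleep_interval(net: Network, driver: SleepDriver, n_cycles: int,
                       homeostasis: bool = True):
    """Run ``n_cycles`` sleep movement cycles on a network, in place.

    Returns ``(hidden_counts_total, input_spikes_total, output_spikes_total)``
    accumulated over the interval.  The agent is untouched by construction:
    sleep never consults or moves it.
    """
    cfg: SimConfig = net.config
    sp = cfg.sleep
    p = cfg.network
    hidden_total = np.zeros(p.n_hidden, dtype=np.int64)
    input_total = 0
    output_total = 0
    for _ in range(n_cycles):
        res = net.run_epoch(
            np.zeros(p.n_input), ih_plasticity=False, ho_traces=True,
            noise_prob=driver.noise_prob(p.epoch_steps), stimulate_input=False)
        net.avg_tr = apply_rewarded_update(
            net.weights, net.trace_buffer, sp.s_rp_sleep, res.epoch,
            net.avg_tr, cfg.stdp)
        heterosynaptic_rescale(net.weights)
        inhibitory_balance(net.weights)
        if homeostasis and sp.homeostasis_during_sleep:
            homeostatic_scale(net.weights, res.output_counts, cfg.homeostasis)
        driver.update(res.hidden_counts.astype(float))
        hidden_total += res.hidden_counts
        input_total += int(res.input_counts.sum())
        output_total += int(res.output_counts.sum())
    return hidden_total, input_total, output_total


def interleave(session, task_name: str, aeons: int):
    """Alternate equal blocks of task training and sleep on a session.

    ``task_name`` is ``"T1"`` or ``"T2"``; blocks last
    ``protocol.block_cycles`` movement cycles each.  Returns the phase
    record (labelled ``interleaved_S_<task>``) with strictly alternating
    block labels.
    """
    from .protocols import Phase  # session lives in protocols; avoid cycle
    if task_name not in ("T1", "T2"):
        raise ValueError("task_name must be 'T1' or 'T2'")
    return session.run_phase(Phase(f"interleaved_S_{task_name}", aeons))
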