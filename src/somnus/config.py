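"""Parameter containers, presets, and structured-text configuration loading.

All tunables of the simulator live here, grouped by the part of the model
they control.  Values quoted in the literature for this class of model
(map-neuron constant ``alpha``, plasticity time constant ``tc`` etc.) are the
defaults; everything else is a calibration constant of this package and is
documented in ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


@dataclass
class MapParams:
    """Constants of the two-variable map (Rulkov-type) neuron.

    ``alpha`` shapes the fast nonlinearity, ``mu`` sets the slow-variable
    timescale, ``sigma`` the intrinsic drive, and ``beta_e`` / ``sigma_e``
    couple external current into the fast and slow equations.  One discrete
    step corresponds to ``dt`` milliseconds.
    """

    alpha: float = 3.65
    mu: float = 0.0005
    sigma: float = 0.06
    beta_e: float = 0.133
    sigma_e: float = 1.0
    dt: float = 0.5
    # Reading of the fast map's subthreshold branch: alpha/(1-V) - 1 + I
    # (the form with a genuine resting state near V = -1).  Setting this
    # False drops the "-1" for sensitivity checks.
    branch1_minus_one: bool = True
    # Slow-variable coupling: -mu*(V_n + 1) (canonical) vs -mu*V_{n+1}.
    literal_slow_term: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.mu < 1):
            raise ConfigError("MapParams.mu must lie in (0, 1)")
        if self.alpha <= 1:
            raise ConfigError("MapParams.alpha must exceed 1")


@dataclass
class SynapseParams:
    """Event-driven conductance synapse: decay, release noise, reversal."""

    gamma: float = 0.6
    release_variability: float = 0.12  # R: release amplitude ~ U[1-R, 1+R]
    v_rp_exc: float = 0.0
    v_rp_inh: float = -1.1
    # How the conductance increment is normalized: "target_sum" divides the
    # plastic weight by the postsynaptic homeostatic target sum; "fixed"
    # uses the raw weight.
    normalization: str = "target_sum"

    def __post_init__(self) -> None:
        if not (0 <= self.gamma < 1):
            raise ConfigError("SynapseParams.gamma must lie in [0, 1)")
        if not (0 <= self.release_variability < 1):
            raise ConfigError("release_variability must lie in [0, 1)")
        if self.normalization not in ("target_sum", "fixed"):
            raise ConfigError(
                "SynapseParams.normalization must be 'target_sum' or 'fixed'"
            )


@dataclass
class StdpParams:
    """Spike-timing plasticity constants.

    A pre/post pairing separated by ``dt_ms`` leaves a trace of value
    ``±k * exp(-|dt_ms| / tc)``; pairs further apart than
    ``pairing_window`` steps leave none.  Hidden-to-output traces survive
    ``trace_lifetime`` epochs and are converted into weight changes only on
    reward events.
    """

    tc: float = 40.0              # ms
    k: float = 0.04               # trace maximum; sign set by pairing order
    pairing_window: int = 120     # steps
    trace_lifetime: int = 6       # epochs
    c: float = 1.0                # epochs; softens very recent traces
    delta: float = 0.01           # running-average rate for Avg_tr
    avg_tr_floor: float = 1e-6
    # Literal order of the reward-normalization ratio in the update:
    # "sum_over_avg" (default) or "avg_over_sum".
    ratio_order: str = "sum_over_avg"
    # Scope of Sum_tr: "per_synapse" sums the discounted live traces of
    # the synapse being updated (coincidence-weighted credit; anti-causal
    # pairings are depressed by rewards), "global" pools all live traces.
    sum_scope: str = "per_synapse"
    # Numerical guards on the rewarded update: |Sum_tr/Avg_tr| is clipped
    # at ratio_clip; the per-event multiplier of any one synapse is clamped
    # into [factor_clip_low, factor_clip_high]; and weights are floored at
    # w_floor_frac of the mean column weight so a fully depressed synapse
    # remains recruitable (a hard zero is absorbing under a product rule).
    ratio_clip: float = 3.0
    factor_clip_low: float = 0.2
    factor_clip_high: float = 5.0
    w_floor_frac: float = 1e-3
    # Unsupervised (input->hidden) application of a trace: multiplicative
    # W*(1+tr), mirroring the rewarded rule; "additive" adds K-scaled trace.
    unsupervised_mode: str = "multiplicative"
    # Rescale each hidden neuron's afferent weights to its initial input
    # sum after every unsupervised update.  Plain STDP with volley-locked
    # timing is potentiation-dominated and diverges without this synaptic
    # scaling; the competition it induces is what carves receptive fields.
    ih_input_scaling: bool = True
    # Cap on any single afferent's share of its neuron's input sum.  With
    # competitive scaling the winner-take-all dynamics would otherwise
    # collapse a receptive field onto one pixel, which cannot carry
    # orientation information; small values keep the field distributed so
    # hidden firing stays a multi-pixel coincidence detector.
    ih_share_cap: float = 0.15

    def __post_init__(self) -> None:
        if self.tc <= 0:
            raise ConfigError("StdpParams.tc must be positive")
        if not (0 < self.delta < 1):
            raise ConfigError("StdpParams.delta must lie in (0, 1)")
        if self.ratio_order not in ("sum_over_avg", "avg_over_sum"):
            raise ConfigError("ratio_order must be 'sum_over_avg' or 'avg_over_sum'")
        if self.sum_scope not in ("per_synapse", "global"):
            raise ConfigError("sum_scope must be 'per_synapse' or 'global'")
        if self.unsupervised_mode not in ("multiplicative", "additive"):
            raise ConfigError("unsupervised_mode must be 'multiplicative' or 'additive'")


@dataclass
class HomeostasisParams:
    """Per-epoch scaling of the output neurons' target input sums."""

    d_tar: float = 5e-5           # relative step of the target sum per epoch
    target_rate: float = 2.0      # spikes per epoch per output neuron


@dataclass
class RewardParams:
    """Reward scalars attached to movement outcomes during awake task phases."""

    s_rp_rewarded: float = 1.0
    s_rp_punished: float = -0.001
    s_rp_empty: float = -0.0001


@dataclass
class PolicyParams:
    explore_base: float = 0.01       # random-move probability floor
    explore_increment: float = 0.01  # added per non-acquiring move


@dataclass
class EnvParams:
    width: int = 50
    height: int = 50
    density: float = 0.10
    # "cell_fraction": density is the fraction of occupied cells (each
    # particle occupies two); "particle_fraction": fraction of cells that
    # carry a particle anchor.
    density_semantics: str = "cell_fraction"

    def __post_init__(self) -> None:
        if not (0 <= self.density <= 0.3):
            raise ConfigError("EnvParams.density must lie in [0, 0.3]")
        if self.density_semantics not in ("cell_fraction", "particle_fraction"):
            raise ConfigError(
                "density_semantics must be 'cell_fraction' or 'particle_fraction'"
            )


@dataclass
class NetworkParams:
    """Architecture and drive calibration of the three-layer network."""

    input_shape: tuple[int, int] = (7, 7)
    hidden_shape: tuple[int, int] = (28, 28)
    output_shape: tuple[int, int] = (3, 3)   # center neuron nonfunctional
    n_afferents: int = 9                     # inputs per hidden neuron
    epoch_steps: int = 600
    decision_steps: int = 300                # output spikes counted here
    pulse_amp: float = 12.0                  # input stimulation amplitude
    pulse_steps: int = 5                     # steps per stimulation pulse
    # The stimulus is re-applied every pulse_every steps while the
    # decision window is open, so the sensory scene drives several
    # feed-forward volleys per movement cycle.  Output spike counts then
    # range over the number of volleys, which makes the count read-out
    # graded rather than an all-tied single-volley snapshot.
    pulse_every: int = 150
    pulse_repeats: int = 4
    # Synaptic gains: scale of the conductance increment per presynaptic
    # spike, applied on top of the weight normalization.  Calibrated so that
    # coincident input arrivals (a particle) make hidden neurons fire while
    # single-pixel drive usually does not, and so that hidden volleys can
    # drive output spiking.
    gain_ih: float = 0.55
    gain_ho_exc: float = 10.0
    gain_ho_inh: float = 10.0
    # Initial weights: input->hidden ~ Normal(w_ih_mean, sd_frac*mean),
    # truncated at 0; hidden->output uniform constant w_ho_init.
    w_ih_mean: float = 0.1
    w_ih_sd_frac: float = 0.25
    w_ho_init: float = 0.0125
    # Return every neuron to the silent fixed point at epoch boundaries.
    # At mu = 5e-4 the slow variable needs several epochs to relax after a
    # burst, so without the reset the "epoch ends at rest" property fails
    # and detector reliability varies with recent firing history.
    reset_state_each_epoch: bool = True

    @property
    def n_input(self) -> int:
        return self.input_shape[0] * self.input_shape[1]

    @property
    def n_hidden(self) -> int:
        return self.hidden_shape[0] * self.hidden_shape[1]

    @property
    def n_output(self) -> int:
        """Functional (decision) output neurons; the grid center is excluded."""
        return self.output_shape[0] * self.output_shape[1] - 1


@dataclass
class SleepParams:
    """REM-like sleep phase: silenced input, Poisson drive to hidden layer."""

    mode: str = "per_neuron_rates"     # or "uniform_rate"
    interval_cycles: int = 100         # movement cycles per sleep block
    s_rp_sleep: float = 0.5
    noise_amp: float = 1.2             # conductance kick per Poisson event
    controller_gain: float = 0.1      # events/epoch correction per spike error
    rate_ema: float = 0.2              # smoothing of the realized-rate estimate
    lambda_init_scale: float = 2.0     # initial drive = scale * target rate
    lambda_max: float = 60.0           # events/epoch ceiling
    homeostasis_during_sleep: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("per_neuron_rates", "uniform_rate"):
            raise ConfigError("SleepParams.mode must be 'per_neuron_rates' or 'uniform_rate'")
        if self.interval_cycles < 1:
            raise ConfigError("SleepParams.interval_cycles must be >= 1")


@dataclass
class ProtocolParams:
    """Phase durations (in aeons; 1 aeon = 100 epochs) and bookkeeping."""

    unsupervised_aeons: int = 2000
    train_aeons: int = 10000
    test_aeons: int = 500
    block_cycles: int = 100            # interleaving granularity
    snapshot_every_aeons: int = 50     # weight snapshot cadence in training
    plasticity_during_test: bool = False


@dataclass
class SimConfig:
    """Bundle of every parameter group; the unit a run is configured by."""

    map: MapParams = field(default_factory=MapParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    stdp: StdpParams = field(default_factory=StdpParams)
    homeostasis: HomeostasisParams = field(default_factory=HomeostasisParams)
    reward: RewardParams = field(default_factory=RewardParams)
    policy: PolicyParams = field(default_factory=PolicyParams)
    env: EnvParams = field(default_factory=EnvParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    sleep: SleepParams = field(default_factory=SleepParams)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        d = self.to_dict()
        d["network"]["input_shape"] = list(d["network"]["input_shape"])
        d["network"]["hidden_shape"] = list(d["network"]["hidden_shape"])
        d["network"]["output_shape"] = list(d["network"]["output_shape"])
        return yaml.safe_dump(d, sort_keys=False)


_GROUPS = {f.name: f.type for f in fields(SimConfig)}
_GROUP_CLASSES = {
    "map": MapParams,
    "synapse": SynapseParams,
    "stdp": StdpParams,
    "homeostasis": HomeostasisParams,
    "reward": RewardParams,
    "policy": PolicyParams,
    "env": EnvParams,
    "network": NetworkParams,
    "sleep": SleepParams,
    "protocol": ProtocolParams,
}

_TUPLE_FIELDS = {"input_shape", "hidden_shape", "output_shape"}


def config_from_dict(data: dict[str, Any] | None) -> SimConfig:
    """Build a :class:`SimConfig` from a (possibly partial) nested dict.

    Unknown group or field names are rejected with a path-to-field message.
    """
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    groups: dict[str, Any] = {}
    for group_name, payload in data.items():
        if group_name not in _GROUP_CLASSES:
            raise ConfigError(f"unknown configuration group: {group_name!r}")
        cls = _GROUP_CLASSES[group_name]
        if payload is None:
            payload = {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{group_name}: expected a mapping of fields")
        known = {f.name for f in fields(cls)}
        for key in payload:
            if key not in known:
                raise ConfigError(f"unknown field: {group_name}.{key}")
        payload = {
            k: tuple(v) if k in _TUPLE_FIELDS else v for k, v in payload.items()
        }
        try:
            groups[group_name] = cls(**payload)
        except ConfigError:
            raise
        except (TypeError, ValueError) as exc:  # pragma: no cover - defensive
            raise ConfigError(f"{group_name}: {exc}") from exc
    return SimConfig(**groups)


def load_config(path: str) -> SimConfig:
    """Load and validate a YAML configuration file.

    An empty file yields all defaults.  Fields not mentioned keep their
    default values; unknown keys are rejected naming the offending field.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def desk_preset() -> SimConfig:
    """Short-phase preset sized so a full protocol runs in minutes on one CPU.

    Only the phase durations differ from the defaults; all model parameters
    are identical to the full-scale configuration.
    """
    cfg = SimConfig()
    cfg.protocol = ProtocolParams(
        unsupervised_aeons=15,
        train_aeons=120,
        test_aeons=15,
        snapshot_every_aeons=5,
    )
    return cfg


def full_preset() -> SimConfig:
    """Full-length phase durations (hours of compute per trial)."""
    return SimConfig()
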