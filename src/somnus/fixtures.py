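"""Deterministic miniature fixtures for tests and examples.

A fixture is a scaled-down world + network (e.g. a 12x12 environment with
a 5x5 visual field and a 6x6 hidden layer) that satisfies every module
invariant at miniature scale, plus optionally planted weight structure
with known analytical properties (for oracle checks of the analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ProtocolParams, SimConfig
from .protocols import Session


@dataclass
class FixtureSpec:
    """Miniature dimensions and planted structure for a test fixture."""

    seed: int = 0
    env_size: int = 12
    density: float = 0.10
    input_side: int = 5
    hidden_side: int = 6
    n_afferents: int = 4
    unsupervised_aeons: int = 1
    train_aeons: int = 2
    test_aeons: int = 1
    snapshot_every_aeons: int = 1


def fixture_config(spec: FixtureSpec | None = None) -> SimConfig:
    spec = spec or FixtureSpec()
    cfg = SimConfig()
    cfg.env.width = cfg.env.height = spec.env_size
    cfg.env.density = spec.density
    cfg.network.input_shape = (spec.input_side, spec.input_side)
    cfg.network.hidden_shape = (spec.hidden_side, spec.hidden_side)
    cfg.network.n_afferents = spec.n_afferents
    cfg.protocol = ProtocolParams(
        unsupervised_aeons=spec.unsupervised_aeons,
        train_aeons=spec.train_aeons,
        test_aeons=spec.test_aeons,
        snapshot_every_aeons=spec.snapshot_every_aeons,
    )
    return cfg


def make_fixture(spec: FixtureSpec | None = None) -> Session:
    """Miniature network + environment session, deterministic from the seed."""
    spec = spec or FixtureSpec()
    return Session(fixture_config(spec), seed=spec.seed)


@dataclass
class PlantedFixture:
    """Tiny hand-wired network with a single meaningful receptive field.

    One hidden neuron (id 0) is wired to exactly the two pixels of a
    horizontal particle in the upper-left of a 7x7 field and projects only
    to the up-left output neuron; all other weights are zero.  PRM and
    receptive-field values on this fixture are hand-computable.
    """

    fov: int = 7
    n_hidden: int = 4
    n_output: int = 8
    rf_weight: float = 1.0
    ho_weight: float = 1.0
    pixel_a: tuple[int, int] = (1, 1)    # horizontal particle: (1,1)-(1,2)
    pixel_b: tuple[int, int] = (1, 2)
    wiring: np.ndarray = field(init=False)
    w_ih: np.ndarray = field(init=False)
    w_ho: np.ndarray = field(init=False)

    def __post_init__(self):
        n_aff = 2
        self.wiring = np.zeros((self.n_hidden, n_aff), dtype=np.int64)
        self.w_ih = np.zeros((self.n_hidden, n_aff))
        ids = [self.pixel_a[0] * self.fov + self.pixel_a[1],
               self.pixel_b[0] * self.fov + self.pixel_b[1]]
        self.wiring[0] = ids
        self.w_ih[0] = self.rf_weight
        # Unused hidden neurons wired to distinct dead pixels, zero weight.
        for h in range(1, self.n_hidden):
            self.wiring[h] = [(2 * h) % (self.fov ** 2),
                              (2 * h + 1) % (self.fov ** 2)]
        self.w_ho = np.zeros((self.n_hidden, self.n_output))
        self.w_ho[0, 0] = self.ho_weight    # output 0 = up-left direction
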