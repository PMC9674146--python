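"""HDF5 run container: write/read of run records with full labelling.

Layout::

    /                attrs: format_version, n_trials
    /config          config echo (YAML string dataset)
    /trial<t>        attrs: seed, trial
      /phase<i>      attrs: label, kind, start_epoch, n_epochs, block_labels
        rewarded, punished, empty        per-aeon consumption counts
        hidden_rate_mean                 per-neuron mean spikes/epoch
        snapshots (n, d) float32         flattened H->O weight snapshots
        snap_aeons (n,)
      /final         wiring and end-of-run weight matrices

Write-then-read is the identity on all datasets and labels.  Containers
are single-writer; concurrent reads of a closed file are safe.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import yaml

from .config import SimConfig, config_from_dict
from .protocols import PhaseRecord, RunRecord

FORMAT_VERSION = 1


class ContainerVersionError(RuntimeError):
    pass


def write_run(records, path: str) -> None:
    """Write one record or a list of trial records to an HDF5 container."""
    if isinstance(records, RunRecord):
        records = [records]
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["n_trials"] = len(records)
        cfg = next((r.config for r in records if r.config is not None), None)
        f.create_dataset("config", data=(cfg or SimConfig()).to_yaml())
        for rec in records:
            g = f.create_group(f"trial{rec.trial}")
            g.attrs["seed"] = rec.seed
            g.attrs["trial"] = rec.trial
            for i, ph in enumerate(rec.phases):
                pg = g.create_group(f"phase{i}")
                pg.attrs["label"] = ph.label
                pg.attrs["kind"] = ph.kind
                pg.attrs["start_epoch"] = ph.start_epoch
                pg.attrs["n_epochs"] = ph.n_epochs
                pg.attrs["block_labels"] = json.dumps(ph.block_labels)
                for name in ("rewarded", "punished", "empty"):
                    arr = getattr(ph, name)
                    if arr is not None:
                        pg.create_dataset(name, data=arr)
                if ph.hidden_rate_mean is not None:
                    pg.create_dataset("hidden_rate_mean", data=ph.hidden_rate_mean)
                if ph.snap_weights:
                    pg.create_dataset(
                        "snapshots",
                        data=np.asarray(ph.snap_weights, dtype=np.float32))
                    pg.create_dataset("snap_aeons",
                                      data=np.asarray(ph.snap_aeons))
            if rec.final_state:
                fg = g.create_group("final")
                for name, arr in rec.final_state.items():
                    fg.create_dataset(name, data=arr)


def read_run(path: str) -> tuple[list[RunRecord], SimConfig]:
    """Read a container back into run records plus its config echo."""
    records = []
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ContainerVersionError(
                f"container format {version} != supported {FORMAT_VERSION}")
        cfg = config_from_dict(yaml.safe_load(f["config"][()].decode()))
        trial_keys = sorted((k for k in f if k.startswith("trial")),
                            key=lambda k: int(k[5:]))
        for tk in trial_keys:
            g = f[tk]
            rec = RunRecord(seed=int(g.attrs["seed"]),
                            trial=int(g.attrs["trial"]), config=cfg)
            phase_keys = sorted((k for k in g if k.startswith("phase")),
                                key=lambda k: int(k[5:]))
            for pk in phase_keys:
                pg = g[pk]
                ph = PhaseRecord(
                    label=str(pg.attrs["label"]),
                    kind=str(pg.attrs["kind"]),
                    start_epoch=int(pg.attrs["start_epoch"]),
                    n_epochs=int(pg.attrs["n_epochs"]),
                    block_labels=json.loads(pg.attrs["block_labels"]),
                )
                for name in ("rewarded", "punished", "empty"):
                    if name in pg:
                        setattr(ph, name, pg[name][:])
                if "hidden_rate_mean" in pg:
                    ph.hidden_rate_mean = pg["hidden_rate_mean"][:]
                if "snapshots" in pg:
                    ph.snap_weights = list(pg["snapshots"][:])
                    ph.snap_aeons = list(pg["snap_aeons"][:])
                rec.phases.append(ph)
            if "final" in g:
                rec.final_state = {name: g["final"][name][:]
                                   for name in g["final"]}
            records.append(rec)
    return records, cfg
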