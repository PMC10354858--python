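"""Artifact persistence: HDF5 datasets, npz model checkpoints, CSV tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from . import nn
from .scnn import SCNNConfig, TrainedSCNN, build_scnn
from .simulate import (BeamRecord, Dataset, DetectorConfig, DoseEngineParams,
                       NoiseConfig, make_detector_geometry)
from .vae import TrainedVAE, VAEConfig, build_vae

__all__ = [
    "save_dataset", "load_dataset",
    "save_vae", "load_vae", "save_scnn", "load_scnn",
]


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a simulated dataset (with provenance) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = dataset.seed
        f.attrs["split"] = dataset.split
        f.attrs["detector_config"] = json.dumps(
            dataclasses.asdict(dataset.geometry.config))
        f.attrs["engine"] = json.dumps(dataclasses.asdict(dataset.engine))
        f.attrs["noise"] = json.dumps(dataclasses.asdict(dataset.noise))
        if dataset.field_axes is not None:
            f.create_dataset("field_axes", data=dataset.field_axes)
        for beam in dataset.beams:
            g = f.create_group(f"beams/{beam.beam_id:05d}")
            g.attrs["beam_id"] = beam.beam_id
            g.attrs["split"] = beam.split
            g.attrs["plan_seed"] = beam.plan_seed
            g.attrs["measurement_seed"] = beam.measurement_seed
            for k in range(2):
                g.create_dataset(f"measured/plane{k + 1}",
                                 data=beam.measured[k])
            for cond, vals in beam.calc.items():
                for k in range(2):
                    g.create_dataset(f"calc/{cond}/plane{k + 1}", data=vals[k])
            if beam.plane_fields is not None:
                for cond, fields in beam.plane_fields.items():
                    for k in range(2):
                        g.create_dataset(f"fields/{cond}/plane{k + 1}",
                                         data=fields[k],
                                         compression="gzip", compression_opts=4)


def load_dataset(path: str | Path) -> Dataset:
    with h5py.File(path, "r") as f:
        geometry = make_detector_geometry(
            DetectorConfig(**{
                **json.loads(f.attrs["detector_config"]),
                "plane_angles": tuple(
                    json.loads(f.attrs["detector_config"])["plane_angles"]),
            }))
        engine = DoseEngineParams(**json.loads(f.attrs["engine"]))
        noise = NoiseConfig(**json.loads(f.attrs["noise"]))
        field_axes = f["field_axes"][()] if "field_axes" in f else None
        beams = []
        for name in sorted(f["beams"]):
            g = f[f"beams/{name}"]
            calc = {
                cond: tuple(g[f"calc/{cond}/plane{k + 1}"][()] for k in range(2))
                for cond in g["calc"]
            }
            fields = None
            if "fields" in g:
                fields = {
                    cond: tuple(g[f"fields/{cond}/plane{k + 1}"][()]
                                for k in range(2))
                    for cond in g["fields"]
                }
            beams.append(BeamRecord(
                beam_id=int(g.attrs["beam_id"]), split=str(g.attrs["split"]),
                plan_seed=int(g.attrs["plan_seed"]),
                measurement_seed=int(g.attrs["measurement_seed"]),
                calc=calc,
                measured=tuple(g[f"measured/plane{k + 1}"][()]
                               for k in range(2)),
                plane_fields=fields,
            ))
        return Dataset(seed=int(f.attrs["seed"]),
                       split=tuple(int(s) for s in f.attrs["split"]),
                       geometry=geometry, engine=engine, noise=noise,
                       beams=beams, field_axes=field_axes)


def _save_net(path: Path, state: dict, config, history: dict) -> None:
    meta = {"config": dataclasses.asdict(config), "history": history}
    np.savez(path, __meta__=np.bytes_(json.dumps(meta)), **state)


def _load_meta(data) -> dict:
    return json.loads(bytes(data["__meta__"].item()).decode())


def save_vae(model: TrainedVAE, path: str | Path) -> None:
    state = {}
    for part, name in ((model.net.trunk, "trunk"), (model.net.head_mu, "mu"),
                       (model.net.head_logvar, "logvar"),
                       (model.net.decoder, "dec")):
        for key, val in nn.state_dict(part).items():
            state[f"{name}.{key}"] = val
    _save_net(Path(path), state, model.config, model.history)


def load_vae(path: str | Path) -> TrainedVAE:
    with np.load(path) as data:
        meta = _load_meta(data)
        cfg = meta["config"]
        cfg["conv_filters"] = tuple(cfg["conv_filters"])
        model = build_vae(VAEConfig(**cfg))
        for part, name in ((model.net.trunk, "trunk"),
                           (model.net.head_mu, "mu"),
                           (model.net.head_logvar, "logvar"),
                           (model.net.decoder, "dec")):
            sub = {k[len(name) + 1:]: data[k] for k in data.files
                   if k.startswith(name + ".")}
            nn.load_state_dict(part, sub)
        model.history = meta["history"]
    return model


def save_scnn(model: TrainedSCNN, path: str | Path) -> None:
    _save_net(Path(path), nn.state_dict(model.net), model.config, model.history)


def load_scnn(path: str | Path) -> TrainedSCNN:
    with np.load(path) as data:
        meta = _load_meta(data)
        cfg = meta["config"]
        for key in ("conv_filters", "dense_nodes", "dropout_rates"):
            cfg[key] = tuple(cfg[key])
        model = build_scnn(SCNNConfig(**cfg))
        nn.load_state_dict(model.net, {k: data[k] for k in data.files
                                       if k != "__meta__"})
        model.history = meta["history"]
    return model
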