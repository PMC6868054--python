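"""Serialization of networks, spike trains, tables and datasets.

Formats are deliberately plain: network definitions as YAML with explicit
units in field names, spike trains as two-column text (``time_ms
neuron_id``) with an HDF5 container for large runs, probability tables as
``bitstring probability`` text, and image datasets as CSV rows of flat 0/1
pixels plus label and split columns.  Every run directory written by the
CLI contains a config snapshot with all seeds, enough to reproduce itself.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .lif_core import (
    NetworkDefinition,
    NeuronParameters,
    PortProjection,
    SpikeTrain,
    SynapseSpec,
)
from .sampling_theory import ProbabilityTable, StateSequence
from .synthetic_data import ImageDataset

__all__ = [
    "RunConfig",
    "save_network",
    "load_network",
    "save_spikes",
    "load_spikes",
    "save_spikes_hdf5",
    "load_spikes_hdf5",
    "save_states_hdf5",
    "save_table",
    "load_table",
    "save_dataset",
    "load_dataset",
    "read_idx",
]

_NEURON_FIELDS = {
    "V_reset_mV": "V_reset", "E_leak_mV": "E_leak", "V_thresh_mV": "V_thresh",
    "E_inh_mV": "E_inh", "E_exc_mV": "E_exc", "tau_ref_ms": "tau_ref",
    "tau_mem_ms": "tau_mem", "C_mem_nF": "C_mem",
    "tau_syn_exc_ms": "tau_syn_exc", "tau_syn_inh_ms": "tau_syn_inh",
}


@dataclass
class RunConfig:
    """Experiment tag, file paths and the full seed hierarchy of one run.

    Independent seed streams (substrate, trial, data, training) ensure that
    changing one does not perturb the others.
    """

    experiment: str
    out_dir: str = "."
    substrate_seed: int = 0
    trial_seed: int = 0
    data_seed: int = 0
    training_seed: int = 0
    extra: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"experiment": self.experiment, "out_dir": self.out_dir,
                 "seeds": {"substrate": self.substrate_seed,
                           "trial": self.trial_seed,
                           "data": self.data_seed,
                           "training": self.training_seed},
                 "extra": self.extra},
                fh, sort_keys=False)

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        seeds = d.get("seeds", {})
        return cls(experiment=d["experiment"], out_dir=d.get("out_dir", "."),
                   substrate_seed=seeds.get("substrate", 0),
                   trial_seed=seeds.get("trial", 0),
                   data_seed=seeds.get("data", 0),
                   training_seed=seeds.get("training", 0),
                   extra=d.get("extra", {}))


def save_network(net: NetworkDefinition, path: str) -> None:
    net.ensure_gains()
    doc = {
        "neurons": [
            {**{k: float(getattr(p, v)) for k, v in _NEURON_FIELDS.items()},
             "role": role}
            for p, role in zip(net.neurons, net.roles)
        ],
        "synapses": [
            {"pre": s.pre, "post": s.post, "weight_nS": float(s.weight),
             "kind": s.kind, "delay_ms": float(s.delay),
             **({"tau_syn_ms": float(s.tau_syn)} if s.tau_syn is not None else {}),
             **({"multapse_group": s.multapse_group}
                if s.multapse_group is not None else {})}
            for s in net.synapses
        ],
        "ports": {
            name: [
                {"post": p.post, "weight_nS": float(p.weight),
                 "kind": p.kind, "delay_ms": float(p.delay)}
                for p in projs
            ] for name, projs in net.ports.items()
        },
        "syn_gain": [float(g) for g in net.syn_gain],
        "tau_syn_exc_gain": [float(g) for g in net.tau_syn_exc_gain],
        "tau_syn_inh_gain": [float(g) for g in net.tau_syn_inh_gain],
        "tau_mem_gain": [float(g) for g in net.tau_mem_gain],
    }
    if net.port_gain:
        doc["port_gain"] = {k: [float(x) for x in v]
                            for k, v in net.port_gain.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_network(path: str) -> NetworkDefinition:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    net = NetworkDefinition()
    try:
        for nd in doc["neurons"]:
            params = NeuronParameters(
                **{v: float(nd[k]) for k, v in _NEURON_FIELDS.items()})
            net.add_neuron(params, role=nd.get("role", "sampling"))
        for sd in doc.get("synapses", []):
            net.synapses.append(SynapseSpec(
                pre=int(sd["pre"]), post=int(sd["post"]),
                weight=float(sd["weight_nS"]), kind=sd["kind"],
                delay=float(sd.get("delay_ms", 1.0)),
                tau_syn=(float(sd["tau_syn_ms"]) if "tau_syn_ms" in sd else None),
                multapse_group=sd.get("multapse_group"),
            ))
        for name, projs in doc.get("ports", {}).items():
            net.ports[name] = [
                PortProjection(post=int(p["post"]), weight=float(p["weight_nS"]),
                               kind=p["kind"], delay=float(p.get("delay_ms", 1.0)))
                for p in projs
            ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed network file {path!r}: {exc}") from exc
    net.ensure_gains()
    for key, attr in (("syn_gain", "syn_gain"),
                      ("tau_syn_exc_gain", "tau_syn_exc_gain"),
                      ("tau_syn_inh_gain", "tau_syn_inh_gain"),
                      ("tau_mem_gain", "tau_mem_gain")):
        if key in doc:
            setattr(net, attr, np.asarray(doc[key], dtype=float))
    if "port_gain" in doc:
        net.port_gain = {k: np.asarray(v, dtype=float)
                         for k, v in doc["port_gain"].items()}
    net.validate()
    return net


def save_spikes(spikes: SpikeTrain, path: str) -> None:
    """Two-column plain text: time_ms neuron_id."""
    with open(path, "w") as fh:
        fh.write("# time_ms neuron_id\n")
        for t, s in zip(spikes.times, spikes.sources):
            fh.write(f"{t:.6f} {s}\n")


def load_spikes(path: str) -> SpikeTrain:
    with open(path) as fh:
        lines = [l for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        return SpikeTrain.empty()
    try:
        data = np.loadtxt(lines, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed spike file {path!r}: {exc}") from exc
    return SpikeTrain(data[:, 0], data[:, 1].astype(np.int64))


def save_spikes_hdf5(spikes: SpikeTrain, path: str, duration: float | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times_ms", data=spikes.times)
        fh.create_dataset("sources", data=spikes.sources)
        if duration is not None:
            fh.attrs["duration_ms"] = duration


def load_spikes_hdf5(path: str) -> SpikeTrain:
    import h5py

    with h5py.File(path, "r") as fh:
        return SpikeTrain(fh["times_ms"][:], fh["sources"][:])


def save_states_hdf5(seq: StateSequence, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("breakpoints_ms", data=seq.breakpoints)
        fh.create_dataset("states", data=seq.states)


def save_table(table: ProbabilityTable, path: str) -> None:
    """Two-column text: state bitstring (unit 0 leftmost), probability."""
    with open(path, "w") as fh:
        fh.write("# state probability\n")
        for idx, p in enumerate(table.p):
            bits = "".join(str((idx >> k) & 1) for k in range(table.n))
            fh.write(f"{bits} {p:.17g}\n")


def load_table(path: str) -> ProbabilityTable:
    bits, probs = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                b, p = line.split()
                bits.append(b)
                probs.append(float(p))
            except ValueError as exc:
                raise ValueError(
                    f"malformed table line {line!r} in {path!r}") from exc
    if not bits:
        raise ValueError(f"empty probability table {path!r}")
    n = len(bits[0])
    p = np.zeros(2 ** n)
    for b, prob in zip(bits, probs):
        idx = sum((1 << k) for k, c in enumerate(b) if c == "1")
        p[idx] = prob
    return ProbabilityTable(n, p)


def save_dataset(data: ImageDataset, path: str) -> None:
    df = pd.DataFrame(data.images,
                      columns=[f"px{i}" for i in range(data.images.shape[1])])
    df["label"] = data.labels
    df["split"] = data.split
    df.to_csv(path, index=False)


def load_dataset(path: str, n_classes: int | None = None) -> ImageDataset:
    df = pd.read_csv(path)
    px_cols = [c for c in df.columns if c.startswith("px")]
    images = df[px_cols].to_numpy(dtype=np.uint8)
    labels = df["label"].to_numpy(dtype=np.int64)
    split = df["split"].to_numpy()
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    return ImageDataset(images=images, labels=labels, split=split,
                        n_classes=n_classes)


def read_idx(path: str) -> np.ndarray:
    """Read an IDX-format array (the distribution format of MNIST-style data)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if raw[0] != 0 or raw[1] != 0:
        raise ValueError("not an IDX file")
    dtype = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
             0x0D: ">f4", 0x0E: ">f8"}[raw[2]]
    ndim = raw[3]
    shape = tuple(int.from_bytes(raw[4 + 4 * i:8 + 4 * i], "big")
                  for i in range(ndim))
    data = np.frombuffer(raw, dtype=dtype, offset=4 + 4 * ndim)
    return data.reshape(shape)
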