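"""File I/O: rasters (CSV/HDF5), weights (Matrix Market/HDF5), checkpoints.

Checkpoints bundle the configuration, seeds and all weight matrices and
neuron states so a run can be resumed or replayed exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .network import Network, NetworkConfig
from .neurons import NeuronState
from .params import (
    ExternalDriveParams,
    default_inh_plasticity,
    default_stdp_ee,
    default_stdp_re,
    population_params,
)
from .plasticity import InhPlasticityParams, StdpParams
from .protocols import TargetSignal
from .simulate import SpikeRaster

__all__ = [
    "save_raster_csv", "load_raster_csv",
    "save_raster_h5", "load_raster_h5",
    "save_weights_mtx", "load_weights_mtx",
    "save_target_csv", "load_target_csv",
    "save_network_h5", "load_network_h5",
    "config_to_dict", "config_from_dict",
]


# -- raster ---------------------------------------------------------------

def save_raster_csv(raster: SpikeRaster, path: str | Path) -> None:
    """Tidy (time_ms, population, neuron) CSV with a JSON metadata header."""
    path = Path(path)
    meta = {"t_start": raster.t_start, "t_stop": raster.t_stop,
            "n_neurons": raster.n_neurons, "metadata": raster.metadata}
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta, default=str) + "\n")
        raster.to_frame().to_csv(fh, index=False)


def load_raster_csv(path: str | Path) -> SpikeRaster:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        meta = json.loads(header.lstrip("# ").strip()) if header.startswith("#") else {}
        df = pd.read_csv(fh)
    raster = SpikeRaster(t_start=meta.get("t_start", 0.0),
                         t_stop=meta.get("t_stop", 0.0),
                         metadata=meta.get("metadata", {}))
    n_neurons = meta.get("n_neurons", {})
    pops = set(df["population"]) | set(n_neurons)
    for p in pops:
        sub = df[df["population"] == p]
        raster.times[p] = sub["time_ms"].to_numpy(dtype=float)
        raster.ids[p] = sub["neuron"].to_numpy(dtype=np.int64)
        raster.n_neurons[p] = int(n_neurons.get(p, raster.ids[p].max() + 1
                                                if len(sub) else 0))
    return raster


def save_raster_h5(raster: SpikeRaster, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["t_start"] = raster.t_start
        h5.attrs["t_stop"] = raster.t_stop
        h5.attrs["metadata"] = json.dumps(raster.metadata, default=str)
        for pop in raster.times:
            g = h5.create_group(pop)
            g.attrs["n_neurons"] = raster.n_neurons[pop]
            g.create_dataset("times", data=raster.times[pop])
            g.create_dataset("ids", data=raster.ids[pop])


def load_raster_h5(path: str | Path) -> SpikeRaster:
    raster = SpikeRaster()
    with h5py.File(path, "r") as h5:
        raster.t_start = float(h5.attrs["t_start"])
        raster.t_stop = float(h5.attrs["t_stop"])
        raster.metadata = json.loads(h5.attrs["metadata"])
        for pop in h5:
            raster.times[pop] = h5[pop]["times"][()]
            raster.ids[pop] = h5[pop]["ids"][()]
            raster.n_neurons[pop] = int(h5[pop].attrs["n_neurons"])
    return raster


# -- weights --------------------------------------------------------------

def save_weights_mtx(W: np.ndarray, mask: np.ndarray, path: str | Path) -> None:
    """Sparse Matrix Market export; masked-in zero weights are kept explicit."""
    post, pre = np.nonzero(mask)
    coo = scipy.sparse.coo_matrix((W[post, pre], (post, pre)), shape=W.shape)
    scipy.io.mmwrite(str(path), coo)


def load_weights_mtx(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (dense weights, topology mask) from a Matrix Market file."""
    coo = scipy.io.mmread(str(path)).tocoo()
    W = np.zeros(coo.shape)
    mask = np.zeros(coo.shape, dtype=bool)
    W[coo.row, coo.col] = coo.data
    mask[coo.row, coo.col] = True
    return W, mask


# -- targets --------------------------------------------------------------

def save_target_csv(target: TargetSignal, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps({"bin_ms": target.bin_ms,
                                    "labels": target.labels}) + "\n")
        target.to_frame().to_csv(fh, index=False)


def load_target_csv(path: str | Path) -> TargetSignal:
    with open(path) as fh:
        header = fh.readline()
        meta = json.loads(header.lstrip("# ").strip())
        df = pd.read_csv(fh)
    labels = meta["labels"]
    bin_ms = float(meta["bin_ms"])
    n = df["time_ms"].nunique()
    rates = np.zeros((n, len(labels)))
    tindex = {t: k for k, t in enumerate(sorted(df["time_ms"].unique()))}
    cindex = {c: k for k, c in enumerate(labels)}
    for _, row in df.iterrows():
        rates[tindex[row["time_ms"]], cindex[str(row["channel"])]] = row["rate_khz"]
    return TargetSignal(rates, bin_ms, labels)


# -- config (de)serialization ----------------------------------------------

_NESTED = {"stdp_ee": (StdpParams, default_stdp_ee),
           "stdp_re": (StdpParams, default_stdp_re),
           "inh_plasticity": (InhPlasticityParams, default_inh_plasticity),
           "drive": (ExternalDriveParams, ExternalDriveParams)}


def config_to_dict(cfg: NetworkConfig) -> dict:
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
    return out


def config_from_dict(d: dict) -> NetworkConfig:
    """Build a validated NetworkConfig; unknown keys are rejected."""
    d = dict(d)
    preset = d.pop("preset", "reference")
    builders = {"reference": NetworkConfig.reference, "large": NetworkConfig.large}
    if preset not in builders:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(builders)}")
    known = {f.name for f in dataclasses.fields(NetworkConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    kwargs = {}
    for key, val in d.items():
        if key in _NESTED and isinstance(val, dict):
            cls, factory = _NESTED[key]
            base = dataclasses.asdict(factory())
            bad = set(val) - set(base)
            if bad:
                raise ValueError(f"unknown key(s) in {key}: {sorted(bad)}")
            base.update(val)
            kwargs[key] = cls(**base)
        else:
            kwargs[key] = val
    base_cfg = builders[preset]()
    merged = {f.name: getattr(base_cfg, f.name) for f in dataclasses.fields(NetworkConfig)}
    merged.update(kwargs)
    return NetworkConfig(**merged)


# -- checkpoints ------------------------------------------------------------

_WEIGHT_FIELDS = ("W_EE", "mask_EE", "W_IE", "mask_IE", "W_EI", "mask_EI",
                  "W_II", "mask_II", "W_RE", "mask_RE", "K")
_STATE_FIELDS = ("V", "V_T_adapt", "a", "refrac_remaining")


def save_network_h5(net: Network, path: str | Path, seed: int | None = None) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["config"] = json.dumps(config_to_dict(net.cfg))
        h5.attrs["t"] = net.t
        if seed is not None:
            h5.attrs["seed"] = seed
        h5.create_dataset("clusters", data=net.clusters)
        wg = h5.create_group("weights")
        for name in _WEIGHT_FIELDS:
            arr = getattr(net, name)
            if arr is not None:
                wg.create_dataset(name, data=arr)
        sg = h5.create_group("states")
        for pop, st in net.states.items():
            g = sg.create_group(pop)
            for f in _STATE_FIELDS:
                g.create_dataset(f, data=getattr(st, f))


def load_network_h5(path: str | Path) -> Network:
    with h5py.File(path, "r") as h5:
        cfg = config_from_dict(json.loads(h5.attrs["config"]))
        weights = {k: h5["weights"][k][()] if k in h5["weights"] else None
                   for k in _WEIGHT_FIELDS}
        for k in weights:
            if weights[k] is not None and k.startswith("mask"):
                weights[k] = weights[k].astype(bool)
        params = {}
        states = {}
        for pop in h5["states"]:
            params[pop] = population_params(pop)
            g = h5["states"][pop]
            states[pop] = NeuronState(
                V=g["V"][()], V_T_adapt=g["V_T_adapt"][()], a=g["a"][()],
                refrac_remaining=g["refrac_remaining"][()],
                spiked=np.zeros(g["V"].shape[0], dtype=bool),
            )
        net = Network(cfg=cfg, params=params, states=states,
                      clusters=h5["clusters"][()], t=float(h5.attrs["t"]),
                      **weights)
    return net
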