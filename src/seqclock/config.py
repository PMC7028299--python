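"""Configuration loading, run manifests and the pipeline entry points.

A run configuration is a YAML/JSON mapping with up to three sections:
``network`` (NetworkConfig fields, plus ``preset: reference|large``),
``protocol`` (schedule parameters) and ``analysis`` (analysis options).
A single global seed expands into named sub-streams (topology, external
input channels, deletion) so experiments can vary one source of randomness
at a time.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis as ana
from . import rate_model as rm
from .io import (
    config_from_dict,
    config_to_dict,
    load_network_h5,
    load_raster_csv,
    save_network_h5,
    save_raster_csv,
    save_target_csv,
    save_weights_mtx,
)
from .network import NetworkConfig, build_network, delete_readout_synapses
from .protocols import (
    SpontaneousProtocol,
    make_letter_target,
    make_stage1_protocol,
    make_stage2_protocol,
    make_synthetic_spectrogram_target,
)
from .simulate import PlasticityFlags, Simulator, run_decoupled_plasticity

__all__ = ["load_config", "RunManifest", "run_pipeline", "COMMANDS"]

COMMANDS = ("train-rnn", "spontaneous", "train-readout", "replay", "decouple",
            "delete-synapses", "analyze", "rate-model", "make-target")


def load_config(path: str | Path | None) -> tuple[NetworkConfig, dict, dict]:
    """Load and validate a config file.

    Returns (network config, protocol options, analysis options); an empty
    or missing file yields pure defaults.  Unknown keys are rejected.
    """
    raw: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file {p} does not exist")
        with open(p) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"network", "protocol", "analysis"}
    if unknown:
        raise ValueError(f"unknown top-level config section(s): {sorted(unknown)}")
    cfg = config_from_dict(raw.get("network", {}))
    return cfg, raw.get("protocol", {}), raw.get("analysis", {})


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    command: str
    seed: int
    config: dict
    protocol: dict
    outputs: list[str]
    version: str = ""
    created: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__
            self.version = __version__
        if not self.created:
            self.created = datetime.datetime.now().isoformat(timespec="seconds")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _finish(outdir: Path, command: str, seed: int, cfg: NetworkConfig | None,
            protocol: dict, outputs: list[Path]) -> dict:
    manifest = RunManifest(
        command=command, seed=seed,
        config=config_to_dict(cfg) if cfg is not None else {},
        protocol=protocol, outputs=[str(o) for o in outputs],
    )
    mpath = outdir / f"{command}-manifest.json"
    manifest.save(mpath)
    return {"manifest": mpath, "outputs": outputs}


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing upstream artifact {path}: {hint}")
    return path


def run_pipeline(command: str, config: str | Path | dict | None = None,
                 seed: int = 0, outdir: str | Path = "runs", **opts) -> dict:
    """Execute one pipeline command and write its outputs plus a manifest."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; choose from {COMMANDS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(config, dict):
        cfg = config_from_dict(config.get("network", config))
        proto_opts = config.get("protocol", {})
    else:
        cfg, proto_opts, _ = load_config(config)
    proto_opts = {**proto_opts, **opts}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ckpt = outdir / "network.h5"
    outputs: list[Path] = []

    if command == "make-target":
        seq = proto_opts.get("sequence")
        if seq:
            target = make_letter_target(seq, step_ms=proto_opts.get("step_ms", 75.0))
        else:
            target = make_synthetic_spectrogram_target(
                D=proto_opts.get("channels", 45),
                duration_ms=proto_opts.get("duration_ms", 600.0), rng=rng)
        tpath = outdir / "target.csv"
        save_target_csv(target, tpath)
        outputs.append(tpath)

    elif command == "train-rnn":
        net = build_network(cfg, rng)
        train_s = proto_opts.get("train_s", 3600.0)
        settle_s = proto_opts.get("settle_s", 0.0)
        proto = make_stage1_protocol(
            cfg.C, stim_ms=proto_opts.get("stim_ms", 10.0),
            gap_ms=proto_opts.get("gap_ms", 5.0),
            duration_ms=train_s * 1000.0)
        sim = Simulator(net, seed=seed, record=())
        sim.run(train_s * 1000.0, protocol=proto,
                plasticity=PlasticityFlags(ee=True, ei=True))
        if settle_s:
            sim.run(settle_s * 1000.0, protocol=SpontaneousProtocol(),
                    plasticity=PlasticityFlags(ee=True, ei=True))
        save_network_h5(net, ckpt, seed=seed)
        wpath = outdir / "W_EE.mtx"
        save_weights_mtx(net.W_EE, net.mask_EE, wpath)
        outputs += [ckpt, wpath]

    elif command in ("spontaneous", "replay"):
        if ckpt.exists():
            net = load_network_h5(ckpt)
        elif command == "spontaneous":
            net = build_network(cfg, rng)
        else:
            _require(ckpt, "run train-rnn / train-readout first")
        duration_s = proto_opts.get("duration_s", 5.0)
        sim = Simulator(net, seed=seed + 1)
        raster = sim.run(duration_s * 1000.0, protocol=SpontaneousProtocol())
        rpath = outdir / f"{command}-raster.csv"
        save_raster_csv(raster, rpath)
        outputs.append(rpath)

    elif command == "train-readout":
        _require(ckpt, "run train-rnn first (or save a constructed clock)")
        net = load_network_h5(ckpt)
        if not net.has_readout:
            raise ValueError("checkpointed network has no read-out layer "
                             "(set network.N_R > 0 before training)")
        seq = proto_opts.get("sequence", "ABCBA")
        target = make_letter_target(seq, step_ms=proto_opts.get("step_ms", 75.0))
        learn_s = proto_opts.get("learn_s", 12.0)
        proto = make_stage2_protocol(target, total_learning_s=learn_s)
        sim = Simulator(net, seed=seed + 2)
        sim.run(learn_s * 1000.0, protocol=proto,
                plasticity=PlasticityFlags(re=True))
        save_network_h5(net, ckpt, seed=seed)
        outputs.append(ckpt)

    elif command == "decouple":
        _require(ckpt, "run train-rnn first")
        net = load_network_h5(ckpt)
        traj = run_decoupled_plasticity(
            net, SpontaneousProtocol(),
            duration_ms=proto_opts.get("duration_s", 5.0) * 1000.0,
            ablate_offdiagonal=proto_opts.get("ablate", False), seed=seed + 3)
        tpath = outdir / "decouple-trajectory.csv"
        traj.to_csv(tpath, index=False)
        outputs.append(tpath)

    elif command == "delete-synapses":
        _require(ckpt, "run train-readout first")
        net = load_network_h5(ckpt)
        if net.W_RE is None:
            raise ValueError("network has no read-out synapses to delete")
        n = proto_opts.get("n_per_cluster", 40)
        net.W_RE, net.mask_RE = delete_readout_synapses(
            net.W_RE, net.mask_RE, net.clusters, n, rng)
        save_network_h5(net, ckpt, seed=seed)
        outputs.append(ckpt)

    elif command == "analyze":
        rpath = _require(Path(proto_opts.get("raster",
                                             outdir / "spontaneous-raster.csv")),
                         "run spontaneous/replay first")
        raster = load_raster_csv(rpath)
        rows = {}
        if proto_opts.get("cv", True):
            for pop in ("E", "I"):
                if raster.n_spikes(pop):
                    _, mean_cv = ana.isi_cv(raster, pop)
                    rows[f"mean_cv_{pop}"] = mean_cv
            if not rows:
                raise ValueError("raster holds no spikes to analyze")
        apath = outdir / "analysis.csv"
        pd.Series(rows).to_csv(apath, header=False)
        outputs.append(apath)

    elif command == "rate-model":
        delta = proto_opts.get("delta", 0.2)
        eps = proto_opts.get("eps", 1.5)
        k = proto_opts.get("k", 2.0)
        spec = rm.closed_form_spectrum(delta, eps, k)
        df = pd.DataFrame({
            "mode": ["uniform_fast", "ei_interplay", "cyclic_plus", "cyclic_minus"],
            "re": [spec.uniform_fast, spec.ei_mode,
                   spec.dominant[0].real, spec.dominant[1].real],
            "im": [0.0, 0.0, spec.dominant[0].imag, spec.dominant[1].imag],
        })
        spath = outdir / "rate-model-spectrum.csv"
        df.to_csv(spath, index=False)
        outputs.append(spath)

    return _finish(outdir, command, seed, cfg, dict(proto_opts), outputs)
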