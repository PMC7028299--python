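"""The main forward-Euler simulation loop over all populations.

Per step, in order: external Poisson inputs are sampled, synaptic
conductances are advanced with the previous step's recurrent spikes plus the
external input, membranes take one Euler step and spikes are detected,
threshold/adaptation variables are updated, plasticity traces are advanced,
the plastic weight deltas are applied and clipped, and every 20 ms the
incoming E->E weights are L1-normalized.  Given identical seeds, runs are
bit-reproducible.

External spike counts are drawn per step from a Poisson distribution
(``rng.poisson(rate * dt)``), the exact discretization of a Poisson process
merged over a large input population; this also covers the high-rate
training and supervisor drives where rate * dt exceeds one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Network
from .neurons import (
    E_REV_EXC,
    E_REV_INH,
    step_membrane,
    step_threshold_and_adaptation,
)
from .plasticity import (
    PlasticityTraces,
    apply_inhibitory_plasticity,
    apply_stdp,
    normalize_incoming,
    update_rate_trace,
    update_traces,
)
from .synapses import EXC_KERNEL, INH_KERNEL, ConductanceState

__all__ = [
    "PlasticityFlags",
    "SpikeRaster",
    "SimulationDiverged",
    "Simulator",
    "simulate",
    "run_decoupled_plasticity",
    "spawn_rngs",
]

NORMALIZATION_INTERVAL_MS = 20.0

_STREAM_NAMES = ("ext_E", "ext_E_inh", "ext_I", "ext_S", "ext_H", "misc")


class SimulationDiverged(RuntimeError):
    """The dynamics left the physical regime (non-finite state or runaway rate)."""


def spawn_rngs(seed: int, names: tuple[str, ...] = _STREAM_NAMES) -> dict[str, np.random.Generator]:
    """Expand one global seed into named independent random streams."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class PlasticityFlags:
    """Which connection classes are plastic during a run."""

    ee: bool = False   # recurrent E->E voltage-STDP + L1 normalization
    ei: bool = False   # homeostatic I->E plasticity
    re: bool = False   # read-out E->R voltage-STDP

    @property
    def any(self) -> bool:
        return self.ee or self.ei or self.re


@dataclass
class SpikeRaster:
    """Timestamped spike events per population, with run metadata."""

    times: dict[str, np.ndarray] = field(default_factory=dict)
    ids: dict[str, np.ndarray] = field(default_factory=dict)
    n_neurons: dict[str, int] = field(default_factory=dict)
    t_start: float = 0.0
    t_stop: float = 0.0
    metadata: dict = field(default_factory=dict)

    def n_spikes(self, pop: str) -> int:
        return int(self.times.get(pop, np.empty(0)).size)

    def window(self, pop: str, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        """Spike (times, ids) of one population restricted to [t0, t1)."""
        t, i = self.times[pop], self.ids[pop]
        sel = (t >= t0) & (t < t1)
        return t[sel], i[sel]

    def spike_trains(self, pop: str) -> list[np.ndarray]:
        """Per-neuron sorted spike time lists."""
        t, i = self.times[pop], self.ids[pop]
        order = np.lexsort((t, i))
        t, i = t[order], i[order]
        bounds = np.searchsorted(i, np.arange(self.n_neurons[pop] + 1))
        return [t[bounds[k]:bounds[k + 1]] for k in range(self.n_neurons[pop])]

    def mean_rate(self, pop: str) -> float:
        """Population mean firing rate in Hz."""
        dur_s = (self.t_stop - self.t_start) * 1e-3
        if dur_s <= 0 or pop not in self.times:
            return 0.0
        return self.n_spikes(pop) / self.n_neurons[pop] / dur_s

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time_ms, population, neuron) table of all events."""
        parts = [
            pd.DataFrame({"time_ms": self.times[p], "population": p,
                          "neuron": self.ids[p]})
            for p in sorted(self.times)
        ]
        if not parts:
            return pd.DataFrame(columns=["time_ms", "population", "neuron"])
        return (pd.concat(parts, ignore_index=True)
                .sort_values(["time_ms", "population", "neuron"], kind="stable")
                .reset_index(drop=True))


class _Recorder:
    def __init__(self, pops: tuple[str, ...]):
        self.pops = pops
        self.buf: dict[str, list[tuple[float, np.ndarray]]] = {p: [] for p in pops}

    def add(self, pop: str, t: float, idx: np.ndarray) -> None:
        if idx.size and pop in self.buf:
            self.buf[pop].append((t, idx))

    def build(self, net: Network, t0: float, t1: float, metadata: dict) -> SpikeRaster:
        raster = SpikeRaster(t_start=t0, t_stop=t1, metadata=metadata)
        sizes = {"E": net.cfg.N_E, "I": net.cfg.N_I,
                 "R": net.cfg.N_R, "S": net.cfg.N_R, "H": net.cfg.N_R}
        for p in self.pops:
            events = self.buf[p]
            if events:
                raster.times[p] = np.concatenate(
                    [np.full(ix.size, t) for t, ix in events])
                raster.ids[p] = np.concatenate([ix for _, ix in events])
            else:
                raster.times[p] = np.empty(0)
                raster.ids[p] = np.empty(0, dtype=np.int64)
            raster.n_neurons[p] = sizes.get(p, 0)
        return raster


class Simulator:
    """Stateful simulator: populations, conductances, traces and weights.

    Can be run in consecutive segments (``run`` may be called repeatedly);
    protocol schedules and plasticity flags can differ between segments,
    which is how the two learning stages and the subsequent replay are
    chained.
    """

    def __init__(
        self,
        network: Network,
        seed: int = 0,
        record: tuple[str, ...] = ("E", "I", "R"),
        frozen_W_EE: np.ndarray | None = None,
        guard_fraction: float = 0.9,
    ):
        self.net = network
        self.rngs = spawn_rngs(seed)
        self.record_pops = tuple(p for p in record if p in network.states)
        # dynamics can optionally run on a frozen copy of the recurrent
        # weights while plastic updates accrue to the original matrix
        # (plasticity/dynamics decoupling experiment)
        self.frozen_W_EE = frozen_W_EE
        self.guard_fraction = guard_fraction

        cfg = network.cfg
        self.cond: dict[str, ConductanceState] = {
            "E_exc": ConductanceState.zeros(EXC_KERNEL, cfg.N_E),
            "E_inh": ConductanceState.zeros(INH_KERNEL, cfg.N_E),
            "I_exc": ConductanceState.zeros(EXC_KERNEL, cfg.N_I),
            "I_inh": ConductanceState.zeros(INH_KERNEL, cfg.N_I),
        }
        if network.has_readout:
            self.cond.update({
                "R_exc": ConductanceState.zeros(EXC_KERNEL, cfg.N_R),
                "R_inh": ConductanceState.zeros(INH_KERNEL, cfg.N_R),
                "S_exc": ConductanceState.zeros(EXC_KERNEL, cfg.N_R),
                "H_exc": ConductanceState.zeros(EXC_KERNEL, cfg.N_R),
            })

        E_L = network.params["E"].E_L
        self.traces_E = PlasticityTraces.zeros(cfg.N_E, cfg.N_E, V_rest=E_L,
                                               with_y=True)
        self.x_RE = np.zeros(cfg.N_E)       # presynaptic trace for E->R (tau_xRE)
        self.y_I = np.zeros(cfg.N_I)
        if network.has_readout:
            self.traces_R = PlasticityTraces.zeros(cfg.N_R, None, V_rest=E_L)

        self._prev_idx = {k: np.empty(0, dtype=np.intp) for k in network.states}
        self._since_norm = 0.0
        self.snapshots: list[tuple[float, dict[str, np.ndarray]]] = []

    # -- helpers ---------------------------------------------------------

    def _external_counts(self, rate, n: int, stream: str, dt: float):
        if rate is None or n == 0:
            return None
        if isinstance(rate, np.ndarray):
            return self.rngs[stream].poisson(rate * dt)
        if rate == 0.0:
            return None
        return self.rngs[stream].poisson(rate * dt, n)

    def take_snapshot(self) -> None:
        snap = {"W_EE": self.net.W_EE.copy(), "W_EI": self.net.W_EI.copy()}
        if self.net.W_RE is not None:
            snap["W_RE"] = self.net.W_RE.copy()
        self.snapshots.append((self.net.t, snap))

    # -- main loop -------------------------------------------------------

    def run(
        self,
        duration_ms: float,
        protocol=None,
        plasticity: PlasticityFlags | None = None,
        snapshot_every_ms: float | None = None,
    ) -> SpikeRaster:
        net = self.net
        cfg = net.cfg
        dt = cfg.dt
        flags = plasticity or PlasticityFlags()
        n_steps = int(round(duration_ms / dt))
        rec = _Recorder(self.record_pops)
        t0 = net.t

        if protocol is not None and hasattr(protocol, "begin"):
            protocol.begin(net)
        adaptive = protocol is not None and hasattr(protocol, "observe_spikes")

        W_EE_dyn = self.frozen_W_EE if self.frozen_W_EE is not None else net.W_EE
        stE, stI = net.states["E"], net.states.get("I")
        pE, pI = net.params["E"], net.params.get("I")
        has_I = stI is not None and cfg.N_I > 0
        has_RO = net.has_readout
        drv = cfg.drive
        next_snap = net.t + snapshot_every_ms if snapshot_every_ms else None

        for _ in range(n_steps):
            t = net.t
            rates = protocol.rates(t) if protocol is not None else None

            # ---- external Poisson inputs
            extE = self._external_counts(
                rates.e_exc if rates else None, cfg.N_E, "ext_E", dt)
            extEi = self._external_counts(
                rates.e_inh if rates else None, cfg.N_E, "ext_E_inh", dt)
            extI = self._external_counts(
                rates.i_exc if rates else None, cfg.N_I, "ext_I", dt)
            extS = extH = None
            if has_RO and rates is not None:
                extS = self._external_counts(rates.s_exc, cfg.N_R, "ext_S", dt)
                extH = self._external_counts(rates.h_exc, cfg.N_R, "ext_H", dt)

            eidx = self._prev_idx["E"]
            iidx = self._prev_idx["I"] if has_I else np.empty(0, dtype=np.intp)

            # ---- conductances (exact exponential decay + this step's input)
            inc_E_exc = W_EE_dyn[:, eidx].sum(axis=1) if eidx.size else 0.0
            if extE is not None:
                inc_E_exc = inc_E_exc + drv.w_ext_E * extE
            inc_E_inh = net.W_EI[:, iidx].sum(axis=1) if iidx.size else 0.0
            if extEi is not None:
                inc_E_inh = inc_E_inh + drv.w_stim_inh * extEi
            self._advance(self.cond["E_exc"], inc_E_exc, dt)
            self._advance(self.cond["E_inh"], inc_E_inh, dt)

            if has_I:
                inc_I_exc = net.W_IE[:, eidx].sum(axis=1) if eidx.size else 0.0
                if extI is not None:
                    inc_I_exc = inc_I_exc + drv.w_ext_I * extI
                inc_I_inh = net.W_II[:, iidx].sum(axis=1) if iidx.size else 0.0
                self._advance(self.cond["I_exc"], inc_I_exc, dt)
                self._advance(self.cond["I_inh"], inc_I_inh, dt)

            if has_RO:
                ridx = self._prev_idx["R"]
                sidx = self._prev_idx["S"]
                hidx = self._prev_idx["H"]
                inc_R = net.W_RE[:, eidx].sum(axis=1) if eidx.size else np.zeros(cfg.N_R)
                if sidx.size:
                    inc_R = inc_R.copy() if eidx.size else inc_R
                    inc_R[sidx] += cfg.w_RS
                inc_R_inh = np.zeros(cfg.N_R)
                if hidx.size:
                    inc_R_inh[hidx] = cfg.w_RH
                inc_H = np.zeros(cfg.N_R)
                if ridx.size:
                    inc_H[ridx] = cfg.w_HR
                if extH is not None:
                    inc_H = inc_H + drv.w_ext_H * extH
                inc_S = drv.w_ext_S * extS if extS is not None else 0.0
                self._advance(self.cond["R_exc"], inc_R, dt)
                self._advance(self.cond["R_inh"], inc_R_inh, dt)
                self._advance(self.cond["S_exc"], inc_S, dt)
                self._advance(self.cond["H_exc"], inc_H, dt)

            # ---- membranes
            drive_E = (
                self.cond["E_exc"].g * (E_REV_EXC - stE.V)
                + self.cond["E_inh"].g * (E_REV_INH - stE.V)
            ) / pE.C
            step_membrane(stE, pE, drive_E, dt)
            step_threshold_and_adaptation(stE, pE, dt)
            if has_I:
                drive_I = (
                    self.cond["I_exc"].g * (E_REV_EXC - stI.V)
                    + self.cond["I_inh"].g * (E_REV_INH - stI.V)
                ) / pI.C
                step_membrane(stI, pI, drive_I, dt)

            if has_RO:
                for k, gexc, ginh in (
                    ("R", self.cond["R_exc"].g, self.cond["R_inh"].g),
                    ("S", self.cond["S_exc"].g, None),
                    ("H", self.cond["H_exc"].g, None),
                ):
                    st, pp = net.states[k], net.params[k]
                    d = gexc * (E_REV_EXC - st.V) / pp.C
                    if ginh is not None:
                        d = d + ginh * (E_REV_INH - st.V) / pp.C
                    step_membrane(st, pp, d, dt)
                    step_threshold_and_adaptation(st, pp, dt)

            # ---- runaway-rate guard (pathological regimes abort, not clamp)
            if cfg.N_E >= 50 and np.count_nonzero(stE.spiked) > self.guard_fraction * cfg.N_E:
                raise SimulationDiverged(
                    f"runaway excitatory activity at t = {t:.1f} ms: "
                    f"{np.count_nonzero(stE.spiked)}/{cfg.N_E} E neurons spiked in one step"
                )

            # ---- traces and plasticity
            e_sp = np.flatnonzero(stE.spiked)
            i_sp = np.flatnonzero(stI.spiked) if has_I else np.empty(0, dtype=np.intp)

            if flags.ee or flags.re:
                update_traces(self.traces_E, stE.V_plast, stE.spiked,
                              None, cfg.stdp_ee, dt)
            if flags.re:
                self.x_RE -= (dt / cfg.stdp_re.tau_x) * self.x_RE
                self.x_RE[e_sp] += 1.0 / cfg.stdp_re.tau_x
                stR = net.states["R"]
                update_traces(self.traces_R, stR.V_plast, None, None,
                              cfg.stdp_re, dt)
                apply_stdp(net.W_RE, net.mask_RE, e_sp, self.x_RE,
                           self.traces_R.u, self.traces_R.v,
                           net.states["R"].V_plast, cfg.stdp_re, dt)
            if flags.ee:
                apply_stdp(net.W_EE, net.mask_EE, e_sp, self.traces_E.x,
                           self.traces_E.u, self.traces_E.v, stE.V_plast,
                           cfg.stdp_ee, dt)
            if flags.ei and has_I:
                update_rate_trace(self.traces_E.y, stE.spiked,
                                  cfg.inh_plasticity.tau_y, dt)
                update_rate_trace(self.y_I, stI.spiked,
                                  cfg.inh_plasticity.tau_y, dt)
                apply_inhibitory_plasticity(net.W_EI, net.mask_EI, e_sp, i_sp,
                                            self.traces_E.y, self.y_I,
                                            cfg.inh_plasticity)

            if flags.ee:
                self._since_norm += dt
                if self._since_norm >= NORMALIZATION_INTERVAL_MS - 1e-9:
                    normalize_incoming(net.W_EE, net.mask_EE, net.K,
                                       cfg.stdp_ee.w_min, cfg.stdp_ee.w_max)
                    self._since_norm = 0.0

            # ---- bookkeeping
            self._prev_idx["E"] = e_sp
            if has_I:
                self._prev_idx["I"] = i_sp
            rec.add("E", t, e_sp)
            if has_I:
                rec.add("I", t, i_sp)
            if has_RO:
                for k in ("R", "S", "H"):
                    idx = np.flatnonzero(net.states[k].spiked)
                    self._prev_idx[k] = idx
                    rec.add(k, t, idx)
            if adaptive:
                protocol.observe_spikes(t, e_sp)

            net.t = t + dt
            if next_snap is not None and net.t >= next_snap - 1e-9:
                self.take_snapshot()
                next_snap += snapshot_every_ms

        meta = {"seed_streams": list(self.rngs), "t_start": t0,
                "duration_ms": duration_ms,
                "protocol": type(protocol).__name__ if protocol else "none"}
        return rec.build(net, t0, net.t, meta)

    @staticmethod
    def _advance(state: ConductanceState, increment, dt: float) -> None:
        fr, fd = state.kernel.decay_factors(dt)
        state.rise *= fr
        state.decay *= fd
        if isinstance(increment, np.ndarray) or increment:
            state.rise += increment
            state.decay += increment


def simulate(
    network: Network,
    protocol,
    duration_ms: float,
    plasticity: PlasticityFlags | None = None,
    seed: int = 0,
    record: tuple[str, ...] = ("E", "I", "R"),
    snapshot_every_ms: float | None = None,
) -> tuple[SpikeRaster, list]:
    """One-shot convenience wrapper: build a Simulator and run it."""
    sim = Simulator(network, seed=seed, record=record)
    raster = sim.run(duration_ms, protocol=protocol, plasticity=plasticity,
                     snapshot_every_ms=snapshot_every_ms)
    return raster, sim.snapshots


def run_decoupled_plasticity(
    network: Network,
    protocol,
    duration_ms: float,
    ablate_offdiagonal: bool = False,
    seed: int = 0,
    sample_every_ms: float = 100.0,
    plasticity: PlasticityFlags | None = None,
) -> pd.DataFrame:
    """Decouple plasticity from dynamics to probe stability of the structure.

    The dynamics runs on a frozen copy of the learned recurrent matrix
    (optionally with the cluster i -> i+1 blocks reset to the background
    level); the plastic updates accrue to the original matrix.  Returns the
    mean cluster i -> i+1 weight of the original matrix versus time.
    """
    import warnings as _warnings

    cfg = network.cfg
    frozen = network.W_EE.copy()
    intra0 = network.offdiagonal_block_mean()
    bg = cfg.stdp_ee.w_min
    if intra0 <= 2 * bg:
        _warnings.warn("recurrent matrix shows little sequential structure; "
                       "decoupling run may be uninformative", stacklevel=2)
    if ablate_offdiagonal:
        cl = network.clusters
        succ = cl[:, None] == (cl[None, :] + 1) % cfg.C
        frozen[succ & network.mask_EE] = bg

    sim = Simulator(network, seed=seed, frozen_W_EE=frozen)
    flags = plasticity or PlasticityFlags(ee=True)
    rows = [(network.t, network.offdiagonal_block_mean())]
    n_chunks = int(round(duration_ms / sample_every_ms))
    for _ in range(n_chunks):
        sim.run(sample_every_ms, protocol=protocol, plasticity=flags)
        rows.append((network.t, network.offdiagonal_block_mean()))
    return pd.DataFrame(rows, columns=["t_ms", "offdiagonal_mean"])
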