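"""Membrane-potential, adaptive-threshold and adaptation-current dynamics.

Five neuron classes share a forward-Euler integrator:

* ``E``  — recurrent excitatory: adaptive exponential integrate-and-fire
  (AdEx) with a strong spike-triggered adaptation current that terminates
  cluster reverberation.
* ``R``/``S`` — read-out and supervisor: AdEx with an adaptive threshold but
  no adaptation current (beta = 0), allowing high firing rates.
* ``I``/``H`` — recurrent inhibitory and read-out interneurons: plain leaky
  integrate-and-fire with a fixed threshold.

Units throughout: mV, ms, pF, pA, kHz.  Synaptic drive is passed in as the
already conductance-weighted term sum_c g_c (E_c - V) / C, in mV/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationParams",
    "NeuronState",
    "InvalidStateError",
    "step_membrane",
    "step_threshold_and_adaptation",
    "E_REV_EXC",
    "E_REV_INH",
]

# Reversal potentials of the two synapse signs (mV), shared by all classes.
E_REV_EXC = 0.0
E_REV_INH = -75.0

# Cap on the AdEx exponential argument.  Spikes are detected by divergence
# past ``spike_cut`` so the unbounded exponential is never needed; the cap
# only limits the size of the single divergent Euler step.
_EXP_ARG_CAP = 10.0

_EXP_KINDS = frozenset({"E", "R", "S"})
_LIF_KINDS = frozenset({"I", "H"})


class InvalidStateError(RuntimeError):
    """A membrane variable became non-finite during integration."""


@dataclass
class PopulationParams:
    """Membrane parameters of one neuron class.

    ``Delta_T`` is ``None`` for the leaky integrate-and-fire kinds (I, H),
    which spike on a plain threshold crossing instead of divergence.
    """

    kind: str
    tau_m: float          # membrane time constant (ms)
    E_L: float            # resting potential (mV)
    C: float              # capacitance (pF)
    V_r: float            # reset potential (mV)
    tau_abs: float        # absolute refractory period (ms)
    V_T0: float           # baseline threshold (mV)
    Delta_T: float | None = None   # exponential slope (mV), AdEx kinds only
    A_T: float = 0.0      # adaptive threshold increment (mV)
    tau_T: float = 30.0   # threshold relaxation (ms)
    tau_a: float = 100.0  # adaptation current time constant (ms)
    beta: float = 0.0     # adaptation current increment (pA)
    spike_cut: float = 20.0  # divergence detection level (mV)
    # Width of the action-potential depolarization as seen by the
    # voltage-based plasticity rule: V_plast holds at spike_cut for this long
    # after a spike (the membrane itself is clamped at V_r).  The rule's
    # potentiation term was fit to voltage traces that include the spike
    # waveform, so collapsing it to a single Euler step would starve LTP.
    ap_width_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in _EXP_KINDS | _LIF_KINDS:
            raise ValueError(f"unknown neuron kind {self.kind!r}")
        for name in ("tau_m", "tau_T", "tau_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.V_r >= self.V_T0:
            raise ValueError("V_r must be below V_T0")
        if self.tau_abs < 0:
            raise ValueError("tau_abs must be >= 0")
        if self.kind in _LIF_KINDS and self.Delta_T is not None:
            raise ValueError(f"kind {self.kind} has no exponential term")
        if self.kind in _EXP_KINDS and self.Delta_T is None:
            raise ValueError(f"kind {self.kind} requires Delta_T")
        if self.kind in {"R", "S"} and self.beta != 0:
            raise ValueError("read-out and supervisor neurons have no adaptation")

    @property
    def is_exponential(self) -> bool:
        return self.Delta_T is not None


@dataclass
class NeuronState:
    """Flat per-neuron state arrays of one population."""

    V: np.ndarray                 # membrane potential (mV)
    V_T_adapt: np.ndarray         # adaptive threshold (mV)
    a: np.ndarray                 # adaptation current (pA)
    refrac_remaining: np.ndarray  # time left in refractory period (ms)
    spiked: np.ndarray            # spike indicator for the current step
    ap_remaining: np.ndarray = field(default=None)  # type: ignore[assignment]
    # Voltage seen by the plasticity machinery: the post-update voltage,
    # clamped at spike_cut on the divergent step and at V_r during
    # refractoriness (the physical clamp).
    V_plast: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.V_plast is None:
            self.V_plast = self.V.copy()
        if self.ap_remaining is None:
            self.ap_remaining = np.zeros_like(self.V)

    @classmethod
    def at_rest(cls, params: PopulationParams, n: int) -> "NeuronState":
        return cls(
            V=np.full(n, params.E_L, dtype=float),
            V_T_adapt=np.full(n, params.V_T0, dtype=float),
            a=np.zeros(n, dtype=float),
            refrac_remaining=np.zeros(n, dtype=float),
            spiked=np.zeros(n, dtype=bool),
        )

    def __len__(self) -> int:
        return self.V.shape[0]


def step_membrane(
    state: NeuronState,
    params: PopulationParams,
    drive: np.ndarray | float,
    dt: float,
) -> NeuronState:
    """Advance membrane potentials one forward-Euler step (in place).

    ``drive`` is the per-neuron synaptic term sum_c g_c (E_c - V)/C minus
    nothing else: leak, exponential and adaptation terms are added here.
    Spiking neurons are reset to ``V_r`` and enter the refractory period;
    refractory neurons hold V = V_r.  Returns ``state``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    V = state.V
    # half-step tolerance so float accumulation cannot stretch the period
    refractory = state.refrac_remaining > 0.5 * dt

    dV = (params.E_L - V) / params.tau_m
    if params.is_exponential:
        arg = (V - state.V_T_adapt) / params.Delta_T
        np.clip(arg, None, _EXP_ARG_CAP, out=arg)
        dV += (params.Delta_T / params.tau_m) * np.exp(arg)
    dV += drive
    if params.kind == "E":
        dV -= state.a / params.C

    V_new = V + dt * dV
    # voltage clamp during the refractory period
    V_new[refractory] = params.V_r

    # cheap divergence guard: a non-finite value poisons the sum
    if not np.isfinite(V_new.sum()):
        bad = int(np.flatnonzero(~np.isfinite(V_new))[0])
        raise InvalidStateError(
            f"non-finite membrane potential in kind {params.kind} at neuron {bad}"
        )

    if params.is_exponential:
        spiked = V_new > params.spike_cut
    else:
        spiked = V_new >= state.V_T_adapt
    spiked &= ~refractory

    # plasticity sees the pre-reset voltage, clamped at the detection level;
    # the spike depolarization persists for ap_width_ms (its own countdown,
    # independent of the refractory clamp)
    V_plast = state.V_plast
    np.copyto(V_plast, V_new)
    if params.ap_width_ms > 0:
        in_ap = state.ap_remaining > 0.5 * dt
        V_plast[in_ap] = params.spike_cut
        state.ap_remaining[in_ap] -= dt
    V_plast[spiked] = params.spike_cut
    state.ap_remaining[spiked] = params.ap_width_ms

    V_new[spiked] = params.V_r
    state.V = V_new
    state.spiked = spiked
    state.refrac_remaining[refractory] = np.maximum(
        state.refrac_remaining[refractory] - dt, 0.0
    )
    state.refrac_remaining[spiked] = params.tau_abs
    return state


def step_threshold_and_adaptation(
    state: NeuronState, params: PopulationParams, dt: float
) -> NeuronState:
    """Relax the adaptive threshold and adaptation current; apply spike jumps.

    Called once per step after spike detection.  Both processes are slow and
    physically distinct from the voltage clamp, so they continue during the
    refractory period.
    """
    if params.is_exponential:
        VT = state.V_T_adapt
        VT += (dt / params.tau_T) * (params.V_T0 - VT)
        VT[state.spiked] = params.V_T0 + params.A_T
    if params.kind == "E":
        a = state.a
        a -= (dt / params.tau_a) * a
        if params.beta:
            a[state.spiked] += params.beta
    return state
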