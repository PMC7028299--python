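"""Voltage-based STDP, L1 weight normalization and inhibitory plasticity.

The excitatory rule (used for E->E and E->R synapses) is

    dW/dt = -A_LTD * s_pre(t) * R(u_post - theta_LTD)
            + A_LTP * x_pre(t) * R(V_post - theta_LTP) * R(v_post - theta_LTD)

where R is the linear rectifier, u and v are slow and fast low-pass filters
of the postsynaptic voltage, and x is a low-pass filter of the presynaptic
spike train whose stationary mean equals the presynaptic rate (increment
1/tau_x per spike).  The presynaptic spike train is a delta train, so the
depression term integrates to a per-spike impulse of size
A_LTD * R(u - theta_LTD); the potentiation term is continuous and integrates
with dt.  For read-out synapses A_LTP decreases linearly with the current
weight (soft upper bound); in the recurrent network A_LTP = A and a hard L1
normalization every 20 ms enforces competition instead.

The homeostatic inhibitory rule for I->E synapses potentiates inhibition
onto excitatory neurons that fire above a target rate r_0:

    dW/dt = A_inh * (y_E - 2 r_0 tau_y) * s_I(t) + A_inh * y_I * s_E(t)

with y the spike trains filtered with tau_y (increment +1 per spike, so the
threshold 2 r_0 tau_y is dimensionless and the rule's fixed point sits at
the target rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StdpParams",
    "InhPlasticityParams",
    "PlasticityTraces",
    "update_traces",
    "update_rate_trace",
    "voltage_stdp_delta",
    "ltp_amplitude_readout",
    "normalize_incoming",
    "inhibitory_plasticity_delta",
    "apply_stdp",
    "apply_inhibitory_plasticity",
]


@dataclass
class StdpParams:
    """Voltage-based STDP parameters for one plastic connection class."""

    A_LTD: float = 0.0014      # depression amplitude (pA mV^-2)
    A: float = 0.0008          # maximum potentiation amplitude (pA mV^-1)
    theta_LTD: float = -70.0   # depression voltage threshold (mV)
    theta_LTP: float = -49.0   # potentiation voltage threshold (mV)
    tau_u: float = 10.0        # slow postsynaptic voltage filter (ms)
    tau_v: float = 7.0         # fast postsynaptic voltage filter (ms)
    tau_x: float = 3.5         # presynaptic spike-train filter (ms)
    weight_dependent_ltp: bool = False
    w_min: float = 1.45        # lower weight bound (pF)
    w_max: float = 32.68       # upper weight bound (pF)

    def __post_init__(self) -> None:
        if self.A_LTD < 0 or self.A < 0:
            raise ValueError("plasticity amplitudes must be >= 0")
        if not self.theta_LTP > self.theta_LTD:
            raise ValueError("theta_LTP must exceed theta_LTD")
        if self.w_max <= self.w_min:
            raise ValueError("w_max must exceed w_min")


@dataclass
class InhPlasticityParams:
    """Homeostatic inhibitory plasticity parameters (I->E synapses)."""

    A_inh: float = 0.1    # amplitude (pF per spike per unit trace)
    r_0: float = 3.0      # target excitatory rate (Hz)
    tau_y: float = 20.0   # spike-train filter (ms)
    w_min: float = 48.7   # lower I->E bound (pF)
    w_max: float = 243.0  # upper I->E bound (pF)

    def __post_init__(self) -> None:
        if min(self.A_inh, self.r_0, self.tau_y) <= 0:
            raise ValueError("inhibitory plasticity parameters must be positive")

    @property
    def alpha(self) -> float:
        """Depression offset 2 r_0 tau_y (dimensionless; r_0 in Hz, tau_y in ms)."""
        return 2.0 * (self.r_0 * 1e-3) * self.tau_y


@dataclass
class PlasticityTraces:
    """Low-pass-filtered voltages and spike trains driving the rules.

    ``u``/``v`` are slow/fast filters of the postsynaptic voltage (mV),
    ``x`` the presynaptic spike-train filter (1/ms, stationary mean = rate),
    ``y`` the rate trace of the inhibitory rule (dimensionless).
    """

    u: np.ndarray | None = None
    v: np.ndarray | None = None
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    @classmethod
    def zeros(cls, n_post: int | None, n_pre: int | None,
              V_rest: float = -70.0, with_y: bool = False) -> "PlasticityTraces":
        u = v = x = y = None
        if n_post is not None:
            u = np.full(n_post, V_rest, dtype=float)
            v = np.full(n_post, V_rest, dtype=float)
        if n_pre is not None:
            x = np.zeros(n_pre, dtype=float)
            if with_y:
                y = np.zeros(n_pre, dtype=float)
        return cls(u=u, v=v, x=x, y=y)


def update_traces(
    traces: PlasticityTraces,
    V_post: np.ndarray | None,
    spikes_pre: np.ndarray | None,
    spikes_post: np.ndarray | None,
    params: StdpParams,
    dt: float,
) -> PlasticityTraces:
    """Advance the voltage and spike-train filters one Euler step (in place).

    ``spikes_pre``/``spikes_post`` are integer spike counts (or boolean
    indicators) for the current step.
    """
    if traces.u is not None and V_post is not None:
        traces.u += (dt / params.tau_u) * (V_post - traces.u)
        traces.v += (dt / params.tau_v) * (V_post - traces.v)
    if traces.x is not None and spikes_pre is not None:
        traces.x -= (dt / params.tau_x) * traces.x
        traces.x += spikes_pre / params.tau_x
    return traces


def update_rate_trace(
    y: np.ndarray, spikes: np.ndarray, tau_y: float, dt: float
) -> np.ndarray:
    """Rate trace of the inhibitory rule: Euler decay, +1 per spike."""
    y -= (dt / tau_y) * y
    y += spikes
    return y


def ltp_amplitude_readout(w: np.ndarray | float, params: StdpParams) -> np.ndarray | float:
    """Weight-dependent LTP amplitude for read-out synapses.

    A_LTP falls linearly from A at w = w_min to 0 at w = w_max, giving the
    read-out weights a soft upper bound.  Evaluated on the weight before the
    current update.
    """
    w_arr = np.asarray(w, dtype=float)
    if np.any(w_arr < params.w_min) or np.any(w_arr > params.w_max):
        warnings.warn("read-out weight outside bounds; clamping for A_LTP",
                      stacklevel=2)
        w_arr = np.clip(w_arr, params.w_min, params.w_max)
    out = params.A * (params.w_max - w_arr) / (params.w_max - params.w_min)
    return float(out) if np.isscalar(w) else out


def voltage_stdp_delta(
    w: np.ndarray | float,
    traces: PlasticityTraces,
    V_post: np.ndarray | float,
    pre_spike: np.ndarray | float,
    params: StdpParams,
    dt: float,
) -> np.ndarray | float:
    """Reference (unvectorized) weight change of the voltage-based rule.

    Depression is a per-spike impulse; potentiation integrates with dt.
    Used as the oracle form; the simulator applies the equivalent vectorized
    updates in :func:`apply_stdp`.
    """
    u, v, x = traces.u, traces.v, traces.x
    ltd = params.A_LTD * np.asarray(pre_spike) * np.maximum(
        np.asarray(u) - params.theta_LTD, 0.0
    )
    a_ltp = ltp_amplitude_readout(w, params) if params.weight_dependent_ltp else params.A
    ltp = (
        a_ltp
        * np.asarray(x)
        * np.maximum(np.asarray(V_post) - params.theta_LTP, 0.0)
        * np.maximum(np.asarray(v) - params.theta_LTD, 0.0)
        * dt
    )
    return -ltd + ltp


def apply_stdp(
    W: np.ndarray,
    mask: np.ndarray,
    pre_spike_idx: np.ndarray,
    x_pre: np.ndarray,
    u_post: np.ndarray,
    v_post: np.ndarray,
    V_post: np.ndarray,
    params: StdpParams,
    dt: float,
) -> None:
    """In-place vectorized voltage-STDP update of a dense (post, pre) matrix.

    Only columns of presynaptic spikers (depression) and rows of postsynaptic
    neurons above the potentiation threshold (potentiation) are touched;
    modified entries are clipped to the bounds and the fixed-zero topology is
    preserved.
    """
    # depression: per presynaptic spike, on all permitted posts
    if pre_spike_idx.size:
        ltd = params.A_LTD * np.maximum(u_post - params.theta_LTD, 0.0)
        if np.any(ltd > 0):
            cols = W[:, pre_spike_idx]
            m = mask[:, pre_spike_idx]
            cols -= ltd[:, None] * m
            np.clip(cols, params.w_min, params.w_max, out=cols)
            W[:, pre_spike_idx] = np.where(m, cols, 0.0)

    # potentiation: rows where both voltage gates open
    gate = np.maximum(V_post - params.theta_LTP, 0.0) * np.maximum(
        v_post - params.theta_LTD, 0.0
    )
    rows = np.flatnonzero(gate)
    if rows.size:
        sub = W[rows]
        m = mask[rows]
        if params.weight_dependent_ltp:
            a_ltp = params.A * (params.w_max - sub) / (params.w_max - params.w_min)
            np.clip(a_ltp, 0.0, params.A, out=a_ltp)
        else:
            a_ltp = params.A
        sub = sub + (dt * a_ltp) * (gate[rows, None] * x_pre[None, :]) * m
        np.clip(sub, params.w_min, params.w_max, out=sub)
        W[rows] = np.where(m, sub, 0.0)


def inhibitory_plasticity_delta(
    w: float | np.ndarray,
    y_E: float | np.ndarray,
    y_I: float | np.ndarray,
    spike_E: float | np.ndarray,
    spike_I: float | np.ndarray,
    params: InhPlasticityParams,
    dt: float,
) -> float | np.ndarray:
    """Reference weight change of the homeostatic inhibitory rule.

    Both terms are gated by spikes (delta trains), so each is a per-spike
    impulse; ``dt`` is accepted for signature symmetry but the impulses do
    not scale with it.
    """
    del dt, w
    return params.A_inh * (
        (np.asarray(y_E) - params.alpha) * np.asarray(spike_I)
        + np.asarray(y_I) * np.asarray(spike_E)
    )


def apply_inhibitory_plasticity(
    W_EI: np.ndarray,
    mask: np.ndarray,
    e_spike_idx: np.ndarray,
    i_spike_idx: np.ndarray,
    y_E: np.ndarray,
    y_I: np.ndarray,
    params: InhPlasticityParams,
) -> None:
    """In-place update of the dense (E, I) inhibitory weight matrix."""
    if i_spike_idx.size:
        cols = W_EI[:, i_spike_idx]
        m = mask[:, i_spike_idx]
        cols += params.A_inh * (y_E - params.alpha)[:, None] * m
        np.clip(cols, params.w_min, params.w_max, out=cols)
        W_EI[:, i_spike_idx] = np.where(m, cols, 0.0)
    if e_spike_idx.size:
        rows = W_EI[e_spike_idx]
        m = mask[e_spike_idx]
        rows += params.A_inh * y_I[None, :] * m
        np.clip(rows, params.w_min, params.w_max, out=rows)
        W_EI[e_spike_idx] = np.where(m, rows, 0.0)


def normalize_incoming(
    W: np.ndarray,
    mask: np.ndarray,
    K: np.ndarray,
    w_min: float,
    w_max: float,
) -> np.ndarray:
    """Hard L1 normalization of incoming E->E weights (in place).

    Every postsynaptic neuron's nonzero incoming weights are multiplicatively
    rescaled so their sum equals its target K, then clipped to the bounds
    (single pass: clipping may leave a small residual deviation from K).
    Masked entries stay exactly zero.
    """
    sums = W.sum(axis=1)
    if np.any(sums <= 0):
        bad = int(np.flatnonzero(sums <= 0)[0])
        raise ValueError(
            f"degenerate topology: neuron {bad} has zero incoming weight sum"
        )
    W *= (np.asarray(K) / sums)[:, None]
    np.clip(W, w_min, w_max, out=W)
    W[~mask] = 0.0
    return W
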