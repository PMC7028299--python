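"""Conductance dynamics and external Poisson input.

Each synaptic channel convolves its weighted input spike train with a
normalized difference-of-exponentials kernel

    K(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / (tau_d - tau_r),

implemented as two coupled first-order states (rise and decay) so the update
is O(1) per step and exactly equivalent to the kernel for delta-train inputs.
The kernel has unit time-integral, so the stationary mean conductance equals
weight x input rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "SynapseKernelParams",
    "ConductanceState",
    "ExternalInput",
    "EXC_KERNEL",
    "INH_KERNEL",
    "update_conductances",
    "sample_poisson_spikes",
]


@dataclass(frozen=True)
class SynapseKernelParams:
    """Kernel time constants, keyed by the presynaptic sign."""

    tau_d: float  # decay time (ms)
    tau_r: float  # rise time (ms)

    def __post_init__(self) -> None:
        if not self.tau_d > self.tau_r > 0:
            raise ValueError("kernel requires tau_d > tau_r > 0")

    def decay_factors(self, dt: float) -> tuple[float, float]:
        """Exact per-step decay multipliers for the (rise, decay) states."""
        return _decay_factors(self.tau_r, self.tau_d, dt)

    @property
    def t_peak(self) -> float:
        """Time of the kernel maximum after an input spike (ms)."""
        return (
            self.tau_d * self.tau_r / (self.tau_d - self.tau_r)
            * np.log(self.tau_d / self.tau_r)
        )


@lru_cache(maxsize=None)
def _decay_factors(tau_r: float, tau_d: float, dt: float) -> tuple[float, float]:
    return float(np.exp(-dt / tau_r)), float(np.exp(-dt / tau_d))


# Excitatory and inhibitory kernel time constants.
EXC_KERNEL = SynapseKernelParams(tau_d=6.0, tau_r=1.0)
INH_KERNEL = SynapseKernelParams(tau_d=2.0, tau_r=0.5)


@dataclass
class ConductanceState:
    """Rise/decay state pair of one channel, one entry per target neuron."""

    kernel: SynapseKernelParams
    rise: np.ndarray
    decay: np.ndarray

    @classmethod
    def zeros(cls, kernel: SynapseKernelParams, n: int) -> "ConductanceState":
        return cls(kernel, np.zeros(n), np.zeros(n))

    @property
    def g(self) -> np.ndarray:
        """Conductance in pF: (decay - rise) / (tau_d - tau_r)."""
        return (self.decay - self.rise) / (self.kernel.tau_d - self.kernel.tau_r)


@dataclass
class ExternalInput:
    """One external Poisson channel targeting a population.

    ``active_window`` is a list of (start, stop) intervals in ms; ``None``
    means always on.
    """

    rate: float                 # kHz per target neuron
    weight: float               # entry synapse strength (pF)
    sign: str = "exc"           # "exc" or "inh"
    active_window: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.sign not in ("exc", "inh"):
            raise ValueError("sign must be 'exc' or 'inh'")
        if self.active_window is not None:
            windows = sorted(self.active_window)
            for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
                if b0 < a1:
                    raise ValueError("schedule windows overlap")

    def active(self, t: float) -> bool:
        if self.active_window is None:
            return True
        return any(a <= t < b for a, b in self.active_window)


def update_conductances(
    state: ConductanceState,
    kernel: SynapseKernelParams,
    weighted_spike_input: np.ndarray | float,
    dt: float,
    check_sign: bool = True,
) -> ConductanceState:
    """Advance the channel one step and add this step's weighted input (pF).

    The rise and decay states decay with their exact exponential factors and
    are then incremented, so the sampled conductance is the kernel
    convolution of the input delta train.
    """
    fr, fd = kernel.decay_factors(dt)
    state.rise *= fr
    state.decay *= fd
    if check_sign and np.min(weighted_spike_input) < 0:
        raise ValueError("negative weighted increment on a synaptic channel")
    state.rise += weighted_spike_input
    state.decay += weighted_spike_input
    return state


def sample_poisson_spikes(
    rate: float | np.ndarray,
    n_neurons: int,
    dt: float,
    rng: np.random.Generator,
    allow_multiple: bool = False,
) -> np.ndarray:
    """Sample one step of independent external Poisson input per neuron.

    By default each neuron emits at most one spike, with probability
    ``rate * dt`` (Bernoulli thinning of the Poisson process); ``rate * dt``
    must then be < 1.  High-rate channels standing in for a large input
    population (e.g. the 18 kHz training drive) set ``allow_multiple=True``
    and draw Poisson counts instead.

    Returns an integer spike-count array of length ``n_neurons``.
    """
    p = np.asarray(rate, dtype=float) * dt
    if np.any(p < 0):
        raise ValueError("rate must be >= 0")
    if allow_multiple:
        return rng.poisson(np.broadcast_to(p, (n_neurons,)))
    pmax = float(np.max(p))
    if pmax >= 1.0:
        raise ValueError(
            f"rate*dt = {pmax:.3g} >= 1 would silently clip the Poisson rate; "
            "use allow_multiple=True for a merged high-rate input population"
        )
    if pmax > 0.5:
        warnings.warn(
            f"rate*dt = {pmax:.3g} > 0.5: Bernoulli thinning is a poor "
            "approximation of the Poisson process",
            stacklevel=2,
        )
    return (rng.random(n_neurons) < p).astype(np.int64)
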