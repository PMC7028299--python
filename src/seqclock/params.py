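"""Default parameter tables for the model.

All values are the published operating point of the balanced recurrent
network and its read-out layer; they were originally obtained by scaling a
balanced E/I network by the square root of the relative network size, which
is why several are not round numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .neurons import PopulationParams
from .plasticity import InhPlasticityParams, StdpParams

__all__ = [
    "population_params",
    "ExternalDriveParams",
    "default_stdp_ee",
    "default_stdp_re",
    "default_inh_plasticity",
]

_MEMBRANE = dict(
    E=dict(tau_m=20.0, E_L=-70.0, C=300.0, V_r=-60.0, tau_abs=5.0,
           V_T0=-52.0, Delta_T=2.0, A_T=10.0, tau_T=30.0,
           tau_a=100.0, beta=1000.0),
    I=dict(tau_m=20.0, E_L=-62.0, C=300.0, V_r=-60.0, tau_abs=5.0,
           V_T0=-52.0),
    R=dict(tau_m=20.0, E_L=-70.0, C=300.0, V_r=-60.0, tau_abs=1.0,
           V_T0=-52.0, Delta_T=2.0, A_T=10.0, tau_T=30.0, beta=0.0),
    S=dict(tau_m=20.0, E_L=-70.0, C=300.0, V_r=-60.0, tau_abs=1.0,
           V_T0=-52.0, Delta_T=2.0, A_T=10.0, tau_T=30.0, beta=0.0),
    H=dict(tau_m=20.0, E_L=-62.0, C=300.0, V_r=-60.0, tau_abs=1.0,
           V_T0=-52.0),
)


def population_params(kind: str, **overrides) -> PopulationParams:
    """Membrane parameters of one neuron class at their default values."""
    if kind not in _MEMBRANE:
        raise ValueError(f"unknown neuron kind {kind!r}")
    kw = dict(_MEMBRANE[kind])
    kw.update(overrides)
    return PopulationParams(kind=kind, **kw)


@dataclass
class ExternalDriveParams:
    """External Poisson input strengths and rates (pF, kHz)."""

    w_ext_E: float = 1.6       # entry weight onto recurrent E neurons
    r_ext_E: float = 4.5       # spontaneous excitatory rate onto E
    w_ext_I: float = 1.52      # entry weight onto recurrent I neurons
    r_ext_I: float = 2.25      # excitatory rate onto I
    w_ext_S: float = 1.6       # entry weight onto supervisor neurons
    w_ext_H: float = 1.6       # entry weight onto interneurons
    r_ext_H: float = 1.0       # rate onto interneurons during learning
    r_stim: float = 18.0       # training drive rate onto the stimulated cluster
    w_stim_inh: float = 2.4    # lateral inhibitory entry weight during training
    r_stim_inh: float = 4.5    # lateral inhibitory rate during training


def default_stdp_ee(**overrides) -> StdpParams:
    """E->E voltage-STDP parameters (recurrent network)."""
    base = StdpParams(A_LTD=0.0014, A=0.0008, theta_LTD=-70.0, theta_LTP=-49.0,
                      tau_u=10.0, tau_v=7.0, tau_x=3.5,
                      weight_dependent_ltp=False, w_min=1.45, w_max=32.68)
    return replace(base, **overrides) if overrides else base


def default_stdp_re(**overrides) -> StdpParams:
    """E->R voltage-STDP parameters (read-out synapses, weight-dependent LTP)."""
    base = StdpParams(A_LTD=0.0014, A=0.0008, theta_LTD=-70.0, theta_LTP=-49.0,
                      tau_u=10.0, tau_v=7.0, tau_x=5.0,
                      weight_dependent_ltp=True, w_min=0.0, w_max=25.0)
    return replace(base, **overrides) if overrides else base


def default_inh_plasticity(**overrides) -> InhPlasticityParams:
    base = InhPlasticityParams(A_inh=0.1, r_0=3.0, tau_y=20.0,
                               w_min=48.7, w_max=243.0)
    return replace(base, **overrides) if overrides else base
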