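"""Network assembly: topology, balanced initialization, scaling, fixtures.

The recurrent module is a sparse balanced network of ``N_E`` excitatory
neurons (partitioned into ``C`` equal clusters) and ``N_I`` inhibitory
neurons; every directed pair is connected independently with probability
``p`` (no self-connections).  The read-out module holds ``N_R`` read-out
neurons driven all-to-all by the recurrent E population, plus one-to-one
supervisor and interneuron partners.

Weight matrices are stored dense as (postsynaptic, presynaptic) arrays with
boolean topology masks; absent synapses stay exactly zero for the lifetime
of the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .neurons import NeuronState, PopulationParams
from .params import (
    ExternalDriveParams,
    default_inh_plasticity,
    default_stdp_ee,
    default_stdp_re,
    population_params,
)
from .plasticity import InhPlasticityParams, StdpParams

__all__ = [
    "NetworkConfig",
    "Network",
    "build_network",
    "make_clock_network",
    "clock_weight_split",
    "make_synfire_chain",
    "delete_readout_synapses",
]

REFERENCE_N_E = 2400


@dataclass
class NetworkConfig:
    """Sizes, initial weights, bounds and parameter tables of one network."""

    N_E: int = 2400
    N_I: int = 600
    N_R: int = 0
    C: int = 30                 # number of excitatory clusters
    p: float = 0.2              # connection probability
    dt: float = 0.1             # integration step (ms)

    # initial / fixed synaptic strengths (pF)
    w0_EE: float = 2.83
    w_IE: float = 1.96
    w0_EI: float = 62.87
    w_II: float = 20.91
    w0_RE: float = 0.0
    w_RS: float = 200.0
    w_RH: float = 200.0
    w_HR: float = 200.0

    stdp_ee: StdpParams = field(default_factory=default_stdp_ee)
    stdp_re: StdpParams = field(default_factory=default_stdp_re)
    inh_plasticity: InhPlasticityParams = field(default_factory=default_inh_plasticity)
    drive: ExternalDriveParams = field(default_factory=ExternalDriveParams)

    def __post_init__(self) -> None:
        if self.C <= 0 or self.N_E % self.C:
            raise ValueError(
                f"N_E = {self.N_E} must be divisible into C = {self.C} equal clusters"
            )
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("connection probability p must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.N_I < 0 or self.N_R < 0:
            raise ValueError("population sizes must be >= 0")

    @property
    def N_C(self) -> int:
        """Cluster size."""
        return self.N_E // self.C

    @property
    def norm_target(self) -> float:
        """Expected incoming E->E weight sum p * N_E * w0_EE (pF)."""
        return self.p * self.N_E * self.w0_EE

    @classmethod
    def reference(cls, **overrides) -> "NetworkConfig":
        """The default 2400E/600I network (30 clusters of 80)."""
        return cls(**overrides)

    @classmethod
    def large(cls, **overrides) -> "NetworkConfig":
        """The scaled-up 6400E/1600I network (80 clusters of 80)."""
        kw = dict(
            N_E=6400, N_I=1600, C=80,
            w0_EE=1.73, w_IE=1.20, w0_EI=40.0, w_II=12.80,
            stdp_ee=default_stdp_ee(w_min=1.27, w_max=30.5),
            stdp_re=default_stdp_re(w_max=15.0),
            inh_plasticity=default_inh_plasticity(w_min=40.0, w_max=200.0),
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def scaled(cls, C: int, N_C: int, N_R: int = 0, **overrides) -> "NetworkConfig":
        """A size-swept configuration preserving the reference operating point.

        The E/I ratio is preserved, the connection probability varies so that
        p * N_C stays constant, and all recurrent weight scales (initial
        values and bounds) are multiplied by sqrt(N_E_ref / N_E) to preserve
        the magnitude of the recurrent currents.
        """
        ref = cls()
        N_E = C * N_C
        s = math.sqrt(ref.N_E / N_E)
        p = min(ref.p * (ref.N_C / N_C), 1.0)
        kw = dict(
            N_E=N_E,
            N_I=max(1, round(N_E * ref.N_I / ref.N_E)),
            N_R=N_R,
            C=C,
            p=p,
            w0_EE=ref.w0_EE * s,
            w_IE=ref.w_IE * s,
            w0_EI=ref.w0_EI * s,
            w_II=ref.w_II * s,
            stdp_ee=default_stdp_ee(w_min=ref.stdp_ee.w_min * s,
                                    w_max=ref.stdp_ee.w_max * s),
            stdp_re=default_stdp_re(w_max=ref.stdp_re.w_max * s),
            inh_plasticity=default_inh_plasticity(
                w_min=ref.inh_plasticity.w_min * s,
                w_max=ref.inh_plasticity.w_max * s),
        )
        kw.update(overrides)
        return cls(**kw)

    def with_(self, **overrides) -> "NetworkConfig":
        return replace(self, **overrides)


@dataclass
class Network:
    """Assembled populations, weight matrices and cluster labels."""

    cfg: NetworkConfig
    params: dict[str, PopulationParams]
    states: dict[str, NeuronState]
    clusters: np.ndarray          # cluster id per E neuron
    # (post, pre) weight matrices and fixed topology masks
    W_EE: np.ndarray
    mask_EE: np.ndarray
    W_IE: np.ndarray
    mask_IE: np.ndarray
    W_EI: np.ndarray
    mask_EI: np.ndarray
    W_II: np.ndarray
    mask_II: np.ndarray
    W_RE: np.ndarray | None = None
    mask_RE: np.ndarray | None = None
    K: np.ndarray | None = None   # per-E-neuron incoming L1 target (pF)
    t: float = 0.0                # simulated clock (ms)

    @property
    def has_readout(self) -> bool:
        return self.cfg.N_R > 0

    def cluster_members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.clusters == c)

    def offdiagonal_block_mean(self, W: np.ndarray | None = None) -> float:
        """Mean weight of the cluster i -> i+1 blocks (cyclic)."""
        W = self.W_EE if W is None else W
        C = self.cfg.C
        vals = []
        for c in range(C):
            pre = self.clusters == c
            post = self.clusters == (c + 1) % C
            block = W[np.ix_(post, pre)]
            m = self.mask_EE[np.ix_(post, pre)]
            if m.any():
                vals.append(block[m].mean())
        return float(np.mean(vals))


def _bernoulli_mask(n_post: int, n_pre: int, p: float,
                    rng: np.random.Generator, no_self: bool = False) -> np.ndarray:
    mask = rng.random((n_post, n_pre)) < p
    if no_self:
        np.fill_diagonal(mask, False)
    return mask


def build_network(cfg: NetworkConfig, rng: np.random.Generator) -> Network:
    """Draw the topology and initialize all weights at their table values."""
    NE, NI, NR = cfg.N_E, cfg.N_I, cfg.N_R

    mask_EE = _bernoulli_mask(NE, NE, cfg.p, rng, no_self=True)
    mask_IE = _bernoulli_mask(NI, NE, cfg.p, rng)
    mask_EI = _bernoulli_mask(NE, NI, cfg.p, rng)
    mask_II = _bernoulli_mask(NI, NI, cfg.p, rng, no_self=True)

    W_EE = mask_EE * cfg.w0_EE
    W_IE = mask_IE * cfg.w_IE
    W_EI = mask_EI * cfg.w0_EI
    W_II = mask_II * cfg.w_II

    params = {"E": population_params("E"), "I": population_params("I")}
    states = {k: NeuronState.at_rest(params[k], n)
              for k, n in (("E", NE), ("I", NI)) if n}

    W_RE = mask_RE = None
    if NR:
        mask_RE = np.ones((NR, NE), dtype=bool)
        W_RE = np.full((NR, NE), float(cfg.w0_RE))
        for k in ("R", "S", "H"):
            params[k] = population_params(k)
            states[k] = NeuronState.at_rest(params[k], NR)

    clusters = np.repeat(np.arange(cfg.C), cfg.N_C)
    K = W_EE.sum(axis=1)

    return Network(
        cfg=cfg, params=params, states=states, clusters=clusters,
        W_EE=W_EE, mask_EE=mask_EE, W_IE=W_IE, mask_IE=mask_IE,
        W_EI=W_EI, mask_EI=mask_EI, W_II=W_II, mask_II=mask_II,
        W_RE=W_RE, mask_RE=mask_RE, K=K,
    )


def clock_weight_split(cfg: NetworkConfig, intra_frac: float = 0.7) -> tuple[float, float]:
    """Intra-cluster and feedforward weights of a constructed clock matrix.

    The construction preserves the L1 operating point of the trained network:
    background synapses sit at the lower bound w_min, and the remaining
    budget K - p (N_E - 2 N_C) w_min is split between the intra-cluster and
    the cluster i -> i+1 synapses, ``intra_frac`` of it to the former.
    """
    w_min = cfg.stdp_ee.w_min
    budget = cfg.norm_target - cfg.p * (cfg.N_E - 2 * cfg.N_C) * w_min
    per_class = budget / (cfg.p * cfg.N_C)
    w_intra = intra_frac * per_class
    w_ff = (1.0 - intra_frac) * per_class
    return float(w_intra), float(w_ff)


def make_clock_network(
    cfg: NetworkConfig,
    rng: np.random.Generator,
    w_intra: float | None = None,
    w_ff: float | None = None,
    intra_frac: float = 0.7,
    w_EI: float | None = None,
) -> Network:
    """A network with a hand-constructed sequential ("clock") weight matrix.

    Emulates the outcome of the first learning stage: strong intra-cluster
    blocks, strong cyclic cluster i -> i+1 blocks, all other E->E synapses at
    the lower bound.  Used as the temporal backbone for read-out experiments
    without re-running the training protocol.
    """
    net = build_network(cfg, rng)
    if w_intra is None or w_ff is None:
        d_intra, d_ff = clock_weight_split(cfg, intra_frac)
        w_intra = d_intra if w_intra is None else w_intra
        w_ff = d_ff if w_ff is None else w_ff

    C, cl = cfg.C, net.clusters
    W = np.where(net.mask_EE, cfg.stdp_ee.w_min, 0.0)
    same = cl[:, None] == cl[None, :]
    succ = cl[:, None] == (cl[None, :] + 1) % C
    W[same & net.mask_EE] = w_intra
    W[succ & net.mask_EE] = w_ff
    net.W_EE = W
    net.K = W.sum(axis=1)
    if w_EI is not None:
        net.W_EI = net.mask_EI * float(w_EI)
    return net


def make_synfire_chain(
    n: int = 120,
    w_chain: float = 100.0,
    N_R: int = 0,
    w_max_RE: float = 75.0,
    circular: bool = True,
) -> Network:
    """A chain of single-neuron clusters (the fragile synfire limit).

    Every "cluster" holds one neuron, connected only to its successor; there
    is no inhibitory population.  ``w_max_RE`` is raised because single
    presynaptic neurons must drive the read-out on their own.
    """
    cfg = NetworkConfig(
        N_E=n, N_I=0, N_R=N_R, C=n, p=0.0,
        stdp_re=default_stdp_re(w_max=w_max_RE),
    )
    mask_EE = np.zeros((n, n), dtype=bool)
    idx = np.arange(n - 1)
    mask_EE[idx + 1, idx] = True
    if circular:
        mask_EE[0, n - 1] = True
    W_EE = mask_EE * w_chain

    params = {"E": population_params("E")}
    states = {"E": NeuronState.at_rest(params["E"], n)}
    W_RE = mask_RE = None
    if N_R:
        mask_RE = np.ones((N_R, n), dtype=bool)
        W_RE = np.zeros((N_R, n))
        for k in ("R", "S", "H"):
            params[k] = population_params(k)
            states[k] = NeuronState.at_rest(params[k], N_R)

    empty = np.zeros((0, 0))
    return Network(
        cfg=cfg, params=params, states=states,
        clusters=np.arange(n),
        W_EE=W_EE, mask_EE=mask_EE,
        W_IE=np.zeros((0, n)), mask_IE=np.zeros((0, n), dtype=bool),
        W_EI=np.zeros((n, 0)), mask_EI=np.zeros((n, 0), dtype=bool),
        W_II=empty, mask_II=empty.astype(bool),
        W_RE=W_RE, mask_RE=mask_RE, K=W_EE.sum(axis=1),
    )


def delete_readout_synapses(
    W_RE: np.ndarray,
    mask_RE: np.ndarray,
    clusters: np.ndarray,
    n_per_cluster: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly delete ``n_per_cluster`` read-out synapses per (neuron, cluster).

    Deleted synapses are zeroed and masked out so plasticity cannot restore
    them.  Returns new (weights, mask) arrays.
    """
    N_C = int(np.bincount(clusters).max())
    if n_per_cluster > N_C:
        raise ValueError(f"cannot delete {n_per_cluster} synapses from clusters of {N_C}")
    W = W_RE.copy()
    mask = mask_RE.copy()
    C = int(clusters.max()) + 1
    for r in range(W.shape[0]):
        for c in range(C):
            members = np.flatnonzero((clusters == c) & mask[r])
            if members.size == 0:
                continue
            k = min(n_per_cluster, members.size)
            kill = rng.choice(members, size=k, replace=False)
            W[r, kill] = 0.0
            mask[r, kill] = False
    return W, mask
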