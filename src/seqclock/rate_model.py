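"""Reduced linear rate model of the sequential dynamics.

Coarse-graining the trained recurrent weight matrix over clusters yields a
small linear system dx/dt = -x + A x + xi whose spectrum explains the time
scale of the sequential switching.  For three excitatory nodes and one
inhibitory node, A is parametrized by the recurrent cluster strength delta,
the feedforward (clockwise vs anticlockwise) asymmetry epsilon, and the
inhibition scale k:

        [ delta   1       eps    -k w ]
    A = [ eps     delta   1      -k w ]      w = delta + eps + 1
        [ 1       eps     delta  -k w ]
        [ w/3     w/3     w/3    -k w ]

epsilon > 1 produces sequential (cyclic) dynamics and k > 1 balances the
network.  The dominant eigenvalues are the complex pair

    lambda = delta - (eps + 1)/2  +/-  i sqrt(3) (eps - 1) / 2,

localized on the excitatory cycle: the imaginary part — hence the switching
frequency — grows linearly with the feedforward strength (eps - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReducedSpectrum",
    "build_reduced_matrix",
    "closed_form_spectrum",
    "simulate_rate_model",
    "coarse_grain_weights",
]


@dataclass
class ReducedSpectrum:
    """Eigenvalues of the reduced matrix with mode labels.

    ``dominant`` is the closed-form complex pair on the excitatory cycle;
    ``uniform_fast`` and ``ei_mode`` are the remaining (real) eigenvalues,
    obtained numerically: the fast uniform decay across all groups and the
    slower excitatory/inhibitory interplay mode.
    """

    dominant: tuple[complex, complex]
    uniform_fast: float
    ei_mode: float

    @property
    def all(self) -> np.ndarray:
        return np.array([self.uniform_fast, self.ei_mode, *self.dominant])


def build_reduced_matrix(delta: float, eps: float, k: float) -> np.ndarray:
    """The parametrized 4-node (3 excitatory + 1 inhibitory) matrix."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if eps <= 1:
        warnings.warn("eps <= 1: no clockwise feedforward dominance, the "
                      "dynamics will not be sequential", stacklevel=2)
    if k <= 1:
        warnings.warn("k <= 1: inhibition too weak to balance the network",
                      stacklevel=2)
    w = delta + eps + 1.0
    return np.array([
        [delta, 1.0, eps, -k * w],
        [eps, delta, 1.0, -k * w],
        [1.0, eps, delta, -k * w],
        [w / 3.0, w / 3.0, w / 3.0, -k * w],
    ])


def closed_form_spectrum(delta: float, eps: float, k: float) -> ReducedSpectrum:
    """Spectrum of the reduced matrix with the dominant pair in closed form.

    The excitatory 3-cycle is circulant, so the pair localized on it is
    delta - (eps+1)/2 +/- i sqrt(3)(eps-1)/2 exactly; the two remaining
    modes (uniform fast decay and E/I interplay) are taken from a numeric
    eigendecomposition.
    """
    re = delta - (eps + 1.0) / 2.0
    im = np.sqrt(3.0) * (eps - 1.0) / 2.0
    pair = (complex(re, im), complex(re, -im))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        A = build_reduced_matrix(delta, eps, k)
    eigs = np.linalg.eigvals(A)
    # peel off the two eigenvalues matching the closed-form pair
    remaining = list(eigs)
    for lam in pair:
        j = int(np.argmin(np.abs(np.asarray(remaining) - lam)))
        remaining.pop(j)
    remaining = sorted((z.real for z in remaining))
    return ReducedSpectrum(dominant=pair, uniform_fast=remaining[0],
                           ei_mode=remaining[1])


def simulate_rate_model(
    A: np.ndarray,
    noise_scale: float,
    dt: float,
    T: float,
    rng: np.random.Generator,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama integration of dx/dt = -x + A x + xi.

    Returns (times, trajectories) with trajectories of shape (n_steps, n).
    With eps > 1 and the dominant pair near the stability edge the
    excitatory nodes oscillate in the cyclic order x1 -> x2 -> x3.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    M = -np.eye(n) + A
    if np.max(np.linalg.eigvals(M).real) > 0:
        warnings.warn("rate model is linearly unstable; trajectories will grow",
                      stacklevel=2)
    n_steps = int(round(T / dt))
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    out = np.empty((n_steps, n))
    sq = noise_scale * np.sqrt(dt)
    for i in range(n_steps):
        x = x + dt * (M @ x) + sq * rng.standard_normal(n)
        out[i] = x
    return dt * np.arange(1, n_steps + 1), out


def coarse_grain_weights(
    W_EE: np.ndarray,
    W_EI: np.ndarray,
    W_IE: np.ndarray,
    W_II: np.ndarray,
    clusters: np.ndarray,
) -> np.ndarray:
    """Block-average the signed full weight matrix over clusters.

    Returns a (C+1) x (C+1) matrix: entry (i, j) is the mean weight from
    cluster j to cluster i (all pairs, absent synapses counting as zero);
    the last row/column is the pooled inhibitory group with negative sign on
    its outgoing weights.
    """
    clusters = np.asarray(clusters)
    if clusters.shape[0] != W_EE.shape[0]:
        raise ValueError("cluster assignment does not match W_EE")
    C = int(clusters.max()) + 1
    groups = [np.flatnonzero(clusters == c) for c in range(C)]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty cluster in assignment")
    A = np.zeros((C + 1, C + 1))
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            A[i, j] = W_EE[np.ix_(gi, gj)].mean()
        A[i, C] = -W_EI[gi].mean()
        A[C, i] = W_IE[:, gi].mean()
    A[C, C] = -W_II.mean() if W_II.size else 0.0
    return A
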