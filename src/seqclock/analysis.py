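"""Spike-train and weight-matrix analytics.

Covers irregularity statistics (ISI CV), cluster-activation detection and
period statistics of the sequential dynamics, the square-root (diffusive)
growth of timing variability, read-out recall and rate reconstruction, and
the eigenvalue spectrum of the signed full weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .simulate import SpikeRaster

__all__ = [
    "ActivationInterval",
    "PeriodStats",
    "isi_cv",
    "detect_activations",
    "period_stats",
    "weber_fit",
    "recall_performance",
    "readout_rate",
    "full_weight_spectrum",
    "coarse_grain_readout",
]

# Gaussian kernel width of ~12 ms interpreted as FWHM -> sigma = 12/2.355
DEFAULT_READOUT_SIGMA_MS = 12.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ActivationInterval:
    """One supra-threshold activation of a cluster."""

    cluster: int
    onset: float    # ms
    offset: float   # ms
    cycle: int      # occurrence index of this cluster

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class PeriodStats:
    """Cycle periods and per-cluster activation-time statistics."""

    periods: np.ndarray               # per-cycle period (ms)
    per_cluster: pd.DataFrame         # columns: cluster, mu_t, sigma_t, n
    n_cycles: int
    n_broken: int                     # cycles excluded for missing clusters

    @property
    def mean_period(self) -> float:
        return float(np.mean(self.periods))

    @property
    def std_period(self) -> float:
        return float(np.std(self.periods, ddof=1)) if self.periods.size > 1 else 0.0


def isi_cv(raster: SpikeRaster, population: str = "E",
           min_spikes: int = 3) -> tuple[pd.Series, float]:
    """Per-neuron coefficient of variation of the inter-spike intervals.

    Neurons with fewer than ``min_spikes`` spikes are excluded.  Returns the
    per-neuron CV distribution (indexed by neuron id) and its mean.
    """
    if raster.n_spikes(population) == 0:
        raise ValueError(f"empty raster for population {population!r}")
    out = {}
    for nid, train in enumerate(raster.spike_trains(population)):
        if train.size < min_spikes:
            continue
        isi = np.diff(train)
        m = isi.mean()
        out[nid] = isi.std() / m if m > 0 else np.nan
    series = pd.Series(out, name="cv").dropna()
    if series.empty:
        raise ValueError(
            f"no neuron in {population!r} reached {min_spikes} spikes")
    return series, float(series.mean())


def _cluster_rate_grid(times: np.ndarray, t0: float, t1: float,
                       bin_ms: float) -> np.ndarray:
    n_bins = max(int(np.ceil((t1 - t0) / bin_ms)), 1)
    counts, _ = np.histogram(times, bins=n_bins, range=(t0, t0 + n_bins * bin_ms))
    return counts.astype(float)


def detect_activations(
    raster: SpikeRaster,
    clusters: np.ndarray,
    bin_ms: float = 2.0,
    smooth_sigma_ms: float = 3.0,
    threshold_frac: float = 0.5,
    population: str = "E",
) -> list[ActivationInterval]:
    """Detect per-cluster activation intervals from the population rate.

    Each cluster's spike count is binned, Gaussian-smoothed and thresholded
    at ``threshold_frac`` of that cluster's own peak; contiguous
    supra-threshold runs longer than one bin become intervals.  Silent
    clusters simply contribute no intervals.
    """
    t, ids = raster.times[population], raster.ids[population]
    t0, t1 = raster.t_start, raster.t_stop
    intervals: list[ActivationInterval] = []
    for c in np.unique(clusters):
        sel = np.isin(ids, np.flatnonzero(clusters == c))
        if not sel.any():
            continue
        rate = _cluster_rate_grid(t[sel], t0, t1, bin_ms)
        rate = gaussian_filter1d(rate, smooth_sigma_ms / bin_ms, mode="constant")
        peak = rate.max()
        if peak <= 0:
            continue
        above = rate >= threshold_frac * peak
        edges = np.diff(above.astype(int))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if above[0]:
            starts = np.r_[0, starts]
        if above[-1]:
            ends = np.r_[ends, above.size]
        cyc = 0
        for s, e in zip(starts, ends):
            if e - s < 2:  # shorter than 2 bins: noise
                continue
            intervals.append(ActivationInterval(
                cluster=int(c), onset=t0 + s * bin_ms, offset=t0 + e * bin_ms,
                cycle=cyc))
            cyc += 1
    intervals.sort(key=lambda iv: (iv.onset, iv.cluster))
    return intervals


def period_stats(
    activations: list[ActivationInterval],
    reference_cluster: int = 0,
    n_clusters: int | None = None,
) -> PeriodStats:
    """Cycle periods and per-cluster activation times of the sequence.

    The period is the difference between successive onsets of the reference
    cluster; within each cycle, every cluster's activation time is measured
    from the cycle start.  Cycles missing any cluster are excluded from the
    per-cluster statistics and counted as broken.
    """
    ref = sorted(iv.onset for iv in activations
                 if iv.cluster == reference_cluster)
    if len(ref) < 2:
        raise ValueError("need at least two reference-cluster activations")
    periods = np.diff(ref)

    if n_clusters is None:
        n_clusters = max(iv.cluster for iv in activations) + 1
    rows, n_broken = [], 0
    per_cluster: dict[int, list[float]] = {c: [] for c in range(n_clusters)}
    for k in range(len(ref) - 1):
        start, stop = ref[k], ref[k + 1]
        onsets: dict[int, float] = {}
        for iv in activations:
            if start <= iv.onset < stop and iv.cluster not in onsets:
                onsets[iv.cluster] = iv.onset - start
        if len(onsets) < n_clusters:
            n_broken += 1
            continue
        for c, t_on in onsets.items():
            per_cluster[c].append(t_on)
    for c in range(n_clusters):
        vals = np.asarray(per_cluster[c])
        rows.append({
            "cluster": c,
            "mu_t": vals.mean() if vals.size else np.nan,
            "sigma_t": vals.std(ddof=1) if vals.size > 1 else np.nan,
            "n": vals.size,
        })
    return PeriodStats(
        periods=np.asarray(periods),
        per_cluster=pd.DataFrame(rows),
        n_cycles=len(ref) - 1,
        n_broken=n_broken,
    )


def weber_fit(mu_t: np.ndarray, sigma_t: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of sigma = a * sqrt(mu) through the origin.

    Timing variability of a Markov-chain clock grows diffusively, i.e. with
    the square root of elapsed time rather than linearly (Weber's law).
    Returns the coefficient ``a`` and the RMSE of the fit.
    """
    mu = np.asarray(mu_t, dtype=float)
    sg = np.asarray(sigma_t, dtype=float)
    ok = np.isfinite(mu) & np.isfinite(sg)
    mu, sg = mu[ok], sg[ok]
    if mu.size < 5:
        raise ValueError("need at least 5 (mu, sigma) cluster positions")
    root = np.sqrt(mu)
    a = float(np.dot(sg, root) / np.dot(root, root))
    rmse = float(np.sqrt(np.mean((sg - a * root) ** 2)))
    return a, rmse


def recall_performance(
    raster_before: SpikeRaster,
    raster_after: SpikeRaster,
    population: str = "R",
) -> float:
    """Read-out spike count after a perturbation, normalized by before.

    The two rasters must cover matched replay windows of equal duration;
    counts are duration-normalized to tolerate small mismatches.
    """
    n_before = raster_before.n_spikes(population)
    if n_before == 0:
        raise ValueError("no read-out spikes in the reference window")
    d_before = raster_before.t_stop - raster_before.t_start
    d_after = raster_after.t_stop - raster_after.t_start
    return float(
        (raster_after.n_spikes(population) / d_after)
        / (n_before / d_before)
    )


def readout_rate(
    raster: SpikeRaster,
    kernel_sigma_ms: float = DEFAULT_READOUT_SIGMA_MS,
    normalize: bool = False,
    population: str = "R",
    grid_ms: float = 1.0,
    t0: float | None = None,
    t1: float | None = None,
) -> pd.DataFrame:
    """Per-channel read-out rates: spikes convolved with a Gaussian kernel.

    The kernel has unit time-integral, so values are rates in kHz; with
    ``normalize`` each channel is min-max scaled to [0, 1] (a silent channel
    stays zero).  Returns a tidy frame indexed by time with one column per
    read-out neuron.
    """
    t0 = raster.t_start if t0 is None else t0
    t1 = raster.t_stop if t1 is None else t1
    n_bins = max(int(np.ceil((t1 - t0) / grid_ms)), 1)
    grid = t0 + np.arange(n_bins) * grid_ms
    out = {}
    times, ids = raster.times[population], raster.ids[population]
    for ch in range(raster.n_neurons[population]):
        sel = (ids == ch) & (times >= t0) & (times < t1)
        counts = _cluster_rate_grid(times[sel], t0, t1, grid_ms)[:n_bins]
        rate = gaussian_filter1d(counts / grid_ms, kernel_sigma_ms / grid_ms,
                                 mode="constant")
        if normalize:
            peak = rate.max()
            if peak > 0:
                rate = rate / peak
        out[ch] = rate
    return pd.DataFrame(out, index=pd.Index(grid, name="time_ms"))


def full_weight_spectrum(
    W_EE: np.ndarray,
    W_EI: np.ndarray,
    W_IE: np.ndarray,
    W_II: np.ndarray,
    n_outliers: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of the signed block matrix [[W_EE, -W_EI], [W_IE, -W_II]].

    Returns all eigenvalues sorted by descending real part, plus the
    outliers: eigenvalues outside the estimated bulk circle (or the top
    ``n_outliers`` by real part if given explicitly).
    """
    NE = W_EE.shape[0]
    NI = W_II.shape[0] if W_II.size else W_IE.shape[0]
    if (W_EE.shape != (NE, NE) or W_EI.shape != (NE, NI)
            or W_IE.shape != (NI, NE) or W_II.shape != (NI, NI)):
        raise ValueError("weight blocks have incompatible shapes")
    W = np.block([[W_EE, -W_EI], [W_IE, -W_II]])
    eigs = np.linalg.eigvals(W)
    eigs = eigs[np.argsort(-eigs.real)]
    if n_outliers is not None:
        return eigs, eigs[:n_outliers]
    # circular-law bulk of radius r has mean |lambda|^2 = r^2 / 2
    r_est = np.sqrt(2.0 * np.mean(np.abs(eigs) ** 2))
    outliers = eigs[np.abs(eigs) > 1.1 * r_est]
    return eigs, outliers


def coarse_grain_readout(W_RE: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    """Mean read-out weight per (read-out neuron, cluster) block."""
    C = int(clusters.max()) + 1
    return np.stack([W_RE[:, clusters == c].mean(axis=1) for c in range(C)],
                    axis=1)
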