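"""Spike-train analytics: CV, activation detection, periods, Weber fit."""

import numpy as np
import pytest

from seqclock.analysis import (
    detect_activations,
    full_weight_spectrum,
    isi_cv,
    period_stats,
    readout_rate,
    recall_performance,
    weber_fit,
)
from seqclock.simulate import SpikeRaster


def _raster(times, ids, n, pop="E", t0=0.0, t1=None):
    times = np.asarray(times, dtype=float)
    ids = np.asarray(ids, dtype=np.int64)
    order = np.argsort(times, kind="stable")
    return SpikeRaster(times={pop: times[order]}, ids={pop: ids[order]},
                       n_neurons={pop: n}, t_start=t0,
                       t_stop=t1 if t1 is not None else
                       (times.max() + 1.0 if times.size else 1.0))


class TestIsiCv:
    def test_periodic_train_has_zero_cv(self):
        r = _raster(np.arange(0, 1000, 10.0), np.zeros(100), 1)
        cvs, mean = isi_cv(r, "E")
        assert mean == 0.0

    def test_poisson_train_cv_near_one(self, rng):
        isi = rng.exponential(10.0, 10000)
        r = _raster(np.cumsum(isi), np.zeros(10000), 1)
        _, mean = isi_cv(r, "E")
        assert abs(mean - 1.0) < 0.05

    def test_sparse_neurons_excluded(self):
        times = [0.0, 10.0, 20.0, 5.0]          # neuron 1 has one spike
        r = _raster(times, [0, 0, 0, 1], 2)
        cvs, _ = isi_cv(r, "E")
        assert list(cvs.index) == [0]

    def test_empty_raster_rejected(self):
        r = _raster([], [], 3)
        with pytest.raises(ValueError, match="empty"):
            isi_cv(r, "E")


class TestDetectActivations:
    def _burst(self, rng, members, t0, t1, rate_hz=150.0):
        n = rng.poisson(rate_hz * 1e-3 * (t1 - t0) * len(members))
        return rng.uniform(t0, t1, n), rng.choice(members, n)

    def test_recovers_planted_interval(self, rng):
        clusters = np.repeat([0, 1], 20)
        t, i = self._burst(rng, np.arange(20, 40), 100.0, 115.0, 400.0)
        r = _raster(t, i, 40, t0=0.0, t1=200.0)
        ivs = detect_activations(r, clusters)
        assert len(ivs) == 1
        assert ivs[0].cluster == 1
        assert abs(ivs[0].onset - 100.0) <= 2.0 + 2.0   # within one bin + smoothing
        assert abs(ivs[0].offset - 115.0) <= 4.0

    def test_two_bursts_two_ordered_intervals(self, rng):
        clusters = np.zeros(20, dtype=int)
        t1, i1 = self._burst(rng, np.arange(20), 50.0, 65.0, 400.0)
        t2, i2 = self._burst(rng, np.arange(20), 150.0, 165.0, 400.0)
        r = _raster(np.r_[t1, t2], np.r_[i1, i2], 20, t1=250.0)
        ivs = detect_activations(r, clusters)
        assert len(ivs) == 2
        assert ivs[0].onset < ivs[1].onset
        assert ivs[0].cycle == 0 and ivs[1].cycle == 1

    def test_silent_cluster_contributes_nothing(self, rng):
        clusters = np.repeat([0, 1], 10)
        t, i = self._burst(rng, np.arange(10), 10.0, 25.0, 400.0)
        ivs = detect_activations(_raster(t, i, 20, t1=50.0), clusters)
        assert all(iv.cluster == 0 for iv in ivs)


class TestPeriodStats:
    def _metronome(self, C=5, period=450.0, cycles=6, dwell=15.0):
        times, ids, clusters = [], [], np.repeat(np.arange(C), 10)
        for cyc in range(cycles):
            for c in range(C):
                onset = cyc * period + c * (period / C)
                for k in range(10):  # spikes tile the dwell uniformly
                    times += [onset + k * dwell / 10, onset + (k + 0.5) * dwell / 10]
                    ids += [c * 10 + k] * 2
        return _raster(times, ids, C * 10, t1=cycles * period), clusters

    def test_metronomic_sequence_exact_period(self):
        raster, clusters = self._metronome()
        ivs = detect_activations(raster, clusters)
        stats = period_stats(ivs, n_clusters=5)
        assert np.isclose(stats.mean_period, 450.0, atol=1e-9)
        assert stats.std_period == 0.0
        assert stats.n_broken == 0

    def test_translation_invariance(self):
        raster, clusters = self._metronome()
        shifted = SpikeRaster(
            times={"E": raster.times["E"] + 1234.0}, ids=raster.ids,
            n_neurons=raster.n_neurons, t_start=1234.0,
            t_stop=raster.t_stop + 1234.0)
        s1 = period_stats(detect_activations(raster, clusters), n_clusters=5)
        s2 = period_stats(detect_activations(shifted, clusters), n_clusters=5)
        assert np.isclose(s1.mean_period, s2.mean_period)
        np.testing.assert_allclose(s1.per_cluster["mu_t"], s2.per_cluster["mu_t"])

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            period_stats([], n_clusters=3)


class TestWeberFit:
    def test_exact_square_root_data(self):
        mu = np.linspace(10, 400, 10)
        a, rmse = weber_fit(mu, 0.2 * np.sqrt(mu))
        assert np.isclose(a, 0.2) and rmse < 1e-12

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            weber_fit([1, 2, 3], [1, 2, 3])

    def test_markov_chain_surrogate_is_diffusive(self, rng):
        """Sum of i.i.d. exponential stage durations: sigma grows as mu^0.5."""
        stages, trials, mean_ms = 30, 400, 15.0
        durations = rng.exponential(mean_ms, (trials, stages))
        onsets = np.cumsum(durations, axis=1)
        mu = onsets.mean(axis=0)
        sigma = onsets.std(axis=0, ddof=1)
        slope = np.polyfit(np.log(mu), np.log(sigma), 1)[0]
        assert 0.4 < slope < 0.6
        # the through-origin sqrt fit recovers the theory coefficient:
        # sigma_k = mean_ms * sqrt(k), mu_k = mean_ms * k -> a = sqrt(mean_ms)
        a, rmse = weber_fit(mu, sigma)
        assert np.isclose(a, np.sqrt(mean_ms), rtol=0.1)
        assert rmse < 0.2 * sigma.max()


class TestRecallAndReadoutRate:
    def test_unchanged_raster_gives_unity(self):
        r = _raster(np.arange(10.0), np.zeros(10), 1, pop="R", t1=100.0)
        assert recall_performance(r, r) == 1.0

    def test_total_deletion_gives_zero(self):
        before = _raster(np.arange(10.0), np.zeros(10), 1, pop="R", t1=100.0)
        after = _raster([], [], 1, pop="R", t0=0.0, t1=100.0)
        assert recall_performance(before, after) == 0.0

    def test_no_reference_spikes_rejected(self):
        empty = _raster([], [], 1, pop="R", t1=100.0)
        with pytest.raises(ValueError):
            recall_performance(empty, empty)

    def test_single_spike_unit_integral_kernel(self):
        r = _raster([50.0], [0], 1, pop="R", t1=100.0)
        rates = readout_rate(r, grid_ms=0.5)
        assert np.isclose(rates[0].sum() * 0.5, 1.0, rtol=0.01)
        assert rates[0].idxmax() == pytest.approx(50.0, abs=1.5)

    def test_min_max_normalization(self):
        r = _raster([20.0, 21.0, 60.0], [0, 0, 1], 2, pop="R", t1=100.0)
        rates = readout_rate(r, normalize=True)
        assert np.isclose(rates[0].max(), 1.0)
        assert np.isclose(rates[1].max(), 1.0)


class TestWeightSpectrum:
    def test_zero_matrix_all_zero(self):
        eigs, outliers = full_weight_spectrum(
            np.zeros((4, 4)), np.zeros((4, 2)), np.zeros((2, 4)),
            np.zeros((2, 2)))
        assert np.allclose(eigs, 0.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            full_weight_spectrum(np.zeros((4, 4)), np.zeros((3, 2)),
                                 np.zeros((2, 4)), np.zeros((2, 2)))

    def test_balanced_random_matrix_bulk_and_balance_outliers(self, rng):
        from seqclock.network import NetworkConfig, build_network
        net = build_network(NetworkConfig.scaled(C=10, N_C=24), rng)
        eigs, outliers = full_weight_spectrum(net.W_EE, net.W_EI, net.W_IE,
                                              net.W_II)
        # at most the two balance eigenvalues leave the bulk circle
        assert len(outliers) <= 2
        r_est = np.sqrt(2.0 * np.mean(np.abs(eigs) ** 2))
        assert np.mean(np.abs(eigs) <= r_est) > 0.95

    def test_sequential_matrix_has_complex_dominant_pairs(self, rng):
        from seqclock.network import NetworkConfig, make_clock_network
        net = make_clock_network(NetworkConfig.scaled(C=10, N_C=24), rng)
        eigs, _ = full_weight_spectrum(net.W_EE, net.W_EI, net.W_IE, net.W_II)
        top = eigs[:6]
        top = top[np.abs(top.imag) > 1e-9]
        assert len(top) >= 4  # dominant eigenvalues come in conjugate pairs
        # near-constant imaginary spacing of the leading pairs
        ims = np.sort(np.abs(top.imag))
        assert ims[-1] > 0
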