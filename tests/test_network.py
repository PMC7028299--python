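"""Network assembly, scaling, determinism and read-out synapse deletion."""

import numpy as np
import pytest

from seqclock.network import (
    NetworkConfig,
    build_network,
    clock_weight_split,
    delete_readout_synapses,
    make_clock_network,
    make_synfire_chain,
)
from seqclock.plasticity import normalize_incoming
from seqclock.protocols import SpontaneousProtocol
from seqclock.simulate import PlasticityFlags, Simulator


class TestConfig:
    def test_reference_defaults(self):
        cfg = NetworkConfig.reference()
        assert (cfg.N_E, cfg.N_I, cfg.p, cfg.C) == (2400, 600, 0.2, 30)
        assert cfg.N_C == 80
        assert np.isclose(cfg.norm_target, 0.2 * 2400 * 2.83)

    def test_cluster_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(N_E=2401, C=30)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(p=1.5)

    def test_scaled_config_preserves_operating_point(self):
        cfg = NetworkConfig.scaled(C=10, N_C=20)
        ref = NetworkConfig.reference()
        # p N_C constant and E/I ratio preserved
        assert np.isclose(cfg.p * cfg.N_C, ref.p * ref.N_C)
        assert np.isclose(cfg.N_E / cfg.N_I, ref.N_E / ref.N_I)
        s = np.sqrt(ref.N_E / cfg.N_E)
        assert np.isclose(cfg.w0_EE, ref.w0_EE * s)
        assert np.isclose(cfg.stdp_ee.w_max, ref.stdp_ee.w_max * s)

    def test_large_preset_matches_published_variant(self):
        cfg = NetworkConfig.large()
        assert (cfg.N_E, cfg.N_I, cfg.C) == (6400, 1600, 80)
        assert cfg.w0_EE == 1.73
        assert cfg.stdp_re.w_max == 15.0


class TestBuild:
    def test_in_degree_binomial_bound(self, rng):
        cfg = NetworkConfig.reference()
        net = build_network(cfg, rng)
        in_deg = net.mask_EE.sum(axis=1)
        expected = cfg.p * (cfg.N_E - 1)
        # population mean within 3 standard errors of the binomial mean
        sem = np.sqrt(expected * (1 - cfg.p) / cfg.N_E)
        assert abs(in_deg.mean() - expected) < 3 * sem
        assert np.all(np.abs(in_deg - expected) < 5 * np.sqrt(expected * 0.8))

    def test_no_self_connections(self, rng):
        net = build_network(NetworkConfig.scaled(C=5, N_C=20), rng)
        assert not np.diag(net.mask_EE).any()
        assert not np.diag(net.mask_II).any()

    def test_initial_weights_at_table_values(self, rng):
        cfg = NetworkConfig.scaled(C=5, N_C=20, N_R=3)
        net = build_network(cfg, rng)
        assert np.all(net.W_EE[net.mask_EE] == cfg.w0_EE)
        assert np.all(net.W_EI[net.mask_EI] == cfg.w0_EI)
        assert np.all(net.W_RE == 0.0)      # read-out starts silent
        assert net.mask_RE.all()            # but all-to-all plastic

    def test_degenerate_empty_topology_fails_at_normalization(self, rng):
        net = build_network(NetworkConfig(N_E=60, N_I=15, C=3, p=0.0), rng)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_incoming(net.W_EE, net.mask_EE, net.K, 1.45, 32.68)


class TestClockConstruction:
    def test_weight_split_preserves_l1_budget(self):
        cfg = NetworkConfig.reference()
        w_in, w_ff = clock_weight_split(cfg)
        w_min = cfg.stdp_ee.w_min
        total = cfg.p * ((cfg.N_E - 2 * cfg.N_C) * w_min
                         + cfg.N_C * (w_in + w_ff))
        assert np.isclose(total, cfg.norm_target)

    def test_block_structure(self, rng):
        cfg = NetworkConfig.scaled(C=5, N_C=20)
        net = make_clock_network(cfg, rng, w_intra=10.0, w_ff=7.0)
        cl = net.clusters
        same = cl[:, None] == cl[None, :]
        succ = cl[:, None] == (cl[None, :] + 1) % cfg.C
        m = net.mask_EE
        assert np.all(net.W_EE[same & m] == 10.0)
        assert np.all(net.W_EE[succ & m] == 7.0)
        assert np.all(net.W_EE[~(same | succ) & m] == cfg.stdp_ee.w_min)


class TestSimulatorContracts:
    def test_zero_duration_run_is_identity(self, rng):
        net = build_network(NetworkConfig.scaled(C=5, N_C=10), rng)
        W0 = net.W_EE.copy()
        sim = Simulator(net, seed=0)
        raster = sim.run(0.0, protocol=SpontaneousProtocol(),
                         plasticity=PlasticityFlags(ee=True))
        assert raster.n_spikes("E") == 0
        np.testing.assert_array_equal(net.W_EE, W0)

    def test_identical_seeds_identical_runs(self):
        cfg = NetworkConfig.scaled(C=5, N_C=10)

        def one_run():
            net = build_network(cfg, np.random.default_rng(7))
            sim = Simulator(net, seed=11)
            raster = sim.run(500.0, protocol=SpontaneousProtocol(),
                             plasticity=PlasticityFlags(ee=True, ei=True))
            return raster, net.W_EE.copy()

        r1, w1 = one_run()
        r2, w2 = one_run()
        np.testing.assert_array_equal(r1.times["E"], r2.times["E"])
        np.testing.assert_array_equal(r1.ids["E"], r2.ids["E"])
        np.testing.assert_array_equal(w1, w2)

    def test_frozen_plasticity_keeps_weights_bitwise(self, rng):
        net = build_network(NetworkConfig.scaled(C=5, N_C=10), rng)
        W0 = net.W_EE.copy()
        EI0 = net.W_EI.copy()
        Simulator(net, seed=3).run(500.0, protocol=SpontaneousProtocol())
        np.testing.assert_array_equal(net.W_EE, W0)
        np.testing.assert_array_equal(net.W_EI, EI0)

    def test_weights_respect_bounds_and_topology_during_training(self, rng):
        cfg = NetworkConfig.scaled(C=5, N_C=10)
        net = build_network(cfg, rng)
        sim = Simulator(net, seed=5)
        from seqclock.protocols import Stage1Protocol
        proto = Stage1Protocol(cfg.C, stim_ms=10, gap_ms=5)
        for _ in range(5):
            sim.run(100.0, protocol=proto,
                    plasticity=PlasticityFlags(ee=True, ei=True))
            m = net.mask_EE
            assert np.all(net.W_EE[~m] == 0.0)
            assert np.all(net.W_EE[m] >= cfg.stdp_ee.w_min - 1e-12)
            assert np.all(net.W_EE[m] <= cfg.stdp_ee.w_max + 1e-12)
            assert np.all(net.W_EI[~net.mask_EI] == 0.0)
            assert np.all(net.W_EI[net.mask_EI] <= cfg.inh_plasticity.w_max)

    def test_one_to_one_supervisor_wiring(self, rng):
        """A supervisor spike raises only its paired read-out conductance."""
        cfg = NetworkConfig.scaled(C=5, N_C=10, N_R=3)
        net = build_network(cfg, rng)
        sim = Simulator(net, seed=0)
        sim._prev_idx["S"] = np.array([1])
        # two steps: the difference-of-exponentials kernel starts at zero
        sim.run(0.2)
        g = sim.cond["R_exc"].g
        assert g[1] > 0 and g[0] == 0 and g[2] == 0


class TestSynfireChain:
    def test_chain_topology(self):
        net = make_synfire_chain(n=10, w_chain=50.0, circular=False)
        assert net.mask_EE.sum() == 9
        assert np.all(np.diag(net.mask_EE, k=-1))

    def test_readout_bound_raised(self):
        net = make_synfire_chain(n=10, N_R=2)
        assert net.cfg.stdp_re.w_max == 75.0


class TestDeletion:
    def test_counting_audit(self, rng):
        cfg = NetworkConfig.scaled(C=5, N_C=20, N_R=2)
        net = build_network(cfg, rng)
        net.W_RE[:] = 1.0
        W, mask = delete_readout_synapses(net.W_RE, net.mask_RE, net.clusters,
                                          4, rng)
        assert (W == 0).sum() - (net.W_RE == 0).sum() == 4 * cfg.C * cfg.N_R
        assert (~mask).sum() == 4 * cfg.C * cfg.N_R

    def test_zero_deletion_is_identity(self, rng):
        cfg = NetworkConfig.scaled(C=5, N_C=20, N_R=2)
        net = build_network(cfg, rng)
        W, mask = delete_readout_synapses(net.W_RE, net.mask_RE, net.clusters,
                                          0, rng)
        np.testing.assert_array_equal(mask, net.mask_RE)

    def test_full_deletion_silences_cluster(self, rng):
        cfg = NetworkConfig.scaled(C=5, N_C=20, N_R=2)
        net = build_network(cfg, rng)
        W, mask = delete_readout_synapses(net.W_RE, net.mask_RE, net.clusters,
                                          cfg.N_C, rng)
        assert not mask[:, net.clusters == 0].any()

    def test_overdeletion_rejected(self, rng):
        cfg = NetworkConfig.scaled(C=5, N_C=20, N_R=2)
        net = build_network(cfg, rng)
        with pytest.raises(ValueError):
            delete_readout_synapses(net.W_RE, net.mask_RE, net.clusters,
                                    cfg.N_C + 1, rng)
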