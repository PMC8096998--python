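import numpy as np
import pytest

from spikewm.circuit import (
    Circuit,
    CircuitConfig,
    ROLE_DETECTOR,
    ROLE_INH,
    ROLE_INPUT,
    SpikeRaster,
    build_circuit,
    run,
)
from oracles import reference_network_sim


class TestBuild:
    def test_default_synapse_counts(self):
        c = build_circuit(seed=0)
        # full E-E connectivity, no self-loops, 4 synapses per ordered pair
        assert int(c.plastic.sum()) == 24 * 23 * 4 == 2208
        assert c.n == 24 + 6 + 2
        # no I-I connections and detectors project nowhere
        for s in range(c.S):
            pre_role = c.roles[c.pre[s]]
            post_role = c.roles[c.post[s]]
            assert not (pre_role == ROLE_INH and post_role == ROLE_INH)
            assert pre_role != ROLE_DETECTOR

    def test_delay_structure(self):
        c = build_circuit(seed=1)
        ee = c.plastic
        d = c.delay[ee]
        k = c.syn_k[ee]
        base = d - 3.0 * k
        # base delay shared by the 4 synapses of a connection, in [3, 12]
        assert base.min() >= 3.0 and base.max() <= 12.0
        assert set(np.unique(k)) == {0, 1, 2, 3}
        ei = ~c.plastic & (c.roles[c.post] != ROLE_DETECTOR)
        assert c.delay[ei].min() >= 1.0 and c.delay[ei].max() <= 20.0

    def test_mean_ee_delay_near_12ms(self):
        ds = [build_circuit(seed=s).delay[build_circuit(seed=s).plastic]
              for s in range(5)]
        grand = np.concatenate(ds).mean()
        assert grand == pytest.approx(12.0, abs=0.5)

    def test_initial_weights_uniform(self):
        c = build_circuit(seed=2)
        w = c.ee_weights()
        assert w.min() >= 0.0 and w.max() <= 0.14
        assert w.mean() == pytest.approx(0.07, abs=0.01)

    def test_same_seed_bitwise_identical(self):
        a = build_circuit(seed=7)
        b = build_circuit(seed=7)
        assert np.array_equal(a.w, b.w)
        assert np.array_equal(a.delay, b.delay)
        assert np.array_equal(a.pre, b.pre)
        assert np.array_equal(a.noise_mean, b.noise_mean)

    def test_noise_seed_changes_only_the_stream(self):
        a = build_circuit(seed=7, noise_seed=1)
        b = build_circuit(seed=7, noise_seed=2)
        assert np.array_equal(a.w, b.w)
        assert np.array_equal(a.noise_mean, b.noise_mean)
        ra = a.run(200.0)
        rb = b.run(200.0)
        assert not (len(ra) == len(rb)
                    and np.array_equal(ra.times, rb.times)
                    and np.array_equal(ra.neurons, rb.neurons))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            CircuitConfig(N_input=30, N_E=24)

    def test_noise_baselines_in_range(self):
        c = build_circuit(seed=3)
        circ = np.concatenate([c.exc_idx, c.inh_idx])
        assert c.noise_mean[circ].min() >= 1.5
        assert c.noise_mean[circ].max() <= 2.0
        assert (c.noise_mean[c.det_idx] == 0).all()


class TestRun:
    def test_zero_noise_no_input_is_silent(self, micro_cfg_quiet):
        c = build_circuit(micro_cfg_quiet)
        raster = c.run(500.0)
        assert len(raster) == 0

    def test_weights_frozen_without_excitatory_spikes(self, micro_cfg_quiet):
        c = build_circuit(micro_cfg_quiet)
        w0 = c.ee_weights()
        c.run(500.0)
        assert np.array_equal(w0, c.ee_weights())

    def test_baseline_low_rate_irregular(self):
        c = build_circuit(seed=4)
        raster = c.run(1000.0)
        circ = np.concatenate([c.exc_idx, c.inh_idx])
        rates = raster.counts(neurons=circ)
        assert 0.3 < rates.mean() < 20.0  # low-rate ground state, not silent

    def test_identical_seeds_identical_rasters(self):
        a = build_circuit(seed=5)
        b = build_circuit(seed=5)
        ra, rb = a.run(500.0), b.run(500.0)
        assert np.array_equal(ra.times, rb.times)
        assert np.array_equal(ra.neurons, rb.neurons)

    def test_chained_runs_equal_single_run(self):
        a = build_circuit(seed=6)
        b = build_circuit(seed=6)
        r1 = a.run(300.0)
        r2 = a.run(200.0)
        rb = b.run(500.0)
        times = np.concatenate([r1.times, r2.times])
        neurons = np.concatenate([r1.neurons, r2.neurons])
        assert np.array_equal(times, rb.times)
        assert np.array_equal(neurons, rb.neurons)
        assert np.array_equal(a.w, b.w)

    def test_forced_spike_outside_run_rejected(self, micro_cfg_quiet):
        c = build_circuit(micro_cfg_quiet)
        with pytest.raises(ValueError):
            c.run(100.0, forced_spikes=[(150.0, 0)])

    def test_module_level_run_wrapper(self, micro_cfg_quiet):
        c = build_circuit(micro_cfg_quiet)
        raster = run(c, 100.0, forced_spikes=[(10.0, 0)])
        assert len(raster) >= 1


class TestEngineAgainstReference:
    def test_matches_object_level_rescan_oracle(self, micro_cfg_quiet):
        """The vectorized event-queue engine reproduces, spike for spike
        and weight for weight, a brute-force simulation that rescans the
        full arrival history every tick (5 neurons, 200 ms, no noise)."""
        forced = [(float(t), n) for t in (10.0, 70.0, 130.0)
                  for n in (0, 1, 2)]
        offsets = np.zeros(7)
        offsets[:4] = 3.0  # mild drive so recurrent spikes occur too
        ref_c = build_circuit(micro_cfg_quiet)
        ref_t, ref_n, ref_w = reference_network_sim(
            ref_c, 200.0, forced_spikes=forced, offsets=offsets)
        c = build_circuit(micro_cfg_quiet)
        raster = c.run(200.0, forced_spikes=forced, offsets=offsets)
        assert np.array_equal(raster.times, ref_t)
        assert np.array_equal(raster.neurons, ref_n)
        assert np.allclose(c.w, ref_w, atol=1e-9)


class TestSpikeRaster:
    def test_counts_window_half_open(self):
        r = SpikeRaster([10.0, 20.0, 20.0], [0, 1, 1], 0.0, 100.0,
                        roles=np.zeros(3, dtype=int))
        assert r.counts(t0=10.0, t1=20.0).tolist() == [1.0, 0.0, 0.0]
        assert r.counts()[1] == 2.0

    def test_select_and_concat(self):
        r1 = SpikeRaster([1.0], [0], 0.0, 10.0, roles=np.zeros(2, dtype=int))
        r2 = SpikeRaster([11.0], [1], 10.0, 20.0, roles=np.zeros(2, dtype=int))
        cat = SpikeRaster.concat([r1, r2])
        assert cat.duration == 20.0
        assert len(cat.select(neurons=[1])) == 1

    def test_roles_roundtrip_frame(self):
        c = build_circuit(seed=0)
        raster = c.run(100.0)
        df = raster.to_frame()
        assert set(df.columns) == {"time_ms", "neuron", "role"}
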