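"""The weight-dependent positive STDP rule, homeostasis and pre-training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from stdpnet.encoding import ImageSample, poisson_encode
from stdpnet.network import LayerParams, SpikingNetwork, forward_pass
from stdpnet.stdp import (
    HomeostasisConfig,
    PreTrace,
    STDPConfig,
    adapt_thresholds,
    apply_conv_stdp,
    pretrain_all,
    pretrain_layer,
    stdp_delta,
    update_trace,
)


def _conv_params(n_out=1, n_in=1, k=3, w=0.0, fan_in=None):
    p = LayerParams(kind="conv", weights=np.full((n_out, n_in, k, k), float(w)),
                    kernel_size=k, n_out=n_out, fan_in=fan_in or n_in * k * k)
    return p


class TestPreTrace:
    def test_single_silent_step_decay(self):
        tr = PreTrace(np.array([1.0]))
        update_trace(tr, np.array([0]), dt_ms=1.0, tau_pre_ms=1.5)
        np.testing.assert_allclose(tr.values[0], np.exp(-1 / 1.5), rtol=1e-12)

    def test_reset_to_one_on_spike_regardless_of_history(self):
        tr = PreTrace(np.array([0.02, 0.9]))
        update_trace(tr, np.array([1, 1]))
        np.testing.assert_array_equal(tr.values, [1.0, 1.0])

    def test_ten_silent_steps_from_one(self):
        tr = PreTrace(np.array([1.0]))
        for _ in range(10):
            update_trace(tr, np.array([0]), 1.0, 1.5)
        np.testing.assert_allclose(tr.values[0], np.exp(-10 / 1.5), rtol=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=40))
    def test_matches_closed_form_for_arbitrary_spike_pattern(self, pattern):
        # after the last spike the trace equals exp(-elapsed/tau); with no
        # spikes at all it stays at its initial decayed value
        tau = 1.5
        tr = PreTrace(np.array([0.0]))
        last_spike = None
        for t, spk in enumerate(pattern):
            update_trace(tr, np.array([int(spk)]), 1.0, tau)
            if spk:
                last_spike = t
        if last_spike is None:
            assert tr.values[0] == 0.0
        else:
            elapsed = len(pattern) - 1 - last_spike
            np.testing.assert_allclose(tr.values[0], np.exp(-elapsed / tau), rtol=1e-9)

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            update_trace(PreTrace(np.array([0.5])), np.array([0]), 1.0, 0.0)


class TestSTDPDelta:
    def test_zero_at_weight_bounds(self):
        cfg = STDPConfig(eta_stdp=0.01, chi_offset=0.4)
        for trace in [0.0, 0.4, 1.0]:
            assert stdp_delta(trace, 1.0, cfg, -1.0, 1.0) == 0.0
            assert stdp_delta(trace, -1.0, cfg, -1.0, 1.0) == 0.0

    def test_zero_at_chi_offset_crossing(self):
        cfg = STDPConfig(eta_stdp=0.01, chi_offset=0.4)
        assert stdp_delta(0.4, 0.3, cfg, -1.0, 1.0) == 0.0

    def test_coincident_spike_value(self):
        # eta=0.01, trace=1, chi=0.4, w=0, bounds +-1 -> 0.01*0.6*1*1
        cfg = STDPConfig(eta_stdp=0.01, chi_offset=0.4)
        np.testing.assert_allclose(stdp_delta(1.0, 0.0, cfg, -1, 1), 0.006, rtol=1e-12)

    def test_sign_structure_over_grid(self):
        # sign(dw) == sign(trace - chi) strictly inside the bounds
        cfg = STDPConfig(eta_stdp=0.01, chi_offset=0.4)
        traces = np.linspace(0, 1, 50)
        ws = np.linspace(-0.99, 0.99, 50)
        for tr in traces:
            d = stdp_delta(tr, ws, cfg, -1, 1)
            if tr > cfg.chi_offset:
                assert (d > 0).all()
            elif tr < cfg.chi_offset:
                assert (d < 0).all()
            else:
                assert (d == 0).all()

    def test_magnitude_maximized_at_midpoint_weight(self):
        cfg = STDPConfig(eta_stdp=0.01, chi_offset=0.4)
        w_min, w_max = -0.3, 0.7
        mid = 0.5 * (w_min + w_max)
        ws = np.linspace(w_min, w_max, 101)
        d = np.abs(stdp_delta(1.0, ws, cfg, w_min, w_max))
        assert np.argmax(d) == 50  # the midpoint of the grid
        assert d.max() == pytest.approx(
            np.abs(stdp_delta(1.0, mid, cfg, w_min, w_max))
        )


class TestApplyConvSTDP:
    def _trace(self, shape, value=1.0):
        return PreTrace(np.full(shape, value))

    def test_no_post_spikes_no_change(self):
        p = _conv_params(w=0.1)
        cfg = STDPConfig(eta_stdp=0.01, w_min=-1, w_max=1)
        before = p.weights.copy()
        apply_conv_stdp(p, np.zeros((1, 4, 4), dtype=np.uint8), self._trace((1, 6, 6)), cfg)
        np.testing.assert_array_equal(p.weights, before)

    def test_single_post_all_traces_one_reduces_to_delta(self):
        p = _conv_params(w=0.0)
        cfg = STDPConfig(eta_stdp=0.01, chi_offset=0.4, w_min=-1, w_max=1)
        post = np.zeros((1, 4, 4), dtype=np.uint8)
        post[0, 2, 1] = 1
        apply_conv_stdp(p, post, self._trace((1, 6, 6)), cfg)
        np.testing.assert_allclose(p.weights, 0.006, rtol=1e-12)

    def test_two_post_spikes_average_against_loop_oracle(self):
        rng = np.random.default_rng(0)
        p = _conv_params(n_out=2, n_in=2, k=3)
        p.weights = rng.uniform(-0.5, 0.5, p.weights.shape)
        trace = PreTrace(rng.random((2, 6, 6)))
        post = np.zeros((2, 4, 4), dtype=np.uint8)
        post[0, 1, 1] = post[0, 3, 2] = 1  # two spiking locations in map 0
        post[1, 0, 0] = 1
        cfg = STDPConfig(eta_stdp=0.05, chi_offset=0.4, w_min=-1, w_max=1)
        expected = oracles.stdp_kernel_update_loops(
            p.weights, post, trace.values, 0.05, 0.4, -1.0, 1.0
        )
        apply_conv_stdp(p, post, trace, cfg)
        np.testing.assert_allclose(p.weights, expected, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), eta=st.floats(0.001, 5.0))
    def test_bounds_preserved_under_any_update_sequence(self, seed, eta):
        rng = np.random.default_rng(seed)
        p = _conv_params(n_out=2, k=2)
        p.weights = rng.uniform(-1, 1, p.weights.shape)
        cfg = STDPConfig(eta_stdp=eta, chi_offset=0.4, w_min=-1, w_max=1)
        for _ in range(20):
            post = (rng.random((2, 5, 5)) < 0.4).astype(np.uint8)
            trace = PreTrace(rng.random((1, 6, 6)))
            apply_conv_stdp(p, post, trace, cfg)
            assert (p.weights >= -1).all() and (p.weights <= 1).all()

    def test_shape_mismatch_rejected(self):
        p = _conv_params()
        cfg = STDPConfig()
        with pytest.raises(ValueError):
            apply_conv_stdp(p, np.zeros((2, 4, 4), dtype=np.uint8),
                            self._trace((1, 6, 6)), cfg)


class TestHomeostasis:
    def test_spiking_map_gains_increment(self):
        th = np.full((1, 1, 1), 1.0)
        floor = np.full((1, 1, 1), 1.0)
        post = np.ones((1, 2, 2), dtype=np.uint8)
        cfg = HomeostasisConfig(theta_plus_rel=0.05, tau_theta_ms=100)
        out = adapt_thresholds(th, post, cfg, floor)
        np.testing.assert_allclose(out, 1.05)

    def test_silent_map_at_floor_stays(self):
        th = np.full((1, 1, 1), 1.0)
        floor = np.full((1, 1, 1), 1.0)
        out = adapt_thresholds(th, np.zeros((1, 2, 2), dtype=np.uint8),
                               HomeostasisConfig(), floor)
        np.testing.assert_allclose(out, 1.0)

    def test_silent_map_relaxes_exponentially(self):
        th = np.full((1, 1, 1), 2.0)
        floor = np.full((1, 1, 1), 1.0)
        cfg = HomeostasisConfig(theta_plus_rel=0.05, tau_theta_ms=100)
        out = adapt_thresholds(th, np.zeros((1, 2, 2), dtype=np.uint8), cfg, floor, 1.0)
        np.testing.assert_allclose(out, 1.0 + np.exp(-0.01), rtol=1e-12)

    def test_firing_rate_non_increasing_in_theta_plus(self):
        # under constant drive, stronger homeostasis never raises the rate
        img = np.zeros((8, 8))
        img[3:5, :] = 1.0
        samples = [ImageSample(img, 0)] * 20
        rates = []
        for theta_plus in (0.0, 0.1, 0.5):
            net = SpikingNetwork.build("8x8-2C3-2P-2FC", np.random.default_rng(1))
            pretrain_layer(
                net, 0, samples, STDPConfig(eta_stdp=0.002),
                HomeostasisConfig(theta_plus_rel=theta_plus),
                np.random.default_rng(2),
            )
            rng = np.random.default_rng(3)
            total = 0
            for _ in range(5):
                r = poisson_encode(samples[0], 200, 25, 1, rng)
                total += forward_pass(net, r).spikes[1].mean()
            rates.append(total)
        assert rates[0] >= rates[1] >= rates[2]


class TestPretraining:
    def test_zero_intensity_samples_leave_kernels_untouched(self):
        net = SpikingNetwork.build("8x8-2C3-2P-2FC", np.random.default_rng(0))
        before = net.params[0].weights.copy()
        samples = [ImageSample(np.zeros((8, 8)), 0)] * 5
        pretrain_layer(net, 0, samples, STDPConfig(), HomeostasisConfig(),
                       np.random.default_rng(1))
        np.testing.assert_array_equal(net.params[0].weights, before)

    def test_bar_drives_potentiation_on_deterministic_raster(self):
        # bar spanning exactly the kernel height, deterministic encoding
        # (1000 Hz at dt=1 -> every bright pixel spikes every step); the
        # threshold admits only the fully-covered window row, whose kernel
        # coordinates all see trace 1 -> every weight strictly increases
        img = np.zeros((8, 8))
        img[3:6, :] = 1.0
        net = SpikingNetwork.build("8x8-1C3-2FC", np.random.default_rng(2))
        c = 0.2
        net.params[0].weights = np.full((1, 1, 3, 3), c)
        # steady-state currents: 9c/(1-d) full window vs 6c/(1-d) partial
        d = np.exp(-0.1)
        net.params[0].thresholds = np.full((1, 1, 1), (7.5 * c) / (1 - d))
        before = net.params[0].weights.copy()
        pretrain_layer(
            net, 0, [ImageSample(img, 0)] * 3,
            STDPConfig(eta_stdp=0.01, w_min=-0.6, w_max=0.6),
            HomeostasisConfig(theta_plus_rel=0.0),
            np.random.default_rng(3), present_ms=25, max_rate_hz=1000,
        )
        assert (net.params[0].weights > before).all()

    def test_depression_for_stale_traces(self):
        # post fires while some pre-units under the kernel never spiked:
        # their trace is 0 < chi, so those coordinates depress
        p = _conv_params(w=0.2)
        trace = PreTrace(np.zeros((1, 6, 6)))
        trace.values[0, :2, :] = 1.0  # only the top rows recently spiked
        post = np.zeros((1, 4, 4), dtype=np.uint8)
        post[0, 0, 0] = 1
        cfg = STDPConfig(eta_stdp=0.01, chi_offset=0.4, w_min=-1, w_max=1)
        before = p.weights.copy()
        apply_conv_stdp(p, post, trace, cfg)
        assert (p.weights[0, 0, :2, :] > before[0, 0, :2, :]).all()
        assert (p.weights[0, 0, 2, :] < before[0, 0, 2, :]).all()

    def test_weights_stay_in_bounds_after_many_presentations(self):
        img = np.zeros((8, 8))
        img[2:6, 2:6] = 1.0
        net = SpikingNetwork.build("8x8-2C3-2FC", np.random.default_rng(4))
        cfg = STDPConfig(eta_stdp=2.0)  # absurdly large learning rate
        lo, hi = cfg.bounds_for(net.params[0])
        pretrain_layer(net, 0, [ImageSample(img, 0)] * 50, cfg, HomeostasisConfig(),
                       np.random.default_rng(5))
        w = net.params[0].weights
        assert (w >= lo - 1e-12).all() and (w <= hi + 1e-12).all()

    def test_rejects_non_conv_target(self):
        net = SpikingNetwork.build("8x8-2C3-2P-2FC", np.random.default_rng(0))
        with pytest.raises(ValueError, match="not conv"):
            pretrain_layer(net, 1, [], STDPConfig(), HomeostasisConfig(),
                           np.random.default_rng(0))

    def test_greedy_pretrain_freezes_fc_and_lower_layers(self):
        net = SpikingNetwork.build("12x12-2C3-2P-2C3-3FC", np.random.default_rng(6))
        fc_before = net.params[3].weights.copy()
        fc_th_before = net.params[3].thresholds.copy()
        img = np.zeros((12, 12))
        img[4:8, :] = 1.0
        conv1_after_phase1 = None

        pretrain_all(net, [ImageSample(img, 0)] * 10,
                     STDPConfig(eta_stdp=0.05), HomeostasisConfig(),
                     np.random.default_rng(7))
        np.testing.assert_array_equal(net.params[3].weights, fc_before)
        np.testing.assert_array_equal(net.params[3].thresholds, fc_th_before)

    def test_pretrain_all_on_fc_only_net_is_identity(self):
        net = SpikingNetwork.build("4x4-3FC", np.random.default_rng(8))
        before = net.params[0].weights.copy()
        pretrain_all(net, [], STDPConfig(), HomeostasisConfig(),
                     np.random.default_rng(9))
        np.testing.assert_array_equal(net.params[0].weights, before)

    def test_map_selectivity_emerges_more_often_than_chance(self):
        # two well-separated templates, two feature maps: after pre-training
        # the maps' preferred templates (row-wise argmax of the mean-rate
        # preference matrix) differ more often than the 50% chance level
        h = np.zeros((8, 8)); h[3:5, :] = 1.0
        v = np.zeros((8, 8)); v[:, 3:5] = 1.0
        tpls = [ImageSample(h, 0), ImageSample(v, 1)]
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            net = SpikingNetwork.build("8x8-2C3-2P-2FC", np.random.default_rng(seed + 100))
            pretrain_layer(net, 0, [tpls[i % 2] for i in range(80)],
                           STDPConfig(eta_stdp=0.05), HomeostasisConfig(), rng)
            pref = np.zeros((2, 2))
            for j, tp in enumerate(tpls):
                for _ in range(8):
                    r = poisson_encode(tp, 200, 25, 1, rng)
                    pref[:, j] += forward_pass(net, r).spikes[1].mean(axis=(1, 2, 3))
            row_pref = pref.argmax(axis=1)
            wins += int(row_pref[0] != row_pref[1])
        assert wins > 5
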