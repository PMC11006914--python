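import numpy as np
import pytest

from axospindle import slowwaves as sw

FS = 25000.0


class TestTroughDetection:
    def test_sinusoid_minima_recovered(self):
        t = np.arange(0, 10, 1 / FS)
        x = 400.0 * np.sin(2 * np.pi * 1.5 * t)
        times, amps = sw.detect_slow_troughs(x, FS)
        # minima at (k + 3/4) / 1.5 within the 10 s window
        expected = (np.arange(15) + 0.75) / 1.5
        assert times.size == 15
        np.testing.assert_allclose(times, expected, atol=0.002)
        assert np.all(amps < -100.0)

    def test_narrow_spikes_rejected_by_width(self, rng):
        t = np.arange(0, 10, 1 / FS)
        x = 400.0 * np.sin(2 * np.pi * 1.5 * t)
        # 1 ms-wide -800 uV deflections between the slow troughs
        for t0 in np.arange(0.33, 10, 1.0):
            k = int(t0 * FS)
            x[k:k + 25] -= 800.0
        times, _ = sw.detect_slow_troughs(x, FS)
        assert times.size == 15  # only the genuine slow minima

    def test_low_amplitude_fails_floor(self):
        t = np.arange(0, 10, 1 / FS)
        times, _ = sw.detect_slow_troughs(80.0 * np.sin(2 * np.pi * 1.5 * t),
                                          FS)
        assert times.size == 0


class TestSoEpochs:
    def test_rank_selection_top_40pct(self):
        # 10 epochs of increasing amplitude: only ranks 7-10 retained
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        x = np.zeros_like(t)
        for k in range(10):
            seg = (t >= k) & (t < k + 1)
            x[seg] = (k + 1) * np.sin(2 * np.pi * 1.0 * (t[seg] - k))
        # closing upward half-cycle so the 10th epoch has a right boundary
        tail = 0.2 * np.sin(2 * np.pi * np.arange(500) / 1000.0)
        evs = sw.detect_so_epochs(np.concatenate([x, tail]), fs,
                                  prefiltered=True)
        assert len(evs) == 4
        assert sorted(round(e.peak_uv) for e in evs) == [7, 8, 9, 10]

    def test_epoch_ordering_invariant(self):
        fs = 1000.0
        t = np.arange(0, 20, 1 / fs)
        x = 300.0 * np.sin(2 * np.pi * 1.0 * t)
        for e in sw.detect_so_epochs(x, fs):
            assert e.peak_s < e.zero_cross_s < e.trough_s

    def test_identical_epochs_all_retained(self):
        fs = 1000.0
        t = np.arange(0, 20, 1 / fs)
        x = 300.0 * np.sin(2 * np.pi * 1.0 * t)
        evs = sw.detect_so_epochs(x, fs, prefiltered=True)
        # every full cycle qualifies (ties kept)
        assert len(evs) >= 18

    def test_few_epochs_warns_and_keeps_all(self):
        fs = 1000.0
        t = np.arange(0, 2, 1 / fs)
        x = 300.0 * np.sin(2 * np.pi * 1.0 * t)
        with pytest.warns(UserWarning):
            sw.detect_so_epochs(x, fs)


class TestPairing:
    def test_constant_offset_recovered(self):
        up = np.arange(1.0, 100.0, 1.0)
        down = up + 0.00132
        delays, uu, ud = sw.pair_troughs(up, down)
        assert delays.size == up.size
        assert delays.mean() == pytest.approx(1.32, abs=1e-6)
        assert uu.size == ud.size == 0

    def test_excessive_shift_gives_no_pairs(self):
        up = np.arange(1.0, 50.0, 1.0)
        delays, uu, ud = sw.pair_troughs(up, up + 0.008)
        assert delays.size == 0
        assert uu.size == ud.size == 49

    def test_extras_reported_unmatched(self):
        up = np.arange(1.0, 50.0, 1.0)
        down = np.sort(np.concatenate([up + 0.001,
                                       np.arange(1.5, 50.0, 1.0)]))
        delays, uu, ud = sw.pair_troughs(up, down)
        assert delays.size == up.size
        assert ud.size == 49

    def test_order_independence(self, rng):
        up = rng.uniform(0, 100, 50)
        down = rng.uniform(0, 100, 60)
        d1, *_ = sw.pair_troughs(up, down)
        d2, *_ = sw.pair_troughs(rng.permutation(up), rng.permutation(down))
        np.testing.assert_allclose(d1, d2)


class TestDelaySummary:
    def test_printed_feedback_example(self):
        cmp = sw.summarize_delays(np.full(15, 0.35), np.full(15, 1.32))
        assert cmp.spike_velocity_m_s == pytest.approx(0.57)
        assert cmp.slow_velocity_m_s == pytest.approx(0.15)
        assert cmp.percent_slower == pytest.approx(74.0)

    def test_printed_feedforward_example(self):
        cmp = sw.summarize_delays(np.full(5, 0.4), np.full(5, 0.86))
        assert cmp.spike_velocity_m_s == pytest.approx(0.5)
        assert cmp.slow_velocity_m_s == pytest.approx(0.23)
        assert cmp.percent_slower == pytest.approx(54.0)

    def test_identical_delays_no_difference(self):
        cmp = sw.summarize_delays(np.full(5, 0.5), np.full(5, 0.5))
        assert cmp.percent_slower == 0.0
        assert cmp.p_value == 1.0

    def test_significant_separation(self, rng):
        sp = 0.4 + rng.normal(0, 0.02, 15)
        sl = 1.3 + rng.normal(0, 0.1, 15)
        cmp = sw.summarize_delays(sp, sl)
        assert cmp.p_value < 1e-4

    def test_exclusion_rule(self):
        est = sw.estimate_delay(np.array([1.0, 1.0, 1.0]), 0.2)
        assert est.excluded and "zero" in est.exclusion_reason
        est = sw.estimate_delay(np.array([0.1, 4.0, -3.5, 2.9]), 0.2)
        assert est.excluded and "exceeds" in est.exclusion_reason
        est = sw.estimate_delay(0.86 + np.random.default_rng(0).normal(
            0, 0.05, 30), 0.2)
        assert not est.excluded


class TestAttenuation:
    def test_equal_amplitudes_p_one(self):
        near = np.full(5, -650.0)
        res = sw.amplitude_attenuation_test(near, near.copy())
        assert res["p_value"] == 1.0
        assert res["mean_decline_uv"] == 0.0

    def test_noisy_decline_nonsignificant(self, rng):
        # decline from ~1420 to ~832 uV but with huge per-axon spread
        near = -(1420.0 + rng.normal(0, 900.0, 9))
        far = -(832.0 + rng.normal(0, 900.0, 9))
        res = sw.amplitude_attenuation_test(near, far)
        assert res["p_value"] > 0.05 or res["mean_decline_uv"] < 0

    def test_clean_decline_significant(self):
        near = -np.linspace(1400, 1440, 8)
        far = near + 500.0  # uniformly shallower
        res = sw.amplitude_attenuation_test(near, far)
        assert res["p_value"] < 0.001

    def test_single_axon_skipped(self):
        with pytest.warns(UserWarning):
            res = sw.amplitude_attenuation_test([-500.0], [-400.0])
        assert np.isnan(res["p_value"])


class TestDelayRecoveryOnSynth:
    def test_sw_delay_recovered(self, small_recording):
        rec, cmap, truth = small_recording
        tt = truth.tunnels["t0"]
        tu, _ = sw.detect_slow_troughs(rec.data[0], rec.rate_hz)
        td, _ = sw.detect_slow_troughs(rec.data[1], rec.rate_hz)
        delays, *_ = sw.pair_troughs(tu, td)
        assert delays.size > 30
        assert abs(delays.mean() - tt.sw_delay_ms) <= 0.25
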