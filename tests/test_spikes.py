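import numpy as np
import pytest

from axospindle import spikes

FS = 25000.0


def _biphasic(fs=FS):
    n1, n2 = int(0.0004 * fs), int(0.0008 * fs)
    return np.concatenate([-np.sin(np.pi * np.arange(n1) / n1),
                           0.35 * np.sin(np.pi * np.arange(n2) / n2)])


def _inject(noise, t_s, amp, fs=FS):
    x = noise.copy()
    tmpl = amp * _biphasic(fs)
    k = int(t_s * fs)
    x[k:k + tmpl.size] += tmpl
    return x


class TestDetectSpikes:
    def test_injected_spike_recovered(self, rng):
        x = _inject(rng.normal(0, 5.0, int(10 * FS)), 4.0, 60.0)
        evs = spikes.detect_spikes(x, FS)
        big = [e for e in evs if e.amplitude_uv < -50]
        assert len(big) == 1
        t_peak = 4.0 + np.argmin(_biphasic()) / FS
        assert abs(big[0].t_s - t_peak) < 0.0002
        assert big[0].amplitude_uv < 0

    def test_huge_artifact_caught_by_second_band(self, rng):
        sd = 5.0
        x = _inject(rng.normal(0, sd, int(10 * FS)), 4.0, 300 * sd)
        evs = spikes.detect_spikes(x, FS)
        assert any(e.amplitude_uv < -100 * sd for e in evs)

    def test_false_positive_rate_on_pure_noise(self, rng):
        # Gaussian tail bound: P(|x|>5 SD) expects < 5 events in 10 s
        x = rng.normal(0, 5.0, int(10 * FS))
        evs = spikes.detect_spikes(x, FS)
        assert len(evs) < 20

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError):
            spikes.detect_spikes(np.zeros(1000), FS)

    def test_refractory_lockout(self, rng):
        x = rng.normal(0, 5.0, int(2 * FS))
        x = _inject(x, 1.0, 60.0)
        x = _inject(x, 1.0003, 60.0)  # within the 1 ms lockout
        evs = [e for e in spikes.detect_spikes(x, FS)
               if e.amplitude_uv < -40]
        assert len(evs) == 1


def _events(times):
    return [spikes.SpikeEvent(channel_id="c", t_s=t, amplitude_uv=-50.0)
            for t in times]


class TestMatching:
    def test_constant_offset_concentrates_one_bin(self, rng):
        t = np.sort(rng.uniform(0, 100, 200))
        h = spikes.match_tunnel_spikes(_events(t), _events(t + 0.00042))
        assert h.matching_index == pytest.approx(1.0)
        k = int(np.argmax(h.counts))
        center = 0.5 * (h.bin_edges_ms[k] + h.bin_edges_ms[k + 1])
        assert abs(center - 0.42) <= 0.04
        assert h.counts[k] == 200

    def test_independent_trains_rarely_match(self, rng):
        a = np.sort(rng.uniform(0, 300, 300))
        b = np.sort(rng.uniform(0, 300, 300))
        h = spikes.match_tunnel_spikes(_events(a), _events(b), max_lag_ms=2.0)
        # chance coincidence rate ~ 1 Hz * 4 ms = 0.4%
        assert h.matching_index < 0.05

    def test_subset_train_fraction(self):
        b = np.arange(0, 100, 0.5)
        a = b[::2]
        h = spikes.match_tunnel_spikes(_events(b + 0.0004), _events(a))
        # downstream side holds only |a| partners for |b| upstream spikes
        assert h.matching_index == pytest.approx(len(a) / len(b))

    def test_empty_inputs_empty_histogram(self):
        h = spikes.match_tunnel_spikes([], _events([1.0]))
        assert h.delays_ms.size == 0
        assert h.matching_index == 0.0

    def test_swap_symmetry_flips_sign(self, rng):
        a = np.sort(rng.uniform(0, 50, 100))
        b = a + 0.0006
        h1 = spikes.match_tunnel_spikes(_events(a), _events(b))
        h2 = spikes.match_tunnel_spikes(_events(b), _events(a))
        np.testing.assert_allclose(np.sort(h1.delays_ms),
                                   np.sort(-h2.delays_ms), atol=1e-9)


class TestIdentifyAxons:
    def _hist(self, delays_ms):
        evs_u = _events(np.arange(len(delays_ms)) * 1.0)
        evs_d = _events(np.arange(len(delays_ms)) * 1.0
                        + np.asarray(delays_ms) / 1000.0)
        return spikes.match_tunnel_spikes(evs_u, evs_d)

    def test_unimodal_feedforward(self, rng):
        h = self._hist(0.40 + rng.normal(0, 0.02, 100))
        tracks = spikes.identify_axons(h, tunnel_id="t")
        assert len(tracks) == 1
        tr = tracks[0]
        assert tr.direction == "feedforward"
        assert tr.mean_delay_ms == pytest.approx(0.40, abs=0.02)
        assert tr.velocity_m_s == pytest.approx(0.5, abs=0.05)
        assert not tr.excluded

    def test_bimodal_opposite_directions(self, rng):
        d = np.concatenate([0.4 + rng.normal(0, 0.02, 80),
                            -0.8 + rng.normal(0, 0.02, 80)])
        rng.shuffle(d)
        tracks = spikes.identify_axons(self._hist(d))
        assert len(tracks) == 2
        dirs = {t.direction for t in tracks}
        assert dirs == {"feedforward", "feedback"}

    def test_zero_se_mode_excluded(self):
        # identical delays -> SE exactly 0 -> excluded
        h = self._hist([0.40] * 30)
        tracks = spikes.identify_axons(h)
        assert len(tracks) == 1
        assert tracks[0].excluded
        assert "zero" in tracks[0].exclusion_reason

    def test_empty_histogram(self):
        h = spikes.match_tunnel_spikes([], [])
        assert spikes.identify_axons(h) == []


class TestConductionVelocity:
    @pytest.mark.parametrize("delay,dist,expect", [
        (0.35, 0.2, 0.57),
        (0.4, 0.2, 0.5),
        (1.0, 1.0, 1.0),
        (0.86, 0.2, 0.23),
        (1.32, 0.2, 0.15),
    ])
    def test_printed_values(self, delay, dist, expect):
        assert spikes.conduction_velocity(delay, dist) == pytest.approx(
            expect)

    def test_nonpositive_delay_rejected(self):
        with pytest.raises(ValueError):
            spikes.conduction_velocity(0.0, 0.2)


class TestEndToEndDelayRecovery:
    def test_modal_delay_within_one_sample(self, small_recording):
        from axospindle import condition

        rec, cmap, truth = small_recording
        tt = truth.tunnels["t0"]
        up = spikes.detect_spikes(condition.bandpass_spike(rec.data[0]),
                                  rec.rate_hz, channel_id="u")
        dn = spikes.detect_spikes(condition.bandpass_spike(rec.data[1]),
                                  rec.rate_hz, channel_id="d")
        h = spikes.match_tunnel_spikes(up, dn)
        tracks = [t for t in spikes.identify_axons(h, tunnel_id="t0")
                  if not t.excluded]
        assert tracks
        assert abs(tracks[0].mean_delay_ms - tt.spike_delay_ms) <= 0.04
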