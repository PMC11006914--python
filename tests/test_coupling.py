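import numpy as np
import pytest

from axospindle import coupling
from axospindle.spikes import SpikeEvent
from axospindle.spindles import SpindleEvent

FS = 1000.0


def _brute_force_m(angles):
    """Oracle: minimum half-circle count by scanning all data directions."""
    a = np.mod(np.asarray(angles), 2 * np.pi)
    best = a.size
    for theta in a:
        inside = np.mod(a - theta, 2 * np.pi) < np.pi
        best = min(best, int(inside.sum()), int((~inside).sum()))
    return best


class TestHodgesAjne:
    def test_statistic_matches_brute_force(self, rng):
        for n in (11, 17, 23, 30):
            a = rng.uniform(0, 2 * np.pi, n)
            assert coupling.hodges_ajne_m(a) == _brute_force_m(a)

    def test_concentrated_quadrant_exact_p(self, rng):
        a = rng.uniform(0, np.pi / 2, 20)
        # m = 0 => p = (n - 0) * C(n,0) * 2^(1-n) = 20 * 2^-19
        assert coupling.hodges_ajne_test(a) == pytest.approx(20 * 2.0 ** -19)

    def test_antipodal_pairs_maximally_uniform(self):
        base = np.linspace(0, np.pi, 10, endpoint=False)
        a = np.concatenate([base, base + np.pi])
        assert coupling.hodges_ajne_test(a) == 1.0

    def test_type_i_error_calibrated(self, rng):
        rejections = sum(
            coupling.hodges_ajne_test(rng.uniform(0, 2 * np.pi, 10000)) < 0.05
            for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            coupling.hodges_ajne_test(np.zeros(5))


def _spindle(t0, t1):
    return SpindleEvent("c", t0, t1, peak_s=(t0 + t1) / 2)


class TestSpikePhase:
    def _tone_phase(self, freq=12.0, duration=60.0):
        t = np.arange(0, duration, 1 / FS)
        x = np.sin(2 * np.pi * freq * t)
        from axospindle.condition import hilbert_envelope

        _, ph = hilbert_envelope(x)
        return t, x, ph

    def test_spikes_at_peaks_land_in_90deg_bin(self):
        t, x, ph = self._tone_phase()
        peak_times = (np.arange(240) + 0.25) / 12.0  # sine peaks
        spikes = [SpikeEvent("c", ts, -50.0) for ts in peak_times]
        res = coupling.spike_phase_histogram(
            spikes, ph, FS, [_spindle(0.0, 60.0)])
        assert res.counts.sum() == res.n_spikes == len(spikes)
        assert res.resultant_length > 0.95
        assert abs(res.preferred_phase_deg - 90.0) < 10.0
        top = int(np.argmax(res.counts))
        assert res.bin_edges_deg[top] <= 90.0 <= res.bin_edges_deg[top + 1]

    def test_uniform_spikes_not_locked(self, rng):
        t, x, ph = self._tone_phase(duration=120.0)
        spikes = [SpikeEvent("c", ts, -50.0)
                  for ts in np.sort(rng.uniform(1, 119, 600))]
        res = coupling.spike_phase_histogram(
            spikes, ph, FS, [_spindle(0.0, 120.0)])
        assert res.resultant_length < 0.1
        assert res.p_omnibus > 0.05

    def test_bimodal_injection_detected(self, rng):
        t, x, ph = self._tone_phase(duration=120.0)
        # spike times at carrier phases 130 deg and 345 deg
        cyc = np.arange(100, 1300)
        t130 = (cyc + 130.0 / 360.0) / 12.0
        t345 = (cyc[::2] + 345.0 / 360.0) / 12.0
        spikes = [SpikeEvent("c", ts, -50.0)
                  for ts in np.sort(np.concatenate([t130, t345]))]
        res = coupling.spike_phase_histogram(
            spikes, ph, FS, [_spindle(0.0, 120.0)])
        assert res.p_omnibus < 0.01
        deg = res.phases_deg
        assert ((deg > 100) & (deg < 160)).sum() > 0.4 * deg.size

    def test_out_of_spindle_spikes_ignored(self):
        t, x, ph = self._tone_phase()
        spikes = [SpikeEvent("c", 30.0, -50.0), SpikeEvent("c", 45.0, -50.0)]
        res = coupling.spike_phase_histogram(spikes, ph, FS,
                                             [_spindle(29.0, 31.0)])
        assert res.n_spikes == 1

    def test_zero_spikes_empty_result(self):
        t, x, ph = self._tone_phase()
        res = coupling.spike_phase_histogram([], ph, FS,
                                             [_spindle(0.0, 10.0)])
        assert res.n_spikes == 0
        assert np.isnan(res.resultant_length)


class TestEffectSize:
    def test_flat_histograms_zero(self):
        c = np.ones((3, 50))
        assert coupling.phase_effect_size(c) == 0.0

    def test_constructed_ratio(self):
        # pooled range 0.02 with per-array SD 0.2 -> effect 0.1
        rng = np.random.default_rng(0)
        base = np.full(50, 1.0 / 50)
        rows = []
        for k in range(6):
            row = base + rng.normal(0, 0.01, 50)
            rows.append(np.abs(row))
        c = np.array(rows)
        effect = coupling.phase_effect_size(c)
        pooled = (c / c.sum(1, keepdims=True)).mean(0)
        sd = np.std(c / c.sum(1, keepdims=True), ddof=1)
        assert effect == pytest.approx((pooled.max() - pooled.min()) / sd)

    def test_scale_invariance(self, rng):
        c = rng.uniform(1, 10, (4, 50))
        assert coupling.phase_effect_size(2.0 * c) == pytest.approx(
            coupling.phase_effect_size(c))

    def test_single_array_rejected(self):
        with pytest.raises(ValueError):
            coupling.phase_effect_size(np.ones((1, 50)))


class TestEnvelopeCorrelation:
    def _env(self, rng, duration=100.0):
        t = np.arange(0, duration, 1 / FS)
        env = np.zeros_like(t)
        wins = []
        for c in np.arange(5, duration - 5, 10.0):
            env += 40.0 * np.exp(-0.5 * ((t - c) / 0.25) ** 2)
            wins.append(_spindle(c - 1.0, c + 1.0))
        return env, wins

    def test_identity_r_one_lag_zero(self, rng):
        env, wins = self._env(rng)
        c = coupling.spindle_envelope_correlation(env, env, wins, wins, FS)
        assert c.r == pytest.approx(1.0)
        assert c.best_lag_s == 0.0

    def test_known_delay_recovered(self, rng):
        env, wins = self._env(rng)
        envB = np.roll(env, 7)  # 7 ms
        winsB = [_spindle(w.start_s + 0.007, w.end_s + 0.007) for w in wins]
        c = coupling.spindle_envelope_correlation(env, envB, wins, winsB, FS)
        assert c.best_lag_s == pytest.approx(0.007, abs=1e-3)
        assert c.r > 0.99
        # minimum velocity bound from a 0.82 mm path
        assert round(0.82 / (c.best_lag_s * 1000.0), 1) == 0.1

    def test_independent_trains_weak(self, rng):
        t = np.arange(0, 100, 1 / FS)
        e1 = np.zeros_like(t)
        e2 = np.zeros_like(t)
        w1, w2 = [], []
        for c in np.sort(rng.uniform(2, 98, 10)):
            e1 += 40 * np.exp(-0.5 * ((t - c) / 0.25) ** 2)
            w1.append(_spindle(c - 1, c + 1))
        for c in np.sort(rng.uniform(2, 98, 10)):
            e2 += 40 * np.exp(-0.5 * ((t - c) / 0.25) ** 2)
            w2.append(_spindle(c - 1, c + 1))
        c = coupling.spindle_envelope_correlation(e1, e2, w1, w2, FS)
        assert abs(c.r) < 0.2

    def test_lag_sign_symmetry(self, rng):
        env, wins = self._env(rng)
        envB = np.roll(env, 12)
        winsB = [_spindle(w.start_s + 0.012, w.end_s + 0.012) for w in wins]
        cab = coupling.spindle_envelope_correlation(env, envB, wins, winsB,
                                                    FS)
        cba = coupling.spindle_envelope_correlation(envB, env, winsB, wins,
                                                    FS)
        assert cab.best_lag_s == pytest.approx(-cba.best_lag_s)
        assert cab.r == pytest.approx(cba.r, abs=1e-9)

    def test_all_zero_after_mask_invalid(self):
        env = np.ones(5000)
        c = coupling.spindle_envelope_correlation(env, env, [], [], FS)
        assert not c.valid
        assert np.isnan(c.r)


class TestGroupCompare:
    def test_separated_groups_significant(self, rng):
        g = {"a": rng.normal(0.8, 0.05, 10), "b": rng.normal(0.3, 0.05, 10)}
        res = coupling.correlation_group_compare(g)
        assert res["p"] < 1e-6

    def test_no_variance_notice(self):
        g = {"a": np.full(5, 0.5), "b": np.full(5, 0.5)}
        res = coupling.correlation_group_compare(g)
        assert "notice" in res

    def test_type_i_calibration(self, rng):
        hits = 0
        for _ in range(400):
            g = {k: rng.normal(0, 1, 8) for k in "abc"}
            from scipy.stats import f_oneway

            _, p = f_oneway(*g.values())
            hits += p < 0.05
        assert 0.02 <= hits / 400 <= 0.09

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            coupling.correlation_group_compare({"a": np.ones(3)})
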