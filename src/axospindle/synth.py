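"""Synthetic tunnel-MEA recordings with exact ground truth.

Each configured tunnel yields two 25 kHz channels emulating the paired
electrodes (200 um apart) of a microfluidic tunnel:

* biphasic extracellular spikes (1.2 ms) at Poisson times, repeated on the
  second electrode after a fixed sub-millisecond conduction delay;
* slow waves — a positive lobe followed by a sharper negative trough lobe
  (a 0.5–4 Hz-band deflection several hundred uV deep) at quasi-rhythmic
  times, delayed on the second electrode by the slow-wave conduction delay;
* spindle bursts — a 10–16 Hz carrier under a Gaussian envelope whose
  FWHM is the spindle duration (drawn log-normally), nested after the peak
  of a slow oscillation at a lag drawn from a power law p(t) ~ t^-alpha;
  the carrier peaks in phase with the envelope maximum so the 90-deg
  phase convention is testable;
* optional von Mises phase locking of in-spindle spike times to the
  spindle carrier;
* independent Gaussian background noise per channel.

Delays are applied as integer sample shifts at 25 kHz; the rounded value is
what the ground truth records.  The same config and seed always produce
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import (ChannelMap, Electrode, Recording, Tunnel,
                 DEFAULT_TUNNEL_SPACING_UM)

RATE_HZ = 25000.0


@dataclass
class TunnelConfig:
    tunnel_id: str
    source_compartment: str
    target_compartment: str
    direction: str = "feedforward"      # propagation along or against feed
    spike_rate_hz: float = 5.0
    spike_amp_uv: float = -80.0          # negative peak of the biphasic spike
    spike_delay_ms: float = 0.40
    sw_rate_hz: float = 1.0              # slow-oscillation event rate
    sw_amp_uv: float = 400.0             # trough depth
    sw_delay_ms: float = 0.86
    spindle_per_min: float = 10.0
    spindle_freq_hz: float = 12.0
    spindle_amp_uv: float = 50.0         # envelope peak
    spindle_dur_mode_s: float = 0.65     # mode of the log-normal duration
    spindle_dur_sigma_log10: float = 0.12
    nesting_alpha: float = 1.5           # lag law p(t) ~ t^-alpha
    nesting_tmin_s: float = 0.05
    nesting_tmax_s: float = 3.0
    phase_lock_kappa: float | None = None
    phase_lock_mu_deg: float = 90.0

    def __post_init__(self):
        for name in ("spike_rate_hz", "sw_rate_hz", "spindle_per_min",
                     "spindle_freq_hz", "spindle_amp_uv", "sw_amp_uv",
                     "spindle_dur_mode_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.direction not in ("feedforward", "feedback"):
            raise ValueError("direction must be feedforward or feedback")
        if not (8.0 <= self.spindle_freq_hz <= 16.0) and \
                self.spindle_per_min > 0:
            import warnings
            warnings.warn(
                f"spindle frequency {self.spindle_freq_hz} Hz outside the "
                "detectable 8-16 Hz band", stacklevel=3)


@dataclass
class SynthConfig:
    duration_s: float = 300.0
    rate_hz: float = RATE_HZ
    noise_sd_uv: float = 10.0
    tunnels: list[TunnelConfig] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.rate_hz <= 0 or self.noise_sd_uv < 0:
            raise ValueError("duration, rate and noise SD must be positive")


@dataclass
class TunnelTruth:
    tunnel_id: str
    direction: str
    spike_times_s: np.ndarray            # on the first-reached electrode
    spike_delay_ms: float                # signed (downstream - upstream)
    sw_trough_times_s: np.ndarray
    sw_delay_ms: float                   # signed
    so_peak_times_s: np.ndarray
    spindles: list[dict]                 # start_s, end_s, peak_s, duration_s
    nesting_lags_s: np.ndarray
    phase_locked: bool
    phase_lock_mu_deg: float


@dataclass
class GroundTruth:
    tunnels: dict[str, TunnelTruth] = field(default_factory=dict)


def _spike_template(rate_hz: float) -> np.ndarray:
    """Biphasic 1.2 ms extracellular spike, unit negative peak."""
    n_neg = int(round(0.0004 * rate_hz))
    n_pos = int(round(0.0008 * rate_hz))
    neg = -np.sin(np.pi * np.arange(n_neg) / n_neg)
    pos = 0.35 * np.sin(np.pi * np.arange(n_pos) / n_pos)
    return np.concatenate([neg, pos])


def _poisson_times(rate_hz: float, duration_s: float,
                   rng: np.random.Generator,
                   refractory_s: float = 0.0) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    t = np.sort(rng.uniform(0, duration_s, n))
    if refractory_s > 0 and t.size:
        keep = [0]
        for i in range(1, t.size):
            if t[i] - t[keep[-1]] >= refractory_s:
                keep.append(i)
        t = t[keep]
    return t


def _power_law(n: int, alpha: float, tmin: float, tmax: float,
               rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(size=n)
    if np.isclose(alpha, 1.0):
        return tmin * (tmax / tmin) ** u
    a1 = 1.0 - alpha
    return (tmin ** a1 + u * (tmax ** a1 - tmin ** a1)) ** (1.0 / a1)


def _shift(a: np.ndarray, k: int) -> np.ndarray:
    """Shift right by k samples (left for k < 0), zero-filling the edges."""
    out = np.zeros_like(a)
    if k >= 0:
        out[k:] = a[:a.size - k] if k else a
    else:
        out[:k] = a[-k:]
    return out


def _add_at(sig: np.ndarray, start_idx: int, wave: np.ndarray) -> None:
    a = max(0, start_idx)
    b = min(sig.size, start_idx + wave.size)
    if b > a:
        sig[a:b] += wave[a - start_idx: b - start_idx]


SW_PEAK_LOBE_S = 0.3   # positive lobe duration
SW_TROUGH_LOBE_S = 0.2  # negative lobe duration (sharper, for timing)
SW_PEAK_RATIO = 0.5    # peak height relative to trough depth


def _slow_wave(amp_uv: float, rate_hz: float) -> tuple[np.ndarray, int, int]:
    """One slow-oscillation waveform; returns (wave, peak_idx, trough_idx)."""
    n_p = int(SW_PEAK_LOBE_S * rate_hz)
    n_t = int(SW_TROUGH_LOBE_S * rate_hz)
    pos = SW_PEAK_RATIO * amp_uv * np.sin(np.pi * np.arange(n_p) / n_p)
    neg = -amp_uv * np.sin(np.pi * np.arange(n_t) / n_t)
    return np.concatenate([pos, neg]), n_p // 2, n_p + n_t // 2


def generate_recording(cfg: SynthConfig) -> tuple[Recording, ChannelMap,
                                                  GroundTruth]:
    """Synthesize a recording, its channel map, and exact ground truth.

    Channel naming: tunnel ``T`` gets electrodes ``T_up`` and ``T_down``
    (upstream/downstream in the feed-forward orientation).  For a feedback
    tunnel the event streams reach the *downstream* electrode first, so all
    signed (downstream - upstream) ground-truth delays are negative.
    """
    fs = cfg.rate_hz
    n = int(round(cfg.duration_s * fs))
    rng = np.random.default_rng(cfg.seed)
    channels = []
    channel_ids = []
    electrodes = []
    tunnels = []
    truth = GroundTruth()
    template = _spike_template(fs)
    tmpl_peak = int(np.argmin(template))

    for ti, tc in enumerate(cfg.tunnels):
        up_id, down_id = f"{tc.tunnel_id}_up", f"{tc.tunnel_id}_down"
        electrodes += [
            Electrode(id=up_id, x_um=0.0, y_um=ti * 400.0,
                      compartment="tunnel"),
            Electrode(id=down_id, x_um=DEFAULT_TUNNEL_SPACING_UM,
                      y_um=ti * 400.0, compartment="tunnel"),
        ]
        tunnels.append(Tunnel(
            tunnel_id=tc.tunnel_id,
            source_compartment=tc.source_compartment,
            target_compartment=tc.target_compartment,
            upstream_electrode_id=up_id,
            downstream_electrode_id=down_id,
        ))
        sign = 1 if tc.direction == "feedforward" else -1
        spike_shift = sign * int(round(tc.spike_delay_ms * fs / 1000.0))
        sw_shift = sign * int(round(tc.sw_delay_ms * fs / 1000.0))
        spike_delay_true = spike_shift / fs * 1000.0
        sw_delay_true = sw_shift / fs * 1000.0

        # --- slow oscillations -------------------------------------------
        sw_wave, pk_off, tr_off = _slow_wave(tc.sw_amp_uv, fs)
        sw_len_s = sw_wave.size / fs
        so_starts = _poisson_times(tc.sw_rate_hz, cfg.duration_s - sw_len_s,
                                   rng, refractory_s=sw_len_s + 0.05)
        so_peaks = so_starts + pk_off / fs
        so_troughs = so_starts + tr_off / fs

        # --- spindles nested after slow-oscillation peaks ----------------
        n_sp = rng.poisson(tc.spindle_per_min * cfg.duration_s / 60.0)
        spindles = []
        lags_kept = []
        if n_sp and so_peaks.size:
            host = np.sort(rng.choice(so_peaks.size, size=n_sp, replace=True))
            lags = _power_law(n_sp, tc.nesting_alpha, tc.nesting_tmin_s,
                              tc.nesting_tmax_s, rng)
            durs = tc.spindle_dur_mode_s * 10.0 ** (
                tc.spindle_dur_sigma_log10 ** 2 * np.log(10.0)
                + rng.normal(0, tc.spindle_dur_sigma_log10, n_sp))
            last_end = -np.inf
            for h, lag, dur in zip(host, lags, durs):
                peak_t = so_peaks[h] + lag
                sig_env = dur / 2.3548  # FWHM -> Gaussian sigma
                start_t, end_t = peak_t - 2.5 * sig_env, peak_t + 2.5 * sig_env
                if start_t < last_end + 1.0:  # keep events well separated
                    continue
                if start_t < 0 or end_t > cfg.duration_s:
                    continue
                spindles.append({"start_s": start_t, "end_s": end_t,
                                 "peak_s": peak_t, "duration_s": dur,
                                 "so_peak_s": so_peaks[h]})
                lags_kept.append(lag)
                last_end = end_t

        # --- spikes -------------------------------------------------------
        spike_times = _poisson_times(tc.spike_rate_hz, cfg.duration_s - 0.01,
                                     rng, refractory_s=0.002)
        if tc.phase_lock_kappa is not None and spindles:
            spike_times = _lock_spikes(spike_times, spindles,
                                       tc.spindle_freq_hz,
                                       np.radians(tc.phase_lock_mu_deg),
                                       tc.phase_lock_kappa, rng)
        spike_idx = np.unique(np.round(spike_times * fs).astype(int))
        spike_idx = spike_idx[(spike_idx >= 0) & (spike_idx < n - 40)]
        spike_times = spike_idx / fs

        # --- render both channels ----------------------------------------
        clean = np.zeros(n)
        for s0 in (so_starts * fs).round().astype(int):
            _add_at(clean, s0, sw_wave)
        for sp in spindles:
            sig_env = sp["duration_s"] / 2.3548
            half = int(round(2.5 * sig_env * fs))
            k0 = int(round(sp["peak_s"] * fs))
            tt = (np.arange(k0 - half, k0 + half + 1) - k0) / fs
            env = np.exp(-0.5 * (tt / sig_env) ** 2)
            carrier = np.sin(2 * np.pi * tc.spindle_freq_hz * tt + np.pi / 2)
            _add_at(clean, k0 - half, tc.spindle_amp_uv * env * carrier)
        spikes_sig = np.zeros(n)
        for k in spike_idx:
            # template has a unit negative peak; scale to |spike_amp_uv|
            _add_at(spikes_sig, k - tmpl_peak, abs(tc.spike_amp_uv) * template)

        ch_up = clean + spikes_sig
        ch_down = _shift(clean, sw_shift) + _shift(spikes_sig, spike_shift)
        if cfg.noise_sd_uv > 0:
            ch_up = ch_up + rng.normal(0, cfg.noise_sd_uv, n)
            ch_down = ch_down + rng.normal(0, cfg.noise_sd_uv, n)
        channels += [ch_up, ch_down]
        channel_ids += [up_id, down_id]

        truth.tunnels[tc.tunnel_id] = TunnelTruth(
            tunnel_id=tc.tunnel_id,
            direction=tc.direction,
            spike_times_s=spike_times,
            spike_delay_ms=spike_delay_true,
            sw_trough_times_s=so_troughs,
            sw_delay_ms=sw_delay_true,
            so_peak_times_s=so_peaks,
            spindles=spindles,
            nesting_lags_s=np.asarray(lags_kept),
            phase_locked=tc.phase_lock_kappa is not None,
            phase_lock_mu_deg=tc.phase_lock_mu_deg,
        )

    data = np.vstack(channels) if channels else np.zeros((0, n))
    rec = Recording(data=data, rate_hz=fs, channel_ids=channel_ids)
    cmap = ChannelMap(electrodes=electrodes, tunnels=tunnels)
    return rec, cmap, truth


def _lock_spikes(spike_times: np.ndarray, spindles: list[dict],
                 freq_hz: float, mu_rad: float, kappa: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Re-time in-spindle spikes so their carrier phase is von Mises."""
    out = spike_times.copy()
    for i, t in enumerate(spike_times):
        for sp in spindles:
            if sp["start_s"] <= t < sp["end_s"]:
                # carrier phase at time t (90 deg at the envelope peak)
                phase = 2 * np.pi * freq_hz * (t - sp["peak_s"]) + np.pi / 2
                theta = rng.vonmises(mu_rad, kappa)
                dphi = np.mod(theta - phase + np.pi, 2 * np.pi) - np.pi
                out[i] = t + dphi / (2 * np.pi * freq_hz)
                break
    return np.sort(out)


def preset_hippocampal_tunnels(duration_s: float = 300.0, seed: int = 0,
                      phase_lock_kappa: float | None = None) -> SynthConfig:
    """Four-tunnel configuration matching the reported study conditions.

    Spike conduction delay 0.40 ms (0.5 m/s over 200 um), slow-wave delay
    0.86 ms (0.23 m/s), ~10 spindles/min at 12 Hz with a log-normal
    duration mode of 0.65 s, nesting lags power-law distributed.  One
    feedback tunnel (CA3 -> DG) is included alongside three feed-forward
    connections of the EC -> DG -> CA3 -> CA1 loop.
    """
    mk = lambda tid, src, tgt, direction: TunnelConfig(
        tunnel_id=tid, source_compartment=src, target_compartment=tgt,
        direction=direction, phase_lock_kappa=phase_lock_kappa)
    return SynthConfig(
        duration_s=duration_s, noise_sd_uv=10.0, seed=seed,
        tunnels=[
            mk("ec_dg", "EC", "DG", "feedforward"),
            mk("dg_ca3", "DG", "CA3", "feedforward"),
            mk("ca3_ca1", "CA3", "CA1", "feedforward"),
            mk("ca3_dg_fb", "DG", "CA3", "feedback"),
        ])
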