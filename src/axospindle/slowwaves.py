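"""Slow-wave trough detection, slow-oscillation epochs, and conduction delays.

Slow waves (0.5–4 Hz, high amplitude) propagate along tunnel axons measurably
more slowly than spikes.  Delays of 0.3–1.5 ms over the 200 um electrode pair
are unresolvable at the 1 kHz LFP rate, so trough detection runs on the 25 kHz
raw trace smoothed with a zero-phase 4th-order Butterworth low-pass at 50 Hz.

Trough acceptance applies four constraints together: inter-trough spacing
>= 100 ms, amplitude at least 20% of the channel's largest negative
deflection, an absolute floor of -100 uV, and a width at half prominence of
at least 4 ms (rejecting spike transients).

A slow-oscillation (SO) epoch is a peak -> positive-to-negative zero
crossing -> trough triplet on the 0.5–4 Hz component; only epochs whose peak
is in the top 40% of peak amplitudes *and* whose trough is in the top 40%
(most negative) are retained for nesting analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

SMOOTH_HZ = 50.0            # low-pass for trough detection on raw data
SO_BAND_HZ = (0.5, 4.0)     # slow-oscillation band for epoch triplets
MIN_TROUGH_SPACING_S = 0.1
TROUGH_FRACTION = 0.2       # of the channel's maximum negative amplitude
TROUGH_FLOOR_UV = -100.0
MIN_WIDTH_S = 0.004
TOP_FRACTION = 0.4          # top-40% epoch selection
MAX_PAIR_DELAY_MS = 5.0


@dataclass
class SlowWaveEvent:
    """One slow-oscillation epoch: peak -> zero crossing -> trough."""
    channel_id: str
    peak_s: float
    peak_uv: float
    zero_cross_s: float
    trough_s: float
    trough_uv: float


@dataclass
class DelayEstimate:
    tunnel_id: str
    direction: str
    n_pairs: int
    mean_delay_ms: float
    se_delay_ms: float
    velocity_m_s: float
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class DelayComparison:
    """Spike vs slow-wave conduction delays for one connection/direction."""
    spike_mean_ms: float
    spike_se_ms: float
    slow_mean_ms: float
    slow_se_ms: float
    spike_velocity_m_s: float
    slow_velocity_m_s: float
    percent_slower: float
    t_stat: float
    p_value: float
    n_spike: int
    n_slow: int


def smooth_slow(x: np.ndarray, rate_hz: float = 25000.0,
                cutoff_hz: float = SMOOTH_HZ) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass used before trough picking."""
    sos = signal.butter(4, cutoff_hz, btype="lowpass", fs=rate_hz,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=np.float64))


def detect_slow_troughs(x: np.ndarray, rate_hz: float = 25000.0,
                        presmoothed: bool = False
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Detect slow-wave trough times and amplitudes on one channel.

    Returns ``(times_s, amplitudes_uv)``; amplitudes are negative.  All four
    acceptance constraints are applied (spacing, 20%-of-maximum, -100 uV
    floor, 4 ms half-prominence width).
    """
    y = np.asarray(x, dtype=np.float64) if presmoothed else \
        smooth_slow(x, rate_hz)
    global_min = y.min()
    if global_min >= TROUGH_FLOOR_UV:
        return np.empty(0), np.empty(0)
    height = max(-TROUGH_FLOOR_UV, TROUGH_FRACTION * (-global_min))
    peaks, props = signal.find_peaks(
        -y,
        height=height,
        distance=max(1, int(MIN_TROUGH_SPACING_S * rate_hz)),
        width=MIN_WIDTH_S * rate_hz,   # width at half prominence by default
    )
    return peaks / rate_hz, y[peaks]


def detect_so_epochs(x: np.ndarray, rate_hz: float = 1000.0,
                     channel_id: str = "",
                     band_hz: tuple[float, float] = SO_BAND_HZ,
                     top_fraction: float = TOP_FRACTION,
                     prefiltered: bool = False) -> list[SlowWaveEvent]:
    """Find slow-oscillation epochs and keep the top-40%/top-40% subset.

    The trace is band-passed to 0.5–4 Hz (zero-phase Butterworth, 4th
    order); each positive-to-negative zero crossing with a local maximum to
    its left and minimum to its right defines an epoch.  Retained epochs
    have peak amplitude >= the 60th percentile of peaks and trough
    amplitude <= the 40th percentile of troughs (ties kept on both sides).
    """
    if prefiltered:
        y = np.asarray(x, dtype=np.float64)
    else:
        sos = signal.butter(4, band_hz, btype="bandpass", fs=rate_hz,
                            output="sos")
        y = signal.sosfiltfilt(sos, np.asarray(x, dtype=np.float64))
    sign = y > 0
    pos2neg = np.flatnonzero(sign[:-1] & ~sign[1:])
    neg2pos = np.flatnonzero(~sign[:-1] & sign[1:])
    epochs: list[SlowWaveEvent] = []
    for zc in pos2neg:
        prev_up = neg2pos[neg2pos < zc]
        next_up = neg2pos[neg2pos > zc]
        if prev_up.size == 0 or next_up.size == 0:
            continue
        a, b = prev_up[-1], next_up[0]
        pk = a + int(np.argmax(y[a:zc + 1]))
        tr = zc + int(np.argmin(y[zc:b + 1]))
        epochs.append(SlowWaveEvent(
            channel_id=channel_id,
            peak_s=pk / rate_hz, peak_uv=float(y[pk]),
            zero_cross_s=zc / rate_hz,
            trough_s=tr / rate_hz, trough_uv=float(y[tr]),
        ))
    if len(epochs) < 3:
        warnings.warn("fewer than 3 slow-oscillation epochs: retaining all",
                      stacklevel=2)
        return epochs
    peaks = np.array([e.peak_uv for e in epochs])
    troughs = np.array([e.trough_uv for e in epochs])
    peak_cut = np.quantile(peaks, 1.0 - top_fraction)
    trough_cut = np.quantile(troughs, top_fraction)
    return [e for e in epochs
            if e.peak_uv >= peak_cut and e.trough_uv <= trough_cut]


def pair_troughs(up_times_s: np.ndarray, down_times_s: np.ndarray,
                 max_delay_ms: float = MAX_PAIR_DELAY_MS
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedily pair troughs across a tunnel's electrodes by minimum |dt|.

    Each trough is used at most once and pairs farther apart than
    ``max_delay_ms`` are not formed.  Returns ``(signed_delays_ms,
    unmatched_up_s, unmatched_down_s)``; delays are downstream minus
    upstream.  The result is independent of input ordering.
    """
    t_up = np.sort(np.asarray(up_times_s, dtype=np.float64))
    t_down = np.sort(np.asarray(down_times_s, dtype=np.float64))
    max_s = max_delay_ms / 1000.0
    cand: list[tuple[float, int, int]] = []
    if t_up.size and t_down.size:
        lo = np.searchsorted(t_down, t_up - max_s, side="left")
        hi = np.searchsorted(t_down, t_up + max_s, side="right")
        for i, (a, b) in enumerate(zip(lo, hi)):
            for j in range(a, b):
                cand.append((abs(t_down[j] - t_up[i]), i, j))
    cand.sort()
    used_u: set[int] = set()
    used_d: set[int] = set()
    delays = []
    for _, i, j in cand:
        if i in used_u or j in used_d:
            continue
        used_u.add(i)
        used_d.add(j)
        delays.append((t_down[j] - t_up[i]) * 1000.0)
    unmatched_up = np.delete(t_up, sorted(used_u))
    unmatched_down = np.delete(t_down, sorted(used_d))
    return np.asarray(sorted(delays)), unmatched_up, unmatched_down


def estimate_delay(delays_ms: np.ndarray, spacing_mm: float,
                   tunnel_id: str = "", direction: str = "feedforward"
                   ) -> DelayEstimate:
    """Mean/SE delay for one axon with the exclusion rule applied."""
    from .spikes import conduction_velocity

    d = np.asarray(delays_ms, dtype=np.float64)
    n = d.size
    mean = float(np.mean(d)) if n else float("nan")
    se = float(np.std(d, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    excluded, reason = False, ""
    if n == 0:
        excluded, reason = True, "no pairs"
    elif se < 1e-9:
        excluded, reason = True, "zero standard error"
    elif se > abs(mean):
        excluded, reason = True, "standard error exceeds mean delay"
    vel = conduction_velocity(abs(mean), spacing_mm) if n and mean != 0 \
        else float("nan")
    return DelayEstimate(tunnel_id=tunnel_id, direction=direction,
                         n_pairs=n, mean_delay_ms=mean, se_delay_ms=se,
                         velocity_m_s=vel, excluded=excluded,
                         exclusion_reason=reason)


def summarize_delays(spike_delays_ms: np.ndarray,
                     slow_delays_ms: np.ndarray,
                     spacing_mm: float = 0.2) -> DelayComparison:
    """Compare spike vs slow-wave conduction delays for one direction.

    Velocities come from the group-mean delays via ``conduction_velocity``
    (2 significant figures); percent-slower is computed from those rounded
    velocities and reported to the nearest percent, matching conventional
    reporting.  A two-sample t-test checks that slow-wave delays exceed
    spike delays.
    """
    from .spikes import conduction_velocity

    sp = np.abs(np.asarray(spike_delays_ms, dtype=np.float64))
    sl = np.abs(np.asarray(slow_delays_ms, dtype=np.float64))
    sp_mean, sl_mean = float(np.mean(sp)), float(np.mean(sl))
    sp_se = float(np.std(sp, ddof=1) / np.sqrt(sp.size)) if sp.size > 1 else 0.0
    sl_se = float(np.std(sl, ddof=1) / np.sqrt(sl.size)) if sl.size > 1 else 0.0
    v_sp = conduction_velocity(sp_mean, spacing_mm)
    v_sl = conduction_velocity(sl_mean, spacing_mm)
    pct = round((1.0 - round(v_sl, 2) / round(v_sp, 2)) * 100.0)
    if sp.size >= 2 and sl.size >= 2:
        t, p = stats.ttest_ind(sl, sp, equal_var=False)
        t, p = float(t), float(p)
        if np.all(sl == sl[0]) and np.all(sp == sp[0]) and sl[0] == sp[0]:
            t, p = 0.0, 1.0
    else:
        warnings.warn("fewer than 2 delays per group: t-test skipped",
                      stacklevel=2)
        t, p = float("nan"), float("nan")
    return DelayComparison(
        spike_mean_ms=sp_mean, spike_se_ms=sp_se,
        slow_mean_ms=sl_mean, slow_se_ms=sl_se,
        spike_velocity_m_s=v_sp, slow_velocity_m_s=v_sl,
        percent_slower=float(pct), t_stat=t, p_value=p,
        n_spike=sp.size, n_slow=sl.size,
    )


def amplitude_attenuation_test(near_uv: np.ndarray, far_uv: np.ndarray
                               ) -> dict:
    """Paired one-sided t-test for slow-wave amplitude decline with distance.

    ``near``/``far`` are per-axon mean trough amplitudes at the electrode
    nearer to / farther from the source subregion (negative uV).  Tests
    |near| > |far|.  Returns means, the mean decline and the p-value; with
    fewer than 2 axons the test is skipped (p = nan).
    """
    near = np.abs(np.asarray(near_uv, dtype=np.float64))
    far = np.abs(np.asarray(far_uv, dtype=np.float64))
    if near.size != far.size:
        raise ValueError("near/far must be paired per axon")
    out = {"n": int(near.size),
           "mean_near_uv": float(np.mean(near)) if near.size else float("nan"),
           "mean_far_uv": float(np.mean(far)) if far.size else float("nan"),
           "mean_decline_uv": float(np.mean(near - far)) if near.size
           else float("nan")}
    if near.size < 2:
        warnings.warn("fewer than 2 axons: paired t-test skipped",
                      stacklevel=2)
        out["p_value"] = float("nan")
        return out
    if np.allclose(near, far):
        out["p_value"] = 1.0
        out["t_stat"] = 0.0
        return out
    t, p = stats.ttest_rel(near, far, alternative="greater")
    out["t_stat"] = float(t)
    out["p_value"] = float(p)
    return out
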