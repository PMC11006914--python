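"""Spike detection on tunnel electrodes and single-axon identification.

A microfluidic tunnel holds two electrodes 200 um apart; an action potential
travelling down an axon in the tunnel appears on both with a sub-millisecond
offset.  The workflow is:

1. ``detect_spikes`` — dual-band negative-threshold detection on the
   spike-band (300–3000 Hz) filtered 25 kHz trace.  Thresholds are expressed
   in units of the channel noise SD; two amplitude bands (5–50 SD and
   50.1–500 SD) capture both ordinary and very large tunnel spikes.
2. ``match_tunnel_spikes`` — greedy nearest-neighbour pairing of spikes
   across the electrode pair; the signed delay histogram (0.04 ms bins) and
   the matched fraction (normalized matching index) characterize the tunnel.
3. ``identify_axons`` — peaks of the smoothed delay histogram define putative
   single axons; each gets a mean conduction delay, standard error, direction
   (sign of the modal delay relative to the feed-forward orientation) and a
   conduction velocity.  Axons with SE larger than the mean delay or SE of
   exactly 0 are excluded as unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: amplitude windows for the negative peak, in channel-SD units
DEFAULT_SD_BANDS = ((5.0, 50.0), (50.1, 500.0))
REFRACTORY_S = 0.001
SNIPPET_HALF_S = 0.0016
DELAY_BIN_MS = 0.04  # one sample at 25 kHz
DEFAULT_MAX_LAG_MS = 2.0  # covers 0.1-0.6 m/s over 200 um


@dataclass
class SpikeEvent:
    channel_id: str
    t_s: float              # time of the negative peak
    amplitude_uv: float     # negative
    snippet: np.ndarray | None = None


@dataclass
class DelayHistogram:
    """Signed cross-electrode delay histogram for one tunnel."""
    delays_ms: np.ndarray         # matched signed delays (down - up)
    bin_edges_ms: np.ndarray
    counts: np.ndarray
    matching_index: float         # matched pairs / upstream spike count
    n_up: int
    n_down: int


@dataclass
class AxonTrack:
    tunnel_id: str
    direction: str                # feedforward | feedback
    mean_delay_ms: float
    se_delay_ms: float
    n_matched_spikes: int
    velocity_m_s: float
    excluded: bool = False
    exclusion_reason: str = ""
    delays_ms: np.ndarray = field(default_factory=lambda: np.empty(0),
                                  repr=False)


def estimate_noise_sd(x: np.ndarray, robust: bool = False) -> float:
    """Channel noise SD of a spike-band trace.

    The plain standard deviation by default; ``robust=True`` uses the
    median-absolute-deviation estimator (0.6745 scaling), which is less
    inflated by the spikes themselves.
    """
    x = np.asarray(x)
    if robust:
        return float(np.median(np.abs(x - np.median(x))) / 0.6745)
    return float(np.std(x))


def detect_spikes(x: np.ndarray, rate_hz: float = 25000.0,
                  channel_id: str = "", sd_bands=DEFAULT_SD_BANDS,
                  robust_sd: bool = False,
                  keep_snippets: bool = False) -> list[SpikeEvent]:
    """Detect negative-peak spikes whose amplitude falls in either SD band.

    A 1 ms refractory lockout follows each detected peak.  Raises
    ``ValueError`` on a flat (SD == 0) trace.
    """
    x = np.asarray(x, dtype=np.float64)
    sd = estimate_noise_sd(x, robust=robust_sd)
    if sd == 0:
        raise ValueError("flat signal: noise SD is zero")
    lo = min(b[0] for b in sd_bands)
    distance = max(1, int(round(REFRACTORY_S * rate_hz)))
    peaks, props = signal.find_peaks(-x, height=lo * sd, distance=distance)
    amps = -props["peak_heights"]  # negative amplitudes
    in_band = np.zeros(peaks.size, dtype=bool)
    for lo_b, hi_b in sd_bands:
        in_band |= (-amps >= lo_b * sd) & (-amps <= hi_b * sd)
    half = int(round(SNIPPET_HALF_S * rate_hz))
    events = []
    for p, a in zip(peaks[in_band], amps[in_band]):
        snip = None
        if keep_snippets:
            snip = x[max(0, p - half): p + half + 1].copy()
        events.append(SpikeEvent(channel_id=channel_id, t_s=p / rate_hz,
                                 amplitude_uv=float(a), snippet=snip))
    return events


def match_tunnel_spikes(up: list[SpikeEvent], down: list[SpikeEvent],
                        max_lag_ms: float = DEFAULT_MAX_LAG_MS,
                        bin_ms: float = DELAY_BIN_MS) -> DelayHistogram:
    """Pair spikes across a tunnel's electrodes and histogram their delays.

    Greedy matching: candidate (up, down) pairs within ``max_lag_ms`` are
    taken in order of increasing |delay|, each spike used at most once.
    Delays are signed as downstream minus upstream, so positive means
    feed-forward propagation.  The matching index is the matched-pair count
    divided by the upstream spike count (1.0 when every upstream spike finds
    a partner).
    """
    t_up = np.array(sorted(e.t_s for e in up))
    t_down = np.array(sorted(e.t_s for e in down))
    max_lag_s = max_lag_ms / 1000.0
    pairs: list[tuple[float, int, int]] = []
    if t_up.size and t_down.size:
        left = np.searchsorted(t_down, t_up - max_lag_s, side="left")
        right = np.searchsorted(t_down, t_up + max_lag_s, side="right")
        for i, (lo_i, hi_i) in enumerate(zip(left, right)):
            for j in range(lo_i, hi_i):
                pairs.append((abs(t_down[j] - t_up[i]), i, j))
    pairs.sort()
    used_up: set[int] = set()
    used_down: set[int] = set()
    delays = []
    for _, i, j in pairs:
        if i in used_up or j in used_down:
            continue
        used_up.add(i)
        used_down.add(j)
        delays.append((t_down[j] - t_up[i]) * 1000.0)
    delays = np.asarray(sorted(delays))
    nbins = max(1, int(np.ceil(2 * max_lag_ms / bin_ms)))
    edges = -max_lag_ms + bin_ms * np.arange(nbins + 1)
    counts, _ = np.histogram(delays, bins=edges)
    nmi = len(delays) / t_up.size if t_up.size else 0.0
    return DelayHistogram(delays_ms=delays, bin_edges_ms=edges, counts=counts,
                          matching_index=nmi, n_up=t_up.size,
                          n_down=t_down.size)


def identify_axons(hist: DelayHistogram, spacing_um: float = 200.0,
                   tunnel_id: str = "", min_count: int = 5,
                   mode_halfwidth_ms: float = 0.2) -> list[AxonTrack]:
    """Identify putative single axons from delay-histogram peaks.

    The histogram is smoothed with a 3-bin moving average; local maxima above
    ``min_count`` define candidate axons.  Each axon's delays are the matched
    delays within ``mode_halfwidth_ms`` of its mode; the sign of the mean
    sets the direction (positive = feed-forward).  The exclusion rule drops
    axons whose delay SE exceeds the mean |delay| or equals 0.
    """
    if hist.counts.sum() == 0:
        return []
    smoothed = np.convolve(hist.counts, np.ones(3) / 3.0, mode="same")
    peaks, _ = signal.find_peaks(smoothed, height=min_count / 3.0)
    # peak must also carry enough raw counts nearby
    centers = 0.5 * (hist.bin_edges_ms[:-1] + hist.bin_edges_ms[1:])
    tracks: list[AxonTrack] = []
    claimed = np.zeros(hist.delays_ms.size, dtype=bool)
    order = np.argsort(-smoothed[peaks])  # strongest mode first
    for p in peaks[order]:
        mode_ms = centers[p]
        sel = (np.abs(hist.delays_ms - mode_ms) <= mode_halfwidth_ms) & ~claimed
        n = int(sel.sum())
        if n < min_count:
            continue
        claimed |= sel
        d = hist.delays_ms[sel]
        mean = float(np.mean(d))
        se = float(np.std(d, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        direction = "feedforward" if mean >= 0 else "feedback"
        vel = conduction_velocity(abs(mean), spacing_um / 1000.0) \
            if mean != 0 else float("nan")
        excluded = False
        reason = ""
        if se < 1e-9:  # zero up to float arithmetic
            excluded, reason = True, "zero standard error"
        elif se > abs(mean):
            excluded, reason = True, "standard error exceeds mean delay"
        tracks.append(AxonTrack(tunnel_id=tunnel_id, direction=direction,
                                mean_delay_ms=mean, se_delay_ms=se,
                                n_matched_spikes=n, velocity_m_s=vel,
                                excluded=excluded, exclusion_reason=reason,
                                delays_ms=d))
    tracks.sort(key=lambda t: -t.n_matched_spikes)
    return tracks


def conduction_velocity(delay_ms: float, distance_mm: float,
                        sig_figs: int = 2) -> float:
    """Conduction velocity = distance / delay (mm/ms == m/s), rounded to
    ``sig_figs`` significant figures (2, matching reported precision)."""
    if delay_ms <= 0:
        raise ValueError("delay must be positive")
    if distance_mm <= 0:
        raise ValueError("distance must be positive")
    v = distance_mm / delay_ms
    if sig_figs is None:
        return v
    exp = np.floor(np.log10(abs(v)))
    return float(round(v, -int(exp) + sig_figs - 1))
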