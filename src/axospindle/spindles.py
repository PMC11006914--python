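"""Spindle detection on the 1 kHz LFP via Hilbert-envelope thresholding.

A spindle is a waxing-and-waning 10–16 Hz burst.  Detection follows the
standard envelope-threshold scheme: band-pass the LFP to the spindle band,
take the Hilbert envelope, and mark windows where the envelope stays above
a *duration* threshold (mean + 1.5 SD of the whole-channel envelope) for
more than 300 ms and exceeds a stricter *event* threshold (mean + 2.5 SD)
at least once.  Detections less than 500 ms apart are merged into one
event, whose metrics are recomputed over the merged span.

Because both thresholds are expressed in SD units of the channel's own
envelope, detection is equivariant under amplitude rescaling: scaling the
channel by any c > 0 leaves event times unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .condition import bandpass_spindle, hilbert_envelope

EVENT_SD = 2.5        # envelope must exceed mean + 2.5 SD at least once
BOUNDARY_SD = 1.5     # continuous mean + 1.5 SD excursion defines the window
MIN_DURATION_S = 0.3  # excursions must last > 300 ms
MERGE_GAP_S = 0.5     # events < 500 ms apart are combined
MIN_STAT_DURATION_S = 0.4  # shorter events excluded from distribution stats


@dataclass
class SpindleEvent:
    channel_id: str
    start_s: float
    end_s: float
    duration_s: float = 0.0
    area_uv_s: float = 0.0       # integral of the envelope over the event
    amplitude_uv: float = 0.0    # area / duration
    peak_env_uv: float = 0.0
    peak_s: float = 0.0          # time of the envelope maximum
    n_cycles: float = 0.0
    merged_from_n: int = 1
    short_flag: bool = False     # < 0.4 s: kept in the table, not in stats
    interval_s: float = float("nan")  # gap to the previous spindle's end


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts, stops))


def detect_spindles(x: np.ndarray, rate_hz: float = 1000.0,
                    channel_id: str = "", band_hz=(8.0, 16.0),
                    t0_s: float = 0.0,
                    return_envelope: bool = False):
    """Detect spindle events on a single LFP channel.

    Returns the event list (and, with ``return_envelope``, the Hilbert
    envelope of the band-passed trace, needed by ``spindle_metrics``).
    Baseline mean/SD are taken over the whole channel's envelope.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 10 * rate_hz:
        warnings.warn("recording shorter than 10 s: envelope baseline "
                      "statistics may be unstable", stacklevel=2)
    filt = bandpass_spindle(x, rate_hz=rate_hz, band_hz=band_hz)
    env, _ = hilbert_envelope(filt)
    mu, sd = float(np.mean(env)), float(np.std(env))
    events: list[SpindleEvent] = []
    if sd > 0:
        hi = mu + EVENT_SD * sd
        lo = mu + BOUNDARY_SD * sd
        min_len = int(MIN_DURATION_S * rate_hz)
        windows = [(a, b) for a, b in _runs_above(env > lo)
                   if (b - a) > min_len and env[a:b].max() >= hi]
        # merge windows separated by < 500 ms
        merged: list[list[int]] = []
        for a, b in windows:
            if merged and (a - merged[-1][1]) < MERGE_GAP_S * rate_hz:
                merged[-1][1] = b
                merged[-1][2] += 1
            else:
                merged.append([a, b, 1])
        for a, b, k in merged:
            events.append(_make_event(channel_id, a, b, k, env, rate_hz,
                                      band_hz, t0_s))
    if return_envelope:
        return events, env
    return events


def _make_event(channel_id: str, a: int, b: int, k: int, env: np.ndarray,
                rate_hz: float, band_hz, t0_s: float) -> SpindleEvent:
    dur = (b - a) / rate_hz
    area = float(np.trapezoid(env[a:b], dx=1.0 / rate_hz))
    center_f = 0.5 * (band_hz[0] + band_hz[1])
    return SpindleEvent(
        channel_id=channel_id,
        start_s=t0_s + a / rate_hz,
        end_s=t0_s + b / rate_hz,
        duration_s=dur,
        area_uv_s=area,
        amplitude_uv=area / dur,
        peak_env_uv=float(env[a:b].max()),
        peak_s=t0_s + (a + int(np.argmax(env[a:b]))) / rate_hz,
        n_cycles=dur * center_f,
        merged_from_n=k,
        short_flag=dur < MIN_STAT_DURATION_S,
    )


def spindle_metrics(events: list[SpindleEvent], envelope: np.ndarray,
                    rate_hz: float = 1000.0,
                    t0_s: float = 0.0) -> list[SpindleEvent]:
    """Recompute per-event metrics from an envelope and fill inter-spindle
    intervals (start of event k+1 minus end of event k, per channel).

    Events must be time-ordered; short events (< 0.4 s) are flagged but
    retained.  Raises ``ValueError`` on out-of-order events.
    """
    out: list[SpindleEvent] = []
    prev_end = None
    for ev in events:
        if prev_end is not None and ev.start_s < prev_end:
            raise ValueError("events out of order or overlapping")
        a = int(round((ev.start_s - t0_s) * rate_hz))
        b = int(round((ev.end_s - t0_s) * rate_hz))
        b = min(b, envelope.size)
        dur = (b - a) / rate_hz
        area = float(np.trapezoid(envelope[a:b], dx=1.0 / rate_hz))
        ev = SpindleEvent(**{**vars(ev)})
        ev.duration_s = dur
        ev.area_uv_s = area
        ev.amplitude_uv = area / dur if dur > 0 else 0.0
        ev.peak_env_uv = float(envelope[a:b].max()) if b > a else 0.0
        ev.short_flag = dur < MIN_STAT_DURATION_S
        ev.interval_s = ev.start_s - prev_end if prev_end is not None \
            else float("nan")
        prev_end = ev.end_s
        out.append(ev)
    return out


def stats_eligible(events: list[SpindleEvent],
                   min_per_channel: int = 2) -> list[SpindleEvent]:
    """Events usable for distribution statistics: drops spindles shorter
    than 0.4 s and channels contributing fewer than two spindles."""
    by_ch: dict[str, int] = {}
    kept = [e for e in events if not e.short_flag]
    for e in kept:
        by_ch[e.channel_id] = by_ch.get(e.channel_id, 0) + 1
    return [e for e in kept if by_ch[e.channel_id] >= min_per_channel]
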