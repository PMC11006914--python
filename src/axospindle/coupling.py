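"""Spike-spindle phase locking and inter-channel spindle-envelope correlation.

Phase locking: every spike falling inside a spindle window is assigned the
instantaneous phase of the 10–16 Hz component at its peak time (0 deg at the
positive-going zero crossing, 90 deg at the wave peak, 270 deg at the
trough); the phases go into a 50-bin circular histogram.  Uniformity is
tested with the Hodges-Ajne omnibus statistic — the minimum number of
points in any closed half-circle — which is sensitive to both unimodal and
bimodal departures.  The resultant vector length r-bar is reported as a
standard effect measure alongside the range-based effect size used for
multi-array comparisons.

Envelope correlation: the spindle envelopes of two channels are zeroed
outside their own spindle windows and cross-correlated with coefficient
normalization; the peak coefficient and its lag bound the propagation
velocity between the sites (distance / |lag|).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats

from .spikes import SpikeEvent
from .spindles import SpindleEvent

N_PHASE_BINS = 50
DEFAULT_MAX_LAG_S = 0.1


@dataclass
class PhaseLockResult:
    bin_edges_deg: np.ndarray
    counts: np.ndarray
    n_spikes: int
    resultant_length: float
    p_omnibus: float
    preferred_phase_deg: float
    phases_deg: np.ndarray = field(default_factory=lambda: np.empty(0),
                                   repr=False)


@dataclass
class EnvelopeCorrelation:
    channel_pair: tuple[str, str]
    r: float
    best_lag_s: float
    valid: bool = True


def hodges_ajne_m(angles_rad: np.ndarray) -> int:
    """Hodges-Ajne statistic: minimum point count in any closed half-circle.

    Computed by sorting the angles and, for each datum, counting points in
    the half-open half-circle starting there; m is n minus the largest such
    count.
    """
    a = np.sort(np.mod(np.asarray(angles_rad, dtype=np.float64), 2 * np.pi))
    n = a.size
    ext = np.concatenate([a, a + 2 * np.pi])
    # count of points in [a_i, a_i + pi)
    hi = np.searchsorted(ext, a + np.pi, side="left")
    counts = hi - np.arange(n)
    return int(n - counts.max())


def hodges_ajne_test(angles_rad: np.ndarray) -> float:
    """P-value of the Hodges-Ajne omnibus test for circular nonuniformity.

    Uses the exact formula p = (n - 2m) * C(n, m) * 2^(1-n) for n <= 50 and
    the asymptotic approximation above that.  Requires n >= 10.
    """
    a = np.asarray(angles_rad, dtype=np.float64)
    n = a.size
    if n < 10:
        raise ValueError(f"need >= 10 angles, got {n}")
    m = hodges_ajne_m(a)
    if 2 * m == n:
        # perfectly balanced half-circles: maximal uniformity
        return 1.0
    if n <= 50:
        p = (n - 2 * m) * comb(n, m) * 2.0 ** (1 - n)
    else:
        A = np.pi * np.sqrt(n) / (2.0 * (n - 2 * m))
        p = np.sqrt(2.0 * np.pi) / A * np.exp(-np.pi ** 2 / (8.0 * A ** 2))
    return float(min(1.0, p))


def resultant_length(angles_rad: np.ndarray) -> float:
    """Length of the normalized resultant vector, in [0, 1]."""
    z = np.exp(1j * np.asarray(angles_rad, dtype=np.float64))
    return float(np.abs(np.mean(z))) if z.size else float("nan")


def spike_phase_histogram(spikes: list[SpikeEvent], phase_rad: np.ndarray,
                          rate_hz: float, spindles: list[SpindleEvent],
                          t0_s: float = 0.0,
                          n_bins: int = N_PHASE_BINS) -> PhaseLockResult:
    """Circular histogram of spike phases within spindle windows.

    ``phase_rad`` is the instantaneous phase of the spindle-band component
    sampled at ``rate_hz`` (typically the 1 kHz LFP); spikes share the same
    clock.  The histogram total equals the number of in-spindle spikes.
    """
    starts = np.array([s.start_s for s in spindles])
    ends = np.array([s.end_s for s in spindles])
    phases = []
    for sp in spikes:
        i = np.searchsorted(starts, sp.t_s, side="right") - 1
        if i < 0 or sp.t_s >= ends[i]:
            continue
        k = int(round((sp.t_s - t0_s) * rate_hz))
        if 0 <= k < phase_rad.size:
            phases.append(phase_rad[k])
    phases = np.asarray(phases)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    deg = np.mod(np.degrees(phases), 360.0)
    counts, _ = np.histogram(deg, bins=edges)
    if phases.size == 0:
        return PhaseLockResult(bin_edges_deg=edges, counts=counts, n_spikes=0,
                               resultant_length=float("nan"),
                               p_omnibus=float("nan"),
                               preferred_phase_deg=float("nan"),
                               phases_deg=deg)
    r = resultant_length(phases)
    pref = float(np.mod(np.degrees(np.angle(np.mean(np.exp(1j * phases)))),
                        360.0))
    p = hodges_ajne_test(phases) if phases.size >= 10 else float("nan")
    return PhaseLockResult(bin_edges_deg=edges, counts=counts,
                           n_spikes=int(phases.size), resultant_length=r,
                           p_omnibus=p, preferred_phase_deg=pref,
                           phases_deg=deg)


def phase_effect_size(per_array_counts: np.ndarray) -> float:
    """Range-based effect size of a pooled phase histogram.

    ``per_array_counts``: (n_arrays, n_bins) spike counts per array.  Each
    row is normalized to sum 1; the effect is the range of the pooled
    (mean) histogram — largest minus smallest bin — divided by the standard
    deviation of the per-array normalized bin values.  Dimensionless and
    invariant to count rescaling.
    """
    c = np.asarray(per_array_counts, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need counts from >= 2 arrays")
    norm = c / c.sum(axis=1, keepdims=True)
    pooled = norm.mean(axis=0)
    sd = float(np.std(norm, ddof=1))
    if sd == 0:
        return 0.0
    return float((pooled.max() - pooled.min()) / sd)


def _mask_envelope(env: np.ndarray, spindles: list[SpindleEvent],
                   rate_hz: float, t0_s: float) -> np.ndarray:
    out = np.zeros_like(env)
    for s in spindles:
        a = max(0, int(round((s.start_s - t0_s) * rate_hz)))
        b = min(env.size, int(round((s.end_s - t0_s) * rate_hz)))
        out[a:b] = env[a:b]
    return out


def spindle_envelope_correlation(env_a: np.ndarray, env_b: np.ndarray,
                                 spindles_a: list[SpindleEvent],
                                 spindles_b: list[SpindleEvent],
                                 rate_hz: float = 1000.0,
                                 max_lag_s: float = DEFAULT_MAX_LAG_S,
                                 t0_s: float = 0.0,
                                 channel_pair: tuple[str, str] = ("a", "b")
                                 ) -> EnvelopeCorrelation:
    """Peak normalized cross-correlation between two masked spindle envelopes.

    Envelopes are zeroed outside their own spindle windows, then the
    coefficient-normalized cross-correlation r(l) = sum a(t) b(t+l) /
    sqrt(sum a^2 sum b^2) is evaluated over |l| <= ``max_lag_s``.  A
    positive best lag means channel B lags channel A.
    """
    if env_a.size != env_b.size:
        raise ValueError("envelopes must have equal length")
    a = _mask_envelope(np.asarray(env_a, float), spindles_a, rate_hz, t0_s)
    b = _mask_envelope(np.asarray(env_b, float), spindles_b, rate_hz, t0_s)
    denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
    if denom == 0:
        return EnvelopeCorrelation(channel_pair=channel_pair, r=float("nan"),
                                   best_lag_s=float("nan"), valid=False)
    max_k = int(round(max_lag_s * rate_hz))
    lags = np.arange(-max_k, max_k + 1)
    rs = np.empty(lags.size)
    for idx, k in enumerate(lags):
        if k >= 0:
            rs[idx] = np.dot(a[:a.size - k], b[k:])
        else:
            rs[idx] = np.dot(a[-k:], b[:b.size + k])
    rs /= denom
    best = int(np.argmax(rs))
    return EnvelopeCorrelation(channel_pair=channel_pair, r=float(rs[best]),
                               best_lag_s=float(lags[best] / rate_hz))


def correlation_group_compare(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA with Tukey HSD across groups of correlation values.

    Returns ``{"F", "df_between", "df_within", "p", "tukey": DataFrame}``.
    Raises on fewer than 2 groups or any group with fewer than 2 values;
    if every group is constant and equal, a "no variance" notice is
    returned instead of a test.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[g], dtype=np.float64) for g in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    allv = np.concatenate(arrays)
    if np.allclose(allv, allv[0]):
        return {"F": float("nan"), "p": float("nan"),
                "notice": "no variance across groups"}
    F, p = stats.f_oneway(*arrays)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * a.size for g, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(values, labels)
    tukey = tk.summary()
    return {"F": float(F), "p": float(p),
            "df_between": len(names) - 1,
            "df_within": int(allv.size - len(names)),
            "tukey": tukey}
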