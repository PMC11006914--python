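"""Spindle nesting within slow oscillations: lag extraction and log-log fit.

Spindles tend to follow the peak of the immediately preceding slow
oscillation with a heavy-tailed lag distribution: on log-spaced bins the
log counts fall linearly in log lag (a power-law tail) over several orders
of magnitude.  The fit searches a grid of short-time boundaries between
1 ms and 0.5 s and keeps the boundary whose tail regression has the best
R^2, since very short lags (below the resolvable coupling delay) deviate
from the power law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .slowwaves import SlowWaveEvent
from .spindles import SpindleEvent

BOUNDARY_RANGE_S = (0.001, 0.5)
DEFAULT_N_BINS = 50


@dataclass
class NestingFit:
    lags_s: np.ndarray
    bin_edges_s: np.ndarray
    counts: np.ndarray
    boundary_s: float
    slope: float
    intercept: float
    r2: float
    median_lag_s: float
    n: int
    n_dropped: int = 0  # spindles with no preceding slow oscillation
    candidate_r2: dict = field(default_factory=dict, repr=False)


def nesting_lags(so_events: list[SlowWaveEvent],
                 spindles: list[SpindleEvent],
                 reference: str = "peak") -> tuple[np.ndarray, int]:
    """Per-spindle lag from the latest preceding slow-oscillation peak.

    ``reference`` selects the spindle anchor: ``"peak"`` (envelope maximum,
    default) or ``"onset"`` (event start).  Spindles with no preceding slow
    oscillation are dropped; their count is returned alongside the lags.
    """
    so_peaks = np.sort(np.array([e.peak_s for e in so_events]))
    anchors = np.array([e.peak_s if reference == "peak" else e.start_s
                        for e in spindles])
    lags = []
    dropped = 0
    for t in anchors:
        i = np.searchsorted(so_peaks, t, side="left") - 1
        if i < 0:
            dropped += 1
            continue
        lags.append(t - so_peaks[i])
    lags = np.asarray(lags)
    keep = lags > 0
    dropped += int((~keep).sum())
    return lags[keep], dropped


def fit_loglog(lags_s: np.ndarray, n_bins: int = DEFAULT_N_BINS,
               boundary_range_s: tuple[float, float] = BOUNDARY_RANGE_S,
               n_dropped: int = 0) -> NestingFit:
    """Fit a power-law tail to the lag distribution on log-spaced bins.

    The histogram uses ``n_bins`` log-spaced bins spanning the data.  For
    each candidate short-time boundary (the bin left edges intersected with
    ``boundary_range_s``), ordinary least squares of log10(count) on
    log10(bin center) is run over the non-empty bins at or above the
    boundary; candidates with fewer than 3 usable bins are skipped.  The
    boundary maximizing R^2 wins.
    """
    lags = np.asarray(lags_s, dtype=np.float64)
    if lags.size < 20:
        raise ValueError(f"need >= 20 lags, got {lags.size}")
    if np.any(lags <= 0):
        raise ValueError("lags must be positive")
    if np.isclose(lags.min(), lags.max()):
        raise ValueError("degenerate lag distribution (all lags equal)")
    edges = np.geomspace(lags.min(), lags.max() * (1 + 1e-12), n_bins + 1)
    counts, _ = np.histogram(lags, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    lo, hi = boundary_range_s
    grid = [e for e in edges[:-1] if lo <= e <= hi]
    if not grid or grid[0] > lags.min():
        grid = [max(lo, lags.min())] + grid
    best = None
    cand_r2 = {}
    for b in grid:
        sel = (centers >= b) & (counts > 0)
        if sel.sum() < 3:
            continue
        lx = np.log10(centers[sel])
        ly = np.log10(counts[sel])
        res = stats.linregress(lx, ly)
        r2 = res.rvalue ** 2
        cand_r2[float(b)] = float(r2)
        if best is None or r2 > best[0]:
            best = (r2, b, res.slope, res.intercept)
    if best is None:
        raise ValueError("no boundary candidate left >= 3 non-empty bins")
    r2, b, slope, intercept = best
    return NestingFit(lags_s=lags, bin_edges_s=edges, counts=counts,
                      boundary_s=float(b), slope=float(slope),
                      intercept=float(intercept), r2=float(r2),
                      median_lag_s=float(np.median(lags)), n=lags.size,
                      n_dropped=n_dropped, candidate_r2=cand_r2)


def sample_power_law(n: int, alpha: float, tmin: float, tmax: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw lags from p(t) proportional to t^-alpha on [tmin, tmax].

    On log-spaced bins such a sample has expected log-log slope
    -(alpha - 1), since the bin width grows proportionally to t.
    """
    u = rng.uniform(size=n)
    if np.isclose(alpha, 1.0):
        return tmin * (tmax / tmin) ** u
    a1 = 1.0 - alpha
    return (tmin ** a1 + u * (tmax ** a1 - tmin ** a1)) ** (1.0 / a1)
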