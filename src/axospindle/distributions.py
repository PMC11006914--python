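"""Log-binned log-normal fitting of spindle metrics and group comparisons.

Spindle durations, amplitudes and inter-spindle intervals are approximately
log-normal, sometimes with two modes.  Following the histogram-fit approach:
values are binned on a log-spaced axis, the bin densities (normalized to
total probability 1 on the log10 axis) are fit by a 1- or 2-component
Gaussian in log10 space by least squares, and the component modes are
back-transformed to original units.

For a log10-Gaussian fit with parameters (mu, sigma) describing the density
of log10(x), the density of x itself peaks at ``10**(mu - sigma^2 * ln 10)``
(the Jacobian shifts the mode below 10**mu); that is the mode reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

DELTA_R2_KEEP_TWO = 0.02  # 2-component fit kept only on this R^2 improvement
LN10 = np.log(10.0)


@dataclass
class LogNormalComponent:
    mu: float        # mean of log10(x)
    sigma: float     # SD of log10(x)
    weight: float

    @property
    def mode(self) -> float:
        """Mode of the implied density in original units."""
        return float(10.0 ** (self.mu - self.sigma ** 2 * LN10))


@dataclass
class LogNormalFit:
    components: list[LogNormalComponent]
    n_bins: int
    r2_fit: float
    bin_edges: np.ndarray = field(repr=False, default=None)
    density: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def modes(self) -> list[float]:
        return [c.mode for c in self.components]


def _gauss(x, mu, sigma, amp):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _r2(y, yhat):
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def fit_log_histogram(values: np.ndarray, n_bins: int = 50,
                      n_components: int = 1) -> LogNormalFit:
    """Fit a 1- or 2-component Gaussian in log10 space to binned densities.

    ``values`` must be positive with n >= 10.  When ``n_components=2`` the
    second component is retained only if it improves the fit R^2 by more
    than 0.02; otherwise the single-component fit is returned.  Fits are
    invariant to unit rescaling (multiplying values by c multiplies modes
    by c).
    """
    v = np.asarray(values, dtype=np.float64)
    bad = int((v <= 0).sum())
    if bad:
        raise ValueError(f"{bad} non-positive values; all must be > 0")
    if v.size < 10:
        raise ValueError(f"need >= 10 values, got {v.size}")
    lv = np.log10(v)
    if np.isclose(lv.min(), lv.max()):
        # all values equal: degenerate single mode at that value
        c = LogNormalComponent(mu=float(lv[0]), sigma=0.0, weight=1.0)
        return LogNormalFit(components=[c], n_bins=n_bins, r2_fit=1.0,
                            degenerate=True)
    edges = np.linspace(lv.min(), lv.max(), n_bins + 1)
    widths = np.diff(edges)
    counts, _ = np.histogram(lv, bins=edges)
    density = counts / (counts.sum() * widths)  # probability density on log10 axis
    centers = 0.5 * (edges[:-1] + edges[1:])

    span = lv.max() - lv.min()
    lo_b = [lv.min() - span, widths[0] / 4, 0.0]
    hi_b = [lv.max() + span, 2 * span, 10 * density.max()]
    fits = {}
    # single component: moment init
    mu0, s0 = float(np.mean(lv)), max(float(np.std(lv)), widths[0])
    amp0 = density.max()
    try:
        popt, _ = optimize.curve_fit(_gauss, centers, density,
                                     p0=[mu0, s0, amp0],
                                     bounds=(lo_b, hi_b), maxfev=20000)
        fits[1] = (popt, _r2(density, _gauss(centers, *popt)))
    except RuntimeError:
        fits[1] = ([mu0, s0, amp0], _r2(density, _gauss(centers, mu0, s0,
                                                        amp0)))
    result_components = None
    if n_components == 2:
        def two_gauss(x, m1, s1, a1, m2, s2, a2):
            return _gauss(x, m1, s1, a1) + _gauss(x, m2, s2, a2)

        # initialize at the two strongest separated histogram peaks
        order = np.argsort(-density)
        m1 = centers[order[0]]
        far = [c for c in centers[order] if abs(c - m1) > 2 * widths[0]]
        m2 = far[0] if far else centers[order[min(1, len(order) - 1)]]
        p0 = [m1, s0 / 2, density.max(), m2, s0 / 2, density.max() / 2]
        try:
            popt2, _ = optimize.curve_fit(two_gauss, centers, density, p0=p0,
                                          bounds=(lo_b + lo_b, hi_b + hi_b),
                                          maxfev=40000)
            r2_two = _r2(density, two_gauss(centers, *popt2))
            if r2_two - fits[1][1] > DELTA_R2_KEEP_TWO:
                m1, s1, a1, m2, s2, a2 = popt2
                w1 = abs(a1 * s1)
                w2 = abs(a2 * s2)
                tot = w1 + w2
                comps = sorted(
                    [LogNormalComponent(float(m1), abs(float(s1)), w1 / tot),
                     LogNormalComponent(float(m2), abs(float(s2)), w2 / tot)],
                    key=lambda c: c.mode)
                result_components = (comps, r2_two)
        except RuntimeError:
            pass
    if result_components is None:
        mu, sigma, _amp = fits[1][0]
        comps = [LogNormalComponent(float(mu), abs(float(sigma)), 1.0)]
        result_components = (comps, fits[1][1])
    comps, r2 = result_components
    return LogNormalFit(components=comps, n_bins=n_bins, r2_fit=float(r2),
                        bin_edges=edges, density=density)


def group_compare(groups: dict[str, np.ndarray],
                  log_transform: bool = True) -> dict:
    """One-way ANOVA + Tukey HSD on per-event metrics by group.

    Duration/amplitude/interval metrics are log-transformed by default
    (they are log-normal).  Shares its contract with
    ``coupling.correlation_group_compare``.
    """
    from .coupling import correlation_group_compare

    if log_transform:
        groups = {g: np.log10(np.asarray(v, dtype=np.float64))
                  for g, v in groups.items()}
    return correlation_group_compare(groups)
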