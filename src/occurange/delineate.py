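"""Range delineation: threshold the occupancy surface at a fixed
false-negative rate, kernel-smooth the pooled presences, and split
suitable habitat into current (occupied) and potential (unoccupied) range.

The threshold is the largest value whose omission (false negative) rate
over presence cells does not exceed the target (default 0.05) — it
maximizes specificity subject to the sensitivity constraint. The current
range is the intersection of suitable habitat with the super-level set of
a bivariate Gaussian kernel density of the pooled presence points that
contains at least 99.5% of them; bandwidths come from the Sheather-Jones
"solve-the-equation" plug-in applied per axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import iqr

from .grids import PresenceRecords, RasterStack

__all__ = [
    "ThresholdAnalysis",
    "KernelSurface",
    "RangePartition",
    "error_rates",
    "select_threshold",
    "ste_bandwidth",
    "kde2d",
    "inclusion_level",
    "partition_range",
]


@dataclass
class ThresholdAnalysis:
    """Omission/commission rates over a threshold sweep."""

    thresholds: np.ndarray
    fnr: np.ndarray
    fpr: np.ndarray
    selected_threshold: float | None = None
    suitable_mask: np.ndarray | None = None
    suitable_area_km2: float | None = None


@dataclass
class KernelSurface:
    """A 2D kernel density surface on the analysis grid."""

    density: np.ndarray
    bandwidth: tuple[float, float]
    level: float | None = None
    included_fraction: float | None = None


@dataclass
class RangePartition:
    """Per-cell range labels: 0 unsuitable, 1 potential, 2 current."""

    labels: np.ndarray
    area_current_km2: float
    area_potential_km2: float
    area_suitable_km2: float

    UNSUITABLE, POTENTIAL, CURRENT = 0, 1, 2


def error_rates(prediction: np.ndarray, truth: np.ndarray,
                nodata_mask=None, n_thresholds: int = 1001) -> ThresholdAnalysis:
    """Omission and commission rates for every threshold on [0, 1].

    ``truth`` is a boolean per-cell presence indicator; unmasked
    non-presence cells act as (pseudo-)absences. At threshold t,
    fnr = fraction of presence cells predicted below t and
    fpr = fraction of absence cells predicted at or above t.
    """
    pred = np.asarray(prediction, dtype=float).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    valid = np.isfinite(pred)
    if nodata_mask is not None:
        valid &= ~np.asarray(nodata_mask, dtype=bool).ravel()
    pres = np.sort(pred[valid & truth])
    absn = np.sort(pred[valid & ~truth])
    if pres.size == 0 or absn.size == 0:
        raise ValueError("need at least one presence and one absence cell")
    ts = np.linspace(0.0, 1.0, n_thresholds)
    fnr = np.searchsorted(pres, ts, side="left") / pres.size
    fpr = 1.0 - np.searchsorted(absn, ts, side="left") / absn.size
    return ThresholdAnalysis(ts, fnr, fpr)


def select_threshold(analysis: ThresholdAnalysis,
                     target_fnr: float = 0.05) -> float:
    """Largest threshold whose false-negative rate does not exceed the
    target; the commission error at that threshold is ``fpr`` at the same
    index of the analysis."""
    ok = analysis.fnr <= target_fnr
    if not ok.any():  # unreachable for a grid starting at 0, kept defensive
        raise RuntimeError("no threshold satisfies the target omission rate")
    # fnr is non-decreasing, so the admissible set is a prefix
    idx = int(np.max(np.flatnonzero(ok)))
    return float(analysis.thresholds[idx])


def apply_threshold(prediction: np.ndarray, threshold: float,
                    cell_size_km: float, nodata_mask=None) -> tuple[np.ndarray, float]:
    """Boolean suitable-habitat mask and its area in km^2."""
    pred = np.asarray(prediction, dtype=float)
    suitable = np.isfinite(pred) & (pred >= threshold)
    if nodata_mask is not None:
        suitable &= ~np.asarray(nodata_mask, dtype=bool)
    return suitable, float(suitable.sum()) * cell_size_km**2


# ------------------------------------------------- bandwidth selection

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _pair_counts(x: np.ndarray, nb: int):
    """Binned pairwise-distance counts: (bin width d, cnt[k] = number of
    pairs whose distance falls in bin k). Exact histogram convolution."""
    rang = (x.max() - x.min()) * 1.01
    d = rang / nb
    idx = np.minimum((x - x.min()) // d, nb - 1).astype(int)
    hist = np.bincount(idx, minlength=nb).astype(float)
    # cnt[k] = sum_b hist[b] * hist[b+k] for k > 0; cnt[0] = C(h_b, 2) sums
    full = np.correlate(hist, hist, mode="full")[nb - 1:]
    cnt = full.copy()
    cnt[0] = (hist * (hist - 1.0)).sum() / 2.0
    cnt[1:] = full[1:]
    return d, cnt


def _phi4_sum(h: float, d: float, cnt: np.ndarray, n: int) -> float:
    k = np.arange(len(cnt))
    delta = (k * d / h) ** 2
    keep = delta < 1000.0
    term = np.exp(-delta[keep] / 2.0) * (delta[keep] ** 2 - 6 * delta[keep] + 3)
    s = 2.0 * float(term @ cnt[keep]) + n * 3.0
    return s / (n * (n - 1) * h**5 * _SQRT_2PI)


def _phi6_sum(h: float, d: float, cnt: np.ndarray, n: int) -> float:
    k = np.arange(len(cnt))
    delta = (k * d / h) ** 2
    keep = delta < 1000.0
    dl = delta[keep]
    term = np.exp(-dl / 2.0) * (dl**3 - 15 * dl**2 + 45 * dl - 15)
    s = 2.0 * float(term @ cnt[keep]) + n * (-15.0)
    return s / (n * (n - 1) * h**7 * _SQRT_2PI)


def silverman_bandwidth(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    scale = min(np.std(x, ddof=1), iqr(x) / 1.349)
    return 0.9 * scale * n ** (-0.2)


def ste_bandwidth(values, nb: int = 1000) -> float:
    """Sheather-Jones solve-the-equation plug-in bandwidth (univariate,
    Gaussian kernel).

    Two pilot bandwidths estimate the density-curvature functionals, and
    the fixed-point equation

        h = [ R(K) / (n * S_D(alpha_2(h))) ]^(1/5)

    is solved by bracketed root finding (the bracket is widened as needed;
    if no root is found Silverman's rule is returned with a warning).
    Pairwise sums use ``nb`` distance bins, exact when the sample is
    smaller than ``nb``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample")
    d, cnt = _pair_counts(x, nb)
    scale = min(np.std(x, ddof=1), iqr(x) / 1.349)
    a = 1.24 * scale * n ** (-1.0 / 7.0)
    b = 1.23 * scale * n ** (-1.0 / 9.0)
    c1 = 1.0 / (2.0 * np.sqrt(np.pi) * n)
    td = -_phi6_sum(b, d, cnt, n)
    if td <= 0:
        warnings.warn("curvature functional not positive; falling back to "
                      "Silverman's rule")
        return silverman_bandwidth(x)
    sda = _phi4_sum(a, d, cnt, n)
    if sda <= 0:
        warnings.warn("pilot functional not positive; falling back to "
                      "Silverman's rule")
        return silverman_bandwidth(x)
    alph2 = 1.357 * (sda / td) ** (1.0 / 7.0)

    def fsd(h):
        s = _phi4_sum(alph2 * h ** (5.0 / 7.0), d, cnt, n)
        if s <= 0:
            return np.inf
        return (c1 / s) ** 0.2 - h

    hmax = 1.144 * scale * n ** (-0.2)
    lo, hi = 0.1 * hmax, hmax
    for _ in range(10):
        flo, fhi = fsd(lo), fsd(hi)
        if np.isfinite(flo) and np.isfinite(fhi) and flo * fhi < 0:
            root = brentq(fsd, lo, hi, xtol=1e-6 * scale)
            return float(root)
        lo *= 0.5
        hi *= 2.0
    warnings.warn("no root bracketed for the solve-the-equation bandwidth; "
                  "falling back to Silverman's rule")
    return silverman_bandwidth(x)


# --------------------------------------------------------------- kde


def kde2d(points: PresenceRecords, grid: RasterStack,
          bandwidth=None) -> KernelSurface:
    """Bivariate Gaussian kernel density of presence points at cell
    centres.

    density(c) = (1/n) sum_k phi((x_c - x_k)/b_x) phi((y_c - y_k)/b_y)
                 / (b_x b_y)

    With ``bandwidth=None`` the solve-the-equation bandwidth is estimated
    per axis (diagonal bandwidth matrix).
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    if bandwidth is None:
        bx = ste_bandwidth(points.x)
        by = ste_bandwidth(points.y)
    else:
        bx, by = float(bandwidth[0]), float(bandwidth[1])
    if bx <= 0 or by <= 0:
        raise ValueError("bandwidths must be positive")
    xs, ys = grid.cell_centres()
    n = len(points)
    gx = np.exp(-0.5 * ((xs[:, None] - points.x[None, :]) / bx) ** 2)
    gy = np.exp(-0.5 * ((ys[:, None] - points.y[None, :]) / by) ** 2)
    dens = (gy @ gx.T) / (n * 2.0 * np.pi * bx * by)
    return KernelSurface(dens, (bx, by))


def inclusion_level(surface: KernelSurface, points: PresenceRecords,
                    grid: RasterStack, fraction: float = 0.995) -> float:
    """Density cut whose super-level set contains at least ``fraction`` of
    the presence points.

    Each point is assigned the density of its cell; the level is the
    ceil(fraction * n)-th largest of those densities, so ties fall inside
    the included region.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    inside = grid.in_extent(points.x, points.y)
    if not inside.all():
        raise ValueError("surface does not cover all points")
    row, col = grid.point_to_cell(points.x, points.y)
    d = np.sort(surface.density[row, col])[::-1]
    k = int(np.ceil(fraction * len(d)))
    level = float(d[k - 1])
    surface.level = level
    surface.included_fraction = float((d >= level).mean())
    return level


def partition_range(suitable_mask: np.ndarray, surface: KernelSurface,
                    level: float, cell_size_km: float) -> RangePartition:
    """Split suitable habitat at the kernel-density level: cells at or
    above it are current (occupied) range, the rest potential range."""
    suitable = np.asarray(suitable_mask, dtype=bool)
    if suitable.shape != surface.density.shape:
        raise ValueError("mask and surface must share a grid")
    current = suitable & (surface.density >= level)
    potential = suitable & ~current
    labels = np.zeros(suitable.shape, dtype=int)
    labels[potential] = RangePartition.POTENTIAL
    labels[current] = RangePartition.CURRENT
    area = cell_size_km**2
    return RangePartition(
        labels,
        area_current_km2=float(current.sum()) * area,
        area_potential_km2=float(potential.sum()) * area,
        area_suitable_km2=float(suitable.sum()) * area,
    )
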