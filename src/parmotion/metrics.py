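"""Motion-artifact quantification: Parzen-window entropy, positivity and
normalized positivity, plus ROI handling and paired statistics.

The CT-value distribution ``P(h)`` inside a region of interest is estimated
by kernel density estimation (Parzen windowing, Gaussian kernel) on a uniform
1-HU grid and treated as a probability mass function.  From it:

* ``Entropy = -sum_h P(h) ln P(h)`` (nats) — rises when motion smears the
  CT-value distribution;
* the automatic threshold ``T = argmax_h P(h)`` (the distribution mode,
  lowest mode on ties);
* ``Positivity = sum_{X in ROI, f(X) <= T} (f(X) - T)^2`` — the power of
  intensities under the threshold, which captures motion shading;
* ``Normalized positivity (NP) = Positivity / n(ROI)``.

Because the grid step is fixed, its additive contribution to the discrete
entropy is constant across compared conditions and cancels in relative
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .grid import Image, ImageGrid

KDE_BANDWIDTH_FLOOR_HU = 5.0


# ---------------------------------------------------------------------------
# Regions of interest
# ---------------------------------------------------------------------------

@dataclass
class ROIMask:
    """A labelled region of interest: an axis-aligned mm rectangle or an
    explicit boolean raster on an image grid."""

    label: str
    rect: tuple[float, float, float, float] | None = None  # x0, y0, x1, y1 mm
    mask: np.ndarray | None = None  # boolean, on the evaluation grid

    def pixels(self, img: Image) -> np.ndarray:
        """CT values of the ROI pixels (center-inclusion for rectangles)."""
        m = self.raster(img.grid)
        vals = img.values[m]
        if vals.size == 0:
            raise ValueError(f"ROI {self.label!r} selects no pixels")
        if vals.size < 25:
            import warnings
            warnings.warn(
                f"ROI {self.label!r} has only {vals.size} pixels; the density "
                "estimate may be unstable", stacklevel=2)
        return vals

    def raster(self, grid: ImageGrid) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != grid.shape:
                raise ValueError("ROI mask shape does not match the grid")
            return self.mask
        if self.rect is None:
            raise ValueError("ROI needs either a rectangle or a mask")
        x0, y0, x1, y1 = self.rect
        X, Y = grid.meshgrid()
        return (X >= min(x0, x1)) & (X <= max(x0, x1)) & \
               (Y >= min(y0, y1)) & (Y <= max(y0, y1))


def union_roi(rois: Sequence[ROIMask], grid: ImageGrid,
              label: str = "union") -> ROIMask:
    m = np.zeros(grid.shape, dtype=bool)
    for r in rois:
        m |= r.raster(grid)
    return ROIMask(label=label, mask=m)


# ---------------------------------------------------------------------------
# Parzen density and derived measures
# ---------------------------------------------------------------------------

@dataclass
class DensityEstimate:
    """Probability masses of CT values on a uniform HU grid."""

    h_grid: np.ndarray  # HU
    P: np.ndarray  # masses, sum to 1
    bandwidth: float  # HU

    def __post_init__(self) -> None:
        if np.any(self.P < 0) or abs(self.P.sum() - 1.0) > 1e-9:
            raise ValueError("P must be a probability mass function")


def silverman_bandwidth(values: np.ndarray,
                        floor: float = KDE_BANDWIDTH_FLOOR_HU) -> float:
    """Silverman's rule-of-thumb bandwidth, floored for near-constant ROIs."""
    v = np.asarray(values, dtype=float)
    n = v.size
    sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) \
        else 0.0
    return max(floor, 0.9 * spread * n ** (-0.2))


def default_h_grid(values: np.ndarray, bandwidth: float,
                   step: float = 1.0) -> np.ndarray:
    """Uniform HU grid spanning the data plus four bandwidths of margin."""
    lo = np.floor(np.min(values) - 4.0 * bandwidth)
    hi = np.ceil(np.max(values) + 4.0 * bandwidth)
    return np.arange(lo, hi + step / 2, step)


def parzen_density(values, bandwidth: float | None = None,
                   h_grid: np.ndarray | None = None) -> DensityEstimate:
    """Gaussian-kernel density of CT values, normalized to unit mass.

    Bandwidth defaults to Silverman's rule floored at 5 HU; the grid defaults
    to 1-HU steps covering the data with a 4-bandwidth margin.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot estimate a density from no values")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(v)
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    if h_grid is None:
        h_grid = default_h_grid(v, bandwidth)
    h_grid = np.asarray(h_grid, dtype=float)
    # Chunk over the sample to bound the (n_values x n_grid) kernel matrix.
    P = np.zeros(h_grid.shape)
    chunk = max(1, int(4e6 / max(h_grid.size, 1)))
    for a in range(0, v.size, chunk):
        z = (h_grid[None, :] - v[a:a + chunk, None]) / bandwidth
        P += np.exp(-0.5 * z * z).sum(axis=0)
    P /= P.sum()
    return DensityEstimate(h_grid=h_grid, P=P, bandwidth=float(bandwidth))


def entropy(values, bandwidth: float | None = None,
            h_grid: np.ndarray | None = None) -> float:
    """Discrete entropy (nats) of the Parzen density, with 0 ln 0 := 0."""
    d = parzen_density(values, bandwidth, h_grid)
    p = d.P[d.P > 0]
    return float(-np.sum(p * np.log(p)))


def auto_threshold(values, bandwidth: float | None = None,
                   h_grid: np.ndarray | None = None) -> float:
    """The CT value maximizing P(h); ties resolve to the lowest h."""
    d = parzen_density(values, bandwidth, h_grid)
    return float(d.h_grid[int(np.argmax(d.P))])


def positivity(values, threshold: float) -> float:
    """Power of intensities at or below the threshold:
    ``sum (f - T)^2`` over pixels with ``f <= T`` (0 above)."""
    v = np.asarray(values, dtype=float).ravel()
    d = v - threshold
    return float(np.sum(np.where(v <= threshold, d * d, 0.0)))


def normalized_positivity(values, threshold: float) -> float:
    """Positivity divided by the ROI pixel count (HU^2)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty ROI")
    return positivity(v, threshold) / v.size


@dataclass
class MetricResult:
    """Entropy / threshold / positivity for one ROI in one image."""

    roi: str
    condition: str = ""
    entropy: float = np.nan
    threshold: float = np.nan
    positivity: float = np.nan
    normalized_positivity: float = np.nan
    bandwidth: float = np.nan
    n_pixels: int = 0


def evaluate_roi(values, roi_label: str, condition: str = "",
                 bandwidth: float | None = None,
                 h_grid: np.ndarray | None = None) -> MetricResult:
    """All metrics for one pixel sample, threshold chosen automatically."""
    v = np.asarray(values, dtype=float).ravel()
    d = parzen_density(v, bandwidth, h_grid)
    T = float(d.h_grid[int(np.argmax(d.P))])
    p = d.P[d.P > 0]
    ent = float(-np.sum(p * np.log(p)))
    pos = positivity(v, T)
    return MetricResult(roi=roi_label, condition=condition, entropy=ent,
                        threshold=T, positivity=pos,
                        normalized_positivity=pos / v.size,
                        bandwidth=d.bandwidth, n_pixels=int(v.size))


# ---------------------------------------------------------------------------
# Comparison arithmetic and paired statistics
# ---------------------------------------------------------------------------

def percent_change(reference: float, value: float) -> float:
    """Relative improvement ``100 * (reference - value) / reference`` (%),
    rounded to one decimal (as reported)."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return round(100.0 * (reference - value) / reference, 1)


def percent_error(reference: float, value: float) -> float:
    """Signed deviation from a ground-truth reference,
    ``100 * (value - reference) / reference`` (%), one decimal."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return round(100.0 * (value - reference) / reference, 1)


@dataclass
class PairedTestResult:
    n: int
    mean_difference: float
    t: float
    p: float


def paired_ttest(a, b) -> PairedTestResult:
    """Two-sided paired t-test on ``d = a - b`` with n - 1 degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1D samples")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise ValueError("paired differences have zero variance; t undefined")
    res = stats.ttest_rel(a, b)
    return PairedTestResult(n=int(a.size), mean_difference=float(d.mean()),
                            t=float(res.statistic), p=float(res.pvalue))
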