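"""Parallel-beam filtered backprojection, partial-angle reconstruction (PAR)
pairs, and band-pass filtering of PAR images.

All reconstruction here is 2D parallel-beam after rebinning.  A half scan is
180 degrees of parallel views, which is complete without redundancy weighting.
A PAR image is the same filtered backprojection restricted to a short angular
segment: incomplete but time-localized.  Conjugate PARs come from segments
centered 90 degrees before and after the target angle; for a static object
they image the same ray lines and therefore agree.

Backprojection is pixel-driven with linear interpolation along the radial
coordinate; each view can be geometrically warped through a displacement
field before sampling, which is the hook the motion-compensated
reconstruction uses (with no field the code path is the plain FBP one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import Image, ImageGrid
from .sim import ParallelSinogram, mu_to_hu

Window = str  # "none" (Ram-Lak) | "shepp_logan" | "hann"


# ---------------------------------------------------------------------------
# Ramp filtering
# ---------------------------------------------------------------------------

def _ramp_kernel_freq(n_fft: int, ds: float, window: Window) -> np.ndarray:
    """Frequency response of the band-limited ramp (Ram-Lak) filter.

    Built by transforming the discrete spatial kernel
    ``h[0] = 1/(4 ds^2)``, ``h[n] = -1/(pi n ds)^2`` for odd n, 0 for even n,
    which avoids the DC bias of sampling |f| directly.  Optional apodization
    multiplies the response by a Shepp-Logan (sinc) or Hann window.
    """
    n = np.arange(-(n_fft // 2), n_fft - n_fft // 2)
    h = np.zeros(n_fft)
    h[n == 0] = 1.0 / (4.0 * ds * ds)
    odd = (n % 2) != 0
    h[odd] = -1.0 / (np.pi * n[odd] * ds) ** 2
    H = np.real(np.fft.fft(np.fft.ifftshift(h)))
    if window == "none":
        return H
    f = np.fft.fftfreq(n_fft)  # cycles/sample in [-0.5, 0.5)
    ratio = np.abs(f) / 0.5
    if window == "shepp_logan":
        w = np.sinc(ratio / 2.0)
    elif window == "hann":
        w = 0.5 * (1.0 + np.cos(np.pi * ratio))
    else:
        raise ValueError(f"unknown filter window {window!r}")
    return H * w


def ramp_filter(sino: ParallelSinogram, window: Window = "none") -> ParallelSinogram:
    """Convolve every view with the band-limited ramp kernel.

    Views are zero-padded to at least twice their length (next power of two)
    to avoid circular wrap-around.  The output is scaled by the radial step
    so that backprojection integrates attenuation directly.
    """
    n_s = sino.values.shape[1]
    n_fft = 1 << max(6, int(math.ceil(math.log2(2 * n_s))))
    H = _ramp_kernel_freq(n_fft, sino.ds, window)
    spec = np.fft.fft(sino.values, n=n_fft, axis=1)
    filtered = np.real(np.fft.ifft(spec * H[None, :], axis=1))[:, :n_s]
    filtered *= sino.ds
    return ParallelSinogram(values=filtered, angles=sino.angles.copy(),
                            s=sino.s.copy(), view_times=sino.view_times.copy())


# ---------------------------------------------------------------------------
# Backprojection
# ---------------------------------------------------------------------------

def backproject(
    filtered: ParallelSinogram,
    grid: ImageGrid,
    view_subset: Sequence[int] | np.ndarray | None = None,
    weights: np.ndarray | None = None,
    displacement_fields: Sequence[np.ndarray] | None = None,
    to_hu: bool = True,
) -> Image:
    """Pixel-driven backprojection with linear radial interpolation.

    The output is scaled by ``pi / (views per 180 deg)`` so a half scan of a
    ramp-filtered sinogram with unit weights reconstructs the attenuation
    coefficient, then converted to HU unless ``to_hu`` is False.

    ``displacement_fields``, when given, holds one (ny, nx, 2) mm field per
    selected view; pixel X then samples the view at the radial position of
    the displaced point ``X + D_view(X)`` — the warped-backprojection form
    used by motion-compensated reconstruction.
    """
    if view_subset is None:
        idx = np.arange(len(filtered.angles))
    else:
        idx = np.asarray(view_subset, dtype=int)
    if idx.size == 0:
        raise ValueError("empty view subset")
    if weights is None:
        weights = np.ones(idx.size)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (idx.size,):
        raise ValueError("weights length must match the view subset")
    if displacement_fields is not None and len(displacement_fields) != idx.size:
        raise ValueError("one displacement field per selected view is required")

    X, Y = grid.meshgrid()
    s0 = filtered.s[0]
    ds = filtered.ds
    n_s = len(filtered.s)
    acc = np.zeros(grid.shape)
    sample_idx = np.arange(n_s, dtype=float)
    for m, k in enumerate(idx):
        th = math.radians(filtered.angles[k])
        cos_t, sin_t = math.cos(th), math.sin(th)
        if displacement_fields is not None:
            D = displacement_fields[m]
            px = X + D[..., 0]
            py = Y + D[..., 1]
        else:
            px, py = X, Y
        s_pix = px * cos_t + py * sin_t
        frac = (s_pix - s0) / ds
        acc += weights[m] * np.interp(frac, sample_idx, filtered.values[k],
                                      left=0.0, right=0.0)

    n_180 = int(round(180.0 / filtered.dtheta))
    mu = acc * (np.pi / n_180)
    values = mu_to_hu(mu) if to_hu else mu
    return Image(grid=grid, values=values,
                 meta={"n_views": int(idx.size), "units": "HU" if to_hu else "mu"})


def _views_in_range(sino: ParallelSinogram, lo: float, hi: float) -> np.ndarray:
    """Indices of views with angle in [lo, hi), with a gap check."""
    dtheta = sino.dtheta
    eps = 1e-6 * dtheta
    if lo < sino.angles[0] - eps or hi > sino.angles[-1] + dtheta + eps:
        raise ValueError(
            f"sinogram does not cover [{lo:.2f}, {hi:.2f}) deg: have "
            f"[{sino.angles[0]:.2f}, {sino.angles[-1]:.2f}]"
        )
    mask = (sino.angles >= lo - eps) & (sino.angles < hi - eps)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError(f"no views in [{lo:.2f}, {hi:.2f}) deg")
    return idx


def fbp_range(
    sino: ParallelSinogram,
    grid: ImageGrid,
    theta_start: float,
    theta_end: float,
    window: Window = "none",
    to_hu: bool = True,
    filtered: ParallelSinogram | None = None,
) -> Image:
    """Filtered backprojection restricted to views in [theta_start, theta_end).

    Passing a pre-filtered sinogram skips the ramp filter (useful when several
    partial reconstructions share one filtering pass — partial images then sum
    exactly to the reconstruction over the union of their view ranges).
    """
    if theta_end <= theta_start:
        raise ValueError("need theta_end > theta_start")
    if filtered is None:
        filtered = ramp_filter(sino, window=window)
    idx = _views_in_range(filtered, theta_start, theta_end)
    img = backproject(filtered, grid, view_subset=idx, to_hu=to_hu)
    tc = 0.5 * (theta_start + theta_end)
    img.meta.update(
        angular_range=(float(theta_start), float(theta_end)),
        time_center=sino.time_at(tc),
        theta_center=float(tc),
        window=window,
    )
    return img


def fbp_half(
    sino: ParallelSinogram,
    grid: ImageGrid,
    theta_c: float,
    window: Window = "none",
) -> Image:
    """Half reconstruction: FBP over exactly 180 degrees centered at theta_c.

    The image's ``time_center`` is the acquisition time at theta_c — the
    middle of the raw data used.
    """
    img = fbp_range(sino, grid, theta_c - 90.0, theta_c + 90.0, window=window)
    img.meta["label"] = "fbp_half"
    return img


# ---------------------------------------------------------------------------
# Conjugate PAR pairs
# ---------------------------------------------------------------------------

@dataclass
class PARPair:
    """Two conjugate partial-angle reconstructions bracketing a target time.

    ``before`` / ``after`` are reconstructed from angular segments of width
    ``segment_length`` centered at ``theta_c -/+ 90`` degrees; their time
    centers differ by half a rotation.  Values are raw attenuation partial
    sums (not normalized to a full reconstruction).
    """

    before: Image
    after: Image
    target_time: float
    target_angle: float  # theta_c, degrees
    segment_length: float  # degrees


def reconstruct_par_pair(
    sino: ParallelSinogram,
    grid: ImageGrid,
    theta_c: float,
    segment_length: float = 50.0,
    window: Window = "hann",
) -> PARPair:
    """Reconstruct the conjugate PAR pair around the target angle.

    The segment length defaults to a typical fan angle, the heuristic choice
    for heart-induced motion.  Both PARs use the same per-view weighting as
    the half reconstruction, so together with the middle-segment partial image
    they partition the views of the enclosing reconstruction exactly.
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    L = segment_length
    filtered = ramp_filter(sino, window=window)
    before = fbp_range(sino, grid, theta_c - 90.0 - L / 2, theta_c - 90.0 + L / 2,
                       to_hu=False, filtered=filtered)
    after = fbp_range(sino, grid, theta_c + 90.0 - L / 2, theta_c + 90.0 + L / 2,
                      to_hu=False, filtered=filtered)
    before.meta["label"] = "par_before"
    after.meta["label"] = "par_after"
    return PARPair(before=before, after=after,
                   target_time=sino.time_at(theta_c),
                   target_angle=float(theta_c), segment_length=float(L))


# ---------------------------------------------------------------------------
# Band-pass filtering
# ---------------------------------------------------------------------------

def bandpass(img: Image, sigma_fine: float = 1.0, sigma_coarse: float = 8.0) -> Image:
    """Difference-of-Gaussians band-pass (pixels), removing low-frequency
    shading and very fine noise while keeping structural edges."""
    if not (0 < sigma_fine < sigma_coarse):
        raise ValueError("need 0 < sigma_fine < sigma_coarse")
    v = img.values
    out = gaussian_filter(v, sigma_fine, mode="nearest") - gaussian_filter(
        v, sigma_coarse, mode="nearest")
    return img.copy_with(out, bandpass=(float(sigma_fine), float(sigma_coarse)))
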