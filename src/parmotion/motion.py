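"""Non-rigid motion estimation between conjugate PAR images.

The deformation model is a free-form deformation (FFD): a dense displacement
field parameterized by cubic B-spline coefficients on a coarse uniform
control grid.  Registration minimizes an intensity similarity (SSD by
default, NCC selectable) between the fixed image and the warped moving image,
plus a bending-energy penalty on the control lattice, by deterministic
gradient descent with Armijo backtracking, coarse-to-fine over control
spacings.  No segmentation enters the estimation path: the only inputs are
the two (band-passed) PAR images.

The estimated motion vector field (MVF) is the forward displacement of
material points from the BEFORE state to the AFTER state, evaluated at
target-frame positions.  Under the linear-in-time motion assumption the
field at any view angle theta is the full field scaled by
``alpha = wrap(theta - theta_c) / 180`` — 0 at the target angle, -/+0.5 at
the conjugate PAR centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter, map_coordinates

from .grid import Image, ImageGrid

_B3_AT_NODE = 2.0 / 3.0  # cubic B-spline central value B3(0)


# ---------------------------------------------------------------------------
# Cubic B-spline control grids
# ---------------------------------------------------------------------------

def _bspline_weights(t: np.ndarray) -> tuple[np.ndarray, ...]:
    """Cubic B-spline weights for the 4 support nodes at fractional offset t."""
    t2 = t * t
    t3 = t2 * t
    w0 = (1.0 - 3.0 * t + 3.0 * t2 - t3) / 6.0
    w1 = (4.0 - 6.0 * t2 + 3.0 * t3) / 6.0
    w2 = (1.0 + 3.0 * t + 3.0 * t2 - 3.0 * t3) / 6.0
    w3 = t3 / 6.0
    return w0, w1, w2, w3


@dataclass
class BsplineControlGrid:
    """Uniform cubic B-spline lattice of 2D displacement coefficients (mm).

    Control nodes sit at ``origin + k * spacing`` per axis.  The lattice
    extends at least one control interval beyond the region it parameterizes
    so the cubic support is complete everywhere inside.
    """

    spacing: float  # mm, both axes
    origin: tuple[float, float]  # mm, first control node
    shape: tuple[int, int]  # (ncy, ncx)
    coefficients: np.ndarray | None = None  # (ncy, ncx, 2) mm

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("control spacing must be positive")
        ncy, ncx = self.shape
        if ncy < 4 or ncx < 4:
            raise ValueError("need at least 4 control points per axis")
        if self.coefficients is None:
            self.coefficients = np.zeros((ncy, ncx, 2))
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (ncy, ncx, 2):
            raise ValueError("coefficient array shape mismatch")

    @classmethod
    def covering(cls, grid: ImageGrid, spacing: float) -> "BsplineControlGrid":
        """Lattice covering an image grid with full cubic support."""
        x0, x1 = grid.x[0], grid.x[-1]
        y0, y1 = grid.y[0], grid.y[-1]
        ncx = int(math.ceil((x1 - x0) / spacing)) + 4
        ncy = int(math.ceil((y1 - y0) / spacing)) + 4
        return cls(spacing=spacing, origin=(x0 - spacing, y0 - spacing),
                   shape=(ncy, ncx))

    def _index(self, coords: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
        u = (np.asarray(coords, dtype=float) - self.origin[axis]) / self.spacing
        i = np.floor(u).astype(int)
        t = u - i
        nc = self.shape[1] if axis == 0 else self.shape[0]
        if np.any(i - 1 < 0) or np.any(i + 2 > nc - 1):
            raise ValueError("point outside the control-grid extent")
        return i, t

    def basis_matrix(self, coords: np.ndarray, axis: int) -> sparse.csr_matrix:
        """Sparse (len(coords) x nc) cubic B-spline evaluation matrix."""
        i, t = self._index(coords, axis)
        nc = self.shape[1] if axis == 0 else self.shape[0]
        n = len(i)
        rows = np.repeat(np.arange(n), 4)
        cols = np.stack([i - 1, i, i + 1, i + 2], axis=1).ravel()
        w = np.stack(_bspline_weights(t), axis=1).ravel()
        return sparse.csr_matrix((w, (rows, cols)), shape=(n, nc))


def ffd_displacement(grid: BsplineControlGrid, points: np.ndarray) -> np.ndarray:
    """Evaluate the FFD displacement (mm) at arbitrary points (N, 2) mm."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ix, tx = grid._index(pts[:, 0], axis=0)
    iy, ty = grid._index(pts[:, 1], axis=1)
    wx = np.stack(_bspline_weights(tx), axis=1)  # (N, 4)
    wy = np.stack(_bspline_weights(ty), axis=1)
    out = np.zeros((len(pts), 2))
    C = grid.coefficients
    for a in range(4):
        for b in range(4):
            out += (wy[:, a] * wx[:, b])[:, None] * C[iy + a - 1, ix + b - 1]
    return out


def _dense_field(ctrl: BsplineControlGrid, grid: ImageGrid,
                 Bx: sparse.csr_matrix | None = None,
                 By: sparse.csr_matrix | None = None) -> np.ndarray:
    """Dense (ny, nx, 2) displacement field of the FFD on an image grid."""
    if Bx is None:
        Bx = ctrl.basis_matrix(grid.x, axis=0)
    if By is None:
        By = ctrl.basis_matrix(grid.y, axis=1)
    out = np.empty((grid.ny, grid.nx, 2))
    for c in range(2):
        out[..., c] = By @ ctrl.coefficients[..., c] @ Bx.T
    return out


@dataclass
class MVF:
    """Dense non-rigid displacement field (mm per pixel) plus its control grid.

    Convention: forward displacement of material points from the BEFORE PAR
    state to the AFTER PAR state, indexed by target-frame position.  The zero
    field is the identity transform.
    """

    grid: ImageGrid
    field: np.ndarray  # (ny, nx, 2) mm; [..., 0] = dx, [..., 1] = dy
    control: BsplineControlGrid | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        if self.field.shape != (self.grid.ny, self.grid.nx, 2):
            raise ValueError("MVF field shape must be (ny, nx, 2)")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("MVF contains non-finite values")

    @classmethod
    def zero(cls, grid: ImageGrid) -> "MVF":
        return cls(grid=grid, field=np.zeros((grid.ny, grid.nx, 2)))


def scale_mvf(mvf: MVF, alpha: float) -> MVF:
    """Pointwise time-scaling of the field (linear motion model)."""
    return MVF(grid=mvf.grid, field=alpha * mvf.field, control=mvf.control,
               info=dict(mvf.info, alpha=float(alpha)))


def alpha_for_view(theta: float, theta_c: float) -> float:
    """Linear time-interpolation factor for the view at angle ``theta``.

    0 at the target angle, -/+0.5 at the conjugate PAR centers 90 degrees
    away (the full MVF spans the before-to-after half-rotation interval).
    """
    d = (theta - theta_c + 180.0) % 360.0 - 180.0
    return d / 180.0


def warp_image(img: Image, mvf: MVF, direction: Literal["pull", "push"] = "pull",
               background: float = 0.0) -> Image:
    """Apply a displacement field to an image.

    Pull (default): ``out(X) = img(X + D(X))`` with bilinear sampling, so
    warping the AFTER image by the full MVF aligns it with the BEFORE image;
    a uniform field (dx, 0) therefore translates content by -dx.  Push
    forward-splats pixels and is for visualization only.
    """
    if mvf.grid != img.grid:
        raise ValueError("MVF and image grids differ")
    sp = img.grid.pixel_spacing
    if direction == "pull":
        jj, ii = np.meshgrid(np.arange(img.grid.nx), np.arange(img.grid.ny))
        ci = ii + mvf.field[..., 1] / sp
        cj = jj + mvf.field[..., 0] / sp
        out = map_coordinates(img.values, [ci, cj], order=1, mode="constant",
                              cval=background)
    elif direction == "push":
        out = np.full(img.grid.shape, background)
        cnt = np.zeros(img.grid.shape)
        jj, ii = np.meshgrid(np.arange(img.grid.nx), np.arange(img.grid.ny))
        ti = np.clip(np.round(ii + mvf.field[..., 1] / sp).astype(int), 0,
                     img.grid.ny - 1)
        tj = np.clip(np.round(jj + mvf.field[..., 0] / sp).astype(int), 0,
                     img.grid.nx - 1)
        np.add.at(out, (ti, tj), img.values)
        np.add.at(cnt, (ti, tj), 1.0)
        nz = cnt > 0
        out[nz] /= cnt[nz]
    else:
        raise ValueError("direction must be 'pull' or 'push'")
    return img.copy_with(out, warped=direction)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationParams:
    """Settings of the coarse-to-fine FFD registration."""

    control_spacing: tuple[float, ...] = (24.0, 12.0)  # mm, coarse to fine
    similarity: Literal["ssd", "ncc"] = "ssd"
    lambda_bending: float = 0.01  # relative to the pixel-normalized data term
    max_iter: int = 100  # per level
    tol: float = 1.0e-6  # relative cost change
    smooth_factor: float = 0.25  # image pre-smoothing sigma = factor * spacing
    min_explained: float = 0.5  # accept the field only if it explains this
    # fraction of the initial PAR mismatch; below it the pair is deemed
    # conjugate-consistent (no detectable motion) and the zero field returned

    def __post_init__(self) -> None:
        if len(self.control_spacing) < 1:
            raise ValueError("need at least one resolution level")
        if any(s <= 0 for s in self.control_spacing):
            raise ValueError("control spacings must be positive")
        if self.lambda_bending < 0:
            raise ValueError("lambda_bending must be >= 0")


def _bending_energy_and_grad(C: np.ndarray,
                             spacing: float) -> tuple[float, np.ndarray]:
    """Thin-plate bending energy of the control lattice and its gradient.

    Sum over components of ||Dyy||^2 + 2 ||Dxy||^2 + ||Dxx||^2 of second
    finite differences of the coefficients, normalized by the lattice size
    and the control spacing so the energy is dimensionless and comparable to
    the range-normalized data term.
    """
    n = C.shape[0] * C.shape[1] * 1.0
    g = np.zeros_like(C)
    e = 0.0
    dxx = C[:, :-2] - 2.0 * C[:, 1:-1] + C[:, 2:]
    e += np.sum(dxx**2)
    g[:, :-2] += 2.0 * dxx
    g[:, 1:-1] += -4.0 * dxx
    g[:, 2:] += 2.0 * dxx
    dyy = C[:-2] - 2.0 * C[1:-1] + C[2:]
    e += np.sum(dyy**2)
    g[:-2] += 2.0 * dyy
    g[1:-1] += -4.0 * dyy
    g[2:] += 2.0 * dyy
    dxy = C[1:, 1:] - C[1:, :-1] - C[:-1, 1:] + C[:-1, :-1]
    e += 2.0 * np.sum(dxy**2)
    g[1:, 1:] += 4.0 * dxy
    g[1:, :-1] += -4.0 * dxy
    g[:-1, 1:] += -4.0 * dxy
    g[:-1, :-1] += 4.0 * dxy
    scale = 1.0 / (n * spacing * spacing)
    return e * scale, g * scale


class _SimilarityTerm:
    """Pixel- and range-normalized similarity and its gradient wrt the dense
    displacement field.

    SSD is divided by the squared dynamic range of the fixed image, which
    makes the cost (and hence the registration) invariant to a common
    rescaling of the PAR pair.  Sampling extends edge values outward so the
    cost is continuous at the zero field.
    """

    def __init__(self, fixed: np.ndarray, moving: np.ndarray, spacing: float,
                 kind: str):
        self.fixed = fixed
        self.moving = moving
        self.spacing = spacing
        self.kind = kind
        gy, gx = np.gradient(moving, spacing)
        self._gx, self._gy = gx, gy
        ny, nx = moving.shape
        jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
        self._ii, self._jj = ii, jj
        self.n = moving.size
        rng = float(np.ptp(fixed))
        self._range2 = rng * rng if rng > 0 else 1.0

    def __call__(self, D: np.ndarray) -> tuple[float, np.ndarray]:
        ci = self._ii + D[..., 1] / self.spacing
        cj = self._jj + D[..., 0] / self.spacing
        w = map_coordinates(self.moving, [ci, cj], order=1, mode="nearest")
        gx = map_coordinates(self._gx, [ci, cj], order=1, mode="nearest")
        gy = map_coordinates(self._gy, [ci, cj], order=1, mode="nearest")
        if self.kind == "ssd":
            r = w - self.fixed
            norm = self.n * self._range2
            cost = float(np.sum(r * r)) / norm
            dw = 2.0 * r / norm  # d cost / d warped-value
        elif self.kind == "ncc":
            f = self.fixed - self.fixed.mean()
            wz = w - w.mean()
            nf = math.sqrt(float(np.sum(f * f))) + 1e-30
            nw = math.sqrt(float(np.sum(wz * wz))) + 1e-30
            ncc = float(np.sum(f * wz)) / (nf * nw)
            cost = 1.0 - ncc
            dw = -(f / (nf * nw) - ncc * wz / (nw * nw))
            dw -= dw.mean()
        else:
            raise ValueError(f"unknown similarity {self.kind!r}")
        grad = np.stack([dw * gx, dw * gy], axis=-1)  # d cost / d D (per mm)
        return cost, grad


def _fit_coefficients(ctrl: BsplineControlGrid, grid: ImageGrid,
                      D: np.ndarray) -> None:
    """Least-squares fit of control coefficients to a dense field (in place).

    Separable normal equations; exact when the field lies in the spline space
    (e.g. when refining from a nested coarser lattice).
    """
    Bx = ctrl.basis_matrix(grid.x, axis=0).toarray()
    By = ctrl.basis_matrix(grid.y, axis=1).toarray()
    Gx = Bx.T @ Bx + 1e-9 * np.eye(Bx.shape[1])
    Gy = By.T @ By + 1e-9 * np.eye(By.shape[1])
    for c in range(2):
        rhs = By.T @ D[..., c] @ Bx
        ctrl.coefficients[..., c] = np.linalg.solve(
            Gy, np.linalg.solve(Gx.T, rhs.T).T)


def register_ffd(fixed: Image, moving: Image,
                 params: RegistrationParams | None = None) -> MVF:
    """Estimate the FFD displacement aligning ``moving`` onto ``fixed``.

    Minimizes ``similarity(fixed, moving(X + D(X))) + lambda * bending(C)``
    over B-spline coefficients by Armijo-backtracked gradient descent,
    coarse-to-fine over the configured control spacings.  Fully deterministic:
    identical inputs give bit-identical fields.  Returns the displacement that
    pulls the moving image onto the fixed one — for conjugate PARs with
    ``fixed=before``, ``moving=after`` this is the before-to-after material
    displacement.
    """
    if params is None:
        params = RegistrationParams()
    if fixed.grid != moving.grid:
        raise ValueError("fixed and moving images must share one grid")
    if not (np.all(np.isfinite(fixed.values)) and np.all(np.isfinite(moving.values))):
        raise ValueError("non-finite pixels in registration input")

    grid = fixed.grid
    sp = grid.pixel_spacing
    D = np.zeros((grid.ny, grid.nx, 2))
    ctrl: BsplineControlGrid | None = None
    history: list[float] = []

    for level, spacing in enumerate(params.control_spacing):
        sigma_px = max(0.0, params.smooth_factor * spacing / sp)
        if sigma_px > 0.3:
            f_l = gaussian_filter(fixed.values, sigma_px, mode="nearest")
            m_l = gaussian_filter(moving.values, sigma_px, mode="nearest")
        else:
            f_l, m_l = fixed.values, moving.values
        sim = _SimilarityTerm(f_l, m_l, sp, params.similarity)

        ctrl = BsplineControlGrid.covering(grid, spacing)
        if level > 0:
            _fit_coefficients(ctrl, grid, D)
        Bx = ctrl.basis_matrix(grid.x, axis=0)
        By = ctrl.basis_matrix(grid.y, axis=1)

        def total_cost(C: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
            Dl = np.empty_like(D)
            for c in range(2):
                Dl[..., c] = By @ C[..., c] @ Bx.T
            data, gD = sim(Dl)
            bend, gB = _bending_energy_and_grad(C, spacing)
            gC = np.empty_like(C)
            for c in range(2):
                gC[..., c] = By.T @ gD[..., c] @ Bx
            gC += params.lambda_bending * gB
            return data + params.lambda_bending * bend, gC, Dl

        C = ctrl.coefficients
        cost, gC, Dl = total_cost(C)
        step = None
        for it in range(params.max_iter):
            gmax = float(np.max(np.abs(gC)))
            if gmax == 0.0:
                break
            if step is None:
                step = 0.4 * spacing / gmax  # cap first move at 0.4 spacing
            accepted = False
            for _ in range(25):
                C_new = C - step * gC
                new_cost, new_gC, new_Dl = total_cost(C_new)
                if new_cost <= cost - 1e-4 * step * float(np.sum(gC * gC)):
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            rel = (cost - new_cost) / max(abs(cost), 1e-30)
            C, cost, gC, Dl = C_new, new_cost, new_gC, new_Dl
            history.append(cost)
            step *= 1.8  # allow the step to grow again
            if not np.isfinite(cost):
                raise RuntimeError("registration diverged: non-finite cost")
            if rel < params.tol:
                break
        ctrl.coefficients = C
        D = Dl

    # Motion-detectability gate: a smooth FFD cannot halve pure
    # interpolation/filtering residue between conjugate-consistent PARs,
    # while genuine motion within capture range is explained almost fully.
    # If the field fails to explain the mismatch, report no motion.
    check = _SimilarityTerm(fixed.values, moving.values, sp, params.similarity)
    c_zero, _ = check(np.zeros_like(D))
    c_final, _ = check(D)
    explained = (c_zero - c_final) / c_zero if c_zero > 0 else 0.0
    if explained < params.min_explained:
        return MVF(grid=grid, field=np.zeros_like(D), control=None,
                   info={"params": params, "cost_history": history,
                         "final_cost": history[-1] if history else None,
                         "explained_fraction": explained,
                         "motion_detected": False})

    return MVF(grid=grid, field=D, control=ctrl,
               info={"params": params, "cost_history": history,
                     "final_cost": history[-1] if history else None,
                     "explained_fraction": explained,
                     "motion_detected": True})
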