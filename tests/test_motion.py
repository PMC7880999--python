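"""FFD displacement model, non-rigid registration, time scaling, warping."""

import inspect

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from parmotion import (ImageGrid, MVF, RegistrationParams, alpha_for_view,
                       ffd_displacement, register_ffd, scale_mvf, warp_image)
from parmotion.grid import Image
from parmotion.motion import BsplineControlGrid, _dense_field


@pytest.fixture
def lattice():
    grid = ImageGrid(64, 64, 1.0)
    return grid, BsplineControlGrid.covering(grid, spacing=8.0)


def blob_image(grid: ImageGrid, shift=(0.0, 0.0), seed=3) -> Image:
    """Smooth multi-blob test image with analytic translation support."""
    rng = np.random.default_rng(seed)
    X, Y = grid.meshgrid()
    v = np.zeros(grid.shape)
    for _ in range(12):
        cx, cy = rng.uniform(-20, 20, 2)
        s = rng.uniform(3, 6)
        a = rng.uniform(0.5, 1.0)
        v += a * np.exp(-((X - shift[0] - cx) ** 2
                          + (Y - shift[1] - cy) ** 2) / (2 * s * s))
    return Image(grid=grid, values=v)


class TestFFDDisplacement:
    def test_zero_coefficients_identity(self, lattice):
        grid, ctrl = lattice
        pts = np.array([[0.0, 0.0], [10.0, -5.0]])
        assert np.all(ffd_displacement(ctrl, pts) == 0)

    def test_partition_of_unity(self, lattice):
        grid, ctrl = lattice
        ctrl.coefficients[..., 0] = 3.0
        ctrl.coefficients[..., 1] = -1.5
        pts = np.stack(np.meshgrid(np.linspace(-25, 25, 9),
                                   np.linspace(-25, 25, 9)), -1).reshape(-1, 2)
        d = ffd_displacement(ctrl, pts)
        assert np.allclose(d[:, 0], 3.0) and np.allclose(d[:, 1], -1.5)

    def test_central_basis_weight(self, lattice):
        """A single unit coefficient contributes (2/3)^2 at its own node."""
        grid, ctrl = lattice
        ky, kx = 5, 6
        ctrl.coefficients[ky, kx, 0] = 1.0
        px = ctrl.origin[0] + kx * ctrl.spacing
        py = ctrl.origin[1] + ky * ctrl.spacing
        d = ffd_displacement(ctrl, np.array([[px, py]]))
        assert d[0, 0] == pytest.approx((2.0 / 3.0) ** 2, rel=1e-12)

    def test_outside_extent_rejected(self, lattice):
        grid, ctrl = lattice
        with pytest.raises(ValueError, match="extent"):
            ffd_displacement(ctrl, np.array([[500.0, 0.0]]))


class TestRegistration:
    def test_identity_recovery(self):
        grid = ImageGrid(96, 96, 1.0)
        img = blob_image(grid)
        mvf = register_ffd(img, img)
        assert np.abs(mvf.field).max() < 0.05

    def test_translation_recovery(self):
        grid = ImageGrid(96, 96, 1.0)
        fixed = blob_image(grid)
        # moving displaced by the before->after translation (2.0, -1.5) px:
        # material at fixed-position x appears at x + t in the moving image
        t = np.array([2.0, -1.5])
        moving = blob_image(grid, shift=(t[0], t[1]))
        mvf = register_ffd(fixed, moving)
        mask = fixed.values > 0.2 * fixed.values.max()
        est = mvf.field[mask].mean(axis=0)
        assert np.abs(est - t).max() < 0.2

    def test_known_ffd_recovery(self):
        grid = ImageGrid(96, 96, 1.0)
        fixed = blob_image(grid)
        ctrl = BsplineControlGrid.covering(grid, spacing=24.0)
        rng = np.random.default_rng(7)
        ctrl.coefficients[:] = gaussian_filter(
            rng.normal(0, 2.0, ctrl.coefficients.shape), (1, 1, 0))
        D = _dense_field(ctrl, grid)
        # moving(x) = fixed(x + D(x)) is exactly the pull-warp of fixed
        moving = warp_image(fixed, MVF(grid=grid, field=D))
        mvf = register_ffd(fixed, moving)
        mask = fixed.values > 0.2 * fixed.values.max()
        # registration pulls moving onto fixed: recovered field ~ -D... check
        # convention: moving(x + U) = fixed(x) => U satisfies
        # fixed(x + U + D(x+U)) = fixed(x), so U ~ -D for smooth small D
        epe = np.sqrt(np.sum((mvf.field + D) ** 2, axis=-1))
        assert np.sqrt(np.mean(epe[mask] ** 2)) < 0.5

    def test_determinism(self):
        grid = ImageGrid(64, 64, 1.0)
        fixed = blob_image(grid)
        moving = blob_image(grid, shift=(1.0, 0.5))
        a = register_ffd(fixed, moving)
        b = register_ffd(fixed, moving)
        assert np.array_equal(a.field, b.field)

    def test_cost_nonincreasing(self):
        grid = ImageGrid(64, 64, 1.0)
        fixed = blob_image(grid)
        moving = blob_image(grid, shift=(1.5, -1.0))
        params = RegistrationParams(control_spacing=(16.0,))
        mvf = register_ffd(fixed, moving, params)
        h = np.asarray(mvf.info["cost_history"])
        assert len(h) > 0 and np.all(np.diff(h) <= 1e-15)

    def test_nonfinite_input_rejected(self):
        grid = ImageGrid(32, 32, 1.0)
        img = blob_image(grid)
        with pytest.raises(ValueError):
            bad = Image(grid=grid, values=img.values.copy())
            bad.values[0, 0] = np.nan
            register_ffd(img, bad)

    def test_no_segmentation_in_estimation_path(self):
        """Registration consumes only the two images and its parameters."""
        sig = inspect.signature(register_ffd)
        assert list(sig.parameters) == ["fixed", "moving", "params"]


class TestAlphaForView:
    @pytest.mark.parametrize("theta,expected", [
        (90.0, 0.0), (180.0, 0.5), (0.0, -0.5), (45.0, -0.25), (135.0, 0.25)])
    def test_linear_interpolation_factor(self, theta, expected):
        assert alpha_for_view(theta, 90.0) == pytest.approx(expected)

    def test_wraps_angles(self):
        assert alpha_for_view(360.0 + 135.0, 90.0) == pytest.approx(0.25)


class TestScaleAndWarp:
    def _mvf(self, grid, dx=2.0, dy=-1.0):
        f = np.zeros((grid.ny, grid.nx, 2))
        f[..., 0] = dx
        f[..., 1] = dy
        return MVF(grid=grid, field=f)

    def test_scale_zero_and_identity(self):
        grid = ImageGrid(16, 16, 1.0)
        mvf = self._mvf(grid)
        assert np.all(scale_mvf(mvf, 0.0).field == 0)
        assert np.array_equal(scale_mvf(mvf, 1.0).field, mvf.field)

    def test_scale_antisymmetry(self):
        grid = ImageGrid(16, 16, 1.0)
        mvf = self._mvf(grid)
        s = scale_mvf(mvf, -0.5).field + scale_mvf(mvf, 0.5).field
        assert np.all(s == 0)

    def test_warp_zero_field_identity(self):
        grid = ImageGrid(32, 32, 1.0)
        img = blob_image(grid)
        out = warp_image(img, MVF.zero(grid))
        assert np.array_equal(out.values, img.values)

    def test_warp_pull_sign_convention(self):
        """Pull-warping by (dx, 0) translates content by -dx."""
        grid = ImageGrid(32, 32, 1.0)
        v = np.zeros(grid.shape)
        v[16, 20] = 1.0
        img = Image(grid=grid, values=v)
        out = warp_image(img, self._mvf(grid, dx=3.0, dy=0.0))
        assert out.values[16, 17] == pytest.approx(1.0)

    def test_inverse_consistency(self):
        grid = ImageGrid(96, 96, 1.0)
        img = blob_image(grid)
        ctrl = BsplineControlGrid.covering(grid, spacing=24.0)
        rng = np.random.default_rng(11)
        ctrl.coefficients[:] = rng.normal(0, 1.0, ctrl.coefficients.shape)
        D = _dense_field(ctrl, grid)
        fwd = warp_image(img, MVF(grid=grid, field=D))
        back = warp_image(fwd, MVF(grid=grid, field=-D))
        rng_v = np.ptp(img.values)
        inner = np.s_[8:-8, 8:-8]
        rmse = np.sqrt(np.mean((back.values - img.values)[inner] ** 2))
        assert rmse < 0.02 * rng_v

    def test_grid_mismatch_rejected(self):
        img = blob_image(ImageGrid(32, 32, 1.0))
        with pytest.raises(ValueError):
            warp_image(img, MVF.zero(ImageGrid(16, 16, 1.0)))
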