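"""Simulator: phantom construction, actuator motion, analytic projection,
fan-to-parallel rebinning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from parmotion import (ImageGrid, MotionTrajectory, Primitive, ScanGeometry,
                       build_phantom, combined_stroke, displacement_at,
                       forward_project_fan, hu_to_mu, path_per_rotation,
                       rasterize, rebin_fan_to_parallel)

from conftest import water_disk


class TestBuildPhantom:
    def test_single_water_disk(self):
        ph = water_disk(radius=100.0)
        assert len(ph.primitives) == 1
        assert ph.background_value == -1000.0
        assert ph.primitives[0].outer_radius == 100.0

    def test_copd_preset_contract(self):
        ph = build_phantom("copd_like")
        assert len(ph.primitives) >= 13
        air = [p for p in ph.primitives
               if p.shape == "disk" and p.value == -1000.0
               and p.center != (0.0, 0.0)]
        tubes = [p for p in ph.primitives if p.shape == "annulus"]
        assert len(set(round(p.outer_radius, 3) for p in air)) >= 6
        assert len(tubes) >= 6
        walls = [p.outer_radius - p.inner_radius for p in tubes]
        assert min(walls) <= 0.5 and max(walls) >= 3.0
        for p in ph.primitives:
            assert np.hypot(*p.center) + p.outer_radius <= 180.0

    def test_rejects_unknown_preset(self):
        with pytest.raises(ValueError, match="preset"):
            build_phantom("nope")

    def test_invalid_primitive_radii(self):
        with pytest.raises(ValueError):
            Primitive("annulus", (0, 0), 4.0, inner_radius=5.0, value=100)

    def test_annulus_wall_mean_hu(self):
        """A rasterized thin ring keeps its nominal wall CT number."""
        ph = build_phantom({"background": -1000, "primitives": [
            {"shape": "annulus", "center": (0, 0), "outer_radius": 5,
             "inner_radius": 4, "value": 100}]})
        grid = ImageGrid(101, 101, 0.2)
        img = rasterize(ph, grid, antialias=3)
        X, Y = grid.meshgrid()
        r = np.hypot(X, Y)
        wall = (r > 4.2) & (r < 4.8)  # interior of the wall, off the edges
        assert img.values[wall].mean() == pytest.approx(100.0, abs=5.0)


class TestMotionTrajectory:
    def test_static_displacement(self):
        traj = MotionTrajectory()
        assert np.all(displacement_at(traj, 123.4) == 0)

    def test_zero_phase_origin(self):
        traj = MotionTrajectory(kind="periodic_1d", amplitude=(20, 7.5), rpm=5)
        assert np.allclose(displacement_at(traj, 0.0), 0.0)

    def test_quarter_cycle_extremum(self):
        traj = MotionTrajectory(kind="periodic_1d", amplitude=(20, 7.5), rpm=5)
        assert np.allclose(displacement_at(traj, 3.0), [20.0, 7.5])

    def test_negative_rpm_rejected(self):
        with pytest.raises(ValueError):
            MotionTrajectory(kind="periodic_1d", rpm=-1.0)

    @given(st.floats(0.0, 100.0), st.floats(1.0, 30.0))
    def test_periodicity(self, t, rpm):
        traj = MotionTrajectory(kind="periodic_1d", amplitude=(20, 7.5),
                                rpm=rpm, phase0=0.3)
        d1 = displacement_at(traj, t)
        d2 = displacement_at(traj, t + 60.0 / rpm)
        assert np.allclose(d1, d2, atol=1e-9)

    @given(st.floats(-10.0, 10.0))
    def test_amplitude_bound(self, t):
        traj = MotionTrajectory(kind="periodic_1d", amplitude=(20, 7.5),
                                rpm=7.0, phase0=1.1)
        d = displacement_at(traj, t)
        assert abs(d[0]) <= 20.0 + 1e-12 and abs(d[1]) <= 7.5 + 1e-12

    def test_triangle_waveform_extrema(self):
        traj = MotionTrajectory(kind="periodic_1d", amplitude=(10, 0),
                                rpm=60.0, waveform="triangle")
        assert np.allclose(displacement_at(traj, 0.25), [10.0, 0.0])
        assert np.allclose(displacement_at(traj, 0.75), [-10.0, 0.0])


class TestPathPerRotation:
    def test_static_is_zero(self):
        assert path_per_rotation(MotionTrajectory(), 0.5) == 0.0

    def test_combined_stroke(self):
        traj = MotionTrajectory(kind="periodic_1d", amplitude=(20, 7.5), rpm=5)
        assert combined_stroke(traj) == pytest.approx(42.7, abs=0.05)

    @pytest.mark.parametrize("rpm,expected", [(5, 3.6), (10, 7.1), (15, 10.7)])
    def test_actuator_travel_per_rotation(self, rpm, expected):
        """Per-rotation travel for the +-20 / +-7.5 mm stroke settings."""
        traj = MotionTrajectory(kind="periodic_1d", amplitude=(20, 7.5),
                                rpm=rpm)
        assert round(path_per_rotation(traj, 0.5), 1) == expected

    @given(st.floats(0.5, 30.0), st.floats(0.5, 30.0))
    def test_linear_in_rpm(self, rpm, factor):
        t1 = MotionTrajectory(kind="periodic_1d", amplitude=(20, 7.5), rpm=rpm)
        t2 = MotionTrajectory(kind="periodic_1d", amplitude=(20, 7.5),
                              rpm=rpm * factor)
        assert path_per_rotation(t2, 0.5) == pytest.approx(
            factor * path_per_rotation(t1, 0.5), rel=1e-12)


class TestRasterize:
    def test_disk_values(self):
        ph = water_disk(radius=50.0)
        grid = ImageGrid(101, 101, 2.0)
        img = rasterize(ph, grid, antialias=1)
        X, Y = grid.meshgrid()
        r = np.hypot(X, Y)
        assert np.all(img.values[r < 45] == 0.0)
        assert np.all(img.values[r > 55] == -1000.0)

    def test_translation_equivariance(self):
        ph = water_disk(radius=30.0)
        grid = ImageGrid(128, 128, 1.0)
        a = rasterize(ph, grid, displacement=(10.0, 0.0), antialias=1)
        b = rasterize(ph, grid, antialias=1)
        assert np.array_equal(a.values, np.roll(b.values, 10, axis=1))

    def test_antialias_boundary_intermediate(self):
        ph = water_disk(radius=30.0)
        grid = ImageGrid(128, 128, 1.0)
        img = rasterize(ph, grid, antialias=3)
        between = (img.values > -999) & (img.values < -1)
        assert between.any()


class TestForwardProjectFan:
    def test_central_channel_diameter_chord(self, small_geometry):
        ph = water_disk(radius=100.0)
        fan = forward_project_fan(ph, small_geometry)
        mu = hu_to_mu(0.0)
        centre = small_geometry.n_channels // 2
        assert fan.values[:, centre] == pytest.approx(2 * 100 * mu, rel=1e-12)

    def test_rotational_symmetry(self, small_geometry):
        ph = water_disk(radius=100.0)
        fan = forward_project_fan(ph, small_geometry)
        assert np.ptp(fan.values, axis=0).max() < 1e-9

    def test_annulus_chord_closed_form(self, small_geometry):
        ph = build_phantom({"background": -1000, "primitives": [
            {"shape": "annulus", "center": (0, 0), "outer_radius": 50,
             "inner_radius": 30, "value": 0}]})
        fan = forward_project_fan(ph, small_geometry)
        mu = hu_to_mu(0.0)
        gammas = np.radians(small_geometry.channel_angles)
        d = np.abs(small_geometry.source_to_iso * np.sin(gammas))
        ro, ri = 50.0, 30.0
        expect = mu * (2 * np.sqrt(np.maximum(ro**2 - d**2, 0))
                       - 2 * np.sqrt(np.maximum(ri**2 - d**2, 0)))
        assert np.allclose(fan.values[0], expect, atol=1e-9)

    def test_nonnegative_for_nonnegative_mu(self, small_geometry):
        fan = forward_project_fan(build_phantom("copd_like"), small_geometry)
        assert fan.values.min() >= -1e-12

    def test_background_must_be_air(self, small_geometry):
        ph = build_phantom({"background": 0.0, "primitives": []})
        with pytest.raises(ValueError, match="air"):
            forward_project_fan(ph, small_geometry)


class TestRebinning:
    def test_centered_disk_closed_form(self, small_geometry):
        """Rebinned p(theta, s) = 2 mu sqrt(R^2 - s^2), every view."""
        sino = rebin_fan_to_parallel(
            forward_project_fan(water_disk(radius=80.0), small_geometry))
        mu = hu_to_mu(0.0)
        expect = 2 * mu * np.sqrt(np.maximum(80.0**2 - sino.s**2, 0))
        inside = np.abs(sino.s) < 80.0 - 2 * sino.ds  # off the sqrt edge
        err = np.abs(sino.values[:, inside] - expect[None, inside]).max() \
            / expect.max()
        assert err < 0.01

    def test_offcenter_disk_closed_form_rmse(self, disk_sinogram):
        """Off-center disk: agreement in relative RMSE (the max-norm error is
        dominated by the square-root edge, where interpolation error of any
        finite sampling concentrates)."""
        ph, sino = disk_sinogram
        mu = hu_to_mu(0.0)
        c = np.array([20.0, -10.0])
        th = np.radians(sino.angles)
        proj_c = c[0] * np.cos(th) + c[1] * np.sin(th)
        expect = 2 * mu * np.sqrt(
            np.maximum(80.0**2 - (sino.s[None, :] - proj_c[:, None])**2, 0))
        rel_rmse = np.sqrt(np.mean((sino.values - expect) ** 2)) / expect.max()
        assert rel_rmse < 0.01

    def test_conjugacy(self, disk_sinogram):
        _, sino = disk_sinogram
        half = [i for i, a in enumerate(sino.angles)
                if a + 180.0 <= sino.angles[-1] + 1e-9][:200]
        dtheta = sino.dtheta
        vmax = sino.values.max()
        for i in half[::20]:
            j = int(round(i + 180.0 / dtheta))
            diff = np.abs(sino.values[i] - sino.values[j][::-1]).max()
            assert diff < 0.01 * vmax

    def test_mass_conservation(self, disk_sinogram):
        _, sino = disk_sinogram
        mass = sino.values.sum(axis=1) * sino.ds
        assert np.ptp(mass) / mass.mean() < 0.005

    def test_translation_peak_position(self, small_geometry):
        """A displaced disk's rebinned profile peaks at s = c . n(theta)."""
        ph = water_disk(center=(30.0, 15.0), radius=20.0)
        sino = rebin_fan_to_parallel(forward_project_fan(ph, small_geometry))
        for i in range(0, len(sino.angles), 97):
            th = np.radians(sino.angles[i])
            expect = 30.0 * np.cos(th) + 15.0 * np.sin(th)
            peak = sino.s[np.argmax(sino.values[i])]
            assert abs(peak - expect) <= sino.ds

    def test_zero_sinogram_maps_to_zero(self, small_geometry):
        ph = build_phantom({"background": -1000, "primitives": []})
        sino = rebin_fan_to_parallel(forward_project_fan(ph, small_geometry))
        assert np.all(sino.values == 0)

    def test_insufficient_coverage_error(self):
        geom = ScanGeometry(n_channels=101, views_per_rotation=720,
                            fan_angle=50.0, n_rotations=1)
        fan = forward_project_fan(water_disk(), geom)
        fan_short = type(fan)(values=fan.values[:200],
                              view_angles=fan.view_angles[:200],
                              view_times=fan.view_times[:200],
                              geometry=geom)
        with pytest.raises(ValueError, match="insufficient"):
            rebin_fan_to_parallel(fan_short)

    def test_parallel_times_increase(self, disk_sinogram):
        _, sino = disk_sinogram
        assert np.all(np.diff(sino.view_times) > 0)


def test_undersampled_geometry_warns():
    with pytest.warns(UserWarning, match="angular sampling"):
        ScanGeometry(n_channels=736, views_per_rotation=1000)
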