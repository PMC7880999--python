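import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from parmotion import (ExperimentConfig, ImageGrid, MotionTrajectory,
                       ScanGeometry, build_phantom, fbp_half,
                       forward_project_fan, rebin_fan_to_parallel)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def water_disk(center=(0.0, 0.0), radius=80.0):
    return build_phantom({"background": -1000, "primitives": [
        {"shape": "disk", "center": center, "outer_radius": radius,
         "value": 0.0}]})


@pytest.fixture(scope="session")
def small_geometry():
    """Fast fan geometry with >180 deg + fan coverage for half-scan work."""
    return ScanGeometry(n_channels=301, views_per_rotation=720,
                        fan_angle=50.0, start_angle=-120.0)


@pytest.fixture(scope="session")
def disk_sinogram(small_geometry):
    """Rebinned parallel sinogram of a static off-center water disk."""
    phantom = water_disk(center=(20.0, -10.0))
    fan = forward_project_fan(phantom, small_geometry)
    return phantom, rebin_fan_to_parallel(fan)


@pytest.fixture(scope="session")
def recon_grid_256():
    return ImageGrid(256, 256, 360.0 / 256)


@pytest.fixture(scope="session")
def desk_config():
    """Desk-scale experiment configuration shared by slow tests."""
    return ExperimentConfig(n_slices=1, grid_n=256)


@pytest.fixture(scope="session")
def copd_static(desk_config):
    """Static scan products of the lung phantom: (sinogram, fbp image)."""
    phantom = build_phantom(desk_config.phantom)
    geom = desk_config.scan_geometry()
    grid = desk_config.recon_grid()
    sino = rebin_fan_to_parallel(forward_project_fan(phantom, geom))
    return phantom, sino, fbp_half(sino, grid, desk_config.theta_c)


@pytest.fixture(scope="session")
def copd_moving_15rpm(desk_config):
    """Moving scan (15 rpm equivalent) products: (trajectory, sinogram)."""
    phantom = build_phantom(desk_config.phantom)
    geom = desk_config.scan_geometry()
    traj = MotionTrajectory(kind="periodic_1d", amplitude=(20.0, 7.5),
                            rpm=15.0, phase0=0.7)
    sino = rebin_fan_to_parallel(forward_project_fan(phantom, geom, traj))
    return traj, sino
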