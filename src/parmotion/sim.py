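"""Moving-phantom CT simulator: analytic phantoms, periodic actuator motion,
fan-beam forward projection and fan-to-parallel rebinning.

The simulator emulates an axial scan of a lung-simulating phantom (a body
shell around lung-equivalent foam holding air columns and polycarbonate
"airway" tubes) mounted on a periodic motion actuator.  Projections are exact
analytic line integrals through disks and annuli, with the phantom rigidly
displaced per view; motion is frozen within a view.

Geometry conventions
--------------------
Angles are degrees in every interface and radians internally.  A parallel
view at angle ``theta`` integrates along the direction
``d(theta) = (-sin, cos)(theta)`` over lines offset by the radial coordinate
``s`` along ``n(theta) = (cos, sin)(theta)``; at ``theta = 0`` rays run along
+y and ``s`` along +x.  A fan view at angle ``beta`` with channel (fan) angle
``gamma`` is the same line as the parallel ray ``theta = beta + gamma``,
``s = R * sin(gamma)`` with ``R`` the source-to-isocenter distance.

CT numbers map to linear attenuation via ``mu = mu_water * (1 + HU / 1000)``
(monochromatic approximation); air (-1000 HU) has ``mu = 0``, which the
analytic projector requires of the background.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .grid import Image, ImageGrid

MU_WATER_PER_MM = 0.019  # /mm, ~70 keV effective energy


def hu_to_mu(hu, mu_water: float = MU_WATER_PER_MM):
    """Hounsfield units -> linear attenuation coefficient (/mm)."""
    return mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0)


def mu_to_hu(mu, mu_water: float = MU_WATER_PER_MM):
    """Linear attenuation coefficient (/mm) -> Hounsfield units."""
    return 1000.0 * (np.asarray(mu, dtype=float) / mu_water - 1.0)


# ---------------------------------------------------------------------------
# Phantom model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Primitive:
    """A disk or annulus of uniform CT number.

    ``inner_radius`` is 0 for disks.  The hole of an annulus exposes whatever
    lies beneath it in the z-order.
    """

    shape: Literal["disk", "annulus"]
    center: tuple[float, float]  # mm
    outer_radius: float  # mm
    inner_radius: float = 0.0  # mm
    value: float = 0.0  # HU

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "annulus"):
            raise ValueError(f"unknown primitive shape {self.shape!r}")
        if not (self.outer_radius > self.inner_radius >= 0.0):
            raise ValueError("need outer_radius > inner_radius >= 0")
        if self.shape == "disk" and self.inner_radius != 0.0:
            raise ValueError("a disk has inner_radius 0")
        if not np.isfinite(self.value):
            raise ValueError("primitive value must be finite")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r2 = (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2
        inside = r2 <= self.outer_radius**2
        if self.inner_radius > 0:
            inside &= r2 >= self.inner_radius**2
        return inside


@dataclass(frozen=True)
class PhantomModel:
    """A stack of analytic primitives over a uniform background.

    The list order is the explicit z-order, bottom to top: where primitives
    overlap, the later (topmost) one defines the CT number.  The analytic
    projector additionally assumes nested overlap — each primitive sits on a
    uniform region of the stack below it — which holds for the built-in
    presets and is probed at construction of projections.
    """

    primitives: tuple[Primitive, ...]
    background_value: float = -1000.0  # HU
    fov_radius: float = 180.0  # mm, scan field of view

    def __post_init__(self) -> None:
        for p in self.primitives:
            cx, cy = p.center
            if math.hypot(cx, cy) + p.outer_radius > self.fov_radius + 1e-9:
                raise ValueError(
                    f"primitive at {p.center} with radius {p.outer_radius} "
                    f"exceeds the {self.fov_radius} mm field of view"
                )

    def value_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Topmost CT number at points (x, y), background elsewhere."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(np.broadcast(x, y).shape, self.background_value)
        for p in self.primitives:
            out[p.contains(x, y)] = p.value
        return out

    def parent_values(self) -> np.ndarray:
        """CT number of the stack directly beneath each primitive.

        Probed at one interior point per primitive (disk center; annulus
        mid-wall), which is exact for nested layouts.
        """
        out = np.empty(len(self.primitives))
        for k, p in enumerate(self.primitives):
            if p.shape == "disk":
                px, py = p.center
            else:
                mid = 0.5 * (p.inner_radius + p.outer_radius)
                px, py = p.center[0] + mid, p.center[1]
            below = PhantomModel(self.primitives[:k], self.background_value,
                                 self.fov_radius)
            out[k] = below.value_at(np.array(px), np.array(py))
        return out


def build_phantom(spec) -> PhantomModel:
    """Build a phantom from a preset name or an explicit specification.

    ``spec`` is either the preset string ``"copd_like"`` or a mapping with
    keys ``background`` (HU) and ``primitives`` (list of dicts with ``shape``,
    ``center``, ``outer_radius``, ``inner_radius``, ``value``); list order is
    the z-order, bottom to top.
    """
    if isinstance(spec, str):
        if spec == "copd_like":
            return _copd_like_phantom()
        raise ValueError(f"unknown phantom preset {spec!r}")
    if isinstance(spec, PhantomModel):
        return spec
    background = float(spec.get("background", -1000.0))
    prims = []
    for d in spec["primitives"]:
        prims.append(
            Primitive(
                shape=d["shape"],
                center=tuple(float(c) for c in d["center"]),
                outer_radius=float(d["outer_radius"]),
                inner_radius=float(d.get("inner_radius", 0.0)),
                value=float(d["value"]),
            )
        )
    return PhantomModel(tuple(prims), background_value=background,
                        fov_radius=float(spec.get("fov_radius", 180.0)))


def _copd_like_phantom() -> PhantomModel:
    """Lung-simulating phantom emulation: a water-equivalent body shell with a
    lung-foam core holding air columns and polycarbonate airway tubes of
    graded wall thickness.  An emulation of the commercial phantom's layout,
    not a replica.
    """
    prims: list[Primitive] = [
        Primitive("disk", (0.0, 0.0), 100.0, value=0.0),        # body shell
        Primitive("disk", (0.0, 0.0), 88.0, value=-856.0),      # lung foam
    ]
    # Air columns and airway tubes (polycarbonate wall + air lumen) spread
    # quasi-uniformly over the foam on three rings, alternating feature type,
    # so any region of the lung field holds a similar structure mix.  Wall
    # thicknesses cycle over 0.5-3 mm; column and tube radii are graded.
    rings = [(25.0, 6, 10.0), (45.0, 8, 32.5), (66.0, 10, 0.0)]
    air_radii = [1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 2.2, 3.2]
    walls = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 0.8, 1.2, 1.8, 2.2, 2.8, 1.4]
    outers = [3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 3.5, 4.5, 5.5, 6.5, 7.5, 5.0]
    i_air = i_tube = 0
    for radius, count, offset_deg in rings:
        for k in range(count):
            ang = math.radians(offset_deg + 360.0 * k / count)
            c = (radius * math.cos(ang), radius * math.sin(ang))
            if (i_air + i_tube) % 2 == 0:
                prims.append(Primitive("disk", c, air_radii[i_air],
                                       value=-1000.0))
                i_air += 1
            else:
                ro, w = outers[i_tube], walls[i_tube]
                ri = ro - w
                prims.append(Primitive("annulus", c, ro, inner_radius=ri,
                                       value=100.0))
                prims.append(Primitive("disk", c, ri, value=-1000.0))  # lumen
                i_tube += 1
    return PhantomModel(tuple(prims))


# ---------------------------------------------------------------------------
# Actuator motion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionTrajectory:
    """Rigid periodic in-plane displacement applied to the whole phantom.

    ``kind="periodic_1d"`` drives both axes with a single scalar phase:
    ``d(t) = amplitude * wave(2*pi*rpm*t/60 + phase0)``, so the motion is a
    1-D oscillation along the fixed direction ``amplitude / |amplitude|``
    with half-stroke ``|amplitude|`` per axis.  ``amplitude`` is the
    half-stroke per axis in mm (peak-to-peak stroke is ``2 * amplitude``).
    """

    kind: Literal["static", "periodic_1d"] = "static"
    amplitude: tuple[float, float] = (0.0, 0.0)  # mm half-stroke per axis
    rpm: float = 0.0  # actuator cycles per minute
    phase0: float = 0.0  # radians
    waveform: Literal["sinusoid", "triangle"] = "sinusoid"

    def __post_init__(self) -> None:
        if self.rpm < 0:
            raise ValueError("rpm must be >= 0")
        if self.kind not in ("static", "periodic_1d"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")


def _wave(phase: np.ndarray, waveform: str) -> np.ndarray:
    if waveform == "sinusoid":
        return np.sin(phase)
    if waveform == "triangle":
        # Triangle wave with the same phase convention as sin: 0 at phase 0,
        # +1 at pi/2, -1 at 3pi/2.
        return 2.0 / np.pi * np.arcsin(np.sin(phase))
    raise ValueError(f"unknown waveform {waveform!r}")


def displacement_at(traj: MotionTrajectory, t) -> np.ndarray:
    """Phantom displacement (mm, 2-vector) at time(s) ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    if traj.kind == "static" or traj.rpm == 0:
        return np.zeros(t.shape + (2,))
    phase = 2.0 * np.pi * traj.rpm * t / 60.0 + traj.phase0
    w = _wave(phase, traj.waveform)
    return np.stack([traj.amplitude[0] * w, traj.amplitude[1] * w], axis=-1)


def path_per_rotation(traj: MotionTrajectory, rotation_period: float = 0.5) -> float:
    """Average travel distance of the phantom per gantry rotation (mm).

    One actuator cycle covers twice the combined (Euclidean) peak-to-peak
    stroke, so the mean travel per rotation is
    ``2 * |2 * amplitude| * rpm * rotation_period / 60`` — independent of the
    waveform and linear in rpm.
    """
    if traj.kind == "static" or traj.rpm == 0:
        return 0.0
    stroke = 2.0 * math.hypot(*traj.amplitude)  # combined peak-to-peak, mm
    return 2.0 * stroke * traj.rpm * rotation_period / 60.0


def combined_stroke(traj: MotionTrajectory) -> float:
    """Euclidean norm of the peak-to-peak stroke vector (mm)."""
    return 2.0 * math.hypot(*traj.amplitude)


# ---------------------------------------------------------------------------
# Scan geometry and sinogram containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanGeometry:
    """Third-generation fan-beam axial scan geometry (2D, single slice)."""

    source_to_iso: float = 600.0  # mm
    fan_angle: float = 50.0  # degrees, full fan
    n_channels: int = 736
    views_per_rotation: int = 1000
    rotation_period: float = 0.5  # s
    n_rotations: int = 1
    start_angle: float = 0.0  # degrees
    direction: int = 1  # +1 CCW / -1 CW

    def __post_init__(self) -> None:
        if not (0.0 < self.fan_angle < 90.0):
            raise ValueError("fan_angle must be in (0, 90) degrees")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.n_channels < 2 or self.views_per_rotation < 4:
            raise ValueError("need >= 2 channels and >= 4 views per rotation")
        nyquist = math.ceil(math.pi * self.n_channels / 2.0)
        if self.views_per_rotation < nyquist:
            warnings.warn(
                f"angular sampling {self.views_per_rotation} views/rotation is "
                f"below the matched-sampling guard of {nyquist} for "
                f"{self.n_channels} channels",
                stacklevel=2,
            )

    @property
    def channel_angles(self) -> np.ndarray:
        """Fan (channel) angles gamma, degrees, uniform over the full fan."""
        half = self.fan_angle / 2.0
        return np.linspace(-half, half, self.n_channels)

    @property
    def view_angles(self) -> np.ndarray:
        """Central-ray angles beta, degrees, monotone in acquisition order."""
        n = self.views_per_rotation * self.n_rotations
        step = self.direction * 360.0 / self.views_per_rotation
        return self.start_angle + step * np.arange(n)

    @property
    def dt(self) -> float:
        return self.rotation_period / self.views_per_rotation

    @property
    def fov_radius(self) -> float:
        return self.source_to_iso * math.sin(math.radians(self.fan_angle / 2.0))


@dataclass
class FanSinogram:
    """Per-view fan-beam line integrals (unitless, mu * mm)."""

    values: np.ndarray  # (n_views, n_channels)
    view_angles: np.ndarray  # degrees
    view_times: np.ndarray  # s
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.view_angles = np.asarray(self.view_angles, dtype=float)
        self.view_times = np.asarray(self.view_times, dtype=float)
        if self.values.shape != (len(self.view_angles), self.geometry.n_channels):
            raise ValueError("fan sinogram shape mismatch")
        dts = np.diff(self.view_times)
        if len(dts) and not np.all(dts > 0):
            raise ValueError("view_times must be strictly increasing")


@dataclass
class ParallelSinogram:
    """Rebinned parallel-beam line integrals p(theta, s).

    ``angles`` are monotone in acquisition order (they may exceed 360 degrees
    for multi-rotation scans); ``s`` is uniform and centered on isocenter.
    Each view carries the acquisition time of the central contributing fan
    view.
    """

    values: np.ndarray  # (n_views, n_s)
    angles: np.ndarray  # degrees
    s: np.ndarray  # mm
    view_times: np.ndarray  # s

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.view_times = np.asarray(self.view_times, dtype=float)
        if self.values.shape != (len(self.angles), len(self.s)):
            raise ValueError("parallel sinogram shape mismatch")

    @property
    def ds(self) -> float:
        return float(self.s[1] - self.s[0])

    @property
    def dtheta(self) -> float:
        return float(abs(self.angles[1] - self.angles[0]))

    def time_at(self, theta: float) -> float:
        """Acquisition time of the view nearest to ``theta`` (interpolated)."""
        return float(np.interp(theta, self.angles, self.view_times))


# ---------------------------------------------------------------------------
# Rasterization (ground-truth images)
# ---------------------------------------------------------------------------

def rasterize(
    phantom: PhantomModel,
    grid: ImageGrid,
    displacement=(0.0, 0.0),
    antialias: int = 3,
) -> Image:
    """Render the (rigidly displaced) phantom on a pixel grid in HU.

    ``antialias`` sub-samples each pixel k x k and averages (1 disables).
    """
    dx, dy = float(displacement[0]), float(displacement[1])
    X, Y = grid.meshgrid()
    k = max(1, int(antialias))
    if k == 1:
        vals = phantom.value_at(X - dx, Y - dy)
    else:
        off = (np.arange(k) + 0.5) / k - 0.5  # sub-pixel offsets in pixels
        acc = np.zeros(grid.shape)
        for oy in off:
            for ox in off:
                acc += phantom.value_at(
                    X + ox * grid.pixel_spacing - dx,
                    Y + oy * grid.pixel_spacing - dy,
                )
        vals = acc / (k * k)
    return Image(grid=grid, values=vals,
                 meta={"label": "rasterized", "displacement_mm": (dx, dy)})


# ---------------------------------------------------------------------------
# Analytic fan-beam forward projection
# ---------------------------------------------------------------------------

def _chord_lengths(r: float, dist: np.ndarray) -> np.ndarray:
    """Chord length of a circle of radius r at perpendicular ray distance."""
    h2 = r * r - dist * dist
    return 2.0 * np.sqrt(np.maximum(h2, 0.0))


def forward_project_fan(
    phantom: PhantomModel,
    geometry: ScanGeometry,
    traj: MotionTrajectory = MotionTrajectory(),
    t0: float = 0.0,
    mu_water: float = MU_WATER_PER_MM,
) -> FanSinogram:
    """Exact analytic fan-beam line integrals of the moving phantom.

    Each view at time ``t = t0 + v * dt`` sees the phantom rigidly displaced
    by ``displacement_at(traj, t)``; motion is frozen within a view.  Requires
    an air background (mu = 0); line integrals are chord lengths times the
    attenuation step of each primitive over its surroundings.
    """
    if abs(hu_to_mu(phantom.background_value, mu_water)) > 1e-12:
        raise ValueError("analytic projection requires an air (-1000 HU) background")

    betas = np.radians(geometry.view_angles)  # (V,)
    gammas = np.radians(geometry.channel_angles)  # (C,)
    thetas = betas[:, None] + gammas[None, :]  # (V, C) parallel angle of each ray
    s = geometry.source_to_iso * np.sin(gammas)[None, :]  # (V, C) broadcast
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)

    times = t0 + geometry.dt * np.arange(len(betas))
    disp = displacement_at(traj, times)  # (V, 2)

    parent_hu = phantom.parent_values()
    values = np.zeros(thetas.shape)
    for p, hu_below in zip(phantom.primitives, parent_hu):
        dmu = hu_to_mu(p.value, mu_water) - hu_to_mu(hu_below, mu_water)
        if dmu == 0.0:
            continue
        cx = p.center[0] + disp[:, 0]
        cy = p.center[1] + disp[:, 1]
        # perpendicular distance of the displaced center from each ray
        d = np.abs(s - (cx[:, None] * cos_t + cy[:, None] * sin_t))
        chord = _chord_lengths(p.outer_radius, d)
        if p.inner_radius > 0:
            chord = chord - _chord_lengths(p.inner_radius, d)
        values += dmu * chord

    return FanSinogram(values=values, view_angles=geometry.view_angles,
                       view_times=times, geometry=geometry)


# ---------------------------------------------------------------------------
# Fan-to-parallel rebinning
# ---------------------------------------------------------------------------

def rebin_fan_to_parallel(
    fan: FanSinogram,
    n_s: int | None = None,
    dtheta: float | None = None,
) -> ParallelSinogram:
    """Rebin fan projections (beta, gamma) onto parallel (theta, s).

    Uses the exact relations ``theta = beta + gamma``, ``s = R sin(gamma)``
    with bilinear interpolation in (beta, gamma).  Each parallel view carries
    the acquisition time of its central contributing fan view (gamma = 0,
    i.e. beta = theta).
    """
    from scipy.ndimage import map_coordinates

    geom = fan.geometry
    half_fan = geom.fan_angle / 2.0
    betas = fan.view_angles
    flip = betas[-1] < betas[0]
    if flip:  # store internally in increasing-angle order
        betas = betas[::-1]
        fan_values = fan.values[::-1]
        fan_times = fan.view_times[::-1]
    else:
        fan_values = fan.values
        fan_times = fan.view_times

    span = betas[-1] - betas[0]
    required = 180.0 + geom.fan_angle
    if span < required - 1e-9:
        raise ValueError(
            f"fan coverage {span:.1f} deg is insufficient: rebinning needs at "
            f"least {required:.1f} deg (missing "
            f"{required - span:.1f} deg beyond {betas[-1]:.1f} deg)"
        )

    if dtheta is None:
        dtheta = 360.0 / geom.views_per_rotation
    if n_s is None:
        n_s = geom.n_channels
    s_max = geom.source_to_iso * math.sin(math.radians(half_fan))
    s = np.linspace(-s_max, s_max, n_s)

    theta0 = betas[0] + half_fan
    theta1 = betas[-1] - half_fan
    n_theta = int(math.floor((theta1 - theta0) / dtheta)) + 1
    thetas = theta0 + dtheta * np.arange(n_theta)

    gam = np.degrees(np.arcsin(np.clip(s / geom.source_to_iso, -1.0, 1.0)))
    beta_needed = thetas[:, None] - gam[None, :]  # (T, S)
    dbeta = betas[1] - betas[0]
    dgamma = geom.fan_angle / (geom.n_channels - 1)
    iv = (beta_needed - betas[0]) / dbeta
    ic = (gam[None, :] + half_fan) / dgamma
    ic = np.broadcast_to(ic, iv.shape)
    values = map_coordinates(fan_values, [iv, ic], order=1, mode="constant",
                             cval=0.0)
    times = np.interp(thetas, betas, fan_times)
    return ParallelSinogram(values=values, angles=thetas, s=s, view_times=times)
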