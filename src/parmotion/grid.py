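"""Reconstruction rasters: pixel grids in physical (mm) coordinates.

Convention: an image array with shape ``(ny, nx)`` maps index ``(i, j)`` to the
physical point ``(x, y) = origin + (j * spacing, i * spacing)``; ``origin`` is
the lower-left pixel *center*.  By default the grid is centered on the scanner
isocenter ``(0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass(frozen=True)
class ImageGrid:
    """A uniform square-pixel raster in scanner coordinates (mm)."""

    nx: int
    ny: int
    pixel_spacing: float  # mm
    origin: tuple[float, float] | None = None  # mm; None -> centered on iso

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one pixel per axis")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")
        if self.origin is None:
            ox = -0.5 * (self.nx - 1) * self.pixel_spacing
            oy = -0.5 * (self.ny - 1) * self.pixel_spacing
            object.__setattr__(self, "origin", (ox, oy))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def x(self) -> np.ndarray:
        """Pixel-center x coordinates, shape (nx,), mm."""
        return self.origin[0] + self.pixel_spacing * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        """Pixel-center y coordinates, shape (ny,), mm."""
        return self.origin[1] + self.pixel_spacing * np.arange(self.ny)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) pixel-center coordinate arrays of shape (ny, nx), mm."""
        return np.meshgrid(self.x, self.y)

    def to_index(self, points: np.ndarray) -> np.ndarray:
        """Convert (N, 2) physical (x, y) mm points to fractional (i, j) indices."""
        pts = np.asarray(points, dtype=float)
        j = (pts[..., 0] - self.origin[0]) / self.pixel_spacing
        i = (pts[..., 1] - self.origin[1]) / self.pixel_spacing
        return np.stack([i, j], axis=-1)


def default_grid(n: int = 512, dfov_mm: float = 360.0) -> ImageGrid:
    """Square grid covering a display field of view (default 360 mm)."""
    return ImageGrid(nx=n, ny=n, pixel_spacing=dfov_mm / n)


@dataclass
class Image:
    """A reconstructed raster with physical spacing and provenance metadata.

    ``values`` are CT numbers (HU) for complete reconstructions; partial-angle
    reconstructions are kept as raw attenuation partial sums (see ``meta``).
    """

    grid: ImageGrid
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    def copy_with(self, values: np.ndarray, **meta: Any) -> "Image":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Image(grid=self.grid, values=values, meta=new_meta)
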