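"""File formats: raw float32 + JSON sidecar sinograms, NIfTI images,
JSON ROI lists and displacement fields."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .grid import Image, ImageGrid
from .metrics import ROIMask
from .motion import MVF
from .sim import FanSinogram, ParallelSinogram, ScanGeometry


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_sinogram(path, sino: FanSinogram | ParallelSinogram) -> None:
    """Write a sinogram as raw little-endian float32 plus a JSON sidecar."""
    path = Path(path)
    sino.values.astype("<f4").tofile(path)
    if isinstance(sino, FanSinogram):
        meta = {
            "kind": "fan",
            "shape": list(sino.values.shape),
            "view_angles_deg": sino.view_angles.tolist(),
            "view_times_s": sino.view_times.tolist(),
            "geometry": dataclasses.asdict(sino.geometry),
        }
    else:
        meta = {
            "kind": "parallel",
            "shape": list(sino.values.shape),
            "angles_deg": sino.angles.tolist(),
            "s_mm": sino.s.tolist(),
            "view_times_s": sino.view_times.tolist(),
        }
    _sidecar(path).write_text(json.dumps(meta))


def read_sinogram(path) -> FanSinogram | ParallelSinogram:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    values = np.fromfile(path, dtype="<f4").reshape(meta["shape"]).astype(float)
    if meta["kind"] == "fan":
        return FanSinogram(
            values=values,
            view_angles=np.asarray(meta["view_angles_deg"]),
            view_times=np.asarray(meta["view_times_s"]),
            geometry=ScanGeometry(**meta["geometry"]),
        )
    return ParallelSinogram(
        values=values,
        angles=np.asarray(meta["angles_deg"]),
        s=np.asarray(meta["s_mm"]),
        view_times=np.asarray(meta["view_times_s"]),
    )


def write_nifti(path, img: Image) -> None:
    """Write an image (or any 2D raster on a grid) as NIfTI with mm spacing."""
    sp = img.grid.pixel_spacing
    affine = np.diag([sp, sp, 1.0, 1.0])
    affine[0, 3] = img.grid.origin[0]
    affine[1, 3] = img.grid.origin[1]
    # NIfTI is (x, y, z); our array is (row=y, col=x).
    data = img.values.T[:, :, None].astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti(path) -> Image:
    n = nib.load(str(path))
    data = np.asanyarray(n.dataobj)
    if data.ndim == 3:
        data = data[..., 0]
    sp = float(n.affine[0, 0])
    origin = (float(n.affine[0, 3]), float(n.affine[1, 3]))
    grid = ImageGrid(nx=data.shape[0], ny=data.shape[1], pixel_spacing=sp,
                     origin=origin)
    return Image(grid=grid, values=np.asarray(data, dtype=float).T)


def write_mvf(path, mvf: MVF) -> None:
    """Write a displacement field as a 2-component NIfTI (mm)."""
    sp = mvf.grid.pixel_spacing
    affine = np.diag([sp, sp, 1.0, 1.0])
    affine[0, 3] = mvf.grid.origin[0]
    affine[1, 3] = mvf.grid.origin[1]
    data = np.transpose(mvf.field, (1, 0, 2))[:, :, None, :].astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_mvf(path) -> MVF:
    n = nib.load(str(path))
    data = np.asanyarray(n.dataobj)
    if data.ndim == 4:
        data = data[:, :, 0, :]
    sp = float(n.affine[0, 0])
    origin = (float(n.affine[0, 3]), float(n.affine[1, 3]))
    grid = ImageGrid(nx=data.shape[0], ny=data.shape[1], pixel_spacing=sp,
                     origin=origin)
    return MVF(grid=grid, field=np.transpose(np.asarray(data, float), (1, 0, 2)))


def read_rois(path) -> list[ROIMask]:
    """Read a JSON list of {label, x0, y0, x1, y1} rectangles (mm)."""
    entries = json.loads(Path(path).read_text())
    return [ROIMask(label=e["label"],
                    rect=(e["x0"], e["y0"], e["x1"], e["y1"]))
            for e in entries]


def write_rois(path, rois: Sequence[ROIMask]) -> None:
    out = []
    for r in rois:
        if r.rect is None:
            raise ValueError("only rectangle ROIs can be serialized to JSON")
        x0, y0, x1, y1 = r.rect
        out.append({"label": r.label, "x0": x0, "y0": y0, "x1": x1, "y1": y1})
    Path(path).write_text(json.dumps(out, indent=1))
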