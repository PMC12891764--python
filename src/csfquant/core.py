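"""Shared image containers, coordinate conventions, and NIfTI I/O.

Conventions used throughout the package
---------------------------------------
* 3D volumes are stored as ``(z, y, x)`` arrays with per-axis voxel spacing
  ``(sz, sy, sx)`` in mm.  2D images are ``(row, col)`` = ``(y, x)``.
* Physical 2D coordinates are cell-centered: pixel ``(r, c)`` of an image
  with spacing ``(sy, sx)`` has its center at ``((r + 0.5) * sy,
  (c + 0.5) * sx)`` mm measured from the image corner.  This makes physical
  extent invariant under resampling.
* Points are always ``(row, col)`` (or ``(row_mm, col_mm)``), never
  ``(x, y)``.
* Ground truth travels with every phantom as a JSON sidecar next to the
  NIfTI file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "px_to_mm",
    "mm_to_px",
    "save_volume",
    "load_volume",
    "save_json",
    "load_json",
]


@dataclass
class Volume3D:
    """Gridded scalar image with physical voxel spacing.

    Parameters
    ----------
    data:
        ``(nz, ny, nx)`` array of image intensities.
    spacing_mm:
        Voxel spacing ``(sz, sy, sx)`` in mm.
    meta:
        Free-form metadata record; phantom generators store ground truth
        here and it is serialized to a JSON sidecar on save.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D expects 3D data, got shape {self.data.shape}")
        sz, sy, sx = self.spacing_mm
        if min(sz, sy, sx) <= 0:
            raise ValueError("voxel spacing must be positive")
        self.spacing_mm = (float(sz), float(sy), float(sx))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def slice(self, k: int) -> np.ndarray:
        """Return the 2D ``(y, x)`` slice at index ``k``."""
        return self.data[k]

    @property
    def plane_spacing_mm(self) -> tuple[float, float]:
        """In-plane spacing ``(sy, sx)``."""
        return self.spacing_mm[1:]


def px_to_mm(points_px: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Cell-centered pixel index -> physical mm, for ``(row, col)`` points."""
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    return (pts + 0.5) * np.asarray(spacing, dtype=float)


def mm_to_px(points_mm: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Physical mm -> fractional pixel index, for ``(row, col)`` points."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    return pts / np.asarray(spacing, dtype=float) - 0.5


class _MetaEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102 - stdlib hook
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, cls=_MetaEncoder, indent=1, sort_keys=True))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name.split(".")[0] + ".json")


def save_volume(vol: Volume3D, path: str | Path) -> Path:
    """Write a :class:`Volume3D` as NIfTI (+ JSON sidecar when meta present).

    The NIfTI on disk is ``(x, y, z)`` ordered with spacing encoded in the
    affine, i.e. readable by any standard viewer.
    """
    path = Path(path)
    sz, sy, sx = vol.spacing_mm
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32).T, affine)
    nib.save(img, str(path))
    if vol.meta:
        save_json(vol.meta, _sidecar(path))
    return path


def load_volume(path: str | Path) -> Volume3D:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64).T
    zooms = img.header.get_zooms()[:3]  # (sx, sy, sz)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = load_json(sc)
    return Volume3D(data, (float(zooms[2]), float(zooms[1]), float(zooms[0])), meta)
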