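"""Core rasters and file I/O for OCT volumes, surfaces and masks.

Conventions used throughout the package:

* A volume is an ``(nx, nB, nz)`` array — ``x`` lateral within a B-scan,
  ``B`` the B-scan index, ``z`` axial depth increasing downward.
* A surface is a per-column axial height map ``z(x, B)`` of integer voxel
  indices; the height is the z index of the boundary voxel itself.
* The slab "between surface A and B" (A above B) is the half-open axial
  range ``(z_A, z_B]`` so adjacent slabs partition the retina.
* Indexing is 0-based everywhere.

On disk, multi-page TIFF stores one page per B-scan with page shape
``(nz, nx)``; NIfTI stores the ``(nx, nB, nz)`` array directly with voxel
spacing in the header. Proprietary vendor formats are not parsed — convert
to TIFF/NIfTI first.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "OctVolume",
    "Surface",
    "RegionMask",
    "FormatError",
    "ContractError",
    "SURFACE_NAMES",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_surfaces",
    "write_surfaces",
]

SURFACE_NAMES = ("ILM", "EZ_ROOF", "RPE_FLOOR", "BM")

#: Intensity range of the raster grey levels used by the package.
INTENSITY_RANGE = (0.0, 255.0)


class FormatError(ValueError):
    """Unreadable file or unexpected on-disk layout."""


class ContractError(ValueError):
    """Caller violated a shape/ordering contract."""


@dataclass
class OctVolume:
    """A 3D SD-OCT intensity raster with anisotropic voxel spacing.

    Parameters
    ----------
    data
        ``(nx, nB, nz)`` array of non-negative grey levels.
    spacing
        Voxel size in micrometres along (x, B, z). The clinical volumes
        this models are 512 x 64 x 480 voxels at 11.72 x 93.75 x 3.50 um.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"volume must be 3D (nx, nB, nz), got ndim={self.data.ndim}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ContractError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ContractError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class Surface:
    """Per-(x, B-scan) axial height map of one retinal boundary."""

    name: str
    heights: np.ndarray  # (nx, nB) integer z indices

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights)
        if self.heights.ndim != 2:
            raise ContractError("surface heights must be a 2D (nx, nB) map")
        if not np.issubdtype(self.heights.dtype, np.integer):
            if np.any(self.heights != np.round(self.heights)):
                raise ContractError("surface heights must be integral")
            self.heights = self.heights.astype(np.int64)

    def validate_for(self, nz: int) -> None:
        if self.heights.min() < 0 or self.heights.max() >= nz:
            raise ContractError(
                f"surface {self.name} heights outside [0, {nz - 1}]"
            )


@dataclass
class RegionMask:
    """Binary 3D raster on the same grid as its volume."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ContractError("mask must be 3D (nx, nB, nz)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.mask.sum())


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def read_volume(path, spacing=None) -> OctVolume:
    """Read a volume from multi-page TIFF or NIfTI-1.

    Spacing comes from the NIfTI header when present, else from the
    ``spacing`` argument, else unit.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 3D NIfTI, got ndim={data.ndim}")
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        if spacing is None and all(z > 0 for z in zooms):
            spacing = zooms
    else:
        import tifffile

        pages = tifffile.imread(str(path))
        if pages.ndim == 2:
            raise FormatError(f"{path}: single 2D image is not a volume")
        if pages.ndim != 3:
            raise FormatError(f"{path}: expected a page stack, got ndim={pages.ndim}")
        # pages are (nB, nz, nx) -> internal (nx, nB, nz)
        data = np.transpose(pages, (2, 0, 1))
    return OctVolume(np.ascontiguousarray(data), tuple(spacing or (1.0, 1.0, 1.0)))


def write_volume(volume: OctVolume, path) -> None:
    """Write a volume as multi-page TIFF or NIfTI-1 (by extension)."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        img = nib.Nifti1Image(np.asarray(volume.data), affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, str(path))
    else:
        import tifffile

        pages = np.transpose(np.asarray(volume.data), (1, 2, 0))  # (nB, nz, nx)
        tifffile.imwrite(str(path), np.ascontiguousarray(pages),
                         photometric="minisblack")


def write_mask(mask: RegionMask, path, volume_shape=None) -> None:
    """Write a binary mask as an 8-bit raster (TIFF or NIfTI)."""
    if volume_shape is not None and tuple(mask.shape) != tuple(volume_shape):
        raise ContractError(
            f"mask shape {mask.shape} != declared volume shape {tuple(volume_shape)}"
        )
    write_volume(OctVolume(mask.mask.astype(np.uint8)), path)


def read_mask(path) -> RegionMask:
    vol = read_volume(path)
    return RegionMask(vol.data > 0)


def write_surfaces(surfaces, path) -> None:
    """Write surfaces as CSV with columns x, bscan, z_<name lowercased>.

    ``surfaces`` maps names (ILM, EZ_ROOF, RPE_FLOOR, BM — any subset) to
    :class:`Surface`. All height maps must share one (nx, nB) grid.
    """
    names = list(surfaces)
    shapes = {tuple(surfaces[n].heights.shape) for n in names}
    if len(shapes) != 1:
        raise ContractError(f"surfaces on mismatched grids: {shapes}")
    nx, nB = shapes.pop()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "bscan"] + [f"z_{n.lower()}" for n in names])
        for b in range(nB):
            for x in range(nx):
                writer.writerow(
                    [x, b] + [int(surfaces[n].heights[x, b]) for n in names]
                )


def read_surfaces(path) -> dict[str, Surface]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        names = [h[2:].upper() for h in header[2:]]
        rows = [[int(v) for v in row] for row in reader]
    arr = np.asarray(rows)
    nx = arr[:, 0].max() + 1
    nB = arr[:, 1].max() + 1
    out: dict[str, Surface] = {}
    for j, name in enumerate(names):
        heights = np.zeros((nx, nB), dtype=np.int64)
        heights[arr[:, 0], arr[:, 1]] = arr[:, 2 + j]
        out[name] = Surface(name, heights)
    return out


def slab_mask(upper: Surface, lower: Surface, nz: int) -> np.ndarray:
    """Boolean (nx, nB, nz) mask of the half-open slab ``(z_upper, z_lower]``."""
    zu = upper.heights[:, :, None]
    zl = lower.heights[:, :, None]
    if np.any(zl < zu):
        raise ContractError(
            f"surface ordering violated: {lower.name} above {upper.name}"
        )
    z = np.arange(nz)[None, None, :]
    return (z > zu) & (z <= zl)
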