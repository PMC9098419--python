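"""Image-volume containers, NIfTI/npz I/O, and the mm coordinate convention.

Every module in the package indexes voxels as ``(slice, row, col)`` (0-based)
and maps them to physical millimetres as

    x = x0 + row * dr      (in-plane row axis; anterior–posterior,
                            perpendicular to the articular face)
    y = y0 + col * dc      (in-plane column axis)
    z = z0 + slice * ds    (through-plane slice axis; medial–lateral)

where ``(ds, dr, dc)`` is the per-axis voxel spacing in mm and
``(x0, y0, z0)`` the volume origin.  The convention is a repository-wide
choice; all sign conventions downstream (signed surface distance along +x)
depend on it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class Modality(str, enum.Enum):
    """Imaging arm the volume emulates (drives default intensities/thresholds)."""

    MRI_T1VIBE = "MRI_T1VIBE"
    MRI_DESS = "MRI_DESS"
    CT = "CT"
    OTHER = "OTHER"


@dataclass
class ImageVolume:
    """A 3D scalar voxel grid with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Scalar intensities, arbitrary units.
    spacing : tuple of float
        ``(ds, dr, dc)`` mm per axis; all strictly positive.
    modality : Modality
        Tag recording which imaging arm the volume represents.
    origin : tuple of float
        ``(x0, y0, z0)`` mm position of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality = Modality.OTHER
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got {self.voxels.ndim}D")
        if any(n < 1 for n in self.voxels.shape):
            raise ValueError("every grid dimension must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive finite values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must all be finite")
        self.modality = Modality(self.modality)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class CropRegion:
    """Inclusive index bounds of a sub-volume around the bone of interest."""

    slice_first: int
    slice_last: int
    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if not (self.slice_first <= self.slice_last
                and self.row_min <= self.row_max
                and self.col_min <= self.col_max):
            raise ValueError(f"degenerate crop region {self}")

    def validate_within(self, volume: ImageVolume) -> None:
        ns, nr, nc = volume.shape
        ok = (0 <= self.slice_first and self.slice_last < ns
              and 0 <= self.row_min and self.row_max < nr
              and 0 <= self.col_min and self.col_max < nc)
        if not ok:
            raise ValueError(f"crop region {self} outside volume of shape {volume.shape}")


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume to NIfTI-1 (``.nii``/``.nii.gz``) or ``.npz``.

    NIfTI stores spacing in the header zooms and the origin in the affine;
    the modality tag goes in the header ``descrip`` field.  The ``.npz``
    container is a lossless raw-array fixture format.
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            voxels=volume.voxels,
            spacing=np.asarray(volume.spacing),
            origin=np.asarray(volume.origin),
            modality=np.array(volume.modality.value),
        )
        return
    ds, dr, dc = volume.spacing
    # Array axes are (slice, row, col) -> world (z, x, y); the affine records
    # the mm step per array axis so spacing round-trips through the zooms.
    affine = np.diag([ds, dr, dc, 1.0])
    x0, y0, z0 = volume.origin
    affine[:3, 3] = (z0, x0, y0)
    img = nib.Nifti1Image(volume.voxels.astype(np.float64), affine)
    img.header["descrip"] = volume.modality.value.encode()
    img.header.set_zooms((ds, dr, dc))
    nib.save(img, str(path))


def read_volume(path: str | Path, format: str | None = None) -> ImageVolume:
    """Read an :class:`ImageVolume` from NIfTI-1 or the npz fixture format.

    Parameters
    ----------
    path : path
        File to read; ``format`` inferred from the suffix when not given
        (``nifti`` for .nii/.nii.gz, ``npz-raw`` for .npz).

    Raises
    ------
    FileNotFoundError
        Missing file.
    ValueError
        Non-3D data or non-positive spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "npz-raw" if path.suffix == ".npz" else "nifti"
    if format == "npz-raw":
        with np.load(path) as f:
            return ImageVolume(
                voxels=f["voxels"],
                spacing=tuple(f["spacing"]),
                modality=Modality(str(f["modality"])),
                origin=tuple(f["origin"]),
            )
    if format != "nifti":
        raise ValueError(f"unknown format {format!r}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, file has {data.ndim} dimensions")
    zooms = img.header.get_zooms()[:3]
    descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="replace")
    try:
        modality = Modality(descrip)
    except ValueError:
        modality = Modality.OTHER
    affine = img.affine
    origin = (float(affine[1, 3]), float(affine[2, 3]), float(affine[0, 3]))
    return ImageVolume(voxels=data, spacing=tuple(float(z) for z in zooms),
                       modality=modality, origin=origin)


def crop(volume: ImageVolume, region: CropRegion) -> ImageVolume:
    """Crop to an inclusive region, shifting the origin so retained voxels
    keep their mm coordinates."""
    region.validate_within(volume)
    ds, dr, dc = volume.spacing
    x0, y0, z0 = volume.origin
    sub = volume.voxels[
        region.slice_first:region.slice_last + 1,
        region.row_min:region.row_max + 1,
        region.col_min:region.col_max + 1,
    ].copy()
    new_origin = (
        x0 + region.row_min * dr,
        y0 + region.col_min * dc,
        z0 + region.slice_first * ds,
    )
    return ImageVolume(sub, volume.spacing, volume.modality, new_origin)


def voxel_to_mm(volume: ImageVolume, slice: int, row: int, col: int) -> tuple[float, float, float]:
    """Map a voxel index triple to its ``(x, y, z)`` mm coordinate."""
    ns, nr, nc = volume.shape
    if not (0 <= slice < ns and 0 <= row < nr and 0 <= col < nc):
        raise ValueError(f"voxel ({slice}, {row}, {col}) outside grid {volume.shape}")
    ds, dr, dc = volume.spacing
    x0, y0, z0 = volume.origin
    return (x0 + row * dr, y0 + col * dc, z0 + slice * ds)


def voxels_to_mm(volume: ImageVolume, indices: np.ndarray) -> np.ndarray:
    """Vectorised :func:`voxel_to_mm` for an ``(N, 3)`` array of
    ``(slice, row, col)`` indices; returns ``(N, 3)`` mm ``(x, y, z)``."""
    idx = np.asarray(indices, dtype=float)
    ds, dr, dc = volume.spacing
    x0, y0, z0 = volume.origin
    out = np.empty_like(idx)
    out[:, 0] = x0 + idx[:, 1] * dr
    out[:, 1] = y0 + idx[:, 2] * dc
    out[:, 2] = z0 + idx[:, 0] * ds
    return out
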