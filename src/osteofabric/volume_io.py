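"""Volume, label-map and field input/output.

Coordinate conventions for the whole toolkit live here:

* voxel indices are 0-based ``(i, j, k)`` with axis 2 (``k``) the slice
  axis (stack acquisition order); after long-axis alignment the anatomical
  proximal--distal axis is the slice axis;
* world coordinates are voxel *centres*: ``world = origin + index * spacing``
  with spacing in micrometres (µm);
* areas are reported in mm², volumes in mm³.

Grayscale volumes are read from TIFF stacks (multi-page files or a
directory of per-slice files in lexicographic order) and from NRRD / MHD
containers through SimpleITK.  Intensities are never rescaled on read.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = [
    "VoxelVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "export_vector_field",
    "read_vector_field_csv",
    "export_histogram",
]

#: label scheme shared across the toolkit
LABEL_AIR = 0
LABEL_CORTICAL = 1
LABEL_TRABECULAR = 2
LABEL_CAVITY = 3


@dataclass
class VoxelVolume:
    """A 3-D grayscale grid with per-axis voxel spacing in µm.

    Parameters
    ----------
    data:
        3-D scalar array of intensities (arbitrary units).
    spacing:
        Per-axis voxel edge length in µm, one value per array axis.
    origin:
        World coordinate (µm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape == ():
            self.spacing = np.repeat(self.spacing[None], 3)
        if self.spacing.shape != (3,):
            raise ValueError("spacing must be a scalar or length-3 sequence")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0]))

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinate (µm) of a (possibly fractional) voxel index."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Fractional voxel index of a world point (µm)."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        """Same geometry, new intensity array (shape must match)."""
        if data.shape != self.data.shape:
            raise ValueError("replacement data must keep the grid shape")
        return replace(self, data=data)


@dataclass
class LabelVolume:
    """Voxelwise compartment labels sharing a :class:`VoxelVolume` geometry.

    Scheme: 0 = air/background, 1 = cortical bone, 2 = trabecular bone,
    3 = internal non-bone space (medullary cavity / marrow).
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        bad = np.setdiff1d(np.unique(self.labels), [0, 1, 2, 3])
        if bad.size:
            raise ValueError(f"labels outside {{0,1,2,3}}: {bad}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape == ():
            self.spacing = np.repeat(self.spacing[None], 3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, which: Sequence[int]) -> np.ndarray:
        """Boolean mask of voxels whose label is in ``which``."""
        return np.isin(self.labels, np.asarray(which))

    def geometry_like(self) -> VoxelVolume:
        return VoxelVolume(self.labels.astype(np.float32), self.spacing, self.origin)


# ---------------------------------------------------------------------------
# readers / writers


def _read_tiff_stack_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir()
        if p.suffix.lower() in {".tif", ".tiff"} and p.is_file()
    )
    if not files:
        raise FileNotFoundError(f"no TIFF slices found in {path}")
    slices = [tifffile.imread(str(f)) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice dimensions in stack: {sorted(shapes)}")
    # stack order: file order along the slice axis (axis 2)
    return np.stack(slices, axis=-1)


def read_volume(path: str | os.PathLike, spacing_override: Sequence[float] | float | None = None) -> VoxelVolume:
    """Read a grayscale volume from a TIFF stack or NRRD/MHD file.

    ``spacing_override`` (µm) is required when the container stores no
    spacing (plain TIFF); when given it always wins over file metadata.
    Intensities are preserved without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if path.is_dir():
        data = _read_tiff_stack_dir(path)
        spacing = None
    elif path.suffix.lower() in {".tif", ".tiff"}:
        pages = tifffile.imread(str(path))
        if pages.ndim == 2:
            pages = pages[None]
        # multipage TIFF comes in as (page, row, col); pages are slices
        data = np.moveaxis(pages, 0, -1)
        spacing = None
    elif path.suffix.lower() in {".nrrd", ".mhd", ".mha", ".nii"}:
        img = sitk.ReadImage(str(path))
        # SimpleITK arrays are (z, y, x); transpose to (x, y, z)=(i, j, k)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = np.asarray(img.GetSpacing(), dtype=float)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")

    if spacing_override is not None:
        spacing = np.asarray(spacing_override, dtype=float)
        if spacing.shape == ():
            spacing = np.repeat(spacing[None], 3)
    if spacing is None:
        raise ValueError(
            f"{path} stores no voxel spacing; pass spacing_override in µm"
        )
    return VoxelVolume(data, spacing)


def write_volume(vol: VoxelVolume | LabelVolume, path: str | os.PathLike) -> None:
    """Write a volume as NRRD/MHD (spacing preserved) or multipage TIFF.

    Label volumes are written as unsigned 8-bit.
    """
    path = Path(path)
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.uint8)
        spacing = vol.spacing
    else:
        data = vol.data
        spacing = vol.spacing
    suffix = path.suffix.lower()
    if suffix in {".nrrd", ".mhd", ".mha", ".nii"}:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in spacing))
        sitk.WriteImage(img, str(path))
    elif suffix in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), np.moveaxis(data, -1, 0))
    else:
        raise ValueError(f"unsupported output format: {suffix}")


def resample_isotropic(vol: VoxelVolume) -> VoxelVolume:
    """Resample onto an isotropic grid at the smallest input spacing.

    Trilinear interpolation; a no-op (same object) when the input is
    already isotropic.  All downstream geometry (spherical VOIs, local
    thickness) assumes isotropic voxels, so this runs once, up front.
    """
    if vol.is_isotropic:
        return vol
    target = float(vol.spacing.min())
    # physical extent covered by voxel centres plus the half-voxel margins
    new_shape = tuple(
        int(round(n * s / target)) for n, s in zip(vol.shape, vol.spacing)
    )
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(vol.data.astype(np.float32).transpose(2, 1, 0))
    )
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    resampler = sitk.ResampleImageFilter()
    resampler.SetOutputSpacing((target,) * 3)
    resampler.SetSize((int(new_shape[0]), int(new_shape[1]), int(new_shape[2])))
    resampler.SetInterpolator(sitk.sitkLinear)
    resampler.SetDefaultPixelValue(float(vol.data.min()))
    out = sitk.GetArrayFromImage(resampler.Execute(img)).transpose(2, 1, 0)
    return VoxelVolume(out, np.repeat(target, 3), vol.origin)


# ---------------------------------------------------------------------------
# fabric-field and histogram export


def export_vector_field(field, path: str | os.PathLike, format: str = "csv") -> None:
    """Write an anisotropy field as CSV or VTK legacy POLYDATA.

    CSV columns: ``x_um, y_um, z_um, da, ax, ay, az, n_normals`` — one row
    per defined sample.  The VTK file carries POINTS plus a scalar array
    ``da`` and a unit vector array ``axis``.
    """
    samples = [s for s in field.samples if s.defined]
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x_um", "y_um", "z_um", "da", "ax", "ay", "az", "n_normals"])
            for s in samples:
                ax = s.axis / np.linalg.norm(s.axis)
                writer.writerow(
                    [f"{s.centre[0]:.6f}", f"{s.centre[1]:.6f}", f"{s.centre[2]:.6f}",
                     f"{s.da:.6f}", f"{ax[0]:.6f}", f"{ax[1]:.6f}", f"{ax[2]:.6f}",
                     s.n_normals]
                )
    elif format == "vtk-legacy":
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write("trabecular fabric field\nASCII\nDATASET POLYDATA\n")
            fh.write(f"POINTS {len(samples)} float\n")
            for s in samples:
                fh.write(f"{s.centre[0]:g} {s.centre[1]:g} {s.centre[2]:g}\n")
            fh.write(f"POINT_DATA {len(samples)}\n")
            fh.write("SCALARS da float 1\nLOOKUP_TABLE default\n")
            for s in samples:
                fh.write(f"{s.da:g}\n")
            fh.write("VECTORS axis float\n")
            for s in samples:
                ax = s.axis / np.linalg.norm(s.axis)
                fh.write(f"{ax[0]:g} {ax[1]:g} {ax[2]:g}\n")
    else:
        raise ValueError(f"unknown vector-field format {format!r}")


def read_vector_field_csv(path: str | os.PathLike):
    """Read back a CSV written by :func:`export_vector_field`.

    Returns a structured record array with the export columns.
    """
    return np.genfromtxt(path, delimiter=",", names=True)


def export_histogram(hist, path: str | os.PathLike) -> None:
    """Write a degree-of-anisotropy histogram as ``bin_left,bin_right,count``.

    Zero-sentinel (undefined) samples were already excluded when the
    histogram was built, so the counts sum to the defined-sample count.
    """
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_left", "bin_right", "count"])
        for left, right, count in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.counts):
            writer.writerow([f"{left:.6f}", f"{right:.6f}", int(count)])
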