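"""CT volume container and file I/O.

A :class:`VoxelGrid` holds a 3-D lattice of Hounsfield units together with
its anisotropic voxel spacing. Array axes are ordered ``(z, y, x)`` — slice,
row, column — and ``spacing``/``origin`` follow the same axis order, so
``spacing[0]`` is the slice-to-slice increment in mm. World coordinates are
``origin + index * spacing`` (0-based indices, voxel centres).

Reconstructed CT series may be *overlapping*: the slab thickness averaged
into each slice can exceed the slice-to-slice increment (e.g. 3 mm slices
every 1.5 mm). ``slice_thickness`` carries that metadata; downstream Agatston
scoring uses it to select a non-overlapping partition.

Volumes are read and written as NIfTI (``.nii``/``.nii.gz``, via nibabel) or
MetaImage (``.mha``/``.mhd``, via SimpleITK). Both formats store spacing in
``(x, y, z)`` order with the array as ``(z, y, x)``; the conversion happens
here. A small JSON sidecar (``<file>.meta.json``) preserves
``slice_thickness`` when it differs from the z spacing, since neither header
carries it losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

HU_MIN = -1024.0
HU_MAX = 3071.0

__all__ = ["VoxelGrid", "load_volume", "save_volume", "HU_MIN", "HU_MAX"]


@dataclass
class VoxelGrid:
    """A CT volume in Hounsfield units on a regular anisotropic grid.

    Parameters
    ----------
    values
        HU array of shape ``(nz, ny, nx)``.
    spacing
        Voxel spacing in mm per axis, ``(dz, dy, dx)``; all positive. ``dz``
        is the slice increment.
    origin
        World position (mm) of voxel ``(0, 0, 0)``, same axis order.
    slice_thickness
        Reconstructed slab thickness in mm; defaults to ``dz``. May exceed
        ``dz`` for overlapping reconstructions.
    calcium
        Optional channel (same shape) holding the calcium-attributable HU of
        each voxel, used by the acquisition simulator to rescale calcium
        contrast with tube voltage.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_thickness: float | None = None
    calcium: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"expected a non-empty 3-D array, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.slice_thickness is None:
            self.slice_thickness = self.spacing[0]
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < HU_MIN - 1e-6 or hi > HU_MAX + 1e-6:
            raise ValueError(f"HU values outside [{HU_MIN}, {HU_MAX}]: range ({lo}, {hi})")
        if self.calcium is not None:
            self.calcium = np.asarray(self.calcium)
            if self.calcium.shape != self.values.shape:
                raise ValueError("calcium channel shape must match values")

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area in mm^2."""
        return self.spacing[1] * self.spacing[2]

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def overlapping(self) -> bool:
        """True when slabs are thicker than the slice increment."""
        return self.slice_thickness > self.spacing[0] * (1 + 1e-9)


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def save_volume(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a volume as NIfTI or MetaImage, chosen by file suffix."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        # nibabel wants (x, y, z); flip axis order and build a diagonal affine
        data = np.ascontiguousarray(np.transpose(grid.values, (2, 1, 0)))
        affine = np.diag([grid.spacing[2], grid.spacing[1], grid.spacing[0], 1.0])
        affine[:3, 3] = [grid.origin[2], grid.origin[1], grid.origin[0]]
        nib.save(nib.Nifti1Image(data, affine), str(path))
    elif name.endswith((".mha", ".mhd")):
        img = sitk.GetImageFromArray(grid.values)
        img.SetSpacing((grid.spacing[2], grid.spacing[1], grid.spacing[0]))
        img.SetOrigin((grid.origin[2], grid.origin[1], grid.origin[0]))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if grid.overlapping():
        _sidecar(path).write_text(json.dumps({"slice_thickness": grid.slice_thickness}))
    return path


def load_volume(path: str | Path) -> VoxelGrid:
    """Read a NIfTI or MetaImage volume back into a :class:`VoxelGrid`."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
        zooms = img.header.get_zooms()[:3]  # (x, y, z)
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        origin = (float(img.affine[2, 3]), float(img.affine[1, 3]), float(img.affine[0, 3]))
    elif name.endswith((".mha", ".mhd")):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        sp = img.GetSpacing()  # (x, y, z)
        spacing = (float(sp[2]), float(sp[1]), float(sp[0]))
        og = img.GetOrigin()
        origin = (float(og[2]), float(og[1]), float(og[0]))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    thickness = None
    sc = _sidecar(path)
    if sc.exists():
        thickness = float(json.loads(sc.read_text())["slice_thickness"])
    return VoxelGrid(np.asarray(data), spacing, origin, slice_thickness=thickness)
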