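"""3-D scalar volumes with physical spacing metadata.

Arrays are indexed ``[x, y, z]`` with ``x`` the right-to-left body axis,
``y`` front-to-back and ``z`` head-to-foot.  ``spacing`` and ``origin``
are in millimetres; ``origin`` is the physical position of the centre of
voxel ``(0, 0, 0)``.  File I/O goes through SimpleITK, which stores
arrays ``[z, y, x]``; the axes are transposed on load/save so that the
in-memory convention above always holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

__all__ = ["Volume3D", "load_volume", "save_volume", "save_mask"]


@dataclass
class Volume3D:
    """Scalar intensity grid (H.U.) with voxel size and physical offset."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have three components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(d < 1 for d in self.values.shape):
            raise ValueError(f"grid dimensions must be >= 1, got {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_isotropic(self) -> bool:
        sx, sy, sz = self.spacing
        return abs(sy - sx) < 1e-9 and abs(sz - sx) < 1e-9

    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to physical mm coordinates."""
        index = np.asarray(index, dtype=float)
        return index * np.asarray(self.spacing) + np.asarray(self.origin)

    def physical_to_index(self, point_mm: np.ndarray) -> np.ndarray:
        point_mm = np.asarray(point_mm, dtype=float)
        return (point_mm - np.asarray(self.origin)) / np.asarray(self.spacing)

    def like(self, values: np.ndarray) -> "Volume3D":
        """A new volume on the same grid holding ``values``."""
        if values.shape != self.values.shape:
            raise ValueError("values shape does not match the reference grid")
        return Volume3D(values, self.spacing, self.origin)


def load_volume(path: str) -> Volume3D:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {img.GetDimension()}-D")
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    return Volume3D(
        np.ascontiguousarray(arr.transpose(2, 1, 0)),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def _to_sitk(volume: Volume3D, dtype) -> sitk.Image:
    arr = np.ascontiguousarray(volume.values.astype(dtype).transpose(2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    return img


def save_volume(volume: Volume3D, path: str) -> None:
    """Write a volume as 32-bit float NIfTI or MetaImage."""
    sitk.WriteImage(_to_sitk(volume, np.float32), str(path))


def save_mask(volume: Volume3D, path: str) -> None:
    """Write a label/binary volume as 8-bit unsigned integers."""
    sitk.WriteImage(_to_sitk(volume, np.uint8), str(path))
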