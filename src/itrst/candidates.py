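"""Initial candidate extraction from a blob-response volume.

The raw response can contain isolated zero voxels inside otherwise
blob-like regions, so a small cubic median filter is applied first;
candidates are then the connected suprathreshold components that are
large enough and touch the mediastinum search region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = ["CandidateParams", "CandidateRegion", "median_fill", "extract_candidates"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class CandidateParams:
    """w_hole: odd cubic median window (voxels); t_blob: response
    threshold; t_small: radius (mm) of the smallest sphere a surviving
    component may have the volume of."""

    w_hole: int = 3
    t_blob: float = 20.0
    t_small: float = 2.0

    def __post_init__(self) -> None:
        if self.w_hole < 3 or self.w_hole % 2 == 0:
            raise ValueError("w_hole must be odd and >= 3")
        if self.t_blob <= 0:
            raise ValueError("t_blob must be positive")
        if self.t_small < 0:
            raise ValueError("t_small must be non-negative")


@dataclass(eq=False)
class CandidateRegion:
    """One connected candidate: voxel indices, centroid and volume in
    physical units, and the component label it came from."""

    label: int
    coords: np.ndarray  # (N, 3) voxel indices
    centroid_mm: np.ndarray  # (3,)
    volume_mm3: float
    grid_shape: tuple[int, int, int] = field(default=None, repr=False)

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    def flat_indices(self) -> np.ndarray:
        return np.ravel_multi_index(self.coords.T, self.grid_shape)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = True
        return m

    def center_voxel(self) -> np.ndarray:
        """Region voxel nearest the centroid (robust for non-convex
        regions whose centroid may fall outside the region)."""
        d = np.linalg.norm(self.coords - self.centroid_voxel, axis=1)
        return self.coords[np.argmin(d)]

    @property
    def centroid_voxel(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def median_fill(response: Volume3D, w_hole: int = 3) -> Volume3D:
    """Cubic median filter of edge ``w_hole`` voxels (odd)."""
    if w_hole % 2 == 0 or w_hole < 1:
        raise ValueError("w_hole must be odd")
    out = ndimage.median_filter(response.values, size=w_hole, mode="nearest")
    return response.like(out)


def extract_candidates(
    filled: Volume3D,
    t_blob: float,
    t_small: float,
    mediastinum: np.ndarray,
) -> list[CandidateRegion]:
    """Threshold at >= t_blob, label 26-connected components, then drop
    components smaller than a sphere of radius t_small mm or having no
    voxel in common with the mediastinum mask."""
    if mediastinum.shape != filled.values.shape:
        raise ValueError("mediastinum mask and response grids differ")
    supra = filled.values >= t_blob
    labels, n = ndimage.label(supra, structure=_CONN26)
    if n == 0:
        return []
    voxel_vol = filled.voxel_volume()
    min_vol = (4.0 / 3.0) * np.pi * t_small**3
    media = np.asarray(mediastinum, dtype=bool)
    sizes = np.bincount(labels.ravel())
    touches = np.zeros(n + 1, dtype=bool)
    touched = labels[media]
    touches[np.unique(touched[touched > 0])] = True
    out: list[CandidateRegion] = []
    spacing = np.asarray(filled.spacing)
    origin = np.asarray(filled.origin)
    objects = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        if sizes[lab] * voxel_vol < min_vol or not touches[lab]:
            continue
        sl = objects[lab - 1]
        local = np.argwhere(labels[sl] == lab)
        coords = local + np.array([s.start for s in sl])
        centroid = coords.mean(axis=0) * spacing + origin
        out.append(
            CandidateRegion(
                label=lab,
                coords=coords,
                centroid_mm=centroid,
                volume_mm3=float(sizes[lab] * voxel_vol),
                grid_shape=filled.values.shape,
            )
        )
    return out
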