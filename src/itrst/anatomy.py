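"""Air/lung segmentation and mediastinum extraction.

The detection search region is the mediastinum — the space between the
two lungs.  Air regions are thresholded and cleaned of components that
touch the volume boundary (the air surrounding the body), the one or
two largest components become the lungs, and the mediastinum is filled
in between the lungs along the right-to-left (x) axis by a literal
line-scan procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = [
    "AnatomyParams",
    "segment_air",
    "select_lungs",
    "extract_mediastinum",
]

_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class AnatomyParams:
    """t_air: H.U. threshold below which a voxel counts as air;
    second_lung_fraction: minimum size ratio of the second-largest air
    component to the largest for it to count as the second lung."""

    t_air: float = -200.0
    second_lung_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.second_lung_fraction < 1:
            raise ValueError("second_lung_fraction must be in (0, 1)")


def segment_air(volume: Volume3D, t_air: float = -200.0) -> np.ndarray:
    """Air mask: voxels with I < t_air, excluding every connected
    component (6-connectivity) that touches a face of the grid."""
    below = volume.values < t_air
    labels, n = ndimage.label(below, structure=_CONN6)
    if n == 0:
        return below
    touching = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            touching.update(np.unique(face[face > 0]).tolist())
    if touching:
        keep = np.ones(n + 1, dtype=bool)
        keep[list(touching)] = False
        keep[0] = False
        return keep[labels]
    return below


def select_lungs(air_mask: np.ndarray, second_lung_fraction: float = 0.2) -> np.ndarray:
    """Union of the two largest air components when the second is at
    least ``second_lung_fraction`` of the largest; the largest alone
    otherwise (covers single-component lungs, e.g. connected via the
    trachea)."""
    labels, n = ndimage.label(air_mask, structure=_CONN6)
    if n == 0:
        return np.zeros_like(air_mask, dtype=bool)
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes)[::-1] + 1
    if n >= 2 and sizes[order[1] - 1] >= second_lung_fraction * sizes[order[0] - 1]:
        return (labels == order[0]) | (labels == order[1])
    return labels == order[0]


def extract_mediastinum(lung_mask: np.ndarray, fill_complete_gap: bool = False) -> np.ndarray:
    """Mediastinum mask from the lung mask by x-axis line scanning.

    For every (y, z) line, count the lung-to-background transitions
    ``a1`` (positions x with lung(x)=1 and lung(x+1)=0).  Where
    ``a1 >= 2`` (at least two lung components on the line), mark x
    whenever the number of transitions strictly before x is in
    ``[1, a1)`` and lung(x+1)=0, checking the mark condition before
    updating the running transition count.  This is applied literally,
    which leaves the last voxel of each inter-lung gap unmarked and
    marks the final voxel of each lung run after the first.

    ``fill_complete_gap=True`` instead fills every background voxel
    that has lung on both sides along x (on lines with two or more lung
    components).
    """
    lung = np.asarray(lung_mask, dtype=bool)
    media = np.zeros_like(lung)
    if lung.shape[0] < 2 or not lung.any():
        return media
    if fill_complete_gap:
        before = np.maximum.accumulate(lung, axis=0)
        after = np.maximum.accumulate(lung[::-1], axis=0)[::-1]
        trans = lung[:-1] & ~lung[1:]
        multi = trans.sum(axis=0) >= 2
        media = before & after & ~lung & multi[None, :, :]
        return media
    trans = lung[:-1] & ~lung[1:]  # trans[x] for x = 0 .. X-2
    a1 = trans.sum(axis=0)
    a2 = np.cumsum(trans, axis=0) - trans  # transitions strictly before x
    fill = (a2 >= 1) & (a2 < a1[None, :, :]) & ~lung[1:]
    media[:-1] = fill & (a1 >= 2)[None, :, :]
    return media
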