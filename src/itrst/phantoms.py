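"""Digital phantoms with ground truth.

Two generators: (a) the artificial validation volume — seven 15-mm
spheres of 50 H.U. on a 0 H.U. background, Gaussian-smoothed, with
three spheres contacting 300 H.U. square poles (contrast-enhanced
vessel stand-ins) and three contacting -1000 H.U. square poles (air
stand-ins), the poles drawn after smoothing so their edges stay sharp;
and (b) a seeded chest-like volume with two air lungs, a soft-tissue
mediastinum, bright vessel tubes, planted lymph nodes with known axis
lengths, and bright non-node decoy blobs that act as false-positive
generators for the classifier stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fp_reduction import GroundTruthNode
from .volume import Volume3D

__all__ = [
    "PhantomSpec",
    "ChestPhantomSpec",
    "ArtificialPhantom",
    "ChestPhantom",
    "generate_artificial_volume",
    "generate_chest_phantom",
    "extract_profile",
    "SPHERE_ISOLATED",
    "SPHERES_BRIGHT",
    "SPHERES_DARK",
    "POLES_BRIGHT",
    "POLES_DARK",
]

# label values in the artificial volume's label grid
SPHERE_ISOLATED = 1
SPHERES_BRIGHT = (2, 3, 4)  # spheres contacting 300 H.U. poles
SPHERES_DARK = (5, 6, 7)  # spheres contacting -1000 H.U. poles
POLES_BRIGHT = (8, 9, 10)
POLES_DARK = (11, 12, 13)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the artificial validation volume.

    Distances in mm, intensities in H.U.  The default layout places all
    seven sphere centres in one axial plane: one isolated, a row of
    three contacting bright poles and a row of three contacting dark
    poles, with contact offsets 0 / 2 / 4 mm of pole intrusion into the
    sphere to vary the overlap severity.
    """

    spacing: float = 0.625
    shape: tuple[int, int, int] = (176, 304, 56)
    sphere_diameter: float = 15.0
    sphere_intensity: float = 50.0
    background: float = 0.0
    smoothing_sigma: float = 1.0
    pole_bright: float = 300.0
    pole_dark: float = -1000.0
    pole_thickness: float = 15.0
    pole_length: float = 50.0
    overlap_offsets: tuple[float, float, float] = (0.0, -2.0, -4.0)
    sphere_columns_x: tuple[float, float, float] = (25.0, 55.0, 85.0)
    dark_row_y: float = 60.0
    bright_row_y: float = 130.0
    isolated_center: tuple[float, float] = (55.0, 95.0)
    plane_z: float = 17.5

    def sphere_centers(self) -> np.ndarray:
        """Centres of the 7 spheres in label order (isolated, bright
        row, dark row)."""
        z = self.plane_z
        rows = [(self.isolated_center[0], self.isolated_center[1], z)]
        rows += [(x, self.bright_row_y, z) for x in self.sphere_columns_x]
        rows += [(x, self.dark_row_y, z) for x in self.sphere_columns_x]
        return np.asarray(rows)

    def validate(self) -> None:
        if self.sphere_diameter <= 0 or self.pole_thickness <= 0:
            raise ValueError("sphere diameter and pole thickness must be positive")
        centers = self.sphere_centers()
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < self.sphere_diameter:
            raise ValueError("spheres overlap each other in the phantom layout")


@dataclass
class ArtificialPhantom:
    volume: Volume3D
    labels: Volume3D  # sphere labels 1-7, pole labels 8-13, background 0


def _coordinate_grids(shape, spacing, origin=(0.0, 0.0, 0.0)):
    axes = [np.arange(n) * s + o for n, s, o in zip(shape, np.broadcast_to(spacing, (3,)), origin)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def generate_artificial_volume(spec: PhantomSpec | None = None) -> ArtificialPhantom:
    """Build the artificial volume: spheres drawn uniform, Gaussian
    smoothing applied, then poles drawn with exact intensities."""
    spec = spec or PhantomSpec()
    spec.validate()
    sp = spec.spacing
    vals = np.full(spec.shape, spec.background, dtype=np.float64)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    gx, gy, gz = _coordinate_grids(spec.shape, sp)
    r = spec.sphere_diameter / 2.0

    centers = spec.sphere_centers()
    for lab, c in zip(
        (SPHERE_ISOLATED, *SPHERES_BRIGHT, *SPHERES_DARK), centers
    ):
        inside = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2 <= r * r
        vals[inside] = spec.sphere_intensity
        labels[inside] = lab

    vals = ndimage.gaussian_filter(vals, sigma=spec.smoothing_sigma / sp, mode="nearest")

    half_t = spec.pole_thickness / 2.0
    z0, z1 = spec.plane_z - half_t, spec.plane_z + half_t
    zin = (gz >= z0) & (gz <= z1)

    def draw_pole(lab, cx, y_lo, y_hi, value):
        box = (
            (gx >= cx - half_t) & (gx <= cx + half_t)
            & (gy >= y_lo) & (gy <= y_hi) & zin
        )
        vals[box] = value
        labels[box] = lab

    # bright poles extend +y from each bright-row sphere; dark poles -y
    for lab, cx, s in zip(POLES_BRIGHT, spec.sphere_columns_x, spec.overlap_offsets):
        face = spec.bright_row_y + (r + s)
        draw_pole(lab, cx, face, face + spec.pole_length, spec.pole_bright)
    for lab, cx, s in zip(POLES_DARK, spec.sphere_columns_x, spec.overlap_offsets):
        face = spec.dark_row_y - (r + s)
        draw_pole(lab, cx, face - spec.pole_length, face, spec.pole_dark)

    return ArtificialPhantom(
        Volume3D(vals, (sp,) * 3), Volume3D(labels, (sp,) * 3)
    )


# ---------------------------------------------------------------------------
# chest phantom


@dataclass(frozen=True)
class ChestPhantomSpec:
    """Seeded chest-like phantom.

    A body cylinder of soft tissue in surrounding air, two air-filled
    lung ellipsoids, vertical contrast-enhanced vessel tubes in the
    inter-lung gap, ``n_nodes`` ellipsoidal lymph nodes (ground truth)
    and ``n_decoys`` smaller, brighter spherical decoys (deliberate
    false-positive sources that a classifier can separate by intensity
    and size).  One node is forced adjacent to a vessel and one
    adjacent to a lung boundary — the hard configurations the
    intensity-targeted filter is designed for.
    """

    seed: int = 0
    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (0.8, 0.8, 1.0)
    body_intensity: float = -20.0
    outside_intensity: float = -1000.0
    lung_intensity: float = -900.0
    body_radii: tuple[float, float] = (36.0, 32.0)
    lung_radii: tuple[float, float, float] = (10.0, 20.0, 24.0)
    lung_offset_x: float = 20.0
    vessel_intensity: float = 250.0
    vessel_radii: tuple[float, float] = (3.5, 3.0)
    vessel_y: tuple[float, float] = (30.0, 48.0)
    vessel_x_offset: tuple[float, float] = (-5.0, 5.0)
    n_nodes: int = 8
    node_short_diameter: tuple[float, float] = (6.0, 12.0)
    node_aspect: tuple[float, float] = (1.0, 1.25)
    node_intensity: tuple[float, float] = (50.0, 70.0)
    n_decoys: int = 20
    decoy_radius: tuple[float, float] = (2.5, 3.5)
    decoy_intensity: tuple[float, float] = (78.0, 92.0)
    noise_sigma: float = 8.0
    max_retries: int = 5000

    def validate(self) -> None:
        if self.node_short_diameter[0] <= 0:
            raise ValueError("node sizes must be positive")
        if 2 * self.lung_offset_x <= 2 * self.lung_radii[0]:
            raise ValueError("lungs must be disjoint")


@dataclass
class ChestPhantom:
    volume: Volume3D
    node_specs: list[dict]  # center_mm, radii_mm, intensity per node
    lung_labels: Volume3D  # 1 = left lung, 2 = right lung
    node_labels: Volume3D  # node i -> label i + 1
    cancer_mask: np.ndarray | None = None

    def ground_truth_nodes(self, grid: Volume3D) -> list[GroundTruthNode]:
        """Rasterise the analytic node ellipsoids on ``grid`` (any
        spacing), with the analytic short/long axis lengths."""
        nodes = []
        gx, gy, gz = _coordinate_grids(grid.shape, grid.spacing, grid.origin)
        for spec in self.node_specs:
            c, rr = spec["center_mm"], spec["radii_mm"]
            inside = (
                ((gx - c[0]) / rr[0]) ** 2
                + ((gy - c[1]) / rr[1]) ** 2
                + ((gz - c[2]) / rr[2]) ** 2
            ) <= 1.0
            coords = np.argwhere(inside)
            if len(coords) == 0:
                continue
            nodes.append(
                GroundTruthNode(
                    coords=coords,
                    short_axis_mm=2.0 * min(rr),
                    long_axis_mm=2.0 * max(rr),
                    grid_shape=grid.shape,
                )
            )
        return nodes


def _ellipsoid(gx, gy, gz, center, radii):
    return (
        ((gx - center[0]) / radii[0]) ** 2
        + ((gy - center[1]) / radii[1]) ** 2
        + ((gz - center[2]) / radii[2]) ** 2
    ) <= 1.0


def generate_chest_phantom(spec: ChestPhantomSpec | None = None) -> ChestPhantom:
    """Deterministic (seeded) chest-like phantom with ground truth."""
    spec = spec or ChestPhantomSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sp = np.asarray(spec.spacing)
    extent = np.asarray(spec.shape) * sp
    cx, cy = extent[0] / 2.0, extent[1] / 2.0
    cz = extent[2] / 2.0
    gx, gy, gz = _coordinate_grids(spec.shape, spec.spacing)

    vals = np.full(spec.shape, spec.outside_intensity, dtype=np.float64)
    body = ((gx - cx) / spec.body_radii[0]) ** 2 + (
        (gy - cy) / spec.body_radii[1]
    ) ** 2 <= 1.0
    body = np.broadcast_to(body, spec.shape)
    vals[body] = spec.body_intensity

    lung_labels = np.zeros(spec.shape, dtype=np.uint8)
    lung_centers = [
        (cx - spec.lung_offset_x, cy, cz),
        (cx + spec.lung_offset_x, cy, cz),
    ]
    for i, lc in enumerate(lung_centers):
        m = _ellipsoid(gx, gy, gz, lc, spec.lung_radii)
        vals[m] = spec.lung_intensity
        lung_labels[m] = i + 1

    gap_half = spec.lung_offset_x - spec.lung_radii[0]  # inner lung edge offset

    # vessels: vertical tubes through the mediastinal gap
    vessel = np.zeros(spec.shape, dtype=bool)
    vessel_defs = []
    for vy, vr, vxo in zip(spec.vessel_y, spec.vessel_radii, spec.vessel_x_offset):
        m = (gx - cx - vxo) ** 2 + (gy - vy) ** 2 <= vr * vr
        vessel |= np.broadcast_to(m, spec.shape)
        vessel_defs.append((cx + vxo, vy, vr))

    occupied = vessel | (lung_labels > 0)

    def node_geometry(short_d):
        short_r = short_d / 2.0
        aspect = rng.uniform(*spec.node_aspect)
        radii = np.array([short_r, short_r * rng.uniform(1.0, aspect),
                          short_r * aspect])
        rng.shuffle(radii)
        return radii

    def fits(center, radii, clearance=0.5):
        m = _ellipsoid(gx, gy, gz, center,
                       np.asarray(radii) + clearance)
        return not (np.broadcast_to(m, spec.shape) & occupied).any()

    node_specs: list[dict] = []
    node_labels = np.zeros(spec.shape, dtype=np.uint8)

    def place_node(center, radii):
        m = _ellipsoid(gx, gy, gz, center, radii)
        intensity = rng.uniform(*spec.node_intensity)
        vals[m] = intensity
        node_labels[m] = len(node_specs) + 1
        node_specs.append(
            {"center_mm": np.asarray(center, dtype=float),
             "radii_mm": np.asarray(radii, dtype=float),
             "intensity": float(intensity)}
        )
        nonlocal occupied
        occupied = occupied | m

    # forced hard cases: one node against a vessel, one against a lung
    if spec.n_nodes >= 1:
        vx, vy, vr = vessel_defs[0]
        radii = node_geometry(rng.uniform(8.0, min(10.0, spec.node_short_diameter[1])))
        center = (vx, vy + vr + radii[1] + 0.6, cz - 8.0)
        if fits(center, radii, clearance=0.3):
            place_node(center, radii)
    if spec.n_nodes >= 2 and len(node_specs) >= 1:
        radii = node_geometry(rng.uniform(8.0, min(10.0, spec.node_short_diameter[1])))
        center = (cx - gap_half + radii[0] + 0.6, cy, cz + 10.0)
        if fits(center, radii, clearance=0.3):
            place_node(center, radii)

    tries = 0
    while len(node_specs) < spec.n_nodes:
        tries += 1
        if tries > spec.max_retries:
            raise RuntimeError("node placement failed after bounded retries")
        short_d = rng.uniform(*spec.node_short_diameter)
        radii = node_geometry(short_d)
        center = (
            cx + rng.uniform(-gap_half * 0.5, gap_half * 0.5),
            rng.uniform(cy - 13.0, cy + 13.0),
            rng.uniform(cz - 18.0, cz + 18.0),
        )
        if fits(center, radii):
            place_node(center, radii)

    # decoys: brighter, smaller spheres; false-positive generators
    n_placed = 0
    tries = 0
    while n_placed < spec.n_decoys:
        tries += 1
        if tries > spec.max_retries:
            raise RuntimeError("decoy placement failed after bounded retries")
        r = rng.uniform(*spec.decoy_radius)
        center = (
            cx + rng.uniform(-gap_half * 0.6, gap_half * 0.6),
            rng.uniform(cy - 14.0, cy + 14.0),
            rng.uniform(cz - 20.0, cz + 20.0),
        )
        radii = (r, r, r)
        if fits(center, radii):
            m = _ellipsoid(gx, gy, gz, center, radii)
            vals[m] = rng.uniform(*spec.decoy_intensity)
            occupied = occupied | m
            n_placed += 1

    vals[vessel] = spec.vessel_intensity
    vals += rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    return ChestPhantom(
        volume=Volume3D(vals, spec.spacing),
        node_specs=node_specs,
        lung_labels=Volume3D(lung_labels, spec.spacing),
        node_labels=Volume3D(node_labels, spec.spacing),
        cancer_mask=None,
    )


# ---------------------------------------------------------------------------
# profiles


def extract_profile(
    volume: Volume3D, a_mm, b_mm, step_mm: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-voxel samples along the segment A-B.

    Returns ``(positions_mm, values, voxel_indices)`` where positions
    are distances from A.  A single sample is returned when A == B.
    """
    a = np.asarray(a_mm, dtype=float)
    b = np.asarray(b_mm, dtype=float)
    step = step_mm if step_mm is not None else min(volume.spacing) / 2.0
    length = float(np.linalg.norm(b - a))
    n = max(1, int(np.floor(length / step)) + 1)
    t = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    points = a[None, :] + t[:, None] * (b - a)[None, :]
    idx = np.rint(volume.physical_to_index(points)).astype(int)
    shape = np.asarray(volume.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise ValueError("profile endpoint outside the grid")
    values = volume.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return t * length, values, idx
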