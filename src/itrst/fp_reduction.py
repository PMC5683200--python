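"""False-positive reduction: per-candidate features, weighted SVM,
FROC evaluation and leave-one-out cross validation.

Each candidate region gets a (9 + 7|D|)-dimensional feature vector:
geometry (volume, surface area, sphericity, maximum interior distance,
long/short axis lengths), location (x, normalised-y within the lung
bounding box, z), and for every dilation radius d in D the mean,
variance, median, maximum, minimum, skewness and kurtosis of the
intensity over the d-dilated region.  A support-vector classifier with
the negative class down-weighted by w_F separates true nodes from the
(far more numerous) false detections; sweeping w_F traces an FROC
curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .candidates import CandidateRegion
from .volume import Volume3D

__all__ = [
    "TrainingPolicy",
    "GroundTruthNode",
    "FROCPoint",
    "axis_lengths",
    "feature_names",
    "extract_features",
    "label_candidates",
    "nodes_from_label_volume",
    "train_classifier",
    "apply_classifier",
    "froc_evaluate",
    "loo_cross_validation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingPolicy:
    """r_target: minimum short axis (mm) of detection targets; w_train:
    fraction of r_target above which ground-truth nodes still provide
    positive training samples; w_F: SVM weight of the negative class."""

    r_target: float = 10.0
    w_train: float = 0.5
    w_F: float = 0.075

    def __post_init__(self) -> None:
        if not 0 < self.w_train < 1:
            raise ValueError("w_train must be in (0, 1)")
        if self.w_F <= 0:
            raise ValueError("w_F must be positive")


@dataclass(eq=False)
class GroundTruthNode:
    """An annotated lymph node: its voxel set on a reference grid and
    its principal-axis lengths in mm."""

    coords: np.ndarray  # (N, 3) voxel indices
    short_axis_mm: float
    long_axis_mm: float
    grid_shape: tuple[int, int, int] = None

    def __post_init__(self) -> None:
        if len(self.coords) == 0:
            raise ValueError("ground-truth node has no voxels")
        if self.short_axis_mm > self.long_axis_mm + 1e-9:
            raise ValueError("short axis exceeds long axis")

    def flat_indices(self) -> np.ndarray:
        return np.ravel_multi_index(self.coords.T, self.grid_shape)


@dataclass(frozen=True)
class FROCPoint:
    """One free-response operating point averaged over volumes."""

    rate_mean: float
    rate_sd: float
    fps_mean: float
    w_F: float | None = None


# ---------------------------------------------------------------------------
# features


def axis_lengths(coords_mm: np.ndarray) -> tuple[float, float]:
    """(long, short) axis lengths as the full extents of the voxel
    centres along the first and third principal components."""
    coords_mm = np.asarray(coords_mm, dtype=float)
    if len(coords_mm) == 1:
        return 0.0, 0.0
    centred = coords_mm - coords_mm.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    _, vecs = np.linalg.eigh(cov)
    proj = centred @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0)
    # for near-spherical regions the variance ordering of the principal
    # axes need not match the extent ordering; take the extremes
    return float(extents.max()), float(extents.min())


def _surface_area(mask: np.ndarray, spacing: np.ndarray) -> float:
    """Exposed-voxel-face area in mm^2."""
    m = np.pad(mask, 1)
    area = 0.0
    vox = float(np.prod(spacing))
    for axis in range(3):
        face = vox / spacing[axis]
        shifted = np.roll(m, 1, axis=axis)
        area += face * (np.count_nonzero(m & ~shifted) + np.count_nonzero(m & ~np.roll(m, -1, axis=axis)))
    return area


def _moments(values: np.ndarray) -> list[float]:
    """mean, variance, median, max, min, skewness, kurtosis with the
    zero-variance convention skew = kurt = 0."""
    v = np.asarray(values, dtype=float)
    var = float(v.var())
    if var <= 1e-30:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(v))
        kurt = float(stats.kurtosis(v))
    return [float(v.mean()), var, float(np.median(v)), float(v.max()),
            float(v.min()), skew, kurt]


def feature_names(D) -> list[str]:
    names = ["u1_volume", "u2_surface_area", "u3_sphericity", "u4_max_contour_dist",
             "u5_long_axis", "u6_short_axis", "u7_x", "u8_norm_y", "u9_z"]
    stats_ = ["avg", "var", "median", "max", "min", "skew", "kurt"]
    for p, d in enumerate(D):
        base = 10 + 7 * p
        names += [f"u{base + k}_{s}_d{d:g}" for k, s in enumerate(stats_)]
    return names


def _dilated_values(
    cand: CandidateRegion, intensity: Volume3D, d_mm: float
) -> np.ndarray:
    """Intensities over the candidate region dilated by a sphere of
    radius d mm (the region itself for d = 0)."""
    sp = np.asarray(intensity.spacing)
    if d_mm <= 0:
        c = cand.coords
        return intensity.values[c[:, 0], c[:, 1], c[:, 2]]
    r_vox = np.ceil(d_mm / sp).astype(int)
    lo = np.maximum(cand.coords.min(axis=0) - r_vox - 1, 0)
    hi = np.minimum(cand.coords.max(axis=0) + r_vox + 2, intensity.values.shape)
    sub = np.zeros(tuple(hi - lo), dtype=bool)
    rel = cand.coords - lo
    sub[rel[:, 0], rel[:, 1], rel[:, 2]] = True
    # spherical structuring element of radius d mm in voxel units
    grids = np.meshgrid(
        *[np.arange(-r, r + 1) * s for r, s in zip(r_vox, sp)], indexing="ij"
    )
    ball = grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2 <= d_mm**2 + 1e-9
    dil = ndimage.binary_dilation(sub, structure=ball)
    vals = intensity.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return vals[dil]


def extract_features(
    candidate: CandidateRegion,
    intensity: Volume3D,
    lung_mask: np.ndarray | None,
    D=(0.0, 1.0, 2.0),
) -> np.ndarray:
    """Feature vector of length 9 + 7|D| for one candidate region."""
    if candidate.n_voxels == 0:
        raise ValueError("empty candidate region")
    sp = np.asarray(intensity.spacing)
    origin = np.asarray(intensity.origin)
    coords_mm = candidate.coords * sp + origin

    u1 = candidate.n_voxels * float(np.prod(sp))
    mask = _local_mask(candidate)
    u2 = _surface_area(mask, sp)
    u3 = np.pi ** (1.0 / 3.0) * (6.0 * u1) ** (2.0 / 3.0) / u2
    edt = ndimage.distance_transform_edt(np.pad(mask, 1), sampling=sp)
    u4 = float(edt.max())
    u5, u6 = axis_lengths(coords_mm)
    centroid = coords_mm.mean(axis=0)
    u7, u9 = float(centroid[0]), float(centroid[2])
    if lung_mask is not None and lung_mask.any():
        ys = np.nonzero(lung_mask.any(axis=(0, 2)))[0]
        y0 = ys[0] * sp[1] + origin[1]
        y1 = ys[-1] * sp[1] + origin[1]
        u8 = float(np.clip((centroid[1] - y0) / max(y1 - y0, 1e-9), 0.0, 1.0))
    else:
        log.debug("no lung bounding box; u8 falls back to 0.5")
        u8 = 0.5
    feats = [u1, u2, u3, u4, u5, u6, u7, u8, u9]
    for d in D:
        feats.extend(_moments(_dilated_values(candidate, intensity, float(d))))
    return np.asarray(feats, dtype=float)


def _local_mask(cand: CandidateRegion) -> np.ndarray:
    lo = cand.coords.min(axis=0)
    rel = cand.coords - lo
    m = np.zeros(tuple(rel.max(axis=0) + 1), dtype=bool)
    m[rel[:, 0], rel[:, 1], rel[:, 2]] = True
    return m


def nodes_from_label_volume(label_volume, grid) -> list["GroundTruthNode"]:
    """Ground-truth nodes from an integer label volume, rasterised onto
    ``grid`` (possibly at a different resolution).

    Every ``grid`` voxel whose centre falls inside a labelled native
    voxel (nearest-neighbour, per-label bounding box) joins that node;
    axis lengths are measured on the native-resolution label.
    """
    lab_vals = np.rint(np.asarray(label_volume.values)).astype(int)
    sp_nat = np.asarray(label_volume.spacing)
    or_nat = np.asarray(label_volume.origin)
    sp_g = np.asarray(grid.spacing)
    or_g = np.asarray(grid.origin)
    shape_g = np.asarray(grid.shape)
    nodes = []
    for lab in np.unique(lab_vals):
        if lab == 0:
            continue
        native = np.argwhere(lab_vals == lab)
        mm = native * sp_nat + or_nat
        lo = np.maximum(np.floor((mm.min(0) - sp_nat - or_g) / sp_g), 0).astype(int)
        hi = np.minimum(
            np.ceil((mm.max(0) + sp_nat - or_g) / sp_g) + 1, shape_g
        ).astype(int)
        if np.any(hi <= lo):
            continue
        box = np.stack(
            np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        nat_idx = np.rint((box * sp_g + or_g - or_nat) / sp_nat).astype(int)
        ok = np.all((nat_idx >= 0) & (nat_idx < lab_vals.shape), axis=1)
        box, nat_idx = box[ok], nat_idx[ok]
        inside = lab_vals[nat_idx[:, 0], nat_idx[:, 1], nat_idx[:, 2]] == lab
        coords = box[inside]
        if len(coords) == 0:
            continue
        long_ax, short_ax = axis_lengths(mm)
        nodes.append(GroundTruthNode(coords, short_ax, long_ax, tuple(shape_g)))
    return nodes


# ---------------------------------------------------------------------------
# training labels


def label_candidates(
    candidates: list[CandidateRegion],
    ground_truth: list[GroundTruthNode],
    policy: TrainingPolicy,
) -> np.ndarray:
    """Boolean training labels: positive iff the candidate's centre
    voxel lies inside a ground-truth node whose short axis is at least
    ``r_target * w_train`` mm."""
    threshold = policy.r_target * policy.w_train
    g_nodes = [g for g in ground_truth if g.short_axis_mm >= threshold]
    flat_sets = [set(map(int, g.flat_indices())) for g in g_nodes]
    labels = np.zeros(len(candidates), dtype=bool)
    for i, cand in enumerate(candidates):
        center = cand.center_voxel()
        flat = int(np.ravel_multi_index(center, cand.grid_shape))
        labels[i] = any(flat in s for s in flat_sets)
    return labels


# ---------------------------------------------------------------------------
# classifier


@dataclass
class ClassifierState:
    """Trained SVM plus the settings needed to apply it consistently."""

    pipeline: Pipeline
    n_features: int
    D: tuple = (0.0, 1.0, 2.0)
    w_F: float = 0.075


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    w_F: float,
    C: float = 1.0,
    D=(0.0, 1.0, 2.0),
) -> ClassifierState:
    """RBF support-vector classifier with negative-class weight w_F and
    libsvm-default kernel width 1/n_features; features standardised to
    zero mean / unit variance with statistics kept in the state."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("training set must contain both classes")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(C=C, kernel="rbf", gamma="auto",
                        class_weight={False: w_F, True: 1.0})),
        ]
    )
    pipe.fit(features, labels)
    return ClassifierState(pipe, features.shape[1], tuple(D), w_F)


def apply_classifier(
    state: ClassifierState,
    candidates: list[CandidateRegion],
    features: np.ndarray,
    grid_shape: tuple[int, int, int] | None = None,
) -> tuple[np.ndarray, list[CandidateRegion]]:
    """Predict each candidate; returns the union mask of the kept
    regions and the kept-candidate list."""
    if len(candidates) == 0:
        shape = grid_shape
        if shape is None:
            raise ValueError("grid_shape required when there are no candidates")
        return np.zeros(shape, dtype=bool), []
    features = np.asarray(features, dtype=float)
    if features.shape[1] != state.n_features:
        raise ValueError(
            f"feature length {features.shape[1]} != trained {state.n_features}"
        )
    pred = state.pipeline.predict(features)
    kept = [c for c, p in zip(candidates, pred) if p]
    shape = grid_shape or candidates[0].grid_shape
    mask = np.zeros(shape, dtype=bool)
    for c in kept:
        mask[c.coords[:, 0], c.coords[:, 1], c.coords[:, 2]] = True
    return mask, kept


# ---------------------------------------------------------------------------
# FROC


def _overlaps(region_flat: np.ndarray, node_flat_sets: list[set]) -> list[bool]:
    s = set(map(int, region_flat))
    return [bool(s & ns) for ns in node_flat_sets]


def froc_evaluate(
    detections_per_volume: list[list[CandidateRegion]],
    ground_truth_per_volume: list[list[GroundTruthNode]],
    r_target: float,
    cancer_masks: list[np.ndarray | None] | None = None,
    w_F: float | None = None,
) -> FROCPoint:
    """Detection rate and FPs/volume averaged over volumes.

    A target node (short axis >= r_target) overlapped by at least one
    detected region (>= 1 shared voxel) is a TP; a detected region
    overlapping no node at all — not even a sub-target one — and no
    lung-cancer label is an FP.  Volumes without any target are
    excluded from the rate average but still contribute FPs.
    """
    if len(detections_per_volume) != len(ground_truth_per_volume):
        raise ValueError("detections and ground truth differ in volume count")
    rates, fps = [], []
    for vi, (regions, nodes) in enumerate(
        zip(detections_per_volume, ground_truth_per_volume)
    ):
        targets = [g for g in nodes if g.short_axis_mm >= r_target]
        node_sets = [set(map(int, g.flat_indices())) for g in nodes]
        target_idx = [i for i, g in enumerate(nodes) if g.short_axis_mm >= r_target]
        cancer = None
        if cancer_masks is not None and cancer_masks[vi] is not None:
            cancer = set(map(int, np.flatnonzero(cancer_masks[vi].ravel())))
        hit = np.zeros(len(nodes), dtype=bool)
        n_fp = 0
        for reg in regions:
            ov = _overlaps(reg.flat_indices(), node_sets)
            if any(ov):
                hit |= np.asarray(ov)
            else:
                rset = set(map(int, reg.flat_indices()))
                if cancer is None or not (rset & cancer):
                    n_fp += 1
        fps.append(n_fp)
        if targets:
            rates.append(hit[target_idx].sum() / len(target_idx))
        else:
            log.info("volume %d has no detection targets; excluded from rate", vi)
    if not rates:
        return FROCPoint(float("nan"), float("nan"), float(np.mean(fps)), w_F)
    return FROCPoint(
        float(np.mean(rates)), float(np.std(rates)), float(np.mean(fps)), w_F
    )


# ---------------------------------------------------------------------------
# leave-one-out


def loo_cross_validation(
    volumes: list[dict],
    policy: TrainingPolicy,
    w_F_list,
    C: float = 1.0,
) -> list[FROCPoint]:
    """FROC point per w_F via leave-one-out cross validation.

    Each entry of ``volumes`` bundles one volume's candidates, their
    feature matrix, its ground-truth nodes, and optionally a
    lung-cancer mask:
    ``{"candidates": [...], "features": (n, F), "nodes": [...],
    "cancer_mask": ... or None}``.
    """
    if len(volumes) < 2:
        raise ValueError("leave-one-out needs at least 2 volumes")
    labels = [
        label_candidates(v["candidates"], v["nodes"], policy) for v in volumes
    ]
    cancer = [v.get("cancer_mask") for v in volumes]
    points = []
    for w_F in w_F_list:
        kept_per_volume = []
        for i, vol in enumerate(volumes):
            train_feats = np.vstack(
                [volumes[j]["features"] for j in range(len(volumes)) if j != i
                 and len(volumes[j]["features"])]
            )
            train_labels = np.concatenate(
                [labels[j] for j in range(len(volumes)) if j != i]
            )
            state = train_classifier(train_feats, train_labels, w_F, C=C)
            if len(vol["candidates"]) == 0:
                kept_per_volume.append([])
                continue
            _, kept = apply_classifier(
                state, vol["candidates"], vol["features"]
            )
            kept_per_volume.append(kept)
        points.append(
            froc_evaluate(
                kept_per_volume,
                [v["nodes"] for v in volumes],
                policy.r_target,
                cancer_masks=cancer,
                w_F=w_F,
            )
        )
    return points
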