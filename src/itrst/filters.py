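"""Radial structure tensor (RST), intensity-targeted RST (ITRST) and
Hessian blob filters.

The RST at a voxel ``x`` accumulates, over a set of radial search
directions ``r_i`` and steps ``j`` along each ray, the outer products
``alpha_ij * r_i g_ij^T`` where ``g_ij`` is the local intensity gradient
at the sampled position and ``alpha_ij`` an opacity derived from the
intensity difference to the starting voxel.  A ray stops when its
accumulated opacity approaches 1 or its length reaches ``t_len``.

The ITRST additionally multiplies every term by an indicator
``gamma_ij`` that is 1 only when all six neighbours of the sampled
position lie inside a target intensity range ``[t_dark, t_bright]`` —
gradients computed next to very bright (contrast-enhanced vessel) or
very dark (air) voxels are discarded, so a huge intensity gap adjacent
to a soft-tissue blob no longer swamps the tensor.

Blob likeness is scored from the eigenvalues of the symmetrised tensor
``T + T^T``: all three negative and of similar magnitude means a bright
blob, and the response is ``|l2|^2 / |l0|`` with eigenvalues ordered by
decreasing magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = [
    "RadialSearchParams",
    "IntensityTargetRange",
    "sample_directions",
    "opacity",
    "gamma_mask",
    "compute_rst",
    "compute_itrst",
    "radial_tensor_field",
    "eigenvalues_by_magnitude",
    "blob_measure",
    "hessian_tensor_field",
    "hessian_blob_filter",
    "filter_volume",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RadialSearchParams:
    """Parameters of the radial search.

    t_min / t_max
        H.U. bounds controlling the gradient sensitivity of the opacity
        (below t_min an intensity difference is transparent, above t_max
        fully opaque).
    t_len
        Maximum search length along a ray, in mm.
    n_directions
        Number of radial directions (near-uniform on the sphere).
    step
        Sampling step along a ray in mm; ``None`` means one voxel.
    beta_tolerance
        A ray terminates once its accumulated opacity reaches
        ``1 - beta_tolerance``.
    opacity_form
        "printed" uses the middle branch ``|dI| / |t_max - t_min|``
        clamped at 1; "continuous" uses ``(|dI| - t_min)/(t_max - t_min)``.
    beta_mode
        ITRST opacity accumulation: "product" sums ``alpha * gamma``
        (default); "literal" terminates once ``max(sum alpha, gamma)``
        reaches 1.
    """

    t_min: float = 10.0
    t_max: float = 110.0
    t_len: float = 15.0
    n_directions: int = 42
    step: float | None = None
    beta_tolerance: float = 1e-6
    opacity_form: str = "printed"
    beta_mode: str = "product"

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError(f"t_min must be < t_max ({self.t_min} >= {self.t_max})")
        if self.t_len <= 0:
            raise ValueError("t_len must be positive")
        if self.n_directions < 6:
            raise ValueError("n_directions must be >= 6")
        if self.step is not None and self.step <= 0:
            raise ValueError("step must be positive")
        if self.opacity_form not in ("printed", "continuous"):
            raise ValueError(f"unknown opacity_form {self.opacity_form!r}")
        if self.beta_mode not in ("product", "literal"):
            raise ValueError(f"unknown beta_mode {self.beta_mode!r}")


@dataclass(frozen=True)
class IntensityTargetRange:
    """Target intensity range [t_dark, t_bright] in H.U. (inclusive)."""

    t_dark: float = -100.0
    t_bright: float = 100.0

    def __post_init__(self) -> None:
        if not self.t_dark < self.t_bright:
            raise ValueError(
                f"t_dark must be < t_bright ({self.t_dark} >= {self.t_bright})"
            )


# ---------------------------------------------------------------------------
# search directions


def _icosahedron() -> np.ndarray:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            verts += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    v = np.array(verts)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _subdivide_on_sphere(verts: np.ndarray) -> np.ndarray:
    """One midpoint subdivision of the convex triangulation of ``verts``."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(verts)
    edges = set()
    for simplex in hull.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            edges.add(tuple(sorted((simplex[a], simplex[b]))))
    mids = np.array([verts[a] + verts[b] for a, b in sorted(edges)])
    mids /= np.linalg.norm(mids, axis=1, keepdims=True)
    return np.vstack([verts, mids])


def sample_directions(n_directions: int) -> np.ndarray:
    """Deterministic set of ``n_directions`` unit vectors, near-uniform
    on the sphere.

    ``n = 6`` gives the axis-aligned directions; icosahedral counts
    (12, 42, 162, 642, ...) give subdivided-icosahedron vertices; any
    other count falls back to a spherical Fibonacci lattice.
    """
    if n_directions < 6:
        raise ValueError("n_directions must be >= 6")
    if n_directions == 6:
        return np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
    verts = _icosahedron()
    while len(verts) < n_directions:
        verts = _subdivide_on_sphere(verts)
    if len(verts) == n_directions:
        order = np.lexsort(verts.T)
        return verts[order]
    # Fibonacci lattice for non-icosahedral counts
    k = np.arange(n_directions)
    z = 1.0 - (2.0 * k + 1.0) / n_directions
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


# ---------------------------------------------------------------------------
# opacity and target-range indicator


def _opacity_array(abs_diff: np.ndarray, params: RadialSearchParams) -> np.ndarray:
    d = np.asarray(abs_diff, dtype=float)
    if params.opacity_form == "printed":
        mid = d / abs(params.t_max - params.t_min)
    else:
        mid = (d - params.t_min) / (params.t_max - params.t_min)
    a = np.where(d < params.t_min, 0.0, np.where(d < params.t_max, mid, 1.0))
    return np.clip(a, 0.0, 1.0)


def opacity(intensity_difference: float, params: RadialSearchParams) -> float:
    """Opacity of one search step given the intensity difference
    ``I(x) - I(x_ij)`` (sign is ignored); piecewise linear in [0, 1]."""
    return float(_opacity_array(abs(float(intensity_difference)), params))


def _gamma_volume(values: np.ndarray, target: IntensityTargetRange) -> np.ndarray:
    """gamma at every voxel: 1 iff all six neighbours lie in the target
    range; 0 on the grid boundary (missing neighbours fail the test)."""
    inr = (values >= target.t_dark) & (values <= target.t_bright)
    g = np.zeros(values.shape, dtype=bool)
    if min(values.shape) < 3:
        return g
    c = np.s_[1:-1]
    g[c, c, c] = (
        inr[2:, c, c] & inr[:-2, c, c]
        & inr[c, 2:, c] & inr[c, :-2, c]
        & inr[c, c, 2:] & inr[c, c, :-2]
    )
    return g


def gamma_mask(volume: Volume3D, point, target: IntensityTargetRange) -> int:
    """Target-range indicator at one voxel: 1 iff every six-neighbour
    intensity satisfies ``t_dark <= I <= t_bright`` (inclusive); voxels
    on the grid boundary return 0."""
    p = np.asarray(point, dtype=int)
    shape = volume.values.shape
    if np.any(p <= 0) or np.any(p >= np.asarray(shape) - 1):
        log.debug("gamma_mask: point %s on grid boundary -> 0", tuple(p))
        return 0
    vals = volume.values
    for axis in range(3):
        for d in (-1, 1):
            q = p.copy()
            q[axis] += d
            v = vals[tuple(q)]
            if not (target.t_dark <= v <= target.t_bright):
                return 0
    return 1


def _gradient_volume(values: np.ndarray, spacing) -> np.ndarray:
    """Central-difference gradient in H.U./mm; the whole vector is zero
    wherever any of the six neighbours falls outside the grid."""
    g = np.zeros((3,) + values.shape)
    if min(values.shape) < 3:
        return g
    c = np.s_[1:-1]
    g[0][c, :, :] = (values[2:, :, :] - values[:-2, :, :]) / (2.0 * spacing[0])
    g[1][:, c, :] = (values[:, 2:, :] - values[:, :-2, :]) / (2.0 * spacing[1])
    g[2][:, :, c] = (values[:, :, 2:] - values[:, :, :-2]) / (2.0 * spacing[2])
    shell = np.zeros(values.shape, dtype=bool)
    shell[c, c, c] = True
    g *= shell
    return g


# ---------------------------------------------------------------------------
# tensor accumulation


def radial_tensor_field(
    volume: Volume3D,
    points: np.ndarray,
    params: RadialSearchParams,
    target: IntensityTargetRange | None = None,
) -> np.ndarray:
    """RST (``target is None``) or ITRST tensors at ``points``.

    ``points`` is an ``(N, 3)`` integer array of voxel indices; the
    result is ``(N, 3, 3)`` of non-symmetrised tensors.  The volume must
    be isotropic (preprocess first).  Positions along a ray are snapped
    to the nearest voxel; rays leaving the grid terminate silently, and
    gradients on the grid boundary contribute nothing.
    """
    if not volume.is_isotropic:
        raise ValueError("radial tensors require an isotropic volume; resample first")
    values = np.asarray(volume.values, dtype=np.float64)
    shape = np.asarray(values.shape)
    h = volume.spacing[0]
    step = params.step if params.step is not None else h
    n_steps = int(np.floor(params.t_len / step + 1e-9))
    if n_steps < 1:
        raise ValueError("t_len smaller than one step")

    points = np.atleast_2d(np.asarray(points, dtype=np.int64))
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be an (N, 3) index array")
    if np.any(points < 0) or np.any(points >= shape):
        raise ValueError("points must lie inside the grid")
    n = len(points)

    grad = _gradient_volume(values, volume.spacing)
    gflat = grad.reshape(3, -1)
    vflat = values.ravel()
    itrst = target is not None
    if itrst:
        gam_flat = _gamma_volume(values, target).ravel().astype(np.float64)

    dirs = sample_directions(params.n_directions)
    i0 = values[points[:, 0], points[:, 1], points[:, 2]]
    tensors = np.zeros((n, 3, 3))
    thr = 1.0 - params.beta_tolerance

    for r in dirs:
        active = np.ones(n, dtype=bool)
        beta = np.zeros(n)
        for j in range(1, n_steps + 1):
            if not active.any():
                break
            off = np.rint(j * step * r / h).astype(np.int64)
            pos = points + off
            inb = np.all((pos >= 0) & (pos < shape), axis=1)
            active = active & inb  # rays leaving the grid terminate
            if not active.any():
                break
            flat = np.ravel_multi_index(pos[active].T, values.shape)
            alpha = _opacity_array(np.abs(i0[active] - vflat[flat]), params)
            if itrst:
                gam = gam_flat[flat]
                w = alpha * gam
            else:
                w = alpha
            # outer product r g^T accumulated per point: T[a, b] += w r[a] g[b]
            g = gflat[:, flat]  # (3, m)
            contrib = (w * g).T  # (m, 3)
            tensors[active] += r[None, :, None] * contrib[:, None, :]
            if itrst:
                if params.beta_mode == "product":
                    beta[active] += w
                else:  # literal printed accumulator max(sum alpha, gamma)
                    beta[active] = np.maximum(beta[active] + alpha, gam)
            else:
                beta[active] += alpha
            active = active & (beta < thr)
    return tensors


def compute_rst(
    volume: Volume3D, point, params: RadialSearchParams
) -> np.ndarray:
    """Radial structure tensor (3x3, non-symmetrised) at one voxel."""
    return radial_tensor_field(volume, np.asarray(point)[None, :], params)[0]


def compute_itrst(
    volume: Volume3D,
    point,
    params: RadialSearchParams,
    target: IntensityTargetRange,
) -> np.ndarray:
    """Intensity-targeted RST (3x3, non-symmetrised) at one voxel."""
    return radial_tensor_field(volume, np.asarray(point)[None, :], params, target)[0]


# ---------------------------------------------------------------------------
# eigenvalues and blob measure


def eigenvalues_by_magnitude(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of the symmetrised ``T + T^T`` ordered by decreasing
    absolute value; magnitude ties put the more negative value first."""
    t = np.asarray(tensor, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("tensor has non-finite entries")
    vals = np.linalg.eigvalsh(t + t.T)
    order = np.lexsort((vals, -np.abs(vals)))
    return vals[order]


def blob_measure(eigs: np.ndarray) -> float:
    """Blob-likeness |l2|^2 / |l0| when all eigenvalues are strictly
    negative, 0 otherwise (eigs ordered by decreasing magnitude)."""
    l0, l1, l2 = (float(e) for e in eigs)
    if l0 < 0 and l1 < 0 and l2 < 0:
        return abs(l2) * abs(l2) / abs(l0)
    return 0.0


def _blob_from_symmetric_eigs(vals: np.ndarray) -> np.ndarray:
    """Vectorised blob measure from ascending eigvalsh output (N, 3)."""
    all_neg = vals[:, 2] < 0  # largest value negative -> all negative
    out = np.zeros(len(vals))
    l0 = np.abs(vals[:, 0])  # most negative = largest magnitude when all < 0
    l2 = np.abs(vals[:, 2])
    np.divide(l2 * l2, l0, out=out, where=all_neg & (l0 > 0))
    return np.where(all_neg, out, 0.0)


# ---------------------------------------------------------------------------
# Hessian filter


def hessian_tensor_field(
    volume: Volume3D, scale: float, points: np.ndarray | None = None
) -> np.ndarray:
    """Gaussian-second-derivative Hessians (units H.U./mm^2) at ``points``
    (all voxels when None); returns (N, 3, 3) or (X, Y, Z, 3, 3)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    values = np.asarray(volume.values, dtype=np.float64)
    sp = np.asarray(volume.spacing)
    sigma_vox = scale / sp
    comps = {}
    for a in range(3):
        for b in range(a, 3):
            d = values
            for axis in range(3):
                if axis == a == b:
                    # two first-derivative passes at sigma/sqrt(2): their
                    # odd kernels sum exactly to zero, so a constant
                    # volume maps to exactly zero (a single order-2
                    # kernel leaks a small DC term when truncated)
                    s = sigma_vox[axis] / np.sqrt(2.0)
                    d = ndimage.gaussian_filter1d(d, s, axis=axis, order=1,
                                                  mode="nearest")
                    d = ndimage.gaussian_filter1d(d, s, axis=axis, order=1,
                                                  mode="nearest")
                else:
                    order = 1 if axis in (a, b) else 0
                    d = ndimage.gaussian_filter1d(d, sigma_vox[axis], axis=axis,
                                                  order=order, mode="nearest")
            comps[(a, b)] = d / (sp[a] * sp[b])
    if points is None:
        out = np.empty(values.shape + (3, 3))
        for (a, b), d in comps.items():
            out[..., a, b] = d
            out[..., b, a] = d
        return out
    points = np.atleast_2d(np.asarray(points, dtype=np.int64))
    out = np.empty((len(points), 3, 3))
    ix, iy, iz = points[:, 0], points[:, 1], points[:, 2]
    for (a, b), d in comps.items():
        out[:, a, b] = d[ix, iy, iz]
        out[:, b, a] = out[:, a, b]
    return out


def hessian_blob_filter(
    volume: Volume3D, scale: float, mask: np.ndarray | None = None
) -> Volume3D:
    """Bright-blob response from Hessian eigenvalues at one scale.

    The sign convention is flipped (bright blobs have negative second
    derivatives, and the blob measure expects negative eigenvalues for a
    bright blob as seen by the radial tensor, whose eigenvalues are
    negative at intensity maxima); the response is normalised by
    ``scale^2`` to compensate the derivative amplitude loss of Gaussian
    smoothing.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if mask is None:
        points = None
        hes = hessian_tensor_field(volume, scale).reshape(-1, 3, 3)
    else:
        points = np.argwhere(mask)
        hes = hessian_tensor_field(volume, scale, points)
    vals = np.linalg.eigvalsh(hes)
    resp = _blob_from_symmetric_eigs(vals) * scale * scale
    out = np.zeros(volume.values.shape)
    if points is None:
        out = resp.reshape(volume.values.shape)
    else:
        out[points[:, 0], points[:, 1], points[:, 2]] = resp
    return volume.like(out)


# ---------------------------------------------------------------------------
# full-volume response


def filter_volume(
    volume: Volume3D,
    mode: str,
    params: RadialSearchParams | None = None,
    target: IntensityTargetRange | None = None,
    mask: np.ndarray | None = None,
    hessian_scale: float = 3.0,
    chunk: int = 200_000,
) -> Volume3D:
    """Blob-response volume for mode "rst", "itrst" or "hessian".

    Voxels on the one-voxel grid border (where no gradient can be
    formed) get response 0; an optional boolean ``mask`` restricts the
    computation for speed, everything outside responding 0.
    """
    if mode == "hessian":
        return hessian_blob_filter(volume, hessian_scale, mask)
    if mode not in ("rst", "itrst"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if params is None:
        params = RadialSearchParams()
    if mode == "itrst" and target is None:
        target = IntensityTargetRange()

    interior = np.zeros(volume.values.shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    if mask is not None:
        interior &= mask.astype(bool)
    points = np.argwhere(interior)
    out = np.zeros(volume.values.shape)
    tgt = target if mode == "itrst" else None
    for start in range(0, len(points), chunk):
        blk = points[start:start + chunk]
        tensors = radial_tensor_field(volume, blk, params, tgt)
        sym = tensors + tensors.transpose(0, 2, 1)
        vals = np.linalg.eigvalsh(sym)
        out[blk[:, 0], blk[:, 1], blk[:, 2]] = _blob_from_symmetric_eigs(vals)
    return volume.like(out)
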