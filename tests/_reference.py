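"""Literal triple-loop reference implementation of the radial tensor
accumulation, independent of the vectorised engine.  Conventions shared
with the engine (and stated in its contract): positions snap to the
nearest voxel (ties to even), rays leaving the grid terminate, central
differences vanish on the boundary, and the termination check runs
after the step that crosses the opacity budget."""

import numpy as np

from itrst.filters import sample_directions


def naive_radial_tensor(volume, point, params, target=None):
    vals = np.asarray(volume.values, dtype=float)
    shape = vals.shape
    h = volume.spacing[0]
    step = params.step if params.step is not None else h
    n_steps = int(np.floor(params.t_len / step + 1e-9))
    point = np.asarray(point, dtype=int)
    i0 = vals[tuple(point)]
    tensor = np.zeros((3, 3))
    thr = 1.0 - params.beta_tolerance

    def alpha_of(d):
        if d < params.t_min:
            return 0.0
        if d < params.t_max:
            return min(d / abs(params.t_max - params.t_min), 1.0)
        return 1.0

    def gamma_of(pos):
        if any(pos[k] <= 0 or pos[k] >= shape[k] - 1 for k in range(3)):
            return 0.0
        for axis in range(3):
            for dd in (-1, 1):
                q = pos.copy()
                q[axis] += dd
                v = vals[tuple(q)]
                if not (target.t_dark <= v <= target.t_bright):
                    return 0.0
        return 1.0

    def gradient_of(pos):
        g = np.zeros(3)
        if any(pos[k] <= 0 or pos[k] >= shape[k] - 1 for k in range(3)):
            return g
        for axis in range(3):
            lo = pos.copy()
            hi = pos.copy()
            lo[axis] -= 1
            hi[axis] += 1
            g[axis] = (vals[tuple(hi)] - vals[tuple(lo)]) / (2.0 * volume.spacing[axis])
        return g

    for r in sample_directions(params.n_directions):
        beta = 0.0
        for j in range(1, n_steps + 1):
            pos = point + np.rint(j * step * r / h).astype(int)
            if np.any(pos < 0) or np.any(pos >= shape):
                break
            a = alpha_of(abs(i0 - vals[tuple(pos)]))
            if target is not None:
                gam = gamma_of(pos)
                w = a * gam
            else:
                w = a
            tensor += w * np.outer(r, gradient_of(pos))
            beta += w if target is not None else a
            if beta >= thr:
                break
    return tensor
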