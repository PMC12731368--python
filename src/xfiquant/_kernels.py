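"""Numba kernels for exact voxel traversal (Siddon-type incremental marching).

Voxel (i, j, k) occupies the half-open box
[b0 + i*sp, b0 + (i+1)*sp) per axis, where b0 = origin - spacing/2, so a point
exactly on a face belongs to the voxel with the larger index.  Space outside
the grid is vacuum.  Lengths are accumulated in cm.
"""

import numba
import numpy as np

_NJIT = dict(cache=False, fastmath=False)


@numba.njit(**_NJIT)
def _clip_to_box(p0, p1, b0, b1):
    """Parametric clip of segment p0->p1 to the axis-aligned box [b0, b1]."""
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        d = p1[ax] - p0[ax]
        if d == 0.0:
            if p0[ax] < b0[ax] or p0[ax] >= b1[ax]:
                return 1.0, 0.0
        else:
            ta = (b0[ax] - p0[ax]) / d
            tb = (b1[ax] - p0[ax]) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    return t0, t1


@numba.njit(**_NJIT)
def siddon_areal(labels, density, sx, sy, sz, ox, oy, oz,
                 p0, p1, areal, lengths):
    """Accumulate per-material areal density (g/cm^2) and path length (cm).

    Returns the total in-grid chord length (cm).
    """
    nx, ny, nz = labels.shape
    sp = np.array((sx, sy, sz))
    b0 = np.array((ox - sx / 2.0, oy - sy / 2.0, oz - sz / 2.0))
    b1 = b0 + np.array((nx * sx, ny * sy, nz * sz))
    t0, t1 = _clip_to_box(p0, p1, b0, b1)
    if t1 <= t0:
        return 0.0
    d = p1 - p0
    seg_norm = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
    # entry voxel (nudge inside to be robust at the entry face)
    eps = 1e-12
    idx = np.empty(3, dtype=np.int64)
    for ax in range(3):
        x = p0[ax] + (t0 + eps) * d[ax]
        i = int(np.floor((x - b0[ax]) / sp[ax]))
        if i < 0:
            i = 0
        n_ax = labels.shape[ax]
        if i > n_ax - 1:
            i = n_ax - 1
        idx[ax] = i
    step = np.empty(3, dtype=np.int64)
    t_max = np.empty(3)
    t_delta = np.empty(3)
    for ax in range(3):
        if d[ax] > 0:
            step[ax] = 1
            boundary = b0[ax] + (idx[ax] + 1) * sp[ax]
            t_max[ax] = (boundary - p0[ax]) / d[ax]
            t_delta[ax] = sp[ax] / d[ax]
        elif d[ax] < 0:
            step[ax] = -1
            boundary = b0[ax] + idx[ax] * sp[ax]
            t_max[ax] = (boundary - p0[ax]) / d[ax]
            t_delta[ax] = -sp[ax] / d[ax]
        else:
            step[ax] = 0
            t_max[ax] = np.inf
            t_delta[ax] = np.inf
    t = t0
    total = 0.0
    while t < t1 - 1e-12:
        t_next = t1
        for ax in range(3):
            if t_max[ax] < t_next:
                t_next = t_max[ax]
        seg_cm = (t_next - t) * seg_norm * 0.1  # mm -> cm
        if seg_cm > 0.0:
            m = labels[idx[0], idx[1], idx[2]]
            areal[m] += density[idx[0], idx[1], idx[2]] * seg_cm
            lengths[m] += seg_cm
            total += seg_cm
        if t_next >= t1 - 1e-12:
            break
        for ax in range(3):
            if t_max[ax] <= t_next + 1e-15:
                idx[ax] += step[ax]
                t_max[ax] += t_delta[ax]
        if (idx[0] < 0 or idx[0] >= nx or idx[1] < 0 or idx[1] >= ny
                or idx[2] < 0 or idx[2] >= nz):
            break
        t = t_next
    return total


@numba.njit(**_NJIT)
def march_tau(labels, density, sx, sy, sz, ox, oy, oz, p0, p1, mu_rho):
    """Optical depth along p0->p1 given per-material mu/rho (cm^2/g)."""
    nx, ny, nz = labels.shape
    sp = np.array((sx, sy, sz))
    b0 = np.array((ox - sx / 2.0, oy - sy / 2.0, oz - sz / 2.0))
    b1 = b0 + np.array((nx * sx, ny * sy, nz * sz))
    t0, t1 = _clip_to_box(p0, p1, b0, b1)
    if t1 <= t0:
        return 0.0
    d = p1 - p0
    seg_norm = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
    eps = 1e-12
    idx = np.empty(3, dtype=np.int64)
    for ax in range(3):
        x = p0[ax] + (t0 + eps) * d[ax]
        i = int(np.floor((x - b0[ax]) / sp[ax]))
        if i < 0:
            i = 0
        n_ax = labels.shape[ax]
        if i > n_ax - 1:
            i = n_ax - 1
        idx[ax] = i
    step = np.empty(3, dtype=np.int64)
    t_max = np.empty(3)
    t_delta = np.empty(3)
    for ax in range(3):
        if d[ax] > 0:
            step[ax] = 1
            t_max[ax] = (b0[ax] + (idx[ax] + 1) * sp[ax] - p0[ax]) / d[ax]
            t_delta[ax] = sp[ax] / d[ax]
        elif d[ax] < 0:
            step[ax] = -1
            t_max[ax] = (b0[ax] + idx[ax] * sp[ax] - p0[ax]) / d[ax]
            t_delta[ax] = -sp[ax] / d[ax]
        else:
            step[ax] = 0
            t_max[ax] = np.inf
            t_delta[ax] = np.inf
    t = t0
    tau = 0.0
    while t < t1 - 1e-12:
        t_next = t1
        for ax in range(3):
            if t_max[ax] < t_next:
                t_next = t_max[ax]
        seg_cm = (t_next - t) * seg_norm * 0.1
        if seg_cm > 0.0:
            m = labels[idx[0], idx[1], idx[2]]
            tau += mu_rho[m] * density[idx[0], idx[1], idx[2]] * seg_cm
        if t_next >= t1 - 1e-12:
            break
        for ax in range(3):
            if t_max[ax] <= t_next + 1e-15:
                idx[ax] += step[ax]
                t_max[ax] += t_delta[ax]
        if (idx[0] < 0 or idx[0] >= nx or idx[1] < 0 or idx[1] >= ny
                or idx[2] < 0 or idx[2] >= nz):
            break
        t = t_next
    return tau


@numba.njit(**_NJIT)
def emission_tau_batch(labels, density, sx, sy, sz, ox, oy, oz,
                       starts, target, mu_rho):
    """Optical depths from each start point to a common target point."""
    n = starts.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = march_tau(labels, density, sx, sy, sz, ox, oy, oz,
                           starts[i], target, mu_rho)
    return out
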