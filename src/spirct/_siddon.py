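"""Numba kernels: exact Siddon ray tracing for the fan-beam system matrix."""

import numpy as np
from numba import njit, prange


@njit(cache=True)
def _trace_ray(sx, sy, ex, ey, n, h, half, cols, lens):
    """Intersection lengths of segment (sx,sy)->(ex,ey) with an n x n grid.

    Grid spans [-half, half]^2 with pixel size h; pixel (iy, ix) is stored as
    linear index iy * n + ix.  Returns the number of crossed pixels written
    into cols/lens.
    """
    rdx = ex - sx
    rdy = ey - sy
    ray_len = np.sqrt(rdx * rdx + rdy * rdy)
    if ray_len == 0.0:
        return 0
    t0 = 0.0
    t1 = 1.0
    if rdx != 0.0:
        ta = (-half - sx) / rdx
        tb = (half - sx) / rdx
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    elif sx <= -half or sx >= half:
        return 0
    if rdy != 0.0:
        ta = (-half - sy) / rdy
        tb = (half - sy) / rdy
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    elif sy <= -half or sy >= half:
        return 0
    if t1 <= t0:
        return 0

    px = sx + t0 * rdx
    py = sy + t0 * rdy
    ix = int(np.floor((px + half) / h))
    iy = int(np.floor((py + half) / h))
    if ix < 0:
        ix = 0
    elif ix > n - 1:
        ix = n - 1
    if iy < 0:
        iy = 0
    elif iy > n - 1:
        iy = n - 1

    big = 1.0e30
    if rdx > 0.0:
        tx = ((-half + (ix + 1) * h) - sx) / rdx
        dtx = h / rdx
        stepx = 1
    elif rdx < 0.0:
        tx = ((-half + ix * h) - sx) / rdx
        dtx = -h / rdx
        stepx = -1
    else:
        tx = big
        dtx = big
        stepx = 0
    if rdy > 0.0:
        ty = ((-half + (iy + 1) * h) - sy) / rdy
        dty = h / rdy
        stepy = 1
    elif rdy < 0.0:
        ty = ((-half + iy * h) - sy) / rdy
        dty = -h / rdy
        stepy = -1
    else:
        ty = big
        dty = big
        stepy = 0

    count = 0
    t = t0
    eps = 1e-12
    while t < t1 - eps:
        if tx <= ty:
            tn = tx
        else:
            tn = ty
        if tn > t1:
            tn = t1
        seg = (tn - t) * ray_len
        if seg > 0.0 and 0 <= ix < n and 0 <= iy < n:
            cols[count] = iy * n + ix
            lens[count] = seg
            count += 1
        if tx <= tn + eps:
            ix += stepx
            tx += dtx
        if ty <= tn + eps:
            iy += stepy
            ty += dty
        t = tn
    return count


@njit(cache=True, parallel=True)
def build_fan_matrix(cos_b, sin_b, det_u, r_si, r_sd, n, h):
    """Siddon intersection data for every (view, detector) ray.

    Source at r_si * (cos b, sin b); flat detector centered on the line
    through the isocenter at distance r_sd from the source, tangential
    direction (-sin b, cos b).  Returns padded (lens, cols, counts) arrays,
    one stripe of width 2n + 8 per ray, rays ordered (view, detector).
    """
    n_views = cos_b.size
    n_det = det_u.size
    n_rays = n_views * n_det
    max_per = 2 * n + 8
    lens = np.zeros(n_rays * max_per, dtype=np.float64)
    cols = np.zeros(n_rays * max_per, dtype=np.int32)
    counts = np.zeros(n_rays, dtype=np.int64)
    half = n * h / 2.0
    for r in prange(n_rays):
        v = r // n_det
        k = r % n_det
        cb = cos_b[v]
        sb = sin_b[v]
        sx = r_si * cb
        sy = r_si * sb
        u = det_u[k]
        ex = sx - r_sd * cb - u * sb
        ey = sy - r_sd * sb + u * cb
        off = r * max_per
        counts[r] = _trace_ray(
            sx, sy, ex, ey, n, h, half, cols[off : off + max_per], lens[off : off + max_per]
        )
    return lens, cols, counts
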