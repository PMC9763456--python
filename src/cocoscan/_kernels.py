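"""Numba kernels: Siddon cone-beam forward projection and FDK backprojection.

World frame: z is the rotation axis, origin at the rotation centre.  The
source sits at ``dsc * (cos b, sin b, 0)``; the flat detector is centred on
the source->centre ray at distance ``dsd`` from the source, with u along
``(-sin b, cos b, 0)`` and v along +z.  Detector arrays are ``[row, col]``
with row 0 at the top (largest v).
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

_EPS = 1e-9


@njit(cache=True)
def _ray_integral(vol, vox, xmin, ymin, zmin, sx, sy, sz, px, py, pz):
    """Exact voxel-intersection-length line integral from S to P (Siddon)."""
    nz, ny, nx = vol.shape
    dx = px - sx
    dy = py - sy
    dz = pz - sz
    length = np.sqrt(dx * dx + dy * dy + dz * dz)
    if length < _EPS:
        return 0.0

    tmin = 0.0
    tmax = 1.0
    # slab clipping against the grid bounding box
    for axis in range(3):
        if axis == 0:
            d = dx
            s0 = sx
            lo = xmin
            hi = xmin + nx * vox
        elif axis == 1:
            d = dy
            s0 = sy
            lo = ymin
            hi = ymin + ny * vox
        else:
            d = dz
            s0 = sz
            lo = zmin
            hi = zmin + nz * vox
        if abs(d) < _EPS:
            if s0 <= lo or s0 >= hi:
                return 0.0
        else:
            t0 = (lo - s0) / d
            t1 = (hi - s0) / d
            if t0 > t1:
                t0, t1 = t1, t0
            if t0 > tmin:
                tmin = t0
            if t1 < tmax:
                tmax = t1
    if tmax <= tmin:
        return 0.0

    # entry voxel (at a point just inside)
    tm = tmin + 1e-7 * (tmax - tmin)
    ix = int((sx + tm * dx - xmin) / vox)
    iy = int((sy + tm * dy - ymin) / vox)
    iz = int((sz + tm * dz - zmin) / vox)
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1

    # parametric distance to next plane crossing per axis
    big = 1e30
    if abs(dx) > _EPS:
        dtx = vox / abs(dx)
        nxt = xmin + (ix + (1 if dx > 0 else 0)) * vox
        tx = (nxt - sx) / dx
        stepx = 1 if dx > 0 else -1
    else:
        dtx = big
        tx = big
        stepx = 0
    if abs(dy) > _EPS:
        dty = vox / abs(dy)
        nyt = ymin + (iy + (1 if dy > 0 else 0)) * vox
        ty = (nyt - sy) / dy
        stepy = 1 if dy > 0 else -1
    else:
        dty = big
        ty = big
        stepy = 0
    if abs(dz) > _EPS:
        dtz = vox / abs(dz)
        nzt = zmin + (iz + (1 if dz > 0 else 0)) * vox
        tz = (nzt - sz) / dz
        stepz = 1 if dz > 0 else -1
    else:
        dtz = big
        tz = big
        stepz = 0

    acc = 0.0
    t = tmin
    while t < tmax - 1e-12:
        tnext = tx
        axis = 0
        if ty < tnext:
            tnext = ty
            axis = 1
        if tz < tnext:
            tnext = tz
            axis = 2
        if tnext > tmax:
            tnext = tmax
            axis = -1
        acc += vol[iz, iy, ix] * (tnext - t) * length
        t = tnext
        if axis == 0:
            ix += stepx
            tx += dtx
            if ix < 0 or ix >= nx:
                break
        elif axis == 1:
            iy += stepy
            ty += dty
            if iy < 0 or iy >= ny:
                break
        elif axis == 2:
            iz += stepz
            tz += dtz
            if iz < 0 or iz >= nz:
                break
        else:
            break
    return acc


@njit(cache=True, parallel=True)
def forward_project_kernel(
    vol,
    vox,
    angles_rad,
    dsc,
    dsd,
    pitch_u,
    pitch_v,
    rows,
    cols,
):
    """Line integrals for every (angle, detector pixel). Returns
    ``(n_angles, rows, cols)`` in attenuation-length units."""
    nz, ny, nx = vol.shape
    xmin = -nx * vox / 2.0
    ymin = -ny * vox / 2.0
    zmin = -nz * vox / 2.0
    n_angles = angles_rad.shape[0]
    out = np.zeros((n_angles, rows, cols))
    for ia in prange(n_angles):
        b = angles_rad[ia]
        cb = np.cos(b)
        sb = np.sin(b)
        sx = dsc * cb
        sy = dsc * sb
        sz = 0.0
        # detector centre
        dcx = (dsc - dsd) * cb
        dcy = (dsc - dsd) * sb
        # u axis
        ux = -sb
        uy = cb
        for j in range(rows):
            v = ((rows - 1) / 2.0 - j) * pitch_v
            for i in range(cols):
                u = (i - (cols - 1) / 2.0) * pitch_u
                px = dcx + u * ux
                py = dcy + u * uy
                pz = v
                out[ia, j, i] = _ray_integral(
                    vol, vox, xmin, ymin, zmin, sx, sy, sz, px, py, pz
                )
    return out


@njit(cache=True, parallel=True)
def fdk_backproject_kernel(
    filtered,
    angles_rad,
    dsc,
    du_iso,
    dv_iso,
    vox,
    nz,
    ny,
    nx,
):
    """Voxel-driven distance-weighted backprojection.

    ``filtered`` is the cosine-weighted, ramp-filtered projection stack
    resampled conceptually at the isocentre scale (sample spacings
    ``du_iso``/``dv_iso``).  The total scaling ``delta_beta / 2`` is applied
    by the caller.
    """
    n_angles, rows, cols = filtered.shape
    vol = np.zeros((nz, ny, nx))
    for k in prange(nz):
        z = (k - (nz - 1) / 2.0) * vox
        for ia in range(n_angles):
            b = angles_rad[ia]
            cb = np.cos(b)
            sb = np.sin(b)
            for j in range(ny):
                y = (j - (ny - 1) / 2.0) * vox
                for i in range(nx):
                    x = (i - (nx - 1) / 2.0) * vox
                    U = dsc - (x * cb + y * sb)
                    if U < 1e-6:
                        continue
                    ratio = dsc / U
                    up = (-x * sb + y * cb) * ratio
                    vp = z * ratio
                    cf = up / du_iso + (cols - 1) / 2.0
                    rf = (rows - 1) / 2.0 - vp / dv_iso
                    c0 = int(np.floor(cf))
                    r0 = int(np.floor(rf))
                    if c0 < 0 or c0 >= cols - 1 or r0 < 0 or r0 >= rows - 1:
                        continue
                    fc = cf - c0
                    fr = rf - r0
                    val = (
                        filtered[ia, r0, c0] * (1 - fr) * (1 - fc)
                        + filtered[ia, r0, c0 + 1] * (1 - fr) * fc
                        + filtered[ia, r0 + 1, c0] * fr * (1 - fc)
                        + filtered[ia, r0 + 1, c0 + 1] * fr * fc
                    )
                    vol[k, j, i] += ratio * ratio * val
    return vol
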