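"""Scalar hot-path kernels for pose sweeps (numba-accelerated when available).

The logic mirrors the vectorized predicates in ``collision``: bounding-sphere
cull, mutual plane-straddle rejection, then exact edge-through-triangle
crossing tests, with early exit on the first crossing pair. fastmath stays
off so results are bit-reproducible and mirror-symmetric.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is in the supported env
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


_EPS = 1e-12


@njit(cache=True)
def _seg_tri_cross(p0, p1, a, b, c) -> bool:
    e1x = b[0] - a[0]; e1y = b[1] - a[1]; e1z = b[2] - a[2]
    e2x = c[0] - a[0]; e2y = c[1] - a[1]; e2z = c[2] - a[2]
    nx = e1y * e2z - e1z * e2y
    ny = e1z * e2x - e1x * e2z
    nz = e1x * e2y - e1y * e2x
    dx = p1[0] - p0[0]; dy = p1[1] - p0[1]; dz = p1[2] - p0[2]
    den = nx * dx + ny * dy + nz * dz
    if abs(den) <= _EPS:
        return False
    t = (nx * (a[0] - p0[0]) + ny * (a[1] - p0[1]) + nz * (a[2] - p0[2])) / den
    if t <= _EPS or t >= 1.0 - _EPS:
        return False
    xx = p0[0] + t * dx - a[0]
    xy = p0[1] + t * dy - a[1]
    xz = p0[2] + t * dz - a[2]
    d00 = e2x * e2x + e2y * e2y + e2z * e2z
    d01 = e2x * e1x + e2y * e1y + e2z * e1z
    d11 = e1x * e1x + e1y * e1y + e1z * e1z
    d02 = e2x * xx + e2y * xy + e2z * xz
    d12 = e1x * xx + e1y * xy + e1z * xz
    det = d00 * d11 - d01 * d01
    if abs(det) < _EPS:
        det = 1.0
    u = (d11 * d02 - d01 * d12) / det
    v = (d00 * d12 - d01 * d02) / det
    return u > _EPS and v > _EPS and (u + v) < 1.0 - _EPS


@njit(cache=True)
def _tris_cross(ta, tb) -> bool:
    for i in range(3):
        j = (i + 1) % 3
        if _seg_tri_cross(ta[i], ta[j], tb[0], tb[1], tb[2]):
            return True
        if _seg_tri_cross(tb[i], tb[j], ta[0], ta[1], ta[2]):
            return True
    return False


@njit(cache=True)
def sweep_pairs_cross(tri_m, im, stri, scent, snorm, rsum2) -> bool:
    """True iff any pre-culled (moving, static) triangle pair crosses.

    tri_m: posed moving triangles (m, 3, 3); im: moving index per pair;
    stri/scent/snorm/rsum2: per-pair static triangle data.
    """
    for k in range(im.shape[0]):
        i = im[k]
        cmx = (tri_m[i, 0, 0] + tri_m[i, 1, 0] + tri_m[i, 2, 0]) / 3.0
        cmy = (tri_m[i, 0, 1] + tri_m[i, 1, 1] + tri_m[i, 2, 1]) / 3.0
        cmz = (tri_m[i, 0, 2] + tri_m[i, 1, 2] + tri_m[i, 2, 2]) / 3.0
        ddx = cmx - scent[k, 0]
        ddy = cmy - scent[k, 1]
        ddz = cmz - scent[k, 2]
        if ddx * ddx + ddy * ddy + ddz * ddz > rsum2[k]:
            continue
        # moving triangle fully on one side of the static plane?
        pos = 0
        neg = 0
        for v in range(3):
            d = (
                (tri_m[i, v, 0] - stri[k, 0, 0]) * snorm[k, 0]
                + (tri_m[i, v, 1] - stri[k, 0, 1]) * snorm[k, 1]
                + (tri_m[i, v, 2] - stri[k, 0, 2]) * snorm[k, 2]
            )
            if d > _EPS:
                pos += 1
            elif d < -_EPS:
                neg += 1
        if pos == 3 or neg == 3:
            continue
        # static triangle fully on one side of the moving plane?
        e1x = tri_m[i, 1, 0] - tri_m[i, 0, 0]
        e1y = tri_m[i, 1, 1] - tri_m[i, 0, 1]
        e1z = tri_m[i, 1, 2] - tri_m[i, 0, 2]
        e2x = tri_m[i, 2, 0] - tri_m[i, 0, 0]
        e2y = tri_m[i, 2, 1] - tri_m[i, 0, 1]
        e2z = tri_m[i, 2, 2] - tri_m[i, 0, 2]
        nx = e1y * e2z - e1z * e2y
        ny = e1z * e2x - e1x * e2z
        nz = e1x * e2y - e1y * e2x
        pos = 0
        neg = 0
        for v in range(3):
            d = (
                (stri[k, v, 0] - tri_m[i, 0, 0]) * nx
                + (stri[k, v, 1] - tri_m[i, 0, 1]) * ny
                + (stri[k, v, 2] - tri_m[i, 0, 2]) * nz
            )
            if d > _EPS:
                pos += 1
            elif d < -_EPS:
                neg += 1
        if pos == 3 or neg == 3:
            continue
        if _tris_cross(tri_m[i], stri[k]):
            return True
    return False
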