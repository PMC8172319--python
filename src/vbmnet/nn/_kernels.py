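"""Numba-compiled inner loops for 3-D convolution and max pooling.

Direct-loop kernels keep the working set (one padded sample plus one output
map) inside the cache, which on a single CPU core is substantially faster
than any im2col/GEMM formulation at the small channel counts this network
uses.  All kernels are float32 and layout ``(N, C, D, H, W)``.

``parallel=True`` uses however many threads numba is given; with a single
thread the ``prange`` loops simply run serially.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

F32 = np.float32


@njit(fastmath=True, parallel=True, cache=True)
def conv3d_fwd(xp, w, b):
    """Valid 3x3x3 correlation of a padded input.

    xp: (N, C, D+2, H+2, W+2); w: (C, 3, 3, 3, F); b: (F,).
    Returns (N, F, D, H, W).
    """
    n_batch, n_in, dp, hp, wp = xp.shape
    d, h, wdim = dp - 2, hp - 2, wp - 2
    n_out = b.shape[0]
    out = np.empty((n_batch, n_out, d, h, wdim), F32)
    for n in prange(n_batch):
        acc = np.empty(wdim, F32)  # one output row accumulated in cache
        for f in range(n_out):
            for z in range(d):
                for y in range(h):
                    for x in range(wdim):
                        acc[x] = b[f]
                    for c in range(n_in):
                        for dz in range(3):
                            for dy in range(3):
                                row = xp[n, c, z + dz, y + dy]
                                w0 = w[c, dz, dy, 0, f]
                                w1 = w[c, dz, dy, 1, f]
                                w2 = w[c, dz, dy, 2, f]
                                for x in range(wdim):
                                    acc[x] += w0 * row[x] + w1 * row[x + 1] + w2 * row[x + 2]
                    for x in range(wdim):
                        out[n, f, z, y, x] = acc[x]
    return out


@njit(fastmath=True, parallel=True, cache=True)
def conv3d_wgrad(xp, gout):
    """Kernel gradient: xp (N, C, D+2, H+2, W+2), gout (N, F, D, H, W)."""
    n_batch, n_in, dp, hp, wp = xp.shape
    d, h, wdim = dp - 2, hp - 2, wp - 2
    n_out = gout.shape[1]
    wg = np.zeros((n_in, 3, 3, 3, n_out), F32)
    for c in prange(n_in):
        for n in range(n_batch):
            for f in range(n_out):
                g = gout[n, f]
                for dz in range(3):
                    for dy in range(3):
                        # the three x-taps share every row load
                        a0 = F32(0.0)
                        a1 = F32(0.0)
                        a2 = F32(0.0)
                        for z in range(d):
                            for y in range(h):
                                row = xp[n, c, z + dz, y + dy]
                                grow = g[z, y]
                                for x in range(wdim):
                                    gv = grow[x]
                                    a0 += gv * row[x]
                                    a1 += gv * row[x + 1]
                                    a2 += gv * row[x + 2]
                        wg[c, dz, dy, 0, f] += a0
                        wg[c, dz, dy, 1, f] += a1
                        wg[c, dz, dy, 2, f] += a2
    return wg


@njit(fastmath=True, parallel=True, cache=True)
def maxpool3d_fwd(x):
    """Window 3, stride 2, pad 1 max pool; returns (out, argmax offsets).

    The argmax offset is the flat index dz*9 + dy*3 + dx (0..26) of the
    winning position inside the (conceptually padded) window; ties resolve to
    the first offset, matching a flat argmax over the window.
    """
    n_batch, n_ch, d, h, wdim = x.shape
    do, ho, wo = (d - 1) // 2 + 1, (h - 1) // 2 + 1, (wdim - 1) // 2 + 1
    out = np.empty((n_batch, n_ch, do, ho, wo), F32)
    idx = np.empty((n_batch, n_ch, do, ho, wo), np.int8)
    for n in prange(n_batch):
        for c in range(n_ch):
            for zo in range(do):
                for yo in range(ho):
                    for xo in range(wo):
                        best = F32(-np.inf)
                        bi = 0
                        for dz in range(3):
                            z = 2 * zo + dz - 1
                            if z < 0 or z >= d:
                                continue
                            for dy in range(3):
                                y = 2 * yo + dy - 1
                                if y < 0 or y >= h:
                                    continue
                                for dx in range(3):
                                    xx = 2 * xo + dx - 1
                                    if xx < 0 or xx >= wdim:
                                        continue
                                    v = x[n, c, z, y, xx]
                                    if v > best:
                                        best = v
                                        bi = dz * 9 + dy * 3 + dx
                        out[n, c, zo, yo, xo] = best
                        idx[n, c, zo, yo, xo] = bi
    return out, idx


@njit(fastmath=True, parallel=True, cache=True)
def maxpool3d_bwd(idx, gout, d, h, wdim):
    """Scatter each pooled gradient back to its argmax voxel."""
    n_batch, n_ch, do, ho, wo = gout.shape
    gin = np.zeros((n_batch, n_ch, d, h, wdim), F32)
    for n in prange(n_batch):
        for c in range(n_ch):
            for zo in range(do):
                for yo in range(ho):
                    for xo in range(wo):
                        o = idx[n, c, zo, yo, xo]
                        dz = o // 9
                        rem = o % 9
                        z = 2 * zo + dz - 1
                        y = 2 * yo + rem // 3 - 1
                        xx = 2 * xo + rem % 3 - 1
                        gin[n, c, z, y, xx] += gout[n, c, zo, yo, xo]
    return gin
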