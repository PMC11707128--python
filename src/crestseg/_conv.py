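"""JIT-compiled 3x3x3 convolution kernels for the NumPy U-Net.

Direct-loop numba kernels ordered so the innermost z runs over contiguous
rows and the padded input rows for one (i, j) site stay cache-hot across all
output channels; they avoid the large im2col window copies a pure-NumPy
implementation needs, which is what keeps whole-volume training steps at
interactive speed on one CPU core. A NumPy fallback is provided in ``unet``
for environments without numba.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard speedup, soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def conv3d_forward(xp, w, b, y):
    """y[o] = sum_c xp[c] * w[o,c] + b[o]; xp is the zero-padded input."""
    n_out, n_in = w.shape[0], w.shape[1]
    nx, ny, nz = y.shape[1], y.shape[2], y.shape[3]
    for i in range(nx):
        for j in range(ny):
            for o in range(n_out):
                acc = y[o, i, j]
                for k in range(nz):
                    acc[k] = b[o]
                for c in range(n_in):
                    for di in range(3):
                        for dj in range(3):
                            row = xp[c, i + di, j + dj]
                            w0 = w[o, c, di, dj, 0]
                            w1 = w[o, c, di, dj, 1]
                            w2 = w[o, c, di, dj, 2]
                            for k in range(nz):
                                acc[k] += (w0 * row[k] + w1 * row[k + 1]
                                           + w2 * row[k + 2])


@njit(cache=True, fastmath=True)
def conv3d_backward_dw(xp, g, dw, db):
    """Accumulate dW[o,c,...] += sum_xyz g[o] * xp[c] windows; db += sum g."""
    n_out, n_in = dw.shape[0], dw.shape[1]
    nx, ny, nz = g.shape[1], g.shape[2], g.shape[3]
    for i in range(nx):
        for j in range(ny):
            for o in range(n_out):
                row_g = g[o, i, j]
                s = 0.0
                for k in range(nz):
                    s += row_g[k]
                db[o] += s
                for c in range(n_in):
                    for di in range(3):
                        for dj in range(3):
                            row_x = xp[c, i + di, j + dj]
                            a0 = 0.0
                            a1 = 0.0
                            a2 = 0.0
                            for k in range(nz):
                                gk = row_g[k]
                                a0 += gk * row_x[k]
                                a1 += gk * row_x[k + 1]
                                a2 += gk * row_x[k + 2]
                            dw[o, c, di, dj, 0] += a0
                            dw[o, c, di, dj, 1] += a1
                            dw[o, c, di, dj, 2] += a2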