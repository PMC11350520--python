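"""Bandwidth-critical kernels for the NumPy network engine.

Each operation exists twice: a numba-jitted single-pass version (used when
numba imports cleanly) and a pure-NumPy fallback with identical semantics.
The convolution GEMMs themselves stay in BLAS; these kernels only move data
(padding, im2col/col2im, 2x2 max pooling with stored argmax).

Layout is NCHW throughout.  The im2col buffer has logical shape
``(batch, c_in, 9, h, w)`` with kernel tap ``j`` meaning spatial offset
``(j // 3 - 1, j % 3 - 1)``.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by the whole test suite
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(fastmath=True)
def _im2col_nb(x, cols):  # pragma: no cover - compiled
    b, c, h, w = x.shape
    for bi in range(b):
        for ci in range(c):
            for j in range(9):
                dy = j // 3 - 1
                dx = j % 3 - 1
                for yy in range(h):
                    sy = yy + dy
                    if sy < 0 or sy >= h:
                        for xx in range(w):
                            cols[bi, ci, j, yy, xx] = 0.0
                    elif dx == -1:
                        cols[bi, ci, j, yy, 0] = 0.0
                        for xx in range(1, w):
                            cols[bi, ci, j, yy, xx] = x[bi, ci, sy, xx - 1]
                    elif dx == 0:
                        for xx in range(w):
                            cols[bi, ci, j, yy, xx] = x[bi, ci, sy, xx]
                    else:
                        for xx in range(w - 1):
                            cols[bi, ci, j, yy, xx] = x[bi, ci, sy, xx + 1]
                        cols[bi, ci, j, yy, w - 1] = 0.0


@njit(fastmath=True)
def _col2im_nb(dcols, dx):  # pragma: no cover - compiled
    b, c, _, h, w = dcols.shape
    for bi in range(b):
        for ci in range(c):
            for j in range(9):
                oy = j // 3 - 1
                ox = j % 3 - 1
                y0 = -oy if oy < 0 else 0
                y1 = h - oy if oy > 0 else h
                x0 = -ox if ox < 0 else 0
                x1 = w - ox if ox > 0 else w
                for yy in range(y0, y1):
                    sy = yy + oy
                    for xx in range(x0, x1):
                        dx[bi, ci, sy, xx + ox] += dcols[bi, ci, j, yy, xx]


@njit(fastmath=True)
def _pool_fwd_nb(x, y, idx):  # pragma: no cover - compiled
    b, c, h2, w2 = y.shape
    for bi in range(b):
        for ci in range(c):
            for yy in range(h2):
                for xx in range(w2):
                    y0, x0 = 2 * yy, 2 * xx
                    best = x[bi, ci, y0, x0]
                    bj = 0
                    v = x[bi, ci, y0, x0 + 1]
                    if v > best:
                        best, bj = v, 1
                    v = x[bi, ci, y0 + 1, x0]
                    if v > best:
                        best, bj = v, 2
                    v = x[bi, ci, y0 + 1, x0 + 1]
                    if v > best:
                        best, bj = v, 3
                    y[bi, ci, yy, xx] = best
                    idx[bi, ci, yy, xx] = bj


@njit(fastmath=True)
def _pool_bwd_nb(dy, idx, dx):  # pragma: no cover - compiled
    b, c, h2, w2 = dy.shape
    for bi in range(b):
        for ci in range(c):
            for yy in range(h2):
                for xx in range(w2):
                    bj = idx[bi, ci, yy, xx]
                    dx[bi, ci, 2 * yy + bj // 2, 2 * xx + bj % 2] += dy[bi, ci, yy, xx]


# ---------------------------------------------------------------------------
# public wrappers (numba path and NumPy fallback share these signatures)
# ---------------------------------------------------------------------------

def im2col(x: np.ndarray) -> np.ndarray:
    """(b, c, h, w) -> (b, 9c, h*w) im2col buffer for a same-padded 3x3 conv."""
    b, c, h, w = x.shape
    cols = np.empty((b, c, 9, h, w), dtype=x.dtype)
    if HAVE_NUMBA:
        _im2col_nb(x, cols)
    else:
        xp = np.zeros((b, c, h + 2, w + 2), dtype=x.dtype)
        xp[:, :, 1:-1, 1:-1] = x
        for j in range(9):
            dy, dx = divmod(j, 3)
            cols[:, :, j] = xp[:, :, dy:dy + h, dx:dx + w]
    return cols.reshape(b, 9 * c, h * w)


def col2im(dcols: np.ndarray, c: int, h: int, w: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add (b, 9c, h*w) back to (b, c, h, w)."""
    b = dcols.shape[0]
    dcols = dcols.reshape(b, c, 9, h, w)
    dx = np.zeros((b, c, h, w), dtype=dcols.dtype)
    if HAVE_NUMBA:
        _col2im_nb(dcols, dx)
    else:
        dxp = np.zeros((b, c, h + 2, w + 2), dtype=dcols.dtype)
        for j in range(9):
            dy, dx_ = divmod(j, 3)
            dxp[:, :, dy:dy + h, dx_:dx_ + w] += dcols[:, :, j]
        dx = dxp[:, :, 1:-1, 1:-1].copy()
    return dx


def pool2_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pool (floor); returns pooled values and uint8 argmax (0..3).

    Ties resolve to the first maximum in row-major window order.
    """
    b, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    y = np.empty((b, c, h2, w2), dtype=x.dtype)
    idx = np.empty((b, c, h2, w2), dtype=np.uint8)
    if HAVE_NUMBA:
        _pool_fwd_nb(x, y, idx)
    else:
        xr = x[:, :, :2 * h2, :2 * w2].reshape(b, c, h2, 2, w2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
        idx[...] = flat.argmax(axis=-1).astype(np.uint8)
        y[...] = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return y, idx


def pool2_backward(dy: np.ndarray, idx: np.ndarray,
                   in_shape: tuple[int, ...]) -> np.ndarray:
    """Route pooled gradients back to the argmax positions."""
    dx = np.zeros(in_shape, dtype=dy.dtype)
    if HAVE_NUMBA:
        _pool_bwd_nb(dy, idx, dx)
    else:
        b, c, h, w = in_shape
        h2, w2 = dy.shape[2], dy.shape[3]
        oy, ox = idx // 2, idx % 2
        bi, ci, yi, xi = np.ogrid[:b, :c, :h2, :w2]
        dx[bi, ci, 2 * yi + oy, 2 * xi + ox] = dy
    return dx
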