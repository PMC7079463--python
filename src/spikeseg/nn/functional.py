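"""Low-level convolution arithmetic on NCHW arrays.

All heavy lifting is im2col/col2im plus matrix multiplication, which keeps
forward and backward passes as single BLAS calls.  Transpose convolution is
expressed through the same three primitives with the roles of input and
output swapped (its forward pass is the data-gradient of an ordinary
convolution).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv_out_size(size: int, kernel: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - kernel) // stride + 1


def im2col(x: np.ndarray, kernel: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, Ho, Wo, C*k*k) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # N, C, Ho, Wo, k, k
    n, c, ho, wo, _, _ = win.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * kernel * kernel)
    return np.ascontiguousarray(cols)


def col2im(
    dcols: np.ndarray,
    x_shape: tuple,
    kernel: int,
    stride: int,
    pad: int,
) -> np.ndarray:
    """Scatter-add inverse of :func:`im2col`."""
    n, c, h, w = x_shape
    _, ho, wo, _ = dcols.shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, ho, wo, c, kernel, kernel).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kernel):
        for j in range(kernel):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[
                :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


def conv_forward(x, w, b, stride: int, pad: int):
    """y = conv(x, w) + b with w of shape (Cout, Cin, k, k); caches cols."""
    cout, cin, k, _ = w.shape
    cols = im2col(x, k, stride, pad)
    n, ho, wo, _ = cols.shape
    y = cols.reshape(-1, cin * k * k) @ w.reshape(cout, -1).T
    if b is not None:
        y = y + b
    return y.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2), cols


def conv_backward_data(dy, w, x_shape, stride: int, pad: int):
    """Gradient w.r.t. the convolution input (also transpose-conv forward)."""
    cout, cin, k, _ = w.shape
    n, _, ho, wo = dy.shape
    dcols = dy.transpose(0, 2, 3, 1).reshape(-1, cout) @ w.reshape(cout, -1)
    return col2im(dcols.reshape(n, ho, wo, cin * k * k), x_shape, k, stride, pad)


def conv_backward_weight(cols, dy, w_shape):
    """Gradient w.r.t. the kernel given cached im2col patches."""
    cout, cin, k, _ = w_shape
    dyr = dy.transpose(0, 2, 3, 1).reshape(-1, cout)
    dw = dyr.T @ cols.reshape(-1, cin * k * k)
    return dw.reshape(w_shape)
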