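"""Low-level numerical primitives: 3x3 same-padding convolution via im2col,
2x2 average pooling, and global average pooling, each with a matching
backward pass.  All arrays are [batch, channel, row, col], float64 unless
noted.  These are internal building blocks; the public simulation API lives
in :mod:`spikemap.snn_core`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d",
    "conv2d_backward",
    "avgpool2",
    "avgpool2_backward",
    "global_avgpool",
    "global_avgpool_backward",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """[B,C,H,W] -> [B, C*k*k, H*W] with zero same-padding (odd k)."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # windows: [B, C, H, W, k, k]
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    b, c, h, w = x.shape
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, h * w)
    return cols


def conv2d(x: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Same-padding stride-1 convolution (cross-correlation).

    x: [B,Cin,H,W]; weight: [Cout,Cin,k,k] -> [B,Cout,H,W].
    """
    b, cin, h, w = x.shape
    cout, cin_w, k, _ = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs weight {cin_w}")
    cols = _im2col(x, k)
    wmat = weight.reshape(cout, cin * k * k)
    out = np.einsum("ok,bkp->bop", wmat, cols, optimize=True)
    return out.reshape(b, cout, h, w)


def conv2d_backward(
    x: np.ndarray, weight: np.ndarray, grad_out: np.ndarray, need_dx: bool = True
) -> tuple[np.ndarray | None, np.ndarray]:
    """Gradients of conv2d. Returns (dx, dweight)."""
    b, cin, h, w = x.shape
    cout, _, k, _ = weight.shape
    cols = _im2col(x, k)  # [B, Cin*k*k, HW]
    go = grad_out.reshape(b, cout, h * w)
    dw = np.einsum("bop,bkp->ok", go, cols, optimize=True).reshape(weight.shape)
    if not need_dx:
        return None, dw
    # dx = "full" correlation of grad_out with flipped weight == conv with
    # weight transposed in channels and spatially flipped.
    w_flip = weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # [Cin,Cout,k,k]
    dx = conv2d(grad_out, np.ascontiguousarray(w_flip))
    return dx, dw


def avgpool2(x: np.ndarray) -> np.ndarray:
    """2x2 non-overlapping average pooling; H and W must be even."""
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"avgpool2 needs even spatial dims, got {h}x{w}")
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def avgpool2_backward(grad_out: np.ndarray) -> np.ndarray:
    g = np.repeat(np.repeat(grad_out, 2, axis=2), 2, axis=3)
    return g / 4.0


def global_avgpool(x: np.ndarray) -> np.ndarray:
    """[B,C,H,W] -> [B,C]."""
    return x.mean(axis=(2, 3))


def global_avgpool_backward(grad_out: np.ndarray, h: int, w: int) -> np.ndarray:
    b, c = grad_out.shape
    return np.broadcast_to(grad_out[:, :, None, None], (b, c, h, w)) / (h * w)
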