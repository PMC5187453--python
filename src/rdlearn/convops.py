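"""Low-level im2col/col2im primitives for convolution and pooling.

Data layout is NCHW.  Padding is explicit per side so that ceil-mode pooling
(pad only bottom/right) and 'same'-style convolution share one code path.
"""

from __future__ import annotations

import numpy as np

__all__ = ["out_size", "pad_input", "im2col", "col2im"]


def out_size(size: int, k: int, stride: int, pad: int, ceil_mode: bool = False) -> int:
    eff = size + pad - k
    if ceil_mode:
        return -(-eff // stride) + 1
    return eff // stride + 1


def pad_input(x: np.ndarray, pt: int, pb: int, pl: int, pr: int, value: float = 0.0):
    if pt == pb == pl == pr == 0:
        return x
    return np.pad(
        x, ((0, 0), (0, 0), (pt, pb), (pl, pr)), mode="constant", constant_values=value
    )


def im2col(
    xp: np.ndarray, kh: int, kw: int, stride: int, oh: int, ow: int
) -> np.ndarray:
    """Extract sliding windows from an already-padded input.

    Returns an array of shape (N, C, kh*kw, oh*ow).
    """
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[
                :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
            ]
    return cols.reshape(n, c, kh * kw, oh * ow)


def col2im(
    dcols: np.ndarray,
    padded_shape: tuple,
    kh: int,
    kw: int,
    stride: int,
    oh: int,
    ow: int,
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add window gradients back."""
    n, c, hp, wp = padded_shape
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[
                :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
            ] += d6[:, :, i, j]
    return dxp
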