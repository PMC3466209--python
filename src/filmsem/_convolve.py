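"""Reflective-boundary FFT convolution shared by image formation and
restoration.

With whole-sample symmetric padding and an even kernel the convolution
operator is symmetric and doubly stochastic (each row and each column sums
to one for a normalized kernel), which is what makes Richardson–Lucy flux
conservation and flat-image fixed points hold to floating precision.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .errors import DomainError


def convolve_reflect(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2D convolution with symmetric (reflective) boundary handling."""
    kh, kw = kernel.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise DomainError("kernel dimensions must be odd")
    py, px = kh // 2, kw // 2
    h, w = arr.shape
    # np.pad cannot reflect by more than the array size in one go
    padded = arr
    ry, rx = py, px
    while ry > 0 or rx > 0:
        sy = min(ry, padded.shape[0])
        sx = min(rx, padded.shape[1])
        padded = np.pad(padded, ((sy, sy), (sx, sx)), mode="symmetric")
        ry -= sy
        rx -= sx
    out = fftconvolve(padded, kernel, mode="same")
    y0 = (padded.shape[0] - h) // 2
    x0 = (padded.shape[1] - w) // 2
    return out[y0 : y0 + h, x0 : x0 + w]
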