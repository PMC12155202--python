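"""Cached-kernel FFT convolution with explicit boundary handling.

Richardson–Lucy iterations apply the same kernel (and its adjoint) many
times, so the kernel transforms are computed once per (kernel, shape,
boundary) and reused.  Three boundary rules:

- ``circular``: exact circular convolution on the unpadded shape.  The
  forward/adjoint pair is an exact transpose and total flux is conserved
  exactly (up to float round-off) for a unit-sum kernel.
- ``zero_pad``: linear convolution with the signal extended by zeros,
  restricted back to the original shape.  Also an exact transpose pair.
- ``reflect``: signal extended by mirror reflection before linear
  convolution.  The adjoint is approximated by correlation under the same
  extension (standard practice; not an exact transpose).
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

BOUNDARIES = ("reflect", "zero_pad", "circular")


class FFTConvolver:
    """Convolve/correlate arrays of a fixed shape with a fixed kernel."""

    def __init__(self, kernel: np.ndarray, shape: tuple[int, ...], boundary: str = "reflect",
                 dtype=np.float64):
        self.dtype = np.dtype(dtype)
        kernel = np.asarray(kernel, dtype=self.dtype)
        if kernel.ndim != len(shape):
            raise ValueError("kernel and data dimensionality differ")
        if boundary == "circular" and any(k > s for k, s in zip(kernel.shape, shape)):
            raise ValueError(
                f"kernel {kernel.shape} larger than volume {shape} under circular boundary"
            )
        if boundary not in BOUNDARIES:
            raise ValueError(f"unknown boundary {boundary!r}; choose from {BOUNDARIES}")
        self.shape = tuple(shape)
        self.boundary = boundary
        self.kshape = kernel.shape
        self.half = tuple(k // 2 for k in kernel.shape)

        if boundary == "circular":
            self.work_shape = self.shape
        else:
            padded = tuple(s + 2 * h for s, h in zip(shape, self.half))
            self.work_shape = tuple(sfft.next_fast_len(p, real=True) for p in padded)

        self._kf = self._kernel_fft(kernel)
        self._kf_adj = self._kernel_fft(np.flip(kernel))

    def _kernel_fft(self, kernel: np.ndarray) -> np.ndarray:
        buf = np.zeros(self.work_shape, dtype=self.dtype)
        buf[tuple(slice(0, k) for k in self.kshape)] = kernel
        # place the kernel center at the origin so output indices align with input
        buf = np.roll(buf, [-h for h in self.half], axis=tuple(range(buf.ndim)))
        return sfft.rfftn(buf)

    def _apply(self, x: np.ndarray, kf: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        mode = "reflect" if self.boundary == "reflect" else "constant"
        # reflect-pad needs half <= axis length - 1; fall back to edge for tiny axes
        if mode == "reflect" and any(h >= s for h, s in zip(self.half, x.shape)):
            mode = "edge"
        xp = np.pad(x, tuple((h, h) for h in self.half), mode=mode)
        grow = tuple((0, w - p) for w, p in zip(self.work_shape, xp.shape))
        xp = np.pad(xp, grow)
        out = sfft.irfftn(sfft.rfftn(xp) * kf, self.work_shape)
        return out[tuple(slice(h, h + s) for h, s in zip(self.half, self.shape))]

    def conv(self, x: np.ndarray) -> np.ndarray:
        """K convolved with x under the boundary rule."""
        if self.boundary == "circular":
            x = np.asarray(x, dtype=self.dtype)
            return sfft.irfftn(sfft.rfftn(x) * self._kf, self.work_shape)
        return self._apply(x, self._kf)

    def conv_adjoint(self, x: np.ndarray) -> np.ndarray:
        """Adjoint (flipped-kernel correlation) under the boundary rule."""
        if self.boundary == "circular":
            x = np.asarray(x, dtype=self.dtype)
            return sfft.irfftn(sfft.rfftn(x) * self._kf_adj, self.work_shape)
        return self._apply(x, self._kf_adj)
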