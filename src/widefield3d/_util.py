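"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def split_even(n: int, k: int) -> list[tuple[int, int]]:
    """Partition range(n) into k contiguous half-open chunks whose sizes differ by <= 1.

    Used both by the z-brick planner and by the slab-wise forward simulator so
    that the restoration model and the simulated blur share the same depth
    partition.
    """
    if not 1 <= k <= n:
        raise ValueError(f"cannot split {n} planes into {k} chunks")
    base, extra = divmod(n, k)
    bounds = [0]
    for i in range(k):
        bounds.append(bounds[-1] + base + (1 if i < extra else 0))
    return [(bounds[i], bounds[i + 1]) for i in range(k)]


def grid_position(index: int, grid_shape: tuple[int, int], pattern: str) -> tuple[int, int]:
    """Map a 0-based acquisition index to (row, col) for the given scan pattern."""
    rows, cols = grid_shape
    if not 0 <= index < rows * cols:
        raise ValueError(f"tile index {index} outside {rows}x{cols} grid")
    row, col = divmod(index, cols)
    if pattern == "serpentine" and row % 2 == 1:
        col = cols - 1 - col
    elif pattern not in ("row_major", "serpentine"):
        raise ValueError(f"unknown acquisition pattern {pattern!r}")
    return row, col


def as_odd(n: int) -> int:
    n = int(n)
    return n if n % 2 == 1 else n + 1


def centered_crop(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Crop the central block of the given shape."""
    slices = tuple(
        slice((s - t) // 2, (s - t) // 2 + t) for s, t in zip(arr.shape, shape)
    )
    return arr[slices]
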