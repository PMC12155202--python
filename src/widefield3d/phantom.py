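"""Ground-truth phantoms emulating cleared-tissue widefield acquisitions.

The generator produces what the pipeline assumes about real data: compact
bright objects ("nuclei" — spheres or ellipsoids) on a dark field, a
low-frequency background, Poisson shot noise with optional Gaussian read
noise, vignetting, and depth-variant blur.  Depth variance is applied
slab-wise with the same even z-partition the deconvolver's brick planner
uses, so the simulator and the restoration share the forward model they
claim to invert; a finer slab count probes model mismatch.

Everything is deterministic under the spec's seed; changing only the seed
changes the noise realization but not explicitly placed objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from ._util import split_even
from .io import ChannelMeta, TileSet, Volume
from .optics import OpticalConfig, generate_psf

__all__ = [
    "PhantomObject",
    "PhantomSpec",
    "render_ground_truth",
    "simulate_widefield",
    "make_tile_fixture",
    "nuclei_spec",
]


@dataclass(frozen=True)
class PhantomObject:
    """A bead/ellipsoid: center in um (z, y, x), radius in um (scalar or per-axis)."""

    center_um: tuple[float, float, float]
    radius_um: float | tuple[float, float, float]
    intensity: float = 1.0

    @property
    def radii(self) -> tuple[float, float, float]:
        r = self.radius_um
        return (r, r, r) if np.isscalar(r) else tuple(r)


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (0.8, 0.34, 0.34)
    objects: tuple[PhantomObject, ...] = ()
    background: str = "none"          # none | ramp | smooth_random
    background_amplitude: float = 0.0
    noise: str = "none"               # none | poisson | poisson_gaussian
    read_noise_sigma: float = 0.0
    vignette: float | None = None     # fractional falloff at the corner, or None
    # abrupt bright layer over the last n planes (uncleared tissue glare below
    # the imaged slab): a background step no axial blur model can explain
    glare_planes: int = 0
    glare_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background not in ("none", "ramp", "smooth_random"):
            raise ValueError(f"unknown background model {self.background!r}")
        if self.noise not in ("none", "poisson", "poisson_gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.vignette is not None and not 0.0 <= self.vignette < 1.0:
            raise ValueError("vignette falloff fraction must lie in [0, 1)")
        extent = [n * v for n, v in zip(self.shape, self.voxel_size)]
        for obj in self.objects:
            if obj.intensity <= 0:
                raise ValueError("object intensities must be positive")
            for c, r, e in zip(obj.center_um, obj.radii, extent):
                if not 0.0 <= c <= e:
                    raise ValueError(f"object center {obj.center_um} outside volume")


def nuclei_spec(
    shape: tuple[int, int, int] = (200, 256, 256),
    voxel_size: tuple[float, float, float] = (0.8, 0.34, 0.34),
    n_objects: int = 150,
    radius_range_um: tuple[float, float] = (2.0, 4.0),
    intensity: float = 500.0,
    background: str = "ramp",
    background_fraction: float = 0.2,
    noise: str = "poisson",
    seed: int = 0,
    margin_um: float = 6.0,
) -> PhantomSpec:
    """Default nuclei phantom: ~150 spheres of radius 2–4 um on a ramp
    background at 20% of the object peak, with Poisson noise."""
    rng = np.random.default_rng(seed)
    extent = [n * v for n, v in zip(shape, voxel_size)]
    objects: list[PhantomObject] = []
    placed: list[tuple[tuple[float, float, float], float]] = []
    attempts = 0
    while len(objects) < n_objects and attempts < 200 * n_objects:
        attempts += 1
        r = rng.uniform(*radius_range_um)
        margin = max(margin_um, r + 1.0)
        center = tuple(
            rng.uniform(min(margin, e / 2), max(e - margin, e / 2)) for e in extent
        )
        # nuclei are solid bodies: reject overlaps (separation > sum of radii + 2 um)
        if any(
            sum((a - b) ** 2 for a, b in zip(center, c0)) < (r + r0 + 2.0) ** 2
            for c0, r0 in placed
        ):
            continue
        placed.append((center, r))
        objects.append(PhantomObject(center_um=center, radius_um=r, intensity=intensity))
    if len(objects) < n_objects:
        warnings.warn(
            f"placed only {len(objects)}/{n_objects} non-overlapping nuclei",
            RuntimeWarning,
            stacklevel=2,
        )
    return PhantomSpec(
        shape=shape,
        voxel_size=voxel_size,
        objects=tuple(objects),
        background=background,
        background_amplitude=background_fraction * intensity,
        noise=noise,
        seed=seed,
    )


def render_ground_truth(spec: PhantomSpec, supersample: int = 3) -> Volume:
    """Noiseless, unblurred object map with antialiased sphere/ellipsoid edges.

    Voxel values are the object intensity times the sub-voxel coverage
    fraction (``supersample**3`` samples per voxel).  Warns when objects
    overlap.
    """
    data = np.zeros(spec.shape)
    occupancy = np.zeros(spec.shape, dtype=np.uint8)
    vs = np.asarray(spec.voxel_size)
    # sub-voxel sample offsets, centered so that voxel i spans [i-0.5, i+0.5)
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5
    for obj in spec.objects:
        center = np.asarray(obj.center_um) / vs  # voxel coords
        radii = np.asarray(obj.radii) / vs
        lo = np.maximum(np.floor(center - radii - 1).astype(int), 0)
        hi = np.minimum(np.ceil(center + radii + 1).astype(int) + 1, spec.shape)
        axes = [lo[d] + np.arange(hi[d] - lo[d]) for d in range(3)]
        # sub-voxel sample positions along each axis, normalized by the radius
        norm = [
            ((ax[:, None] + sub[None, :] - center[d]) / radii[d]) ** 2
            for d, ax in enumerate(axes)
        ]
        inside = (
            norm[0][:, None, None, :, None, None]
            + norm[1][None, :, None, None, :, None]
            + norm[2][None, None, :, None, None, :]
        ) <= 1.0
        coverage = inside.mean(axis=(3, 4, 5))
        block = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        data[block] += obj.intensity * coverage
        occupancy[block] += coverage > 0
    if np.any(occupancy > 1):
        warnings.warn(
            f"{int(np.sum(occupancy > 1))} voxels covered by more than one object",
            RuntimeWarning,
            stacklevel=2,
        )
    return Volume(data=data, voxel_size=spec.voxel_size,
                  channels=[ChannelMeta(em_wavelength_nm=520.0, name="phantom")])


def background_field(spec: PhantomSpec) -> np.ndarray:
    """The deterministic (seeded) low-frequency background field."""
    nz, ny, nx = spec.shape
    amp = spec.background_amplitude
    base = np.zeros(spec.shape)
    if spec.glare_planes > 0 and spec.glare_amplitude > 0:
        base[nz - spec.glare_planes:] += spec.glare_amplitude
    if spec.background == "none" or amp == 0:
        return base
    if spec.background == "ramp":
        z = np.linspace(0.0, 1.0, nz)[:, None, None]
        y = np.linspace(0.0, 1.0, ny)[None, :, None]
        x = np.linspace(0.0, 1.0, nx)[None, None, :]
        return base + amp * (0.2 + 0.8 * (0.4 * z + 0.3 * y + 0.3 * x))
    rng = np.random.default_rng(spec.seed + 1)
    from scipy.ndimage import gaussian_filter

    # smooth within each x-y plane but only weakly correlated along z:
    # thick-tissue stacks show strong plane-to-plane background variability,
    # which is exactly what defeats a naive axial blur model
    field_ = rng.standard_normal(spec.shape)
    field_ = gaussian_filter(field_, sigma=(1.0, max(2, ny / 8), max(2, nx / 8)),
                             mode="nearest")
    field_ -= field_.min()
    if field_.max() > 0:
        field_ /= field_.max()
    return base + amp * field_


def _vignette_field(spec: PhantomSpec) -> np.ndarray:
    ny, nx = spec.shape[1:]
    y = (np.arange(ny) - (ny - 1) / 2) / ((ny - 1) / 2)
    x = (np.arange(nx) - (nx - 1) / 2) / ((nx - 1) / 2)
    r2 = (y[:, None] ** 2 + x[None, :] ** 2) / 2.0  # 1 at the corner
    return 1.0 - spec.vignette * r2


def simulate_widefield(
    spec: PhantomSpec,
    cfg: OpticalConfig,
    n_depth_slabs: int = 1,
    psf_support: tuple[int, int, int] | None = None,
) -> Volume:
    """Forward-simulate an observed widefield stack from a phantom.

    The ground truth is partitioned into ``n_depth_slabs`` even z-slabs; each
    slab is convolved (zero-boundary linear convolution) with the theoretical
    PSF at its slab-center depth and the contributions are summed.  Then the
    background field is added, vignetting applied, and seeded noise drawn.
    """
    gt = render_ground_truth(spec).data
    nz = spec.shape[0]
    if n_depth_slabs > nz:
        raise ValueError("more depth slabs than z planes")
    cfg = _cfg_with_voxels(cfg, spec.voxel_size)
    observed = np.zeros_like(gt)
    for z0, z1 in split_even(nz, n_depth_slabs):
        depth = cfg.plane_depth_um(0.5 * (z0 + z1 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            kernel = generate_psf(cfg, depth, support=psf_support)
        slab = np.zeros_like(gt)
        slab[z0:z1] = gt[z0:z1]
        if not slab.any():
            continue
        observed += fftconvolve(slab, kernel, mode="same")
    np.clip(observed, 0.0, None, out=observed)

    observed = _apply_background_and_noise(spec, observed)
    return Volume(data=observed, voxel_size=spec.voxel_size,
                  channels=[ChannelMeta(em_wavelength_nm=cfg.em_wavelength_nm,
                                        name="simulated")])


def _apply_background_and_noise(spec: PhantomSpec, signal: np.ndarray) -> np.ndarray:
    out = signal + background_field(spec)
    if spec.vignette:
        out = out * _vignette_field(spec)[None, :, :]
    rng = np.random.default_rng(spec.seed)
    if spec.noise in ("poisson", "poisson_gaussian"):
        out = rng.poisson(out).astype(np.float64)
    if spec.noise == "poisson_gaussian" and spec.read_noise_sigma > 0:
        out = out + rng.normal(0.0, spec.read_noise_sigma, size=out.shape)
    np.clip(out, 0.0, None, out=out)
    return out


def _cfg_with_voxels(cfg: OpticalConfig, voxel_size) -> OpticalConfig:
    if tuple(cfg.voxel_size) != tuple(voxel_size):
        from dataclasses import replace

        cfg = replace(cfg, voxel_size=tuple(voxel_size))
    return cfg


def make_tile_fixture(
    spec: PhantomSpec,
    grid_shape: tuple[int, int],
    overlap: float,
    jitter_voxels: int,
    seed: int,
    cfg: OpticalConfig | None = None,
    n_depth_slabs: int = 1,
    pattern: str = "row_major",
) -> tuple[TileSet, dict[tuple[int, int], tuple[int, int, int]], Volume]:
    """Cut one simulated (or noiseless ground-truth) volume into overlapping
    tiles with planted integer origin jitters.

    Returns the tile set, the ground-truth absolute (z, y, x) origin per grid
    position, and the source volume the tiles were cut from.
    """
    if cfg is not None:
        source = simulate_widefield(spec, cfg, n_depth_slabs)
    else:
        gt = render_ground_truth(spec)
        source = gt.with_data(_apply_background_and_noise(spec, gt.data))
    rows, cols = grid_shape
    nz, ny, nx = spec.shape
    # tile size such that nominal steps of size*(1-overlap) tile the canvas
    ty = int(np.ceil(ny / (rows - (rows - 1) * overlap))) if rows > 1 else ny
    tx = int(np.ceil(nx / (cols - (cols - 1) * overlap))) if cols > 1 else nx
    wy, wx = int(round(ty * overlap)), int(round(tx * overlap))
    if rows * cols > 1 and jitter_voxels >= min(wy if rows > 1 else wx,
                                               wx if cols > 1 else wy):
        raise ValueError(
            f"jitter {jitter_voxels} too large for overlap strips of "
            f"{min(wy, wx)} voxels"
        )
    rng = np.random.default_rng(seed)
    truth: dict[tuple[int, int], tuple[int, int, int]] = {}
    tiles_by_pos: dict[tuple[int, int], Volume] = {}
    for r in range(rows):
        for c in range(cols):
            y0 = r * (ty - wy)
            x0 = c * (tx - wx)
            if (r, c) != (0, 0) and jitter_voxels > 0:
                y0 += int(rng.integers(-jitter_voxels, jitter_voxels + 1))
                x0 += int(rng.integers(-jitter_voxels, jitter_voxels + 1))
            y0 = int(np.clip(y0, 0, ny - ty))
            x0 = int(np.clip(x0, 0, nx - tx))
            truth[(r, c)] = (0, y0, x0)
            tiles_by_pos[(r, c)] = Volume(
                data=source.data[:, y0:y0 + ty, x0:x0 + tx].copy(),
                voxel_size=spec.voxel_size,
                channels=list(source.channels),
            )
    from ._util import grid_position

    ordered = [None] * (rows * cols)
    for i in range(rows * cols):
        ordered[i] = tiles_by_pos[grid_position(i, grid_shape, pattern)]
    tileset = TileSet(tiles=ordered, grid_shape=grid_shape, pattern=pattern,
                      overlap_fraction=overlap)
    return tileset, truth, source
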