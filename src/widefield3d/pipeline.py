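"""End-to-end orchestration: background-subtract, brick-wise depth-variant
deconvolution, mosaic stitching.

The stage order is fixed — estimate background, subtract it, plan z-bricks,
deconvolve depth-variantly — because the maximum-likelihood deconvolver
assumes the image reaching it is background-free; the deconvolver background
is implicitly zero for filtered images.  A batch run applies the per-tile
pipeline to every tile of a grid and then stitches.

All settings live in one :class:`PipelineConfig`, serializable to YAML (the
reusable "template" workflow); results are deterministic given config and
inputs.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import background as bg
from .deconv import DeconvSettings, deconvolve_depth_variant, plan_bricks
from .io import TileSet, Volume
from .optics import OpticalConfig, default_support, generate_psf, nyquist_axial_um
from .stitch import stitch_tileset

__all__ = ["PipelineConfig", "PipelineStageError", "run_tile", "run_batch"]

log = logging.getLogger("widefield3d")


class PipelineStageError(RuntimeError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class StitchSettings:
    grid_shape: tuple[int, int] = (1, 1)
    pattern: str = "row_major"
    overlap_fraction: float = 0.1
    flatfield_path: str | None = None


@dataclass
class PipelineConfig:
    """All settings of an end-to-end run, mirroring a parameter template."""

    optical: OpticalConfig
    deconv: DeconvSettings = field(default_factory=DeconvSettings)
    background: bg.BackgroundSettings | str | None = "auto"
    n_bricks: int = 7
    stitch: StitchSettings = field(default_factory=StitchSettings)
    psf_support: tuple[int, int, int] | None = None
    dtype_policy: str = "float"
    seed: int = 0

    def to_yaml(self, path) -> None:
        from dataclasses import asdict

        payload = {
            "optical": asdict(self.optical),
            "deconv": asdict(self.deconv),
            "background": (
                self.background if isinstance(self.background, (str, type(None)))
                else asdict(self.background)
            ),
            "n_bricks": self.n_bricks,
            "stitch": asdict(self.stitch),
            "psf_support": list(self.psf_support) if self.psf_support else None,
            "dtype_policy": self.dtype_policy,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        optical = payload["optical"]
        optical["voxel_size"] = tuple(optical["voxel_size"])
        bg_cfg = payload.get("background", "auto")
        if isinstance(bg_cfg, dict):
            bg_cfg = bg.BackgroundSettings(**bg_cfg)
        stitch_cfg = payload.get("stitch", {})
        if "grid_shape" in stitch_cfg:
            stitch_cfg["grid_shape"] = tuple(stitch_cfg["grid_shape"])
        support = payload.get("psf_support")
        return cls(
            optical=OpticalConfig(**optical),
            deconv=DeconvSettings(**payload.get("deconv", {})),
            background=bg_cfg,
            n_bricks=int(payload.get("n_bricks", 7)),
            stitch=StitchSettings(**stitch_cfg),
            psf_support=tuple(support) if support else None,
            dtype_policy=payload.get("dtype_policy", "float"),
            seed=int(payload.get("seed", 0)),
        )


def _resolve_background(cfg: PipelineConfig) -> bg.BackgroundSettings | None:
    if cfg.background is None:
        return None
    if isinstance(cfg.background, bg.BackgroundSettings):
        return cfg.background
    if cfg.background == "auto":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            kernel = generate_psf(cfg.optical, cfg.optical.coverslip_distance_um,
                                  support=cfg.psf_support)
            return bg.auto_settings(cfg.optical, kernel)
    raise ValueError(f"unsupported background config {cfg.background!r}")


def run_tile(tile: Volume, cfg: PipelineConfig) -> Volume:
    """Per-tile pipeline: estimate background -> subtract -> plan bricks ->
    deconvolve depth-variantly.  Errors carry the failing stage's name."""
    if tile.data.ndim != 3:
        raise ValueError("run_tile processes single-channel (z, y, x) stacks")
    nyq = nyquist_axial_um(cfg.optical)
    dz = cfg.optical.voxel_size[0]
    log.info("axial Nyquist interval %.3f um (z-step %.3f um)", nyq, dz)
    if dz > nyq:
        log.warning("z-step %.3f um exceeds the axial Nyquist interval %.3f um", dz, nyq)

    settings = _resolve_background(cfg)
    work = tile
    if settings is not None:
        try:
            field_ = bg.estimate_background(work, settings)
            work = bg.subtract_background(work, field_)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("background", exc) from exc

    try:
        support = cfg.psf_support or default_support(
            cfg.optical, cfg.optical.plane_depth_um(tile.data.shape[0] / 2)
        )
        plan = plan_bricks(tile.data.shape[0], cfg.n_bricks, support[0])
    except Exception as exc:
        raise PipelineStageError("plan_bricks", exc) from exc

    try:
        t0 = time.perf_counter()
        out = deconvolve_depth_variant(work, cfg.optical, cfg.deconv, plan,
                                       psf_support=cfg.psf_support)
        log.info("deconvolved %s in %.1f s (%d bricks, %d iterations)",
                 tile.data.shape, time.perf_counter() - t0, plan.n_bricks,
                 cfg.deconv.effective_iterations)
    except Exception as exc:
        raise PipelineStageError("deconvolve", exc) from exc
    return out


def run_batch(tiles: TileSet, cfg: PipelineConfig, flatfield=None) -> Volume:
    """Run the per-tile pipeline on every tile, then stitch.

    Tiles are independent units; the result does not depend on processing
    order.  A failing tile aborts the batch with its acquisition index.
    """
    processed = []
    for i, tile in enumerate(tiles.tiles):
        try:
            t0 = time.perf_counter()
            processed.append(run_tile(tile, cfg))
            log.info("tile %d/%d done in %.1f s", i + 1, len(tiles.tiles),
                     time.perf_counter() - t0)
        except Exception as exc:
            raise PipelineStageError(f"tile {i}", exc) from exc
    if len(processed) == 1:
        return processed[0]
    out_tiles = TileSet(tiles=processed, grid_shape=tiles.grid_shape,
                        pattern=tiles.pattern,
                        overlap_fraction=tiles.overlap_fraction)
    fused, layout, offsets = stitch_tileset(out_tiles, flatfield=flatfield)
    for pair, est in offsets.items():
        log.info("offset %s -> %s: shift=%s score=%.3f%s", *pair, est.shift,
                 est.score, " (low confidence)" if est.low_confidence else "")
    return fused
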