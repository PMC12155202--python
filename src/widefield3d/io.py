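"""Calibrated z-stack and tile-set I/O.

Volumes are (z, y, x) or (channel, z, y, x) arrays with voxel sizes in
micrometers and per-channel emission wavelengths in nanometers.  The on-disk
container is OME-TIFF; voxel calibration travels in the OME PhysicalSize
attributes and auxiliary values (u16 scale factors, imaging direction) in a
JSON block inside the OME image description.

The z axis is oriented so that index 0 is the plane nearest the coverslip
when the imaging direction is "downward" — depth below the coverslip is then
``coverslip_distance + z_index * dz``, the convention every depth-variant
stage of the pipeline relies on.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ChannelMeta",
    "Volume",
    "TileSet",
    "read_volume",
    "write_volume",
    "load_tileset",
    "VolumeMetadataError",
]


class VolumeMetadataError(ValueError):
    """Raised when required calibration metadata is absent."""


@dataclass(frozen=True)
class ChannelMeta:
    em_wavelength_nm: float
    name: str = ""


@dataclass
class Volume:
    """A calibrated intensity stack.

    Parameters
    ----------
    data
        (z, y, x) or (c, z, y, x) array, non-negative.
    voxel_size
        (dz, dy, dx) in micrometers, all strictly positive.
    channels
        One :class:`ChannelMeta` per channel (a single entry for 3D data).
    imaging_direction
        "downward" (z=0 at the coverslip) or "upward".
    meta
        Free-form auxiliary metadata (e.g. u16 scale factors).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channels: list[ChannelMeta] = field(default_factory=list)
    imaging_direction: str = "downward"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("Volume data must be 3D (z,y,x) or 4D (c,z,y,x)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three strictly positive values (dz, dy, dx)")
        if self.imaging_direction not in ("downward", "upward"):
            raise ValueError(f"unknown imaging direction {self.imaging_direction!r}")
        if not self.channels:
            self.channels = [ChannelMeta(em_wavelength_nm=0.0) for _ in range(self.n_channels)]
        if len(self.channels) != self.n_channels:
            raise ValueError(
                f"{len(self.channels)} channel entries for {self.n_channels} data channels"
            )
        if self.data.size and float(np.min(self.data)) < 0:
            raise ValueError(
                "Volume data contains negative values; clip or reject them at ingestion"
            )

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    def channel_data(self, c: int) -> np.ndarray:
        """The (z, y, x) array of channel ``c``."""
        return self.data if self.data.ndim == 3 else self.data[c]

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data, meta=dict(self.meta))


@dataclass
class TileSet:
    """Tiles in acquisition order plus the grid geometry that places them."""

    tiles: list[Volume]
    grid_shape: tuple[int, int]
    pattern: str = "row_major"
    overlap_fraction: float = 0.1

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if len(self.tiles) != rows * cols:
            raise ValueError(
                f"{len(self.tiles)} tiles do not fill a {rows}x{cols} grid"
            )
        if not 0.0 < self.overlap_fraction < 0.5:
            raise ValueError("overlap_fraction must lie in (0, 0.5)")
        first = self.tiles[0]
        for i, t in enumerate(self.tiles[1:], start=1):
            if t.data.shape != first.data.shape:
                raise ValueError(f"tile {i} shape {t.data.shape} != tile 0 {first.data.shape}")
            if t.voxel_size != first.voxel_size:
                raise ValueError(f"tile {i} voxel size differs from tile 0")

    def grid_index(self, acquisition_index: int) -> tuple[int, int]:
        from ._util import grid_position

        return grid_position(acquisition_index, self.grid_shape, self.pattern)

    def tile_at(self, row: int, col: int) -> Volume:
        from ._util import grid_position

        for i in range(len(self.tiles)):
            if grid_position(i, self.grid_shape, self.pattern) == (row, col):
                return self.tiles[i]
        raise KeyError((row, col))


_DESC_KEY = "widefield3d"


def read_volume(
    path,
    voxel_size: tuple[float, float, float] | None = None,
    channels: list[ChannelMeta] | None = None,
    imaging_direction: str | None = None,
    clip_negative: bool = False,
) -> Volume:
    """Read a TIFF/OME-TIFF stack into a :class:`Volume`.

    Calibration must be present in the file's OME metadata or supplied via the
    override arguments; a stack with neither raises
    :class:`VolumeMetadataError` naming the missing fields rather than
    assuming a default.  Negative values are rejected unless
    ``clip_negative=True`` (maximum-likelihood deconvolution assumes
    non-negative counts).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        ome = tf.ome_metadata

    file_voxel = file_channels = None
    file_direction = None
    extra: dict = {}
    if ome:
        file_voxel, file_channels, extra = _parse_ome(ome)
        file_direction = extra.get("imaging_direction")

    if data.ndim == 2:
        data = data[None]
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected a 3D/4D stack, got shape {data.shape}")

    missing = []
    vs = voxel_size or file_voxel
    if vs is None:
        missing.append("voxel_size (dz, dy, dx)")
    ch = channels or file_channels
    if missing:
        raise VolumeMetadataError(
            f"{path}: missing required calibration metadata: {', '.join(missing)}; "
            "supply overrides to read_volume"
        )

    if data.size and float(np.min(data)) < 0:
        if clip_negative:
            data = np.clip(data, 0, None)
        else:
            raise ValueError(
                f"{path}: stack contains negative values; pass clip_negative=True to clip"
            )

    return Volume(
        data=data,
        voxel_size=vs,
        channels=ch or [],
        imaging_direction=imaging_direction or file_direction or "downward",
        meta=extra,
    )


def write_volume(v: Volume, path, dtype_policy: str = "float") -> None:
    """Write a :class:`Volume` as OME-TIFF.

    ``u16_scaled`` maps each channel linearly from [0, channel max] onto
    [0, 65535] and records the per-channel scale factor (value per grey level)
    in the embedded metadata; an all-zero channel gets scale 1 by convention.
    ``float`` writes values unchanged (float32 input stays float32).
    """
    path = Path(path)
    data = v.data
    extra = dict(v.meta)
    extra["imaging_direction"] = v.imaging_direction
    if dtype_policy == "u16_scaled":
        chans = data[None] if data.ndim == 3 else data
        scaled = np.empty(chans.shape, dtype=np.uint16)
        scales = []
        for c in range(chans.shape[0]):
            mx = float(chans[c].max()) if chans[c].size else 0.0
            scale = mx / 65535.0 if mx > 0 else 1.0
            scaled[c] = np.round(chans[c] / scale).astype(np.uint16) if mx > 0 else 0
            scales.append(scale)
        data = scaled[0] if v.data.ndim == 3 else scaled
        extra["u16_scale"] = scales
    elif dtype_policy == "float":
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
    else:
        raise ValueError(f"unknown dtype policy {dtype_policy!r}")

    dz, dy, dx = v.voxel_size
    axes = "ZYX" if data.ndim == 3 else "CZYX"
    metadata = {
        "axes": axes,
        "PhysicalSizeZ": dz,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeY": dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeX": dx,
        "PhysicalSizeXUnit": "µm",
        "Description": json.dumps({_DESC_KEY: extra}),
    }
    if any(c.em_wavelength_nm for c in v.channels):
        metadata["Channel"] = {
            "Name": [c.name or f"ch{i}" for i, c in enumerate(v.channels)],
            "EmissionWavelength": [c.em_wavelength_nm for c in v.channels],
            "EmissionWavelengthUnit": ["nm"] * len(v.channels),
        }
    tifffile.imwrite(path, data, ome=True, metadata=metadata)


def _parse_ome(ome_xml: str):
    """Extract voxel size, channel metadata and our JSON extras from OME-XML."""
    import xml.etree.ElementTree as ET

    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}

    def find(el, tag):
        return el.find(f"ome:{tag}", ns) if ns else el.find(tag)

    def findall(el, tag):
        return el.findall(f"ome:{tag}", ns) if ns else el.findall(tag)

    voxel = channels = None
    extra: dict = {}
    image = find(root, "Image")
    if image is not None:
        pixels = find(image, "Pixels")
        if pixels is not None:
            sz = pixels.get("PhysicalSizeZ")
            sy = pixels.get("PhysicalSizeY")
            sx = pixels.get("PhysicalSizeX")
            if sz and sy and sx:
                voxel = (float(sz), float(sy), float(sx))
            chans = findall(pixels, "Channel")
            if chans:
                channels = [
                    ChannelMeta(
                        em_wavelength_nm=float(c.get("EmissionWavelength") or 0.0),
                        name=c.get("Name") or "",
                    )
                    for c in chans
                ]
        desc = find(image, "Description")
        if desc is not None and desc.text:
            try:
                payload = json.loads(desc.text)
                extra = payload.get(_DESC_KEY, {})
            except (json.JSONDecodeError, AttributeError):
                pass
    return voxel, channels, extra


_NUM_SUFFIX = re.compile(r"(\d+)\D*$")


def load_tileset(
    directory,
    grid_shape: tuple[int, int],
    pattern: str = "row_major",
    overlap_fraction: float = 0.1,
    voxel_size: tuple[float, float, float] | None = None,
    **read_kwargs,
) -> TileSet:
    """Load a directory of numbered tile stacks into a :class:`TileSet`.

    Files are ordered by the numeric suffix of their stem (acquisition order);
    the grid position of each tile follows from the acquisition pattern
    (serpentine reverses every other row).
    """
    directory = Path(directory)
    rows, cols = grid_shape
    files = []
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() not in (".tif", ".tiff"):
            continue
        m = _NUM_SUFFIX.search(p.stem)
        if m:
            files.append((int(m.group(1)), p))
    files.sort(key=lambda t: t[0])
    if len(files) != rows * cols:
        raise ValueError(
            f"{directory}: found {len(files)} numbered tiles, expected {rows * cols}"
        )
    tiles = [read_volume(p, voxel_size=voxel_size, **read_kwargs) for _, p in files]
    return TileSet(tiles=tiles, grid_shape=grid_shape, pattern=pattern,
                   overlap_fraction=overlap_fraction)
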