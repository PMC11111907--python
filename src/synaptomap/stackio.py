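"""Reading and writing multi-channel 3D image stacks and run configuration.

Stacks are stored as TIFF: either one multi-channel file with a ``CZYX``
axis layout, or one single-channel ``ZYX`` file per marker.  Both dialects
load into the same in-memory representation, a list of
:class:`ChannelStack`, so downstream code never sees the difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml

from .geometry import VoxelGeometry

LAYER_LABELS = ("molecular-proximal", "molecular-distal", "granule")


class ChannelCountMismatchError(ValueError):
    """The file's channel count does not match the channel map."""


class NotThreeDimensionalError(ValueError):
    """The image data are not a 3D (or multi-channel 3D) stack."""


@dataclass
class ChannelStack:
    """One marker channel of a 3D acquisition.

    ``data`` is a non-empty float array in ``(z, y, x)`` order with
    non-negative intensities; ``geometry`` is shared by all channels of
    one stack.  ``provenance`` carries identifiers used for hierarchical
    aggregation (mouse, section, stack) plus the layer label.
    """

    marker: str
    data: np.ndarray
    geometry: VoxelGeometry
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise NotThreeDimensionalError(f"channel data must be 3D, got shape {arr.shape}")
        if arr.size == 0:
            raise ValueError("channel data must be non-empty")
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.float32)
        if arr.min() < 0:
            raise ValueError("intensities must be non-negative")
        self.data = arr


def write_stack(path: str | Path, stacks: Sequence[ChannelStack]) -> Path:
    """Write channels as one multi-channel TIFF (axes ``CZYX``).

    Channel order in the file follows the order of ``stacks``.
    """
    path = Path(path)
    if not stacks:
        raise ValueError("no channels to write")
    shapes = {s.data.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError(f"channels must share one grid, got shapes {shapes}")
    arr = np.stack([s.data.astype(np.float32) for s in stacks], axis=0)
    tifffile.imwrite(path, arr, photometric="minisblack", metadata={"axes": "CZYX"})
    return path


def write_stack_per_channel(directory: str | Path, stacks: Sequence[ChannelStack]) -> dict[str, Path]:
    """Write one single-channel ``ZYX`` TIFF per marker; returns marker -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for s in stacks:
        p = directory / f"{s.marker}.tif"
        tifffile.imwrite(p, s.data.astype(np.float32), photometric="minisblack", metadata={"axes": "ZYX"})
        paths[s.marker] = p
    return paths


def read_stack(
    path: str | Path,
    channel_map: Sequence[str],
    geometry: VoxelGeometry,
    provenance: Mapping | None = None,
) -> list[ChannelStack]:
    """Read a multi-channel TIFF into one :class:`ChannelStack` per mapped channel.

    ``channel_map`` assigns a marker name to every channel, in file order.
    A plain 3D file is accepted when the map has exactly one entry.
    Integer data are promoted to float unchanged in value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 3:
        arr = arr[None, ...]
    if arr.ndim != 4:
        raise NotThreeDimensionalError(
            f"expected 3D or channel-plus-3D data, got shape {arr.shape}"
        )
    if arr.shape[0] != len(channel_map):
        raise ChannelCountMismatchError(
            f"file has {arr.shape[0]} channels but channel_map names {len(channel_map)}"
        )
    prov = dict(provenance or {})
    prov.setdefault("path", str(path))
    return [
        ChannelStack(marker=name, data=arr[i], geometry=geometry, provenance=dict(prov))
        for i, name in enumerate(channel_map)
    ]


def read_stack_files(
    paths: Mapping[str, str | Path],
    geometry: VoxelGeometry,
    provenance: Mapping | None = None,
) -> list[ChannelStack]:
    """Read the one-file-per-channel dialect; ``paths`` maps marker -> file."""
    out = []
    for marker, p in paths.items():
        (stack,) = read_stack(p, [marker], geometry, provenance)
        out.append(stack)
    shapes = {s.data.shape for s in out}
    if len(shapes) > 1:
        raise ValueError(f"per-channel files disagree on grid shape: {shapes}")
    return out


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration (channel map, voxel size, thresholds...)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"run config must be a mapping, got {type(cfg).__name__}")
    return cfg


def save_run_config(cfg: Mapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
    return path


def geometry_from_config(cfg: Mapping) -> VoxelGeometry:
    """Build a :class:`VoxelGeometry` from config keys ``voxel_size_nm`` (x, y, z)
    and ``expansion_factor``."""
    return VoxelGeometry.from_xyz(
        cfg.get("voxel_size_nm", [50.0, 50.0, 190.0]),
        float(cfg.get("expansion_factor", 1.0)),
    )
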