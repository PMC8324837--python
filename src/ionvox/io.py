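"""On-disk data model: multichannel ion-count volumes, manifests, tables.

A multiplexed SIMS acquisition is stored as one multi-page TIFF per isotope
channel (pages ordered by increasing depth, i.e. acquisition plane) plus a
YAML manifest listing, in order, each channel's name, marker and file.
Voxel feature tables and line scans are plain TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ChannelStack",
    "MultiplexVolume",
    "LineScan",
    "read_volume",
    "write_volume",
    "read_voxel_table",
    "write_voxel_table",
    "read_linescan",
    "write_linescan",
    "VOXEL_META_COLUMNS",
]

#: columns every voxel table carries besides one column per channel
VOXEL_META_COLUMNS = [
    "fov_id", "center_x", "center_y", "center_z",
    "wx", "wy", "wz", "sx", "sy", "sz", "normalization",
]


@dataclass
class ChannelStack:
    """A single isotope channel: 3D grid of ion counts, axis order (z, y, x)."""

    channel_name: str
    marker: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"channel {self.channel_name!r}: expected 3D (z, y, x) data, "
                f"got {self.data.ndim}D"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"channel {self.channel_name!r}: non-finite values")
        if np.any(self.data < 0):
            raise ValueError(f"channel {self.channel_name!r}: negative counts")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class MultiplexVolume:
    """Aligned per-channel stacks for one field of view (FOV)."""

    stacks: list[ChannelStack]
    fov_id: str = "fov0"
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        if not self.stacks:
            raise ValueError("a MultiplexVolume needs at least one channel")
        dims = {s.dims for s in self.stacks}
        if len(dims) > 1:
            raise ValueError(f"channel stacks disagree on dimensions: {sorted(dims)}")
        names = [s.channel_name for s in self.stacks]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names in {names}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.stacks[0].dims

    @property
    def channel_names(self) -> list[str]:
        return [s.channel_name for s in self.stacks]

    def channel(self, name: str) -> ChannelStack:
        for s in self.stacks:
            if s.channel_name == name:
                return s
        raise KeyError(f"no channel {name!r}; have {self.channel_names}")

    def array(self, channels: Sequence[str] | None = None) -> np.ndarray:
        """Stack the requested channels into a (C, z, y, x) array."""
        chans = list(channels) if channels is not None else self.channel_names
        return np.stack([self.channel(c).data for c in chans])


@dataclass
class LineScan:
    """Intensity profile sampled along a line, e.g. across a structure edge."""

    position: np.ndarray
    intensity: np.ndarray
    unit: str = "px"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position.shape != self.intensity.shape or self.position.ndim != 1:
            raise ValueError("position and intensity must be equal-length 1D arrays")
        if self.position.size and np.any(np.diff(self.position) <= 0):
            raise ValueError("positions must be strictly increasing")


# ---------------------------------------------------------------------------
# volumes

def write_volume(volume: MultiplexVolume, directory: str | os.PathLike) -> dict:
    """Write one multi-page TIFF per channel plus a YAML manifest.

    Integer data are written losslessly as uint16/uint32; float data as
    float32. Returns the manifest dict (also written to ``manifest.yaml``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for stack in volume.stacks:
        fname = f"{stack.channel_name}.tiff"
        data = stack.data
        if np.issubdtype(data.dtype, np.integer) or np.all(data == np.floor(data)):
            data = data.astype(np.uint16 if data.max(initial=0) < 2**16 else np.uint32)
        else:
            data = data.astype(np.float32)
        tifffile.imwrite(directory / fname, data, photometric="minisblack")
        entries.append(
            {"channel_name": stack.channel_name, "marker": stack.marker, "file": fname}
        )
    manifest = {"fov_id": volume.fov_id, "channels": entries}
    if volume.pixel_size_nm is not None:
        manifest["pixel_size_nm"] = float(volume.pixel_size_nm)
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def read_volume(directory: str | os.PathLike,
                manifest: str | os.PathLike | dict | None = None) -> MultiplexVolume:
    """Read a volume written by :func:`write_volume`.

    Channel order follows the manifest; dimensions are validated across
    channels and negative values rejected.
    """
    directory = Path(directory)
    if manifest is None:
        manifest = directory / "manifest.yaml"
    if not isinstance(manifest, dict):
        with open(manifest) as fh:
            manifest = yaml.safe_load(fh)
    stacks = []
    for entry in manifest["channels"]:
        path = directory / entry["file"]
        if not path.exists():
            raise FileNotFoundError(
                f"channel {entry['channel_name']!r}: file {path} missing"
            )
        data = tifffile.imread(path)
        if data.ndim == 2:  # single-page stack
            data = data[None]
        stacks.append(
            ChannelStack(entry["channel_name"], entry.get("marker", ""), data)
        )
    dims = {s.dims for s in stacks}
    if len(dims) > 1:
        detail = {s.channel_name: s.dims for s in stacks}
        raise ValueError(f"channel dimension mismatch: {detail}")
    return MultiplexVolume(
        stacks,
        fov_id=manifest.get("fov_id", "fov0"),
        pixel_size_nm=manifest.get("pixel_size_nm"),
    )


def write_label_volume(labels: np.ndarray, path: str | os.PathLike) -> Path:
    """Write an integer label volume (ground truth or neighborhood map)."""
    path = Path(path)
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label volume must be integer typed")
    tifffile.imwrite(path, labels.astype(np.int32), photometric="minisblack")
    return path


def read_label_volume(path: str | os.PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(path))


# ---------------------------------------------------------------------------
# tables

def write_voxel_table(table: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write a voxel feature table as TSV (floats at 6 significant digits)."""
    missing = [c for c in VOXEL_META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"voxel table is missing required columns {missing}")
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_voxel_table(path: str | os.PathLike) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed voxel table {path}: {err}") from err
    missing = [c for c in VOXEL_META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"voxel table {path} is missing required columns {missing}")
    return table


def write_linescan(scan: LineScan, path: str | os.PathLike) -> Path:
    path = Path(path)
    pd.DataFrame({"position": scan.position, "intensity": scan.intensity}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_linescan(path: str | os.PathLike) -> LineScan:
    df = pd.read_csv(path, sep="\t")
    if not {"position", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'position' and 'intensity'")
    return LineScan(df["position"].to_numpy(), df["intensity"].to_numpy())
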