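"""Sliding-window voxel features, sampling, filtering and normalisation.

A "voxel" here is a 3D window over the image grid summarised by the mean ion
count of each channel. Windows are indexed (x, y, z) in pixel units to match
the acquisition convention; data arrays are (z, y, x). Only fully contained
windows are emitted, and window centers are reported in the original
(untrimmed) pixel frame so that distances downstream are in true pixels.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io import VOXEL_META_COLUMNS, MultiplexVolume

__all__ = [
    "sliding_window_features",
    "window_starts",
    "middle_z_range",
    "majority_window_labels",
    "channel_columns",
    "mask_filter",
    "sample_voxels",
    "filter_low_carbon",
    "zscore",
    "minmax",
    "log2_pseudocount",
    "percentile_normalize",
    "clip_normalize",
]

logger = logging.getLogger(__name__)

_NON_CHANNEL = set(VOXEL_META_COLUMNS) | {"label", "neighborhood", "cluster",
                                          "condition", "cell_id"}


def channel_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a voxel table holding per-channel values."""
    return [c for c in table.columns
            if c not in _NON_CHANNEL and not str(c).startswith("truth_")]


def window_starts(length: int, window: int, step: int) -> np.ndarray:
    """Start offsets of fully contained windows: 0, step, ... (count
    = floor((length - window) / step) + 1)."""
    if window > length:
        return np.array([], dtype=int)
    return np.arange(0, length - window + 1, step)


def middle_z_range(depth: int, n_planes: int = 40) -> tuple[int, int]:
    """Centered slab of ``n_planes`` (all planes if the stack is shallower);
    for odd remainders the extra plane is left on the leading side."""
    if n_planes >= depth:
        return (0, depth)
    start = (depth - n_planes + 1) // 2
    return (start, start + n_planes)


def _window_view_mean(data: np.ndarray, win_zyx, step_zyx) -> np.ndarray:
    wz, wy, wx = win_zyx
    sz, sy, sx = step_zyx
    view = sliding_window_view(data, (wz, wy, wx))[::sz, ::sy, ::sx]
    return view.mean(axis=(-3, -2, -1))


def sliding_window_features(
    volume: MultiplexVolume,
    window: tuple[int, int, int] = (10, 10, 5),
    step: tuple[int, int, int] | None = None,
    z_range: tuple[int, int] | None = None,
    border: int = 0,
) -> pd.DataFrame:
    """Mean ion count per channel in each 3D sliding window.

    ``window`` and ``step`` are (x, y, z) pixel sizes; ``step`` defaults to
    the window (non-overlapping tiling). ``border`` pixels are discarded on
    each lateral edge and ``z_range`` (half-open) limits the planes used.
    One row per fully contained window; centers in original-frame pixels.
    """
    wx, wy, wz = window
    sx, sy, sz = step if step is not None else window
    if min(sx, sy, sz) < 1:
        raise ValueError("steps must be >= 1")
    nz, ny, nx = volume.dims
    z0, z1 = z_range if z_range is not None else (0, nz)
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"z_range {z_range} outside stack of depth {nz}")
    y0 = x0 = border
    region = (z1 - z0, ny - 2 * border, nx - 2 * border)
    if border < 0 or region[1] <= 0 or region[2] <= 0:
        raise ValueError(f"border {border} leaves no interior in {ny}x{nx}")
    if wz > region[0] or wy > region[1] or wx > region[2]:
        raise ValueError(
            f"window (x,y,z)=({wx},{wy},{wz}) larger than region {region}"
        )

    zs = window_starts(region[0], wz, sz)
    ys = window_starts(region[1], wy, sy)
    xs = window_starts(region[2], wx, sx)
    zc, yc, xc = np.meshgrid(z0 + zs + (wz - 1) / 2,
                             y0 + ys + (wy - 1) / 2,
                             x0 + xs + (wx - 1) / 2, indexing="ij")
    out = pd.DataFrame({
        "fov_id": volume.fov_id,
        "center_x": xc.ravel(),
        "center_y": yc.ravel(),
        "center_z": zc.ravel(),
        "wx": wx, "wy": wy, "wz": wz, "sx": sx, "sy": sy, "sz": sz,
        "normalization": "raw",
    })
    for stack in volume.stacks:
        data = stack.data[z0:z1, y0:ny - border, x0:nx - border]
        out[stack.channel_name] = _window_view_mean(
            data.astype(float), (wz, wy, wx), (sz, sy, sx)
        ).ravel()
    return out


def majority_window_labels(
    label_volume: np.ndarray,
    window: tuple[int, int, int],
    step: tuple[int, int, int] | None = None,
    z_range: tuple[int, int] | None = None,
    border: int = 0,
) -> np.ndarray:
    """Majority ground-truth label per window, in the row order produced by
    :func:`sliding_window_features` with the same geometry."""
    wx, wy, wz = window
    sx, sy, sz = step if step is not None else window
    nz, ny, nx = label_volume.shape
    z0, z1 = z_range if z_range is not None else (0, nz)
    region = label_volume[z0:z1, border:ny - border, border:nx - border]
    labels = np.unique(region)
    counts = np.stack([
        _window_view_mean((region == l).astype(float), (wz, wy, wx),
                          (sz, sy, sx))
        for l in labels
    ])
    return labels[np.argmax(counts, axis=0)].ravel()


# ---------------------------------------------------------------------------
# row filters and sampling

def mask_filter(table: pd.DataFrame, mask2d: np.ndarray) -> pd.DataFrame:
    """Keep rows whose (center_x, center_y) lands on a true mask pixel."""
    mask2d = np.asarray(mask2d, dtype=bool)
    ys = np.floor(table["center_y"].to_numpy() + 0.5).astype(int)
    xs = np.floor(table["center_x"].to_numpy() + 0.5).astype(int)
    if len(table) and (ys.max() >= mask2d.shape[0] or xs.max() >= mask2d.shape[1]):
        raise ValueError("voxel centers fall outside the mask frame")
    return table.loc[mask2d[ys, xs]].reset_index(drop=True)


def sample_voxels(table: pd.DataFrame, n: int, seed: int = 0,
                  per_group: str | None = None) -> pd.DataFrame:
    """Uniform sampling of ``n`` rows without replacement, optionally per
    group (e.g. per FOV); deterministic given the seed."""
    rng = np.random.default_rng(seed)
    if per_group is None:
        groups = [(None, table)]
    else:
        groups = [(k, g) for k, g in table.groupby(per_group, sort=True)]
    parts = []
    for key, g in groups:
        if len(g) < n:
            raise ValueError(
                f"cannot sample {n} voxels from group {key!r} of size {len(g)}"
            )
        idx = rng.choice(len(g), size=n, replace=False)
        parts.append(g.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def filter_low_carbon(table: pd.DataFrame, channel: str = "12C",
                      fraction: float = 0.2,
                      per_group: str = "fov_id") -> pd.DataFrame:
    """Drop the lowest-``fraction`` quantile of rows by carbon counts per
    group (voxels over bare substrate). Ties broken by stable row order;
    exactly floor(fraction * n) rows removed per group."""
    if channel not in table.columns:
        raise ValueError(f"channel {channel!r} not in table")
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    keep_parts = []
    for key, g in table.groupby(per_group, sort=True):
        n_drop = int(np.floor(fraction * len(g)))
        order = np.argsort(g[channel].to_numpy(), kind="stable")
        drop = set(order[:n_drop])
        keep_parts.append(g.iloc[[i for i in range(len(g)) if i not in drop]])
    out = pd.concat(keep_parts).sort_index().reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# normalisations

def _tag(table: pd.DataFrame, tag: str) -> pd.DataFrame:
    prev = table["normalization"].iloc[0] if len(table) else "raw"
    table["normalization"] = tag if prev in ("raw", "") else f"{prev}+{tag}"
    return table


def zscore(table: pd.DataFrame, channels: list[str] | None = None
           ) -> pd.DataFrame:
    """Per-channel (x - mean) / sd with the population (1/n) sd."""
    out = table.copy()
    for c in channels or channel_columns(table):
        x = out[c].to_numpy(dtype=float)
        sd = x.std()  # population
        if sd == 0:
            logger.warning("zscore: channel %s is constant; output set to 0", c)
            out[c] = 0.0
        else:
            out[c] = (x - x.mean()) / sd
    return _tag(out, "zscore")


def minmax(table: pd.DataFrame, channels: list[str] | None = None
           ) -> pd.DataFrame:
    """Per-channel (x - min) / (max - min), range [0, 1]."""
    out = table.copy()
    for c in channels or channel_columns(table):
        x = out[c].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            logger.warning("minmax: channel %s is constant; output set to 0", c)
            out[c] = 0.0
        else:
            out[c] = (x - lo) / (hi - lo)
    return _tag(out, "minmax")


def log2_pseudocount(table: pd.DataFrame, channels: list[str] | None = None,
                     pc: float = 0.0001) -> pd.DataFrame:
    """x -> log2(x + pc); the small pseudocount avoids log of zero counts."""
    out = table.copy()
    for c in channels or channel_columns(table):
        out[c] = np.log2(out[c].to_numpy(dtype=float) + pc)
    return _tag(out, f"log2+{pc:g}")


def percentile_normalize(table: pd.DataFrame,
                         channels: list[str] | None = None,
                         lo: float = 20.0, hi: float = 95.0,
                         per_group: str | None = "fov_id") -> pd.DataFrame:
    """Scale each channel's mean to 1 per group, then map the [lo, hi]
    percentile span linearly to [0, 1], clipping outside.

    Percentiles use linear interpolation between order statistics. The
    initial mean-scaling is affine, so it does not change the result; it is
    kept to mirror the published procedure exactly.
    """
    if lo >= hi:
        raise ValueError(f"lo percentile {lo} must be < hi {hi}")
    out = table.copy()
    for c in channels or channel_columns(table):
        col = out[c].to_numpy(dtype=float).copy()
        for key, g in ([(None, out)] if per_group is None
                       else out.groupby(per_group, sort=True)):
            idx = g.index.to_numpy()
            x = col[idx]
            m = x.mean()
            if m != 0:
                x = x / m
            p_lo, p_hi = np.percentile(x, [lo, hi])
            if p_hi == p_lo:
                logger.warning(
                    "percentile_normalize: channel %s constant in group %r",
                    c, key)
                col[idx] = 0.0
            else:
                col[idx] = np.clip((x - p_lo) / (p_hi - p_lo), 0.0, 1.0)
        out[c] = col
    return _tag(out, f"pct{lo:g}-{hi:g}")


def clip_normalize(table: pd.DataFrame, channel: str,
                   lo: float = 0.01, hi: float = 0.05) -> pd.DataFrame:
    """Global clamp-and-rescale: x -> clip((x - lo) / (hi - lo), 0, 1).

    Used for the drug channel, whose per-FOV normalisation would inflate
    untreated fields; limits are on the raw mean-count scale.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    out = table.copy()
    x = out[channel].to_numpy(dtype=float)
    out[channel] = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return _tag(out, f"clip[{lo:g},{hi:g}]:{channel}")
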