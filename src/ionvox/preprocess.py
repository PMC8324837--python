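"""Denoising and masking of sparse ion-count stacks.

Low-current acquisitions yield sparse counts where signal density, not
intensity, separates real structure from noise. The filter used here sums a
channel over a block of planes, computes for every positive pixel the mean
Euclidean distance to its k nearest positive neighbours, and keeps the
pixels whose local density is high (mean distance below a cutoff). The
resulting 2D mask is applied to every plane of the channel.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .io import ChannelStack, MultiplexVolume

__all__ = [
    "sum_planes",
    "knn_mean_distances",
    "knn_density_mask",
    "suggest_cutoff",
    "apply_mask_per_plane",
    "denoise_volume",
    "trim_border",
    "nucleus_mask",
]

logger = logging.getLogger(__name__)


def sum_planes(stack: ChannelStack | np.ndarray,
               z_range: tuple[int, int] | None = None) -> np.ndarray:
    """Pixelwise sum of the planes ``z_range = (start, stop)`` (half-open)."""
    data = stack.data if isinstance(stack, ChannelStack) else np.asarray(stack)
    if z_range is None:
        z_range = (0, data.shape[0])
    start, stop = z_range
    if not (0 <= start < stop <= data.shape[0]):
        raise ValueError(
            f"z_range {z_range} empty or outside stack of depth {data.shape[0]}"
        )
    return data[start:stop].sum(axis=0)


def knn_mean_distances(image2d: np.ndarray, k: int = 25,
                       channel: str = "") -> tuple[np.ndarray, np.ndarray]:
    """Mean distance from each positive pixel to its k nearest positive pixels.

    Returns ``(coords, mean_dist)`` where coords are the (row, col) positions
    of positive pixels. Raises if fewer than ``k + 1`` pixels are positive.
    """
    image2d = np.asarray(image2d)
    coords = np.argwhere(image2d > 0)
    label = f" in channel {channel!r}" if channel else ""
    if len(coords) < k + 1:
        raise ValueError(
            f"need at least {k + 1} positive pixels{label} for a {k}-NN "
            f"density estimate, found {len(coords)}"
        )
    tree = cKDTree(coords)
    # k+1 neighbours: the closest is the pixel itself at distance 0
    dists, _ = tree.query(coords, k=k + 1)
    return coords, dists[:, 1:].mean(axis=1)


def suggest_cutoff(image2d: np.ndarray, k: int = 25) -> float:
    """Data-driven density cutoff: Otsu threshold of the mean k-NN distances.

    Separates the dense (signal) and sparse (noise) modes of the distance
    histogram; use when no per-channel cutoff is configured.
    """
    _, mean_dist = knn_mean_distances(image2d, k=k)
    if np.allclose(mean_dist, mean_dist[0]):
        return float(mean_dist[0])
    return float(threshold_otsu(mean_dist))


def knn_density_mask(image2d: np.ndarray, k: int = 25,
                     cutoff: float | None = None,
                     channel: str = "") -> np.ndarray:
    """Boolean mask of positive pixels in dense regions.

    True exactly where a pixel is positive and its mean distance to the k
    nearest other positive pixels is <= ``cutoff`` (Otsu-derived when None).
    """
    image2d = np.asarray(image2d)
    coords, mean_dist = knn_mean_distances(image2d, k=k, channel=channel)
    if cutoff is None:
        cutoff = suggest_cutoff(image2d, k=k)
    mask = np.zeros(image2d.shape, dtype=bool)
    keep = mean_dist <= cutoff
    mask[coords[keep, 0], coords[keep, 1]] = True
    return mask


def apply_mask_per_plane(stack: ChannelStack, mask: np.ndarray) -> ChannelStack:
    """Zero all values outside the 2D mask, in every plane."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.data.shape[1:]:
        raise ValueError(
            f"mask shape {mask.shape} does not match plane shape "
            f"{stack.data.shape[1:]}"
        )
    return ChannelStack(stack.channel_name, stack.marker, stack.data * mask)


def denoise_volume(volume: MultiplexVolume, k: int = 25,
                   cutoffs: dict[str, float] | None = None,
                   channels: list[str] | None = None,
                   z_range: tuple[int, int] | None = None) -> MultiplexVolume:
    """KNN-density denoise selected channels of a volume.

    For each channel: sum planes over ``z_range``, build the density mask,
    apply it per plane. Channels not listed are passed through untouched.
    """
    cutoffs = cutoffs or {}
    stacks = []
    for stack in volume.stacks:
        if channels is not None and stack.channel_name not in channels:
            stacks.append(stack)
            continue
        summed = sum_planes(stack, z_range)
        mask = knn_density_mask(summed, k=k,
                                cutoff=cutoffs.get(stack.channel_name),
                                channel=stack.channel_name)
        stacks.append(apply_mask_per_plane(stack, mask))
        logger.info("denoised %s: kept %d/%d positive pixels",
                    stack.channel_name, int(mask.sum()), int((summed > 0).sum()))
    return MultiplexVolume(stacks, fov_id=volume.fov_id,
                           pixel_size_nm=volume.pixel_size_nm)


def trim_border(volume: MultiplexVolume, n_pixels: int
                ) -> tuple[MultiplexVolume, tuple[int, int]]:
    """Discard ``n_pixels`` around each lateral border (z untouched).

    Returns the trimmed volume and the (y, x) offset of its origin in the
    original frame, so voxel centers can stay in original-frame coordinates.
    """
    if n_pixels < 0:
        raise ValueError("border width must be >= 0")
    nz, ny, nx = volume.dims
    if 2 * n_pixels >= ny or 2 * n_pixels >= nx:
        raise ValueError(
            f"border of {n_pixels} px leaves no interior in a {ny}x{nx} frame"
        )
    if n_pixels == 0:
        return volume, (0, 0)
    stacks = [
        ChannelStack(s.channel_name, s.marker,
                     s.data[:, n_pixels:ny - n_pixels, n_pixels:nx - n_pixels])
        for s in volume.stacks
    ]
    return (MultiplexVolume(stacks, fov_id=volume.fov_id,
                            pixel_size_nm=volume.pixel_size_nm),
            (n_pixels, n_pixels))


def nucleus_mask(phosphorus: ChannelStack | np.ndarray,
                 z_range: tuple[int, int] | None = None,
                 closing_radius: int = 3,
                 min_area: int = 64) -> np.ndarray:
    """Nucleus mask from the phosphorus (DNA) channel.

    Otsu threshold on the plane-summed image, morphological closing, hole
    filling, then removal of components below ``min_area`` pixels.
    """
    summed = sum_planes(phosphorus, z_range).astype(float)
    if not np.any(summed > 0):
        raise ValueError("phosphorus channel is empty; cannot build nucleus mask")
    if summed.min() == summed.max():
        return np.ones(summed.shape, dtype=bool)
    mask = summed > threshold_otsu(summed)
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius)).astype(bool)
    mask = ndimage.binary_fill_holes(mask)
    comp, n = ndimage.label(mask)
    if n:
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        mask = np.isin(comp, np.nonzero(sizes >= min_area)[0])
    if not mask.any():
        raise ValueError("no nucleus-sized component found in phosphorus channel")
    return mask
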