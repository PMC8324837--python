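"""Preset pipelines from raw volumes to neighborhood models.

Three published analysis recipes are encoded as presets:

* ``nuclear`` — conventional single-cell acquisition: (3, 3, 10) windows
  tiled inside the phosphorus-derived nucleus mask, z-scored channels,
  Ward clustering into 10 neighborhoods.
* ``iterative`` — low-current high-resolution acquisition: KNN density
  denoising, 100 px border trim, (10, 10, 5) windows at step (5, 5, 3),
  log2(x + 1e-4), Ward clustering (10 fine clusters, merged to a target
  count), Barnes-Hut t-SNE for display.
* ``multidrug`` — multi-FOV drug-resistance comparison: 12 px border trim,
  middle-40-plane slab, (3, 3, 7) windows at step (2, 2, 5), bottom-20%
  carbon filter, per-FOV 20-95 percentile normalisation (drug channel
  instead clipped globally to [0.01, 0.05] mean counts), 5000 voxels/FOV,
  t-SNE on all channels except carbon and drug, 40 embedding clusters
  merged to 7 neighborhoods.

Every size and threshold is a dataclass field, so scaled-down variants are
``dataclasses.replace`` away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import preprocess, voxels
from .io import MultiplexVolume
from .neighborhoods import (NeighborhoodModel, auto_merge_map,
                            cluster_on_embedding, embed_tsne,
                            hierarchical_cluster, merge_clusters, profile)

__all__ = ["Preset", "PRESETS", "featurize", "build_neighborhoods",
           "run_pipeline", "get_preset"]

logger = logging.getLogger(__name__)


@dataclass
class Preset:
    name: str
    window: tuple[int, int, int]                 # (x, y, z)
    step: tuple[int, int, int] | None = None     # None = tile by window
    border: int = 0
    z_planes: int | None = None                  # middle slab; None = all
    denoise: bool = False
    knn_k: int = 25
    denoise_channels: list[str] | None = None
    knn_cutoffs: dict[str, float] = field(default_factory=dict)
    nucleus_mask_channel: str | None = None
    carbon_filter_channel: str | None = None
    carbon_filter_fraction: float = 0.2
    sample_n: int | None = None
    normalization: str = "zscore"                # zscore | log2 | percentile
    percentile_lo: float = 20.0
    percentile_hi: float = 95.0
    clip_channel: str | None = None
    clip_lo: float = 0.01
    clip_hi: float = 0.05
    cluster_channels: list[str] | None = None    # None = all channels
    cluster_on: str = "features"                 # features | embedding
    k_initial: int = 10
    k_final: int | None = None                   # None = keep k_initial
    tsne_perplexity: float = 30.0
    exclude_neighborhoods: list[int] = field(default_factory=list)


PRESETS: dict[str, Preset] = {
    "nuclear": Preset(
        name="nuclear", window=(3, 3, 10), step=None, border=0,
        z_planes=40, nucleus_mask_channel="31P", sample_n=20000,
        normalization="zscore",
        cluster_channels=["197Au", "81Br", "31P", "19F", "127I"],
        cluster_on="features", k_initial=10,
    ),
    "iterative": Preset(
        name="iterative", window=(10, 10, 5), step=(5, 5, 3), border=100,
        denoise=True, sample_n=20000, normalization="log2",
        cluster_channels=["197Au", "81Br", "31P", "19F", "127I", "194Pt"],
        cluster_on="features", k_initial=10, k_final=None,
    ),
    "multidrug": Preset(
        name="multidrug", window=(3, 3, 7), step=(2, 2, 5), border=12,
        z_planes=40, carbon_filter_channel="12C", sample_n=5000,
        normalization="percentile", clip_channel="194Pt",
        cluster_channels=None,  # all except carbon and drug, see featurize
        cluster_on="embedding", k_initial=40, k_final=7,
    ),
}


def get_preset(name: str, **overrides) -> Preset:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides) if overrides else PRESETS[name]


def featurize(volume: MultiplexVolume, preset: Preset, seed: int = 0,
              truth_labels: np.ndarray | None = None) -> pd.DataFrame:
    """One volume -> voxel feature table per the preset (raw counts).

    Applies denoising, border trim (via the feature extractor), the middle-z
    slab, the nucleus mask and the carbon filter; sampling and normalisation
    happen later, across FOVs, in :func:`run_pipeline`. When a ground-truth
    label volume is supplied (phantom validation), the per-window majority
    label is carried along as a ``truth_label`` column through all filters.
    """
    vol = volume
    nz = vol.dims[0]
    z_range = (voxels.middle_z_range(nz, preset.z_planes)
               if preset.z_planes else (0, nz))
    if preset.denoise:
        vol = preprocess.denoise_volume(
            vol, k=preset.knn_k, cutoffs=preset.knn_cutoffs,
            channels=preset.denoise_channels, z_range=z_range,
        )
    table = voxels.sliding_window_features(
        vol, window=preset.window, step=preset.step, z_range=z_range,
        border=preset.border,
    )
    if truth_labels is not None:
        table["truth_label"] = voxels.majority_window_labels(
            np.asarray(truth_labels), window=preset.window, step=preset.step,
            z_range=z_range, border=preset.border,
        )
    logger.info("%s: %d voxels from %s", vol.fov_id, len(table), vol.dims)
    if preset.nucleus_mask_channel:
        mask = preprocess.nucleus_mask(
            vol.channel(preset.nucleus_mask_channel), z_range=z_range
        )
        table = voxels.mask_filter(table, mask)
        logger.info("%s: %d voxels inside nucleus mask", vol.fov_id, len(table))
    if preset.carbon_filter_channel:
        table = voxels.filter_low_carbon(
            table, channel=preset.carbon_filter_channel,
            fraction=preset.carbon_filter_fraction,
        )
        logger.info("%s: %d voxels after carbon filter", vol.fov_id, len(table))
    return table


def _normalize(table: pd.DataFrame, preset: Preset) -> pd.DataFrame:
    chans = voxels.channel_columns(table)
    if preset.normalization == "zscore":
        return voxels.zscore(table, chans)
    if preset.normalization == "log2":
        return voxels.log2_pseudocount(table, chans)
    if preset.normalization == "percentile":
        pct_chans = [c for c in chans if c != preset.clip_channel]
        out = voxels.percentile_normalize(
            table, pct_chans, lo=preset.percentile_lo,
            hi=preset.percentile_hi, per_group="fov_id",
        )
        if preset.clip_channel:
            out = voxels.clip_normalize(out, preset.clip_channel,
                                        preset.clip_lo, preset.clip_hi)
        return out
    raise ValueError(f"unknown normalization {preset.normalization!r}")


def build_neighborhoods(table: pd.DataFrame, preset: Preset,
                        seed: int = 0) -> NeighborhoodModel:
    """Cluster a normalised voxel table into final neighborhoods."""
    chans = preset.cluster_channels
    if chans is None:
        chans = [c for c in voxels.channel_columns(table)
                 if c not in ("12C", preset.clip_channel)]
    missing = [c for c in chans if c not in table.columns]
    if missing:
        raise ValueError(f"clustering channels {missing} not in table")
    X = table[chans].to_numpy(dtype=float)

    embedding = None
    if preset.cluster_on == "embedding":
        embedding = embed_tsne(X, perplexity=preset.tsne_perplexity, seed=seed)
        fine = cluster_on_embedding(embedding, k=preset.k_initial)
    else:
        fine = hierarchical_cluster(X, k=preset.k_initial)

    if preset.k_final and preset.k_final < preset.k_initial:
        fine_profiles = profile(table, fine, stat="mean", channels=chans)
        merge_map = auto_merge_map(fine_profiles, preset.k_final)
    else:
        merge_map = {int(l): int(l) for l in np.unique(fine)}
    final = merge_clusters(fine, merge_map)
    profiles = profile(table, final, stat="mean", channels=chans)
    return NeighborhoodModel(
        labels=final, k_initial=preset.k_initial,
        k_final=len(set(merge_map.values())), merge_map=merge_map,
        profiles=profiles, channels_used=list(chans), embedding=embedding,
    )


def run_pipeline(volumes: list[MultiplexVolume], preset: Preset,
                 seed: int = 0,
                 truth_labels: list[np.ndarray] | None = None,
                 ) -> tuple[pd.DataFrame, NeighborhoodModel]:
    """Featurize each volume, pool, sample per FOV, normalise, cluster.

    Returns the pooled normalised voxel table (row-aligned with the model's
    labels) and the fitted :class:`NeighborhoodModel`. ``truth_labels``
    (one label volume per input, phantom validation) adds a ``truth_label``
    column that survives sampling and filtering.
    """
    if truth_labels is None:
        tables = [featurize(v, preset, seed=seed) for v in volumes]
    else:
        tables = [featurize(v, preset, seed=seed, truth_labels=t)
                  for v, t in zip(volumes, truth_labels)]
    table = pd.concat(tables, ignore_index=True)
    if preset.sample_n:
        table = voxels.sample_voxels(table, preset.sample_n, seed=seed,
                                     per_group="fov_id")
        logger.info("sampled %d voxels per FOV (%d total)",
                    preset.sample_n, len(table))
    table = _normalize(table, preset)
    model = build_neighborhoods(table, preset, seed=seed)
    if preset.exclude_neighborhoods:
        keep = ~np.isin(model.labels, preset.exclude_neighborhoods)
        table = table.loc[keep].reset_index(drop=True)
        model.labels = model.labels[keep]
        if model.embedding is not None:
            model.embedding = model.embedding[keep]
    return table, model
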