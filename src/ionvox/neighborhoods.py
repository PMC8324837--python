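"""Neighborhood identification: clustering, embedding, merging, rendering.

Voxels with similar multichannel profiles are grouped into "neighborhoods"
(subcellular microenvironments such as nucleoli, nuclear speckles, hetero-
and euchromatin). Two published routes are supported: agglomerative (Ward)
clustering directly on normalized features, and clustering on a 2D
Barnes-Hut t-SNE embedding followed by a merge of the fine clusters into a
small number of annotated neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .voxels import channel_columns

__all__ = [
    "NeighborhoodModel",
    "hierarchical_cluster",
    "embed_tsne",
    "cluster_on_embedding",
    "merge_clusters",
    "auto_merge_map",
    "profile",
    "gate_embedding",
    "render_neighborhood_map",
]


@dataclass
class NeighborhoodModel:
    """Voxel -> neighborhood assignment with its provenance.

    ``labels`` are final (merged) 1-based neighborhood ids; ``merge_map``
    records how the ``k_initial`` fine clusters map onto the ``k_final``
    neighborhoods; ``profiles`` is the per-neighborhood channel summary.
    """

    labels: np.ndarray
    k_initial: int
    k_final: int
    merge_map: dict[int, int]
    profiles: pd.DataFrame
    channels_used: list[str]
    embedding: np.ndarray | None = None

    def __post_init__(self) -> None:
        observed = set(np.unique(self.labels).tolist())
        final = set(self.merge_map.values())
        if not observed <= final:
            raise ValueError(f"labels {observed - final} missing from merge map")

    def summary(self) -> str:
        sizes = pd.Series(self.labels).value_counts().sort_index()
        lines = [
            f"NeighborhoodModel: {self.k_initial} initial -> "
            f"{self.k_final} final neighborhoods, "
            f"{len(self.labels)} voxels, channels {self.channels_used}",
            "voxels per neighborhood: "
            + ", ".join(f"{k}: {v}" for k, v in sizes.items()),
            self.profiles.round(3).to_string(),
        ]
        return "\n".join(lines)


def hierarchical_cluster(features: np.ndarray | pd.DataFrame, k: int,
                         linkage_method: str = "ward",
                         metric: str = "euclidean") -> np.ndarray:
    """Agglomerative clustering cut at ``k`` clusters; labels are 1..k.

    Ward linkage on Euclidean distance by default; deterministic for a fixed
    row order.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if k == n:
        return np.arange(1, n + 1)
    Z = linkage(X, method=linkage_method, metric=metric)
    return fcluster(Z, t=k, criterion="maxclust")


def embed_tsne(features: np.ndarray | pd.DataFrame, perplexity: float = 30.0,
               seed: int = 0, n_iter: int = 1000) -> np.ndarray:
    """2D Barnes-Hut t-SNE embedding; deterministic given the seed."""
    from sklearn.manifold import TSNE

    X = np.asarray(features, dtype=float)
    if len(X) <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {len(X)} voxels "
            f"(need n > 3 * perplexity)"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                max_iter=n_iter, init="pca", method="barnes_hut")
    return tsne.fit_transform(X)


def cluster_on_embedding(coords: np.ndarray, k: int = 40) -> np.ndarray:
    """Ward clustering on the 2D embedding (Euclidean distance)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2) embedding coordinates")
    return hierarchical_cluster(coords, k, metric="euclidean")


def merge_clusters(labels: np.ndarray, merge_map: dict[int, int]) -> np.ndarray:
    """Relabel fine clusters by the (total) merge map."""
    labels = np.asarray(labels)
    observed = np.unique(labels)
    missing = [int(l) for l in observed if l not in merge_map]
    if missing:
        raise ValueError(f"merge map does not cover labels {missing}")
    lut = {int(k): int(v) for k, v in merge_map.items()}
    return np.array([lut[int(l)] for l in labels])


def auto_merge_map(profiles: pd.DataFrame, k_final: int,
                   metric: str = "euclidean",
                   linkage_method: str = "ward") -> dict[int, int]:
    """Reproducible stand-in for manual annotation: cluster the fine-cluster
    profiles into ``k_final`` neighborhoods and map each fine id to its
    profile-cluster id.

    Ward on Euclidean profile distance by default: correlation distance is
    unstable for near-constant profiles (e.g. a background/cytoplasm cluster
    that is low in every channel), which Euclidean handles cleanly.
    """
    if k_final > len(profiles):
        raise ValueError(
            f"cannot merge {len(profiles)} clusters into {k_final}"
        )
    if k_final == len(profiles):
        return {int(i): int(i) for i in profiles.index}
    X = profiles.to_numpy(dtype=float)
    Z = linkage(pdist(X, metric=metric), method=linkage_method)
    grouped = fcluster(Z, t=k_final, criterion="maxclust")
    return {int(fine): int(g) for fine, g in zip(profiles.index, grouped)}


def profile(table: pd.DataFrame, labels: np.ndarray, stat: str = "mean",
            row_normalize: str = "none",
            channels: list[str] | None = None) -> pd.DataFrame:
    """Neighborhood x channel summary matrix (mean or median).

    ``row_normalize='zscore'`` z-scores each row (population sd) for
    heatmap display.
    """
    if len(labels) != len(table):
        raise ValueError("labels must align with table rows")
    if stat not in {"mean", "median"}:
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    chans = channels or channel_columns(table)
    if len(table) == 0:
        raise ValueError("cannot profile an empty table")
    out = table[chans].groupby(np.asarray(labels)).agg(stat)
    out.index.name = "neighborhood"
    if row_normalize == "zscore":
        vals = out.to_numpy(dtype=float)
        sd = vals.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        out.loc[:, :] = (vals - vals.mean(axis=1, keepdims=True)) / sd
    elif row_normalize != "none":
        raise ValueError(f"unknown row_normalize {row_normalize!r}")
    return out


def gate_embedding(coords: np.ndarray, polygon) -> np.ndarray:
    """Select embedding points inside or on the boundary of a polygon gate."""
    import shapely
    from shapely import Polygon

    poly = Polygon(polygon)
    if not poly.is_valid or poly.area == 0:
        raise ValueError("degenerate gating polygon")
    coords = np.asarray(coords, dtype=float)
    return shapely.covers(poly, shapely.points(coords))


def render_neighborhood_map(table: pd.DataFrame, labels: np.ndarray,
                            frame_dims: tuple[int, int, int],
                            mode: str = "projection_xy") -> np.ndarray:
    """Paint each voxel's window footprint with its neighborhood id.

    ``frame_dims`` is the original (z, y, x) frame. Unassigned pixels are 0.
    ``mode='volume'`` returns the 3D label volume (later rows overwrite
    earlier ones where windows overlap); ``mode='projection_xy'`` collapses
    z by majority nonzero label per (y, x) pixel.
    """
    nz, ny, nx = frame_dims
    vol = np.zeros(frame_dims, dtype=np.int32)
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValueError("labels must align with table rows")
    for row, lab in zip(table.itertuples(index=False), labels):
        wx, wy, wz = int(row.wx), int(row.wy), int(row.wz)
        x0 = int(round(row.center_x - (wx - 1) / 2))
        y0 = int(round(row.center_y - (wy - 1) / 2))
        z0 = int(round(row.center_z - (wz - 1) / 2))
        if (x0 < 0 or y0 < 0 or z0 < 0 or x0 + wx > nx or y0 + wy > ny
                or z0 + wz > nz):
            raise ValueError(
                f"voxel footprint at ({row.center_x}, {row.center_y}, "
                f"{row.center_z}) falls outside frame {frame_dims}"
            )
        vol[z0:z0 + wz, y0:y0 + wy, x0:x0 + wx] = int(lab)
    if mode == "volume":
        return vol
    if mode != "projection_xy":
        raise ValueError(f"unknown mode {mode!r}")
    k_max = int(vol.max())
    if k_max == 0:
        return np.zeros((ny, nx), dtype=np.int32)
    counts = np.zeros((k_max + 1, ny, nx), dtype=np.int32)
    for lab in range(1, k_max + 1):
        counts[lab] = (vol == lab).sum(axis=0)
    proj = counts[1:].argmax(axis=0) + 1
    proj[counts[1:].max(axis=0) == 0] = 0
    return proj.astype(np.int32)
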