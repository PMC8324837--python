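"""Figure-style rendering of pipeline outputs (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .interactions import InteractionResult
from .neighborhoods import NeighborhoodModel

__all__ = ["profile_heatmap", "embedding_scatter", "neighborhood_violin",
           "interaction_graph_plot"]


def profile_heatmap(model: NeighborhoodModel, row_normalize: bool = True,
                    ax=None):
    """Neighborhood x channel mean-expression heatmap (rows z-scored for
    display by default)."""
    data = model.profiles.to_numpy(dtype=float)
    if row_normalize:
        sd = data.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        data = (data - data.mean(axis=1, keepdims=True)) / sd
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * data.shape[1],
                                      1 + 0.4 * data.shape[0]))
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(data.shape[1]), model.profiles.columns, rotation=45)
    ax.set_yticks(range(data.shape[0]), model.profiles.index)
    ax.set_xlabel("channel")
    ax.set_ylabel("neighborhood")
    ax.figure.colorbar(im, ax=ax, label="z-score" if row_normalize else "mean")
    return ax


def embedding_scatter(model: NeighborhoodModel, ax=None, s: float = 2.0):
    """t-SNE embedding coloured by final neighborhood."""
    if model.embedding is None:
        raise ValueError("model has no embedding")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(model.embedding[:, 0], model.embedding[:, 1],
                    c=model.labels, cmap="tab20", s=s, linewidths=0)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.figure.colorbar(sc, ax=ax, label="neighborhood")
    return ax


def neighborhood_violin(table: pd.DataFrame, labels: np.ndarray,
                        channel: str, ax=None):
    """Violin plot of a channel's per-voxel values by neighborhood."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    data = [table.loc[labels == i, channel].to_numpy(dtype=float)
            for i in ids]
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.8 * len(ids), 4))
    ax.violinplot(data, positions=range(len(ids)), showmedians=True)
    ax.set_xticks(range(len(ids)), ids)
    ax.set_xlabel("neighborhood")
    ax.set_ylabel(channel)
    return ax


def interaction_graph_plot(result: InteractionResult, alpha: float = 0.05,
                           node_sizes: dict | None = None, ax=None):
    """Significance graph: nodes are neighborhoods, edges the significant
    interactions (solid enriched, dashed depleted, width ~ |log2 FE|)."""
    import networkx as nx

    from .interactions import to_graph

    g = to_graph(result, alpha)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pos = nx.circular_layout(g)
    sizes = [300 * (node_sizes or {}).get(n, 1.0) for n in g.nodes]
    nx.draw_networkx_nodes(g, pos, ax=ax, node_size=sizes,
                           node_color=range(len(g.nodes)), cmap="tab10")
    nx.draw_networkx_labels(g, pos, ax=ax)
    for u, v, attrs in g.edges(data=True):
        w = attrs["weight"]
        width = 0.5 + 2 * min(abs(w) if np.isfinite(w) else 3.0, 3.0)
        style = "solid" if attrs["sign"] > 0 else "dashed"
        nx.draw_networkx_edges(g, pos, edgelist=[(u, v)], ax=ax,
                               width=width, style=style)
    ax.set_axis_off()
    return ax
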