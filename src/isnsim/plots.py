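"""Optional static figures (matplotlib): rasters, population rates,
adjacency heat map and the population graph with size/width minima."""

from __future__ import annotations

import numpy as np

from .analysis import ConnectivitySummary, RateSeries
from .engine import SpikeData


def plot_raster(spikes: SpikeData, ax=None, colors=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    colors = colors or {}
    for name, (lo, hi) in spikes.pop_slices.items():
        mask = (spikes.ids >= lo) & (spikes.ids < hi)
        ax.plot(spikes.times[mask], spikes.ids[mask], ".", ms=1,
                color=colors.get(name), label=name)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("cell id")
    ax.legend(loc="upper right", markerscale=8)
    return ax


def plot_rates(series: dict, ax=None):
    """``series``: label -> RateSeries."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for label, rs in series.items():
        ax.plot(rs.times, rs.rate, label=label)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("rate (Hz)")
    ax.legend()
    return ax


def plot_adjacency(summary: ConnectivitySummary, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    lim = np.abs(summary.adjacency).max() or 1.0
    im = ax.imshow(summary.adjacency, cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(len(summary.populations)), summary.populations)
    ax.set_yticks(range(len(summary.populations)), summary.populations)
    ax.set_xlabel("postsynaptic")
    ax.set_ylabel("presynaptic")
    ax.figure.colorbar(im, ax=ax, label="mean summed conductance (nS)")
    return ax


def plot_population_graph(summary: ConnectivitySummary, ax=None):
    import matplotlib.pyplot as plt
    import networkx as nx

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    g = nx.MultiDiGraph()
    for node in summary.graph["nodes"]:
        g.add_node(node["name"], size=node["size"], role=node["role"])
    for e in summary.graph["edges"]:
        g.add_edge(e["pre"], e["post"], width=e["width"], sign=e["sign"])
    pos = nx.circular_layout(g)
    sizes = [4000 * g.nodes[n]["size"] for n in g.nodes]
    colors = ["tab:red" if g.nodes[n]["role"] == "E" else "tab:blue" for n in g.nodes]
    nx.draw_networkx_nodes(g, pos, node_size=sizes, node_color=colors, ax=ax)
    nx.draw_networkx_labels(g, pos, ax=ax)
    for u, v, data in g.edges(data=True):
        nx.draw_networkx_edges(
            g, pos, [(u, v)], width=data["width"],
            edge_color="tab:red" if data["sign"] == "+" else "tab:blue",
            connectionstyle="arc3,rad=0.15", ax=ax,
        )
    ax.set_axis_off()
    return ax
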