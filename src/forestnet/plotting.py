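"""Optional matplotlib rendering of networks and summary tables.

Thin display layer over the exported tables; nothing here is load-bearing.
Requires the ``plots`` extra (matplotlib).
"""

from __future__ import annotations

import numpy as np


def _get_ax(ax, figsize):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=figsize)
    return ax


def plot_network(net, ax=None):
    """Draw a decision network: node size ∝ importance, colour = influence
    (blue positive, orange negative), dashed edges for opposite directions."""
    import networkx as nx

    ax = _get_ax(ax, (8, 8))
    g = net.graph
    if g.number_of_nodes() == 0:
        ax.set_axis_off()
        return ax
    pos = nx.spring_layout(g, seed=7)
    imp = np.array([d.get("importance", 0.0) for _, d in g.nodes(data=True)])
    scale = imp / imp.max() if imp.max() > 0 else np.zeros_like(imp)
    colors = [
        "#2166ac" if d.get("influence", 0.0) >= 0 else "#e08214"
        for _, d in g.nodes(data=True)
    ]
    nx.draw_networkx_nodes(
        g, pos, ax=ax, node_size=200 + 1200 * scale, node_color=colors,
        alpha=0.85,
    )
    for a, b, d in g.edges(data=True):
        style = "solid" if d.get("direction", "solid") == "solid" else "dashed"
        width = 0.5 + 3.0 * d.get("importance_norm", 0.0)
        color = "#2166ac" if d.get("influence", 0.0) > 0 else (
            "#e08214" if d.get("influence", 0.0) < 0 else "#999999"
        )
        nx.draw_networkx_edges(
            g, pos, edgelist=[(a, b)], ax=ax, style=style, width=width,
            edge_color=color, alpha=0.8,
        )
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    ax.set_axis_off()
    return ax


def plot_importance_influence(table, ax=None, top: int = 20):
    """Bar plot of per-feature importance with per-level influence markers;
    absent levels are left blank."""
    ax = _get_ax(ax, (7, 0.4 * top + 2))
    feats = (
        table.drop_duplicates("feature")
        .sort_values("importance", ascending=False)
        .head(top)["feature"]
        .tolist()
    )
    sub = table[table["feature"].isin(feats)]
    ypos = {f: i for i, f in enumerate(reversed(feats))}
    ax.barh(
        [ypos[f] for f in feats],
        sub.drop_duplicates("feature").set_index("feature").loc[feats, "importance"],
        color="#bbbbbb",
    )
    for _, row in sub.iterrows():
        if not row["present"]:
            continue
        color = "#2166ac" if row["influence"] >= 0 else "#e08214"
        ax.plot(
            0, ypos[row["feature"]], marker="s", color=color, markersize=6,
            clip_on=False,
        )
    ax.set_yticks(list(ypos.values()))
    ax.set_yticklabels(list(ypos.keys()), fontsize=8)
    ax.set_xlabel("feature importance F")
    return ax
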