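"""Decision networks and the importance/influence summary table.

Nodes are (feature, admitted level-set) pseudo-features occurring in the
stable decision ensemble (e.g. ``Group=a``, ``V1__High``); node size/colour
carry importance and influence.  Edges are pairwise interaction effects
between pseudo-features that are co-active, with positive interaction
importance, in at least one stable decision; the pair-direction sign η is
rendered solid (same direction) or dashed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .metrics import DecisionMetrics, aggregate_node_metrics
from .regularize import StableEnsemble

logger = logging.getLogger(__name__)


@dataclass
class DecisionNetwork:
    """An undirected feature-level interaction network with provenance."""

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_frame(self) -> pd.DataFrame:
        rows = [
            {"node": n, **attrs} for n, attrs in sorted(self.graph.nodes(data=True))
        ]
        cols = ["node", "feature", "levels", "entities", "importance",
                "importance_norm", "influence", "n_active"]
        return pd.DataFrame(rows, columns=cols)

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"node_a": min(a, b), "node_b": max(a, b), **attrs}
            for a, b, attrs in self.graph.edges(data=True)
        ]
        rows.sort(key=lambda r: (r["node_a"], r["node_b"]))
        cols = ["node_a", "node_b", "importance", "importance_norm", "influence",
                "eta", "direction", "n_active"]
        return pd.DataFrame(rows, columns=cols)


def _subset_metrics(stable: StableEnsemble,
                    min_prob: Optional[float]) -> DecisionMetrics:
    keep = stable.stable_mask(min_prob)
    dm = stable.pool_metrics
    return dataclasses.replace(dm, present=dm.present & keep)


def build_network(
    stable: StableEnsemble,
    disc_features: Optional[set] = None,
    min_prob: Optional[float] = None,
    provenance: Optional[dict] = None,
) -> DecisionNetwork:
    """Build the decision network from a stable ensemble.

    ``min_prob`` overrides the stability threshold (used by TP/FP curves);
    an empty stable ensemble yields an empty network.
    """
    dm = _subset_metrics(stable, min_prob)
    nodes, edges = aggregate_node_metrics(stable.pool, dm, disc_features)
    g = nx.Graph()
    max_imp = float(nodes["importance"].max()) if len(nodes) else 0.0
    for _, r in nodes.iterrows():
        g.add_node(
            r["node"],
            feature=r["feature"],
            levels=r["levels"],
            entities=r["entities"],
            importance=float(r["importance"]),
            importance_norm=(
                float(r["importance"]) / max_imp if max_imp > 0 else 0.0
            ),
            influence=float(r["influence"]),
            n_active=int(r["n_active"]),
        )
    edges = edges[edges["any_positive_delta"]]
    max_eimp = float(edges["importance"].max()) if len(edges) else 0.0
    for _, r in edges.iterrows():
        if r["node_a"] == r["node_b"]:
            continue
        g.add_edge(
            r["node_a"],
            r["node_b"],
            importance=float(r["importance"]),
            importance_norm=(
                float(r["importance"]) / max_eimp if max_eimp > 0 else 0.0
            ),
            influence=float(r["influence"]),
            eta=float(r["eta"]),
            direction="solid" if r["eta"] > 0 else "dashed",
            n_active=int(r["n_active"]),
        )
    prov = {
        "q": stable.q,
        "d_mean": stable.d_mean,
        "pi_thr": stable.params.pi_thr,
        "alpha": stable.params.alpha_reg,
        "B": stable.params.B,
        "seed": stable.params.seed,
    }
    if provenance:
        prov.update(provenance)
    return DecisionNetwork(graph=g, provenance=prov)


def reduce_network(net: DecisionNetwork, max_path: int = 3) -> DecisionNetwork:
    """Remove lowest-importance edges until every connected component has
    diameter ≤ ``max_path``.

    Deterministic threshold scan: candidate thresholds are −inf plus the
    distinct edge importances in ascending order; edges strictly above the
    threshold are kept; the first qualifying subgraph is returned.  Node
    attributes are untouched; the result is always a subgraph of the input.
    """
    if max_path < 1:
        raise ValueError("max_path must be >= 1")
    g = net.graph
    importances = sorted({d["importance"] for _, _, d in g.edges(data=True)})
    for thr in [-np.inf] + importances:
        keep = [
            (a, b) for a, b, d in g.edges(data=True) if d["importance"] > thr
        ]
        sub = g.edge_subgraph(keep).copy() if keep else nx.Graph()
        sub.add_nodes_from(g.nodes(data=True))
        if _max_component_diameter(sub) <= max_path:
            return DecisionNetwork(
                graph=sub,
                provenance={**net.provenance, "reduced_max_path": max_path},
            )
    raise AssertionError("unreachable: the empty graph always qualifies")


def _max_component_diameter(g: nx.Graph) -> int:
    worst = 0
    for comp in nx.connected_components(g):
        if len(comp) > 1:
            worst = max(worst, nx.diameter(g.subgraph(comp)))
    return worst


def export_network(net: DecisionNetwork, graphml_path=None,
                   nodes_tsv=None, edges_tsv=None) -> None:
    """Write GraphML and/or paired node/edge TSVs (losslessly reimportable)."""
    if graphml_path is not None:
        g = net.graph.copy()
        for key, val in net.provenance.items():
            g.graph[str(key)] = str(val)
        nx.write_graphml(g, graphml_path)
    if nodes_tsv is not None:
        net.nodes_frame().to_csv(nodes_tsv, sep="\t", index=False,
                                 float_format="%.10g")
    if edges_tsv is not None:
        net.edges_frame().to_csv(edges_tsv, sep="\t", index=False,
                                 float_format="%.10g")


def read_network(graphml_path) -> DecisionNetwork:
    g = nx.read_graphml(graphml_path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    prov = dict(g.graph)
    return DecisionNetwork(graph=nx.Graph(g), provenance=prov)


def importance_influence_table(
    stable: StableEnsemble,
    disc_features: Optional[set] = None,
    min_prob: Optional[float] = None,
) -> pd.DataFrame:
    """Long summary table: feature importance plus per-level influence.

    Importance is summed across a feature's level-sets.  A level's influence
    averages the importance-weighted prediction shift over the stable
    decisions whose admitted set contains the level; levels appearing in no
    stable decision are flagged absent (blank influence).
    """
    data = stable.data
    dm = _subset_metrics(stable, min_prob)
    I = dm.importance
    feat = dm.feat[dm.present[dm.feat["decision"].to_numpy()]]
    rows = feat.assign(I=I[feat["decision"].to_numpy()])

    # per-feature totals
    totals = {}
    for name, g in rows.groupby("feature"):
        totals[name] = float((g["delta"] * g["I"]).sum())

    # per-(feature, level) influence
    acc: dict = {}
    for _, r in rows.iterrows():
        d = stable.pool.decisions[int(r["decision"])]
        cond = d.condition(r["feature"])
        levels = cond.levels if cond.levels is not None else ("",)
        for lvl in levels:
            key = (r["feature"], lvl)
            num, den = acc.get(key, (0.0, 0.0))
            acc[key] = (num + r["ydiff"] * r["I"], den + r["I"])

    out = []
    for feature in sorted(totals):
        if data.is_numeric(feature):
            all_levels = [""]
        else:
            all_levels = list(data.levels(feature))
        for lvl in all_levels:
            key = (feature, lvl)
            if key in acc:
                num, den = acc[key]
                influence = num / den if den != 0.0 else 0.0
                present = True
            else:
                influence, present = np.nan, False
            out.append(
                {
                    "feature": feature,
                    "level": lvl,
                    "importance": totals[feature],
                    "influence": influence,
                    "present": present,
                }
            )
    return pd.DataFrame(
        out, columns=["feature", "level", "importance", "influence", "present"]
    )
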