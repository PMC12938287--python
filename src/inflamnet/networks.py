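"""Bipartite transfer-entropy networks and betweenness-centrality summaries.

Per condition (stimulus level x aging preset) the pooled distribution of
defined pairwise transfer entropies yields an edge criterion: its first and
third quartiles, bracketing the most likely values.  A macrophage-fibroblast
pair whose transfer entropy falls inside [Q1, Q3] receives an (undirected)
edge; every slot is a node even when isolated.  Normalised shortest-path
betweenness centrality is computed per node, summed per part, and the
fibroblast/macrophage sum ratio F/M summarises which side of the bipartite
graph carries the network's shortest paths: F/M > 1 means fibroblast-centred
topology, F/M < 1 macrophage-centred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .infoflow import TEMatrix

MACROPHAGE_PART = "macrophage"
FIBROBLAST_PART = "fibroblast"


@dataclass
class EdgeCriterion:
    """Quartile bounds of a TE distribution, plus its histogram mode."""

    lower: float
    upper: float
    mode: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("criterion lower bound exceeds upper bound")

    def contains(self, value: float) -> bool:
        return np.isfinite(value) and self.lower <= value <= self.upper


def edge_criterion(te_values, histogram_bins: int = 20) -> EdgeCriterion:
    """Build the [Q1, Q3] edge criterion from pooled defined TE values.

    Quartiles use the linear-interpolation convention; the mode (midpoint of
    the tallest of *histogram_bins* equal bins over the value range) is
    reported as a diagnostic reference point.  Fewer than 4 defined values
    raise an error.
    """
    vals = np.asarray(te_values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 4:
        raise ValueError(f"need >= 4 defined TE values for a criterion, got {vals.size}")
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    if vals.max() > vals.min():
        hist, edges = np.histogram(vals, bins=histogram_bins)
        k = int(np.argmax(hist))
        mode = float((edges[k] + edges[k + 1]) / 2.0)
    else:
        mode = float(vals[0])
    return EdgeCriterion(lower=float(q1), upper=float(q3), mode=mode)


@dataclass
class BipartiteTENetwork:
    """Thresholded macrophage-fibroblast graph with centrality annotations."""

    graph: nx.Graph
    centrality: Optional[dict] = field(default=None)

    def nodes_in_part(self, part: str) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["part"] == part]


def build_network(te: TEMatrix, criterion: EdgeCriterion) -> BipartiteTENetwork:
    """Generate edges for pairs whose TE lies inside the criterion.

    All macrophage and fibroblast slots appear as nodes (named ``M<slot>``
    and ``F<slot>``) even when isolated; missing (NaN) entries never produce
    edges.  The graph is undirected, matching the bipartite representation
    on which ordinary betweenness is computed.
    """
    g = nx.Graph()
    for slot in te.macrophage_slots:
        g.add_node(f"M{int(slot)}", part=MACROPHAGE_PART, slot=int(slot), bipartite=0)
    for slot in te.fibroblast_slots:
        g.add_node(f"F{int(slot)}", part=FIBROBLAST_PART, slot=int(slot), bipartite=1)
    for i, m in enumerate(te.macrophage_slots):
        for j, f in enumerate(te.fibroblast_slots):
            v = te.values[i, j]
            if criterion.contains(v):
                g.add_edge(f"M{int(m)}", f"F{int(f)}", te=float(v))
    return BipartiteTENetwork(graph=g)


def betweenness(network: BipartiteTENetwork) -> dict:
    """Normalised shortest-path betweenness centrality per node.

    Standard unweighted betweenness, divided by (n-1)(n-2)/2 for n graph
    nodes; isolated nodes score 0.  The result is cached on the network.
    """
    bc = nx.betweenness_centrality(network.graph, normalized=True)
    network.centrality = bc
    return bc


def fm_ratio(network: BipartiteTENetwork) -> float:
    """Ratio of summed fibroblast to summed macrophage betweenness.

    Returns NaN (an undefined flag, not an error) when the macrophage sum is
    zero — e.g. for an edgeless network.
    """
    bc = network.centrality if network.centrality is not None else betweenness(network)
    parts = nx.get_node_attributes(network.graph, "part")
    f_sum = sum(v for n, v in bc.items() if parts[n] == FIBROBLAST_PART)
    m_sum = sum(v for n, v in bc.items() if parts[n] == MACROPHAGE_PART)
    if m_sum == 0:
        return float("nan")
    return f_sum / m_sum


@dataclass
class ConditionSummary:
    """Replicate-level network summary for one (stimulus, aging) condition."""

    criterion: EdgeCriterion
    networks: list
    fm_ratios: np.ndarray            # one entry per replicate (NaN = undefined)
    mean_fm: float
    fm_stderr: float
    macrophage_betweenness: np.ndarray  # pooled over replicates and nodes
    fibroblast_betweenness: np.ndarray


def condition_summary(te_matrices: list[TEMatrix]) -> ConditionSummary:
    """Pool TE values across replicates, then build one network per replicate.

    The edge criterion comes from the pooled distribution of all defined TE
    entries of the condition; each replicate then gets its own network, F/M
    ratio and per-node betweenness.  The summary reports the mean F/M over
    replicates with a defined ratio, its standard error (sample sd / sqrt(n),
    0 for a single replicate), and the pooled per-part betweenness values.
    """
    if not te_matrices:
        raise ValueError("need at least one replicate TE matrix")
    pooled = np.concatenate([tm.defined_values() for tm in te_matrices])
    criterion = edge_criterion(pooled)

    networks, fms, mac_bc, fib_bc = [], [], [], []
    for tm in te_matrices:
        net = build_network(tm, criterion)
        bc = betweenness(net)
        parts = nx.get_node_attributes(net.graph, "part")
        mac_bc.extend(v for n, v in bc.items() if parts[n] == MACROPHAGE_PART)
        fib_bc.extend(v for n, v in bc.items() if parts[n] == FIBROBLAST_PART)
        fms.append(fm_ratio(net))
        networks.append(net)

    fms = np.asarray(fms, dtype=float)
    defined = fms[np.isfinite(fms)]
    mean_fm = float(defined.mean()) if defined.size else float("nan")
    if defined.size > 1:
        stderr = float(defined.std(ddof=1) / np.sqrt(defined.size))
    else:
        stderr = 0.0 if defined.size == 1 else float("nan")
    return ConditionSummary(
        criterion=criterion,
        networks=networks,
        fm_ratios=fms,
        mean_fm=mean_fm,
        fm_stderr=stderr,
        macrophage_betweenness=np.asarray(mac_bc),
        fibroblast_betweenness=np.asarray(fib_bc),
    )


def write_graphml(network: BipartiteTENetwork, path) -> None:
    nx.write_graphml(network.graph, path)


def write_edgelist(network: BipartiteTENetwork, path) -> None:
    """Tab-separated edge list: m_node, f_node, te_value."""
    with open(path, "w") as fh:
        fh.write("m_node\tf_node\tte\n")
        for u, v, d in sorted(network.graph.edges(data=True)):
            m, f = (u, v) if u.startswith("M") else (v, u)
            fh.write(f"{m}\t{f}\t{d['te']:.6f}\n")
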