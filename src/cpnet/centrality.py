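"""Degree/betweenness centrality and hub-bottleneck classification.

A node is a hub (H) when its degree strictly exceeds the network's mean
degree, and a bottleneck (B) when its betweenness strictly exceeds the mean
betweenness; the four classes H-B, H-NB, NH-B, NH-NB partition the nodes.
Betweenness is the Freeman/Brandes pair-fraction form: for each unordered
pair s != t the node receives the fraction of shortest s-t paths passing
through it, endpoints excluded, edges unweighted, unreachable pairs
contributing zero. Quarters re-rank the H-B nodes against the medians of
degree and betweenness taken over H-B nodes only: Q4 exceeds both medians,
Q3 only the degree median, Q2 only the betweenness median, Q1 neither.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CpnetWarning, InputError

HB = "H-B"
H_NB = "H-NB"
NH_B = "NH-B"
NH_NB = "NH-NB"


@dataclass(frozen=True)
class CentralityThresholds:
    degree_mean: float
    betweenness_mean: float
    degree_median_hb: float = float("nan")
    betweenness_median_hb: float = float("nan")


def compute_centralities(net: nx.Graph, include_chemicals: bool = True) -> pd.DataFrame:
    """Per-node degree and betweenness records, sorted by node id.

    With ``include_chemicals`` false, chemical nodes are removed before the
    analysis (they then appear in no record).
    """
    if include_chemicals:
        g = net
    else:
        g = net.subgraph(
            [n for n, d in net.nodes(data=True) if d.get("kind") != "chemical"]
        )
    if g.number_of_nodes() < 2:
        raise InputError("centrality needs >= 2 nodes")
    btw = nx.betweenness_centrality(g, normalized=False, weight=None)
    records = pd.DataFrame(
        {
            "node": sorted(g.nodes),
        }
    )
    records["kind"] = [g.nodes[n].get("kind", "protein") for n in records["node"]]
    records["degree"] = [g.degree[n] for n in records["node"]]
    records["betweenness"] = [btw[n] for n in records["node"]]
    return records


def classify_hb(records: pd.DataFrame):
    """Assign H/B flags against the network-average thresholds (strict >)."""
    deg_mean = float(records["degree"].mean())
    btw_mean = float(records["betweenness"].mean())
    is_h = records["degree"] > deg_mean
    is_b = records["betweenness"] > btw_mean
    hb_class = np.where(
        is_h & is_b, HB, np.where(is_h, H_NB, np.where(is_b, NH_B, NH_NB))
    )
    out = records.copy()
    out["hb_class"] = hb_class
    return out, CentralityThresholds(deg_mean, btw_mean)


def hb_subnetwork(net: nx.Graph, records: pd.DataFrame) -> nx.Graph:
    """Induced subgraph on the H-B nodes (all edges between them kept)."""
    hb_nodes = list(records.loc[records["hb_class"] == HB, "node"])
    if not hb_nodes:
        warnings.warn("no H-B nodes; subnetwork is empty", CpnetWarning)
    return net.subgraph(hb_nodes).copy()


def assign_quarters(records: pd.DataFrame):
    """Quarter the H-B nodes by the H-B medians of degree and betweenness."""
    hb = records[records["hb_class"] == HB]
    if hb.empty:
        raise InputError("quarter assignment needs >= 1 H-B node")
    deg_med = float(hb["degree"].median())
    btw_med = float(hb["betweenness"].median())
    out = records.copy()
    quarters = []
    for _, row in out.iterrows():
        if row["hb_class"] != HB:
            quarters.append("none")
            continue
        hi_d = row["degree"] > deg_med
        hi_b = row["betweenness"] > btw_med
        quarters.append("Q4" if hi_d and hi_b else "Q3" if hi_d else "Q2" if hi_b else "Q1")
    out["quarter"] = quarters
    return out, deg_med, btw_med


def analyze_network(net: nx.Graph, include_chemicals: bool = True):
    """Convenience: centralities + H-B classes (+ quarters when any H-B)."""
    records = compute_centralities(net, include_chemicals=include_chemicals)
    records, thresholds = classify_hb(records)
    if (records["hb_class"] == HB).any():
        records, deg_med, btw_med = assign_quarters(records)
        thresholds = CentralityThresholds(
            thresholds.degree_mean, thresholds.betweenness_mean, deg_med, btw_med
        )
    else:
        records = records.copy()
        records["quarter"] = "none"
    return records, thresholds


def hb_nodes(records: pd.DataFrame) -> set:
    return set(records.loc[records["hb_class"] == HB, "node"])


def consensus_hb(classifications) -> tuple:
    """Intersection of >= 2 H-B node sets plus the full Venn partition.

    Returns ``(consensus, venn)`` where ``venn`` maps each node to its
    membership pattern, a tuple of booleans per input set.
    """
    sets = [set(s) for s in classifications]
    if len(sets) < 2:
        raise InputError("consensus needs >= 2 node sets")
    consensus = set.intersection(*sets)
    venn = {}
    for node in set.union(*sets):
        venn[node] = tuple(node in s for s in sets)
    return consensus, venn
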