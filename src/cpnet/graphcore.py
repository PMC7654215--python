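"""Network construction, filtering, combination and annotation.

Networks are simple undirected :class:`networkx.Graph` objects whose nodes
carry a ``kind`` attribute (protein or chemical) and whose edges carry a
``confidence`` in [0, 1]. The chain mirrors the analysis: build a PPI
network from an edge table at a confidence cutoff, attach chemical nodes to
form a CP-PPI network, select disease genes, and intersect two networks to
obtain their common topology.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import pandas as pd

from .errors import CpnetWarning, EmptyResultError, InputError
from .netio import DiseaseAssociationTable, InteractionTable, normalize_edges

log = logging.getLogger(__name__)


def build_network(table: InteractionTable, confidence_cutoff: float = 0.400) -> nx.Graph:
    """Keep edges with confidence >= cutoff (inclusive); drop isolated inputs.

    Nodes are the endpoints of retained edges only, so the result never
    contains isolated nodes.
    """
    if not 0.0 <= confidence_cutoff <= 1.0:
        raise InputError("confidence_cutoff must lie in [0, 1]")
    edges = table.edges
    keep = edges["confidence"] >= confidence_cutoff
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("confidence filter %.3f dropped %d edge(s)", confidence_cutoff, n_dropped)
    kept = edges[keep]
    if kept.empty:
        raise EmptyResultError(
            f"no edges at confidence >= {confidence_cutoff:.3f} "
            f"({len(edges)} input edges, max confidence "
            f"{edges['confidence'].max():.3f})"
        )
    g = nx.Graph()
    for a, b, conf, ka, kb in kept[
        ["node_a", "node_b", "confidence", "kind_a", "kind_b"]
    ].itertuples(index=False):
        g.add_node(a, kind=ka)
        g.add_node(b, kind=kb)
        g.add_edge(a, b, confidence=float(conf))
    return g


def select_disease_genes(
    table: DiseaseAssociationTable, confidence_cutoff: float, top_n: int
) -> list:
    """Rows passing the cutoff, by confidence desc then id asc, first top_n."""
    if top_n < 1:
        raise InputError("top_n must be >= 1")
    rows = table.rows[table.rows["confidence"] >= confidence_cutoff]
    if rows.empty:
        warnings.warn("no disease genes pass the confidence cutoff", CpnetWarning)
        return []
    rows = rows.sort_values(
        ["confidence", "gene"], ascending=[False, True], kind="mergesort"
    )
    return list(rows["gene"].head(top_n))


def attach_chemicals(
    net: nx.Graph, chem_table: InteractionTable, confidence_cutoff: float = 0.400
) -> nx.Graph:
    """Add chemical nodes and their passing edges to a copy of ``net``.

    Chemical-protein edges whose protein endpoint is absent from the
    network are dropped; protein-protein rows in the table are ignored
    (the PPI part of the network is already built). A chemical with no
    surviving edge is not added.
    """
    out = net.copy()
    dropped_absent = 0
    added = 0
    for a, b, conf, ka, kb in chem_table.edges[
        ["node_a", "node_b", "confidence", "kind_a", "kind_b"]
    ].itertuples(index=False):
        kinds = {ka, kb}
        if "chemical" not in kinds:
            continue
        if ka == "chemical" and kb != "chemical":
            chem, prot = a, b
        elif kb == "chemical" and ka != "chemical":
            chem, prot = b, a
        else:  # chemical-chemical pairs are kept if both ends exist or added fresh
            chem, prot = a, b
            if conf >= confidence_cutoff:
                out.add_node(a, kind="chemical")
                out.add_node(b, kind="chemical")
                out.add_edge(a, b, confidence=float(conf))
                added += 1
            continue
        if conf < confidence_cutoff:
            continue
        if prot not in net:
            dropped_absent += 1
            continue
        out.add_node(chem, kind="chemical")
        out.add_edge(chem, prot, confidence=float(conf))
        added += 1
    if dropped_absent:
        log.info("dropped %d chemical edge(s) to proteins absent from network", dropped_absent)
    if added == 0:
        warnings.warn("no chemical edge survives; network unchanged", CpnetWarning)
        return net.copy()
    return out


def intersect(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Common-topology intersection: shared nodes, shared edges, min confidence."""
    common_nodes = set(a.nodes) & set(b.nodes)
    g = nx.Graph()
    for n in common_nodes:
        g.add_node(n, kind=a.nodes[n].get("kind", "protein"))
    for u, v, data in a.edges(data=True):
        if u in common_nodes and v in common_nodes and b.has_edge(u, v):
            conf = min(data["confidence"], b[u][v]["confidence"])
            g.add_edge(u, v, confidence=conf)
    if g.number_of_nodes() == 0:
        warnings.warn("network intersection is empty", CpnetWarning)
    return g


def drug_adjacent(net: nx.Graph, chemicals) -> dict:
    """Map each protein node to the subset of chemicals it touches.

    Proteins adjacent to no listed chemical are omitted. "Directly
    modulated" at the network level means sharing an edge with the drug.
    """
    for chem in chemicals:
        if chem not in net or net.nodes[chem].get("kind") != "chemical":
            raise InputError(f"chemical {chem!r} absent from network")
    out = {}
    for chem in chemicals:
        for neigh in net.neighbors(chem):
            if net.nodes[neigh].get("kind") == "chemical":
                continue
            out.setdefault(neigh, set()).add(chem)
    return out


def annotate_regulation(net: nx.Graph, de_table: dict) -> nx.Graph:
    """Set a 'regulation' attribute (up/down/none) on every node."""
    out = net.copy()
    for node in out.nodes:
        out.nodes[node]["regulation"] = de_table.get(node, "none")
    return out


def network_to_table(net: nx.Graph) -> InteractionTable:
    """Serialize a network back to an edge table (for the netio writers)."""
    rows = [
        {
            "node_a": u,
            "node_b": v,
            "confidence": data["confidence"],
            "kind_a": net.nodes[u].get("kind", "protein"),
            "kind_b": net.nodes[v].get("kind", "protein"),
        }
        for u, v, data in net.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence", "kind_a", "kind_b"])
    return InteractionTable(normalize_edges(df)) if len(df) else InteractionTable(df)


def node_attributes(net: nx.Graph) -> dict:
    return {
        node: {k: str(v) for k, v in data.items()} for node, data in net.nodes(data=True)
    }
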