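"""Hypergeometric gene-set enrichment and the pathway-interface ranking.

Enrichment of a query gene set against a collection is the upper-tail
hypergeometric probability P(X >= overlap) with the universe as population,
the (universe-restricted) set as successes and the query as draws;
Benjamini-Hochberg adjusts across the collection, and a set is significant
when its FDR is at or below alpha (default 1e-4).

The pathway-interface step re-ranks candidate genes inside a merged
cell-process network: it records each candidate's Venn membership across
the pathway sets, builds the induced interactome network over the union of
pathway genes and candidates, classifies hubs/bottlenecks, quarters the
H-B nodes, and reports which candidates are H-B and which reach Q4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .centrality import HB, analyze_network
from .errors import InputError
from .graphcore import build_network
from .netio import GeneSetCollection, InteractionTable


def hypergeometric_enrichment(
    query, collection: GeneSetCollection, universe, alpha: float = 1e-4
) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of the collection."""
    universe = set(universe)
    query = set(query)
    if not universe:
        raise InputError("empty universe")
    if not query:
        raise InputError("empty query")
    if not query <= universe:
        raise InputError("query must be a subset of the universe")
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        overlap = len(query & members)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] <= alpha
    return df


@dataclass
class PathwayInterfaceReport:
    table: pd.DataFrame  # gene, venn_membership, degree, betweenness, hb_class, quarter
    candidate_hb: list
    candidate_q4: list
    network_nodes: int = 0
    network_edges: int = 0
    hb_count: int = 0
    unconnected: list = field(default_factory=list)


def pathway_interface(
    candidates,
    pathways: GeneSetCollection,
    interactome: InteractionTable,
    confidence_cutoff: float = 0.400,
) -> PathwayInterfaceReport:
    """Venn membership + centrality re-ranking of candidates in the merged
    cell-process network."""
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise InputError("no candidate genes")
    if not pathways.sets:
        raise InputError("no pathway sets")

    set_names = sorted(pathways.sets)
    venn = {
        gene: tuple(name for name in set_names if gene in pathways.sets[name])
        for gene in candidates
    }

    pool = pathways.union() | set(candidates)
    sub = interactome.subset(pool)
    net = build_network(sub, confidence_cutoff)
    records, _ = analyze_network(net)
    by_node = records.set_index("node")

    rows = []
    unconnected = []
    for gene in candidates:
        if gene in by_node.index:
            rec = by_node.loc[gene]
            rows.append(
                {
                    "gene": gene,
                    "venn_membership": "|".join(venn[gene]),
                    "degree": int(rec["degree"]),
                    "betweenness": float(rec["betweenness"]),
                    "hb_class": rec["hb_class"],
                    "quarter": rec["quarter"],
                }
            )
        else:
            unconnected.append(gene)
            rows.append(
                {
                    "gene": gene,
                    "venn_membership": "|".join(venn[gene]),
                    "degree": 0,
                    "betweenness": 0.0,
                    "hb_class": "unconnected",
                    "quarter": "none",
                }
            )
    table = pd.DataFrame(rows)
    candidate_hb = sorted(table.loc[table["hb_class"] == HB, "gene"])
    candidate_q4 = sorted(table.loc[table["quarter"] == "Q4", "gene"])
    return PathwayInterfaceReport(
        table=table,
        candidate_hb=candidate_hb,
        candidate_q4=candidate_q4,
        network_nodes=net.number_of_nodes(),
        network_edges=net.number_of_edges(),
        hb_count=int((records["hb_class"] == HB).sum()),
        unconnected=unconnected,
    )
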