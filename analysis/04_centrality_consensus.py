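"""Hub-bottleneck classification per network and the consensus H-B core.

Reads the three network edge tables written by 03_network_chain.py,
classifies every node against the network-average degree and betweenness
(strict >), intersects the three H-B sets into the consensus core, and
partitions the core by drug adjacency. Reports go to results/centrality/.
"""

import sys
from pathlib import Path

from cpnet import centrality as ct
from cpnet import graphcore as gc, netio

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1] / "results"
NETS = ROOT / "networks"
OUT = ROOT / "centrality"
OUT.mkdir(parents=True, exist_ok=True)

if not NETS.exists():
    sys.exit("run 03_network_chain.py first")

hb_sets = []
networks = {}
for name in ("cell_line_cp_ppi", "disease_cp_ppi", "intersection_cp_ppi"):
    net = gc.build_network(netio.read_edge_table(NETS / f"{name}.tsv"), 0.0)
    networks[name] = net
    records, thresholds = ct.analyze_network(net)
    records.to_csv(OUT / f"{name}_centrality.tsv", sep="\t", index=False)
    hb = ct.hb_nodes(records)
    hb_sets.append(hb)
    print(f"{name}: {len(hb)} H-B of {len(records)} nodes "
          f"(mean degree {thresholds.degree_mean:.2f}, "
          f"mean betweenness {thresholds.betweenness_mean:.2f})")

consensus, venn = ct.consensus_hb(hb_sets)
print(f"consensus H-B core: {len(consensus)} nodes: {', '.join(sorted(consensus))}")

inter = networks["intersection_cp_ppi"]
chemicals = [n for n, d in inter.nodes(data=True) if d.get("kind") == "chemical"]
adjacency = gc.drug_adjacent(inter, chemicals)
with open(OUT / "consensus_core.tsv", "w") as fh:
    fh.write("node\tdrug_adjacency\tvenn_pattern\n")
    for node in sorted(consensus):
        chems = ",".join(sorted(adjacency.get(node, set())))
        pattern = "".join("1" if x else "0" for x in venn[node])
        fh.write(f"{node}\t{chems}\t{pattern}\n")
        print(f"  {node}: modulated by {chems or '(none)'}")
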