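"""Build the network chain: cell-line CP-PPI, disease CP-PPI, intersection.

The cell-line network is the interactome induced on the rank-product
called genes at the medium-confidence cutoff (0.400), with the two drugs
attached; the disease network is induced on the top disease-associated
genes; the intersection keeps common nodes and edges. Edge tables for all
three go to results/networks/.
"""

import sys
from pathlib import Path

from cpnet import SyntheticConfig
from cpnet import graphcore as gc, netio, synth
from cpnet.rankprod import rp_significance

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "networks"
OUT.mkdir(parents=True, exist_ok=True)

cfg = SyntheticConfig(seed=SEED)
CUTOFF = 0.400

expr = synth.gen_expression_dataset(cfg)
called = rp_significance(expr, n_perm=1000, seed=SEED, alpha=0.01)
called = sorted(called.index[called["called"]])

interactome = synth.gen_interactome(cfg)
chem = synth.gen_chemical_links(interactome, list(cfg.chemicals), cfg.targets_per_chemical, cfg)

cell = gc.attach_chemicals(gc.build_network(interactome.subset(called), CUTOFF), chem, CUTOFF)
disease_genes = gc.select_disease_genes(synth.gen_disease_table(cfg.protein_ids, cfg), 0.5, 1000)
dis = gc.attach_chemicals(gc.build_network(interactome.subset(disease_genes), CUTOFF), chem, CUTOFF)
inter = gc.intersect(cell, dis)

for name, net in (("cell_line_cp_ppi", cell), ("disease_cp_ppi", dis),
                  ("intersection_cp_ppi", inter)):
    netio.write_edge_table(gc.network_to_table(net), OUT / f"{name}.tsv")
    print(f"{name}: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")
print(f"(confidence cutoff {CUTOFF}; {len(called)} called genes; "
      f"{len(disease_genes)} disease genes)")
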