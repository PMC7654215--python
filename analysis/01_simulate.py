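"""Generate the synthetic study universe used by all downstream analyses.

Writes the expression matrix, the chemical-protein interactome, the
disease-association table, the cell-process gene sets, the survival cohort
and the morphometry control population to results/synthetic/, together
with the planted ground truth (module genes, expressed genes).
"""

import json
import sys
from pathlib import Path

from cpnet import SyntheticConfig
from cpnet import netio, synth
from cpnet.morphometry import records_to_frame

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)

cfg = SyntheticConfig(seed=SEED)
expr = synth.gen_expression_dataset(cfg)
netio.write_expression_tsv(expr.to_frame(), OUT / "expression.tsv")

table = synth.gen_interactome(cfg)
table = synth.gen_chemical_links(table, list(cfg.chemicals), cfg.targets_per_chemical, cfg)
netio.write_edge_table(table, OUT / "interactome.tsv")
netio.write_disease_table(synth.gen_disease_table(cfg.protein_ids, cfg), OUT / "disease.tsv")
netio.write_gmt(synth.gen_pathways(cfg), OUT / "pathways.gmt")
synth.gen_survival_cohort(cfg.protein_ids, table.meta["module"], cfg).write_tsv(OUT / "survival.tsv")
records_to_frame(synth.gen_morphometry(cfg, {"N": 1.0})).to_csv(
    OUT / "morphometry_control.tsv", sep="\t", index=False
)
truth = {"module": table.meta["module"], "expressed": table.meta["expressed"], "seed": SEED}
(OUT / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))

print(f"seed {SEED}: universe of {cfg.n_genes} genes / {cfg.n_proteins} proteins written to {OUT}")
print(f"planted module ({len(truth['module'])} genes): {', '.join(truth['module'])}")
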