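# cpnet — chemical–protein network screening for drug-modulated genes

Combination regimens in breast cancer (a chemotherapeutic such as
doxorubicin plus an adjuvant such as resveratrol) act through genes that
sit at the interface of drug–target networks, disease biology and patient
outcome. `cpnet` implements, as a tested and reusable pipeline, the
multistep in silico funnel used to nominate such genes:

1. **rank-product calling** of constitutively expressed genes from
   replicated intensity arrays (RP = geometric mean of within-array
   ranks; permutation p ≤ 0.01),
2. **network chain**: cell-line PPI network at combined confidence
   ≥ 0.400 → chemical–protein (CP-PPI) network → disease CP-PPI network
   from top disease-associated genes → **intersection** network,
3. **hub–bottleneck (H-B) classification** (degree > mean degree and
   betweenness > mean betweenness) on all three networks, and the
   **consensus H-B core** common to them,
4. **drug adjacency**: core genes sharing an edge with a drug node,
5. **median-split Kaplan–Meier screening** (logrank p < 0.05, O/E hazard
   ratio with 95% CI),
6. **pathway-interface ranking** inside a merged
   apoptosis/senescence/autophagy network (Venn membership, H-B status,
   quarters Q1–Q4 against H-B medians),

plus the study's two in vitro formulas: cumulative population doubling
(`PD = [log N(t) − log N(t₀)]/log 2`, summed over passages) and the
nuclear irregularity index (`NII = Asp − Arbx + Rr + Rou`) with
control-referenced classification of nuclei into N / SR / SI / LR / LIr.

A synthetic-data module generates every input the pipeline consumes —
replicated expression arrays, a scale-free interactome with a planted
high-centrality drug-adjacent module, disease-association tables,
cell-process gene sets, a survival cohort whose hazard tracks the planted
genes, and nuclear morphometry — together with the planted ground truth,
so the whole funnel is exercisable and testable at desk scale. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

Run the numbered analyses (each is a thin driver over the library and
writes its tables under `results/`):

```bash
python analysis/01_simulate.py 1
python analysis/02_expression_calling.py 1
python analysis/03_network_chain.py 1
python analysis/04_centrality_consensus.py 1
python analysis/05_survival_screen.py 1
python analysis/06_pathway_interface.py 1
python analysis/07_growth_morphometry.py 1
```

At seed 1 the funnel prints:

```
50 / 1000 genes called at p <= 0.01 (planted expressed: 50)
cell_line_cp_ppi: 43 nodes, 91 edges
disease_cp_ppi: 95 nodes, 160 edges
intersection_cp_ppi: 43 nodes, 91 edges
consensus H-B core: 8 nodes: G0141, G0297, G0325, G0456, G0463, G0464, G0549, G0556
8 / 8 core genes significant at alpha=0.05 (cohort n=1000, censoring 20%)
  G0141: HR=1.78 [1.54, 2.06], p=1.37e-16
funnel: called=50 -> consensus H-B=8 -> drug-adjacent=8 -> KM-significant=8 -> final=8
planted module recovered: 8 / 8; false positives: 0
```

Reading this: of 1000 genes, the rank product calls exactly the 50
consistently high-intensity ones; the three CP-PPI networks share an
8-node hub–bottleneck core, every core gene touches both drug nodes, all
eight dichotomize patient survival (hazard ratios ≈ 1.5–2.0, as expected
for a planted log hazard of 1.0 under median-split attenuation), all
eight are hubs–bottlenecks of the merged cell-process network — and the
final candidate list equals the planted module with no false positives.
The in vitro driver prints a control CPD of 7.85 versus 2.86 for the
treated arm at day 15, and classifies a treated-like nucleus mixture with
98.3% agreement to the generator's truth.

The same stages are available as subcommands of the `cpnet` CLI
(`simulate`, `rankprod`, `build-net`, `attach-chem`, `disease-genes`,
`intersect`, `centrality`, `enrich`, `survival`, `nma`, `cpd`,
`run-all`), all reading and writing plain TSV/GMT files:

```bash
cpnet simulate --seed 1 --outdir universe/
cpnet run-all --seed 1 --outdir run/
```

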