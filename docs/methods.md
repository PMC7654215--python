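# Methods

`cpnet` implements a multistep in silico funnel for nominating genes that a
drug pair (here a chemotherapeutic, "Doxo", plus an adjuvant polyphenol,
"Rsv") plausibly modulates in breast cancer, together with the two
quantitative in vitro endpoints that accompany such studies (cumulative
population doubling and nuclear morphometry). This note documents the
models, the defaults and why, the synthetic study universe, numerical
choices, and known limitations.

## The funnel

1. **Rank-product expression calling.** Constitutive expression of the
   cell line is called from replicated intensity arrays. Each array is
   ranked by descending intensity (midranks for ties); a gene's rank
   product is the geometric mean of its ranks, so small RP means
   consistently abundant. Significance comes from a pooled permutation
   null: gene labels are permuted independently within each array
   `n_perm` times, all null rank products are pooled, and
   `p = (1 + #{null <= observed}) / (1 + n_perm * n_genes)` (the +1 keeps
   p positive). The estimated percentage of false positives is
   `pfp = p * n_genes / rank(p)`. The call rule is `p <= 0.01` by
   default; a switch applies the threshold to pfp instead, since either
   reading of "significance value of 0.01" is defensible. When several
   expression series are combined, the default is the union of the
   per-series call sets (an intersection switch exists); neither rule is
   canonical and the choice is logged.
2. **Network chain.** A cell-line PPI network is the interactome induced
   on the called genes, keeping edges with combined confidence >= 0.400
   (the "medium confidence" convention; the comparison is inclusive, and
   the 0-999 integer score dialect is divided by 1000 on read). Chemical
   nodes are attached from a STITCH-style chemical-protein table at the
   same cutoff (CP-PPI). A disease network is built the same way from the
   genes passing a disease-association confidence cutoff, truncated to the
   top N by confidence (ties broken by ascending identifier for
   determinism). The intersection network keeps nodes present in both and
   edges present in both, with the minimum of the two confidences;
   intersection is by topology only, which makes it idempotent,
   commutative and associative.
3. **Hub-bottleneck classification.** Degree and betweenness are computed
   per node; betweenness is the Freeman/Brandes pair-fraction form
   (sum over unordered pairs of the fraction of shortest paths through the
   node, endpoints excluded, edges unweighted, unreachable pairs
   contributing zero). A node is a hub when its degree strictly exceeds
   the network mean degree and a bottleneck when its betweenness strictly
   exceeds the mean betweenness; the four classes (H-B, H-NB, NH-B,
   NH-NB) partition every network. Strict comparison means perfectly
   regular graphs (cycles) have no hubs at all, which is the intended
   reading of "high compared to the average". Chemical nodes participate
   by default (drugs can legitimately be hubs); a flag excludes them.
   Quarters re-rank the H-B nodes against the medians of degree and
   betweenness over H-B nodes only: Q4 exceeds both, Q3 only the degree
   median, Q2 only the betweenness median, Q1 neither.
4. **Consensus core and drug adjacency.** The H-B sets of the cell-line,
   disease and intersection CP-PPI networks are intersected into a
   consensus core (the full Venn partition is reported). A core protein is
   "directly modulated" by a drug when it shares an edge with that
   chemical node in the intersection network.
5. **Survival screen.** For each candidate, patients are dichotomized at
   the cohort median of that gene's expression (ties go to the high
   group), and the two overall-survival curves are compared with the
   standard two-group logrank test (hypergeometric variance with tie
   correction; chi-square with 1 df). The hazard ratio is the
   observed/expected form `HR = (O_h/E_h)/(O_l/E_l)` with
   `95% CI = exp(log HR +- 1.96 sqrt(1/E_h + 1/E_l))`. Genes are judged
   individually at alpha = 0.05 with no multiplicity correction, matching
   how such screens are run gene-by-gene against a survival server; a
   Benjamini-Hochberg switch exists.
6. **Pathway interface.** The KM-significant candidates are re-ranked
   inside a merged cell-process network: the union of three process gene
   sets (apoptosis / senescence / autophagy) plus the candidates, induced
   from the interactome at the same 0.400 cutoff (only interactome edges
   are used; pathway-map edge semantics are out of scope). The report
   gives each candidate's Venn membership across the three sets, H-B
   status and quarter. Final candidates are the KM-significant,
   drug-adjacent consensus H-B genes that are H-B in this network. The
   funnel sets are nested by construction and the nesting is asserted on
   every run.

Gene-set enrichment (used for annotating networks) is the upper-tail
hypergeometric probability P(X >= overlap) with the network's gene set as
the default universe (configurable), BH-adjusted across the collection,
significant at FDR <= 1e-4.

## In vitro formulas

- Population doubling of a passage: `PD = [log N(t) - log N(t0)] / log 2`;
  the cumulative PD is the running sum across passages, indexed by day.
- Nuclear irregularity index: `NII = Asp - Arbx + Rr + Rou` (aspect ratio,
  area/bounding-box ratio, radius ratio, roundness); it increases with
  irregularity. Classification is control-referenced: size is
  small/normal/large by the area against the control mean +- k_area SD,
  shape is irregular when NII exceeds the control mean + k_nii SD
  (one-sided, because NII grows with irregularity by construction). Small
  nuclei become SR/SI, large nuclei LR/LIr, normal-sized nuclei are N.
  The published procedure delegates its numeric thresholds to an external
  spreadsheet whose constants are not printed, so the rule family is
  preserved and the constants are configuration; the defaults are
  k_area = k_nii = 2.5. The choice follows from the rule itself: on pure
  control data N-recovery equals P(|z| < k_area), which is 0.68 at k = 1
  and 0.988 at k = 2.5, and only the latter leaves sampling margin for the
  >= 95% control-recovery property at a few hundred nuclei per group.

## The synthetic study universe

All inputs can be generated at desk scale with the statistical structure
the funnel assumes, plus the planted ground truth, so recovery is
testable without downloads. One master seed fans out to fixed, named
substreams (truth, expression, interactome, chemicals, disease, survival,
morphometry, pathways, regulation), so adding a generator never perturbs
another and identical configs give byte-identical outputs.

A shared latent truth coordinates the generators: a set of constitutively
expressed genes (default 5% of a 1000-gene universe) containing a planted
8-gene module of interactome proteins. The *anchor* set — expressed genes
that are also interactome proteins — seeds the module's spokes and the
disease and pathway gene pools. This models the real overlap between a
cell line's expressed genes and the disease-associated genes for its
tissue, which is exactly what makes the network intersection non-trivial
in practice.

- **Expression** (1000 genes x 6 replicates): log2 intensities are normal
  (SD 1) around a background mean; expressed genes sit `separation_sd`
  SDs higher in every replicate. The default separation is 3.5 SD and the
  default expressed fraction 0.05; both follow from an order-statistics
  analysis of the pooled permutation null. The largest rank product among
  m equally expressed genes concentrates near `exp(ln m - 1 + 2.5/sqrt(k))`
  for k replicates, and the p = 0.01 boundary sits near rank 0.11 n; with
  m = 50 of n = 1000 the worst expressed gene stays far below the
  boundary (so "all planted genes called" is a property, not luck), while
  m = 150 provably crosses it regardless of separation. At 3.5 SD a
  background gene outranks an expressed gene in one array with
  probability ~0.007, keeping rank intrusion negligible.
- **Interactome** (900 proteins): a preferential-attachment backbone
  (3 edges per new node) reproduces the heavy-tailed degree distribution
  H-B analysis presumes; the module occupies the earliest (highest-degree)
  attachment positions, is completed to a clique, and each member carries
  20 extra spokes. Anchor spokes are *partitioned* round-robin across
  members, so every member owns exclusive satellite genes whose shortest
  paths must route through it in any anchor-preserving subnetwork —
  independent spoke sampling leaves unlucky members without exclusive
  satellites and their betweenness below the network mean. Backbone edge
  confidences are Beta(5, 2), so the 0.400 cutoff trims a real minority
  of edges; planted wiring (clique, spokes, chemical-target edges) lies in
  [0.4, 1], the curated tier of interaction databases, so the cutoff
  cannot sever the few structurally critical edges.
- **Chemicals**: each drug targets the module (shared pool; the overlap
  between the two drugs' target sets is a parameter, default full) plus
  chemical-specific extras, exactly `targets_per_chemical` edges each.
- **Disease associations**: module genes carry maximal confidence (1.0 on
  a configurable scale, since the emulated resource's filtered scale is
  not printed), anchors high confidence (0.55-1.0), background Beta(2, 5).
- **Survival** (1000 patients): expression is standard normal; each
  planted gene adds `planted_log_hazard` (default 1.0) to the log hazard
  of an exponential survival time when the patient's expression exceeds
  that gene's cohort median; baseline median survival 24 months;
  independent censoring at rate 0.2. With independent planted indicators
  the marginal per-gene hazard ratio stays near e^beta, which the O/E
  estimator recovers within +-0.3 on the log scale at n = 1000.
- **Morphometry** (300 nuclei/group): control nuclei are N(100, 15) in
  area with shape metrics tuned to an NII of ~3.05 (SD ~0.13); abnormal
  size classes shift the area by 5 control SD and irregular classes shift
  NII by 5 SD (split over aspect and radius ratio), giving >= 97% class
  recovery through the classifier at its default thresholds.
- **Pathways**: three overlapping process sets (60 genes each) drawn with
  the anchor bias; the first module gene joins all three processes and the
  rest are spread round-robin, mirroring the way real candidate genes
  distribute over apoptosis/senescence/autophagy maps.

What the generator does *not* emulate: probe-level microarray artifacts
and normalization, literature text-mining noise in disease associations,
correlated expression between interacting proteins, non-proportional
hazards, and batch structure across expression series. Passing recovery
tests therefore show the pipeline's logic is sound and calibrated under
its own assumptions — not that those assumptions hold on any particular
public dataset.

## Numerical choices

- Ties: midranks in rank products; median-split ties go "high"; disease
  selection ties break by ascending identifier; duplicate undirected edges
  keep the maximum confidence (conservative for thresholding).
- All threshold comparisons on confidences are inclusive (>=); H/B and
  quarter comparisons are strict (>), so equality never promotes a node.
- Degenerate inputs: constant arrays rank to (n+1)/2 with a warning;
  constant expression makes a median split an error that the screen
  reports per gene rather than aborting; a logrank with no comparable
  events returns p = 1 with a warning; an empty network intersection
  degrades the pipeline to an empty report (exit code 2 in the CLI)
  rather than a hard error.
- The pipeline asserts its funnel nesting (final candidates inside the
  pathway H-B/Q4 set inside the KM-significant set inside the
  drug-adjacent consensus core) on every run.
- Default problem sizes (1000 genes, 900 proteins, 1000 patients, 200-1000
  permutations) keep a full funnel run under a second and a 20-seed
  recovery study under a minute on one core, while leaving every
  calibration check (type-I error, power, hazard-ratio recovery)
  comfortably resolved.

## Known limitations

- The betweenness variant excludes endpoints and ignores edge weights; a
  raw-path-count variant is not provided (the pair-fraction form is what
  the common centrality plugins compute).
- The survival screen is univariate Kaplan-Meier/logrank only; no Cox
  adjustment, stratification, or probe-collapsing logic.
- Enrichment reports plain hypergeometric tables; term-grouping/kappa
  clustering of annotation tools is out of scope.
- Network intersection requires an edge in both inputs; whether the
  emulated plugin kept single-sided edges between common nodes cannot be
  settled from published counts, so the stricter rule is the documented
  default.
- The rank-product caller is one-class (presence calling); two-class
  differential RP is out of scope.
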