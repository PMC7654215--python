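"""End-to-end orchestration of the candidate-gene funnel.

Stages, in order: rank-product expression calling; cell-line PPI build at
the medium-confidence cutoff (0.400); chemical attachment (CP-PPI);
disease-gene selection (confidence cutoff + top-N); disease CP-PPI build;
network intersection; centrality + hub-bottleneck classification on all
three networks; consensus H-B core; drug-adjacency partition; regulation
annotation; median-split Kaplan-Meier screen (alpha 0.05); pathway-interface
Venn + quarters; final candidates = KM-significant, drug-adjacent consensus
H-B genes that are H-B in the merged cell-process network.

The report's funnel sets are nested:

    final <= pathway H-B/Q4 candidates <= KM-significant <= drug-adjacent
    consensus H-B core

and that nesting is asserted on every run. Every stage's thresholds and
row counts are logged, and intermediates can be persisted as TSV so each
stage is independently inspectable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import centrality as ct
from . import graphcore as gc
from . import netio
from .config import SyntheticConfig
from .errors import CpnetError, CpnetWarning, EmptyResultError, StageError
from .enrichment import pathway_interface
from .rankprod import rp_significance
from .survival import km_screen
from .synth import (
    gen_chemical_links,
    gen_disease_table,
    gen_expression_dataset,
    gen_interactome,
    gen_pathways,
    gen_regulation,
    gen_survival_cohort,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds of the funnel plus the synthetic-universe block."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    confidence_cutoff: float = 0.400
    rp_alpha: float = 0.01
    rp_n_perm: int = 200
    rp_use_pfp: bool = False
    disease_cutoff: float = 0.5
    disease_top_n: int = 1000
    km_alpha: float = 0.05
    include_chemicals_in_centrality: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = d.pop("synthetic", {})
        if isinstance(synth, dict):
            synth = SyntheticConfig(**synth)
        return cls(synthetic=synth, **d)


@dataclass
class PipelineReport:
    stages: dict = field(default_factory=dict)  # stage -> summary dict
    thresholds: dict = field(default_factory=dict)
    consensus_hb: list = field(default_factory=list)
    drug_adjacency: dict = field(default_factory=dict)  # gene -> sorted chems
    regulation: dict = field(default_factory=dict)
    km_results: list = field(default_factory=list)  # row dicts
    pathway_table: list = field(default_factory=list)
    final_candidates: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "stages": self.stages,
            "thresholds": self.thresholds,
            "consensus_hb": self.consensus_hb,
            "drug_adjacency": self.drug_adjacency,
            "regulation": self.regulation,
            "km_results": self.km_results,
            "pathway_table": self.pathway_table,
            "final_candidates": self.final_candidates,
            "warnings": self.warnings,
            "truth": self.truth,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def _net_summary(net) -> dict:
    return {"nodes": net.number_of_nodes(), "edges": net.number_of_edges()}


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineReport:
    """Execute the full funnel on the synthetic universe in ``config``.

    A hard error in any stage raises :class:`StageError` naming the stage;
    an empty network intersection degrades to an empty report with
    warnings. When ``outdir`` is given, per-stage TSV intermediates are
    written there.
    """
    cfg = config.synthetic
    report = PipelineReport()
    report.thresholds = {
        "confidence_cutoff": config.confidence_cutoff,
        "rp_alpha": config.rp_alpha,
        "disease_cutoff": config.disease_cutoff,
        "disease_top_n": config.disease_top_n,
        "km_alpha": config.km_alpha,
    }
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        log.info("stage: %s", name)
        return name

    caught = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always", CpnetWarning)

        # --- expression calling -----------------------------------------
        stage = _stage("rankprod")
        try:
            expr = gen_expression_dataset(cfg)
            rp = rp_significance(
                expr, n_perm=config.rp_n_perm, seed=cfg.seed,
                alpha=config.rp_alpha, use_pfp=config.rp_use_pfp,
            )
            called = sorted(rp.index[rp["called"]])
        except CpnetError as exc:
            raise StageError(stage, exc) from exc
        report.stages["rankprod"] = {
            "n_genes": cfg.n_genes,
            "n_replicates": cfg.n_replicates,
            "n_perm": config.rp_n_perm,
            "alpha": config.rp_alpha,
            "called": len(called),
        }
        report.truth = {
            "module": list(expr.meta["module"]),
            "expressed": list(expr.meta["expressed"]),
        }
        if outdir is not None:
            rp.to_csv(outdir / "rankprod.tsv", sep="\t")

        # --- cell-line CP-PPI network -----------------------------------
        stage = _stage("cell_line_network")
        try:
            interactome = gen_interactome(cfg)
            chem_table = gen_chemical_links(
                interactome, list(cfg.chemicals), cfg.targets_per_chemical, cfg
            )
            cell_ppi = gc.build_network(
                interactome.subset(called), config.confidence_cutoff
            )
        except CpnetError as exc:
            raise StageError(stage, exc) from exc

        stage = _stage("attach_chemicals")
        try:
            if not cfg.chemicals:
                raise EmptyResultError("no chemical nodes configured")
            for chem in cfg.chemicals:
                if chem not in chem_table.nodes:
                    raise EmptyResultError(f"chemical {chem!r} absent from edge tables")
            cell_cp = gc.attach_chemicals(cell_ppi, chem_table, config.confidence_cutoff)
        except CpnetError as exc:
            raise StageError(stage, exc) from exc
        report.stages["cell_line_cp_ppi"] = _net_summary(cell_cp)

        # --- disease CP-PPI network -------------------------------------
        stage = _stage("disease_network")
        try:
            disease = gen_disease_table(cfg.protein_ids, cfg)
            disease_genes = gc.select_disease_genes(
                disease, config.disease_cutoff, config.disease_top_n
            )
            dis_ppi = gc.build_network(
                interactome.subset(disease_genes), config.confidence_cutoff
            )
            dis_cp = gc.attach_chemicals(dis_ppi, chem_table, config.confidence_cutoff)
        except CpnetError as exc:
            raise StageError(stage, exc) from exc
        report.stages["disease_cp_ppi"] = {
            "selected_genes": len(disease_genes), **_net_summary(dis_cp)
        }

        # --- intersection -------------------------------------------------
        stage = _stage("intersection")
        inter = gc.intersect(cell_cp, dis_cp)
        report.stages["intersection_cp_ppi"] = _net_summary(inter)
        if outdir is not None:
            for name, net in (
                ("cell_line_cp_ppi", cell_cp),
                ("disease_cp_ppi", dis_cp),
                ("intersection_cp_ppi", inter),
            ):
                netio.write_edge_table(gc.network_to_table(net), outdir / f"{name}.tsv")

        if inter.number_of_nodes() == 0:
            report.warnings.append("empty intersection: report degraded to empty")
            report.warnings.extend(str(w.message) for w in wlist)
            return report

        # --- centralities + consensus H-B core ---------------------------
        stage = _stage("centrality")
        try:
            hb_sets = []
            for name, net in (
                ("cell_line_cp_ppi", cell_cp),
                ("disease_cp_ppi", dis_cp),
                ("intersection_cp_ppi", inter),
            ):
                records, thresholds = ct.analyze_network(
                    net, include_chemicals=config.include_chemicals_in_centrality
                )
                hb = ct.hb_nodes(records)
                hb_sets.append(hb)
                report.stages[name + "_hb"] = {
                    "hb": len(hb),
                    "degree_mean": round(thresholds.degree_mean, 6),
                    "betweenness_mean": round(thresholds.betweenness_mean, 6),
                }
                if outdir is not None:
                    records.to_csv(outdir / f"{name}_centrality.tsv", sep="\t", index=False)
            consensus, _venn = ct.consensus_hb(hb_sets)
        except CpnetError as exc:
            raise StageError(stage, exc) from exc
        report.consensus_hb = sorted(consensus)
        report.stages["consensus_hb"] = {"nodes": len(consensus)}

        # --- drug adjacency + regulation ----------------------------------
        stage = _stage("drug_adjacency")
        try:
            adjacency = gc.drug_adjacent(inter, list(cfg.chemicals))
        except CpnetError as exc:
            raise StageError(stage, exc) from exc
        core_genes = [
            g for g in report.consensus_hb
            if inter.nodes[g].get("kind") == "protein" and g in adjacency
        ]
        report.drug_adjacency = {g: sorted(adjacency[g]) for g in core_genes}

        regulation = gen_regulation(cfg)
        annotated = gc.annotate_regulation(inter, regulation)
        report.regulation = {
            g: annotated.nodes[g]["regulation"] for g in core_genes
        }
        report.stages["drug_adjacent_core"] = {"genes": len(core_genes)}

        # --- Kaplan-Meier screen ------------------------------------------
        stage = _stage("km_screen")
        try:
            cohort = gen_survival_cohort(cfg.protein_ids, report.truth["module"], cfg)
            screen = km_screen(cohort, core_genes, alpha=config.km_alpha)
        except CpnetError as exc:
            raise StageError(stage, exc) from exc
        km_sig = sorted(screen.loc[screen["significant"], "gene"])
        report.km_results = screen.round(6).to_dict(orient="records")
        report.stages["km_screen"] = {
            "screened": len(core_genes), "significant": len(km_sig),
            "alpha": config.km_alpha,
        }
        if outdir is not None:
            screen.to_csv(outdir / "km_screen.tsv", sep="\t", index=False)

        # --- pathway interface --------------------------------------------
        stage = _stage("pathway_interface")
        final = []
        if km_sig:
            try:
                pathways = gen_pathways(cfg)
                pi = pathway_interface(
                    km_sig, pathways, interactome, config.confidence_cutoff
                )
            except CpnetError as exc:
                raise StageError(stage, exc) from exc
            report.pathway_table = pi.table.round(6).to_dict(orient="records")
            report.stages["pathway_interface"] = {
                "network_nodes": pi.network_nodes,
                "network_edges": pi.network_edges,
                "hb": pi.hb_count,
                "candidate_hb": len(pi.candidate_hb),
                "candidate_q4": len(pi.candidate_q4),
            }
            final = sorted(set(pi.candidate_hb))
            if outdir is not None:
                pi.table.to_csv(outdir / "pathway_interface.tsv", sep="\t", index=False)
            pathway_funnel = set(pi.candidate_hb) | set(pi.candidate_q4)
        else:
            report.warnings.append("no KM-significant genes; pathway stage skipped")
            pathway_funnel = set()
        report.final_candidates = final

        # Funnel nesting invariant, asserted every run.
        assert set(final) <= pathway_funnel or not final
        assert pathway_funnel <= set(km_sig)
        assert set(km_sig) <= set(core_genes)
        assert set(core_genes) <= set(report.consensus_hb)

        caught = [str(w.message) for w in wlist]
    report.warnings.extend(caught)
    if outdir is not None:
        (outdir / "report.json").write_text(report.to_json())
    return report
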