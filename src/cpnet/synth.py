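"""Synthetic study-universe generators.

Every input the pipeline consumes can be generated here with the
statistical structure the downstream analysis assumes, together with the
planted ground truth (expressed genes, module members, hazard-linked genes,
nucleus classes) so recovery is testable without any external downloads.

The universe is coordinated through a shared latent truth drawn once per
config: a set of constitutively *expressed* genes containing a small
clique-like *module* of interactome proteins. The module is wired to be
high-degree/high-betweenness, is targeted by the chemicals, carries maximal
disease confidence, and drives the survival hazard — it is the planted
answer the pipeline should recover. The *anchor* set (expressed genes that
are also interactome proteins) seeds the module's spokes and the
disease/pathway gene pools; this models the real overlap between a cell
line's expressed genes and the disease-associated genes, which is what
makes the network intersection non-trivial in practice.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .config import SyntheticConfig
from .errors import CpnetWarning, DegenerateError, InputError
from .morphometry import NucleusRecord, nii
from .netio import DiseaseAssociationTable, GeneSetCollection, InteractionTable
from .rankprod import ExpressionMatrix
from .survival import SurvivalTable

#: Background log2-intensity mean and within-replicate SD of the chip model.
_LOG_MEAN = 6.0
_LOG_SD = 1.0

#: Baseline hazard: median overall survival of 24 months in the reference group.
_BASELINE_HAZARD = np.log(2) / 24.0

#: Per-class morphometry model (control = class N).
_MORPH_BASE = {
    "area": (100.0, 15.0),
    "aspect": (1.3, 0.08),
    "areabox": (0.75, 0.04),
    "radius_ratio": (1.5, 0.08),
    "roundness": (1.0, 0.06),
}
_AREA_SHIFT_SD = 5.0  # small/large classes sit 5 control-SD off the mean
_SHAPE_SHIFT_SD = 5.0  # irregular classes add 5 NII-SD, split over Asp and Rr


def planted_truth(cfg: SyntheticConfig) -> dict:
    """Shared latent truth: module, expressed genes, anchors.

    Drawn from its own substream so every generator sees the same truth.
    """
    rng = cfg.rng("truth")
    genes = cfg.gene_ids
    proteins = cfg.protein_ids
    n_expressed = int(round(cfg.frac_expressed * cfg.n_genes))
    if n_expressed < 1:
        warnings.warn("no expressed genes planted", CpnetWarning)
        return {"module": [], "expressed": [], "anchors": []}

    module_size = min(cfg.planted_module_size, n_expressed, cfg.n_proteins)
    module = sorted(str(g) for g in rng.choice(proteins, size=module_size, replace=False))
    rest = [g for g in genes if g not in set(module)]
    extra = sorted(
        str(g) for g in rng.choice(rest, size=n_expressed - module_size, replace=False)
    )
    expressed = sorted(set(module) | set(extra))
    anchors = sorted(set(expressed) & set(proteins))
    return {"module": module, "expressed": expressed, "anchors": anchors}


def gen_expression_dataset(cfg: SyntheticConfig) -> ExpressionMatrix:
    """Replicated intensity matrix with a consistently high-intensity subset.

    Log2 intensities are normal around the background mean; expressed genes
    (always including the planted module) sit ``separation_sd`` SDs above
    it in every replicate. Planted genes are recorded in the metadata.
    """
    truth = planted_truth(cfg)
    rng = cfg.rng("expression")
    genes = cfg.gene_ids
    expressed = set(truth["expressed"])
    loc = np.where(
        np.isin(genes, sorted(expressed)),
        _LOG_MEAN + cfg.separation_sd * _LOG_SD,
        _LOG_MEAN,
    )
    log2 = rng.normal(
        loc=loc[:, None], scale=_LOG_SD, size=(cfg.n_genes, cfg.n_replicates)
    )
    samples = [f"rep{j + 1}" for j in range(cfg.n_replicates)]
    return ExpressionMatrix(
        genes,
        samples,
        np.exp2(log2),
        meta={"expressed": sorted(expressed), "module": truth["module"]},
    )


def _beta_confidence(rng, size):
    """Beta(5, 2) edge confidences: a 0.400 cutoff trims a small minority."""
    return rng.beta(5.0, 2.0, size=size)


def gen_interactome(cfg: SyntheticConfig) -> InteractionTable:
    """Scale-free interactome with a planted high-centrality module.

    A preferential-attachment backbone (the module occupies the earliest,
    highest-degree positions) plus a module clique plus ``module_spokes``
    extra edges per module member. Backbone confidences are Beta(5, 2), so
    a 0.400 cutoff trims a nontrivial minority; planted wiring (clique and
    spokes) carries curated-tier confidences in [0.4, 1], like the
    chemical-target edges.
    """
    if cfg.attachment_parameter >= cfg.n_proteins:
        raise DegenerateError("degenerate generator: attachment_parameter >= n_proteins")
    truth = planted_truth(cfg)
    rng = cfg.rng("interactome")
    proteins = cfg.protein_ids
    module = truth["module"]

    backbone = nx.barabasi_albert_graph(
        cfg.n_proteins, cfg.attachment_parameter, seed=int(rng.integers(2**31))
    )
    # Module members take the earliest attachment positions (highest degree).
    others = [p for p in proteins if p not in set(module)]
    order = list(rng.permutation(others))
    position_to_id = {i: (module[i] if i < len(module) else order[i - len(module)])
                      for i in range(cfg.n_proteins)}

    pairs = set()
    for u, v in backbone.edges():
        a, b = position_to_id[u], position_to_id[v]
        pairs.add((min(a, b), max(a, b)))
    planted_pairs = set()
    for i, a in enumerate(module):
        for b in module[i + 1:]:
            planted_pairs.add((min(a, b), max(a, b)))

    # Anchor spokes are PARTITIONED round-robin across module members: each
    # anchor is spoked by exactly one member, so every member owns exclusive
    # satellites that route their shortest-path traffic through it in any
    # anchor-preserving subnetwork (this is what keeps every member's
    # betweenness above average, not just the lucky ones).
    anchor_pool = [g for g in truth["anchors"] if g not in set(module)]
    other_pool = [g for g in proteins if g not in set(module)]
    dealt = {m: [] for m in module}
    if module:
        for i, anchor in enumerate(rng.permutation(anchor_pool)):
            dealt[module[i % len(module)]].append(str(anchor))
    for m in module:
        targets = list(dealt[m])
        n_rest = cfg.module_spokes - len(targets)
        if n_rest > 0:
            targets.extend(str(g) for g in rng.choice(other_pool, size=n_rest, replace=False))
        for t in targets:
            if t != m:
                planted_pairs.add((min(m, t), max(m, t)))

    pairs -= planted_pairs
    all_pairs = sorted(pairs) + sorted(planted_pairs)
    edges = pd.DataFrame(all_pairs, columns=["node_a", "node_b"])
    conf = np.empty(len(all_pairs))
    conf[: len(pairs)] = _beta_confidence(rng, len(pairs))
    conf[len(pairs):] = 0.4 + 0.6 * _beta_confidence(rng, len(planted_pairs))
    edges["confidence"] = conf
    edges["kind_a"] = "protein"
    edges["kind_b"] = "protein"
    return InteractionTable(
        edges,
        meta={"module": module, "anchors": truth["anchors"], "expressed": truth["expressed"]},
    )


def gen_chemical_links(
    table: InteractionTable,
    chemicals,
    targets_per_chemical: int,
    cfg: SyntheticConfig,
    overlap: int = None,
) -> InteractionTable:
    """Augment an interactome with chemical-protein edges.

    Every chemical targets the planted module (the shared target pool);
    ``overlap`` targets are shared between chemicals (default: all of
    them), the remainder are chemical-specific draws. Confidences lie in
    [0.4, 1] (curated drug-target associations are at least medium
    confidence). Adds exactly ``len(chemicals) * targets_per_chemical``
    edges.
    """
    known = set(cfg.chemicals)
    for chem in chemicals:
        if chem not in known:
            raise InputError(f"unknown chemical identifier {chem!r}")
    if overlap is None:
        overlap = targets_per_chemical
    if not 0 <= overlap <= targets_per_chemical:
        raise InputError("overlap must lie in [0, targets_per_chemical]")

    rng = cfg.rng("chemicals")
    module = list(table.meta.get("module", []))
    proteins = sorted(table.nodes)
    if not module:
        raise InputError("interactome metadata lacks a planted module")

    pool = [p for p in proteins if p not in set(module)]
    shared = module[:overlap]
    if len(shared) < overlap:
        extra = rng.choice(pool, size=overlap - len(shared), replace=False)
        shared = shared + sorted(str(g) for g in extra)

    rows = []
    target_map = {}
    for chem in chemicals:
        own_pool = [p for p in pool if p not in set(shared)]
        n_own = targets_per_chemical - len(shared)
        own = (
            sorted(str(g) for g in rng.choice(own_pool, size=n_own, replace=False))
            if n_own
            else []
        )
        targets = list(shared) + own
        target_map[chem] = targets
        conf = 0.4 + 0.6 * _beta_confidence(rng, len(targets))
        for t, c in zip(targets, conf):
            rows.append(
                {"node_a": chem, "node_b": t, "confidence": c,
                 "kind_a": "chemical", "kind_b": "protein"}
            )
    chem_edges = pd.DataFrame(rows)
    edges = pd.concat([table.edges, chem_edges], ignore_index=True)
    meta = dict(table.meta)
    meta["chemical_targets"] = target_map
    return InteractionTable(edges, meta)


def gen_disease_table(genes, cfg: SyntheticConfig) -> DiseaseAssociationTable:
    """Gene-disease confidences: module maximal, anchors high, rest low."""
    if len(genes) == 0:
        raise InputError("genes must be nonempty")
    truth = planted_truth(cfg)
    rng = cfg.rng("disease")
    module = set(truth["module"])
    anchors = set(truth["anchors"]) - module
    conf = np.empty(len(genes))
    for i, g in enumerate(genes):
        if g in module:
            conf[i] = 1.0
        elif g in anchors:
            conf[i] = 0.55 + 0.45 * rng.beta(5.0, 2.0)
        else:
            conf[i] = rng.beta(2.0, 5.0)
    rows = pd.DataFrame({"gene": list(genes), "confidence": conf * cfg.disease_scale})
    return DiseaseAssociationTable(rows, meta={"module": sorted(module)})


def gen_survival_cohort(genes, planted, cfg: SyntheticConfig) -> SurvivalTable:
    """Exponential survival cohort whose hazard tracks the planted genes.

    Expression is standard normal per patient and gene. Each planted gene
    adds ``planted_log_hazard`` to the log hazard when the patient's
    expression exceeds that gene's cohort median; non-planted genes are
    independent of survival. Censoring is independent at
    ``censoring_rate``.
    """
    genes = list(genes)
    planted = list(planted)
    if not set(planted) <= set(genes):
        raise InputError("planted genes must be a subset of the cohort genes")
    if cfg.censoring_rate >= 1:
        raise InputError("censoring_rate must be < 1")
    rng = cfg.rng("survival")
    n = cfg.n_patients
    expr = rng.normal(size=(n, len(genes)))
    df = pd.DataFrame(expr, columns=genes)

    log_hazard = np.zeros(n)
    for g in planted:
        high = df[g].to_numpy() >= np.median(df[g])
        log_hazard += cfg.planted_log_hazard * high
    hazard = _BASELINE_HAZARD * np.exp(log_hazard)
    t_true = rng.exponential(1.0 / hazard)

    censored = rng.random(n) < cfg.censoring_rate
    t_obs = np.where(censored, t_true * rng.uniform(0.0, 1.0, size=n), t_true)
    t_obs = np.maximum(t_obs, np.finfo(float).tiny)
    data = pd.DataFrame({"time": t_obs, "event": (~censored).astype(int)})
    data.index = [f"P{i + 1:05d}" for i in range(n)]
    data = pd.concat([data, df.set_index(data.index)], axis=1)
    return SurvivalTable(data, meta={"planted": planted})


def gen_morphometry(cfg: SyntheticConfig, group_fractions: dict):
    """Nucleus metric records sampled from per-class shifted distributions.

    Classes shift area (small/large) by 5 control SD and the NII components
    (irregular) by 5 NII-SD relative to the control (N) reference; the true
    class is recorded on every record.
    """
    total = sum(group_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise InputError(f"group fractions sum to {total}, expected 1")
    for cls in group_fractions:
        if cls not in ("N", "SR", "SI", "LR", "LIr"):
            raise InputError(f"unknown nucleus class {cls!r}")
    rng = cfg.rng("morphometry")
    classes = sorted(group_fractions)
    probs = np.array([group_fractions[c] for c in classes])
    draws = rng.choice(len(classes), size=cfg.n_nuclei, p=probs)

    area_mu, area_sd = _MORPH_BASE["area"]
    # Shape shift split between aspect and radius ratio.
    nii_sd = np.sqrt(sum(_MORPH_BASE[k][1] ** 2 for k in ("aspect", "areabox", "radius_ratio", "roundness")))
    shape_shift = _SHAPE_SHIFT_SD * nii_sd / 2.0

    records = []
    for idx in draws:
        cls = classes[idx]
        mu_area = area_mu
        if cls in ("SR", "SI"):
            mu_area -= _AREA_SHIFT_SD * area_sd
        elif cls in ("LR", "LIr"):
            mu_area += _AREA_SHIFT_SD * area_sd
        irregular = cls in ("SI", "LIr")
        area = max(1.0, rng.normal(mu_area, area_sd))
        aspect = max(
            1.0,
            rng.normal(_MORPH_BASE["aspect"][0] + (shape_shift if irregular else 0.0),
                       _MORPH_BASE["aspect"][1]),
        )
        areabox = float(np.clip(rng.normal(*_MORPH_BASE["areabox"]), 0.01, 1.0))
        rr = max(
            1.0,
            rng.normal(_MORPH_BASE["radius_ratio"][0] + (shape_shift if irregular else 0.0),
                       _MORPH_BASE["radius_ratio"][1]),
        )
        rou = max(0.01, rng.normal(*_MORPH_BASE["roundness"]))
        rec = NucleusRecord(
            area=area, aspect=aspect, areabox=areabox,
            radius_ratio=rr, roundness=rou, true_class=cls,
        )
        rec.nii = nii(rec)
        records.append(rec)
    return records


def gen_pathways(cfg: SyntheticConfig) -> GeneSetCollection:
    """Three overlapping cell-process gene sets (apoptosis-, senescence-,
    autophagy-like) over the interactome, biased toward the anchor pool.

    The first module gene joins all three sets; the remaining module genes
    are spread round-robin, so every planted gene sits in >= 1 process.
    """
    truth = planted_truth(cfg)
    rng = cfg.rng("pathways")
    names = ["apoptosis", "senescence", "autophagy"]
    module = truth["module"]
    anchors = [g for g in truth["anchors"] if g not in set(module)]
    others = [g for g in cfg.protein_ids if g not in set(module)]

    sets = {}
    for name in names:
        n_anchor = int(round(cfg.anchor_bias * cfg.pathway_size))
        members = set()
        if anchors:
            members |= {
                str(g)
                for g in rng.choice(anchors, size=min(n_anchor, len(anchors)), replace=False)
            }
        n_rest = cfg.pathway_size - len(members)
        if n_rest > 0:
            members |= {str(g) for g in rng.choice(others, size=n_rest, replace=False)}
        sets[name] = members
    for i, g in enumerate(module):
        if i == 0:
            for name in names:
                sets[name].add(g)
        else:
            sets[names[i % len(names)]].add(g)
    descriptions = {name: "synthetic cell-process gene set" for name in names}
    return GeneSetCollection(sets, descriptions)


def gen_regulation(cfg: SyntheticConfig) -> dict:
    """Differential-regulation annotation: module up, background mixed."""
    truth = planted_truth(cfg)
    rng = cfg.rng("regulation")
    out = {g: "up" for g in truth["module"]}
    for g in cfg.protein_ids:
        if g in out:
            continue
        u = rng.random()
        out[g] = "up" if u < 0.15 else "down" if u < 0.30 else "none"
    return out
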