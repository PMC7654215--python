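"""Configuration for the synthetic study universe.

A single :class:`SyntheticConfig` describes one synthetic "study": a gene
universe with a constitutively expressed subset, a scale-free protein
interactome carrying a planted high-centrality module, chemical (drug) nodes
wired to that module, a disease-association table, a patient survival cohort
whose hazard tracks the planted genes, and nuclear-morphometry measurements.
Every generator derives its randomness from ``seed`` through a named
substream, so adding a generator never perturbs the others and an identical
config yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError

#: Fixed substream offsets: one per generator, so streams never collide.
_SUBSTREAMS = {
    "truth": 1,
    "expression": 2,
    "interactome": 3,
    "chemicals": 4,
    "disease": 5,
    "survival": 6,
    "morphometry": 7,
    "pathways": 8,
    "regulation": 9,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study universe.

    Attributes
    ----------
    seed:
        Master seed; fans out to per-generator substreams.
    n_genes:
        Size of the gene universe (chip genes).
    n_replicates:
        Replicate arrays per expression dataset.
    frac_expressed:
        Fraction of genes drawn from the high-intensity (expressed)
        component, consistently across replicates.
    separation_sd:
        Distance between the expressed and background log-intensity
        component means, in units of the within-replicate SD.
    n_proteins:
        Number of interactome nodes (a prefix of the gene universe).
    attachment_parameter:
        Edges added per new node in the preferential-attachment growth.
    planted_module_size:
        Size of the planted clique-like high-centrality module.
    module_spokes:
        Extra edges per module member fanning out into the interactome.
    anchor_bias:
        Probability that a spoke (or a disease/pathway pool draw) targets
        the expressed-and-disease-associated anchor gene set rather than an
        arbitrary protein; models the real overlap between cell-line
        expressed genes and disease genes.
    chemicals:
        Chemical (drug) node identifiers.
    targets_per_chemical:
        Protein targets wired to each chemical.
    n_patients:
        Survival-cohort size.
    planted_log_hazard:
        Additive log-hazard per planted gene dichotomized above its cohort
        median.
    censoring_rate:
        Probability a patient's follow-up is censored.
    n_nuclei:
        Nuclei per morphometry group.
    disease_scale:
        Upper end of the disease-association confidence scale.
    pathway_size:
        Genes per synthetic cell-process pathway set.
    """

    seed: int = 0
    n_genes: int = 1000
    n_replicates: int = 6
    frac_expressed: float = 0.05
    separation_sd: float = 3.5
    n_proteins: int = 900
    attachment_parameter: int = 3
    planted_module_size: int = 8
    module_spokes: int = 20
    anchor_bias: float = 0.7
    chemicals: tuple = ("Rsv", "Doxo")
    targets_per_chemical: int = 10
    n_patients: int = 1000
    planted_log_hazard: float = 1.0
    censoring_rate: float = 0.2
    n_nuclei: int = 300
    disease_scale: float = 1.0
    pathway_size: int = 60

    def __post_init__(self):
        counts = {
            "n_genes": self.n_genes,
            "n_replicates": self.n_replicates,
            "n_proteins": self.n_proteins,
            "attachment_parameter": self.attachment_parameter,
            "planted_module_size": self.planted_module_size,
            "n_patients": self.n_patients,
            "n_nuclei": self.n_nuclei,
            "targets_per_chemical": self.targets_per_chemical,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise InputError(f"{name} must be a positive integer, got {value!r}")
        for name, value in (
            ("frac_expressed", self.frac_expressed),
            ("anchor_bias", self.anchor_bias),
        ):
            if not 0.0 <= value <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {value!r}")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise InputError(
                f"censoring_rate must lie in [0, 1), got {self.censoring_rate!r}"
            )
        if self.n_proteins > self.n_genes:
            raise InputError("n_proteins cannot exceed n_genes")
        if self.planted_module_size >= self.n_proteins:
            raise InputError("planted_module_size must be smaller than n_proteins")

    def rng(self, stream: str) -> np.random.Generator:
        """Return the named deterministic substream."""
        return np.random.default_rng([int(self.seed), _SUBSTREAMS[stream]])

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)

    @property
    def gene_ids(self) -> list:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def protein_ids(self) -> list:
        return self.gene_ids[: self.n_proteins]
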