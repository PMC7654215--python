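"""Rank-product calling of constitutively expressed genes.

Given a genes x replicates intensity matrix, each array is ranked by
descending intensity (rank 1 = most abundant, ties get midranks) and each
gene's rank product is the geometric mean of its ranks across arrays. A
small rank product means the gene is consistently abundant, i.e.
constitutively expressed. Significance comes from a permutation null built
by independently permuting the gene labels within each array: the null rank
products of all genes across all permutations are pooled, and

    p(g) = (1 + #{null rp <= rp(g)}) / (1 + n_perm * n_genes)

with the conventional +1 smoothing so p is never zero. The percentage of
false positives (pfp), the rank-product analogue of the FDR, is
p * n_genes / rank(p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import CpnetWarning, InputError


@dataclass
class ExpressionMatrix:
    """Genes x samples positive intensities with unique gene ids."""

    gene_ids: list
    sample_ids: list
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InputError("intensity matrix shape does not match labels")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputError("gene_ids must be unique")
        if len(self.sample_ids) < 2:
            raise InputError("need >= 2 samples")
        if not np.all(np.isfinite(self.intensities)):
            raise InputError("intensities contain missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta=None) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(float), meta or {})


def collapse_probes(matrix: ExpressionMatrix, probe_map: dict) -> ExpressionMatrix:
    """Average probe rows mapping to the same gene; drop unmapped probes."""
    groups = {}
    for i, probe in enumerate(matrix.gene_ids):
        gene = probe_map.get(probe)
        if gene is not None:
            groups.setdefault(gene, []).append(i)
    if not groups:
        raise InputError("no probes map to any gene")
    genes = sorted(groups)
    collapsed = np.vstack(
        [matrix.intensities[groups[g]].mean(axis=0) for g in genes]
    )
    return ExpressionMatrix(genes, list(matrix.sample_ids), collapsed, dict(matrix.meta))


def _ranks_desc(intensities: np.ndarray) -> np.ndarray:
    """Within-column ranks, descending intensity, midranks for ties."""
    ranks = np.empty_like(intensities, dtype=float)
    for j in range(intensities.shape[1]):
        col = intensities[:, j]
        if np.ptp(col) == 0:
            warnings.warn(
                f"constant column {j}: all ranks set to (n+1)/2", CpnetWarning
            )
        ranks[:, j] = rankdata(-col, method="average")
    return ranks


def rank_product(matrix: ExpressionMatrix) -> pd.Series:
    """Geometric mean of each gene's within-array descending ranks."""
    ranks = _ranks_desc(matrix.intensities)
    rp = np.exp(np.log(ranks).mean(axis=1))
    return pd.Series(rp, index=matrix.gene_ids, name="rp")


def rp_significance(
    matrix: ExpressionMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
    use_pfp: bool = False,
) -> pd.DataFrame:
    """Permutation p-values and pfp for every gene's rank product.

    The null permutes gene labels within each array independently, which
    on the rank scale amounts to shuffling each rank column. The call rule
    is ``p <= alpha`` by default; set ``use_pfp`` to threshold the
    estimated percentage of false positives instead.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    n_genes, n_samples = matrix.intensities.shape
    ranks = _ranks_desc(matrix.intensities)
    rp = np.exp(np.log(ranks).mean(axis=1))

    rng = np.random.default_rng(seed)
    log_ranks = np.log(ranks)
    null = np.empty((n_perm, n_genes))
    for b in range(n_perm):
        acc = np.zeros(n_genes)
        for j in range(n_samples):
            acc += log_ranks[rng.permutation(n_genes), j]
        null[b] = acc / n_samples
    null_rp = np.sort(np.exp(null).ravel())

    count_le = np.searchsorted(null_rp, rp, side="right")
    p = (1.0 + count_le) / (1.0 + n_perm * n_genes)
    order_rank = rankdata(p, method="average")
    pfp = p * n_genes / order_rank
    called = (pfp <= alpha) if use_pfp else (p <= alpha)
    return pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "rp": rp,
            "p_value": p,
            "pfp": pfp,
            "called": called,
        }
    ).set_index("gene")


def call_expressed(
    matrices, n_perm: int = 1000, seed: int = 0, alpha: float = 0.01,
    combine: str = "union", use_pfp: bool = False,
) -> set:
    """Run rank-product calling per dataset and combine the called sets.

    ``combine`` is "union" (default) or "intersection"; the source analysis
    pooled several expression series without stating the rule.
    """
    called_sets = []
    for k, matrix in enumerate(matrices):
        res = rp_significance(matrix, n_perm=n_perm, seed=seed + k, alpha=alpha,
                              use_pfp=use_pfp)
        called_sets.append(set(res.index[res["called"]]))
    if not called_sets:
        raise InputError("no expression datasets supplied")
    out = called_sets[0]
    for s in called_sets[1:]:
        out = out | s if combine == "union" else out & s
    return out
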