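"""Tissue-specific co-expression weighting of the mutated-gene subnetwork.

Functional modules of driver genes tend to be co-expressed in the tumor's
tissue of origin, so edges of the mutated-gene subnetwork are weighted by
the Pearson correlation of the two genes' expression profiles in one or more
disease-relevant tissues: per tissue, correlations with absolute value
strictly greater than the cutoff (default 0.3) are kept as |r|, the rest set
to 0; with several tissues the thresholded matrices are averaged elementwise
(averaged entries may fall below the cutoff and are kept). The resulting
weighted mutated graph W carries the edge weights plus the per-gene
nonzero-weight neighborhoods and degrees used by the edge clustering
coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_COMPLETE_SAMPLES = 3


@dataclass
class WeightedMutGraph:
    """Symmetric nonnegative weight matrix over retained mutated genes.

    ``degrees`` counts nonzero-weight neighbors; ``neighbors`` maps each gene
    to the set of genes it shares a nonzero-weight edge with. Sub-threshold
    co-expression removes an edge entirely: it contributes neither weight nor
    degree.
    """

    W: pd.DataFrame
    degrees: pd.Series = field(init=False)
    neighbors: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        values = self.W.to_numpy()
        if not np.allclose(values, values.T):
            raise ValueError("weight matrix must be symmetric")
        if (values < 0).any():
            raise ValueError("weight matrix must be nonnegative")
        support = values != 0
        self.degrees = pd.Series(support.sum(axis=1), index=self.W.index)
        genes = list(self.W.index)
        self.neighbors = {
            g: {genes[j] for j in np.flatnonzero(support[i])}
            for i, g in enumerate(genes)
        }

    @property
    def genes(self) -> list[str]:
        return list(self.W.index)


def threshold_correlations(r: np.ndarray, cutoff: float, signed: bool = False) -> np.ndarray:
    """Keep correlations with |r| strictly above ``cutoff``; zero the rest.

    Stored values are absolute correlations unless ``signed`` is set.
    An |r| of exactly ``cutoff`` is zeroed.
    """
    mask = np.abs(r) > cutoff
    out = np.where(mask, r if signed else np.abs(r), 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def compute_tissue_pcc(
    tissue_expr: pd.DataFrame,
    pcc_cutoff: float = 0.3,
    signed: bool = False,
) -> pd.DataFrame:
    """Thresholded gene-gene Pearson correlation matrix for one tissue.

    Correlations use pairwise-complete samples with a minimum of
    ``MIN_COMPLETE_SAMPLES``; pairs with fewer complete samples or zero
    variance in either gene get weight 0, as does the diagonal.
    """
    n_samples, n_genes = tissue_expr.shape
    if n_samples < MIN_COMPLETE_SAMPLES:
        raise ValueError(
            f"need at least {MIN_COMPLETE_SAMPLES} tissue samples, got {n_samples}"
        )
    if n_genes < 2:
        raise ValueError("need at least 2 genes for co-expression")
    values = tissue_expr.to_numpy(dtype=float)
    if np.isfinite(values).all():
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(values, rowvar=False)
        r = np.nan_to_num(r, nan=0.0)  # zero-variance genes
    else:
        r = (
            tissue_expr.corr(method="pearson", min_periods=MIN_COMPLETE_SAMPLES)
            .fillna(0.0)
            .to_numpy()
        )
    weights = threshold_correlations(r, pcc_cutoff, signed=signed)
    return pd.DataFrame(weights, index=tissue_expr.columns, columns=tissue_expr.columns)


def average_tissue_pcc(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Elementwise mean of per-tissue thresholded PCC matrices.

    The output covers the union of the gene sets; a pair absent from a
    tissue contributes 0 for that tissue. No re-thresholding is applied, so
    averaged weights may fall below the single-tissue cutoff.
    """
    if not matrices:
        raise ValueError("need at least one tissue PCC matrix")
    if len(matrices) == 1:
        return matrices[0]
    genes: list[str] = []
    seen: set[str] = set()
    for m in matrices:
        for g in m.index:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    total = np.zeros((len(genes), len(genes)))
    for m in matrices:
        total += m.reindex(index=genes, columns=genes, fill_value=0.0).to_numpy()
    return pd.DataFrame(total / len(matrices), index=genes, columns=genes)


def write_pcc(pcc: pd.DataFrame, path) -> None:
    """Serialize a PCC matrix as a sparse gene-pair TSV (gene_a gene_b weight)."""
    genes = list(pcc.index)
    values = pcc.to_numpy()
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for i, a in enumerate(genes):
            for j in range(i + 1, len(genes)):
                if values[i, j] != 0:
                    fh.write(f"{a}\t{genes[j]}\t{values[i, j]:.12g}\n")


def read_pcc(path) -> pd.DataFrame:
    """Load a gene-pair TSV written by :func:`write_pcc` into a dense matrix."""
    pairs = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    genes = sorted(set(pairs["gene_a"]) | set(pairs["gene_b"]))
    out = pd.DataFrame(0.0, index=genes, columns=genes)
    for row in pairs.itertuples(index=False):
        out.loc[row.gene_a, row.gene_b] = row.weight
        out.loc[row.gene_b, row.gene_a] = row.weight
    return out


def weight_mutmut(mutmut: pd.DataFrame, pcc: pd.DataFrame) -> WeightedMutGraph:
    """Mask the tissue PCC matrix onto the mutated-gene adjacency.

    ``W(i,j) = pcc(i,j)`` where the binary adjacency is 1, else 0. Genes
    missing from the PCC matrix get weight 0 on all their edges; the PCC
    matrix never creates edges absent from the adjacency.
    """
    genes = list(mutmut.index)
    missing = [g for g in genes if g not in pcc.index]
    if missing:
        logger.info(
            "%d retained genes absent from the tissue PCC matrix get zero weights",
            len(missing),
        )
    aligned = pcc.reindex(index=genes, columns=genes, fill_value=0.0).to_numpy()
    W = np.abs(aligned) * (mutmut.to_numpy() != 0)
    return WeightedMutGraph(pd.DataFrame(W, index=genes, columns=genes))
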