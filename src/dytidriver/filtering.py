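"""Expression-outlier calling and the dysregulation filter on mutated genes.

Driver mutations tend to perturb the transcription of the mutated gene's
network neighborhood. This module operationalizes that: genes whose
expression z-score in a patient exceeds the cutoff in magnitude are called
*outlying* (dysregulated) in that patient, and a mutated gene is retained
only if, in at least one patient carrying the mutation, at least one of its
interaction-network neighbors is outlying in that same patient. The retained
genes induce a binary adjacency matrix (the mutated-gene subnetwork) that all
downstream scoring operates on.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def compute_zscores(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across the cohort's samples.

    For gene g and sample s, ``z = (x - mean_g) / sd_g`` with mean and sample
    standard deviation (ddof=1) taken over the samples. Genes with zero
    variance, or with fewer than two finite values, get z = 0 everywhere and
    can therefore never be called outlying.
    """
    values = expr.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN / dof<=0 slices
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1)
    n_finite = np.isfinite(values).sum(axis=0)
    degenerate = (n_finite < 2) | ~np.isfinite(sd) | (sd == 0)
    if degenerate.any():
        logger.warning(
            "%d genes with zero variance or <2 finite values; z set to 0",
            int(degenerate.sum()),
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    z = (values - np.where(np.isfinite(mean), mean, 0.0)) / safe_sd
    z[:, degenerate] = 0.0
    z[~np.isfinite(z)] = 0.0
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def call_outlying(z: pd.DataFrame, cutoff: float = 2.0) -> pd.DataFrame:
    """Boolean patient x gene matrix of outlying calls.

    A gene is outlying for a patient iff its z-score strictly exceeds
    ``cutoff`` or falls strictly below ``-cutoff``; a score of exactly
    +/- cutoff is not outlying.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return (z > cutoff) | (z < -cutoff)


def filter_mutated_genes(
    mutations: pd.DataFrame,
    outlying: pd.DataFrame,
    network: nx.Graph,
    per_patient: bool = True,
) -> set[str]:
    """Retain mutated genes adjacent in the network to an outlying gene.

    Parameters
    ----------
    mutations : DataFrame
        Binary patient x gene mutation calls.
    outlying : DataFrame
        Boolean patient x gene outlying calls (from :func:`call_outlying`).
    network : Graph
        Undirected functional interaction network.
    per_patient : bool
        If True (default), the mutation and the neighbor's dysregulation must
        co-occur in the same patient. If False (pooled sensitivity mode), a
        neighbor outlying in any patient suffices.

    Returns
    -------
    set of retained gene symbols (union over patients of per-patient
    retained genes).
    """
    shared = mutations.index.intersection(outlying.index)
    if len(shared) == 0:
        raise ValueError(
            "no overlap between mutation-cohort patients and expression samples"
        )
    n_dropped = len(mutations.index) - len(shared)
    if n_dropped:
        logger.info("%d patients lack expression data and are ignored by the filter",
                    n_dropped)
    muts = mutations.loc[shared].to_numpy(dtype=bool)
    out = outlying.loc[shared]
    expr_genes = out.columns
    expr_pos = {g: i for i, g in enumerate(expr_genes)}
    out_values = out.to_numpy()

    retained: set[str] = set()
    for j, gene in enumerate(mutations.columns):
        mut_col = muts[:, j]
        if not mut_col.any() or gene not in network:
            continue
        nbr_idx = [expr_pos[n] for n in network[gene] if n in expr_pos]
        if not nbr_idx:
            continue
        nbr_out = out_values[:, nbr_idx].any(axis=1)
        hit = (mut_col & nbr_out).any() if per_patient else nbr_out.any()
        if hit:
            retained.add(gene)
    logger.info(
        "dysregulation filter retained %d of %d mutated genes",
        len(retained),
        int((mutations.sum(axis=0) > 0).sum()),
    )
    return retained


def build_mutmut(retained: set[str], network: nx.Graph) -> pd.DataFrame:
    """Binary adjacency matrix of the subnetwork induced by retained genes.

    Genes with no retained neighbor stay as isolated (all-zero) rows; they
    score zero downstream. Gene order is sorted for reproducible output.
    """
    if not retained:
        raise ValueError(
            "dysregulation filter retained no genes; check patient overlap, "
            "z-score cutoff and network coverage"
        )
    genes = sorted(retained)
    sub = network.subgraph([g for g in genes if g in network])
    adj = pd.DataFrame(0, index=genes, columns=genes, dtype=np.int8)
    for a, b in sub.edges():
        adj.loc[a, b] = 1
        adj.loc[b, a] = 1
    return adj
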