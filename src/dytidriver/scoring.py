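"""Edge clustering coefficients and the final driver-gene ranking.

For an edge (i, j) of the weighted mutated graph W the edge clustering
coefficient is

    ECC(i, j) = sum_{k in N_i ^ N_j} (W_ik + W_jk) / min(d_i, d_j)

where N_i is the set of nonzero-weight neighbors of i and d_i = |N_i|. The
denominator is implemented exactly as printed in the method's definition,
min(d_i, d_j); the classical edge-clustering literature instead uses
min(d_i - 1, d_j - 1) as the maximal number of triangles through the edge,
and that variant is available via ``classic=True`` (guarded by
max(denominator, 1)). Pairs that are not edges of W, or share no common
neighbor, get ECC 0.

A gene's module score M_i sums the ECC values of its incident edges, its
variation frequency V_i is the fraction of cohort patients in which it is
mutated, and the final ranking score is F_i = V_i * M_i, sorted descending.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .weighting import WeightedMutGraph


def compute_ecc(graph: WeightedMutGraph, classic: bool = False) -> pd.DataFrame:
    """Edge clustering coefficient for every edge of the weighted graph.

    Returns a symmetric gene x gene DataFrame, zero off the support of W.
    """
    W = graph.W.to_numpy(dtype=float)
    support = (W != 0).astype(float)
    d = support.sum(axis=1)

    # sum over common neighbors k of (W_ik + W_jk):
    # (W @ A)_ij = sum_k W_ik A_jk restricts W_ik to k adjacent to both.
    numerator = W @ support + support @ W
    dmin = np.minimum.outer(d, d)
    if classic:
        denom = np.maximum(dmin - 1, 1.0)
    else:
        denom = np.where(dmin > 0, dmin, 1.0)
    ecc = np.where(support > 0, numerator / denom, 0.0)
    return pd.DataFrame(ecc, index=graph.W.index, columns=graph.W.columns)


def module_score(ecc: pd.DataFrame) -> pd.Series:
    """M_i = sum of ECC over gene i's incident edges; isolated genes get 0."""
    return ecc.sum(axis=1)


def variation_frequency(mutations: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Fraction of cohort patients in which each gene carries a mutation.

    The denominator is the full tumor cohort regardless of the
    dysregulation filter; genes absent from the cohort get frequency 0.
    """
    n_patients = mutations.shape[0]
    if n_patients == 0:
        raise ValueError("mutation cohort has no patients")
    counts = mutations.reindex(columns=genes, fill_value=0).sum(axis=0)
    return counts / n_patients


def final_scores(M: pd.Series, V: pd.Series) -> pd.DataFrame:
    """Unranked driver-score table with F_i = V_i * M_i."""
    missing = set(M.index).symmetric_difference(V.index)
    if missing:
        raise ValueError(f"module-score and frequency gene sets differ: {sorted(missing)[:5]}")
    V = V.reindex(M.index)
    return pd.DataFrame(
        {
            "gene": M.index,
            "variation_frequency": V.to_numpy(dtype=float),
            "module_score": M.to_numpy(dtype=float),
            "final_score": (V * M).to_numpy(dtype=float),
        }
    ).reset_index(drop=True)


def rank_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Sort by final score descending and assign ranks 1..n.

    Ties break by variation frequency descending, then gene symbol
    ascending, giving a deterministic total order and byte-stable output.
    """
    out = table.sort_values(
        by=["final_score", "variation_frequency", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
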