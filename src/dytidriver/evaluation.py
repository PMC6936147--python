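"""Top-K evaluation of a driver ranking against a benchmark gene set.

For each K from 1 to K_max the top-K ranked genes are treated as predicted
drivers; TP counts predictions in the benchmark, FP = K - TP, and FN counts
benchmark genes in the ranking universe that did not make the top K (genes
never scored cannot be retrieved at any K, so the false-negative universe is
the benchmark restricted to ranked genes; the unrestricted benchmark size is
reported alongside). Precision = TP/(TP+FP), recall = TP/(TP+FN), and the
F-score is their harmonic mean, defined as 0 when both are 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .scoring import rank_genes

logger = logging.getLogger(__name__)

CURVE_COLUMNS = ["K", "TP", "FP", "FN", "precision", "recall", "fscore"]


def evaluate_topk(
    ranking: pd.DataFrame, benchmark: set[str], k_max: int = 200
) -> pd.DataFrame:
    """Precision/recall/F-score curves over K = 1..k_max.

    ``ranking`` must carry ``gene`` in rank order (as produced by
    :func:`dytidriver.scoring.rank_genes`); ``k_max`` is truncated to the
    ranking length with a warning. The returned DataFrame has columns
    K, TP, FP, FN, precision, recall, fscore and attrs
    ``benchmark_in_universe`` / ``benchmark_total``.
    """
    if not benchmark:
        raise ValueError("benchmark gene set is empty")
    if len(ranking) == 0:
        raise ValueError("ranking is empty")
    genes = ranking["gene"].tolist()
    universe = set(genes)
    positives = benchmark & universe
    n_pos = len(positives)
    if k_max > len(genes):
        logger.warning(
            "k_max %d exceeds ranking length %d; truncating", k_max, len(genes)
        )
        k_max = len(genes)
    hits = np.cumsum([g in positives for g in genes[:k_max]])
    K = np.arange(1, k_max + 1)
    TP = hits
    FP = K - TP
    FN = n_pos - TP
    precision = TP / K
    recall = TP / n_pos if n_pos else np.zeros_like(TP, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        fscore = np.where(
            (precision + recall) > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    curve = pd.DataFrame(
        {
            "K": K,
            "TP": TP,
            "FP": FP,
            "FN": FN,
            "precision": precision,
            "recall": recall,
            "fscore": fscore,
        }
    )
    curve.attrs["benchmark_in_universe"] = n_pos
    curve.attrs["benchmark_total"] = len(benchmark)
    return curve


def frequency_baseline(mutations: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by mutation frequency alone (sanity baseline).

    Module scores are fixed at 1 so the final score equals the variation
    frequency; ties break exactly as in the main ranking.
    """
    if mutations.shape[0] == 0:
        raise ValueError("mutation cohort has no patients")
    V = mutations.sum(axis=0) / mutations.shape[0]
    table = pd.DataFrame(
        {
            "gene": V.index,
            "variation_frequency": V.to_numpy(dtype=float),
            "module_score": 1.0,
            "final_score": V.to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    return rank_genes(table)


def write_curves(curve: pd.DataFrame, path) -> None:
    """Write an evaluation curve as TSV with 12-significant-digit floats."""
    with open(path, "w") as fh:
        fh.write("\t".join(CURVE_COLUMNS) + "\n")
        for row in curve.itertuples(index=False):
            fh.write(
                f"{row.K}\t{row.TP}\t{row.FP}\t{row.FN}\t"
                f"{row.precision:.12g}\t{row.recall:.12g}\t{row.fscore:.12g}\n"
            )


def plot_curves(curve: pd.DataFrame, path=None, title: str = ""):
    """Plot the precision, recall and F-score curves against K."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for col in ("precision", "recall", "fscore"):
        ax.plot(curve["K"], curve[col], label=col)
    ax.set_xlabel("top K predicted driver genes")
    ax.set_ylabel("value")
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
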