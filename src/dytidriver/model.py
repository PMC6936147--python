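"""Model/results interface tying the pipeline stages together.

:class:`DyTidriver` holds the data (somatic mutation calls, tumor
expression, a functional interaction network and one or more tissue
expression matrices) plus the tunables; :meth:`DyTidriver.fit` runs the
four-stage procedure — outlier calling, the dysregulation filter,
tissue-specific co-expression weighting, and ECC-based scoring — and
returns a :class:`DriverResults` carrying the ranked driver-score table,
the intermediate matrices and run diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import evaluation, filtering, io, scoring, weighting
from .weighting import WeightedMutGraph


class DyTidriver:
    """Tissue-aware network model for prioritizing cancer driver genes.

    Parameters
    ----------
    mutations : DataFrame
        Binary patient x gene somatic mutation calls.
    tumor_expression : DataFrame
        Patient x gene tumor expression, used only to call per-patient
        outlying (dysregulated) genes.
    network : networkx.Graph
        Undirected gene functional interaction network.
    tissue_expressions : DataFrame or sequence of DataFrame
        Sample x gene expression of the disease-relevant tissue(s), used for
        co-expression edge weights. Several tissues are thresholded
        separately and averaged.
    zscore_cutoff : float
        Outlying-gene cutoff: |z| strictly greater than this (default 2.0).
    pcc_cutoff : float
        Co-expression cutoff: |r| strictly greater than this (default 0.3).
    per_patient : bool
        Require mutation and neighbor dysregulation in the same patient
        (default). False pools outliers across patients (sensitivity mode).
    classic_ecc : bool
        Use the classical min(d_i - 1, d_j - 1) triangle denominator
        instead of min(d_i, d_j).
    log2_transform : bool
        Apply log2(x + 1) to tumor expression before z-scoring.
    tumor_samples : sequence of str, optional
        Explicit tumor-sample annotation; when given, expression samples and
        mutation patients are restricted to it. By default every sample is
        treated as a tumor.
    """

    def __init__(
        self,
        mutations: pd.DataFrame,
        tumor_expression: pd.DataFrame,
        network: nx.Graph,
        tissue_expressions: pd.DataFrame | Sequence[pd.DataFrame],
        *,
        zscore_cutoff: float = 2.0,
        pcc_cutoff: float = 0.3,
        per_patient: bool = True,
        classic_ecc: bool = False,
        log2_transform: bool = False,
        tumor_samples: Sequence[str] | None = None,
    ):
        if isinstance(tissue_expressions, pd.DataFrame):
            tissue_expressions = [tissue_expressions]
        self.mutations = mutations
        self.tumor_expression = tumor_expression
        self.network = network
        self.tissue_expressions = list(tissue_expressions)
        if not self.tissue_expressions:
            raise ValueError("at least one tissue expression matrix is required")
        self.zscore_cutoff = zscore_cutoff
        self.pcc_cutoff = pcc_cutoff
        self.per_patient = per_patient
        self.classic_ecc = classic_ecc
        self.log2_transform = log2_transform
        self.tumor_samples = list(tumor_samples) if tumor_samples is not None else None

    @classmethod
    def from_files(
        cls,
        mutations_path,
        expression_path,
        network_path,
        tissue_paths: Sequence,
        *,
        mutations_format: str = "binary-tsv",
        network_format: str = "edge-list",
        orientation: str = "genes-in-columns",
        **kwargs,
    ) -> "DyTidriver":
        """Build a model directly from the standard on-disk formats."""
        return cls(
            io.read_mutations(mutations_path, format=mutations_format),
            io.read_expression(expression_path, orientation=orientation),
            io.read_network(network_path, format=network_format),
            [io.read_expression(p, orientation=orientation) for p in tissue_paths],
            **kwargs,
        )

    def fit(self) -> "DriverResults":
        """Run the pipeline and return the ranked results."""
        mutations = self.mutations
        expr = self.tumor_expression
        if self.tumor_samples is not None:
            expr = expr.loc[expr.index.intersection(self.tumor_samples)]
            mutations = mutations.loc[mutations.index.intersection(self.tumor_samples)]
        if self.log2_transform:
            expr = np.log2(expr + 1.0)

        z = filtering.compute_zscores(expr)
        outlying = filtering.call_outlying(z, cutoff=self.zscore_cutoff)
        retained = filtering.filter_mutated_genes(
            mutations, outlying, self.network, per_patient=self.per_patient
        )
        mutmut = filtering.build_mutmut(retained, self.network)

        per_tissue = [
            weighting.compute_tissue_pcc(t, pcc_cutoff=self.pcc_cutoff)
            for t in self.tissue_expressions
        ]
        pcc = weighting.average_tissue_pcc(per_tissue)
        graph = weighting.weight_mutmut(mutmut, pcc)

        ecc = scoring.compute_ecc(graph, classic=self.classic_ecc)
        M = scoring.module_score(ecc)
        V = scoring.variation_frequency(mutations, graph.genes)
        ranking = scoring.rank_genes(scoring.final_scores(M, V))

        n_mutated = int((mutations.sum(axis=0) > 0).sum())
        diagnostics = {
            "n_patients": int(mutations.shape[0]),
            "n_mutated_genes": n_mutated,
            "n_retained_genes": len(retained),
            "n_filtered_out": n_mutated - len(retained),
            "n_mutmut_edges": int(mutmut.to_numpy().sum() // 2),
            "n_weighted_edges": int((graph.W.to_numpy() != 0).sum() // 2),
            "n_outlying_calls": int(outlying.to_numpy().sum()),
            "zscore_cutoff": self.zscore_cutoff,
            "pcc_cutoff": self.pcc_cutoff,
            "n_tissues": len(self.tissue_expressions),
        }
        return DriverResults(
            model=self,
            ranking=ranking,
            retained_genes=retained,
            mutmut=mutmut,
            weighted_graph=graph,
            ecc=ecc,
            outlying=outlying,
            diagnostics=diagnostics,
        )


@dataclass
class DriverResults:
    """Fitted driver ranking plus intermediates and diagnostics."""

    model: DyTidriver
    ranking: pd.DataFrame
    retained_genes: set[str]
    mutmut: pd.DataFrame
    weighted_graph: WeightedMutGraph
    ecc: pd.DataFrame
    outlying: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    def top(self, n: int = 20) -> pd.DataFrame:
        """The first n rows of the ranking."""
        return self.ranking.head(n)

    def evaluate(self, benchmark: set[str], k_max: int = 200) -> pd.DataFrame:
        """Top-K precision/recall/F-score curves against a benchmark set."""
        return evaluation.evaluate_topk(self.ranking, benchmark, k_max=k_max)

    def save(self, path, benchmark: set[str] | None = None) -> None:
        """Write the ranked table as TSV (see :func:`dytidriver.io.write_ranking`)."""
        io.write_ranking(self.ranking, Path(path), benchmark=benchmark)

    def summary(self, n_top: int = 10) -> str:
        """Human-readable run summary with the top-ranked genes."""
        d = self.diagnostics
        lines = [
            "DyTidriver ranking summary",
            "=" * 60,
            f"patients: {d['n_patients']}   mutated genes: {d['n_mutated_genes']}",
            f"retained after dysregulation filter: {d['n_retained_genes']} "
            f"(dropped {d['n_filtered_out']})",
            f"mutated-gene subnetwork edges: {d['n_mutmut_edges']} "
            f"(co-expression weighted: {d['n_weighted_edges']})",
            f"cutoffs: |z| > {d['zscore_cutoff']}, |r| > {d['pcc_cutoff']} "
            f"over {d['n_tissues']} tissue(s)",
            "-" * 60,
            f"{'rank':>4} {'gene':<12} {'V':>8} {'M':>10} {'F':>10}",
        ]
        for row in self.ranking.head(n_top).itertuples(index=False):
            lines.append(
                f"{row.rank:>4} {row.gene:<12} {row.variation_frequency:>8.4f} "
                f"{row.module_score:>10.4f} {row.final_score:>10.4f}"
            )
        return "\n".join(lines)
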