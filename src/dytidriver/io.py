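"""Readers and writers for mutation, expression, network and gene-list inputs.

All gene and sample identifiers are harmonized by :func:`normalize_symbols`
(trim + uppercase, order-preserving); identifiers present in one input but not
another are excluded from joint computations downstream, with dropped counts
surfaced in the run diagnostics rather than raised as errors.

In-memory containers follow the field's conventions:

* mutation cohorts and expression matrices are :class:`pandas.DataFrame`
  objects (patients/samples on the index, genes on the columns),
* functional interaction networks are undirected :class:`networkx.Graph`
  objects over gene symbols,
* benchmark gene lists are plain ``set`` objects of symbols.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKING_COLUMNS = [
    "rank",
    "gene",
    "variation_frequency",
    "module_score",
    "final_score",
    "in_benchmark",
]


class FormatError(ValueError):
    """A structural problem with an input file (missing column, bad shape)."""


def normalize_symbols(raw: Iterable[str]) -> list[str]:
    """Trim whitespace and uppercase gene symbols, preserving order.

    Raises
    ------
    ValueError
        If any entry is empty after trimming.
    """
    out = []
    for i, sym in enumerate(raw):
        s = str(sym).strip().upper()
        if not s:
            raise ValueError(f"empty gene symbol at position {i}")
        out.append(s)
    return out


def read_mutations(
    path: str | Path,
    format: str = "binary-tsv",
    exclude_classes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Read somatic mutation calls into a binary patient x gene matrix.

    Parameters
    ----------
    path : path
        Input file.
    format : {"maf", "binary-tsv"}
        ``maf``: tab-separated with at least ``Hugo_Symbol`` and
        ``Tumor_Sample_Barcode`` columns; every variant record sets the
        (patient, gene) call to 1, duplicates collapse. ``binary-tsv``:
        first column patient IDs, remaining columns gene symbols, 0/1 cells.
    exclude_classes : iterable of str, optional
        MAF only: drop variant records whose ``Variant_Classification``
        matches (case-insensitive), e.g. ``{"Silent"}``. Off by default:
        every somatic record counts.

    Returns
    -------
    DataFrame of int8 in {0, 1}, patients on the index, genes on the columns.
    """
    path = Path(path)
    if format == "maf":
        maf = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        for col in ("Hugo_Symbol", "Tumor_Sample_Barcode"):
            if col not in maf.columns:
                raise FormatError(f"MAF file {path} is missing required column {col!r}")
        if exclude_classes:
            if "Variant_Classification" not in maf.columns:
                raise FormatError(
                    f"MAF file {path} has no Variant_Classification column "
                    "to filter on"
                )
            drop = {c.strip().lower() for c in exclude_classes}
            keep = ~maf["Variant_Classification"].str.strip().str.lower().isin(drop)
            logger.info("excluded %d variant records by class", int((~keep).sum()))
            maf = maf[keep]
        if len(maf) == 0:
            raise ValueError(f"no variant records left in {path}")
        genes = normalize_symbols(maf["Hugo_Symbol"])
        patients = [str(p).strip() for p in maf["Tumor_Sample_Barcode"]]
        pairs = pd.DataFrame({"patient": patients, "gene": genes})
        calls = (
            pd.crosstab(pairs["patient"], pairs["gene"])
            .astype(bool)
            .astype(np.int8)
        )
        calls.index.name = None
        calls.columns.name = None
        return calls
    if format == "binary-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = normalize_symbols(df.columns)
        df.index = [str(p).strip() for p in df.index]
        _check_unique(df.index, "patient", path)
        _check_unique(df.columns, "gene", path)
        values = df.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary entry {values[r, c]!r} at patient "
                f"{df.index[r]!r}, gene {df.columns[c]!r} in {path}"
            )
        return df.astype(np.int8)
    raise ValueError(f"unknown mutation format {format!r}")


def read_expression(
    path: str | Path, orientation: str = "genes-in-columns"
) -> pd.DataFrame:
    """Read an expression matrix into canonical sample x gene orientation.

    Duplicate gene columns (e.g. multiple array probes mapping to one symbol)
    are collapsed by their arithmetic mean.

    Parameters
    ----------
    orientation : {"genes-in-columns", "genes-in-rows"}
        Which axis of the file carries gene symbols.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    # read the header separately: pandas would mangle duplicate gene
    # columns (multi-probe symbols) to "SYM.1" before we can collapse them
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=1, header=None)
    df.columns = header[1:]
    if orientation == "genes-in-rows":
        df = df.T
    elif orientation != "genes-in-columns":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.columns = normalize_symbols(df.columns)
    df.index = [str(s).strip() for s in df.index]
    _check_unique(df.index, "sample", path)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    if df.columns.has_duplicates:
        n_before = df.shape[1]
        df = df.T.groupby(level=0, sort=False).mean().T
        logger.info(
            "collapsed %d duplicate gene columns in %s by mean",
            n_before - df.shape[1],
            path,
        )
    if df.shape[1] == 0:
        raise FormatError(f"expression matrix {path} has no gene columns")
    df.index.name = None
    df.columns.name = None
    return df


def read_network(path: str | Path, format: str = "edge-list") -> nx.Graph:
    """Read an undirected gene interaction network.

    Self-loops are dropped and reversed duplicate edges merged; the number of
    dropped records is logged.

    Parameters
    ----------
    format : {"edge-list", "sif"}
        ``edge-list``: two whitespace-separated gene symbols per line.
        ``sif``: three columns, the middle (relation type) ignored.
    """
    path = Path(path)
    need = 2 if format == "edge-list" else 3
    if format not in ("edge-list", "sif"):
        raise ValueError(f"unknown network format {format!r}")
    graph = nx.Graph()
    dropped_loops = dropped_dups = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < need:
                raise FormatError(
                    f"{path}:{lineno}: expected at least {need} columns, "
                    f"got {len(parts)}"
                )
            a = parts[0]
            b = parts[2] if format == "sif" else parts[1]
            a, b = normalize_symbols([a, b])
            if a == b:
                dropped_loops += 1
                continue
            if graph.has_edge(a, b):
                dropped_dups += 1
                continue
            graph.add_edge(a, b)
    if dropped_loops or dropped_dups:
        logger.info(
            "%s: dropped %d self-loops and %d duplicate edges",
            path,
            dropped_loops,
            dropped_dups,
        )
    return graph


def read_gene_list(path: str | Path, label: str = "") -> set[str]:
    """Read a one-symbol-per-line gene list (``#`` comments allowed)."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(line)
    return set(normalize_symbols(symbols))


def write_ranking(
    table: pd.DataFrame, path: str | Path, benchmark: set[str] | None = None
) -> None:
    """Write a ranked driver-score table as TSV.

    Columns: ``rank gene variation_frequency module_score final_score
    in_benchmark``. Floats carry 12 significant digits so that a
    write/read round trip reproduces scores to well below 1e-9.
    """
    out = table.copy()
    if benchmark is not None:
        out["in_benchmark"] = out["gene"].isin(benchmark).astype(int).astype(str)
    elif "in_benchmark" not in out.columns:
        out["in_benchmark"] = "NA"
    out = out[RANKING_COLUMNS]
    with open(path, "w") as fh:
        fh.write("\t".join(RANKING_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            fh.write(
                f"{row.rank}\t{row.gene}\t{row.variation_frequency:.12g}\t"
                f"{row.module_score:.12g}\t{row.final_score:.12g}\t"
                f"{row.in_benchmark}\n"
            )


def read_ranking(path: str | Path) -> pd.DataFrame:
    """Parse a TSV written by :func:`write_ranking`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "in_benchmark": str})
    missing = [c for c in RANKING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ranking file {path} is missing columns {missing}")
    return df


def _check_unique(ids: Sequence[str], kind: str, path: Path) -> None:
    index = pd.Index(ids)
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {kind} identifiers in {path}: {dups[:5]}")
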