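"""Readers and writers for the pipeline's plain-text interchange formats.

Beta matrix: TSV, row 1 = ``site_id`` followed by sample ids.
Annotation: TSV with header ``site_id  gene_symbol  [chromosome  position]``.
Clinical: TSV with header ``sample_id group event time age stage_T stage_N stage_M``.
Prior network: two-column CSV edge list (header auto-detected).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CLINICAL_COLUMNS,
    BetaMatrix,
    ClinicalTable,
    PriorNetwork,
    SiteAnnotation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_annotation",
    "write_annotation",
    "read_clinical",
    "write_clinical",
    "read_prior_network",
    "write_prior_network",
    "write_weighted_network",
]

# tokens that mark the first row of an edge-list file as a header
_HEADER_TOKENS = {
    "source", "target", "from", "to", "gene_a", "gene_b",
    "node1", "node2", "gene1", "gene2", "parent", "child",
}


def read_annotation(path: str | Path) -> SiteAnnotation:
    """Load a probe annotation table; multi-gene probes keep the first symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "site_id" not in df.columns or "gene_symbol" not in df.columns:
        raise ValueError("annotation must have site_id and gene_symbol columns")
    multi = df["gene_symbol"].str.contains(";", na=False)
    if multi.any():
        n = int(multi.sum())
        logger.warning("%d multi-gene probes resolved to their first symbol", n)
        df.loc[multi, "gene_symbol"] = df.loc[multi, "gene_symbol"].str.split(";").str[0]
    df = df.set_index("site_id")
    if "position" in df.columns:
        df["position"] = pd.to_numeric(df["position"], errors="coerce")
    return SiteAnnotation(df)


def read_beta_matrix(
    path: str | Path, annotation_path: str | Path | None = None
) -> BetaMatrix | tuple[BetaMatrix, SiteAnnotation]:
    """Read a site x sample beta TSV (and optionally its annotation).

    Non-numeric cells become missing; values outside [0, 1] raise with the
    offending site/sample named; duplicate ids are a hard error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    bm = BetaMatrix(df)  # validation happens in the container
    if annotation_path is None:
        return bm
    return bm, read_annotation(annotation_path)


def write_beta_matrix(bm: BetaMatrix, path: str | Path) -> None:
    out = bm.values.copy()
    out.index.name = "site_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def write_annotation(annot: SiteAnnotation, path: str | Path) -> None:
    out = annot.table.copy()
    out.index.name = "site_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("clinical table must have a sample_id column")
    df = df.set_index("sample_id")
    for c in CLINICAL_COLUMNS:
        if c == "group":
            continue
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    out = clin.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_prior_network(
    path: str | Path, columns: tuple[int, int] = (0, 1), source: str | None = None
) -> PriorNetwork:
    """Read an undirected edge list from a CSV such as HumanSignalingNetwork_v6.

    The first row is treated as a header when either of the selected cells
    matches a common column name (Source/Target/From/To/...). Self-loops are
    dropped and reciprocal duplicates collapsed.
    """
    path = Path(path)
    raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    if raw.shape[1] <= max(columns):
        raise ValueError(
            f"edge list has {raw.shape[1]} columns, need at least {max(columns) + 1}"
        )
    first = [str(raw.iloc[0, c]).strip().lower() for c in columns]
    if any(tok in _HEADER_TOKENS for tok in first):
        raw = raw.iloc[1:]
    a = raw.iloc[:, columns[0]].astype(str).str.strip()
    b = raw.iloc[:, columns[1]].astype(str).str.strip()
    edges = [
        (x, y)
        for x, y in zip(a, b)
        if x and y and x.lower() not in ("nan", "na") and y.lower() not in ("nan", "na")
    ]
    net = PriorNetwork(edges=edges, source=source or path.name)
    if len(net) < 1:
        raise ValueError("prior network has no edges after cleaning")
    logger.info("prior network: %d edges over %d genes", len(net), len(net.nodes))
    return net


def write_prior_network(net: PriorNetwork, path: str | Path) -> None:
    pd.DataFrame(net.edges, columns=["source", "target"]).to_csv(path, index=False)


def write_weighted_network(net, path: str | Path, fmt: str = "tsv") -> None:
    """Export a weighted network as a TSV edge list or GraphML."""
    if fmt == "tsv":
        df = pd.DataFrame(net.edges, columns=["gene_a", "gene_b", "weight"])
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif fmt == "graphml":
        g = net.to_igraph()
        g.vs["component"] = [net.component_id.get(n, 0) for n in net.nodes]
        g.write_graphml(str(path))
    else:
        raise ValueError(f"unknown network format {fmt!r}")
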