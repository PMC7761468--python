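"""Gene -> enzyme -> pathway cross-reference.

A local join replacing live annotation services: genes carrying TAVs are
matched against a user-supplied table of (gene_id, enzyme EC-style code,
pathway name) rows, with per-pathway gene/enzyme summaries.  Genes absent
from the table are reported separately, so the join is lossless on the
TAV side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = ["PathwayTable", "load_pathway_table", "cross_reference", "XrefReport"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayTable:
    rows: pd.DataFrame  # columns: gene_id, enzyme, pathway

    def __post_init__(self) -> None:
        required = ["gene_id", "enzyme", "pathway"]
        if list(self.rows.columns[:3]) != required:
            raise ValueError(f"pathway table needs columns {required}")
        if self.rows.duplicated(subset=required).any():
            dupes = self.rows[self.rows.duplicated(subset=required)]
            raise ValueError(
                f"duplicate (gene, enzyme, pathway) triples: {dupes.values.tolist()}"
            )


def load_pathway_table(path: str | Path) -> PathwayTable:
    rows = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return PathwayTable(rows[["gene_id", "enzyme", "pathway"]])


@dataclass(frozen=True)
class XrefReport:
    annotated: pd.DataFrame  # gene_id, enzyme, pathway (+ carried TAV columns)
    unannotated: list[str]
    pathway_summary: pd.DataFrame  # pathway, n_genes, n_enzymes


def cross_reference(
    tav_genes: Sequence[str] | pd.DataFrame,
    table: PathwayTable,
) -> XrefReport:
    """Inner-join TAV-carrying genes with the pathway table.

    ``tav_genes`` is either a list of gene ids or a DataFrame with a
    ``gene_id`` column whose remaining columns (TAV details) are carried
    into the annotated report.  Every input gene lands in exactly one of
    the annotated / unannotated sections.
    """
    if isinstance(tav_genes, pd.DataFrame):
        genes_df = tav_genes.drop_duplicates(subset="gene_id")
    else:
        genes_df = pd.DataFrame({"gene_id": list(dict.fromkeys(tav_genes))})
    if table.rows.empty:
        logger.warning("empty pathway table: all %d genes unannotated", len(genes_df))
    annotated = genes_df.merge(table.rows, on="gene_id", how="inner")
    hit = set(annotated["gene_id"])
    unannotated = [g for g in genes_df["gene_id"] if g not in hit]
    if annotated.empty:
        summary = pd.DataFrame(columns=["pathway", "n_genes", "n_enzymes"])
    else:
        summary = (
            annotated.groupby("pathway")
            .agg(n_genes=("gene_id", "nunique"), n_enzymes=("enzyme", "nunique"))
            .reset_index()
        )
    return XrefReport(annotated, unannotated, summary)
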