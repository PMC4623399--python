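"""Compartment-aware RPKM quantification and expressed-gene summaries.

Transcript abundance for each gene in each library is expressed as
RPKM = 1e9 * C / (N * L), with C the mappable reads on the gene, N the
library's total mappable reads and L the gene length in bp.  Genes are
tallied by genome of origin — nuclear (Chr1-5), mitochondrial (ATMG) or
chloroplast (ATCG) — and by gene type, producing the expressed-gene
cross-tabulation used to summarize an annotation release.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COMPARTMENTS",
    "GENE_TYPES",
    "CountMatrix",
    "compute_rpkm",
    "detect_expressed",
    "summarize_gene_types",
    "partition_by_compartment",
]

COMPARTMENTS = ("nuclear", "mitochondrial", "chloroplast")

GENE_TYPES = (
    "protein_coding",
    "pre_tRNA",
    "rRNA",
    "snRNA",
    "snoRNA",
    "miRNA",
    "other_RNA",
    "pseudogene",
    "TE",
)

#: compartment -> row label used in the summary table
COMPARTMENT_LABELS: Mapping[str, str] = {
    "nuclear": "Chr1-5",
    "mitochondrial": "ATMG",
    "chloroplast": "ATCG",
}


@dataclass
class CountMatrix:
    """Integer read counts per gene per library, with library totals.

    ``counts`` is indexed by gene_id with one integer column per
    library; ``library_sizes`` maps library name to its total mappable
    reads N (which may exceed the column sum: N counts reads on genes
    outside the table too).
    """

    counts: pd.DataFrame
    library_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lib in self.counts.columns:
            if lib not in self.library_sizes:
                raise ValueError(f"no library size given for {lib!r}")
            n = self.library_sizes[lib]
            if n <= 0:
                raise ValueError(f"library size for {lib!r} must be positive")
            col = self.counts[lib]
            if (col < 0).any():
                raise ValueError(f"negative counts in library {lib!r}")
            if col.sum() > n:
                raise ValueError(
                    f"gene counts in {lib!r} exceed the library total {n}"
                )


def _check_annotation(annot: pd.DataFrame) -> None:
    required = {"gene_id", "compartment", "gene_type", "length_bp"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"annotation is missing columns: {sorted(missing)}")
    bad = set(annot["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ValueError(f"unknown compartment labels: {sorted(bad)}")
    if (annot["length_bp"] < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")


def compute_rpkm(counts: CountMatrix, annot: pd.DataFrame) -> pd.DataFrame:
    """RPKM = 1e9 * C / (N * L) per gene per library.

    Every gene in the count matrix must be annotated with a length;
    genes missing from the annotation are reported by id.
    """
    _check_annotation(annot)
    lengths = annot.set_index("gene_id")["length_bp"]
    missing = counts.counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise ValueError(
            f"genes without annotation: {sorted(missing.tolist())[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    length = lengths.reindex(counts.counts.index).to_numpy(dtype=float)
    out = {}
    for lib in counts.counts.columns:
        n = counts.library_sizes[lib]
        c = counts.counts[lib].to_numpy(dtype=float)
        out[lib] = 1e9 * c / (n * length)
    return pd.DataFrame(out, index=counts.counts.index)


def detect_expressed(counts: CountMatrix, min_count: int = 1) -> pd.Series:
    """Flag genes reaching ``min_count`` reads in at least one library.

    The detection criterion is an explicit choice (default: any mapped
    read); tighten ``min_count`` for stricter definitions.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return (counts.counts >= min_count).any(axis=1)


def summarize_gene_types(
    annot: pd.DataFrame, expressed_ids: pd.Index | list[str]
) -> pd.DataFrame:
    """Cross-tabulate expressed features by compartment x gene type.

    Rows are the compartment groups (Chr1-5, ATMG, ATCG) plus a
    ``Total expressed genes`` row; columns are the gene types plus a
    leading ``Total`` column.  Works at gene or transcript level
    depending on what the annotation rows represent.
    """
    _check_annotation(annot)
    sub = annot[annot["gene_id"].isin(pd.Index(expressed_ids))]
    table = pd.crosstab(sub["compartment"], sub["gene_type"])
    table = table.reindex(
        index=list(COMPARTMENTS), columns=list(GENE_TYPES), fill_value=0
    )
    table.index = [COMPARTMENT_LABELS[c] for c in COMPARTMENTS]
    table.insert(0, "Total", table.sum(axis=1))
    total_row = table.sum(axis=0)
    table.loc["Total expressed genes"] = total_row
    table.index.name = None
    table.columns.name = None
    return table


def total_expressed(summary: pd.DataFrame) -> int:
    """Grand total of the expressed-feature summary table."""
    return int(summary.loc["Total expressed genes", "Total"])


def partition_by_compartment(
    expr: pd.DataFrame, annot: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Split an expression (or count) matrix by genome of origin.

    Returns a disjoint, exhaustive partition keyed by compartment; rows
    of ``expr`` must all be annotated.
    """
    _check_annotation(annot)
    comp = annot.set_index("gene_id")["compartment"]
    missing = expr.index.difference(comp.index)
    if len(missing) > 0:
        raise ValueError(f"unannotated genes: {sorted(missing.tolist())[:10]}")
    comp = comp.reindex(expr.index)
    return {c: expr.loc[comp == c] for c in COMPARTMENTS}
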