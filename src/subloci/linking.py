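"""Enhancer-gene linking from correlated activity across tissues.

For each enhancer, candidate target genes (TSS within +/-500 kb,
expressed in both reference tissue and differentiated cardiomyocytes) are
tested with a one-sided rank test for higher expression in tissues where
the enhancer is active.  A nearest-gene baseline is provided for
comparison, and linked gene sets feed 2x2 phenotype-enrichment tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import AnnotationSet, GenomicInterval
from .stats import Table2x2, rank_sum


@dataclass(frozen=True)
class LinkConfig:
    window_bp: int = 500_000
    min_rpkm: float = 1.0
    alpha: float = 0.05
    reference_tissue: str = "left_ventricle"
    cardiomyocyte_column: str = "cardiomyocyte"

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class GeneLink:
    enhancer_id: str
    gene_id: str
    pvalue: float | None
    linked: bool
    status: str  # "tested" | "skipped_all_active" | "skipped_all_inactive"


def gene_tss(gene: GenomicInterval) -> int:
    """TSS of a gene interval: start for + strand, end - 1 for - strand."""
    if gene.strand == "-":
        return gene.end - 1
    return gene.start


def candidate_genes(
    enhancer: GenomicInterval,
    genes: AnnotationSet,
    expression: pd.DataFrame,
    cfg: LinkConfig = LinkConfig(),
) -> list[GenomicInterval]:
    """Genes with TSS within the window of the enhancer midpoint and
    expression >= min_rpkm in both required columns."""
    for col in (cfg.reference_tissue, cfg.cardiomyocyte_column):
        if col not in expression.columns:
            raise ValueError(f"expression matrix lacks column {col!r}")
    mid = enhancer.midpoint
    out = []
    for gene in genes.intervals(enhancer.chrom):
        if gene.name is None or gene.name not in expression.index:
            continue
        if abs(gene_tss(gene) - mid) > cfg.window_bp:
            continue
        row = expression.loc[gene.name]
        if (
            row[cfg.reference_tissue] >= cfg.min_rpkm
            and row[cfg.cardiomyocyte_column] >= cfg.min_rpkm
        ):
            out.append(gene)
    return out


def link_test(
    enhancer_id: str,
    gene_id: str,
    activity: np.ndarray,
    expression: np.ndarray,
    cfg: LinkConfig = LinkConfig(),
) -> GeneLink:
    """One-sided rank test: is the gene more expressed in tissues where
    the enhancer is active?

    ``activity`` is the boolean activity row of the enhancer and
    ``expression`` the matched expression row of the gene (same tissue
    order).  Degenerate splits (all active / all inactive) are skipped
    with a reason rather than tested.
    """
    act = np.asarray(activity, dtype=bool)
    expr = np.asarray(expression, dtype=float)
    if act.shape != expr.shape:
        raise ValueError("activity and expression rows must align")
    if act.all():
        return GeneLink(enhancer_id, gene_id, None, False, "skipped_all_active")
    if not act.any():
        return GeneLink(enhancer_id, gene_id, None, False, "skipped_all_inactive")
    res = rank_sum(expr[act], expr[~act], sidedness="one", alternative="greater")
    return GeneLink(enhancer_id, gene_id, res.pvalue, res.pvalue < cfg.alpha,
                    "tested")


def link_enhancer(
    enhancer: GenomicInterval,
    enhancer_id: str,
    genes: AnnotationSet,
    activity_row: np.ndarray,
    expression: pd.DataFrame,
    tissue_columns: list[str],
    cfg: LinkConfig = LinkConfig(),
) -> list[GeneLink]:
    """Candidate selection followed by the link test for one enhancer."""
    links = []
    for gene in candidate_genes(enhancer, genes, expression, cfg):
        expr_row = expression.loc[gene.name, tissue_columns].to_numpy(dtype=float)
        links.append(
            link_test(enhancer_id, gene.name, activity_row, expr_row, cfg)
        )
    return links


def nearest_gene_baseline(
    enhancer: GenomicInterval,
    genes: AnnotationSet,
    k: int = 1,
    max_dist: int = 1_000_000,
    expression: pd.DataFrame | None = None,
    min_rpkm: float = 1.0,
    expression_column: str = "left_ventricle",
) -> list[GenomicInterval]:
    """The k nearest genes (TSS distance from the enhancer midpoint)
    within ``max_dist``; ties broken by gene id.  Optionally restricted
    to genes expressed above ``min_rpkm``."""
    mid = enhancer.midpoint
    scored = []
    for gene in genes.intervals(enhancer.chrom):
        if gene.name is None:
            continue
        dist = abs(gene_tss(gene) - mid)
        if dist > max_dist:
            continue
        if expression is not None:
            if gene.name not in expression.index:
                continue
            if expression.loc[gene.name, expression_column] < min_rpkm:
                continue
        scored.append((dist, gene.name, gene))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [g for _, _, g in scored[:k]]


def phenotype_enrichment_counts(
    linked_genes: list[str],
    phenotype_table: pd.DataFrame,
    background_genes: list[str],
) -> Table2x2:
    """2x2 table of relevant-phenotype rates in linked vs background genes.

    ``phenotype_table`` has columns ``gene`` and ``has_phenotype``; genes
    absent from the table count as phenotype-free.
    """
    if not linked_genes:
        raise ValueError("empty linked gene set")
    if not background_genes:
        raise ValueError("empty background gene set")
    flags = dict(
        zip(phenotype_table["gene"], phenotype_table["has_phenotype"].astype(bool))
    )
    a = sum(flags.get(g, False) for g in linked_genes)
    c = sum(flags.get(g, False) for g in background_genes)
    return Table2x2(a, len(linked_genes) - a, c, len(background_genes) - c)
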