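"""Sliding-threshold enrichment of annotation-overlapping SNPs across the
p-value spectrum.

At each -log10(p) cut-off c the fold is the proportion of foreground SNPs
(those inside the annotation) with p < 10^-c, divided by the same
proportion over all SNPs.  Enrichment persisting between the sub-threshold
cut-off (1e-4) and genome-wide significance (5e-8) after exclusion of
known loci is the signature of novel biologically relevant signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import AnnotationSet, GenomicInterval, SignalTrack
from .ld import LdPanel, Locus, SubthresholdLocus, exclude_near_known


@dataclass
class EnrichmentCurve:
    """Fold enrichment on a -log10(p) grid.

    ``fold`` is NaN where undefined (no background SNP below the cut-off
    or empty foreground).
    """

    thresholds: np.ndarray  # -log10 p grid
    n_fg_below: np.ndarray
    n_fg_total: int
    n_bg_below: np.ndarray
    n_bg_total: int
    fold: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neg_log10_p": self.thresholds,
                "n_fg_below": self.n_fg_below,
                "n_fg_total": self.n_fg_total,
                "n_bg_below": self.n_bg_below,
                "n_bg_total": self.n_bg_total,
                "fold": self.fold,
            }
        )


@dataclass
class ExclusionZones:
    known_locus_radius_bp: int = 1_000_000
    masked_regions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.known_locus_radius_bp < 0:
            raise ValueError("radius must be >= 0")


def default_grid(max_neglog: float = 10.0, step: float = 0.1) -> np.ndarray:
    return np.round(np.arange(0.0, max_neglog + step / 2, step), 10)


def enrichment_curve(
    snps: pd.DataFrame,
    annotation: AnnotationSet,
    grid: np.ndarray | None = None,
    label: str | None = None,
) -> EnrichmentCurve:
    """Fold enrichment of annotation-overlapping SNPs at each cut-off.

    'More significant than the cut-off' is strict: p < 10^-c.
    """
    if grid is None:
        grid = default_grid()
    snps = snps.reset_index(drop=True)
    pvals = snps["pvalue"].to_numpy(dtype=float)
    if np.isnan(pvals).any():
        raise ValueError("all SNPs must carry p-values")
    in_fg = np.zeros(len(snps), dtype=bool)
    for chrom, sub in snps.groupby("chrom", sort=False):
        in_fg[sub.index.to_numpy()] = annotation.contains_points(
            str(chrom), sub["pos"].to_numpy()
        )
    n_fg_total = int(in_fg.sum())
    if n_fg_total == 0:
        raise ValueError("no SNP falls inside the annotation (empty foreground)")
    n_bg_total = len(snps)
    neglog = -np.log10(pvals)
    # p < 10^-c  <=>  -log10 p > c (strict)
    fg_sorted = np.sort(neglog[in_fg])
    bg_sorted = np.sort(neglog)
    n_fg_below = fg_sorted.size - np.searchsorted(fg_sorted, grid, side="right")
    n_bg_below = bg_sorted.size - np.searchsorted(bg_sorted, grid, side="right")
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = (n_fg_below / n_fg_total) / (n_bg_below / n_bg_total)
    fold = np.where(n_bg_below > 0, fold, np.nan)
    return EnrichmentCurve(
        thresholds=np.asarray(grid, dtype=float),
        n_fg_below=n_fg_below.astype(np.int64),
        n_fg_total=n_fg_total,
        n_bg_below=n_bg_below.astype(np.int64),
        n_bg_total=n_bg_total,
        fold=fold,
        label=label or annotation.label,
    )


def apply_exclusions(
    snps: pd.DataFrame,
    zones: ExclusionZones,
    known_loci: list[Locus] | None = None,
) -> pd.DataFrame:
    """Remove SNPs near known loci and SNPs inside masked regions (HLA)."""
    out = exclude_near_known(
        snps, known_loci or [], radius_bp=zones.known_locus_radius_bp
    )
    if zones.masked_regions:
        masks = AnnotationSet("mask", zones.masked_regions)
        keep = np.ones(len(out), dtype=bool)
        for chrom, sub in out.groupby("chrom", sort=False):
            keep[sub.index.to_numpy()] = ~masks.contains_points(
                str(chrom), sub["pos"].to_numpy()
            )
        out = out.loc[keep].reset_index(drop=True)
    return out


def refine_annotation(
    annotation: AnnotationSet,
    track: SignalTrack,
    cutoff: float,
    label: str | None = None,
) -> AnnotationSet:
    """Subset of intervals whose mean signal reaches ``cutoff``."""
    kept = [
        iv
        for iv in annotation
        if track.mean_over(iv.chrom, iv.start, iv.end) >= cutoff
    ]
    refined = AnnotationSet(
        label or f"{annotation.label}|{track.name}>={cutoff:g}", kept
    )
    if len(refined) == 0:
        raise ValueError(
            f"refinement {track.name} >= {cutoff:g} empties the annotation"
        )
    return refined


def refined_subset_curves(
    snps: pd.DataFrame,
    base_annotation: AnnotationSet,
    refinements: list[tuple[SignalTrack, float]],
    grid: np.ndarray | None = None,
) -> list[EnrichmentCurve]:
    """One enrichment curve per feature-refined enhancer subset."""
    return [
        enrichment_curve(snps, refine_annotation(base_annotation, track, cutoff), grid)
        for track, cutoff in refinements
    ]


def flag_annotation_overlap(
    locus: SubthresholdLocus, annotation: AnnotationSet
) -> bool:
    """Does any member SNP of the locus fall inside the annotation?"""
    return any(
        bool(annotation.contains_points(m.chrom, np.array([m.pos]))[0])
        for m in locus.all_members
    )


def assign_replication_p(
    locus: SubthresholdLocus,
    panel: LdPanel,
    replication_stats: pd.DataFrame,
) -> float | None:
    """Replication p-value of a sub-threshold locus in a second GWAS.

    ``replication_stats`` holds one or more p-value columns (one per
    trait) keyed by SNP id.  Per SNP the assigned p is the minimum across
    traits; per locus, the minimum over LD partners of the representative
    at r2 > 0.8 (including the representative).  Returns ``None`` when no
    partner appears in the replication data.
    """
    pcols = [c for c in replication_stats.columns if c.startswith("pvalue")]
    if not pcols:
        raise ValueError("replication stats need >= 1 'pvalue*' column")
    per_snp = replication_stats.set_index("id")[pcols].min(axis=1)
    rid = locus.representative.id
    partners = [rid]
    if rid in panel:
        partners += panel.partners_above(rid, 0.8)
    hits = per_snp.reindex(partners).dropna()
    if hits.empty:
        return None
    return float(hits.min())
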