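"""Matched-control permutation enrichment.

Tests whether trait loci overlap an annotation (enhancer states, motif
instances of expressed TFs, ...) more often than random loci built around
control lead SNPs matched on genetic covariates: LD block size, minor
allele frequency, distance to the nearest gene, number of nearby genes,
and genotyping-array membership.  Control leads are expanded into loci by
the same r2 > 0.8 rule as the test loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import AnnotationSet, GenomicInterval
from .io import VariantRecord
from .ld import LdPanel, Locus, expand_locus
from .stats import empirical_p


@dataclass(frozen=True)
class MatchTolerances:
    """Covariate windows for matched-control sampling (all inclusive).

    The distance-to-gene window applies only when the test lead lies
    outside a gene (distance > 0); leads inside genes are matched on the
    remaining covariates.
    """

    block_size: int = 5
    maf: float = 0.1
    dist_to_gene_bp: int = 25_000
    n_genes_500kb: int = 3
    require_on_array: bool = True

    def __post_init__(self) -> None:
        if min(self.block_size, self.dist_to_gene_bp, self.n_genes_500kb) < 0:
            raise ValueError("tolerances must be >= 0")
        if self.maf < 0:
            raise ValueError("tolerances must be >= 0")


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    n_perm: int
    degenerate: bool = False


@dataclass
class MotifInstanceSet:
    """Motif instances of one TF; ``tf_expressed`` marks TFs with RPKM > 1
    in the reference tissue."""

    motif_id: str
    tf_name: str
    instances: AnnotationSet
    tf_expressed: bool = True


def match_controls(
    lead: VariantRecord,
    candidate_pool: pd.DataFrame,
    tol: MatchTolerances = MatchTolerances(),
    exclude_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Rows of the pool satisfying every matching window for ``lead``."""
    pool = candidate_pool
    ok = np.abs(pool["block_size"].to_numpy() - lead.block_size) <= tol.block_size
    ok &= np.abs(pool["maf"].to_numpy() - lead.maf) <= tol.maf + 1e-12
    ok &= (
        np.abs(pool["n_genes_500kb"].to_numpy() - lead.n_genes_500kb)
        <= tol.n_genes_500kb
    )
    if lead.dist_to_nearest_gene > 0:
        ok &= (
            np.abs(pool["dist_to_nearest_gene"].to_numpy() - lead.dist_to_nearest_gene)
            <= tol.dist_to_gene_bp
        )
    if tol.require_on_array:
        ok &= pool["on_array"].to_numpy()
    exclude = {lead.id} | (exclude_ids or set())
    ok &= ~pool["id"].isin(exclude).to_numpy()
    matched = pool.loc[ok]
    if len(matched) == 0:
        raise ValueError(f"no matched control candidates for lead {lead.id}")
    return matched


def count_locus_overlaps(loci: list[Locus], annotation: AnnotationSet) -> int:
    """Number of loci with >= 1 member SNP inside >= 1 annotation interval.

    A locus counts once however many members overlap.
    """
    n = 0
    for locus in loci:
        for m in locus.members.values():
            if annotation.contains_points(m.chrom, np.array([m.pos]))[0]:
                n += 1
                break
    return n


def _annotation_membership(
    variants: dict[str, VariantRecord], annotation: AnnotationSet
) -> dict[str, bool]:
    """Vectorized SNP-in-annotation flags for every variant."""
    by_chrom: dict[str, tuple[list[str], list[int]]] = {}
    for v in variants.values():
        ids, pos = by_chrom.setdefault(v.chrom, ([], []))
        ids.append(v.id)
        pos.append(v.pos)
    flags: dict[str, bool] = {}
    for chrom, (ids, pos) in by_chrom.items():
        hit = annotation.contains_points(chrom, np.array(pos, dtype=np.int64))
        flags.update(zip(ids, hit.tolist()))
    return flags


def _locus_overlap_flags(
    pool: pd.DataFrame,
    panel: LdPanel,
    variants: dict[str, VariantRecord],
    snp_flags: dict[str, bool],
) -> dict[str, bool]:
    """For each pool SNP id, whether any member of its r2>0.8-expanded
    locus carries a true SNP-level flag."""
    flags: dict[str, bool] = {}
    for sid in pool["id"]:
        members = [sid] + [
            p for p in (panel.partners_above(sid, 0.8) if sid in panel else [])
            if p in variants
        ]
        flags[sid] = any(snp_flags.get(m, False) for m in members)
    return flags


def _permute(
    observed: int,
    test_loci: list[Locus],
    candidate_pool: pd.DataFrame,
    panel: LdPanel,
    variants: dict[str, VariantRecord],
    snp_flags: dict[str, bool],
    tol: MatchTolerances,
    n_perm: int,
    seed: int,
) -> EnrichmentResult:
    """Shared permutation engine.

    Per permutation, one matched control lead is drawn per test lead
    (uniformly, with replacement across permutations); each control lead
    is expanded at r2 > 0.8 and the locus-level overlap count recomputed.
    """
    rng = np.random.default_rng(seed)
    test_member_ids: set[str] = set()
    for locus in test_loci:
        test_member_ids |= locus.member_ids
    flags = _locus_overlap_flags(candidate_pool, panel, variants, snp_flags)
    per_lead_flags: list[np.ndarray] = []
    for locus in test_loci:
        matched = match_controls(
            locus.lead, candidate_pool, tol, exclude_ids=test_member_ids
        )
        per_lead_flags.append(
            np.fromiter((flags[s] for s in matched["id"]), dtype=bool,
                        count=len(matched))
        )
    null = np.zeros(n_perm, dtype=np.int64)
    for f in per_lead_flags:
        draws = rng.integers(0, f.size, size=n_perm)
        null += f[draws]
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    degenerate = sd == 0.0
    if degenerate:
        z = 0.0 if observed == mean else float(np.sign(observed - mean) * np.inf)
    else:
        z = (observed - mean) / sd
    return EnrichmentResult(
        observed=observed,
        null_mean=mean,
        null_sd=sd,
        z=float(z),
        empirical_p=empirical_p(observed, null),
        n_perm=n_perm,
        degenerate=degenerate,
    )


def permutation_enrichment(
    test_loci: list[Locus],
    candidate_pool: pd.DataFrame,
    panel: LdPanel,
    variants: dict[str, VariantRecord],
    annotation: AnnotationSet,
    tol: MatchTolerances = MatchTolerances(),
    n_perm: int = 100_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Annotation-overlap enrichment of test loci vs matched controls."""
    snp_flags = _annotation_membership(variants, annotation)
    observed = count_locus_overlaps(test_loci, annotation)
    return _permute(observed, test_loci, candidate_pool, panel, variants,
                    snp_flags, tol, n_perm, seed)


def motif_disruption_statistic(
    loci: list[Locus],
    enhancers: AnnotationSet,
    motifs: list[MotifInstanceSet],
) -> int:
    """Loci with a member SNP inside an enhancer that also falls inside a
    motif instance of an expressed TF."""
    expressed = [m for m in motifs if m.tf_expressed]
    n = 0
    for locus in loci:
        hit = False
        for v in locus.members.values():
            pos = np.array([v.pos])
            if not enhancers.contains_points(v.chrom, pos)[0]:
                continue
            if any(ms.instances.contains_points(v.chrom, pos)[0]
                   for ms in expressed):
                hit = True
                break
        n += hit
    return n


def motif_disruption_enrichment(
    test_loci: list[Locus],
    candidate_pool: pd.DataFrame,
    panel: LdPanel,
    variants: dict[str, VariantRecord],
    enhancers: AnnotationSet,
    motifs: list[MotifInstanceSet],
    tol: MatchTolerances = MatchTolerances(),
    n_perm: int = 100_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of enhancer-motif-disrupting SNPs in test loci."""
    expressed = [m for m in motifs if m.tf_expressed]
    enh_flags = _annotation_membership(variants, enhancers)
    snp_flags = {sid: False for sid in variants}
    for ms in expressed:
        for sid, hit in _annotation_membership(variants, ms.instances).items():
            snp_flags[sid] = snp_flags[sid] or (hit and enh_flags[sid])
    observed = motif_disruption_statistic(test_loci, enhancers, motifs)
    return _permute(observed, test_loci, candidate_pool, panel, variants,
                    snp_flags, tol, n_perm, seed)


def shuffle_motif_instances(
    motifs: list[MotifInstanceSet],
    genome: dict[str, int],
    seed: int = 0,
) -> list[MotifInstanceSet]:
    """Re-map motif instances to uniform random positions, preserving the
    instance count and lengths of each set (a negative control)."""
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64)
    probs = lengths / lengths.sum()
    out: list[MotifInstanceSet] = []
    for ms in motifs:
        new: list[GenomicInterval] = []
        for iv in ms.instances:
            width = len(iv)
            ci = int(rng.choice(len(chroms), p=probs))
            start = int(rng.integers(0, max(1, lengths[ci] - width)))
            new.append(GenomicInterval(chroms[ci], start, start + width))
        out.append(
            MotifInstanceSet(
                motif_id=ms.motif_id,
                tf_name=ms.tf_name,
                instances=AnnotationSet(ms.instances.label + "_shuffled", new),
                tf_expressed=ms.tf_expressed,
            )
        )
    return out


def build_control_locus(
    control_id: str,
    panel: LdPanel,
    variants: dict[str, VariantRecord],
) -> Locus:
    """Expand one control lead into a locus by the r2 > 0.8 rule."""
    return expand_locus(variants[control_id], panel, variants, r2_min=0.8)
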