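"""Stage orchestration: chain the analysis stages over an output
directory with conventional file names, so the CLI and tests can run the
full synthetic end-to-end workflow.

Each stage writes its result as TSV/JSON plus a log line with the seed
and parameters used.  Deterministic stages are byte-reproducible for a
fixed (config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig
from .enrichment import MatchTolerances, permutation_enrichment
from .fourc import FourCConfig, FragendProfile, call_peaks
from .imbalance import ImbalanceConfig, analyze_counts, imbalance_summary
from .intervals import AnnotationSet
from .ld import LdPanel, define_subthreshold_loci, expand_locus
from .linking import LinkConfig, link_enhancer
from .scan import ExclusionZones, apply_exclusions, enrichment_curve
from .simulate import (
    SimulationConfig,
    plant_in_enhancers,
    simulate_allele_counts,
    simulate_fourc,
    simulate_gwas,
    simulate_tissue_panels,
    simulate_variants_and_ld,
)

logger = logging.getLogger("subloci")

STAGES = ("simulate", "loci", "enrich", "scan", "link", "imbalance", "fourc")


def _require(out_dir: Path, filename: str, stage: str) -> Path:
    path = out_dir / filename
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs missing upstream output {filename}; "
            f"run 'simulate' (or provide the file) first"
        )
    return path


def stage_simulate(
    config: PipelineConfig,
    out_dir: Path,
    sim: SimulationConfig | None = None,
    n_planted: int = 15,
    planted_ncp: float = 4.313,
) -> dict:
    sim = sim or SimulationConfig(seed=config.seed)
    out_dir.mkdir(parents=True, exist_ok=True)
    variants, panel, genes = simulate_variants_and_ld(sim, seed=config.seed)
    panels = simulate_tissue_panels(sim, genes, seed=config.seed + 1)
    ref_set: AnnotationSet = panels["tissue_sets"][sim.reference_tissue]
    planted = plant_in_enhancers(
        variants, ref_set, n_planted, planted_ncp, seed=config.seed + 2
    )
    stats = simulate_gwas(
        variants, planted, seed=config.seed + 3,
        within_block_r2=sim.within_block_r2,
    )
    io.write_table(variants, out_dir / "variants.tsv")
    io.write_table(
        stats[["id", "chrom", "pos", "maf", "pvalue", "on_array", "block",
               "block_size", "dist_to_nearest_gene", "n_genes_500kb"]],
        out_dir / "summary_stats.tsv",
    )
    pairs = [
        (a, b, r2)
        for (a, b), r2 in sorted(_pair_items(panel))
    ]
    io.write_ld_table(pairs, out_dir / "ld.tsv")
    io.write_intervals(genes, out_dir / "genes.bed")
    io.write_intervals(ref_set, out_dir / "enhancers.bed")
    panels["activity"].to_csv(out_dir / "activity.tsv", sep="\t")
    panels["expression"].to_csv(out_dir / "expression.tsv", sep="\t")
    io.write_bedgraph(panels["h3k27ac"], out_dir / "h3k27ac.bedgraph")
    io.write_bedgraph(panels["dhs"], out_dir / "dhs.bedgraph")
    io.write_bedgraph(panels["methylation"], out_dir / "methylation.bedgraph")
    counts = simulate_allele_counts(
        2000, allele_imbalance_frac=sim.allele_imbalance_frac,
        seed=config.seed + 4,
    )
    io.write_table(counts, out_dir / "allele_counts.tsv")
    profile = simulate_fourc(
        ("chr1", 5_000_000), decay=sim.fourc_decay,
        spacing_bp=sim.fourc_spacing_bp,
        planted_peaks=[(200_000, 50.0)], seed=config.seed + 5,
    )
    pd.DataFrame({"position": profile.positions, "count": profile.counts}).to_csv(
        out_dir / "fragends.tsv", sep="\t", index=False
    )
    manifest = {
        "seed": config.seed,
        "n_snps": sim.n_snps,
        "n_tissues": sim.n_tissues,
        "planted": [{"snp_id": p.snp_id, "ncp": p.ncp} for p in planted],
        "fourc_viewpoint": "chr1:5000000",
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("simulate: seed=%d n_snps=%d planted=%d", config.seed,
                sim.n_snps, n_planted)
    return manifest


def _pair_items(panel: LdPanel):
    seen = set()
    for a in panel.snp_ids:
        for b in panel.partners_above(a, 0.0):
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                yield key, panel.r2(a, b)


def stage_loci(config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    stats = io.read_table(_require(out_dir, "summary_stats.tsv", "loci"),
                          "summary_stats")
    panel = LdPanel(pair_table=io.read_ld_table(_require(out_dir, "ld.tsv", "loci")))
    zones = ExclusionZones(config.exclusion_radius_bp, config.masked_regions)
    filtered = apply_exclusions(stats, zones, known_loci=[])
    loci = define_subthreshold_loci(
        filtered, panel, p_max=config.p_subthreshold, r2_prune=config.r2_prune
    )
    rows = [
        {
            "locus": i,
            "representative": loc.representative.id,
            "pvalue": loc.representative.pvalue,
            "n_members": len(loc.all_members),
            "members": ",".join(m.id for m in loc.all_members),
        }
        for i, loc in enumerate(loci)
    ]
    df = pd.DataFrame(rows)
    io.write_table(df, out_dir / "subthreshold_loci.tsv")
    logger.info("loci: %d independent sub-threshold loci (p<%g)",
                len(df), config.p_subthreshold)
    return df


def stage_enrich(config: PipelineConfig, out_dir: Path,
                 n_perm: int | None = None) -> dict:
    stats = io.read_table(_require(out_dir, "summary_stats.tsv", "enrich"),
                          "summary_stats")
    panel = LdPanel(pair_table=io.read_ld_table(_require(out_dir, "ld.tsv", "enrich")))
    enhancers = io.read_intervals(_require(out_dir, "enhancers.bed", "enrich"))
    variants = {v.id: v for v in io.variant_records(stats)}
    # test loci: strongest sub-threshold leads, expanded at r2 > 0.8
    top = stats.loc[stats["pvalue"] < config.p_subthreshold] \
        .sort_values(["pvalue", "id"]).head(20)
    seen: set[str] = set()
    test_loci = []
    for sid in top["id"]:
        if sid in seen:
            continue
        locus = expand_locus(variants[sid], panel, variants, config.r2_expand) \
            if sid in panel else None
        if locus is None:
            from .ld import Locus
            locus = Locus(lead=variants[sid])
        seen |= locus.member_ids
        test_loci.append(locus)
    if not test_loci:
        raise ValueError("no sub-threshold loci to test")
    pool = stats.loc[stats["pvalue"] >= 0.01].reset_index(drop=True)
    result = permutation_enrichment(
        test_loci, pool, panel, variants, enhancers,
        MatchTolerances(), n_perm=n_perm or config.n_perm, seed=config.seed,
    )
    payload = {
        "annotation": enhancers.label,
        "n_test_loci": len(test_loci),
        "observed": result.observed,
        "null_mean": result.null_mean,
        "null_sd": result.null_sd,
        "z": result.z,
        "empirical_p": result.empirical_p,
        "n_perm": result.n_perm,
    }
    (out_dir / "enrichment.json").write_text(json.dumps(payload, indent=2))
    logger.info("enrich: observed=%d z=%.2f p=%.3g", result.observed,
                result.z, result.empirical_p)
    return payload


def stage_scan(config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    stats = io.read_table(_require(out_dir, "summary_stats.tsv", "scan"),
                          "summary_stats")
    enhancers = io.read_intervals(_require(out_dir, "enhancers.bed", "scan"))
    zones = ExclusionZones(config.exclusion_radius_bp, config.masked_regions)
    filtered = apply_exclusions(stats, zones, known_loci=[])
    curve = enrichment_curve(filtered, enhancers)
    df = curve.to_frame()
    io.write_table(df, out_dir / "enrichment_curve.tsv")
    logger.info("scan: %d grid points, fold at -log p=4: %.2f",
                len(df), df.loc[np.isclose(df["neg_log10_p"], 4.0), "fold"].iloc[0])
    return df


def stage_link(config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    enhancers = io.read_intervals(_require(out_dir, "enhancers.bed", "link"))
    genes = io.read_intervals(_require(out_dir, "genes.bed", "link"))
    expr = io.read_table(_require(out_dir, "expression.tsv", "link"), "expression")
    activity = pd.read_csv(_require(out_dir, "activity.tsv", "link"),
                           sep="\t", index_col=0).astype(bool)
    cfg = LinkConfig()
    tissue_cols = list(activity.columns)
    rows = []
    for enh in enhancers:
        if enh.name not in activity.index:
            continue
        for link in link_enhancer(
            enh, enh.name, genes, activity.loc[enh.name].to_numpy(), expr,
            tissue_cols, cfg,
        ):
            rows.append(
                {
                    "enhancer": link.enhancer_id,
                    "gene": link.gene_id,
                    "pvalue": link.pvalue,
                    "linked": link.linked,
                    "status": link.status,
                }
            )
    df = pd.DataFrame(rows)
    io.write_table(df, out_dir / "gene_links.tsv")
    logger.info("link: %d candidate pairs, %d linked", len(df),
                int(df["linked"].sum()) if len(df) else 0)
    return df


def stage_imbalance(config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    counts = io.read_table(
        _require(out_dir, "allele_counts.tsv", "imbalance"), "allele_counts"
    )
    analyzed = analyze_counts(counts, ImbalanceConfig())
    io.write_table(analyzed, out_dir / "imbalance.tsv")
    summary = imbalance_summary(analyzed)
    (out_dir / "imbalance_summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("imbalance: %d het SNPs, median ref-alt=%g",
                summary["n_het"], summary["median_ref_minus_alt"])
    return analyzed


def stage_fourc(config: PipelineConfig, out_dir: Path,
                viewpoint: tuple[str, int] = ("chr1", 5_000_000)) -> pd.DataFrame:
    frag = io.read_table(_require(out_dir, "fragends.tsv", "fourc"), "fragends")
    profile = FragendProfile.from_frame(frag, *viewpoint)
    peaks, table = call_peaks(profile, FourCConfig())
    io.write_table(table, out_dir / "fourc_fragends.tsv")
    with open(out_dir / "fourc_peaks.bed", "w") as fh:
        for p in peaks:
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                     f"\t{p.side}\t{p.max_exceedance:.3f}\n")
    logger.info("fourc: %d peaks", len(peaks))
    return table


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "loci": stage_loci,
    "enrich": stage_enrich,
    "scan": stage_scan,
    "link": stage_link,
    "imbalance": stage_imbalance,
    "fourc": stage_fourc,
}


def run_pipeline(
    config: PipelineConfig, stage_list: list[str], out_dir: str | Path
) -> None:
    """Run the requested stages in order over ``out_dir``."""
    out_dir = Path(out_dir)
    for stage in stage_list:
        if stage not in STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        STAGE_FUNCS[stage](config, out_dir)
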