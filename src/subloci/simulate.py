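"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the study's data sources at desk scale: GWAS
summary statistics with uniform null p-values and planted
normal-noncentrality signals placed preferentially in enhancers; block LD
structure with a single exchangeable within-block r2; tissue panels with
shared/specific enhancer activity coupled to gene expression; balanced
and imbalanced allele-specific read counts; and distance-decaying 4C
fragment-end coverage with planted contacts.

Every generator is bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fourc import FragendProfile
from .intervals import AnnotationSet, GenomicInterval, SignalTrack
from .ld import LdPanel


@dataclass
class PlantedLocus:
    snp_id: str
    ncp: float

    def __post_init__(self) -> None:
        if self.ncp < 0:
            raise ValueError("ncp must be >= 0")


@dataclass
class SimulationConfig:
    """Study-scale knobs of the synthetic genome.

    Defaults mirror the structural features the analysis relies on: 59
    tissues with RNA-seq and enhancer calls, LD blocks tight enough that
    r2 > 0.8 expansion groups them, MAF spread wide enough that the
    matched-control sampler always finds candidates, and an expression
    shift of 3 noise SD for truly linked enhancer-gene pairs.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len_bp: int = 10_000_000
    n_snps: int = 4000
    snp_margin_bp: int = 500_000  # SNP-free telomeric margin
    ld_block_len_bp: int = 20_000
    within_block_r2: float = 0.9
    maf_beta: tuple[float, float] = (1.2, 2.0)
    n_genes_per_chrom: int = 160
    gene_len_bp: int = 20_000
    n_tissues: int = 59
    enhancer_count: int = 150
    enhancer_len_bp: int = 1000
    enhancer_sharing: float = 0.3
    expression_effect_delta: float = 3.0  # log2 shift, units of noise SD
    expression_noise_sd: float = 1.0
    fourc_decay: tuple[float, float] = (200.0, 0.7)  # (scale, exponent)
    fourc_spacing_bp: int = 264  # median DpnII fragend spacing in hg19
    allele_imbalance_frac: float = 0.1
    reference_tissue: str = "left_ventricle"

    def __post_init__(self) -> None:
        if min(self.n_chrom, self.n_snps, self.n_tissues,
               self.enhancer_count, self.n_genes_per_chrom) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.within_block_r2 <= 1:
            raise ValueError("within_block_r2 must be in [0, 1]")
        if not 0 <= self.enhancer_sharing <= 1:
            raise ValueError("enhancer_sharing must be in [0, 1]")
        if not 0 <= self.allele_imbalance_frac <= 1:
            raise ValueError("allele_imbalance_frac must be in [0, 1]")

    @property
    def genome(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_len_bp for i in range(self.n_chrom)}

    @property
    def tissues(self) -> list[str]:
        return [self.reference_tissue] + [
            f"tissue_{i:02d}" for i in range(1, self.n_tissues)
        ]


def _gene_annotation(cfg: SimulationConfig, rng: np.random.Generator) -> AnnotationSet:
    # genes sit on a jittered grid: gene deserts wider than the
    # matched-control distance window would starve the sampler at desk
    # scale, so spacing is kept comparable to the +/-25 kb window
    genes = []
    spacing = cfg.chrom_len_bp // cfg.n_genes_per_chrom
    jitter_max = max(1, (spacing - cfg.gene_len_bp) // 2)
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        grid = np.arange(cfg.n_genes_per_chrom) * spacing
        starts = grid + rng.integers(0, jitter_max, size=cfg.n_genes_per_chrom)
        for gi, s in enumerate(starts):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GenomicInterval(chrom, int(s), int(s) + cfg.gene_len_bp,
                                name=f"gene_{chrom}_{gi:03d}", strand=strand)
            )
    return AnnotationSet("genes", genes)


def simulate_variants_and_ld(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, LdPanel, AnnotationSet]:
    """SNP table with matching covariates, block LD panel, gene annotation.

    SNPs are uniformly placed; the LD block of a SNP is its
    ``ld_block_len_bp`` window, with pairwise r2 equal to
    ``within_block_r2`` inside a block and 0 across blocks.  Covariates
    (MAF, block size, distance to nearest gene, gene count within 500 kb,
    alternating array membership) are derived from the generated genome.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    per_chrom = cfg.n_snps // cfg.n_chrom
    if per_chrom > cfg.chrom_len_bp:
        raise ValueError("more SNPs than available positions")
    genes = _gene_annotation(cfg, rng)
    rows = []
    pair_table: dict[tuple[str, str], float] = {}
    snp_counter = 0
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        n = per_chrom + (cfg.n_snps % cfg.n_chrom if ci == cfg.n_chrom - 1 else 0)
        # SNPs stay clear of the chromosome ends so every SNP sees a full
        # +/-500 kb gene window (arrays carry no probes in those margins)
        span = cfg.chrom_len_bp - 2 * cfg.snp_margin_bp
        if n > span:
            raise ValueError("more SNPs than available positions")
        pos = cfg.snp_margin_bp + np.sort(rng.choice(span, size=n, replace=False)) + 1
        block = pos // cfg.ld_block_len_bp
        maf = np.clip(rng.beta(*cfg.maf_beta, size=n) * 0.5, 0.01, 0.5)
        gene_ivs = genes.intervals(chrom)
        tss = np.array([g.start for g in gene_ivs])
        gene_starts = np.array([g.start for g in gene_ivs])
        gene_ends = np.array([g.end for g in gene_ivs])
        for i in range(n):
            sid = f"rs{snp_counter:06d}"
            snp_counter += 1
            p0 = pos[i] - 1
            inside = np.any((gene_starts <= p0) & (p0 < gene_ends))
            dist = 0 if inside else int(
                np.min(np.abs(np.concatenate([gene_starts, gene_ends]) - p0))
            )
            n_genes = int(np.sum(np.abs(tss - p0) <= 500_000))
            rows.append(
                {
                    "id": sid,
                    "chrom": chrom,
                    "pos": int(pos[i]),
                    "maf": float(maf[i]),
                    "on_array": snp_counter % 2 == 0,
                    "dist_to_nearest_gene": dist,
                    "n_genes_500kb": n_genes,
                    "block": f"{chrom}:{int(block[i])}",
                }
            )
        if cfg.within_block_r2 > 0:
            ids = [rows[-(n - j)]["id"] for j in range(n)]
            for b in np.unique(block):
                members = [ids[j] for j in np.flatnonzero(block == b)]
                for x in range(len(members)):
                    for y in range(x + 1, len(members)):
                        pair_table[(members[x], members[y])] = cfg.within_block_r2
    variants = pd.DataFrame(rows)
    if cfg.within_block_r2 > 0.8:
        sizes = variants.groupby("block")["id"].transform("size")
    else:
        sizes = pd.Series(1, index=variants.index)
    variants["block_size"] = sizes.astype(np.int64)
    panel = LdPanel(pair_table=pair_table)
    return variants, panel, genes


def simulate_gwas(
    variants: pd.DataFrame,
    planted: list[PlantedLocus],
    seed: int = 0,
    within_block_r2: float | None = None,
) -> pd.DataFrame:
    """Per-SNP association z and two-sided p under the single-causal
    approximation.

    Null SNPs of a block share an exchangeable z-correlation equal to the
    LD correlation r = sqrt(r2).  Planted SNPs draw z ~ Normal(ncp, 1);
    their block partners receive r*z_lead + sqrt(1 - r2)*noise.
    """
    rng = np.random.default_rng(seed)
    out = variants.copy().reset_index(drop=True)
    planted_map = {p.snp_id: p.ncp for p in planted}
    unknown = set(planted_map) - set(out["id"])
    if unknown:
        raise KeyError(f"planted SNPs absent from variant table: {sorted(unknown)}")
    n = len(out)
    z = np.empty(n)
    if within_block_r2 is None:
        # infer from block sizes: exchangeable blocks carry their r2 in
        # the panel; default to independent draws when not supplied
        within_block_r2 = 0.0
    r = float(np.sqrt(within_block_r2))
    ids = out["id"].to_numpy()
    blocks = out["block"].to_numpy() if "block" in out.columns else ids
    for b in pd.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        members = ids[idx]
        lead = next((m for m in members if m in planted_map), None)
        if lead is not None:
            z_lead = planted_map[lead] + rng.standard_normal()
            for j, m in zip(idx, members):
                if m == lead:
                    z[j] = z_lead
                elif m in planted_map:
                    z[j] = planted_map[m] + rng.standard_normal()
                else:
                    z[j] = r * z_lead + np.sqrt(1 - r * r) * rng.standard_normal()
        elif idx.size == 1 or r == 0.0:
            z[idx] = rng.standard_normal(idx.size)
        else:
            shared = rng.standard_normal()
            z[idx] = (
                np.sqrt(r) * shared
                + np.sqrt(1 - r) * rng.standard_normal(idx.size)
            )
    from scipy.stats import norm

    out["z"] = z
    out["pvalue"] = np.clip(2 * norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    return out


def plant_in_enhancers(
    variants: pd.DataFrame,
    enhancers: AnnotationSet,
    n_loci: int,
    ncp: float,
    in_enhancer: bool = True,
    seed: int = 0,
) -> list[PlantedLocus]:
    """Choose ``n_loci`` SNPs (one per LD block) inside or outside
    enhancer intervals and assign them the given non-centrality."""
    rng = np.random.default_rng(seed)
    flags = np.zeros(len(variants), dtype=bool)
    for chrom, sub in variants.reset_index(drop=True).groupby("chrom", sort=False):
        flags[sub.index.to_numpy()] = enhancers.contains_points(
            str(chrom), sub["pos"].to_numpy()
        )
    eligible = variants.loc[flags if in_enhancer else ~flags]
    eligible = eligible.drop_duplicates(subset="block")
    if len(eligible) < n_loci:
        raise ValueError(
            f"only {len(eligible)} eligible blocks for {n_loci} planted loci"
        )
    picks = rng.choice(len(eligible), size=n_loci, replace=False)
    return [PlantedLocus(sid, ncp) for sid in eligible.iloc[np.sort(picks)]["id"]]


def simulate_tissue_panels(
    cfg: SimulationConfig,
    genes: AnnotationSet,
    seed: int | None = None,
) -> dict[str, object]:
    """Enhancer calls per tissue, activity and expression matrices,
    enhancer-gene link truth, and H3K27ac / methylation / DHS tracks.

    Each enhancer is active in the reference tissue and independently
    shared with every other tissue with probability ``enhancer_sharing``.
    Each enhancer regulates one gene within the linking window: in
    tissues where the enhancer is active the gene's log2 expression is
    shifted up by ``expression_effect_delta`` noise SDs.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tissues = cfg.tissues
    # enhancer catalog on the reference tissue
    enhancers: list[GenomicInterval] = []
    per_chrom = cfg.enhancer_count // cfg.n_chrom
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        k = per_chrom + (cfg.enhancer_count % cfg.n_chrom
                         if ci == cfg.n_chrom - 1 else 0)
        starts = np.sort(
            rng.choice(cfg.chrom_len_bp // cfg.enhancer_len_bp // 2, size=k,
                       replace=False)
        ) * cfg.enhancer_len_bp * 2
        for ei, s in enumerate(starts):
            enhancers.append(
                GenomicInterval(chrom, int(s), int(s) + cfg.enhancer_len_bp,
                                name=f"enh_{chrom}_{ei:03d}")
            )
    enh_ids = [e.name for e in enhancers]
    activity = np.zeros((len(enhancers), len(tissues)), dtype=bool)
    activity[:, 0] = True
    activity[:, 1:] = rng.random((len(enhancers), len(tissues) - 1)) < cfg.enhancer_sharing
    activity_df = pd.DataFrame(activity, index=enh_ids, columns=tissues)
    tissue_sets = {
        t: AnnotationSet(
            f"enhancers_{t}",
            [e for e, on in zip(enhancers, activity[:, j]) if on],
        )
        for j, t in enumerate(tissues)
    }
    # each enhancer linked to the nearest generated gene within the window
    link_truth: dict[str, str] = {}
    for e in enhancers:
        near = genes.query_interval(e.chrom, max(0, e.midpoint - 500_000),
                                    e.midpoint + 500_000)
        if near:
            link_truth[e.name] = min(
                near, key=lambda g: (abs(g.start - e.midpoint), g.name)
            ).name
    # expression: genes x (tissues + cardiomyocyte); log2 RPKM = base + shift
    gene_ids = [g.name for g in genes]
    base = rng.uniform(2.0, 6.0, size=len(gene_ids))
    log2 = (
        base[:, None]
        + rng.normal(0.0, cfg.expression_noise_sd, size=(len(gene_ids), len(tissues)))
    )
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    delta = cfg.expression_effect_delta * cfg.expression_noise_sd
    for eid, gid in link_truth.items():
        gi = gene_idx[gid]
        log2[gi, activity_df.loc[eid].to_numpy()] += delta
    expr = pd.DataFrame(2.0 ** log2, index=gene_ids, columns=tissues)
    expr["cardiomyocyte"] = 2.0 ** (
        np.log2(expr[cfg.reference_tissue].to_numpy())
        + rng.normal(0.0, 0.2, size=len(gene_ids))
    )
    # signal tracks over the reference tissue's enhancers
    h3k27ac = SignalTrack(
        [(e.chrom, e.start, e.end, float(rng.uniform(5, 15))) for e in enhancers],
        name="H3K27ac",
    )
    dhs = SignalTrack(
        [(e.chrom, e.start, e.end, float(rng.uniform(2, 10))) for e in enhancers],
        name="DHS",
    )
    meth_segments = [
        (e.chrom, e.start, e.end, float(rng.uniform(5, 20))) for e in enhancers
    ]
    methylation = SignalTrack(meth_segments, name="percent_methylation")
    return {
        "enhancers": enhancers,
        "tissue_sets": tissue_sets,
        "activity": activity_df,
        "expression": expr,
        "link_truth": link_truth,
        "h3k27ac": h3k27ac,
        "dhs": dhs,
        "methylation": methylation,
    }


def simulate_allele_counts(
    n_snps: int,
    depth_mean: float = 50.0,
    allele_imbalance_frac: float = 0.0,
    imbalance_ratio: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Allele-specific read counts at heterozygous SNPs.

    Depth is Poisson with the given mean; balanced SNPs draw reference
    reads Binomial(depth, 0.5), imbalanced ones Binomial(depth,
    imbalance_ratio).  Unique-position counts are generated alongside
    (capped by the read counts).
    """
    if not 0 < imbalance_ratio < 1:
        raise ValueError("imbalance_ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    depth = rng.poisson(depth_mean, size=n_snps)
    imbalanced = rng.random(n_snps) < allele_imbalance_frac
    p = np.where(imbalanced, imbalance_ratio, 0.5)
    ref = rng.binomial(depth, p)
    alt = depth - ref
    ref_u = np.minimum(ref, rng.binomial(np.maximum(ref, 1), 0.9))
    alt_u = np.minimum(alt, rng.binomial(np.maximum(alt, 1), 0.9))
    return pd.DataFrame(
        {
            "snp_id": [f"as{i:06d}" for i in range(n_snps)],
            "ref_reads": ref,
            "alt_reads": alt,
            "ref_unique_pos": ref_u,
            "alt_unique_pos": alt_u,
            "truly_imbalanced": imbalanced,
        }
    )


def simulate_fourc(
    viewpoint: tuple[str, int],
    n_fragends_per_side: int = 1000,
    spacing_bp: int = 264,
    decay: tuple[float, float] = (200.0, 0.7),
    planted_peaks: list[tuple[int, float]] | None = None,
    peak_width_bp: int = 5000,
    seed: int = 0,
) -> FragendProfile:
    """Poisson fragment-end counts with power-law distance decay.

    lambda(d) = scale * (1 + d)^(-exponent), multiplied by ``fold``
    within ``peak_width_bp`` of each planted peak offset (signed offsets:
    negative = upstream of the viewpoint).
    """
    scale, exponent = decay
    if exponent <= 0 or scale <= 0:
        raise ValueError("decay parameters must be positive")
    rng = np.random.default_rng(seed)
    chrom, vp = viewpoint
    offsets = np.concatenate(
        [
            -np.arange(n_fragends_per_side, 0, -1) * spacing_bp,
            np.arange(1, n_fragends_per_side + 1) * spacing_bp,
        ]
    )
    lam = scale * (1.0 + np.abs(offsets)) ** (-exponent)
    for off, fold in planted_peaks or []:
        lam = np.where(np.abs(offsets - off) <= peak_width_bp / 2, lam * fold, lam)
    positions = vp + offsets
    keep = positions >= 1
    counts = rng.poisson(lam[keep])
    return FragendProfile(chrom, vp, positions[keep], counts.astype(float))
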