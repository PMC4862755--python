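"""Allelic imbalance at heterozygous SNPs from allele-specific read counts.

A sample is treated as heterozygous at a SNP when reads carrying each
allele map to at least 3 unique positions.  SNPs covered by more than 21
reads are tested with an exact two-sided binomial test against equal
mapping to both alleles, and Benjamini-Hochberg correction is applied
across all heterozygous enhancer-overlapping SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, binomial_exact


@dataclass(frozen=True)
class ImbalanceConfig:
    min_unique_pos: int = 3
    min_total_reads_exclusive: int = 21  # test requires reads > 21
    null_prob: float = 0.5
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.null_prob < 1:
            raise ValueError("null_prob must be in (0, 1)")


def call_heterozygous(
    ref_unique_pos: int, alt_unique_pos: int, cfg: ImbalanceConfig = ImbalanceConfig()
) -> bool:
    """Heterozygous iff both alleles map to >= min_unique_pos positions."""
    return (ref_unique_pos >= cfg.min_unique_pos
            and alt_unique_pos >= cfg.min_unique_pos)


def imbalance_test(
    ref_reads: int, alt_reads: int, cfg: ImbalanceConfig = ImbalanceConfig()
) -> float | None:
    """Exact two-sided binomial p for allelic imbalance, or ``None`` when
    total coverage does not exceed the read threshold."""
    total = ref_reads + alt_reads
    if total <= cfg.min_total_reads_exclusive:
        return None
    return binomial_exact(ref_reads, total, cfg.null_prob, sidedness="two").pvalue


def analyze_counts(
    counts: pd.DataFrame,
    cfg: ImbalanceConfig = ImbalanceConfig(),
    in_family: np.ndarray | None = None,
) -> pd.DataFrame:
    """Heterozygote calling, imbalance testing and BH correction.

    ``in_family`` optionally restricts the BH family (e.g. to
    enhancer-overlapping SNPs); SNPs outside the family keep their raw p
    but receive no adjusted value.  Returns the input frame extended with
    ``het``, ``n``, ``pvalue``, ``p_adj``, ``direction`` columns.
    """
    out = counts.copy().reset_index(drop=True)
    out["het"] = [
        call_heterozygous(r, a, cfg)
        for r, a in zip(out["ref_unique_pos"], out["alt_unique_pos"])
    ]
    out["n"] = out["ref_reads"] + out["alt_reads"]
    pvals: list[float | None] = []
    for het, ref, alt in zip(out["het"], out["ref_reads"], out["alt_reads"]):
        pvals.append(imbalance_test(int(ref), int(alt), cfg) if het else None)
    out["pvalue"] = pvals
    if in_family is None:
        in_family = np.ones(len(out), dtype=bool)
    family = out["pvalue"].notna().to_numpy() & np.asarray(in_family, dtype=bool)
    p_adj = np.full(len(out), np.nan)
    if family.any():
        p_adj[family] = benjamini_hochberg(
            out.loc[family, "pvalue"].to_numpy(dtype=float)
        )
    out["p_adj"] = p_adj
    diff = out["ref_reads"] - out["alt_reads"]
    out["direction"] = np.select(
        [diff > 0, diff < 0], ["ref", "alt"], default="equal"
    )
    return out


def imbalance_summary(analyzed: pd.DataFrame) -> dict[str, float]:
    """Direction tallies over heterozygous SNPs and the median ref-alt
    read difference (0 in unbiased data)."""
    het = analyzed.loc[analyzed["het"]]
    diff = (het["ref_reads"] - het["alt_reads"]).to_numpy()
    return {
        "n_het": int(len(het)),
        "n_ref_more": int((diff > 0).sum()),
        "n_alt_more": int((diff < 0).sum()),
        "n_equal": int((diff == 0).sum()),
        "median_ref_minus_alt": float(np.median(diff)) if len(het) else float("nan"),
    }
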