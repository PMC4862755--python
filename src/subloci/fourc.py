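"""4C-seq interaction peak calling around a viewpoint.

Coverage at restriction fragment ends is smoothed with a centered running
window (21 fragends), a monotone non-increasing background in distance to
the viewpoint is fitted per side by least-squares isotonic regression,
and fragends whose residual exceeds Q3 + q*IQR of the per-side residual
distribution are called significant and merged into peak intervals.
Peaks intersecting annotated promoters (up to 2.5 kb upstream of a TSS,
strand-aware) within the proximal window are reported as
enhancer-promoter interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .intervals import AnnotationSet, GenomicInterval


@dataclass
class FragendProfile:
    """Fragment-end coordinates and read counts around one viewpoint."""

    chrom: str
    viewpoint: int  # 1-based position
    positions: np.ndarray  # 1-based, strictly increasing
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.counts.shape:
            raise ValueError("positions and counts must be equal-length vectors")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("fragend positions must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, chrom: str, viewpoint: int
    ) -> "FragendProfile":
        df = df.sort_values("position")
        return cls(chrom, viewpoint, df["position"].to_numpy(),
                   df["count"].to_numpy())


@dataclass(frozen=True)
class FourCConfig:
    window_fragends: int = 21
    q: float = 5.0
    promoter_upstream_bp: int = 2500
    proximal_bp: int = 500_000

    def __post_init__(self) -> None:
        if self.window_fragends < 1 or self.window_fragends % 2 == 0:
            raise ValueError("window_fragends must be odd and >= 1")
        if self.q <= 0:
            raise ValueError("q must be > 0")


@dataclass
class PeakCall:
    interval: GenomicInterval
    max_exceedance: float
    side: str  # "upstream" | "downstream"
    promoter_hit: str | None = None
    fragend_index: tuple[int, int] = (0, 0)  # [first, last] profile indices


def windowed_coverage(counts: np.ndarray, window: int = 21) -> np.ndarray:
    """Centered running mean over fragends, truncated at the profile ends
    (smaller effective window near the edges; no padding)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty profile")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    idx = np.arange(counts.size)
    lo = np.clip(idx - half, 0, None)
    hi = np.clip(idx + half + 1, None, counts.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def fit_monotone_background(
    smoothed: np.ndarray, distances: np.ndarray
) -> np.ndarray:
    """Least-squares non-increasing fit of signal against distance to the
    viewpoint (pool-adjacent-violators)."""
    smoothed = np.asarray(smoothed, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if smoothed.size < 2:
        return smoothed.copy()
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    return iso.fit_transform(distances, smoothed)


def _call_side(
    profile: FragendProfile,
    idx: np.ndarray,
    smoothed: np.ndarray,
    side: str,
    cfg: FourCConfig,
) -> tuple[np.ndarray, np.ndarray, list[PeakCall]]:
    """Background fit, residual thresholding and peak merging on one side.

    Returns (background, residuals, peaks) for the fragends in ``idx``.
    """
    dists = np.abs(profile.positions[idx] - profile.viewpoint).astype(float)
    order = np.argsort(dists, kind="stable")
    bg = np.empty(idx.size)
    bg[order] = fit_monotone_background(smoothed[idx][order], dists[order])
    resid = smoothed[idx] - bg
    q1, q3 = np.percentile(resid, [25, 75])
    threshold = q3 + cfg.q * (q3 - q1)
    significant = resid > threshold
    peaks: list[PeakCall] = []
    i = 0
    while i < idx.size:
        if significant[i]:
            j = i
            while j + 1 < idx.size and significant[j + 1]:
                j += 1
            first, last = int(idx[i]), int(idx[j])
            start0 = int(profile.positions[first]) - 1
            end0 = int(profile.positions[last])  # half-open, covers last fragend
            peaks.append(
                PeakCall(
                    interval=GenomicInterval(profile.chrom, start0, end0),
                    max_exceedance=float((resid[i : j + 1] - threshold).max()),
                    side=side,
                    fragend_index=(first, last),
                )
            )
            i = j + 1
        else:
            i += 1
    return bg, resid, peaks


def call_peaks(
    profile: FragendProfile, cfg: FourCConfig = FourCConfig()
) -> tuple[list[PeakCall], pd.DataFrame]:
    """Full caller: smoothing, per-side background, Q3 + q*IQR exceedance.

    Returns the peak list and a per-fragend diagnostic table (raw,
    smoothed, background, residual, significant flag).
    """
    smoothed = windowed_coverage(profile.counts, cfg.window_fragends)
    up = np.flatnonzero(profile.positions < profile.viewpoint)
    down = np.flatnonzero(profile.positions >= profile.viewpoint)
    background = np.full(profile.positions.size, np.nan)
    residual = np.full(profile.positions.size, np.nan)
    peaks: list[PeakCall] = []
    for idx, side in ((up, "upstream"), (down, "downstream")):
        if idx.size == 0:
            continue
        bg, resid, side_peaks = _call_side(profile, idx, smoothed, side, cfg)
        background[idx] = bg
        residual[idx] = resid
        peaks.extend(side_peaks)
    table = pd.DataFrame(
        {
            "position": profile.positions,
            "raw": profile.counts,
            "smoothed": smoothed,
            "background": background,
            "residual": residual,
        }
    )
    sig = np.zeros(profile.positions.size, dtype=bool)
    for p in peaks:
        sig[p.fragend_index[0] : p.fragend_index[1] + 1] = True
    table["significant"] = sig
    peaks.sort(key=lambda p: p.interval.start)
    return peaks, table


def promoter_interval(gene: GenomicInterval, upstream_bp: int = 2500) -> GenomicInterval:
    """Strand-aware promoter window: TSS plus ``upstream_bp`` upstream."""
    if gene.strand == "-":
        tss = gene.end - 1
        return GenomicInterval(gene.chrom, tss, tss + upstream_bp + 1,
                               name=gene.name, strand="-")
    tss = gene.start
    return GenomicInterval(gene.chrom, max(0, tss - upstream_bp), tss + 1,
                           name=gene.name, strand="+")


def annotate_promoter_interactions(
    peaks: list[PeakCall],
    genes: list[GenomicInterval],
    viewpoint: tuple[str, int],
    cfg: FourCConfig = FourCConfig(),
) -> list[PeakCall]:
    """Set ``promoter_hit`` on peaks intersecting a promoter, restricted
    to the proximal window around the viewpoint."""
    chrom, vp = viewpoint
    promoters = AnnotationSet(
        "promoters",
        [promoter_interval(g, cfg.promoter_upstream_bp) for g in genes
         if g.name is not None],
    )
    for peak in peaks:
        iv = peak.interval
        if iv.chrom != chrom:
            continue
        if min(abs(iv.start - (vp - 1)), abs(iv.end - 1 - (vp - 1))) > cfg.proximal_bp:
            continue
        hits = promoters.query_interval(iv.chrom, iv.start, iv.end)
        if hits:
            peak.promoter_hit = sorted(h.name for h in hits)[0]
    return peaks
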