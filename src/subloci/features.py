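"""Functional characterization of trait-associated enhancers versus the
full enhancer background of the same tissue: signal density (H3K27ac,
DHS, CAGE), cross-tissue activity, tissue-specific CpG methylation calls,
and best-window evolutionary conservation with size-matched null sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import AnnotationSet, GenomicInterval, SignalTrack
from .stats import empirical_p, rank_sum


@dataclass(frozen=True)
class FeatureComparison:
    feature: str
    fold_change: float  # ratio of group medians, foreground / background
    u_statistic: float
    pvalue: float
    n_fg: int
    n_bg: int


@dataclass(frozen=True)
class MethylationConfig:
    """Joint criterion for tissue-specific methylation calls: the
    reference tissue must differ from the mean of the comparison tissues
    by at least ``sd_multiple`` standard deviations AND at least
    ``min_abs_diff_pp`` percentage points."""

    sd_multiple: float = 2.0
    min_abs_diff_pp: float = 15.0

    def __post_init__(self) -> None:
        if self.sd_multiple <= 0 or self.min_abs_diff_pp < 0:
            raise ValueError("invalid methylation thresholds")


@dataclass(frozen=True)
class ConservationConfig:
    window_bp: int = 100
    n_control_sets: int = 1000
    size_tolerance_bp: int = 1000

    def __post_init__(self) -> None:
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")


def average_signal(track: SignalTrack, interval: GenomicInterval) -> float:
    """Mean per-base signal over an interval (absent bases count 0)."""
    return track.mean_over(interval.chrom, interval.start, interval.end)


def compare_feature(
    fg_values: np.ndarray, bg_values: np.ndarray, feature: str = "feature"
) -> FeatureComparison:
    """Median fold change (fg/bg) and two-sided Mann-Whitney U p-value."""
    fg = np.asarray(fg_values, dtype=float)
    bg = np.asarray(bg_values, dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("both groups must be non-empty")
    med_bg = float(np.median(bg))
    if med_bg == 0:
        fold = float("nan")
    else:
        fold = float(np.median(fg)) / med_bg
    res = rank_sum(fg, bg, sidedness="two")
    return FeatureComparison(feature, fold, res.statistic, res.pvalue,
                             fg.size, bg.size)


def call_tissue_specific_methylation(
    ref_value: float,
    comparison_values: np.ndarray,
    cfg: MethylationConfig = MethylationConfig(),
) -> str:
    """Classify a CpG as ``hypo``, ``hyper`` or ``neither`` in the
    reference tissue relative to the comparison tissues.

    The standard deviation is computed over the comparison tissues only
    (sample sd).  Both the sd criterion and the absolute-difference
    criterion must hold.
    """
    if ref_value is None or not np.isfinite(ref_value):
        raise ValueError("missing reference methylation value")
    comp = np.asarray(comparison_values, dtype=float)
    if comp.size < 2:
        raise ValueError("need >= 2 comparison tissues for an sd")
    mean = float(comp.mean())
    sd = float(comp.std(ddof=1))
    diff = ref_value - mean
    if abs(diff) >= cfg.sd_multiple * sd and abs(diff) >= cfg.min_abs_diff_pp:
        return "hypo" if diff < 0 else "hyper"
    return "neither"


def best_conserved_window(
    track: SignalTrack,
    enhancer: GenomicInterval,
    window_bp: int = 100,
) -> tuple[int, float]:
    """The ``window_bp`` sub-window of an enhancer with greatest mean
    score (1 bp step; ties resolved leftmost).

    Enhancers shorter than the window fall back to the whole-enhancer
    mean (start position = enhancer start).
    """
    length = len(enhancer)
    values = track.values_per_base(enhancer.chrom, enhancer.start, enhancer.end)
    if length <= window_bp:
        return enhancer.start, float(values.mean())
    csum = np.concatenate([[0.0], np.cumsum(values)])
    sums = csum[window_bp:] - csum[:-window_bp]
    # leftmost tie, robust to cumulative-sum float noise
    tol = 1e-9 * max(1.0, float(np.abs(sums).max()))
    best = int(np.flatnonzero(sums >= sums.max() - tol)[0])
    return enhancer.start + best, float(sums[best] / window_bp)


def size_matched_conservation_test(
    fg_enhancers: list[GenomicInterval],
    bg_enhancers: list[GenomicInterval],
    track: SignalTrack,
    cfg: ConservationConfig = ConservationConfig(),
    seed: int = 0,
) -> dict[str, float]:
    """Empirical p for elevated best-window conservation of foreground
    enhancers against random size-matched background sets.

    The statistic is the median best-window score over the foreground;
    each null set draws, per foreground enhancer, one background enhancer
    whose length is within ``size_tolerance_bp``.
    """
    rng = np.random.default_rng(seed)
    if not fg_enhancers:
        raise ValueError("empty foreground")
    bg_scores = np.array(
        [best_conserved_window(track, e, cfg.window_bp)[1] for e in bg_enhancers]
    )
    bg_lengths = np.array([len(e) for e in bg_enhancers])
    fg_scores = np.array(
        [best_conserved_window(track, e, cfg.window_bp)[1] for e in fg_enhancers]
    )
    observed = float(np.median(fg_scores))
    candidates: list[np.ndarray] = []
    for e in fg_enhancers:
        idx = np.flatnonzero(np.abs(bg_lengths - len(e)) <= cfg.size_tolerance_bp)
        if idx.size == 0:
            raise ValueError(
                f"no size-matched background enhancer for "
                f"{e.chrom}:{e.start}-{e.end} (length {len(e)})"
            )
        candidates.append(idx)
    null = np.empty(cfg.n_control_sets)
    for i in range(cfg.n_control_sets):
        picks = [c[int(rng.integers(c.size))] for c in candidates]
        null[i] = np.median(bg_scores[picks])
    return {
        "observed_median": observed,
        "null_median_mean": float(null.mean()),
        "empirical_p": empirical_p(observed, null),
        "n_control_sets": cfg.n_control_sets,
    }


def cross_tissue_activity(
    enhancer: GenomicInterval,
    other_tissue_sets: list[AnnotationSet],
) -> tuple[np.ndarray, int]:
    """Per-tissue activity indicator (>= 1 bp overlap) and its sum."""
    flags = np.array(
        [s.overlaps_interval(enhancer) for s in other_tissue_sets], dtype=bool
    )
    return flags, int(flags.sum())
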