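"""LD-based locus construction: expansion of lead SNPs at r2 > 0.8,
merging/deduplication of overlapping loci, the 1 Mb exclusion buffer
around known loci, significance-ordered LD pruning at r2 > 0.2, and the
80%-of-max causal-candidate filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import VariantRecord


def r2_from_haplotypes(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Squared allelic correlation between two SNPs from 0/1 haplotypes.

    r2 = D^2 / (pA (1-pA) pB (1-pB)) with D = pAB - pA pB.
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("haplotype vectors must be equal-length, length >= 2")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("r2 undefined for a monomorphic SNP")
    d = (a * b).mean() - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


class LdPanel:
    """Pairwise r2 lookup, backed by either a sparse pair table or a
    haplotype matrix (haplotypes x SNPs, 0/1 alleles).

    Absent pairs in a table-backed panel have r2 = 0.
    """

    def __init__(
        self,
        pair_table: dict[tuple[str, str], float] | None = None,
        haplotypes: np.ndarray | None = None,
        snp_ids: list[str] | None = None,
    ):
        if (pair_table is None) == (haplotypes is None):
            raise ValueError("provide exactly one of pair_table or haplotypes")
        self._table = pair_table
        self._adj: dict[str, dict[str, float]] = {}
        self._haps = None
        self._ids: list[str] = []
        self._idx: dict[str, int] = {}
        if haplotypes is not None:
            if snp_ids is None:
                raise ValueError("snp_ids required with a haplotype matrix")
            self._haps = np.asarray(haplotypes, dtype=float)
            if self._haps.shape[1] != len(snp_ids):
                raise ValueError("snp_ids length must match haplotype columns")
            self._ids = list(snp_ids)
            self._idx = {s: i for i, s in enumerate(snp_ids)}
        elif pair_table is not None:
            adj: dict[str, dict[str, float]] = {}
            for (a, b), r2 in pair_table.items():
                adj.setdefault(a, {})[b] = r2
                adj.setdefault(b, {})[a] = r2
            self._adj = adj
            self._ids = sorted(adj)
            self._idx = {s: i for i, s in enumerate(self._ids)}

    @property
    def snp_ids(self) -> list[str]:
        return list(self._ids)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._idx

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        if self._haps is not None:
            return r2_from_haplotypes(
                self._haps[:, self._idx[a]], self._haps[:, self._idx[b]]
            )
        return self._adj.get(a, {}).get(b, 0.0)

    def partners_above(self, snp_id: str, r2_min: float) -> list[str]:
        """SNP ids with r2 strictly above ``r2_min`` with ``snp_id``."""
        if self._haps is not None:
            col = self._haps[:, self._idx[snp_id]]
            out = []
            for j, other in enumerate(self._ids):
                if other == snp_id:
                    continue
                try:
                    if r2_from_haplotypes(col, self._haps[:, j]) > r2_min:
                        out.append(other)
                except ValueError:
                    continue
            return out
        return sorted(
            b for b, r2 in self._adj.get(snp_id, {}).items()
            if b != snp_id and r2 > r2_min
        )


@dataclass
class Locus:
    """A lead variant plus its LD partners above the expansion threshold."""

    lead: VariantRecord
    members: dict[str, VariantRecord] = field(default_factory=dict)
    r2_threshold: float = 0.8

    def __post_init__(self) -> None:
        self.members.setdefault(self.lead.id, self.lead)

    @property
    def member_ids(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)


def expand_locus(
    lead: VariantRecord,
    panel: LdPanel,
    variants: dict[str, VariantRecord],
    r2_min: float = 0.8,
) -> Locus:
    """Members = lead plus all SNPs with r2 strictly > ``r2_min``."""
    if lead.id not in panel:
        raise KeyError(f"lead {lead.id} absent from LD panel")
    members = {lead.id: lead}
    for pid in panel.partners_above(lead.id, r2_min):
        if pid in variants:
            members[pid] = variants[pid]
    return Locus(lead=lead, members=members, r2_threshold=r2_min)


def build_loci(
    leads: list[VariantRecord],
    panel: LdPanel,
    variants: dict[str, VariantRecord],
    r2_min: float = 0.8,
) -> list[Locus]:
    """Expand each lead, treating leads absent from a sparse pair-table
    panel as singletons (no recorded LD partners)."""
    out = []
    for lead in leads:
        if lead.id in panel:
            out.append(expand_locus(lead, panel, variants, r2_min))
        else:
            out.append(Locus(lead=lead, r2_threshold=r2_min))
    return out


def merge_and_deduplicate(
    loci: list[Locus], panel: LdPanel, seed: int
) -> list[Locus]:
    """Merge loci whose leads are in LD (r2 > threshold) and assign each
    SNP shared between non-merged loci to exactly one, uniformly at random.

    Output loci have pairwise-disjoint member sets.
    """
    rng = np.random.default_rng(seed)
    if not loci:
        return []
    thr = loci[0].r2_threshold
    # union-find over loci whose leads are in LD with each other
    parent = list(range(len(loci)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            both = (loci[i].lead.id in panel) and (loci[j].lead.id in panel)
            if both and panel.r2(loci[i].lead.id, loci[j].lead.id) > thr:
                parent[find(j)] = find(i)

    groups: dict[int, list[Locus]] = {}
    for i, locus in enumerate(loci):
        groups.setdefault(find(i), []).append(locus)

    merged: list[Locus] = []
    for group in groups.values():
        # lead of the merged locus: strongest p-value, then lexicographic id
        leads = [g.lead for g in group]
        leads.sort(key=lambda v: (v.pvalue if v.pvalue is not None else 1.0, v.id))
        members: dict[str, VariantRecord] = {}
        for g in group:
            members.update(g.members)
        merged.append(Locus(lead=leads[0], members=members, r2_threshold=thr))

    # resolve members shared across distinct merged loci by a uniform draw
    merged.sort(key=lambda loc: loc.lead.id)
    owners: dict[str, list[int]] = {}
    for i, locus in enumerate(merged):
        for sid in locus.member_ids:
            owners.setdefault(sid, []).append(i)
    for sid, idxs in sorted(owners.items()):
        if len(idxs) > 1:
            keep = idxs[int(rng.integers(len(idxs)))]
            for i in idxs:
                if i != keep:
                    del merged[i].members[sid]
    return merged


def exclude_near_known(
    snps: pd.DataFrame, known_loci: list[Locus], radius_bp: int = 1_000_000
) -> pd.DataFrame:
    """Drop every SNP within ``radius_bp`` (inclusive) of any member of any
    known locus on the same chromosome."""
    if not known_loci:
        return snps.copy()
    keep = np.ones(len(snps), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for locus in known_loci:
        for m in locus.members.values():
            by_chrom.setdefault(m.chrom, []).append(m.pos)
    pos = snps["pos"].to_numpy(dtype=np.int64)
    chrom = snps["chrom"].to_numpy()
    for c, member_pos in by_chrom.items():
        mp = np.sort(np.asarray(member_pos, dtype=np.int64))
        on_c = chrom == c
        if not on_c.any():
            continue
        p = pos[on_c]
        left = np.searchsorted(mp, p - radius_bp, side="left")
        right = np.searchsorted(mp, p + radius_bp, side="right")
        keep[on_c] &= right == left  # no member within the inclusive window
    return snps.loc[keep].reset_index(drop=True)


@dataclass
class SubthresholdLocus:
    """An independent sub-threshold association signal.

    ``representative`` is the strongest-p surviving SNP after pruning at
    r2 > 0.2; ``attached`` are the SNPs pruned against it.
    """

    representative: VariantRecord
    attached: list[VariantRecord] = field(default_factory=list)
    overlaps_enhancer: bool | None = None
    replication_p: float | None = None

    @property
    def all_members(self) -> list[VariantRecord]:
        return [self.representative, *self.attached]


def define_subthreshold_loci(
    snps: pd.DataFrame,
    panel: LdPanel,
    p_max: float = 1e-4,
    r2_prune: float = 0.2,
) -> list[SubthresholdLocus]:
    """LD-prune sub-threshold SNPs into independent loci.

    Restrict to p < ``p_max``, sort by (p ascending, id), then greedily
    keep a SNP iff its r2 with every already-kept SNP is <= ``r2_prune``;
    a removed SNP is attached to the first kept SNP that excluded it.
    The result is order-invariant by construction.
    """
    if snps["pvalue"].isna().any():
        raise ValueError("all SNPs must carry p-values for pruning")
    from .io import variant_records

    sub = snps.loc[snps["pvalue"] < p_max]
    records = variant_records(sub)
    records.sort(key=lambda v: (v.pvalue, v.id))
    kept: list[SubthresholdLocus] = []
    for rec in records:
        home = None
        for locus in kept:
            rid = locus.representative.id
            in_panel = rec.id in panel and rid in panel
            if in_panel and panel.r2(rid, rec.id) > r2_prune:
                home = locus
                break
        if home is None:
            kept.append(SubthresholdLocus(representative=rec))
        else:
            home.attached.append(rec)
    return kept


def causal_candidate_filter(members: list[VariantRecord]) -> list[VariantRecord]:
    """Keep members whose -log10 p is at least 80% of the locus maximum.

    SNPs strictly below the 80% line are unlikely to be causal and are
    dropped; equality retains.  Members without p-values are dropped.
    """
    with_p = [m for m in members if m.pvalue is not None]
    if not with_p:
        raise ValueError("no member carries a p-value")
    neglog = {m.id: -np.log10(m.pvalue) for m in with_p}
    cutoff = 0.8 * max(neglog.values())
    return [m for m in with_p if neglog[m.id] >= cutoff]
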