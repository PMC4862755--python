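"""LD computation, locus expansion/merging, exclusion and pruning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from subloci.io import VariantRecord
from subloci.ld import (
    LdPanel,
    Locus,
    causal_candidate_filter,
    define_subthreshold_loci,
    exclude_near_known,
    expand_locus,
    merge_and_deduplicate,
    r2_from_haplotypes,
)


def var(sid, pos=100, p=0.01, chrom="chr1", maf=0.2):
    return VariantRecord(id=sid, chrom=chrom, pos=pos, maf=maf, pvalue=p)


class TestR2:
    def test_perfect_and_zero_ld(self):
        a = np.array([0, 0, 1, 1])
        assert r2_from_haplotypes(a, a) == pytest.approx(1.0)
        b = np.array([0, 1, 0, 1])
        assert r2_from_haplotypes(a, b) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # pA=1/3, pB=1/6, pAB=1/6, D=1/9 -> r2 = 0.4
        a = np.array([1, 1, 0, 0, 0, 0])
        b = np.array([1, 0, 0, 0, 0, 0])
        assert r2_from_haplotypes(a, b) == pytest.approx(0.4)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            r2_from_haplotypes(np.zeros(4), np.array([0, 1, 0, 1]))

    def test_symmetry_on_random_haplotypes(self, rng):
        haps = (rng.random((30, 10)) < 0.4).astype(int)
        for i, j in itertools.combinations(range(10), 2):
            a, b = haps[:, i], haps[:, j]
            if a.var() == 0 or b.var() == 0:
                continue
            assert r2_from_haplotypes(a, b) == pytest.approx(
                r2_from_haplotypes(b, a)
            )
            assert 0 <= r2_from_haplotypes(a, b) <= 1


class TestExpandLocus:
    def test_strict_threshold_boundary(self):
        lead, other = var("a"), var("b", pos=200)
        variants = {"a": lead, "b": other}
        panel = LdPanel(pair_table={("a", "b"): 0.8})
        assert expand_locus(lead, panel, variants).member_ids == {"a"}
        panel = LdPanel(pair_table={("a", "b"): 0.81})
        assert expand_locus(lead, panel, variants).member_ids == {"a", "b"}

    def test_absent_lead_raises(self):
        panel = LdPanel(pair_table={("x", "y"): 0.9})
        with pytest.raises(KeyError):
            expand_locus(var("z"), panel, {})

    def test_matches_all_pairs_oracle_on_haplotype_panel(self, rng):
        n_snps, n_hap = 40, 60
        haps = (rng.random((n_hap, n_snps)) < rng.uniform(0.1, 0.5, n_snps)).astype(int)
        polymorphic = [j for j in range(n_snps) if 0 < haps[:, j].mean() < 1]
        ids = [f"s{j}" for j in range(n_snps)]
        panel = LdPanel(haplotypes=haps, snp_ids=ids)
        variants = {f"s{j}": var(f"s{j}", pos=j + 1) for j in polymorphic}
        for j in polymorphic[:10]:
            locus = expand_locus(variants[f"s{j}"], panel, variants)
            expected = {f"s{j}"} | {
                f"s{k}"
                for k in polymorphic
                if k != j
                and r2_from_haplotypes(haps[:, j], haps[:, k]) > 0.8
            }
            assert locus.member_ids == expected


class TestMergeAndDeduplicate:
    def test_leads_in_ld_merged(self):
        a, b = var("a", p=1e-9), var("b", pos=300, p=1e-8)
        panel = LdPanel(pair_table={("a", "b"): 0.9})
        merged = merge_and_deduplicate(
            [Locus(lead=a), Locus(lead=b)], panel, seed=0
        )
        assert len(merged) == 1
        assert merged[0].member_ids == {"a", "b"}
        assert merged[0].lead.id == "a"  # stronger p

    def test_disjoint_loci_unchanged(self):
        a, b = var("a"), var("b", pos=300)
        panel = LdPanel(pair_table={("a", "b"): 0.1})
        merged = merge_and_deduplicate([Locus(lead=a), Locus(lead=b)], panel, 0)
        assert sorted(m.lead.id for m in merged) == ["a", "b"]

    def test_shared_member_assigned_uniformly(self):
        counts = {"a": 0, "b": 0}
        shared = var("s", pos=500)
        for seed in range(400):
            a, b = var("a"), var("b", pos=900)
            la = Locus(lead=a, members={"a": a, "s": shared})
            lb = Locus(lead=b, members={"b": b, "s": shared})
            panel = LdPanel(pair_table={("a", "b"): 0.0})
            merged = merge_and_deduplicate([la, lb], panel, seed)
            assert sum("s" in m.member_ids for m in merged) == 1
            owner = next(m.lead.id for m in merged if "s" in m.member_ids)
            counts[owner] += 1
        assert 140 < counts["a"] < 260  # ~Binomial(400, 0.5)


class TestExcludeNearKnown:
    def test_inclusive_radius_boundary(self):
        member = var("k", pos=2_000_000)
        known = [Locus(lead=member)]
        snps = pd.DataFrame(
            {
                "id": ["in", "out"],
                "chrom": ["chr1", "chr1"],
                "pos": [2_999_999, 3_000_001],
                "maf": [0.2, 0.2],
                "pvalue": [0.5, 0.5],
                "on_array": [True, True],
                "dist_to_nearest_gene": [0, 0],
                "n_genes_500kb": [1, 1],
            }
        )
        kept = exclude_near_known(snps, known, radius_bp=1_000_000)
        assert kept["id"].tolist() == ["out"]

    def test_matches_brute_force_on_random_placement(self, rng):
        members = [var(f"k{i}", pos=int(p)) for i, p in
                   enumerate(rng.integers(1, 10_000_000, 5))]
        known = [Locus(lead=m) for m in members]
        pos = rng.integers(1, 10_000_000, 500)
        snps = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(500)],
                "chrom": "chr1",
                "pos": pos,
                "maf": 0.2,
                "pvalue": 0.5,
                "on_array": True,
                "dist_to_nearest_gene": 0,
                "n_genes_500kb": 1,
            }
        )
        kept = set(exclude_near_known(snps, known, radius_bp=750_000)["id"])
        expected = {
            f"s{i}"
            for i in range(500)
            if all(abs(int(pos[i]) - m.pos) > 750_000 for m in members)
        }
        assert kept == expected

    def test_other_chromosome_untouched(self):
        known = [Locus(lead=var("k", pos=100))]
        snps = pd.DataFrame(
            {"id": ["x"], "chrom": ["chr2"], "pos": [100], "maf": [0.2],
             "pvalue": [0.5], "on_array": [True],
             "dist_to_nearest_gene": [0], "n_genes_500kb": [1]}
        )
        assert len(exclude_near_known(snps, known)) == 1


def _snp_frame(records):
    return pd.DataFrame(
        [
            {
                "id": r.id, "chrom": r.chrom, "pos": r.pos, "maf": r.maf,
                "pvalue": r.pvalue, "on_array": True,
                "dist_to_nearest_gene": 0, "n_genes_500kb": 1,
            }
            for r in records
        ]
    )


class TestSubthresholdPruning:
    def test_weaker_snp_pruned_into_stronger_locus(self):
        snps = _snp_frame([var("a", p=1e-5), var("b", pos=300, p=5e-5)])
        panel = LdPanel(pair_table={("a", "b"): 0.3})
        loci = define_subthreshold_loci(snps, panel)
        assert len(loci) == 1
        assert loci[0].representative.id == "a"
        assert [m.id for m in loci[0].attached] == ["b"]

    def test_below_threshold_pairs_stay_separate(self):
        snps = _snp_frame([var("a", p=1e-5), var("b", pos=300, p=5e-5)])
        panel = LdPanel(pair_table={("a", "b"): 0.1})
        assert len(define_subthreshold_loci(snps, panel)) == 2

    def test_p_max_is_strict(self):
        snps = _snp_frame([var("a", p=1e-4), var("b", pos=300, p=9.9e-5)])
        panel = LdPanel(pair_table={})
        loci = define_subthreshold_loci(snps, panel, p_max=1e-4)
        assert [l.representative.id for l in loci] == ["b"]

    def test_matches_exhaustive_oracle_and_order_invariance(self, rng):
        # random panel <= 100 SNPs; survivors must match greedy-by-p oracle
        n = 60
        ids = [f"s{i:02d}" for i in range(n)]
        pvals = rng.uniform(1e-8, 9e-5, n)
        table = {}
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.05:
                table[(ids[i], ids[j])] = float(rng.uniform(0, 1))
        panel = LdPanel(pair_table=table)
        records = [var(ids[i], pos=i + 1, p=float(pvals[i])) for i in range(n)]
        snps = _snp_frame(records)
        loci = define_subthreshold_loci(snps, panel)
        # oracle: independent greedy pass in (p, id) order
        order = sorted(range(n), key=lambda i: (pvals[i], ids[i]))
        kept: list[int] = []
        for i in order:
            if all(panel.r2(ids[i], ids[k]) <= 0.2 for k in kept):
                kept.append(i)
        assert [l.representative.id for l in loci] == [ids[k] for k in kept]
        # order invariance under row permutation
        shuffled = snps.sample(frac=1, random_state=7).reset_index(drop=True)
        loci2 = define_subthreshold_loci(shuffled, panel)
        assert [l.representative.id for l in loci2] == [
            l.representative.id for l in loci
        ]
        assert [sorted(m.id for m in l.attached) for l in loci2] == [
            sorted(m.id for m in l.attached) for l in loci
        ]

    def test_representative_has_minimum_p(self, rng):
        snps = _snp_frame(
            [var(f"s{i}", pos=i + 1, p=float(p))
             for i, p in enumerate(rng.uniform(1e-8, 9e-5, 30))]
        )
        table = {(f"s{i}", f"s{j}"): 0.5 for i in range(30) for j in range(i + 1, 30)
                 if (i + j) % 3 == 0}
        loci = define_subthreshold_loci(snps, LdPanel(pair_table=table))
        for locus in loci:
            assert all(
                m.pvalue >= locus.representative.pvalue for m in locus.attached
            )


class TestCausalCandidateFilter:
    def test_equality_retains_and_below_excludes(self):
        members = [
            var("top", p=1e-5),          # -log10 p = 5
            var("edge", pos=2, p=1e-4),  # 4.0 == 0.8 * 5 -> retained
            var("low", pos=3, p=10 ** -3.9),  # 3.9 < 4 -> excluded
        ]
        kept = {m.id for m in causal_candidate_filter(members)}
        assert kept == {"top", "edge"}

    def test_singleton_always_retained(self):
        assert causal_candidate_filter([var("only", p=0.03)])[0].id == "only"

    def test_all_pvalues_absent_raises(self):
        v = VariantRecord(id="x", chrom="chr1", pos=5, maf=0.1, pvalue=None)
        with pytest.raises(ValueError):
            causal_candidate_filter([v])
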