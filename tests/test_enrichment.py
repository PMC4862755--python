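"""Matched-control sampling and permutation enrichment."""

import numpy as np
import pandas as pd
import pytest

from subloci.enrichment import (
    MatchTolerances,
    MotifInstanceSet,
    count_locus_overlaps,
    match_controls,
    motif_disruption_enrichment,
    motif_disruption_statistic,
    permutation_enrichment,
    shuffle_motif_instances,
)
from subloci.intervals import AnnotationSet, GenomicInterval
from subloci.io import VariantRecord
from subloci.ld import Locus, build_loci


def make_pool(rows):
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "pos", "maf", "on_array", "block_size",
                 "dist_to_nearest_gene", "n_genes_500kb"],
    )


def lead(sid="lead", block=10, maf=0.30, dist=50_000, genes=4):
    return VariantRecord(
        id=sid, chrom="chr1", pos=1000, maf=maf, on_array=True,
        block_size=block, dist_to_nearest_gene=dist, n_genes_500kb=genes,
    )


class TestMatchControls:
    def test_all_windows_inclusive(self):
        pool = make_pool(
            [("c1", "chr1", 99, 0.39, True, 14, 74_000, 7)]
        )
        assert match_controls(lead(), pool)["id"].tolist() == ["c1"]

    def test_maf_window_rejects(self):
        pool = make_pool([("c1", "chr1", 99, 0.12, True, 10, 50_000, 4)])
        with pytest.raises(ValueError, match="lead"):
            match_controls(lead(), pool)

    def test_distance_window_skipped_for_genic_lead(self):
        pool = make_pool([("c1", "chr1", 99, 0.30, True, 10, 900_000, 4)])
        genic = lead(dist=0)
        assert len(match_controls(genic, pool)) == 1

    def test_off_array_candidates_rejected_when_required(self):
        pool = make_pool([("c1", "chr1", 99, 0.30, False, 10, 50_000, 4)])
        with pytest.raises(ValueError):
            match_controls(lead(), pool)
        tol = MatchTolerances(require_on_array=False)
        assert len(match_controls(lead(), pool, tol)) == 1

    def test_matches_brute_force_filter(self, sim_bundle, variant_map):
        variants, _, _ = sim_bundle
        pool = variants[variants.on_array].reset_index(drop=True)
        for sid in pool["id"].iloc[::200]:
            v = variant_map[sid]
            got = set(match_controls(v, pool)["id"])
            expected = set()
            for row in pool.itertuples():
                if row.id == sid or not row.on_array:
                    continue
                if abs(row.block_size - v.block_size) > 5:
                    continue
                if abs(row.maf - v.maf) > 0.1 + 1e-12:
                    continue
                if abs(row.n_genes_500kb - v.n_genes_500kb) > 3:
                    continue
                if v.dist_to_nearest_gene > 0 and abs(
                    row.dist_to_nearest_gene - v.dist_to_nearest_gene
                ) > 25_000:
                    continue
                expected.add(row.id)
            assert got == expected


class TestCountLocusOverlaps:
    def test_locus_counts_once_regardless_of_members(self):
        ann = AnnotationSet("enh", [GenomicInterval("chr1", 0, 10_000)])
        members = {
            f"m{i}": VariantRecord(id=f"m{i}", chrom="chr1", pos=100 + i, maf=0.2)
            for i in range(3)
        }
        locus = Locus(lead=members["m0"], members=dict(members))
        assert count_locus_overlaps([locus], ann) == 1

    def test_whole_genome_annotation_counts_all_loci(self):
        ann = AnnotationSet("all", [GenomicInterval("chr1", 0, 10**9)])
        loci = [
            Locus(lead=VariantRecord(id=f"l{i}", chrom="chr1", pos=i * 50 + 1,
                                     maf=0.2))
            for i in range(5)
        ]
        assert count_locus_overlaps(loci, ann) == 5

    def test_matches_double_loop_oracle(self, rng):
        ivs = [GenomicInterval("chr1", int(s), int(s) + 500)
               for s in rng.integers(0, 100_000, 40)]
        ann = AnnotationSet("r", ivs)
        loci = []
        for i in range(30):
            members = {}
            for j in range(int(rng.integers(1, 5))):
                sid = f"v{i}_{j}"
                members[sid] = VariantRecord(
                    id=sid, chrom="chr1", pos=int(rng.integers(1, 101_000)),
                    maf=0.2,
                )
            loci.append(Locus(lead=list(members.values())[0], members=members))
        expected = sum(
            any(
                any(iv.start <= m.pos - 1 < iv.end for iv in ivs)
                for m in locus.members.values()
            )
            for locus in loci
        )
        assert count_locus_overlaps(loci, ann) == expected


@pytest.fixture(scope="module")
def enrichment_setup(sim_bundle, null_stats, variant_map):
    _, panel, _ = sim_bundle
    pool = null_stats[null_stats.on_array].reset_index(drop=True)
    return panel, pool, variant_map


class TestPermutationEnrichment:
    def test_annotation_on_test_loci_gives_extreme_p(self, enrichment_setup):
        panel, pool, variants = enrichment_setup
        leads = [variants[s] for s in pool["id"].iloc[:15]]
        test_loci = build_loci(leads, panel, variants)
        ivs = [GenomicInterval(v.chrom, v.pos - 1, v.pos) for v in leads]
        ann = AnnotationSet("perfect", ivs)
        res = permutation_enrichment(
            test_loci, pool, panel, variants, ann, n_perm=999, seed=3
        )
        assert res.observed == 15
        assert res.empirical_p == pytest.approx(1 / 1000)
        assert res.z > 5

    def test_empirical_p_never_zero_and_plus_one_rule(self, enrichment_setup):
        panel, pool, variants = enrichment_setup
        leads = [variants[s] for s in pool["id"].iloc[:5]]
        test_loci = build_loci(leads, panel, variants)
        ann = AnnotationSet(
            "none", [GenomicInterval("chr1", 0, 1)]
        )  # overlaps nothing
        res = permutation_enrichment(
            test_loci, pool, panel, variants, ann, n_perm=499, seed=4
        )
        assert res.observed == 0
        assert res.empirical_p == 1.0  # every null >= 0 ties the observed
        assert res.empirical_p > 0

    def test_null_sd_zero_flagged_degenerate(self, enrichment_setup):
        panel, pool, variants = enrichment_setup
        leads = [variants[s] for s in pool["id"].iloc[:3]]
        test_loci = build_loci(leads, panel, variants)
        genome = AnnotationSet(
            "genome", [GenomicInterval(c, 0, 10**8) for c in ("chr1", "chr2")]
        )
        res = permutation_enrichment(
            test_loci, pool, panel, variants, genome, n_perm=200, seed=5
        )
        assert res.degenerate and res.z == 0.0 and res.observed == 3

    def test_toy_z_score_uses_sample_sd(self):
        # null counts {1,2,3}, observed 4 -> z = (4-2)/1 with ddof=1
        null = np.array([1, 2, 3])
        z = (4 - null.mean()) / null.std(ddof=1)
        assert z == pytest.approx(2.0)


class TestMotifEnrichment:
    def test_statistic_requires_enhancer_and_motif(self, enrichment_setup):
        panel, pool, variants = enrichment_setup
        leads = [variants[s] for s in pool["id"].iloc[::40][:8]]
        test_loci = build_loci(leads, panel, variants)
        enh = AnnotationSet(
            "enh", [GenomicInterval(v.chrom, v.pos - 1, v.pos) for v in leads[:4]]
        )
        motif_ivs = [GenomicInterval(v.chrom, v.pos - 1, v.pos) for v in leads[:2]]
        motifs = [
            MotifInstanceSet("M1", "TF1", AnnotationSet("m1", motif_ivs), True),
            MotifInstanceSet(
                "M2", "TF2",
                AnnotationSet("m2", [GenomicInterval(leads[5].chrom,
                                                     leads[5].pos - 1,
                                                     leads[5].pos)]),
                True,
            ),
        ]
        # leads 0,1: enhancer+motif; leads 2,3: enhancer only; lead 5: motif only
        assert motif_disruption_statistic(test_loci, enh, motifs) == 2
        unexpressed = [
            MotifInstanceSet(m.motif_id, m.tf_name, m.instances, False)
            for m in motifs
        ]
        assert motif_disruption_statistic(test_loci, enh, unexpressed) == 0

    def test_enrichment_runs_and_matches_statistic(self, enrichment_setup):
        panel, pool, variants = enrichment_setup
        leads = [variants[s] for s in pool["id"].iloc[::40][:8]]
        test_loci = build_loci(leads, panel, variants)
        enh = AnnotationSet(
            "enh", [GenomicInterval(v.chrom, v.pos - 1, v.pos) for v in leads[:4]]
        )
        motifs = [
            MotifInstanceSet(
                "M1", "TF1",
                AnnotationSet("m1", [GenomicInterval(v.chrom, v.pos - 1, v.pos)
                                     for v in leads[:3]]),
                True,
            )
        ]
        res = motif_disruption_enrichment(
            test_loci, pool, panel, variants, enh, motifs, n_perm=299, seed=6
        )
        assert res.observed == 3
        assert res.empirical_p <= 0.05


class TestShuffleMotifs:
    def test_lengths_and_counts_preserved_and_deterministic(self, rng):
        ivs = [GenomicInterval("chr1", int(s), int(s) + int(w))
               for s, w in zip(rng.integers(0, 10**6, 50),
                               rng.integers(5, 30, 50))]
        motifs = [MotifInstanceSet("M", "TF", AnnotationSet("m", ivs), True)]
        genome = {"chr1": 2_000_000, "chr2": 1_000_000}
        s1 = shuffle_motif_instances(motifs, genome, seed=9)
        s2 = shuffle_motif_instances(motifs, genome, seed=9)
        assert len(s1[0].instances) == 50
        assert sorted(len(iv) for iv in s1[0].instances) == sorted(
            len(iv) for iv in ivs
        )
        assert list(s1[0].instances) == list(s2[0].instances)
        for iv in s1[0].instances:
            assert 0 <= iv.start and iv.end <= genome[iv.chrom]
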