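"""Variant filters, specificity, MAF strata, enrichment, and the pipeline."""

import numpy as np
import pytest

from fxpoi.variants import (
    Consequence,
    EnrichmentResult,
    Genotype,
    MafClass,
    Specificity,
    consequence_filter,
    gene_enrichment,
    intersect_gene_lists,
    maf_stratify,
    prioritize,
    region_filter,
    site_quality_filter,
    specificity,
)

from .conftest import make_variant


class TestSiteQuality:
    @pytest.mark.parametrize(
        "kw",
        [
            {"quality": 29.9},
            {"qd": 4.9},
            {"hrun": 6},
            {"sb": -0.10},  # pass requires strictly more negative
            {"sb": 0.2},
            {"no_calls": ("poi3",)},
            {"no_calls": ("ctr9",)},
        ],
    )
    def test_failing_site_removed(self, design, kw):
        assert site_quality_filter([make_variant(**kw)], design) == []

    def test_passing_site_retained(self, design):
        v = make_variant(quality=35.0, qd=6.0, hrun=2, sb=-0.5)
        assert site_quality_filter([v], design) == [v]

    def test_boundary_values_pass(self, design):
        v = make_variant(quality=30.0, qd=5.0, hrun=5, sb=-0.11)
        assert site_quality_filter([v], design) == [v]

    def test_missing_metric_dropped_and_counted(self, design):
        v = make_variant(qd=None)
        diag = {}
        assert site_quality_filter([v], design, diagnostics=diag) == []
        assert diag["missing_quality"] == 1


class TestRegion:
    EXONS = [("1", 100, 200), ("2", 0, 50)]
    SEGDUP = [("1", 150, 160)]

    def test_coordinate_convention(self):
        # 1-based position 101 -> 0-based 100, the first base of the exon
        v = make_variant(pos=101)
        assert region_filter([v], [], self.EXONS)[0].in_refseq_exon is True
        # 1-based 200 -> 0-based 199 is the last in-exon base; 201 is out
        assert region_filter([make_variant(pos=200)], [], self.EXONS)
        assert not region_filter([make_variant(pos=201)], [], self.EXONS)

    def test_segdup_overrides_exon(self):
        v = make_variant(pos=155)  # inside both the segdup and the exon
        assert region_filter([v], self.SEGDUP, self.EXONS) == []

    def test_empty_exon_file_removes_everything(self):
        assert region_filter([make_variant(pos=101)], self.SEGDUP, []) == []

    def test_malformed_bed_is_hard_failure(self, tmp_path):
        from fxpoi.io import read_bed

        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t100\n")
        with pytest.raises(ValueError, match="bad.bed:1"):
            read_bed(bad)


class TestConsequence:
    @pytest.mark.parametrize(
        "cons,kept",
        [
            (Consequence.MISSENSE, True),
            (Consequence.STOP_GAIN, True),
            (Consequence.STOP_LOSS, True),
            (Consequence.START_LOSS, True),
            (Consequence.SYNONYMOUS, False),
            (Consequence.SPLICE, False),
            (Consequence.OTHER_NONCODING, False),
        ],
    )
    def test_nonsynonymous_definition(self, cons, kept):
        got = consequence_filter([make_variant(consequence=cons)])
        assert bool(got) is kept


class TestSpecificity:
    @pytest.mark.parametrize(
        "carriers,expected",
        [
            (("poi2",), Specificity.CASE_SPECIFIC),
            (("poi1", "poi4"), Specificity.CASE_SPECIFIC),
            (("ctr6",), Specificity.CONTROL_SPECIFIC),
            (("poi1", "ctr6"), Specificity.SHARED),
            ((), Specificity.ABSENT),
        ],
    )
    def test_classes(self, design, carriers, expected):
        assert specificity(make_variant(carriers=carriers), design) == expected

    def test_uncalled_sample_is_an_error(self, design):
        with pytest.raises(ValueError, match="not called"):
            specificity(make_variant(no_calls=("ctr7",)), design)

    def test_classes_partition_fully_called_variants(self, design, random_variant_pool):
        counts = {s: 0 for s in Specificity}
        for v in random_variant_pool:
            counts[specificity(v, design)] += 1
        assert sum(counts.values()) == len(random_variant_pool)


class TestMafStrata:
    @pytest.mark.parametrize(
        "kw,expected",
        [
            ({"mafs": {"EVS": 0.08}}, MafClass.COMMON),
            ({"mafs": {"EVS": 0.005, "1000G": 0.009}}, MafClass.RARE),
            ({"mafs": {"EVS": 0.01}}, MafClass.RARE),  # boundary 1% -> rare
            ({"mafs": {"EVS": 0.005, "1000G": 0.02}}, MafClass.COMMON),  # max rule
            ({"mafs": {}, "dbsnp_known": True}, MafClass.RARE),
            ({"mafs": {}, "dbsnp_known": False}, MafClass.NOVEL),
        ],
    )
    def test_stratification(self, kw, expected):
        assert maf_stratify(make_variant(**kw)) == expected

    def test_classes_exclusive_and_exhaustive(self, random_variant_pool):
        rng = np.random.default_rng(0)
        for v in random_variant_pool[:200]:
            assert maf_stratify(v) in MafClass


class TestGeneLists:
    def test_variant_on_two_lists_reported_twice(self):
        v = make_variant(gene="MSH5")
        out = intersect_gene_lists([v], {"a": ["MSH5", "NBN"], "b": ["msh5"], "c": []})
        assert out["a"] == [v] and out["b"] == [v] and out["c"] == []


class TestEnrichment:
    @pytest.mark.parametrize(
        "nc,nk,expected",
        [
            (5, 2, True),   # boundary of both rules
            (4, 0, False),  # fails the >=5 rule
            (6, 3, True),
            (5, 3, False),  # fails the 2x rule
            (10, 5, True),
            (0, 4, False),
        ],
    )
    def test_rule_boundaries(self, design, nc, nk, expected):
        variants = [
            make_variant(pos=100 + i, gene="G", carriers=("poi1",)) for i in range(nc)
        ] + [
            make_variant(pos=500 + i, gene="G", carriers=("ctr6",)) for i in range(nk)
        ]
        (res,) = gene_enrichment(variants, design)
        assert res.case_specific_count == nc
        assert res.control_specific_count == nk
        assert res.enriched is expected

    def test_blocklist_vetoes_enrichment(self, design):
        variants = [
            make_variant(pos=100 + i, gene="HUGE1", carriers=("poi1",)) for i in range(8)
        ]
        (res,) = gene_enrichment(variants, design, blocklist=["huge1"])
        assert res.blocklisted and not res.enriched

    def test_agrees_with_brute_force_recount(self, design, random_variant_pool):
        """Enrichment verdicts match an independent per-gene recount over a
        1000-variant pool."""
        results = {r.gene: r for r in gene_enrichment(random_variant_pool, design)}
        cases = sorted(design.case_ids)
        controls = sorted(design.control_ids)
        genes = sorted({v.gene for v in random_variant_pool})
        for gene in genes:
            nc = nk = 0
            for v in random_variant_pool:
                if v.gene != gene:
                    continue
                carr_case = [s for s in cases if v.genotypes[s] != Genotype.HOM_REF]
                carr_ctrl = [s for s in controls if v.genotypes[s] != Genotype.HOM_REF]
                if carr_case and not carr_ctrl:
                    nc += 1
                elif carr_ctrl and not carr_case:
                    nk += 1
            if nc == 0 and nk == 0:
                assert gene not in results
                continue
            r = results[gene]
            assert (r.case_specific_count, r.control_specific_count) == (nc, nk)
            assert r.enriched is (nc >= 5 and nc >= 2 * nk)

    def test_enriched_blocklisted_result_is_invalid(self):
        with pytest.raises(ValueError):
            EnrichmentResult("G", 6, 0, enriched=True, blocklisted=True)


class TestFilterInvariants:
    def test_filters_shrink_and_are_idempotent(self, design, random_variant_pool):
        exons = [("1", 0, 10_000)]
        pool = random_variant_pool
        q = site_quality_filter(pool, design)
        assert set(v.key for v in q) <= set(v.key for v in pool)
        assert site_quality_filter(q, design) == q
        c = consequence_filter(q)
        assert consequence_filter(c) == c
        r = region_filter(c, [], exons)
        assert [v.key for v in region_filter(r, [], exons)] == [v.key for v in r]

    def test_region_and_consequence_commute(self, design, random_variant_pool):
        exons = [("1", 0, 1500)]  # splits the pool by position
        a = consequence_filter(region_filter(random_variant_pool, [], exons))
        b = region_filter(consequence_filter(random_variant_pool), [], exons)
        assert [v.key for v in a] == [v.key for v in b]


class TestPipeline:
    def test_recovers_planted_signal(self, variant_table_dir, design):
        from fxpoi.io import read_bed, read_gene_list, read_vcf_with_annotations

        outdir, config, truth = variant_table_dir
        variants = read_vcf_with_annotations(
            outdir / "variants.vcf", outdir / "annotations.tsv"
        )
        gene_lists = {
            p.stem: read_gene_list(p) for p in sorted((outdir / "gene_lists").glob("*.txt"))
        }
        report = prioritize(
            variants,
            design,
            gene_lists,
            read_bed(outdir / "segdup.bed"),
            read_bed(outdir / "exons.bed"),
        )
        assert report.enriched_genes == truth["planted_enriched_genes"]
        goi = report.candidate_tables["genes_of_interest"]
        common = goi[goi["maf_class"] == "common"]
        planted_common = {tuple(x[:4]) for x in truth["planted_common_goi"]}
        got_common = {
            (r.chromosome, r.position, r.ref, r.alt) for r in common.itertuples()
        }
        assert got_common == {(c, int(p), r, a) for c, p, r, a in planted_common}
        # attrition monotone along the pipeline
        att = report.attrition
        assert att["input"] >= att["site_quality"] >= att["region"] >= att["consequence"]

    def test_idempotent_on_retained_output(self, variant_table_dir, design):
        from fxpoi.io import read_bed, read_gene_list, read_vcf_with_annotations

        outdir, config, truth = variant_table_dir
        variants = read_vcf_with_annotations(
            outdir / "variants.vcf", outdir / "annotations.tsv"
        )
        gene_lists = {
            p.stem: read_gene_list(p) for p in sorted((outdir / "gene_lists").glob("*.txt"))
        }
        segdup = read_bed(outdir / "segdup.bed")
        exons = read_bed(outdir / "exons.bed")
        first = prioritize(variants, design, gene_lists, segdup, exons)
        second = prioritize(first.retained, design, gene_lists, segdup, exons)
        assert [v.key for v in second.retained] == [v.key for v in first.retained]
        assert second.enrichment.equals(first.enrichment)
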