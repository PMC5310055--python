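"""Known-variant lookup, tallies, seed-gene expansion, interactome scan."""

import numpy as np
import pytest

from tmau.cascade import CascadeConfig
from tmau.catalog_network import (
    CatalogEntry,
    CatalogHit,
    ExtraGenotype,
    InteractionNetwork,
    KnownVariantCatalog,
    expand_seed_genes,
    interactome_variant_scan,
    lookup_known_variants,
    parse_genotype_string,
    tally_catalog_hits,
)
from tmau.variants import (
    AnnotationStore,
    SiftCall,
    VariantAnnotation,
    VariantKey,
    Zygosity,
)

from conftest import make_matrix


class TestCatalogLookup:
    def test_fixture_known_variant_zygosities(self, fixture):
        hits = lookup_known_variants(fixture.matrix, fixture.catalog, fixture.extra_genotypes)
        tally = tally_catalog_hits(hits)
        assert tally["rs2266782"] == (5, 0)
        assert tally["rs7072216"] == (2, 3)
        assert tally["rs72549325"] == (1, 0)

    def test_extra_genotypes_cover_off_exome_assays(self, fixture):
        # without the side channel the intronic assay produces no hits
        hits = lookup_known_variants(fixture.matrix, fixture.catalog, None)
        assert "rs7072216" not in tally_catalog_hits(hits)

    def test_empty_catalog_yields_no_hits(self, fixture):
        assert lookup_known_variants(fixture.matrix, KnownVariantCatalog()) == []

    def test_no_hits_for_reference_or_missing_cells(self):
        Z = Zygosity
        m = make_matrix([[Z.HOM_REF], [Z.MISSING], [Z.HET]])
        (v,) = m.variants
        catalog = KnownVariantCatalog([CatalogEntry("rs1", v, "G1")])
        hits = lookup_known_variants(m, catalog)
        assert [(h.subject_id, h.zygosity) for h in hits] == [("s3", Z.HET)]

    def test_allele_collision_warns(self):
        Z = Zygosity
        m = make_matrix([[Z.HET]], keys=[VariantKey("1", 1000, "A", "G")])
        catalog = KnownVariantCatalog(
            [CatalogEntry("rs1", VariantKey("1", 1000, "A", "T"), "G1")]
        )
        with pytest.warns(UserWarning, match="collides"):
            assert lookup_known_variants(m, catalog) == []

    def test_duplicate_catalog_entries_rejected(self):
        k = VariantKey("1", 5, "A", "G")
        catalog = KnownVariantCatalog([CatalogEntry("rs1", k, "G1")])
        with pytest.raises(ValueError, match="duplicate"):
            catalog.add(CatalogEntry("rs1", VariantKey("1", 6, "A", "G"), "G1"))


class TestTally:
    def test_het_hom_and_hemi_counting(self):
        hits = [
            CatalogHit("s64", "rs2266782", "FMO3", Zygosity.HET),
            CatalogHit("s98", "rs2266782", "FMO3", Zygosity.HET),
            CatalogHit("s35", "rsX", "G", Zygosity.HOM_ALT),
            CatalogHit("s52", "rsX", "G", Zygosity.HET),
            CatalogHit("s113", "rsY", "G", Zygosity.HEMI_ALT),
        ]
        tally = tally_catalog_hits(hits)
        assert tally["rs2266782"] == (2, 0)
        assert tally["rsX"] == (1, 1)
        assert tally["rsY"] == (0, 1)  # hemizygous counts as homozygous


class TestGenotypeStrings:
    @pytest.mark.parametrize(
        "gt,hemi,expected",
        [
            ("0/1", False, Zygosity.HET),
            ("1/1", False, Zygosity.HOM_ALT),
            ("1/1", True, Zygosity.HEMI_ALT),
            ("1", True, Zygosity.HEMI_ALT),
            ("0", False, Zygosity.HOM_REF),
            (".", False, Zygosity.MISSING),
            ("./.", False, Zygosity.MISSING),
        ],
    )
    def test_parse(self, gt, hemi, expected):
        assert parse_genotype_string(gt, hemi) is expected

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            parse_genotype_string("2/1")


class TestSeedExpansion:
    def net(self):
        return InteractionNetwork(
            [
                ("DMGDH", "BHMT", 0.9),
                ("DMGDH", "SARDH", 0.8),
                ("DMGDH", "SHMT1", 0.5),
                ("DMGDH", "XLOW", 0.3),
            ]
        )

    def test_score_cut(self):
        out = expand_seed_genes(self.net(), ["DMGDH"])
        assert out == {"DMGDH", "BHMT", "SARDH", "SHMT1"}

    def test_truncation_with_lexicographic_ties(self):
        net = InteractionNetwork(
            [("S", f"N{chr(65 + i)}", 0.9) for i in range(12)]
        )
        out = expand_seed_genes(net, ["S"], max_interactors=10)
        assert out == {"S"} | {f"N{chr(65 + i)}" for i in range(10)}

    def test_union_over_seeds_deduplicates(self):
        net = InteractionNetwork([("A", "SHAREDX", 0.9), ("B", "SHAREDX", 0.9)])
        out = expand_seed_genes(net, ["A", "B"])
        assert out == {"A", "B", "SHAREDX"}

    def test_absent_seed_warns_but_is_included(self):
        with pytest.warns(UserWarning, match="GHOST"):
            out = expand_seed_genes(self.net(), ["GHOST"])
        assert out == {"GHOST"}

    def test_size_bound_and_min_score_monotonicity(self):
        net = self.net()
        seeds = ["DMGDH", "BHMT"]
        low = expand_seed_genes(net, seeds, min_score=0.2)
        for s in (0.4, 0.6, 0.95):
            cur = expand_seed_genes(net, seeds, min_score=s)
            assert cur <= low
            assert len(cur) <= len(seeds) * 11
            low = cur

    def test_network_invariants(self):
        with pytest.raises(ValueError, match="self-loop"):
            InteractionNetwork([("A", "A", 0.5)])
        with pytest.raises(ValueError, match="duplicate"):
            InteractionNetwork([("A", "B", 0.5), ("B", "A", 0.6)])
        with pytest.raises(ValueError, match="score"):
            InteractionNetwork([("A", "B", 1.5)])


class TestInteractomeScan:
    def test_fixture_dmgdh_scan_is_exact(self, fixture):
        genes = expand_seed_genes(fixture.network, ["DMGDH"])
        scan = interactome_variant_scan(fixture.matrix, fixture.annotations, genes)
        assert sorted(fixture.annotations[k].gene for k in scan) == [
            "BHMT2",
            "SARDH",
            "SHMT1",
        ]
        # all carriers of the interactome hits are heterozygous
        for key in scan:
            for sid in fixture.matrix.carriers(key):
                assert fixture.matrix.zygosity(sid, key) is Zygosity.HET

    def test_fixture_fmo3_and_pyroxd2_scans_empty(self, fixture):
        for seed in ("FMO3", "PYROXD2"):
            genes = expand_seed_genes(fixture.network, [seed])
            assert interactome_variant_scan(fixture.matrix, fixture.annotations, genes) == set()

    def test_distributes_over_gene_set_union(self, fixture):
        ann = fixture.annotations
        m = fixture.matrix
        s1 = frozenset({"BHMT2", "SARDH"})
        s2 = frozenset({"SHMT1", "CP"})
        union = interactome_variant_scan(m, ann, s1 | s2)
        assert union == interactome_variant_scan(m, ann, s1) | interactome_variant_scan(m, ann, s2)

    def test_disjoint_gene_set_yields_empty(self, fixture):
        out = interactome_variant_scan(
            fixture.matrix, fixture.annotations, frozenset({"NOSUCHGENE"})
        )
        assert out == set()
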