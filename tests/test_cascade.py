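"""Filter-cascade behaviour: component filters, nestedness, oracle parity."""

import numpy as np
import pytest

from oracle import brute_force_cascade
from tmau.cascade import (
    Branch,
    CascadeConfig,
    GeneSetMode,
    SharingZygosity,
    cohort_presence_filter,
    gene_set_filter,
    pathogenicity_filter,
    rarity_filter,
    run_cascade,
    shared_variant_filter,
)
from tmau.variants import (
    AnnotationStore,
    GenotypeMatrix,
    PolyphenCall,
    Sex,
    SiftCall,
    SubjectInfo,
    VariantAnnotation,
    VariantKey,
    Zygosity,
)

from conftest import make_matrix

CFG = CascadeConfig()


def ann_store(*annotations):
    return AnnotationStore(annotations)


def ann(key, gene="G1", sift=None, poly=None, maf=None):
    return VariantAnnotation(
        key=key,
        gene=gene,
        sift_call=SiftCall(sift[1]) if sift and sift[1] else None,
        sift_score=sift[0] if sift else None,
        polyphen_call=PolyphenCall(poly[1]) if poly and poly[1] else None,
        polyphen_score=poly[0] if poly else None,
        maf=maf,
    )


class TestCohortPresence:
    def test_requires_a_cohort_homozygote_by_default(self, toy_matrix):
        v1, v2, v3, v4 = toy_matrix.variants
        kept = cohort_presence_filter(toy_matrix, CFG)
        # v1 has one HOM_ALT; v2 is het-only; v3 has a homozygote despite a
        # missing cell; v4 is all reference
        assert kept == {v1, v3}

    def test_any_carrier_when_homozygote_not_required(self, toy_matrix):
        cfg = CascadeConfig(require_cohort_homozygote=False)
        kept = cohort_presence_filter(toy_matrix, cfg)
        assert kept == set(toy_matrix.variants[:3])


class TestPathogenicity:
    k = VariantKey("1", 10, "A", "G")

    @pytest.mark.parametrize(
        "sift,poly,kept",
        [
            ((0.01, "DELETERIOUS"), (0.1, "BENIGN"), True),   # SIFT alone
            ((0.4, "TOLERATED"), (0.9, "DAMAGING"), True),    # PolyPhen alone
            ((0.4, "TOLERATED"), (0.1, "BENIGN"), False),
            (None, None, False),                               # unscored
        ],
    )
    def test_either_rule(self, sift, poly, kept):
        store = ann_store(ann(self.k, sift=sift, poly=poly))
        result = pathogenicity_filter({self.k}, store, CFG)
        assert (self.k in result) is kept

    def test_score_used_when_call_absent(self):
        store = ann_store(ann(self.k, sift=(0.01, None)))
        assert pathogenicity_filter({self.k}, store, CFG) == {self.k}

    def test_missing_annotation_is_error(self):
        with pytest.raises(KeyError, match="1:10"):
            pathogenicity_filter({self.k}, ann_store(), CFG)


class TestGeneSetAndRarity:
    k = VariantKey("1", 10, "A", "G")

    def test_include_and_exclude(self):
        store = ann_store(ann(self.k, gene="CP"))
        assert gene_set_filter({self.k}, store, {"cp"}, GeneSetMode.INCLUDE) == {self.k}
        assert gene_set_filter({self.k}, store, {"CP"}, GeneSetMode.EXCLUDE) == set()

    def test_unknown_gene_cannot_prove_membership(self):
        store = ann_store(ann(self.k, gene=None))
        assert gene_set_filter({self.k}, store, {"CP"}, GeneSetMode.INCLUDE) == set()
        assert gene_set_filter({self.k}, store, {"CP"}, GeneSetMode.EXCLUDE) == {self.k}

    def test_empty_include_set_warns_and_keeps_nothing(self):
        store = ann_store(ann(self.k, gene="CP"))
        with pytest.warns(UserWarning):
            assert gene_set_filter({self.k}, store, set(), GeneSetMode.INCLUDE) == set()

    @pytest.mark.parametrize(
        "maf,kept", [(0.011, True), (0.383, False), (None, True)]
    )
    def test_rarity(self, maf, kept):
        store = ann_store(ann(self.k, maf=maf))
        assert (self.k in rarity_filter({self.k}, store, CFG)) is kept

    def test_missing_maf_excluded_under_strict_policy(self):
        cfg = CascadeConfig(missing_maf_policy="EXCLUDE")
        store = ann_store(ann(self.k, maf=None))
        assert rarity_filter({self.k}, store, cfg) == set()


class TestSharedVariants:
    def test_hom_only_vs_any_carrier(self):
        Z = Zygosity
        m = make_matrix([[Z.HOM_ALT], [Z.HET], [Z.HOM_REF]])
        (v,) = m.variants
        hom = shared_variant_filter(m, {v}, CFG, SharingZygosity.HOM_ALT_ONLY)
        assert hom == {}
        any_c = shared_variant_filter(m, {v}, CFG, SharingZygosity.ANY_CARRIER)
        assert any_c == {v: frozenset({"s1", "s2"})}

    def test_two_homozygotes_shared(self):
        Z = Zygosity
        m = make_matrix([[Z.HOM_ALT], [Z.HOM_ALT], [Z.HOM_REF]])
        (v,) = m.variants
        hom = shared_variant_filter(m, {v}, CFG, SharingZygosity.HOM_ALT_ONLY)
        assert hom == {v: frozenset({"s1", "s2"})}

    def test_hemizygous_counts_as_homozygous_sharing(self):
        Z = Zygosity
        m = make_matrix(
            [[Z.HEMI_ALT], [Z.HEMI_ALT]],
            sexes=[Sex.M, Sex.M],
            keys=[VariantKey("X", 100, "C", "T")],
        )
        (v,) = m.variants
        hom = shared_variant_filter(m, {v}, CFG, SharingZygosity.HOM_ALT_ONLY)
        assert hom == {v: frozenset({"s1", "s2"})}


def random_cohort(rng, n_subjects=6, n_variants=40):
    """Random matrix + annotations exercising every criterion combination."""
    genes = ["CP", "AOC2", "FMO3", "PYROXD2", "OTHER1", "OTHER2", None]
    subjects = [
        SubjectInfo(f"s{i}", Sex.M if i % 3 == 0 else Sex.F)
        for i in range(n_subjects)
    ]
    keys, cols, anns = [], [], []
    for j in range(n_variants):
        chrom = str(rng.integers(1, 23))
        ref, alt = ("A", "G") if rng.random() < 0.8 else ("A", "AT")
        key = VariantKey(chrom, 100 + j, ref, alt)
        col = rng.choice(
            [Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT, Zygosity.MISSING],
            size=n_subjects,
            p=[0.4, 0.25, 0.25, 0.1],
        ).astype(np.int8)
        sift = (
            (float(rng.uniform(0, 0.049)), "DELETERIOUS")
            if rng.random() < 0.5
            else (float(rng.uniform(0.05, 1)), "TOLERATED")
        )
        maf = None if rng.random() < 0.2 else float(rng.uniform(0, 0.5))
        keys.append(key)
        cols.append(col)
        anns.append(
            ann(key, gene=genes[int(rng.integers(len(genes)))], sift=sift, maf=maf)
        )
    matrix = GenotypeMatrix(
        subjects=subjects, variants=keys, cells=np.stack(cols, axis=1)
    )
    return matrix, AnnotationStore(anns)


@pytest.mark.parametrize("seed", range(8))
def test_cascade_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    matrix, store = random_cohort(rng)
    oxido = {"CP", "AOC2"}
    report = run_cascade(matrix, store, oxido, CFG)
    oracle = brute_force_cascade(matrix, store, oxido, CFG)
    by_step = {(s.branch.value, s.label): s.keys for s in report.steps}
    assert by_step[("MAIN", "cohort_presence")] == oracle["cohort_presence"]
    assert by_step[("MAIN", "pathogenic")] == oracle["pathogenic"]
    assert by_step[("OXIDOREDUCTASE", "oxidoreductase_genes")] == oracle["oxidoreductase_genes"]
    assert by_step[("OXIDOREDUCTASE", "rare")] == oracle["oxidoreductase_rare"]
    assert by_step[("SHARED", "exclude_known_tma_genes")] == oracle["exclude_known"]
    assert by_step[("SHARED", "shared_any_carrier")] == oracle["shared_any"]
    assert by_step[("SHARED", "shared_homozygous")] == oracle["shared_hom"]
    assert by_step[("SHARED", "rare")] == oracle["shared_rare"]


@pytest.mark.parametrize("seed", range(4))
def test_survivor_sets_are_nested_along_each_branch(seed):
    rng = np.random.default_rng(100 + seed)
    matrix, store = random_cohort(rng)
    report = run_cascade(matrix, store, {"CP", "AOC2"}, CFG)
    trunk = report.branch_steps(Branch.MAIN)
    for prev, cur in zip(trunk, trunk[1:]):
        assert cur.keys <= prev.keys
    for branch in (Branch.OXIDOREDUCTASE, Branch.SHARED):
        steps = trunk[-1:] + report.branch_steps(branch)
        for prev, cur in zip(steps, steps[1:]):
            assert cur.keys <= prev.keys


def test_counts_invariant_under_subject_and_variant_permutation():
    rng = np.random.default_rng(7)
    matrix, store = random_cohort(rng)
    report = run_cascade(matrix, store, {"CP"}, CFG)
    perm = matrix.reordered(
        subject_ids=[s.id for s in matrix.subjects][::-1],
        variant_keys=list(matrix.variants)[::-1],
    )
    report_perm = run_cascade(perm, store, {"CP"}, CFG)
    assert {(s.branch, s.label): s.keys for s in report.steps} == {
        (s.branch, s.label): s.keys for s in report_perm.steps
    }


def test_empty_matrix_yields_all_zero_counts():
    m = GenotypeMatrix(
        subjects=[SubjectInfo("a", Sex.F)],
        variants=[],
        cells=np.empty((1, 0), dtype=np.int8),
    )
    with pytest.warns(UserWarning, match="empty gene set"):
        report = run_cascade(m, AnnotationStore(), set(), CFG)
    assert all(s.snp_count == 0 and s.indel_count == 0 for s in report.steps)


def test_config_rejects_bad_thresholds():
    with pytest.raises(ValueError):
        CascadeConfig(maf_threshold=0.0)
    with pytest.raises(ValueError):
        CascadeConfig(min_sharing_subjects=1)
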