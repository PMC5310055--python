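"""Genotype matrix and annotation I/O behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmau.variants import (
    GenotypeMatrix,
    Sex,
    SubjectInfo,
    VariantAnnotation,
    VariantClass,
    VariantKey,
    Zygosity,
    classify_variant,
    read_annotation_table,
    read_multisample_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##FORMAT=<ID=GT,Number=1,Type=String,Description=\"Genotype\">\n"
    "##contig=<ID=1>\n##contig=<ID=X>\n"
)


def write_vcf(tmp_path, body, samples):
    p = tmp_path / "in.vcf"
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    p.write_text(VCF_HEADER + cols + "\n" + body)
    return p


class TestVcfReading:
    def test_gt_semantics_and_multiallelic_split(self, tmp_path):
        # one biallelic + one two-ALT record -> 3 variant columns
        body = (
            "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\t./.\n"
            "1\t200\t.\tC\tT,G\t.\t.\t.\tGT\t1/2\t2/2\t0/0\n"
        )
        path = write_vcf(tmp_path, body, ["a", "b", "c"])
        m = read_multisample_vcf(path, {"a": "F", "b": "F", "c": "F"})
        assert m.n_variants == 3
        k1 = VariantKey("1", 100, "A", "G")
        assert m.zygosity("a", k1) is Zygosity.HET
        assert m.zygosity("b", k1) is Zygosity.HOM_ALT
        assert m.zygosity("c", k1) is Zygosity.MISSING
        kt = VariantKey("1", 200, "C", "T")
        kg = VariantKey("1", 200, "C", "G")
        # GT 1/2 is het for both split columns; 2/2 is hom only for ALT2
        assert m.zygosity("a", kt) is Zygosity.HET
        assert m.zygosity("a", kg) is Zygosity.HET
        assert m.zygosity("b", kt) is Zygosity.HOM_REF
        assert m.zygosity("b", kg) is Zygosity.HOM_ALT

    def test_multiallelic_split_conserves_alt_dosage(self, tmp_path):
        body = "1\t200\t.\tC\tT,G\t.\t.\t.\tGT\t1/2\t2/2\t0/1\n"
        path = write_vcf(tmp_path, body, ["a", "b", "c"])
        m = read_multisample_vcf(path, {"a": "F", "b": "F", "c": "F"})
        # per-sample ALT dosage across split columns == dosage in original GT
        expected = {"a": 2, "b": 2, "c": 1}
        for sid, want in expected.items():
            got = sum(m.zygosity(sid, k).alt_dosage for k in m.variants)
            assert got == want

    def test_male_x_haploid_is_hemizygous(self, tmp_path):
        body = "X\t103495552\t.\tC\tT\t.\t.\t.\tGT\t1\t0\t0/1\n"
        path = write_vcf(tmp_path, body, ["113", "114", "fem"])
        m = read_multisample_vcf(path, {"113": "M", "114": "M", "fem": "F"})
        k = VariantKey("X", 103495552, "C", "T")
        assert m.zygosity("113", k) is Zygosity.HEMI_ALT
        assert m.zygosity("114", k) is Zygosity.HEMI_REF
        assert m.zygosity("fem", k) is Zygosity.HET

    def test_male_x_homozygous_coded_is_hemizygous(self, tmp_path):
        body = "X\t500\t.\tC\tT\t.\t.\t.\tGT\t1/1\t1/1\n"
        path = write_vcf(tmp_path, body, ["m", "f"])
        m = read_multisample_vcf(path, {"m": "M", "f": "F"})
        k = VariantKey("X", 500, "C", "T")
        assert m.zygosity("m", k) is Zygosity.HEMI_ALT
        assert m.zygosity("f", k) is Zygosity.HOM_ALT

    def test_sample_missing_from_sexes_is_configuration_error(self, tmp_path):
        body = "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n"
        path = write_vcf(tmp_path, body, ["orphan"])
        with pytest.raises(ValueError, match="orphan"):
            read_multisample_vcf(path, {})


class TestVariantKey:
    @pytest.mark.parametrize(
        "chrom,pos,ref,alt,expected",
        [
            ("10", 102295637, "A", "AT", VariantClass.INDEL),
            ("1", 171076936, "G", "T", VariantClass.SNP),
            ("2", 100, "AT", "A", VariantClass.INDEL),
        ],
    )
    def test_classification(self, chrom, pos, ref, alt, expected):
        assert classify_variant(VariantKey(chrom, pos, ref, alt)) is expected

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="1", pos=0, ref="A", alt="G"),
            dict(chrom="1", pos=5, ref="A", alt="A"),
            dict(chrom="1", pos=5, ref="", alt="G"),
            dict(chrom="1", pos=5, ref="A", alt="Z"),
        ],
    )
    def test_invalid_keys_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariantKey(**kwargs)

    def test_chr_prefix_normalized(self):
        assert VariantKey("chr1", 5, "A", "G").chrom == "1"


class TestAnnotationTable:
    def test_round_trip_fields(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "chrom\tpos\tref\talt\tgene\trsid\tsift_score\tsift_call\t"
            "polyphen_score\tpolyphen_call\tmaf\n"
            "1\t171076966\tG\tA\tFMO3\trs2266782\t0.18\tTOLERATED\t.\t.\t0.383\n"
            "2\t10\tC\tCA\tGENE2\t.\t.\t.\t.\t.\t.\n"
        )
        store = read_annotation_table(p)
        ann = store[VariantKey("1", 171076966, "G", "A")]
        assert ann.gene == "FMO3" and ann.maf == 0.383 and ann.rsid == "rs2266782"
        assert ann.variant_class is VariantClass.SNP
        indel = store[VariantKey("2", 10, "C", "CA")]
        assert indel.variant_class is VariantClass.INDEL
        assert indel.maf is None

    def test_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "chrom\tpos\tref\talt\tgene\n1\t5\tA\tG\tX\n1\t5\tA\tG\tX\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_annotation_table(p)

    def test_maf_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("chrom\tpos\tref\talt\tgene\tmaf\n1\t5\tA\tG\tX\t0.9\n")
        with pytest.raises(ValueError, match="MAF"):
            read_annotation_table(p)

    def test_call_score_conflict_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            VariantAnnotation(
                key=VariantKey("1", 5, "A", "G"),
                gene="X",
                sift_call="DELETERIOUS",
                sift_score=0.8,
            )


class TestMatrixInvariants:
    def test_hemizygous_cell_requires_male_sex_chromosome(self):
        with pytest.raises(ValueError, match="hemizygous"):
            GenotypeMatrix(
                subjects=[SubjectInfo("f1", Sex.F)],
                variants=[VariantKey("1", 10, "A", "G")],
                cells=np.array([[Zygosity.HEMI_ALT]], dtype=np.int8),
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="cell block"):
            GenotypeMatrix(
                subjects=[SubjectInfo("a", Sex.F)],
                variants=[],
                cells=np.zeros((1, 2), dtype=np.int8),
            )


# -- round trip property ----------------------------------------------------

_AUTO_ZYG = st.sampled_from(
    [Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT, Zygosity.MISSING]
)
_MALE_X_ZYG = st.sampled_from(
    [Zygosity.HEMI_REF, Zygosity.HEMI_ALT, Zygosity.MISSING]
)


@st.composite
def normalized_matrices(draw):
    """Matrices in reader-normalized form (male X cells hemizygous)."""
    n_subj = draw(st.integers(1, 4))
    n_var = draw(st.integers(1, 6))
    sexes = draw(st.lists(st.sampled_from([Sex.F, Sex.M]), min_size=n_subj, max_size=n_subj))
    subjects = [SubjectInfo(f"s{i}", sexes[i]) for i in range(n_subj)]
    chroms = draw(
        st.lists(st.sampled_from(["1", "2", "X"]), min_size=n_var, max_size=n_var)
    )
    keys = []
    for j, chrom in enumerate(chroms):
        ref, alt = draw(st.sampled_from([("A", "G"), ("C", "T"), ("A", "AT"), ("CT", "C")]))
        keys.append(VariantKey(chrom, 100 + j, ref, alt))
    cells = np.empty((n_subj, n_var), dtype=np.int8)
    for i in range(n_subj):
        for j in range(n_var):
            hemi = keys[j].chrom == "X" and sexes[i] is Sex.M
            cells[i, j] = draw(_MALE_X_ZYG if hemi else _AUTO_ZYG)
    return GenotypeMatrix(subjects=subjects, variants=keys, cells=cells)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(matrix=normalized_matrices())
def test_vcf_round_trip_preserves_every_cell(matrix, tmp_path_factory):
    path = tmp_path_factory.mktemp("rt") / "m.vcf"
    matrix.to_vcf(path)
    back = read_multisample_vcf(path, {s.id: s.sex for s in matrix.subjects})
    assert [s.id for s in back.subjects] == [s.id for s in matrix.subjects]
    assert back.variants == matrix.variants
    assert np.array_equal(back.cells, matrix.cells)
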