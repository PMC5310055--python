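"""Genotype and annotation I/O for small exome cohorts.

Reads multi-sample VCF genotypes into a dense subjects x variants zygosity
matrix and per-variant annotation tables (gene, SIFT/PolyPhen-2 calls, MAF)
into an annotation store.  Coordinates are 1-based GRCh37/hg19-style; the
VCF ALT allele is treated as the minor allele throughout.

Multiallelic records are split into one column per ALT allele, because every
downstream filter operates per allele.  Male genotypes on X/Y are normalized
to hemizygous states: a one-allele GT or a homozygous-coded diploid GT
becomes ``HEMI_REF``/``HEMI_ALT`` (pseudo-autosomal regions are not
modelled; a het-coded male X call is kept as ``HET`` so the anomaly stays
visible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "Sex",
    "Zygosity",
    "VariantClass",
    "SiftCall",
    "PolyphenCall",
    "VariantKey",
    "SubjectInfo",
    "VariantAnnotation",
    "AnnotationStore",
    "GenotypeMatrix",
    "classify_variant",
    "normalize_chrom",
    "read_multisample_vcf",
    "read_annotation_table",
    "read_gene_set",
    "read_sex_table",
    "VcfParseError",
]

_VALID_BASES = frozenset("ACGTN")
SEX_CHROMOSOMES = frozenset({"X", "Y"})

#: conventional tool cut-offs used to cross-check call/score consistency
SIFT_DELETERIOUS_MAX = 0.05
POLYPHEN_DAMAGING_MIN = 0.446


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into a genotype matrix."""


class Sex(str, Enum):
    M = "M"
    F = "F"


class VariantClass(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"


class SiftCall(str, Enum):
    TOLERATED = "TOLERATED"
    DELETERIOUS = "DELETERIOUS"


class PolyphenCall(str, Enum):
    BENIGN = "BENIGN"
    DAMAGING = "DAMAGING"


class Zygosity(IntEnum):
    """Genotype state of one subject at one (split, biallelic) variant."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    HEMI_REF = 3
    HEMI_ALT = 4
    MISSING = 5

    @property
    def alt_dosage(self) -> int | None:
        """Copies of the ALT allele; ``None`` when the call is missing."""
        return _DOSAGE[self]

    @property
    def is_carrier(self) -> bool:
        """True when at least one ALT allele is present."""
        return self in (Zygosity.HET, Zygosity.HOM_ALT, Zygosity.HEMI_ALT)

    @property
    def is_hom_alt(self) -> bool:
        """True for fully-ALT genotypes; hemizygous ALT counts as homozygous
        because a one-allele genotype cannot be heterozygous."""
        return self in (Zygosity.HOM_ALT, Zygosity.HEMI_ALT)

    @property
    def mark(self) -> str:
        """Report mark for carrier states: 'het', 'hom' or 'hemi'."""
        if self is Zygosity.HET:
            return "het"
        if self is Zygosity.HOM_ALT:
            return "hom"
        if self is Zygosity.HEMI_ALT:
            return "hemi"
        raise ValueError(f"no report mark for non-carrier state {self.name}")


_DOSAGE: dict[Zygosity, int | None] = {
    Zygosity.HOM_REF: 0,
    Zygosity.HET: 1,
    Zygosity.HOM_ALT: 2,
    Zygosity.HEMI_REF: 0,
    Zygosity.HEMI_ALT: 1,
    Zygosity.MISSING: None,
}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix; '1', '10', 'X' style labels are kept."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if not c:
        raise ValueError("empty chromosome label")
    return c


@dataclass(frozen=True, order=True)
class VariantKey:
    """A single alternate allele at a 1-based genomic position."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name in ("ref", "alt"):
            allele = getattr(self, name)
            if not allele or set(allele.upper()) - _VALID_BASES:
                raise ValueError(f"invalid {name} allele {allele!r}")
            object.__setattr__(self, name, allele.upper())
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def variant_class(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNP
        return VariantClass.INDEL

    @property
    def is_autosomal(self) -> bool:
        return self.chrom not in SEX_CHROMOSOMES

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def classify_variant(key: VariantKey) -> VariantClass:
    """SNP iff both alleles are single bases, otherwise INDEL."""
    return key.variant_class


@dataclass(frozen=True)
class SubjectInfo:
    id: str
    sex: Sex
    age_years: int | None = None
    ancestry_label: str | None = None


@dataclass(frozen=True)
class VariantAnnotation:
    """Per-allele annotation consumed (never computed) by the pipeline."""

    key: VariantKey
    gene: str | None = None
    sift_call: SiftCall | None = None
    sift_score: float | None = None
    polyphen_call: PolyphenCall | None = None
    polyphen_score: float | None = None
    maf: float | None = None
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.sift_call is not None:
            object.__setattr__(self, "sift_call", SiftCall(self.sift_call))
        if self.polyphen_call is not None:
            object.__setattr__(self, "polyphen_call", PolyphenCall(self.polyphen_call))
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(
                f"MAF must lie in [0, 0.5], got {self.maf} for {self.key.label}"
            )
        for score, name in ((self.sift_score, "sift"), (self.polyphen_score, "polyphen")):
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValueError(f"{name} score outside [0,1]: {score}")
        # call/score pairs must agree with the conventional tool thresholds
        if self.sift_call is not None and self.sift_score is not None:
            expected = (
                SiftCall.DELETERIOUS
                if self.sift_score < SIFT_DELETERIOUS_MAX
                else SiftCall.TOLERATED
            )
            if expected is not self.sift_call:
                raise ValueError(
                    f"SIFT call {self.sift_call.value} inconsistent with score "
                    f"{self.sift_score} at {self.key.label}"
                )
        if self.polyphen_call is not None and self.polyphen_score is not None:
            expected_pp = (
                PolyphenCall.DAMAGING
                if self.polyphen_score >= POLYPHEN_DAMAGING_MIN
                else PolyphenCall.BENIGN
            )
            if expected_pp is not self.polyphen_call:
                raise ValueError(
                    f"PolyPhen call {self.polyphen_call.value} inconsistent with "
                    f"score {self.polyphen_score} at {self.key.label}"
                )

    @property
    def variant_class(self) -> VariantClass:
        return self.key.variant_class


class AnnotationStore:
    """Keyed collection of :class:`VariantAnnotation`, unique per variant."""

    def __init__(self, annotations: Iterable[VariantAnnotation] = ()) -> None:
        self._by_key: dict[VariantKey, VariantAnnotation] = {}
        for ann in annotations:
            self.add(ann)

    def add(self, ann: VariantAnnotation) -> None:
        if ann.key in self._by_key:
            raise ValueError(f"duplicate annotation for {ann.key.label}")
        self._by_key[ann.key] = ann

    def __getitem__(self, key: VariantKey) -> VariantAnnotation:
        return self._by_key[key]

    def get(self, key: VariantKey, default=None):
        return self._by_key.get(key, default)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._by_key

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key)

    def values(self):
        return self._by_key.values()

    def missing_keys(self, keys: Iterable[VariantKey]) -> list[VariantKey]:
        return [k for k in keys if k not in self._by_key]


@dataclass
class GenotypeMatrix:
    """Dense zygosity calls for an ordered cohort over ordered variants."""

    subjects: list[SubjectInfo]
    variants: list[VariantKey]
    cells: np.ndarray  # int8, shape (n_subjects, n_variants), Zygosity values
    _subject_index: dict[str, int] = field(init=False, repr=False)
    _variant_index: dict[VariantKey, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"cell block {self.cells.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        self._subject_index = {s.id: i for i, s in enumerate(self.subjects)}
        if len(self._subject_index) != len(self.subjects):
            raise ValueError("subject ids are not unique")
        self._variant_index = {v: j for j, v in enumerate(self.variants)}
        if len(self._variant_index) != len(self.variants):
            raise ValueError("variant keys are not unique")
        self._check_hemizygosity()

    def _check_hemizygosity(self) -> None:
        hemi = np.isin(self.cells, (Zygosity.HEMI_REF, Zygosity.HEMI_ALT))
        for i, j in zip(*np.nonzero(hemi)):
            subj, var = self.subjects[i], self.variants[j]
            if var.is_autosomal or subj.sex is not Sex.M:
                raise ValueError(
                    f"hemizygous call for {subj.id} ({subj.sex.value}) at "
                    f"{var.label}: only male X/Y cells may be hemizygous"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.cells == Zygosity.MISSING))

    def subject(self, subject_id: str) -> SubjectInfo:
        return self.subjects[self._subject_index[subject_id]]

    def zygosity(self, subject_id: str, key: VariantKey) -> Zygosity:
        return Zygosity(
            int(self.cells[self._subject_index[subject_id], self._variant_index[key]])
        )

    def column(self, key: VariantKey) -> np.ndarray:
        return self.cells[:, self._variant_index[key]]

    def carriers(self, key: VariantKey, hom_only: bool = False) -> list[str]:
        """Subject ids carrying the ALT allele at ``key`` (matrix order)."""
        col = self.column(key)
        out = []
        for i, s in enumerate(self.subjects):
            z = Zygosity(int(col[i]))
            if (z.is_hom_alt if hom_only else z.is_carrier):
                out.append(s.id)
        return out

    def reordered(
        self,
        subject_ids: Sequence[str] | None = None,
        variant_keys: Sequence[VariantKey] | None = None,
    ) -> "GenotypeMatrix":
        """Permuted copy; used to assert order invariance of the filters."""
        sids = list(subject_ids) if subject_ids is not None else [s.id for s in self.subjects]
        keys = list(variant_keys) if variant_keys is not None else list(self.variants)
        rows = [self._subject_index[s] for s in sids]
        cols = [self._variant_index[k] for k in keys]
        return GenotypeMatrix(
            subjects=[self.subjects[i] for i in rows],
            variants=keys,
            cells=self.cells[np.ix_(rows, cols)].copy(),
        )

    def to_vcf(
        self,
        path: str | Path,
        ids: Mapping[VariantKey, str] | None = None,
    ) -> None:
        """Write the matrix as an uncompressed multi-sample VCF.

        Each (possibly split) variant column becomes one biallelic record.
        Hemizygous cells are written as one-allele GTs, missing cells as
        './.'; ``ids`` optionally supplies rsIDs for the ID column.
        """
        header = pysam.VariantHeader()
        header.formats.add("GT", 1, "String", "Genotype")
        seen: list[str] = []
        for key in self.variants:
            if key.chrom not in seen:
                seen.append(key.chrom)
        for chrom in seen:
            header.contigs.add(chrom)
        for s in self.subjects:
            header.add_sample(s.id)
        gt_codes = {
            Zygosity.HOM_REF: (0, 0),
            Zygosity.HET: (0, 1),
            Zygosity.HOM_ALT: (1, 1),
            Zygosity.HEMI_REF: (0,),
            Zygosity.HEMI_ALT: (1,),
            Zygosity.MISSING: (None, None),
        }
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for j, key in enumerate(self.variants):
                rec = out.new_record(
                    contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
                )
                if ids and key in ids:
                    rec.id = ids[key]
                for i, s in enumerate(self.subjects):
                    rec.samples[s.id]["GT"] = gt_codes[Zygosity(int(self.cells[i, j]))]
                out.write(rec)


def _zygosity_from_alleles(
    alleles: tuple[int | None, ...] | None, alt_index: int, hemi_context: bool
) -> Zygosity:
    """Map a pysam GT tuple to a Zygosity for one split ALT column."""
    if alleles is None or len(alleles) == 0 or any(a is None for a in alleles):
        return Zygosity.MISSING
    dosage = sum(1 for a in alleles if a == alt_index)
    if len(alleles) == 1:
        if hemi_context:
            return Zygosity.HEMI_ALT if dosage else Zygosity.HEMI_REF
        # haploid-coded call outside a hemizygous context: degrade to a
        # homozygous call of the single observed allele
        return Zygosity.HOM_ALT if dosage else Zygosity.HOM_REF
    if dosage == len(alleles):
        return Zygosity.HEMI_ALT if hemi_context else Zygosity.HOM_ALT
    if dosage == 0:
        return Zygosity.HEMI_REF if hemi_context else Zygosity.HOM_REF
    return Zygosity.HET


def read_multisample_vcf(
    path: str | Path,
    subject_sexes: Mapping[str, Sex | str],
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    ``subject_sexes`` must cover every sample in the file; sex is needed to
    normalize male X/Y genotypes to hemizygous states.  Multiallelic records
    are split into one column per ALT allele; symbolic ALTs are skipped with
    a warning.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        missing = [s for s in samples if s not in subject_sexes]
        if missing:
            raise ValueError(
                f"samples in VCF missing from subject_sexes: {', '.join(missing)}"
            )
        subjects = [SubjectInfo(id=s, sex=Sex(subject_sexes[s])) for s in samples]
        variants: list[VariantKey] = []
        columns: list[np.ndarray] = []
        try:
            records = list(vf)
        except (OSError, ValueError) as exc:
            raise VcfParseError(f"malformed record in {path}: {exc}") from exc
        for rec in records:
            chrom = normalize_chrom(rec.chrom)
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                if alt is None or set(alt.upper()) - _VALID_BASES:
                    warnings.warn(
                        f"skipping symbolic ALT {alt!r} at {chrom}:{rec.pos}",
                        stacklevel=2,
                    )
                    continue
                try:
                    key = VariantKey(chrom, rec.pos, rec.ref, alt)
                except ValueError as exc:
                    raise VcfParseError(
                        f"invalid record at {chrom}:{rec.pos}: {exc}"
                    ) from exc
                if key in variants:
                    raise VcfParseError(f"duplicate variant record {key.label}")
                col = np.empty(len(subjects), dtype=np.int8)
                for i, subj in enumerate(subjects):
                    hemi_context = (
                        key.chrom in SEX_CHROMOSOMES and subj.sex is Sex.M
                    )
                    gt = rec.samples[subj.id].get("GT")
                    col[i] = _zygosity_from_alleles(gt, alt_index, hemi_context)
                variants.append(key)
                columns.append(col)
    cells = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(subjects), 0), dtype=np.int8)
    )
    return GenotypeMatrix(subjects=subjects, variants=variants, cells=cells)


_REQUIRED_ANNOTATION_COLUMNS = ("chrom", "pos", "ref", "alt", "gene")


def _parse_enum(value, enum_cls, aliases: Mapping[str, str] = {}):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip().upper()
    text = aliases.get(text, text)
    try:
        return enum_cls(text)
    except ValueError:
        raise ValueError(f"unrecognized {enum_cls.__name__} value {value!r}") from None


_POLYPHEN_ALIASES = {"POSSIBLY_DAMAGING": "DAMAGING", "PROBABLY_DAMAGING": "DAMAGING"}


def read_annotation_table(path: str | Path) -> AnnotationStore:
    """Read a tab-delimited annotation table ('.' marks missing fields).

    Expected columns: chrom, pos, ref, alt, gene, and optionally rsid,
    sift_score, sift_call, polyphen_score, polyphen_call, maf.  Unknown
    columns are ignored; duplicate variant rows and out-of-range MAFs are
    errors.
    """
    df = pd.read_csv(
        str(path), sep="\t", dtype={"chrom": str}, na_values=["."], keep_default_na=True
    )
    missing_cols = [c for c in _REQUIRED_ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"annotation table missing columns: {missing_cols}")
    store = AnnotationStore()
    for row in df.itertuples(index=False):
        key = VariantKey(row.chrom, int(row.pos), str(row.ref), str(row.alt))

        def opt_float(name: str) -> float | None:
            v = getattr(row, name, None)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return float(v)

        gene = getattr(row, "gene", None)
        if isinstance(gene, float) and np.isnan(gene):
            gene = None
        rsid = getattr(row, "rsid", None)
        if rsid is not None and isinstance(rsid, float) and np.isnan(rsid):
            rsid = None
        store.add(
            VariantAnnotation(
                key=key,
                gene=str(gene) if gene is not None else None,
                sift_call=_parse_enum(getattr(row, "sift_call", None), SiftCall),
                sift_score=opt_float("sift_score"),
                polyphen_call=_parse_enum(
                    getattr(row, "polyphen_call", None), PolyphenCall, _POLYPHEN_ALIASES
                ),
                polyphen_score=opt_float("polyphen_score"),
                maf=opt_float("maf"),
                rsid=str(rsid) if rsid is not None else None,
            )
        )
    return store


def read_gene_set(path: str | Path) -> frozenset[str]:
    """Plain-text gene list, one symbol per line; '#' starts a comment."""
    symbols: set[str] = set()
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            symbols.add(token.upper())
    return frozenset(symbols)


def read_sex_table(path: str | Path) -> dict[str, Sex]:
    """TSV with columns subject_id, sex (optionally age_years, ancestry)."""
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    if "subject_id" not in df.columns or "sex" not in df.columns:
        raise ValueError("sex table needs columns subject_id and sex")
    out: dict[str, Sex] = {}
    for row in df.itertuples(index=False):
        sid = str(row.subject_id)
        if sid in out:
            raise ValueError(f"duplicate subject id {sid}")
        out[sid] = Sex(str(row.sex).strip().upper())
    return out
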