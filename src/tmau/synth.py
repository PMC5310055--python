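"""Synthetic cohorts with known truth, and the published-table fixture.

Two generators back the test surface of the whole pipeline:

``generate_cohort``
    builds a cohort from a :class:`CohortSpec`: background variants with
    MAF ~ U(0, 0.5), per-subject genotypes drawn binomially from the MAF,
    an exact number of missing cells, and *planted* variants written
    verbatim from :class:`PlantSpec` records.  Plants satisfy every
    criterion of their target branch; decoys are leave-one-out — they
    satisfy all criteria except exactly one — so any filter-ordering bug
    flips a truth label.

``study_fixture``
    transcribes the study's printed tables into pipeline inputs: the
    ten-subject demographics and TMAO:TMA ratios, the known FMO3/PYROXD2
    variants with their zygosity marks, the novel oxidoreductase /
    interactome / shared variants, a minimal scored interaction network
    around the three seed genes, and matching orthogonal genotyping calls.
    Urine concentrations are not published; they are back-solved from each
    printed ratio (TMA = 100*(1-r), TMAO = 100*r), which is exact because
    the ratio is scale-invariant.  All genotype-level content is a
    synthetic reconstruction from the printed per-subject marks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalog_network import (
    CatalogEntry,
    ExtraGenotype,
    InteractionNetwork,
    KnownVariantCatalog,
)
from .concordance import OrthogonalCall
from .variants import (
    AnnotationStore,
    GenotypeMatrix,
    PolyphenCall,
    Sex,
    SiftCall,
    SubjectInfo,
    VariantAnnotation,
    VariantClass,
    VariantKey,
    Zygosity,
)

__all__ = [
    "PlantBranch",
    "PlantSpec",
    "CohortSpec",
    "CohortBundle",
    "StudyFixture",
    "standard_plants",
    "generate_cohort",
    "generate_orthogonal_calls",
    "study_fixture",
    "write_cohort",
    "write_fixture",
    "write_orthogonal_calls",
    "GT_STRING",
]

GT_STRING = {
    Zygosity.HOM_REF: "0/0",
    Zygosity.HET: "0/1",
    Zygosity.HOM_ALT: "1/1",
    Zygosity.HEMI_REF: "0",
    Zygosity.HEMI_ALT: "1",
    Zygosity.MISSING: "./.",
}


class PlantBranch(str, Enum):
    OXIDOREDUCTASE = "OXIDOREDUCTASE"
    SHARED = "SHARED"
    INTERACTOME = "INTERACTOME"
    CATALOG = "CATALOG"
    NONE = "NONE"


@dataclass(frozen=True)
class PlantSpec:
    """One variant planted with known truth.

    ``fail_criterion`` None makes this a plant (satisfies every criterion
    of ``target_branch``); a named criterion makes it a decoy violating
    exactly that one.  ``carriers`` maps subject ids to zygosities.
    """

    target_branch: PlantBranch
    gene: str
    carriers: Mapping[str, Zygosity]
    maf: float | None = 0.01
    deleterious: bool = True
    variant_class: VariantClass = VariantClass.SNP
    fail_criterion: str | None = None
    in_oxidoreductase_set: bool | None = None
    interactome_seed: str | None = None

    @property
    def role(self) -> str:
        return "decoy" if self.fail_criterion else "plant"


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    The default missingness (0.19) sits inside the 15-23% per-subject
    missing-genotype band observed for SNP sites in the study cohort.
    """

    n_subjects: int = 10
    n_background_variants: int = 200
    missing_rate: float = 0.19
    planted: tuple[PlantSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0,1]")
        object.__setattr__(self, "planted", tuple(self.planted))


@dataclass
class CohortBundle:
    """In-memory synthetic cohort plus its truth labels."""

    spec: CohortSpec
    matrix: GenotypeMatrix
    annotations: AnnotationStore
    oxidoreductase_genes: frozenset[str]
    known_tma_genes: frozenset[str]
    network: InteractionNetwork
    interactome_seeds: tuple[str, ...]
    catalog: KnownVariantCatalog
    truth: list[dict]
    n_missing_injected: int
    plant_keys: dict[VariantKey, PlantSpec]

    def expected_terminal(self, branch: PlantBranch) -> frozenset[VariantKey]:
        """Keys planted (not decoyed) for a branch — the ground truth."""
        return frozenset(
            k
            for k, spec in self.plant_keys.items()
            if spec.target_branch is branch and spec.role == "plant"
        )


def standard_plants(
    branch: PlantBranch,
    subject_ids: Sequence[str],
    n_plants: int = 3,
    n_decoys: int = 5,
) -> list[PlantSpec]:
    """Leave-one-out plant/decoy battery for one branch.

    Plants satisfy the branch's full criteria; each decoy violates exactly
    one criterion, cycling through the branch's criterion list.
    """
    if len(subject_ids) < 3:
        raise ValueError("need at least 3 subjects for plant templates")
    tag = {"OXIDOREDUCTASE": "OX", "SHARED": "SH", "INTERACTOME": "IN"}[branch.value]
    specs: list[PlantSpec] = []

    def subj(i: int) -> str:
        return subject_ids[i % len(subject_ids)]

    if branch is PlantBranch.OXIDOREDUCTASE:
        for i in range(n_plants):
            specs.append(
                PlantSpec(branch, f"{tag}P{i}", {subj(i): Zygosity.HOM_ALT})
            )
        criteria = ["presence_hom", "pathogenicity", "gene_set", "rarity"]
        for i in range(n_decoys):
            crit = criteria[i % len(criteria)]
            gene = f"{tag}D{i}" if crit != "gene_set" else f"{tag}DG{i}"
            specs.append(
                PlantSpec(
                    branch,
                    gene,
                    {subj(i): Zygosity.HET if crit == "presence_hom" else Zygosity.HOM_ALT},
                    maf=0.30 if crit == "rarity" else 0.01,
                    deleterious=crit != "pathogenicity",
                    fail_criterion=crit,
                    in_oxidoreductase_set=crit != "gene_set",
                )
            )
    elif branch is PlantBranch.SHARED:
        for i in range(n_plants):
            specs.append(
                PlantSpec(
                    branch,
                    f"{tag}P{i}",
                    {subj(i): Zygosity.HOM_ALT, subj(i + 1): Zygosity.HOM_ALT},
                )
            )
        criteria = [
            "pathogenicity",
            "known_gene_exclusion",
            "sharing",
            "hom_sharing",
            "rarity",
        ]
        for i in range(n_decoys):
            crit = criteria[i % len(criteria)]
            gene = "FMO3" if crit == "known_gene_exclusion" else f"{tag}D{i}"
            if crit == "sharing":
                carriers = {subj(i): Zygosity.HOM_ALT}
            elif crit == "hom_sharing":
                carriers = {subj(i): Zygosity.HOM_ALT, subj(i + 1): Zygosity.HET}
            else:
                carriers = {subj(i): Zygosity.HOM_ALT, subj(i + 1): Zygosity.HOM_ALT}
            specs.append(
                PlantSpec(
                    branch,
                    gene,
                    carriers,
                    maf=0.25 if crit == "rarity" else 0.01,
                    deleterious=crit != "pathogenicity",
                    fail_criterion=crit,
                )
            )
    elif branch is PlantBranch.INTERACTOME:
        for i in range(n_plants):
            specs.append(
                PlantSpec(
                    branch,
                    f"{tag}P{i}",
                    {subj(i): Zygosity.HET},
                    interactome_seed="SEED1",
                )
            )
        criteria = ["pathogenicity", "interactome_membership", "rarity"]
        for i in range(n_decoys):
            crit = criteria[i % len(criteria)]
            specs.append(
                PlantSpec(
                    branch,
                    f"{tag}D{i}",
                    {subj(i): Zygosity.HET},
                    maf=0.20 if crit == "rarity" else 0.01,
                    deleterious=crit != "pathogenicity",
                    fail_criterion=crit,
                    interactome_seed="SEED1",
                )
            )
    else:
        raise ValueError(f"no standard plant battery for branch {branch.value}")
    return specs


def _plant_annotation(
    key: VariantKey, spec: PlantSpec, rsid: str | None
) -> VariantAnnotation:
    if spec.deleterious:
        return VariantAnnotation(
            key=key,
            gene=spec.gene,
            sift_call=SiftCall.DELETERIOUS,
            sift_score=0.01,
            maf=spec.maf,
            rsid=rsid,
        )
    return VariantAnnotation(
        key=key,
        gene=spec.gene,
        sift_call=SiftCall.TOLERATED,
        sift_score=0.60,
        polyphen_call=PolyphenCall.BENIGN,
        polyphen_score=0.10,
        maf=spec.maf,
        rsid=rsid,
    )


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Materialize a synthetic cohort; fully deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    subjects = [
        SubjectInfo(id=f"S{i:02d}", sex=Sex.M if i % 5 == 0 else Sex.F)
        for i in range(1, spec.n_subjects + 1)
    ]
    subject_ids = [s.id for s in subjects]
    for p in spec.planted:
        for sid in p.carriers:
            if sid not in subject_ids:
                raise ValueError(f"plant in gene {p.gene} references unknown subject {sid}")

    variants: list[VariantKey] = []
    columns: list[np.ndarray] = []
    annotations = AnnotationStore()
    truth: list[dict] = []
    plant_keys: dict[VariantKey, PlantSpec] = {}
    oxido_genes: set[str] = {"OXFILL1", "OXFILL2"}
    network = InteractionNetwork()
    seeds: list[str] = []
    catalog = KnownVariantCatalog()

    # planted variants occupy a reserved low-coordinate block, autosomes only
    for idx, plant in enumerate(spec.planted):
        chrom = str((idx % 22) + 1)
        pos = 100_000 + idx * 10
        ref, alt = ("C", "T") if plant.variant_class is VariantClass.SNP else ("C", "CT")
        key = VariantKey(chrom, pos, ref, alt)
        col = np.full(len(subjects), Zygosity.HOM_REF, dtype=np.int8)
        for sid, zyg in plant.carriers.items():
            col[subject_ids.index(sid)] = zyg
        rsid = f"rsP{idx:04d}"
        annotations.add(_plant_annotation(key, plant, rsid))
        variants.append(key)
        columns.append(col)
        plant_keys[key] = plant
        truth.append(
            {
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "gene": plant.gene,
                "target_branch": plant.target_branch.value,
                "fail_criterion": plant.fail_criterion or ".",
                "role": plant.role,
            }
        )
        if plant.target_branch is PlantBranch.OXIDOREDUCTASE:
            in_set = (
                plant.in_oxidoreductase_set
                if plant.in_oxidoreductase_set is not None
                else True
            )
            if in_set:
                oxido_genes.add(plant.gene.upper())
        if plant.target_branch is PlantBranch.INTERACTOME:
            seed = (plant.interactome_seed or "SEED1").upper()
            if seed not in seeds:
                seeds.append(seed)
            score = 0.2 if plant.fail_criterion == "interactome_membership" else 0.9
            network.add_edge(seed, plant.gene, score)
        if plant.target_branch is PlantBranch.CATALOG:
            catalog.add(CatalogEntry(rsid=rsid, key=key, gene=plant.gene, maf=plant.maf))

    # background variants: benign, genes outside every curated set
    for j in range(spec.n_background_variants):
        chrom = str(int(rng.integers(1, 23)))
        pos = 1_000_000 + j * 50 + int(rng.integers(0, 50))
        key = VariantKey(chrom, pos, "A", "G")
        while key in plant_keys or key in annotations:
            pos += 1
            key = VariantKey(chrom, pos, "A", "G")
        maf = float(rng.uniform(0.0, 0.5))
        dosages = rng.binomial(2, maf, size=len(subjects))
        col = np.array(
            [
                (Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT)[d]
                for d in dosages
            ],
            dtype=np.int8,
        )
        annotations.add(
            VariantAnnotation(
                key=key,
                gene=f"BG{j:05d}",
                sift_call=SiftCall.TOLERATED,
                sift_score=float(rng.uniform(0.05, 1.0)),
                polyphen_call=PolyphenCall.BENIGN,
                polyphen_score=float(rng.uniform(0.0, 0.44)),
                maf=maf,
            )
        )
        variants.append(key)
        columns.append(col)
        truth.append(
            {
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "gene": f"BG{j:05d}",
                "target_branch": PlantBranch.NONE.value,
                "fail_criterion": ".",
                "role": "background",
            }
        )

    cells = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(subjects), 0), dtype=np.int8)
    )

    # exact missingness, injected into background cells only so that plant
    # genotypes stay intact for truth recovery
    n_bg = spec.n_background_variants
    n_missing = int(round(spec.missing_rate * len(subjects) * n_bg))
    if n_missing and n_bg:
        offset = len(spec.planted)
        flat = rng.choice(len(subjects) * n_bg, size=n_missing, replace=False)
        rows, cols_idx = np.unravel_index(flat, (len(subjects), n_bg))
        cells[rows, cols_idx + offset] = Zygosity.MISSING

    matrix = GenotypeMatrix(subjects=subjects, variants=variants, cells=cells)
    return CohortBundle(
        spec=spec,
        matrix=matrix,
        annotations=annotations,
        oxidoreductase_genes=frozenset(oxido_genes),
        known_tma_genes=frozenset({"FMO3", "PYROXD2", "DMGDH"}),
        network=network,
        interactome_seeds=tuple(seeds),
        catalog=catalog,
        truth=truth,
        n_missing_injected=n_missing,
        plant_keys=plant_keys,
    )


def generate_orthogonal_calls(
    matrix: GenotypeMatrix,
    n_calls: int,
    n_mismatches: int,
    seed: int,
    platform: str = "synthetic",
) -> list[OrthogonalCall]:
    """Sample non-missing cells without replacement; flip exactly
    ``n_mismatches`` of them to a different valid zygosity."""
    if n_mismatches > n_calls:
        raise ValueError("n_mismatches cannot exceed n_calls")
    rng = np.random.default_rng(seed)
    non_missing = np.argwhere(matrix.cells != Zygosity.MISSING)
    if n_calls > len(non_missing):
        raise ValueError(
            f"requested {n_calls} calls but only {len(non_missing)} "
            "non-missing cells are available"
        )
    chosen = non_missing[rng.choice(len(non_missing), size=n_calls, replace=False)]
    flip = {
        Zygosity.HOM_REF: Zygosity.HET,
        Zygosity.HET: Zygosity.HOM_ALT,
        Zygosity.HOM_ALT: Zygosity.HET,
        Zygosity.HEMI_REF: Zygosity.HEMI_ALT,
        Zygosity.HEMI_ALT: Zygosity.HEMI_REF,
    }
    calls: list[OrthogonalCall] = []
    for n, (i, j) in enumerate(chosen):
        z = Zygosity(int(matrix.cells[i, j]))
        if n < n_mismatches:
            z = flip[z]
        calls.append(
            OrthogonalCall(
                subject_id=matrix.subjects[i].id,
                key=matrix.variants[j],
                platform=platform,
                zygosity=z,
            )
        )
    return calls


# --------------------------------------------------------------------------
# Published-table fixture
# --------------------------------------------------------------------------

#: subject id, age, sex, ancestry label, TMAO fraction after choline load
FIXTURE_SUBJECTS: tuple[tuple[str, int, str, str, float], ...] = (
    ("52", 78, "F", "C", 0.13),
    ("114", 18, "M", "AA", 0.37),
    ("122", 64, "F", "AA", 0.47),
    ("35", 45, "F", "C", 0.54),
    ("99", 59, "F", "AA", 0.58),
    ("64", 51, "F", "C", 0.61),
    ("62", 51, "F", "AA", 0.79),
    ("113", 47, "M", "C", 0.79),
    ("98", 44, "F", "C", 0.86),
    ("56", 70, "F", "C", 0.87),
)

#: category tags for fixture variants
_KNOWN, _OXIDO, _INTERACTOME, _SHARED, _DECOY = (
    "known",
    "oxidoreductase",
    "interactome",
    "shared",
    "decoy",
)

#: (rsid, chrom, pos, ref, alt, gene, maf, sift, polyphen, carriers, category)
#: sift/polyphen are (score, call) or None; carriers map id -> 'het'|'hom'
_FIXTURE_VARIANTS: tuple[tuple, ...] = (
    # known FMO3 variants; the stop-gain rs72549325 carries no predictor
    # scores (SIFT/PolyPhen-2 score missense changes only)
    ("rs72549325", "1", 171076936, "G", "T", "FMO3", 8.236e-06, None, None,
     {"99": "het"}, _KNOWN),
    ("rs2266782", "1", 171076966, "G", "A", "FMO3", 0.383,
     (0.18, "TOLERATED"), (0.05, "BENIGN"),
     {"64": "het", "98": "het", "113": "het", "114": "het", "122": "het"}, _KNOWN),
    ("rs1736557", "1", 171080080, "G", "A", "FMO3", 0.080,
     (0.25, "TOLERATED"), (0.10, "BENIGN"), {"122": "het"}, _KNOWN),
    ("rs2266780", "1", 171083242, "A", "G", "FMO3", 0.153,
     (0.31, "TOLERATED"), (0.08, "BENIGN"), {"98": "het"}, _KNOWN),
    # novel SNPs in oxidoreductase pathway genes (homozygous carriers)
    ("rs61733458", "3", 148916215, "C", "T", "CP", 0.0110,
     (0.01, "DELETERIOUS"), None, {"52": "hom"}, _OXIDO),
    ("rs34625494", "17", 41002169, "C", "T", "AOC2", 0.0032,
     None, (0.97, "DAMAGING"), {"62": "hom"}, _OXIDO),
    ("rs7294759", "18", 9887167, "C", "T", "TXNDC2", 0.0179,
     (0.02, "DELETERIOUS"), None, {"52": "hom"}, _OXIDO),
    ("rs116368403", "19", 41600254, "C", "T", "CYP2A13", 0.0046,
     None, (0.99, "DAMAGING"), {"122": "hom"}, _OXIDO),
    # 1 bp insertion in an oxidoreductase gene
    (None, "10", 102295637, "A", "AT", "HIF1AN", 0.0200,
     (None, "DELETERIOUS"), None, {"114": "hom"}, _OXIDO),
    # heterozygous SNPs in the DMGDH interactome
    ("rs58580238", "5", 78378644, "C", "T", "BHMT2", 0.000154,
     (0.001, "DELETERIOUS"), None, {"56": "het"}, _INTERACTOME),
    ("rs35664470", "9", 136584082, "C", "T", "SARDH", 0.00692,
     None, (0.88, "DAMAGING"), {"99": "het"}, _INTERACTOME),
    ("rs78909145", "17", 18243524, "C", "T", "SHMT1", 0.00701,
     (0.03, "DELETERIOUS"), None, {"98": "het"}, _INTERACTOME),
    # SNPs shared homozygously by two subjects
    ("rs73891273", "3", 196235191, "C", "T", "SMCO1", 0.0445,
     (0.01, "DELETERIOUS"), None, {"62": "hom", "99": "hom"}, _SHARED),
    ("rs77469804", "6", 110679450, "C", "T", "METTL24", 0.0262,
     None, (0.95, "DAMAGING"), {"114": "hom", "122": "hom"}, _SHARED),
    ("rs77749341", "7", 149462317, "C", "T", "ZNF467", 0.0142,
     (0.02, "DELETERIOUS"), None, {"99": "hom", "114": "hom"}, _SHARED),
    ("rs7091756", "10", 1094906, "C", "T", "IDI1", 0.0207,
     (0.01, "DELETERIOUS"), None, {"35": "hom", "56": "hom"}, _SHARED),
    ("rs7956250", "12", 93966693, "C", "T", "SOCS2", 0.0257,
     None, (0.91, "DAMAGING"), {"99": "hom", "122": "hom"}, _SHARED),
    ("rs55739813", "15", 41803754, "C", "T", "LTK", 0.0367,
     (0.03, "DELETERIOUS"), None, {"35": "hom", "52": "hom"}, _SHARED),
    ("rs138735905", "19", 17638121, "C", "T", "FAM129C", 0.0193,
     (0.01, "DELETERIOUS"), None, {"64": "hom", "98": "hom"}, _SHARED),
    ("rs114989947", "22", 17265194, "C", "T", "XKR3", 0.0344,
     None, (0.89, "DAMAGING"), {"99": "hom", "113": "hom"}, _SHARED),
    ("rs41305431", "X", 103495552, "C", "T", "ESX1", 0.0266,
     (0.02, "DELETERIOUS"), None, {"113": "hom", "114": "hom"}, _SHARED),
    # 1 bp insertion shared by two subjects
    (None, "1", 158533298, "A", "AT", "OR6P1", 0.0100,
     (None, "DELETERIOUS"), None, {"62": "hom", "122": "hom"}, _SHARED),
    # leave-one-out decoys, one criterion violated each
    (None, "3", 50000001, "C", "T", "OXD1", 0.3000,       # rarity (oxido)
     (0.01, "DELETERIOUS"), None, {"64": "hom"}, _DECOY),
    (None, "3", 50000002, "C", "T", "OXD2", 0.0100,       # pathogenicity
     (0.60, "TOLERATED"), (0.10, "BENIGN"), {"99": "hom"}, _DECOY),
    (None, "4", 50000003, "C", "T", "NOXD1", 0.0100,      # gene-set inclusion
     (0.01, "DELETERIOUS"), None, {"56": "hom"}, _DECOY),
    (None, "4", 50000004, "C", "T", "OXD3", 0.0100,       # cohort homozygote
     (0.01, "DELETERIOUS"), None, {"35": "het"}, _DECOY),
    (None, "5", 50000005, "C", "T", "SHD1", 0.2500,       # rarity (shared)
     (0.01, "DELETERIOUS"), None, {"35": "hom", "64": "hom"}, _DECOY),
    (None, "6", 50000006, "C", "T", "SHD2", 0.0100,       # hom-sharing
     (0.01, "DELETERIOUS"), None, {"98": "hom", "56": "het"}, _DECOY),
    (None, "5", 78407604, "C", "T", "BHMT", 0.2000,       # rarity (interactome)
     (0.01, "DELETERIOUS"), None, {"62": "het"}, _DECOY),
    (None, "17", 18243600, "C", "T", "SHMT1", 0.0050,     # pathogenicity (int.)
     (0.55, "TOLERATED"), (0.12, "BENIGN"), {"52": "het"}, _DECOY),
)

#: rs7072216 is intronic, typed by allele-specific assay rather than exome
#: capture; genotype per subject from the printed zygosity marks
_RS7072216 = ("rs7072216", "10", 100156853, "T", "C", "PYROXD2", 0.4012)
_RS7072216_GENOTYPES = {
    "52": "0/1", "56": "0/1", "35": "1/1", "64": "1/1", "113": "1/1",
    "62": "0/0", "98": "0/0", "99": "0/0", "114": "0/0", "122": "0/0",
}

FIXTURE_OXIDOREDUCTASE_GENES = frozenset(
    {"CP", "AOC2", "TXNDC2", "CYP2A13", "HIF1AN", "OXD1", "OXD2", "OXD3",
     "MAOA", "CYP1A2"}
)
FIXTURE_KNOWN_TMA_GENES = frozenset({"FMO3", "PYROXD2", "DMGDH"})

#: gene_a, gene_b, combined score (0-1); seeds FMO3/PYROXD2/DMGDH
FIXTURE_NETWORK_EDGES: tuple[tuple[str, str, float], ...] = (
    ("DMGDH", "BHMT", 0.95),
    ("DMGDH", "SARDH", 0.92),
    ("DMGDH", "BHMT2", 0.90),
    ("DMGDH", "SHMT1", 0.85),
    ("DMGDH", "OXD1", 0.30),
    ("FMO3", "FMO1", 0.93),
    ("FMO3", "FMO2", 0.91),
    ("FMO3", "CYP1A2", 0.60),
    ("PYROXD2", "NDOR1", 0.62),
    ("PYROXD2", "TXN", 0.45),
)

FIXTURE_SEED_GENES = ("FMO3", "PYROXD2", "DMGDH")


@dataclass
class StudyFixture:
    """Pipeline inputs reconstructed from the study's printed tables."""

    subjects: list[SubjectInfo]
    ratios: dict[str, float]
    urine_samples: list  # list[UrineSample]; import cycle avoided
    matrix: GenotypeMatrix
    annotations: AnnotationStore
    catalog: KnownVariantCatalog
    extra_genotypes: list[ExtraGenotype]
    network: InteractionNetwork
    oxidoreductase_genes: frozenset[str]
    known_tma_genes: frozenset[str]
    orthogonal_calls: list[OrthogonalCall]
    variant_ids: dict[VariantKey, str]
    seed_genes: tuple[str, ...] = FIXTURE_SEED_GENES

    @property
    def subject_sexes(self) -> dict[str, Sex]:
        return {s.id: s.sex for s in self.subjects}


def _chrom_rank(chrom: str) -> int:
    return int(chrom) if chrom.isdigit() else {"X": 23, "Y": 24}[chrom]


def study_fixture() -> StudyFixture:
    """Build the published-table fixture bundle in memory."""
    from .metabolic import UrineSample  # local import: metabolic is independent

    subjects = [
        SubjectInfo(id=sid, sex=Sex(sex), age_years=age, ancestry_label=anc)
        for sid, age, sex, anc, _ in FIXTURE_SUBJECTS
    ]
    ratios = {sid: ratio for sid, _, _, _, ratio in FIXTURE_SUBJECTS}

    # urine back-solved from the printed two-decimal ratios; the peak-TMA
    # collection is interval 2, with TMAO measured there only
    urine: list[UrineSample] = []
    for sid, ratio in ratios.items():
        tmao = round(100 * ratio)
        tma_peak = 100 - tmao
        urine.append(UrineSample(sid, 0, tma_conc=5.0))
        urine.append(UrineSample(sid, 1, tma_conc=tma_peak * 0.5))
        urine.append(UrineSample(sid, 2, tma_conc=float(tma_peak), tmao_conc=float(tmao)))
        urine.append(UrineSample(sid, 3, tma_conc=tma_peak * 0.25))

    records = sorted(_FIXTURE_VARIANTS, key=lambda r: (_chrom_rank(r[1]), r[2]))
    subject_ids = [s.id for s in subjects]
    sex_by_id = {s.id: s.sex for s in subjects}
    variants: list[VariantKey] = []
    columns: list[np.ndarray] = []
    annotations = AnnotationStore()
    variant_ids: dict[VariantKey, str] = {}
    for rsid, chrom, pos, ref, alt, gene, maf, sift, poly, carriers, _cat in records:
        key = VariantKey(chrom, pos, ref, alt)
        col = np.empty(len(subjects), dtype=np.int8)
        for i, sid in enumerate(subject_ids):
            hemi = not key.is_autosomal and sex_by_id[sid] is Sex.M
            mark = carriers.get(sid)
            if mark is None:
                col[i] = Zygosity.HEMI_REF if hemi else Zygosity.HOM_REF
            elif mark == "het":
                col[i] = Zygosity.HET
            else:
                col[i] = Zygosity.HEMI_ALT if hemi else Zygosity.HOM_ALT
        variants.append(key)
        columns.append(col)
        if rsid:
            variant_ids[key] = rsid
        sift_score, sift_call = (sift if sift else (None, None))
        poly_score, poly_call = (poly if poly else (None, None))
        annotations.add(
            VariantAnnotation(
                key=key,
                gene=gene,
                sift_call=SiftCall(sift_call) if sift_call else None,
                sift_score=sift_score,
                polyphen_call=PolyphenCall(poly_call) if poly_call else None,
                polyphen_score=poly_score,
                maf=maf,
                rsid=rsid,
            )
        )
    matrix = GenotypeMatrix(
        subjects=subjects, variants=variants, cells=np.stack(columns, axis=1)
    )

    catalog = KnownVariantCatalog()
    for rsid, chrom, pos, ref, alt, gene, maf, *_rest in _FIXTURE_VARIANTS:
        if _rest[-1] == _KNOWN:
            catalog.add(
                CatalogEntry(rsid=rsid, key=VariantKey(chrom, pos, ref, alt),
                             gene=gene, maf=maf)
            )
    rsid, chrom, pos, ref, alt, gene, maf = _RS7072216
    rs7072216_key = VariantKey(chrom, pos, ref, alt)
    catalog.add(CatalogEntry(rsid=rsid, key=rs7072216_key, gene=gene, maf=maf))

    from .catalog_network import parse_genotype_string

    extra = [
        ExtraGenotype(
            subject_id=sid,
            rsid=rsid,
            key=rs7072216_key,
            zygosity=parse_genotype_string(gt),
        )
        for sid, gt in _RS7072216_GENOTYPES.items()
    ]

    network = InteractionNetwork(FIXTURE_NETWORK_EDGES)

    # orthogonal validation calls: 29 Sanger calls over the FMO3 exons and
    # 30 Taqman calls (two FMO3 assays plus the intronic PYROXD2 assay),
    # all agreeing with the exome/extra genotypes
    key_by_rsid = {v: k for k, v in variant_ids.items()}
    calls: list[OrthogonalCall] = []

    def add_calls(platform: str, rsid: str, sids: Iterable[str]) -> None:
        for sid in sids:
            if rsid == "rs7072216":
                key = rs7072216_key
                zyg = parse_genotype_string(_RS7072216_GENOTYPES[sid])
            else:
                key = key_by_rsid[rsid]
                zyg = matrix.zygosity(sid, key)
            calls.append(OrthogonalCall(sid, key, platform, zyg, rsid=rsid))

    add_calls("sanger", "rs72549325", subject_ids)
    add_calls("sanger", "rs2266782", subject_ids)
    add_calls("sanger", "rs2266780", [s for s in subject_ids if s != "35"])
    add_calls("taqman", "rs2266782", subject_ids)
    add_calls("taqman", "rs1736557", subject_ids)
    add_calls("taqman", "rs7072216", subject_ids)

    return StudyFixture(
        subjects=subjects,
        ratios=ratios,
        urine_samples=urine,
        matrix=matrix,
        annotations=annotations,
        catalog=catalog,
        extra_genotypes=extra,
        network=network,
        oxidoreductase_genes=FIXTURE_OXIDOREDUCTASE_GENES,
        known_tma_genes=FIXTURE_KNOWN_TMA_GENES,
        orthogonal_calls=calls,
        variant_ids=variant_ids,
    )


# --------------------------------------------------------------------------
# File writers (all plain text; byte-deterministic for identical inputs)
# --------------------------------------------------------------------------


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def _write_annotations(annotations: AnnotationStore, path: Path) -> None:
    cols = (
        "chrom", "pos", "ref", "alt", "gene", "rsid",
        "sift_score", "sift_call", "polyphen_score", "polyphen_call", "maf",
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ann in annotations.values():
            k = ann.key
            fh.write(
                "\t".join(
                    (
                        k.chrom, str(k.pos), k.ref, k.alt,
                        _fmt(ann.gene), _fmt(ann.rsid),
                        _fmt(ann.sift_score),
                        _fmt(ann.sift_call.value if ann.sift_call else None),
                        _fmt(ann.polyphen_score),
                        _fmt(ann.polyphen_call.value if ann.polyphen_call else None),
                        _fmt(ann.maf),
                    )
                )
                + "\n"
            )


def _write_gene_set(genes: Iterable[str], path: Path) -> None:
    path.write_text("".join(f"{g}\n" for g in sorted(genes)))


def _write_network(network: InteractionNetwork, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tcombined_score\n")
        for a, b, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['score']:g}\n")


def _write_subjects(subjects: Sequence[SubjectInfo], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("subject_id\tsex\tage_years\tancestry\n")
        for s in subjects:
            fh.write(
                f"{s.id}\t{s.sex.value}\t{_fmt(s.age_years)}\t{_fmt(s.ancestry_label)}\n"
            )


def write_orthogonal_calls(calls: Sequence[OrthogonalCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("subject_id\trsid\tchrom\tpos\tref\talt\tplatform\tgenotype\n")
        for c in calls:
            fh.write(
                f"{c.subject_id}\t{_fmt(c.rsid)}\t{c.key.chrom}\t{c.key.pos}\t"
                f"{c.key.ref}\t{c.key.alt}\t{c.platform}\t{GT_STRING[c.zygosity]}\n"
            )


def _write_catalog(catalog: KnownVariantCatalog, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tref\talt\tgene\tmaf\thgvs_c\thgvs_p\tevidence\n")
        for e in catalog:
            fh.write(
                f"{e.rsid}\t{e.key.chrom}\t{e.key.pos}\t{e.key.ref}\t{e.key.alt}\t"
                f"{e.gene}\t{_fmt(e.maf)}\t{_fmt(e.hgvs_c)}\t{_fmt(e.hgvs_p)}\t"
                f"{_fmt(e.evidence)}\n"
            )


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort bundle as the standard input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "annotations": out / "annotations.tsv",
        "oxidoreductase_genes": out / "oxidoreductase_genes.txt",
        "known_tma_genes": out / "known_tma_genes.txt",
        "network": out / "network.tsv",
        "subjects": out / "subjects.tsv",
        "truth": out / "truth.tsv",
    }
    bundle.matrix.to_vcf(paths["vcf"])
    _write_annotations(bundle.annotations, paths["annotations"])
    _write_gene_set(bundle.oxidoreductase_genes, paths["oxidoreductase_genes"])
    _write_gene_set(bundle.known_tma_genes, paths["known_tma_genes"])
    _write_network(bundle.network, paths["network"])
    _write_subjects(bundle.matrix.subjects, paths["subjects"])
    with open(paths["truth"], "w") as fh:
        cols = ("chrom", "pos", "ref", "alt", "gene", "target_branch",
                "fail_criterion", "role")
        fh.write("\t".join(cols) + "\n")
        for row in bundle.truth:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    if len(bundle.catalog):
        paths["catalog"] = out / "catalog.tsv"
        _write_catalog(bundle.catalog, paths["catalog"])
    return paths


def write_fixture(fixture: StudyFixture, out_dir: str | Path) -> dict[str, Path]:
    """Write the study fixture as the standard input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "annotations": out / "annotations.tsv",
        "urine": out / "urine.tsv",
        "catalog": out / "catalog.tsv",
        "extra_genotypes": out / "extra_genotypes.tsv",
        "network": out / "network.tsv",
        "oxidoreductase_genes": out / "oxidoreductase_genes.txt",
        "known_tma_genes": out / "known_tma_genes.txt",
        "orthogonal_calls": out / "orthogonal_calls.tsv",
        "subjects": out / "subjects.tsv",
    }
    fixture.matrix.to_vcf(paths["vcf"], ids=fixture.variant_ids)
    _write_annotations(fixture.annotations, paths["annotations"])
    with open(paths["urine"], "w") as fh:
        fh.write("subject_id\tinterval_index\tvolume_ml\ttma_conc\ttmao_conc\n")
        for s in fixture.urine_samples:
            fh.write(
                f"{s.subject_id}\t{s.interval_index}\t{_fmt(s.volume_ml)}\t"
                f"{_fmt(s.tma_conc)}\t{_fmt(s.tmao_conc)}\n"
            )
    _write_catalog(fixture.catalog, paths["catalog"])
    with open(paths["extra_genotypes"], "w") as fh:
        fh.write("subject_id\trsid\tchrom\tpos\tref\talt\tgenotype\n")
        for eg in fixture.extra_genotypes:
            fh.write(
                f"{eg.subject_id}\t{eg.rsid}\t{eg.key.chrom}\t{eg.key.pos}\t"
                f"{eg.key.ref}\t{eg.key.alt}\t{GT_STRING[eg.zygosity]}\n"
            )
    _write_network(fixture.network, paths["network"])
    _write_gene_set(fixture.oxidoreductase_genes, paths["oxidoreductase_genes"])
    _write_gene_set(fixture.known_tma_genes, paths["known_tma_genes"])
    write_orthogonal_calls(fixture.orthogonal_calls, paths["orthogonal_calls"])
    _write_subjects(fixture.subjects, paths["subjects"])
    return paths
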