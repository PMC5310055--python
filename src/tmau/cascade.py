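"""Multi-branch rare-variant prioritization cascade.

The cascade reduces a cohort genotype matrix to small candidate sets along
two discovery branches, after a shared MAIN trunk:

MAIN trunk
    1. cohort presence — keep variants observed in the cohort, by default
       requiring at least one subject homozygous (or hemizygous) for the
       ALT allele;
    2. pathogenicity — keep variants called deleterious by SIFT or damaging
       by PolyPhen-2 (EITHER rule by default; categorical calls take
       precedence over numeric scores).

OXIDOREDUCTASE branch
    3. restrict to genes annotated with oxidoreductase activity (the
       FMO3-like pathway candidate set);
    4. rarity — keep MAF < 0.05 (1000 Genomes-style frequencies supplied
       via the annotation table; missing MAF is treated as rare by default,
       since novel variants absent from reference panels are the point).

SHARED branch
    5. exclude genes already known to affect TMA metabolism
       (FMO3, PYROXD2, DMGDH);
    6. keep variants carried by >= 2 subjects (any carrier zygosity);
    7. tighten to variants homozygous/hemizygous in >= 2 subjects;
    8. rarity, as above.

SNPs and indels are tallied separately at every step.  Survivor sets are
nested along each branch by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

from .variants import (
    AnnotationStore,
    GenotypeMatrix,
    PolyphenCall,
    SiftCall,
    VariantAnnotation,
    VariantClass,
    VariantKey,
    Zygosity,
)

__all__ = [
    "PathogenicityRule",
    "PresenceRule",
    "SharingZygosity",
    "MissingMafPolicy",
    "GeneSetMode",
    "Branch",
    "CascadeConfig",
    "CascadeStep",
    "CascadeReport",
    "is_deleterious",
    "cohort_presence_filter",
    "pathogenicity_filter",
    "gene_set_filter",
    "rarity_filter",
    "shared_variant_filter",
    "run_cascade",
]

KNOWN_TMA_GENES = frozenset({"FMO3", "PYROXD2", "DMGDH"})


class PathogenicityRule(str, Enum):
    EITHER = "EITHER"
    BOTH = "BOTH"


class PresenceRule(str, Enum):
    ANY_SUBJECT = "ANY_SUBJECT"
    ALL_SUBJECTS = "ALL_SUBJECTS"


class SharingZygosity(str, Enum):
    ANY_CARRIER = "ANY_CARRIER"
    HOM_ALT_ONLY = "HOM_ALT_ONLY"


class MissingMafPolicy(str, Enum):
    TREAT_AS_RARE = "TREAT_AS_RARE"
    EXCLUDE = "EXCLUDE"


class GeneSetMode(str, Enum):
    INCLUDE = "INCLUDE"
    EXCLUDE = "EXCLUDE"


class Branch(str, Enum):
    MAIN = "MAIN"
    OXIDOREDUCTASE = "OXIDOREDUCTASE"
    SHARED = "SHARED"


@dataclass(frozen=True)
class CascadeConfig:
    """Tunable thresholds and policies for the filter cascade.

    Defaults mirror the study conditions: MAF < 0.05 for rarity, the
    conventional SIFT (< 0.05) and PolyPhen-2 (>= 0.446) cut-offs, an
    EITHER-predictor pathogenicity rule, presence requiring at least one
    cohort homozygote, and sharing by two or more subjects.
    """

    maf_threshold: float = 0.05
    sift_deleterious_max: float = 0.05
    polyphen_damaging_min: float = 0.446
    pathogenicity_rule: PathogenicityRule = PathogenicityRule.EITHER
    presence_rule: PresenceRule = PresenceRule.ANY_SUBJECT
    require_cohort_homozygote: bool = True
    min_sharing_subjects: int = 2
    sharing_zygosity: SharingZygosity = SharingZygosity.ANY_CARRIER
    missing_maf_policy: MissingMafPolicy = MissingMafPolicy.TREAT_AS_RARE
    known_tma_genes: frozenset[str] = KNOWN_TMA_GENES

    def __post_init__(self) -> None:
        for name, enum_cls in (
            ("pathogenicity_rule", PathogenicityRule),
            ("presence_rule", PresenceRule),
            ("sharing_zygosity", SharingZygosity),
            ("missing_maf_policy", MissingMafPolicy),
        ):
            object.__setattr__(self, name, enum_cls(getattr(self, name)))
        for name in ("maf_threshold", "sift_deleterious_max", "polyphen_damaging_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if self.min_sharing_subjects < 2:
            raise ValueError("min_sharing_subjects must be >= 2")
        object.__setattr__(
            self, "known_tma_genes", frozenset(g.upper() for g in self.known_tma_genes)
        )


@dataclass(frozen=True)
class CascadeStep:
    label: str
    branch: Branch
    snp_keys: frozenset[VariantKey]
    indel_keys: frozenset[VariantKey]

    @property
    def keys(self) -> frozenset[VariantKey]:
        return self.snp_keys | self.indel_keys

    @property
    def snp_count(self) -> int:
        return len(self.snp_keys)

    @property
    def indel_count(self) -> int:
        return len(self.indel_keys)


@dataclass
class CascadeReport:
    """Ordered per-step survivor sets, plus the sharing map of the SHARED
    branch terminal set (variant -> homozygous sharing subjects)."""

    steps: list[CascadeStep] = field(default_factory=list)
    sharing: dict[VariantKey, frozenset[str]] = field(default_factory=dict)

    def branch_steps(self, branch: Branch) -> list[CascadeStep]:
        return [s for s in self.steps if s.branch is branch]

    def terminal(self, branch: Branch) -> CascadeStep:
        steps = self.branch_steps(branch)
        if not steps:
            raise KeyError(f"no steps recorded for branch {branch.value}")
        return steps[-1]

    def as_rows(self) -> list[dict]:
        return [
            {
                "branch": s.branch.value,
                "step": s.label,
                "snp_count": s.snp_count,
                "indel_count": s.indel_count,
            }
            for s in self.steps
        ]


def _sift_vote(ann: VariantAnnotation, config: CascadeConfig) -> bool | None:
    if ann.sift_call is not None:
        return ann.sift_call is SiftCall.DELETERIOUS
    if ann.sift_score is not None:
        return ann.sift_score < config.sift_deleterious_max
    return None


def _polyphen_vote(ann: VariantAnnotation, config: CascadeConfig) -> bool | None:
    if ann.polyphen_call is not None:
        return ann.polyphen_call is PolyphenCall.DAMAGING
    if ann.polyphen_score is not None:
        return ann.polyphen_score >= config.polyphen_damaging_min
    return None


def is_deleterious(ann: VariantAnnotation, config: CascadeConfig) -> bool:
    """Predicted-pathogenicity verdict under the configured predictor rule.

    A predictor with neither call nor score abstains; a variant with no
    usable prediction is not deleterious (it cannot be proven pathogenic).
    """
    votes = (_sift_vote(ann, config), _polyphen_vote(ann, config))
    if config.pathogenicity_rule is PathogenicityRule.EITHER:
        return any(v is True for v in votes)
    return all(v is True for v in votes)


def cohort_presence_filter(
    matrix: GenotypeMatrix, config: CascadeConfig
) -> set[VariantKey]:
    """Variants present in the cohort under the configured presence rule."""
    out: set[VariantKey] = set()
    for key in matrix.variants:
        col = [Zygosity(int(z)) for z in matrix.column(key)]
        if config.require_cohort_homozygote:
            present = any(z.is_hom_alt for z in col)
        else:
            present = any(z.is_carrier for z in col)
        if present and config.presence_rule is PresenceRule.ALL_SUBJECTS:
            present = all(z.is_carrier for z in col)
        if present:
            out.add(key)
    return out


def pathogenicity_filter(
    keys: Iterable[VariantKey], annotations: AnnotationStore, config: CascadeConfig
) -> set[VariantKey]:
    keys = set(keys)
    if missing := annotations.missing_keys(keys):
        raise KeyError(
            "no annotation for variants: "
            + ", ".join(sorted(k.label for k in missing))
        )
    return {k for k in keys if is_deleterious(annotations[k], config)}


def gene_set_filter(
    keys: Iterable[VariantKey],
    annotations: AnnotationStore,
    gene_set: frozenset[str] | set[str],
    mode: GeneSetMode,
) -> set[VariantKey]:
    """Keep keys whose gene is inside (INCLUDE) or outside (EXCLUDE) the set.

    Matching is case-insensitive.  A key without a gene symbol cannot prove
    membership: it is dropped under INCLUDE and kept under EXCLUDE.
    """
    genes = frozenset(g.upper() for g in gene_set)
    if mode is GeneSetMode.INCLUDE and not genes:
        warnings.warn("INCLUDE filter with an empty gene set keeps nothing", stacklevel=2)
        return set()
    out: set[VariantKey] = set()
    for key in keys:
        ann = annotations.get(key)
        gene = ann.gene.upper() if ann is not None and ann.gene else None
        member = gene in genes if gene is not None else False
        if (mode is GeneSetMode.INCLUDE) == member:
            out.add(key)
    return out


def rarity_filter(
    keys: Iterable[VariantKey], annotations: AnnotationStore, config: CascadeConfig
) -> set[VariantKey]:
    """Keep keys with MAF below the threshold; missing MAF per policy."""
    out: set[VariantKey] = set()
    for key in keys:
        ann = annotations.get(key)
        maf = ann.maf if ann is not None else None
        if maf is None:
            if config.missing_maf_policy is MissingMafPolicy.TREAT_AS_RARE:
                out.add(key)
        elif maf < config.maf_threshold:
            out.add(key)
    return out


def shared_variant_filter(
    matrix: GenotypeMatrix,
    keys: Iterable[VariantKey],
    config: CascadeConfig,
    zygosity_rule: SharingZygosity | None = None,
) -> dict[VariantKey, frozenset[str]]:
    """Variants carried by >= ``min_sharing_subjects`` subjects.

    Returns the sharing subjects per surviving key.  ``zygosity_rule``
    overrides the config's sharing rule, letting the cascade run the
    any-carrier and homozygous-only passes back to back.
    """
    rule = zygosity_rule or config.sharing_zygosity
    hom_only = rule is SharingZygosity.HOM_ALT_ONLY
    out: dict[VariantKey, frozenset[str]] = {}
    for key in keys:
        sharers = frozenset(matrix.carriers(key, hom_only=hom_only))
        if len(sharers) >= config.min_sharing_subjects:
            out[key] = sharers
    return out


def _split(keys: Iterable[VariantKey]) -> tuple[frozenset[VariantKey], frozenset[VariantKey]]:
    keys = set(keys)
    snps = frozenset(k for k in keys if k.variant_class is VariantClass.SNP)
    return snps, frozenset(keys - snps)


def run_cascade(
    matrix: GenotypeMatrix,
    annotations: AnnotationStore,
    oxidoreductase_set: frozenset[str] | set[str],
    config: CascadeConfig | None = None,
) -> CascadeReport:
    """Run the MAIN trunk and both discovery branches; see module docstring."""
    config = config or CascadeConfig()
    report = CascadeReport()

    def record(label: str, branch: Branch, keys: Iterable[VariantKey]) -> None:
        snps, indels = _split(keys)
        report.steps.append(CascadeStep(label, branch, snps, indels))

    present = cohort_presence_filter(matrix, config)
    record("cohort_presence", Branch.MAIN, present)
    pathogenic = pathogenicity_filter(present, annotations, config)
    record("pathogenic", Branch.MAIN, pathogenic)

    # OXIDOREDUCTASE branch: FMO3-like pathway genes, then rarity
    in_pathway = gene_set_filter(
        pathogenic, annotations, oxidoreductase_set, GeneSetMode.INCLUDE
    )
    record("oxidoreductase_genes", Branch.OXIDOREDUCTASE, in_pathway)
    rare_pathway = rarity_filter(in_pathway, annotations, config)
    record("rare", Branch.OXIDOREDUCTASE, rare_pathway)

    # SHARED branch: novel genes, carried then homozygous in >= 2, then rarity
    novel = gene_set_filter(
        pathogenic, annotations, config.known_tma_genes, GeneSetMode.EXCLUDE
    )
    record("exclude_known_tma_genes", Branch.SHARED, novel)
    shared_any = shared_variant_filter(
        matrix, novel, config, SharingZygosity.ANY_CARRIER
    )
    record("shared_any_carrier", Branch.SHARED, shared_any)
    shared_hom = shared_variant_filter(
        matrix, shared_any, config, SharingZygosity.HOM_ALT_ONLY
    )
    record("shared_homozygous", Branch.SHARED, shared_hom)
    rare_shared = rarity_filter(shared_hom, annotations, config)
    record("rare", Branch.SHARED, rare_shared)
    report.sharing = {k: shared_hom[k] for k in rare_shared}
    return report
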