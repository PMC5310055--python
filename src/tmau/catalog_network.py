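"""Known-variant catalog lookup and interactome expansion.

Two complementary prioritization routes around the cascade: (1) direct
lookup of catalogued TMAU-associated variants (FMO3 loss-of-function and
common decreased-function alleles, the PYROXD2 urine-TMA allele) in the
cohort genotypes, with a side channel for variants genotyped off-exome
(e.g. an intronic Taqman assay); and (2) expansion of seed genes through a
pre-scored protein-protein interaction network (STRING-style combined
scores) followed by a rare-deleterious variant scan over the expanded gene
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cascade import CascadeConfig, is_deleterious, rarity_filter
from .variants import (
    AnnotationStore,
    GenotypeMatrix,
    Sex,
    VariantKey,
    Zygosity,
    normalize_chrom,
)

__all__ = [
    "CatalogEntry",
    "KnownVariantCatalog",
    "CatalogHit",
    "ExtraGenotype",
    "InteractionNetwork",
    "read_catalog",
    "read_extra_genotypes",
    "read_network",
    "parse_genotype_string",
    "lookup_known_variants",
    "tally_catalog_hits",
    "expand_seed_genes",
    "interactome_variant_scan",
]


@dataclass(frozen=True)
class CatalogEntry:
    rsid: str
    key: VariantKey
    gene: str
    maf: float | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    evidence: str | None = None


class KnownVariantCatalog:
    """Catalogued pathogenic/associated variants, unique by rsID and key."""

    def __init__(self, entries: Iterable[CatalogEntry] = ()) -> None:
        self.entries: list[CatalogEntry] = []
        self._by_rsid: dict[str, CatalogEntry] = {}
        self._by_key: dict[VariantKey, CatalogEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: CatalogEntry) -> None:
        if entry.rsid in self._by_rsid:
            raise ValueError(f"duplicate catalog rsID {entry.rsid}")
        if entry.key in self._by_key:
            raise ValueError(f"duplicate catalog variant {entry.key.label}")
        self.entries.append(entry)
        self._by_rsid[entry.rsid] = entry
        self._by_key[entry.key] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class CatalogHit:
    """One subject carrying one catalogued variant."""

    subject_id: str
    rsid: str
    gene: str
    zygosity: Zygosity

    def __post_init__(self) -> None:
        if not self.zygosity.is_carrier:
            raise ValueError("catalog hits must carry the ALT allele")


@dataclass(frozen=True)
class ExtraGenotype:
    """Genotype obtained outside the exome VCF (e.g. Taqman assay)."""

    subject_id: str
    rsid: str
    key: VariantKey
    zygosity: Zygosity


def parse_genotype_string(gt: str, hemi_context: bool = False) -> Zygosity:
    """Parse a coded genotype string: 0/0, 0/1, 1/1, 1, 0, . or ./."""
    text = gt.strip().replace("|", "/")
    if text in (".", "./.", ""):
        return Zygosity.MISSING
    alleles = text.split("/")
    if any(a not in ("0", "1") for a in alleles) or not 1 <= len(alleles) <= 2:
        raise ValueError(f"unrecognized genotype string {gt!r}")
    dosage = sum(a == "1" for a in alleles)
    if len(alleles) == 1:
        if hemi_context:
            return Zygosity.HEMI_ALT if dosage else Zygosity.HEMI_REF
        return Zygosity.HOM_ALT if dosage else Zygosity.HOM_REF
    if dosage == 2:
        return Zygosity.HEMI_ALT if hemi_context else Zygosity.HOM_ALT
    if dosage == 0:
        return Zygosity.HEMI_REF if hemi_context else Zygosity.HOM_REF
    return Zygosity.HET


def read_catalog(path: str | Path) -> KnownVariantCatalog:
    """TSV columns: rsid, chrom, pos, ref, alt, gene, maf, hgvs_c, hgvs_p, evidence."""
    df = pd.read_csv(str(path), sep="\t", dtype={"chrom": str}, na_values=["."])
    catalog = KnownVariantCatalog()
    for row in df.itertuples(index=False):
        maf = getattr(row, "maf", None)
        if maf is not None and isinstance(maf, float) and np.isnan(maf):
            maf = None

        def opt(name: str) -> str | None:
            v = getattr(row, name, None)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return str(v)

        catalog.add(
            CatalogEntry(
                rsid=str(row.rsid),
                key=VariantKey(row.chrom, int(row.pos), str(row.ref), str(row.alt)),
                gene=str(row.gene),
                maf=float(maf) if maf is not None else None,
                hgvs_c=opt("hgvs_c"),
                hgvs_p=opt("hgvs_p"),
                evidence=opt("evidence"),
            )
        )
    return catalog


def read_extra_genotypes(
    path: str | Path, subject_sexes: Mapping[str, Sex | str]
) -> list[ExtraGenotype]:
    """TSV columns: subject_id, rsid, chrom, pos, ref, alt, genotype."""
    df = pd.read_csv(str(path), sep="\t", dtype={"chrom": str, "subject_id": str})
    out: list[ExtraGenotype] = []
    for row in df.itertuples(index=False):
        key = VariantKey(row.chrom, int(row.pos), str(row.ref), str(row.alt))
        sid = str(row.subject_id)
        if sid not in subject_sexes:
            raise ValueError(f"extra genotype for unknown subject {sid}")
        hemi = not key.is_autosomal and Sex(subject_sexes[sid]) is Sex.M
        out.append(
            ExtraGenotype(
                subject_id=sid,
                rsid=str(row.rsid),
                key=key,
                zygosity=parse_genotype_string(str(row.genotype), hemi),
            )
        )
    return out


def lookup_known_variants(
    matrix: GenotypeMatrix,
    catalog: KnownVariantCatalog,
    extra_genotypes: Sequence[ExtraGenotype] | None = None,
) -> list[CatalogHit]:
    """One hit per subject carrying each catalogued variant.

    Variants absent from the matrix are resolved through ``extra_genotypes``
    (by rsID), the side channel for assays not captured by exome sequencing.
    A matrix variant at a catalog position with different alleles triggers a
    warning, not a hit.
    """
    extra_by_rsid: dict[str, list[ExtraGenotype]] = {}
    for eg in extra_genotypes or ():
        extra_by_rsid.setdefault(eg.rsid, []).append(eg)
    positions = {(v.chrom, v.pos): v for v in matrix.variants}
    hits: list[CatalogHit] = []
    for entry in catalog:
        if entry.key in matrix._variant_index:
            for subj in matrix.subjects:
                z = matrix.zygosity(subj.id, entry.key)
                if z.is_carrier:
                    hits.append(CatalogHit(subj.id, entry.rsid, entry.gene, z))
            continue
        colliding = positions.get((entry.key.chrom, entry.key.pos))
        if colliding is not None:
            warnings.warn(
                f"catalog variant {entry.rsid} collides with matrix variant "
                f"{colliding.label} (different alleles)",
                stacklevel=2,
            )
        for eg in extra_by_rsid.get(entry.rsid, ()):
            if eg.zygosity.is_carrier:
                hits.append(CatalogHit(eg.subject_id, entry.rsid, entry.gene, eg.zygosity))
    return hits


def tally_catalog_hits(hits: Iterable[CatalogHit]) -> dict[str, tuple[int, int]]:
    """Per-rsID (n_het, n_hom) counts; hemizygous ALT counts as homozygous."""
    tally: dict[str, tuple[int, int]] = {}
    for hit in hits:
        n_het, n_hom = tally.get(hit.rsid, (0, 0))
        if hit.zygosity is Zygosity.HET:
            n_het += 1
        elif hit.zygosity.is_hom_alt:
            n_hom += 1
        tally[hit.rsid] = (n_het, n_hom)
    return tally


class InteractionNetwork:
    """Undirected gene-gene network with combined scores in [0, 1]."""

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()) -> None:
        self.graph = nx.Graph()
        for a, b, score in edges:
            self.add_edge(a, b, score)

    def add_edge(self, gene_a: str, gene_b: str, score: float) -> None:
        a, b = gene_a.upper(), gene_b.upper()
        if a == b:
            raise ValueError(f"self-loop on {a}")
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score outside [0,1] for {a}--{b}: {score}")
        if self.graph.has_edge(a, b):
            raise ValueError(f"duplicate edge {a}--{b}")
        self.graph.add_edge(a, b, score=float(score))

    def neighbors_scored(self, gene: str) -> list[tuple[str, float]]:
        g = gene.upper()
        if g not in self.graph:
            return []
        return [(n, self.graph[g][n]["score"]) for n in self.graph.neighbors(g)]

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.graph


def read_network(path: str | Path) -> InteractionNetwork:
    """TSV columns: gene_a, gene_b, combined_score.

    Scores on the STRING 0-1000 integer scale are auto-detected (any value
    above 1) and divided by 1000.
    """
    df = pd.read_csv(str(path), sep="\t")
    required = {"gene_a", "gene_b", "combined_score"}
    if missing := required - set(df.columns):
        raise ValueError(f"network table missing columns: {sorted(missing)}")
    scores = df["combined_score"].astype(float)
    if (scores > 1.0).any():
        scores = scores / 1000.0
    net = InteractionNetwork()
    for (_, row), score in zip(df.iterrows(), scores):
        net.add_edge(str(row["gene_a"]), str(row["gene_b"]), float(score))
    return net


def expand_seed_genes(
    network: InteractionNetwork,
    seeds: Sequence[str],
    min_score: float = 0.4,
    max_interactors: int = 10,
) -> frozenset[str]:
    """Expand each seed to its top-scoring neighborhood and take the union.

    Per seed: neighbors with score >= ``min_score``, sorted by descending
    score then lexicographically by symbol, truncated to
    ``max_interactors``.  Seeds themselves are part of the result; a seed
    absent from the network contributes only itself (with a warning).
    """
    if not seeds:
        raise ValueError("no seed genes supplied")
    expanded: set[str] = set()
    for seed in seeds:
        seed_u = seed.upper()
        expanded.add(seed_u)
        if seed_u not in network:
            warnings.warn(f"seed gene {seed_u} absent from network", stacklevel=2)
            continue
        ranked = sorted(
            (ns for ns in network.neighbors_scored(seed_u) if ns[1] >= min_score),
            key=lambda ns: (-ns[1], ns[0]),
        )
        expanded.update(gene for gene, _ in ranked[:max_interactors])
    return frozenset(expanded)


def interactome_variant_scan(
    matrix: GenotypeMatrix,
    annotations: AnnotationStore,
    interactome: frozenset[str] | set[str],
    config: CascadeConfig | None = None,
) -> set[VariantKey]:
    """Rare deleterious variants inside an expanded gene set.

    Any carrier zygosity qualifies — the scan does not require cohort
    homozygotes, so heterozygous-only candidates survive here even though
    they fall out of the cascade trunk.
    """
    if not interactome:
        raise ValueError("empty interactome gene set")
    config = config or CascadeConfig()
    genes = frozenset(g.upper() for g in interactome)
    candidates = set()
    for key in matrix.variants:
        ann = annotations.get(key)
        if ann is None or not ann.gene or ann.gene.upper() not in genes:
            continue
        if not matrix.carriers(key):
            continue
        if is_deleterious(ann, config):
            candidates.add(key)
    return rarity_filter(candidates, annotations, config)
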