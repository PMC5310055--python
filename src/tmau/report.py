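"""Per-subject aggregation of all prioritization stages.

Builds one summary per subject listing the qualifying variants by category
— known-gene catalog hits (one category per catalogued gene), the
oxidoreductase-branch survivors, interactome-scan hits and the
rare-shared-branch survivors — each with a zygosity mark (het / hom /
hemi), ordered from the most severely impaired subject (lowest TMAO
fraction) upward.  Rendering is deterministic: stable ordering, ratios to
two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .cascade import Branch, CascadeReport
from .catalog_network import CatalogHit
from .metabolic import MetabolicProfile
from .variants import AnnotationStore, GenotypeMatrix, VariantKey, Zygosity

__all__ = [
    "CATEGORY_OXIDOREDUCTASE",
    "CATEGORY_INTERACTOME",
    "CATEGORY_RARE_SHARED",
    "SubjectSummary",
    "known_gene_category",
    "build_subject_summaries",
    "render_tables",
]

CATEGORY_OXIDOREDUCTASE = "OXIDOREDUCTASE"
CATEGORY_INTERACTOME = "INTERACTOME"
CATEGORY_RARE_SHARED = "RARE_SHARED"


def known_gene_category(gene: str) -> str:
    """Catalog hits are grouped per catalogued gene, e.g. ``FMO3_KNOWN``."""
    return f"{gene.upper()}_KNOWN"


@dataclass
class SubjectSummary:
    subject_id: str
    ratio: float
    categories: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.categories.values())


def _variant_label(key: VariantKey, annotations: AnnotationStore | None) -> str:
    if annotations is not None:
        ann = annotations.get(key)
        if ann is not None and ann.rsid:
            return ann.rsid
    return key.label


def build_subject_summaries(
    matrix: GenotypeMatrix,
    profiles: Sequence[MetabolicProfile],
    catalog_hits: Iterable[CatalogHit],
    cascade_report: CascadeReport,
    interactome_hits: Iterable[VariantKey],
    annotations: AnnotationStore | None = None,
) -> list[SubjectSummary]:
    """One summary per profiled subject, sorted by ascending ratio.

    A shared variant contributes one entry to every sharing subject.
    Rare-shared entries are restricted to the homozygous sharers recorded
    by the cascade; oxidoreductase and interactome entries list every
    carrier.  Ties in ratio are broken by subject id.
    """
    by_subject: dict[str, SubjectSummary] = {}
    for p in profiles:
        if p.subject_id in by_subject:
            raise ValueError(f"duplicate profile for subject {p.subject_id}")
        by_subject[p.subject_id] = SubjectSummary(p.subject_id, p.ratio)

    def entry(subject_id: str, category: str, label: str, zyg: Zygosity) -> None:
        if subject_id not in by_subject:
            raise ValueError(
                f"subject {subject_id} has variants but no metabolic profile"
            )
        by_subject[subject_id].categories.setdefault(category, []).append(
            (label, zyg.mark)
        )

    for hit in sorted(catalog_hits, key=lambda h: (h.gene, h.rsid, h.subject_id)):
        entry(hit.subject_id, known_gene_category(hit.gene), hit.rsid, hit.zygosity)

    oxido = cascade_report.terminal(Branch.OXIDOREDUCTASE)
    for key in sorted(oxido.keys):
        for sid in matrix.carriers(key):
            entry(
                sid,
                CATEGORY_OXIDOREDUCTASE,
                _variant_label(key, annotations),
                matrix.zygosity(sid, key),
            )

    for key in sorted(set(interactome_hits)):
        for sid in matrix.carriers(key):
            entry(
                sid,
                CATEGORY_INTERACTOME,
                _variant_label(key, annotations),
                matrix.zygosity(sid, key),
            )

    shared = cascade_report.terminal(Branch.SHARED)
    for key in sorted(shared.keys):
        sharers = cascade_report.sharing.get(key, frozenset(matrix.carriers(key)))
        for sid in sorted(sharers):
            entry(
                sid,
                CATEGORY_RARE_SHARED,
                _variant_label(key, annotations),
                matrix.zygosity(sid, key),
            )

    return sorted(by_subject.values(), key=lambda s: (s.ratio, s.subject_id))


_SUMMARY_COLUMNS = (
    "subject_id",
    "ratio",
    "total",
    "category",
    "variant",
    "zygosity",
)


def _summaries_rows(summaries: Sequence[SubjectSummary]) -> list[tuple]:
    rows = []
    for s in summaries:
        if not s.categories:
            rows.append((s.subject_id, f"{s.ratio:.2f}", s.total, "", "", ""))
        for category in sorted(s.categories):
            for label, mark in s.categories[category]:
                rows.append(
                    (s.subject_id, f"{s.ratio:.2f}", s.total, category, label, mark)
                )
    return rows


def render_tables(
    summaries: Sequence[SubjectSummary],
    cascade_report: CascadeReport,
    out_dir: str | Path,
    fmt: str = "TSV",
) -> list[Path]:
    """Write subject summaries and the cascade step table.

    ``fmt`` is 'TSV' or 'JSON'.  Output is byte-deterministic for identical
    inputs.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = fmt.upper()
    written: list[Path] = []
    if fmt == "TSV":
        p = out_dir / "subject_summaries.tsv"
        with open(p, "w") as fh:
            fh.write("\t".join(_SUMMARY_COLUMNS) + "\n")
            for row in _summaries_rows(summaries):
                fh.write("\t".join(str(x) for x in row) + "\n")
        written.append(p)
        p = out_dir / "cascade_steps.tsv"
        with open(p, "w") as fh:
            fh.write("branch\tstep\tsnp_count\tindel_count\n")
            for row in cascade_report.as_rows():
                fh.write(
                    f"{row['branch']}\t{row['step']}\t{row['snp_count']}\t"
                    f"{row['indel_count']}\n"
                )
        written.append(p)
    elif fmt == "JSON":
        payload = {
            "subjects": [
                {
                    "subject_id": s.subject_id,
                    "ratio": round(s.ratio, 2),
                    "total": s.total,
                    "categories": {
                        cat: [
                            {"variant": label, "zygosity": mark}
                            for label, mark in entries
                        ]
                        for cat, entries in sorted(s.categories.items())
                    },
                }
                for s in summaries
            ],
            "cascade": cascade_report.as_rows(),
        }
        p = out_dir / "report.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(p)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected TSV or JSON)")
    return written
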