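"""Concordance between exome genotypes and orthogonal genotyping calls.

Validates the sequencing pipeline by comparing the zygosity matrix against
Sanger- or Taqman-style calls.  A (subject, variant, platform) pair enters
the denominator when both sides are non-missing; it matches when the
zygosities are identical (optionally treating hemizygous and homozygous
states as equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .catalog_network import ExtraGenotype, parse_genotype_string
from .variants import GenotypeMatrix, Sex, VariantKey, Zygosity

__all__ = [
    "OrthogonalCall",
    "PlatformCounts",
    "ConcordanceReport",
    "read_orthogonal_calls",
    "compare_genotypes",
]


@dataclass(frozen=True)
class OrthogonalCall:
    subject_id: str
    key: VariantKey
    platform: str
    zygosity: Zygosity
    rsid: str | None = None


@dataclass(frozen=True)
class PlatformCounts:
    n_compared: int
    n_matched: int

    @property
    def rate_percent(self) -> float:
        if self.n_compared == 0:
            raise ValueError("concordance rate undefined: nothing compared")
        return 100.0 * self.n_matched / self.n_compared


@dataclass
class ConcordanceReport:
    platforms: dict[str, PlatformCounts] = field(default_factory=dict)

    @property
    def n_compared(self) -> int:
        return sum(p.n_compared for p in self.platforms.values())

    @property
    def n_matched(self) -> int:
        return sum(p.n_matched for p in self.platforms.values())

    @property
    def rate_percent(self) -> float:
        if self.n_compared == 0:
            raise ValueError("concordance rate undefined: nothing compared")
        return 100.0 * self.n_matched / self.n_compared


def read_orthogonal_calls(
    path: str | Path, subject_sexes: Mapping[str, Sex | str]
) -> list[OrthogonalCall]:
    """TSV columns: subject_id, rsid, chrom, pos, ref, alt, platform, genotype."""
    df = pd.read_csv(str(path), sep="\t", dtype={"chrom": str, "subject_id": str})
    calls: list[OrthogonalCall] = []
    for row in df.itertuples(index=False):
        key = VariantKey(row.chrom, int(row.pos), str(row.ref), str(row.alt))
        sid = str(row.subject_id)
        if sid not in subject_sexes:
            raise ValueError(f"orthogonal call for unknown subject {sid}")
        hemi = not key.is_autosomal and Sex(subject_sexes[sid]) is Sex.M
        rsid = getattr(row, "rsid", None)
        calls.append(
            OrthogonalCall(
                subject_id=sid,
                key=key,
                platform=str(row.platform),
                zygosity=parse_genotype_string(str(row.genotype), hemi),
                rsid=None if rsid is None or str(rsid) == "nan" else str(rsid),
            )
        )
    return calls


def _zygosities_match(wes: Zygosity, call: Zygosity, lenient_hemi: bool) -> bool:
    if wes == call:
        return True
    if lenient_hemi:
        hom_like = {Zygosity.HOM_ALT, Zygosity.HEMI_ALT}
        ref_like = {Zygosity.HOM_REF, Zygosity.HEMI_REF}
        return ({wes, call} <= hom_like) or ({wes, call} <= ref_like)
    return False


def compare_genotypes(
    matrix: GenotypeMatrix,
    calls: Sequence[OrthogonalCall],
    extra_genotypes: Sequence[ExtraGenotype] | None = None,
    lenient_hemi: bool = False,
    count_missing_as_mismatch: bool = False,
) -> ConcordanceReport:
    """Compare orthogonal calls against the exome matrix.

    Variants absent from the matrix are resolved through
    ``extra_genotypes``; a call that resolves to neither is an error, as is
    a call for an unknown subject.  Pairs with a missing side are excluded
    from the denominator unless ``count_missing_as_mismatch``.  Raises when
    nothing is comparable (the rate would be undefined).
    """
    extra_index: dict[tuple[str, VariantKey], Zygosity] = {
        (eg.subject_id, eg.key): eg.zygosity for eg in extra_genotypes or ()
    }
    counts: dict[str, list[int]] = {}
    for call in calls:
        if call.subject_id not in matrix._subject_index:
            raise ValueError(f"call references unknown subject {call.subject_id}")
        if call.key in matrix._variant_index:
            wes = matrix.zygosity(call.subject_id, call.key)
        elif (call.subject_id, call.key) in extra_index:
            wes = extra_index[(call.subject_id, call.key)]
        else:
            raise ValueError(
                f"call at {call.key.label} resolves to no exome or extra genotype"
            )
        pair = counts.setdefault(call.platform, [0, 0])
        if wes is Zygosity.MISSING or call.zygosity is Zygosity.MISSING:
            if count_missing_as_mismatch:
                pair[0] += 1
            continue
        pair[0] += 1
        if _zygosities_match(wes, call.zygosity, lenient_hemi):
            pair[1] += 1
    report = ConcordanceReport(
        platforms={
            name: PlatformCounts(n_compared=c, n_matched=m)
            for name, (c, m) in sorted(counts.items())
        }
    )
    if report.n_compared == 0:
        raise ValueError("concordance rate undefined: no comparable genotype pairs")
    return report
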