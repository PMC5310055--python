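"""Choline-challenge urine analysis and TMAU classification.

After a fixed oral choline dose, urine is collected over three consecutive
8-hour intervals (interval 0 is the pre-challenge first-morning sample).
TMA is quantified in every interval; TMAO is measured in the post-challenge
interval with the highest TMA concentration.  The outcome measure is the
TMAO fraction of total TMA species,

    ratio = TMAO / (TMA + TMAO),

which lies in [0, 1]; healthy adults convert at least 90% of TMA, so a
ratio below 0.90 meets the criterion for trimethylaminuria (TMAU).  The
raw TMAO/TMA quotient is also exposed for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TmauStatus",
    "UrineSample",
    "MetabolicProfile",
    "CohortSummary",
    "select_peak_sample",
    "oxidation_ratio",
    "tmao_tma_quotient",
    "classify_tmau",
    "profile_subject",
    "profile_cohort",
    "summarize_cohort",
    "read_urine_table",
    "write_profiles",
]

#: below this TMAO fraction a subject meets the TMAU criterion
TMAU_THRESHOLD = 0.90


class TmauStatus(str, Enum):
    TMAU = "TMAU"
    NORMAL = "NORMAL"


@dataclass(frozen=True)
class UrineSample:
    """One timed urine collection for one subject.

    ``interval_index`` 0 is the pre-challenge first-morning sample; 1-3 are
    the consecutive 8-h post-challenge collections.  Concentrations are in
    arbitrary but mutually consistent units (the ratio is scale-invariant).
    """

    subject_id: str
    interval_index: int
    tma_conc: float
    tmao_conc: float | None = None
    volume_ml: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.interval_index <= 3:
            raise ValueError(f"interval_index must be 0..3, got {self.interval_index}")
        if self.tma_conc < 0:
            raise ValueError("tma_conc must be non-negative")
        if self.tmao_conc is not None and self.tmao_conc < 0:
            raise ValueError("tmao_conc must be non-negative")
        if self.volume_ml is not None and self.volume_ml <= 0:
            raise ValueError("volume_ml must be positive")


@dataclass(frozen=True)
class MetabolicProfile:
    subject_id: str
    selected_interval: int
    ratio: float
    status: TmauStatus
    quotient: float | None = None  # raw TMAO/TMA, None when TMA == 0


@dataclass(frozen=True)
class CohortSummary:
    n: int
    n_tmau: int
    min_ratio: float
    max_ratio: float


def select_peak_sample(
    samples: Sequence[UrineSample], include_prechallenge: bool = False
) -> int:
    """Interval index of the sample with the highest TMA concentration.

    Only post-challenge samples (intervals 1-3) are considered unless
    ``include_prechallenge`` is set; ties go to the earliest interval.
    """
    eligible = [
        s
        for s in samples
        if (include_prechallenge or s.interval_index >= 1) and s.tma_conc is not None
    ]
    if not eligible:
        raise ValueError("no eligible urine sample with a TMA measurement")
    intervals = [s.interval_index for s in eligible]
    if len(set(intervals)) != len(intervals):
        raise ValueError("duplicate interval_index within one subject")
    best = max(eligible, key=lambda s: (s.tma_conc, -s.interval_index))
    return best.interval_index


def oxidation_ratio(tma_conc: float, tmao_conc: float) -> float:
    """TMAO fraction of total TMA species: tmao / (tma + tmao)."""
    if tma_conc < 0 or tmao_conc < 0:
        raise ValueError("concentrations must be non-negative")
    total = tma_conc + tmao_conc
    if total == 0:
        raise ValueError("undefined ratio: TMA and TMAO both zero")
    return tmao_conc / total


def tmao_tma_quotient(tma_conc: float, tmao_conc: float) -> float | None:
    """Raw TMAO/TMA quotient; ``None`` when TMA is zero."""
    if tma_conc == 0:
        return None
    return tmao_conc / tma_conc


def classify_tmau(ratio: float, threshold: float = TMAU_THRESHOLD) -> TmauStatus:
    """TMAU iff ratio < threshold (strictly); ratio must lie in [0, 1]."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio outside [0,1]: {ratio}")
    return TmauStatus.TMAU if ratio < threshold else TmauStatus.NORMAL


def profile_subject(
    samples: Sequence[UrineSample],
    threshold: float = TMAU_THRESHOLD,
    include_prechallenge: bool = False,
) -> MetabolicProfile:
    """Select the peak-TMA sample, compute the ratio, classify the subject."""
    if not samples:
        raise ValueError("empty sample list")
    subject_ids = {s.subject_id for s in samples}
    if len(subject_ids) != 1:
        raise ValueError(f"samples span multiple subjects: {sorted(subject_ids)}")
    peak = select_peak_sample(samples, include_prechallenge=include_prechallenge)
    sample = next(s for s in samples if s.interval_index == peak)
    if sample.tmao_conc is None:
        raise ValueError(
            f"peak sample (interval {peak}) of subject {sample.subject_id} "
            "has no TMAO measurement"
        )
    ratio = oxidation_ratio(sample.tma_conc, sample.tmao_conc)
    return MetabolicProfile(
        subject_id=sample.subject_id,
        selected_interval=peak,
        ratio=ratio,
        status=classify_tmau(ratio, threshold),
        quotient=tmao_tma_quotient(sample.tma_conc, sample.tmao_conc),
    )


def profile_cohort(
    samples: Iterable[UrineSample],
    threshold: float = TMAU_THRESHOLD,
    include_prechallenge: bool = False,
) -> list[MetabolicProfile]:
    """One profile per subject, in order of first appearance."""
    by_subject: dict[str, list[UrineSample]] = {}
    for s in samples:
        by_subject.setdefault(s.subject_id, []).append(s)
    return [
        profile_subject(group, threshold, include_prechallenge)
        for group in by_subject.values()
    ]


def summarize_cohort(profiles: Sequence[MetabolicProfile]) -> CohortSummary:
    if not profiles:
        raise ValueError("no profiles to summarize")
    ratios = [p.ratio for p in profiles]
    return CohortSummary(
        n=len(profiles),
        n_tmau=sum(p.status is TmauStatus.TMAU for p in profiles),
        min_ratio=min(ratios),
        max_ratio=max(ratios),
    )


def read_urine_table(path: str | Path) -> list[UrineSample]:
    """TSV columns: subject_id, interval_index, volume_ml, tma_conc, tmao_conc."""
    df = pd.read_csv(str(path), sep="\t", dtype={"subject_id": str}, na_values=["."])
    required = {"subject_id", "interval_index", "tma_conc"}
    if missing := required - set(df.columns):
        raise ValueError(f"urine table missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        def opt(name: str) -> float | None:
            v = getattr(row, name, None)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return float(v)

        samples.append(
            UrineSample(
                subject_id=str(row.subject_id),
                interval_index=int(row.interval_index),
                tma_conc=float(row.tma_conc),
                tmao_conc=opt("tmao_conc"),
                volume_ml=opt("volume_ml"),
            )
        )
    return samples


def write_profiles(profiles: Sequence[MetabolicProfile], path: str | Path) -> None:
    """Write profiles as a TSV with ratios fixed to two decimals."""
    with open(path, "w") as fh:
        fh.write("subject_id\tselected_interval\tratio\tstatus\n")
        for p in profiles:
            fh.write(
                f"{p.subject_id}\t{p.selected_interval}\t{p.ratio:.2f}\t{p.status.value}\n"
            )
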