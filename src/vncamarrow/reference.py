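"""Age/sex-stratified reference statistics of marrow VNCa attenuation.

Exams are stratified by sex and four age bands (21-40, 41-60, 61-80, >80
years; age at exam, integer-truncated, 80 still belongs to 61-80) and by
calcium-suppression level (low/medium/maximum, vendor indices 76/50/25).
Per stratum the unit-mass exam histograms are averaged with equal weight —
so patients with many exams do not dominate — and summarized by bin-center
quantiles.  A packaged reference table built from a 500-exam cohort of
individuals with healthy trabecular bone ships with the package.

Intra-individual consistency between consecutive exams is graded on the
histogram overlap: > 0.90 is "excellent", > 0.80 "good" (strict
inequalities).  A new exam is classified against the matched stratum's
95th percentile: a marrow attenuation statistic strictly above it flags
the exam, since marrow-replacing disease raises VNCa attenuation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .histogram import (
    AttenuationHistogram,
    HistogramSummary,
    average_histograms,
    histogram_statistics,
    normalize,
    overlap,
)

logger = logging.getLogger(__name__)

SEXES = ("female", "male")
AGE_BANDS = ("21-40", "41-60", "61-80", ">80")
LEVELS = ("low", "medium", "maximum")
#: vendor calcium-suppression index per level name
VENDOR_INDEX = {"low": 76, "medium": 50, "maximum": 25}
LEVEL_FOR_INDEX = {v: k for k, v in VENDOR_INDEX.items()}

_PACKAGED_TABLE_FILE = "reference_table_v1.csv"

__all__ = [
    "DemographicGroup",
    "ReferenceEntry",
    "ReferenceTable",
    "ExamRecord",
    "ConsistencyResult",
    "ClassificationResult",
    "UnbandedAgeError",
    "assign_group",
    "build_reference_table",
    "packaged_reference",
    "consistency_grade",
    "intra_individual_consistency",
    "group_average_histograms",
    "pairwise_group_overlap",
    "classify_exam",
    "SEXES",
    "AGE_BANDS",
    "LEVELS",
    "VENDOR_INDEX",
]


class UnbandedAgeError(ValueError):
    """Age below the youngest reference band (bands start at 21 years)."""


@dataclass(frozen=True)
class DemographicGroup:
    sex: str
    age_band: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"age band must be one of {AGE_BANDS}, got {self.age_band!r}")

    @property
    def label(self) -> str:
        return f"{self.sex} {self.age_band}"


def assign_group(sex: str, age: float) -> DemographicGroup:
    """Map (sex, age at exam) onto a reference stratum.

    Age is integer-truncated.  The bands start at 21; exactly 80 belongs to
    61-80 and ">80" is strict.  Younger ages raise :class:`UnbandedAgeError`
    — they are excluded from reference building, never merged into 21-40.
    """
    age = int(age)
    if age < 21:
        raise UnbandedAgeError(f"age {age} is below the 21-40 band; exam is un-banded")
    if age <= 40:
        band = "21-40"
    elif age <= 60:
        band = "41-60"
    elif age <= 80:
        band = "61-80"
    else:
        band = ">80"
    return DemographicGroup(sex=sex, age_band=band)


@dataclass(frozen=True)
class ReferenceEntry:
    """Summary statistics of one (sex, age band, suppression level) cell."""

    group: DemographicGroup
    level: str
    median: float
    q1: float
    q3: float
    p95: float
    mode: float
    n_exams: int | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")

    @property
    def summary(self) -> HistogramSummary:
        return HistogramSummary(self.median, self.q1, self.q3, self.p95, self.mode)

    def quantiles_ordered(self) -> bool:
        return self.q1 <= self.median <= self.q3 <= self.p95


@dataclass
class ReferenceTable:
    """Complete or partial grid of reference entries over 2 x 4 x 3 cells."""

    entries: dict[tuple[str, str, str], ReferenceEntry]
    provenance: str = "built"

    def get(self, sex: str, age_band: str, level: str) -> ReferenceEntry:
        key = (sex, age_band, level)
        if key not in self.entries:
            raise KeyError(f"reference cell {key} is missing")
        return self.entries[key]

    def lookup(self, group: DemographicGroup, level: str) -> ReferenceEntry:
        return self.get(group.sex, group.age_band, level)

    def missing_cells(self) -> list[tuple[str, str, str]]:
        return [
            (s, b, l)
            for l in LEVELS
            for s in SEXES
            for b in AGE_BANDS
            if (s, b, l) not in self.entries
        ]

    def is_complete(self) -> bool:
        return not self.missing_cells()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in LEVELS:
            for sex in SEXES:
                for band in AGE_BANDS:
                    e = self.entries.get((sex, band, level))
                    if e is None:
                        continue
                    rows.append(
                        {
                            "sex": sex,
                            "age_band": band,
                            "level": level,
                            "median": e.median,
                            "q1": e.q1,
                            "q3": e.q3,
                            "p95": e.p95,
                            "mode": e.mode,
                            "n_exams": e.n_exams,
                        }
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "built") -> "ReferenceTable":
        entries: dict[tuple[str, str, str], ReferenceEntry] = {}
        for row in frame.itertuples(index=False):
            key = (str(row.sex), str(row.age_band), str(row.level))
            if key in entries:
                raise ValueError(f"duplicate reference cell {key}")
            n = getattr(row, "n_exams", None)
            n = None if n is None or (isinstance(n, float) and np.isnan(n)) else int(n)
            entries[key] = ReferenceEntry(
                group=DemographicGroup(key[0], key[1]),
                level=key[2],
                median=float(row.median),
                q1=float(row.q1),
                q3=float(row.q3),
                p95=float(row.p95),
                mode=float(row.mode),
                n_exams=n,
            )
        return cls(entries=entries, provenance=provenance)

    @classmethod
    def from_csv(cls, path, provenance: str = "built") -> "ReferenceTable":
        return cls.from_frame(pd.read_csv(path), provenance=provenance)


def packaged_reference() -> ReferenceTable:
    """The reference table shipped with the package (24 cells).

    Median, quartiles, 95th percentile and histogram-maximum location per
    (sex x age band x suppression level), on the 5 HU bin-center grid, from
    a 500-exam cohort of individuals with healthy trabecular bone.
    """
    with resources.files("vncamarrow.data").joinpath(_PACKAGED_TABLE_FILE).open() as fh:
        frame = pd.read_csv(fh)
    return ReferenceTable.from_frame(frame, provenance="packaged")


@dataclass
class ExamRecord:
    """One exam: patient metadata plus the per-level marrow histograms."""

    patient_id: str
    sex: str
    age: float
    exam_date: str
    histograms: dict[str, AttenuationHistogram] = field(default_factory=dict)
    n_vertebrae_retained: int = 0
    n_vertebrae_segmented: int = 0

    def group(self) -> DemographicGroup:
        return assign_group(self.sex, self.age)


def _dedupe(cohort: Sequence[ExamRecord]) -> list[ExamRecord]:
    seen: dict[tuple[str, str], ExamRecord] = {}
    for exam in cohort:
        key = (exam.patient_id, exam.exam_date)
        if key in seen:
            warnings.warn(
                f"duplicate exam {key} collapsed to the first occurrence", RuntimeWarning
            )
            continue
        seen[key] = exam
    return list(seen.values())


def build_reference_table(
    cohort: Iterable[ExamRecord], levels: Sequence[str] = LEVELS
) -> ReferenceTable:
    """Build a reference table from exam records.

    Per cell, exam histograms are unit-mass normalized, averaged with equal
    weight per exam, and summarized by bin-center quantiles.  Un-banded
    (sub-21) exams are excluded with a logged warning; duplicate exams
    (same patient id and date) are collapsed.  Unpopulated cells are left
    missing rather than raising.
    """
    cohort = _dedupe(list(cohort))
    cells: dict[tuple[str, str, str], list[AttenuationHistogram]] = {}
    for exam in cohort:
        try:
            group = exam.group()
        except UnbandedAgeError:
            logger.warning(
                "exam %s/%s: age %s below reference bands; excluded",
                exam.patient_id,
                exam.exam_date,
                exam.age,
            )
            continue
        for level in levels:
            h = exam.histograms.get(level)
            if h is None or h.is_empty():
                continue
            cells.setdefault((group.sex, group.age_band, level), []).append(normalize(h))
    entries: dict[tuple[str, str, str], ReferenceEntry] = {}
    for key, hists in cells.items():
        mean = average_histograms(hists)
        stats = histogram_statistics(mean)
        entries[key] = ReferenceEntry(
            group=DemographicGroup(key[0], key[1]),
            level=key[2],
            median=stats.median,
            q1=stats.q1,
            q3=stats.q3,
            p95=stats.p95,
            mode=stats.mode,
            n_exams=len(hists),
        )
    return ReferenceTable(entries=entries, provenance="built")


def consistency_grade(value: float) -> str:
    """Grade a histogram overlap: > 0.90 'excellent', > 0.80 'good', else 'below-good'.

    Both boundaries are strict; an overlap of exactly 0.80 is below-good.
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"overlap must lie in [0, 1], got {value}")
    if value > 0.90:
        return "excellent"
    if value > 0.80:
        return "good"
    return "below-good"


@dataclass
class ConsistencyResult:
    """Overlaps of consecutive exam pairs, per suppression level."""

    per_level: dict[str, list[float]]
    pooled_median: float | None

    def all_values(self) -> list[float]:
        return [v for vals in self.per_level.values() for v in vals]


def intra_individual_consistency(
    exams: Sequence[ExamRecord], levels: Sequence[str] = LEVELS
) -> ConsistencyResult:
    """Histogram overlap between consecutive exams of one patient.

    Exams are ordered by date; n exams yield n-1 consecutive pairs per
    level.  The pooled median is taken across all pair-level overlap
    values.  Fewer than two exams give an empty result, not an error.
    """
    ordered = sorted(exams, key=lambda e: e.exam_date)
    per_level: dict[str, list[float]] = {level: [] for level in levels}
    if len(ordered) >= 2:
        for level in levels:
            for a, b in zip(ordered[:-1], ordered[1:]):
                ha, hb = a.histograms.get(level), b.histograms.get(level)
                if ha is None or hb is None:
                    continue
                per_level[level].append(overlap(normalize(ha), normalize(hb)))
    values = [v for vals in per_level.values() for v in vals]
    pooled = float(np.median(values)) if values else None
    return ConsistencyResult(per_level=per_level, pooled_median=pooled)


def group_average_histograms(
    cohort: Iterable[ExamRecord], level: str
) -> dict[DemographicGroup, AttenuationHistogram]:
    """Equal-weight average unit-mass histogram per demographic stratum."""
    buckets: dict[DemographicGroup, list[AttenuationHistogram]] = {}
    for exam in cohort:
        try:
            group = exam.group()
        except UnbandedAgeError:
            continue
        h = exam.histograms.get(level)
        if h is None or h.is_empty():
            continue
        buckets.setdefault(group, []).append(normalize(h))
    return {g: average_histograms(hs) for g, hs in buckets.items()}


def pairwise_group_overlap(
    averages: Mapping[DemographicGroup, AttenuationHistogram], level: str | None = None
) -> pd.DataFrame:
    """Symmetric matrix of overlaps between group-average histograms.

    Rows/columns cover all eight (sex, age band) strata in a fixed order;
    a stratum without an average histogram yields NaN in its row and
    column.  The diagonal is exactly 1 for present strata.
    """
    groups = [DemographicGroup(s, b) for s in SEXES for b in AGE_BANDS]
    labels = [g.label for g in groups]
    mat = np.full((len(groups), len(groups)), np.nan)
    for i, gi in enumerate(groups):
        hi = averages.get(gi)
        if hi is None:
            continue
        for j, gj in enumerate(groups):
            if j < i:
                continue
            hj = averages.get(gj)
            if hj is None:
                continue
            value = 1.0 if i == j else overlap(hi, hj)
            mat[i, j] = mat[j, i] = value
    frame = pd.DataFrame(mat, index=labels, columns=labels)
    frame.attrs["level"] = level
    return frame


@dataclass(frozen=True)
class ClassificationResult:
    category: str  # 'above-95th-percentile' | 'within-reference' | 'below-reference-support'
    margin_hu: float
    statistic: str
    statistic_hu: float
    reference_p95: float


def classify_exam(
    exam: ExamRecord,
    reference: ReferenceTable,
    level: str,
    statistic: str = "median",
) -> ClassificationResult:
    """Compare an exam's marrow attenuation against the matched 95th percentile.

    ``statistic`` selects the exam-side summary: the histogram median
    (default) or the exam's own 95th percentile ('p95').  A value strictly
    above the matched stratum's reference P95 classifies the exam as
    above the reference range; margin = statistic - P95.  Values far below
    the reference body (beyond Q1 - 1.5 IQR, the Tukey lower fence) are
    flagged as below the reference support.
    """
    group = exam.group()  # raises UnbandedAgeError for sub-21 ages
    entry = reference.lookup(group, level)
    h = exam.histograms.get(level)
    if h is None or h.is_empty():
        raise ValueError(f"exam has no histogram for level {level!r}")
    stats = histogram_statistics(h)
    if statistic == "median":
        value = stats.median
    elif statistic == "p95":
        value = stats.p95
    else:
        raise ValueError("statistic must be 'median' or 'p95'")
    margin = value - entry.p95
    if value > entry.p95:
        category = "above-95th-percentile"
    elif value < entry.q1 - 1.5 * (entry.q3 - entry.q1):
        category = "below-reference-support"
    else:
        category = "within-reference"
    return ClassificationResult(
        category=category,
        margin_hu=float(margin),
        statistic=statistic,
        statistic_hu=float(value),
        reference_p95=float(entry.p95),
    )
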