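"""Batch orchestration: manifest-driven processing, summaries and reports.

The pipeline mirrors a fully automated workflow: a cohort manifest lists
the label map and VNCa volumes of each exam; every exam is processed
without interaction, failures are logged and skipped so one corrupt file
never halts the batch, and the cohort summary records the inclusion
fraction, intra-individual consistency and grade proportions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import nifti
from .histogram import compute_histogram, save_histogram
from .reference import (
    LEVELS,
    ConsistencyResult,
    ExamRecord,
    ReferenceTable,
    consistency_grade,
    intra_individual_consistency,
)
from .voi import extract_marrow_voi, transfer_mask

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "exam_date",
    "labels_path",
    "vnca_low_path",
    "vnca_medium_path",
    "vnca_maximum_path",
]

__all__ = [
    "PipelineConfig",
    "CohortSummary",
    "PipelineResult",
    "run_pipeline",
    "inclusion_fraction",
    "export_report",
    "write_cohort",
    "MANIFEST_COLUMNS",
]


@dataclass
class PipelineConfig:
    """Processing constants; the defaults are the reference settings.

    margin 3 mm cortical erosion, at most 17 thoracolumbar vertebrae
    counted from the bottom, 5 HU bins, -1000 HU lower cutoff, all three
    calcium-suppression levels, physical-distance erosion.
    """

    margin_mm: float = 3.0
    max_vertebrae: int = 17
    bin_width: float = 5.0
    lower_cutoff: float = -1000.0
    levels: tuple[str, ...] = ("low", "medium", "maximum")
    erosion_mode: str = "physical"
    per_vertebra: bool = True
    seed: int = 0
    out_dir: str = "vncamarrow_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["levels"] = list(self.levels)
        return d


def inclusion_fraction(retained: int, exams: int, max_per_exam: int = 17) -> float:
    """Percentage of all possible vertebrae that entered the analysis.

    100 * retained / (exams * max_per_exam), rounded half-up to one
    decimal — e.g. 8298 vertebrae over 500 exams of up to 17 give 97.6.
    """
    if exams <= 0 or max_per_exam <= 0:
        raise ValueError("exams and max_per_exam must be positive")
    if retained < 0 or retained > exams * max_per_exam:
        raise ValueError(
            f"retained count {retained} outside [0, {exams * max_per_exam}]"
        )
    pct = Decimal(100 * retained) / Decimal(exams * max_per_exam)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Cohort-level bookkeeping and consistency statistics."""

    n_exams: int
    n_patients: int
    vertebrae_segmented: int
    vertebrae_retained: int
    inclusion_fraction_pct: float
    overlap_median_per_level: dict[str, float | None]
    overlap_iqr_per_level: dict[str, tuple[float, float] | None]
    pooled_overlap_median: float | None
    grade_proportions_pct: dict[str, float]
    n_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "n_exams": self.n_exams,
            "n_patients": self.n_patients,
            "vertebrae_segmented": self.vertebrae_segmented,
            "vertebrae_retained": self.vertebrae_retained,
            "inclusion_fraction_pct": self.inclusion_fraction_pct,
            "overlap_median_per_level": self.overlap_median_per_level,
            "overlap_iqr_per_level": {
                k: (list(v) if v is not None else None)
                for k, v in self.overlap_iqr_per_level.items()
            },
            "pooled_overlap_median": self.pooled_overlap_median,
            "grade_proportions_pct": self.grade_proportions_pct,
            "n_failures": self.n_failures,
        }


@dataclass
class PipelineResult:
    records: list[ExamRecord]
    summary: CohortSummary
    failures: list[tuple[str, str]] = field(default_factory=list)  # (exam id, reason)

    @property
    def fully_successful(self) -> bool:
        return not self.failures


def _round1(x: float) -> float:
    return float(Decimal(x).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _process_exam(row, config: PipelineConfig, out_dir: Path) -> ExamRecord:
    labels = nifti.load_label_map(row.labels_path)
    n_segmented = int(labels.labels().size)
    voi = extract_marrow_voi(
        labels,
        margin=config.margin_mm,
        per_vertebra=config.per_vertebra,
        max_count=config.max_vertebrae,
        mode=config.erosion_mode,
    )
    exam_id = f"{row.patient_id}_{row.exam_date}"
    exam_dir = out_dir / exam_id
    exam_dir.mkdir(parents=True, exist_ok=True)
    histograms = {}
    for level in config.levels:
        path = getattr(row, f"vnca_{level}_path")
        volume = nifti.load_vnca(path, level=level)
        values, vol_mm3 = transfer_mask(voi, volume)
        h = compute_histogram(
            values,
            lower_cutoff=config.lower_cutoff,
            bin_width=config.bin_width,
            volume_mm3=vol_mm3,
        )
        histograms[level] = h
        save_histogram(h, exam_dir / f"hist_{level}.csv")
    record = ExamRecord(
        patient_id=str(row.patient_id),
        sex=str(row.sex),
        age=float(row.age),
        exam_date=str(row.exam_date),
        histograms=histograms,
        n_vertebrae_retained=len(voi.labels_retained),
        n_vertebrae_segmented=n_segmented,
    )
    meta = {
        "patient_id": record.patient_id,
        "sex": record.sex,
        "age": record.age,
        "exam_date": record.exam_date,
        "n_vertebrae_segmented": record.n_vertebrae_segmented,
        "n_vertebrae_retained": record.n_vertebrae_retained,
        "voi_volume_mm3": voi.volume_mm3,
        "histograms": {level: f"hist_{level}.csv" for level in config.levels},
    }
    (exam_dir / "exam.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return record


def _consistency_summary(
    records: Sequence[ExamRecord], levels: Sequence[str]
) -> tuple[dict, dict, float | None, dict]:
    by_patient: dict[str, list[ExamRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    per_level_values: dict[str, list[float]] = {level: [] for level in levels}
    all_values: list[float] = []
    for exams in by_patient.values():
        if len(exams) < 2:
            continue
        res: ConsistencyResult = intra_individual_consistency(exams, levels)
        for level, vals in res.per_level.items():
            per_level_values[level].extend(vals)
        all_values.extend(res.all_values())
    medians = {
        level: (float(np.median(v)) if v else None) for level, v in per_level_values.items()
    }
    iqrs = {
        level: (
            (float(np.percentile(v, 25)), float(np.percentile(v, 75))) if v else None
        )
        for level, v in per_level_values.items()
    }
    pooled = float(np.median(all_values)) if all_values else None
    if all_values:
        n = len(all_values)
        grades = {
            "good_or_better": _round1(
                100 * sum(1 for v in all_values if consistency_grade(v) != "below-good") / n
            ),
            "excellent": _round1(
                100 * sum(1 for v in all_values if consistency_grade(v) == "excellent") / n
            ),
        }
    else:
        grades = {"good_or_better": 0.0, "excellent": 0.0}
    return medians, iqrs, pooled, grades


def run_pipeline(manifest_path: str | Path, config: PipelineConfig) -> PipelineResult:
    """Process every exam of a cohort manifest without interaction.

    Per-exam failures (unreadable volume, grid mismatch, ...) are logged
    and skipped; an unreadable manifest is rejected up front.  Outputs are
    one directory per exam (histogram CSV/JSON plus metadata) and a
    cohort summary.
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = pd.read_csv(manifest_path)
    except Exception as exc:  # noqa: BLE001 - any read failure rejects the run
        raise ValueError(f"cannot read manifest {manifest_path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    # only the levels actually configured need their path column
    missing = [
        c
        for c in missing
        if not c.startswith("vnca_") or c in [f"vnca_{l}_path" for l in config.levels]
    ]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records: list[ExamRecord] = []
    failures: list[tuple[str, str]] = []
    for row in manifest.itertuples(index=False):
        exam_id = f"{row.patient_id}_{row.exam_date}"
        try:
            records.append(_process_exam(row, config, out_dir))
        except Exception as exc:  # noqa: BLE001 - skip-and-log per exam
            logger.error("exam %s failed: %s", exam_id, exc)
            failures.append((exam_id, str(exc)))

    segmented = sum(r.n_vertebrae_segmented for r in records)
    retained = sum(r.n_vertebrae_retained for r in records)
    medians, iqrs, pooled, grades = _consistency_summary(records, config.levels)
    summary = CohortSummary(
        n_exams=len(records),
        n_patients=len({r.patient_id for r in records}),
        vertebrae_segmented=segmented,
        vertebrae_retained=retained,
        inclusion_fraction_pct=(
            inclusion_fraction(retained, len(records), config.max_vertebrae)
            if records
            else 0.0
        ),
        overlap_median_per_level=medians,
        overlap_iqr_per_level=iqrs,
        pooled_overlap_median=pooled,
        grade_proportions_pct=grades,
        n_failures=len(failures),
    )
    (out_dir / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return PipelineResult(records=records, summary=summary, failures=failures)


def export_report(
    summary: CohortSummary,
    table: ReferenceTable | None,
    matrix: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the cohort report: summary JSON, reference CSV, overlap matrix CSV.

    Serialization is deterministic (sorted keys, fixed column order) so a
    write -> read -> write cycle is byte-identical.  A missing matrix cell
    is written as an empty field.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n")
    paths["summary"] = summary_path
    if table is not None:
        ref_path = out_dir / "reference.csv"
        table.to_csv(ref_path)
        paths["reference"] = ref_path
    if matrix is not None:
        mat_path = out_dir / "overlap_matrix.csv"
        matrix.to_csv(mat_path)
        paths["matrix"] = mat_path
    return paths


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read an overlap-matrix CSV losslessly (exact float round trip)."""
    return pd.read_csv(path, index_col=0, float_precision="round_trip")


def read_reference_frame(path: str | Path) -> pd.DataFrame:
    """Read a reference-table CSV losslessly (exact float round trip)."""
    return pd.read_csv(path, float_precision="round_trip")


def write_cohort(exams, out_dir: str | Path) -> Path:
    """Write simulated exams (volumes + metadata) and return the manifest path.

    Exams must carry rendered volumes (``render_volumes=True``).  Layout:
    one directory per exam holding labels.nii.gz and vnca_<level>.nii.gz,
    plus a cohort manifest CSV wiring them together.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for exam in exams:
        if exam.label_map is None or exam.volumes is None:
            raise ValueError("write_cohort needs rendered volumes")
        rec = exam.record
        exam_dir = out_dir / f"{rec.patient_id}_{rec.exam_date}"
        exam_dir.mkdir(parents=True, exist_ok=True)
        labels_path = nifti.save_label_map(exam.label_map, exam_dir / "labels.nii.gz")
        row = {
            "patient_id": rec.patient_id,
            "sex": rec.sex,
            "age": rec.age,
            "exam_date": rec.exam_date,
            "labels_path": str(labels_path),
        }
        for level in LEVELS:
            key = f"vnca_{level}_path"
            if level in exam.volumes:
                row[key] = str(
                    nifti.save_vnca(exam.volumes[level], exam_dir / f"vnca_{level}.nii.gz")
                )
            else:
                row[key] = ""
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest
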