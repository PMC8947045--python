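"""Stratification, packaged reference table, consistency grading, classification."""

import numpy as np
import pandas as pd
import pytest

from vncamarrow.histogram import AttenuationHistogram, compute_histogram, histogram_statistics
from vncamarrow.reference import (
    AGE_BANDS,
    LEVELS,
    SEXES,
    VENDOR_INDEX,
    DemographicGroup,
    ExamRecord,
    ReferenceTable,
    UnbandedAgeError,
    assign_group,
    build_reference_table,
    classify_exam,
    consistency_grade,
    group_average_histograms,
    intra_individual_consistency,
    packaged_reference,
    pairwise_group_overlap,
)


def make_exam(pid="P1", sex="female", age=50, date="d0", values=None, levels=LEVELS):
    if values is None:
        values = [-400.0, -380.0, -360.0]
    return ExamRecord(
        patient_id=pid,
        sex=sex,
        age=age,
        exam_date=date,
        histograms={level: compute_histogram(values) for level in levels},
        n_vertebrae_retained=17,
    )


class TestAssignGroup:
    @pytest.mark.parametrize(
        "sex,age,band",
        [
            ("female", 21, "21-40"),
            ("female", 40, "21-40"),
            ("female", 61, "61-80"),
            ("male", 80, "61-80"),
            ("male", 81, ">80"),
            ("male", 41, "41-60"),
            ("female", 60.9, "41-60"),  # age is integer-truncated
        ],
    )
    def test_band_boundaries(self, sex, age, band):
        assert assign_group(sex, age) == DemographicGroup(sex, band)

    @pytest.mark.parametrize("age", [19, 20, 20.9])
    def test_sub_21_is_unbanded(self, age):
        with pytest.raises(UnbandedAgeError):
            assign_group("female", age)

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            assign_group("other", 50)


class TestPackagedReference:
    def test_quoted_p95_cells(self, reference_table):
        assert reference_table.get("female", "41-60", "maximum").p95 == -212.5
        assert reference_table.get("female", ">80", "maximum").p95 == -122.5

    def test_complete_grid_of_24_cells(self, reference_table):
        assert reference_table.is_complete()
        assert len(reference_table.entries) == 24
        assert reference_table.provenance == "packaged"

    def test_quantile_ordering_in_every_cell(self, reference_table):
        for entry in reference_table.entries.values():
            assert entry.quantiles_ordered()

    def test_values_on_bin_center_grid(self, reference_table):
        for e in reference_table.entries.values():
            for v in (e.median, e.q1, e.q3, e.p95, e.mode):
                assert abs(v % 5.0) == pytest.approx(2.5)

    def test_vendor_suppression_indices(self):
        assert VENDOR_INDEX == {"low": 76, "medium": 50, "maximum": 25}

    def test_csv_round_trip(self, reference_table, tmp_path):
        path = tmp_path / "ref.csv"
        reference_table.to_csv(path)
        back = ReferenceTable.from_csv(path)
        for key, e in reference_table.entries.items():
            b = back.entries[key]
            assert (b.median, b.q1, b.q3, b.p95, b.mode) == (
                e.median,
                e.q1,
                e.q3,
                e.p95,
                e.mode,
            )


class TestBuildReferenceTable:
    def test_identical_histograms_reproduce_their_statistics(self):
        cohort = [
            make_exam(pid=f"P{i}", sex=sex, age=age, values=[-400.0, -250.0, -250.0])
            for i, (sex, age) in enumerate(
                [(s, a) for s in SEXES for a in (30, 50, 70, 85)]
            )
        ]
        table = build_reference_table(cohort)
        expected = histogram_statistics(compute_histogram([-400.0, -250.0, -250.0]))
        assert table.is_complete()
        for entry in table.entries.values():
            assert entry.median == expected.median
            assert entry.p95 == expected.p95
            assert entry.mode == expected.mode
            assert entry.n_exams == 1

    def test_single_exam_cohort_flags_other_cells(self):
        table = build_reference_table([make_exam()])
        assert len(table.entries) == len(LEVELS)
        assert ("female", "41-60", "maximum") in table.entries
        assert len(table.missing_cells()) == 24 - 3

    def test_duplicate_exams_collapsed_with_warning(self):
        with pytest.warns(RuntimeWarning):
            table = build_reference_table([make_exam(), make_exam()])
        assert table.entries[("female", "41-60", "maximum")].n_exams == 1

    def test_sub_21_exams_excluded(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="vncamarrow.reference"):
            table = build_reference_table([make_exam(age=19)])
        assert not table.entries
        assert "below reference bands" in caplog.text


class TestConsistencyGrade:
    @pytest.mark.parametrize(
        "value,grade",
        [
            (0.95, "excellent"),
            (0.901, "excellent"),
            (0.90, "good"),
            (0.85, "good"),
            (0.801, "good"),
            (0.80, "below-good"),
            (0.5, "below-good"),
            (1.0, "excellent"),
        ],
    )
    def test_strict_thresholds(self, value, grade):
        assert consistency_grade(value) == grade

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            consistency_grade(bad)


class TestIntraIndividualConsistency:
    def test_duplicated_exam_overlaps_fully(self):
        a = make_exam(date="d0")
        b = make_exam(date="d1")
        res = intra_individual_consistency([a, b])
        for vals in res.per_level.values():
            assert vals == [pytest.approx(1.0)]
        assert consistency_grade(res.pooled_median) == "excellent"

    def test_three_exams_give_two_pairs_per_level(self, rng):
        exams = [
            make_exam(date=f"d{i}", values=list(rng.normal(-300, 50, 500))) for i in range(3)
        ]
        res = intra_individual_consistency(exams)
        for vals in res.per_level.values():
            assert len(vals) == 2

    def test_fewer_than_two_exams_is_empty(self):
        res = intra_individual_consistency([make_exam()])
        assert res.pooled_median is None
        assert res.all_values() == []

    def test_pairs_follow_date_order(self, rng):
        # a distant middle exam must appear in both consecutive pairs
        base = list(rng.normal(-300, 30, 2000))
        far = list(rng.normal(-100, 30, 2000))
        exams = [
            make_exam(date="d0", values=base, levels=("maximum",)),
            make_exam(date="d1", values=far, levels=("maximum",)),
            make_exam(date="d2", values=base, levels=("maximum",)),
        ]
        res = intra_individual_consistency(exams, levels=("maximum",))
        assert all(v < 0.2 for v in res.per_level["maximum"])


class TestPairwiseGroupOverlap:
    def _averages(self, rng):
        out = {}
        for s in SEXES:
            for i, band in enumerate(AGE_BANDS):
                values = rng.normal(-400 + 60 * i, 50, 3000)
                from vncamarrow.histogram import normalize

                out[DemographicGroup(s, band)] = normalize(compute_histogram(values))
        return out

    def test_symmetric_with_unit_diagonal(self, rng):
        mat = pairwise_group_overlap(self._averages(rng), level="maximum")
        assert mat.shape == (8, 8)
        np.testing.assert_allclose(np.diag(mat.values), 1.0)
        np.testing.assert_allclose(mat.values, mat.values.T)
        assert ((mat.values >= 0) & (mat.values <= 1 + 1e-12)).all()

    def test_missing_group_yields_nan_row_and_column(self, rng):
        averages = self._averages(rng)
        missing = DemographicGroup("female", ">80")
        del averages[missing]
        mat = pairwise_group_overlap(averages)
        assert mat.loc[missing.label].isna().all()
        assert mat[missing.label].isna().all()
        assert mat.drop(index=missing.label, columns=missing.label).notna().all().all()


class TestClassifyExam:
    def test_exam_above_matched_p95(self, reference_table):
        exam = make_exam(sex="female", age=45, values=[-150.0] * 100)
        res = classify_exam(exam, reference_table, "maximum")
        assert res.category == "above-95th-percentile"
        assert res.margin_hu == pytest.approx(-147.5 - (-212.5))

    def test_same_attenuation_physiological_in_elderly(self, reference_table):
        exam = make_exam(sex="female", age=85, values=[-150.0] * 100)
        res = classify_exam(exam, reference_table, "maximum")
        assert res.category == "within-reference"

    def test_statistic_exactly_at_p95_is_within(self, reference_table):
        # bin center -212.5 equals the reference P95; strict '>' keeps it inside
        exam = make_exam(sex="female", age=45, values=[-212.4] * 10)
        res = classify_exam(exam, reference_table, "maximum")
        assert res.statistic_hu == -212.5
        assert res.category == "within-reference"

    def test_upward_shift_never_moves_above_to_within(self, reference_table):
        # monotonicity: adding +delta to every value can only raise the statistic
        base = np.array([-250.0] * 50)
        last = None
        for delta in (0.0, 20.0, 50.0, 100.0):
            exam = make_exam(sex="female", age=45, values=list(base + delta))
            res = classify_exam(exam, reference_table, "maximum")
            if last == "above-95th-percentile":
                assert res.category == "above-95th-percentile"
            last = res.category

    def test_far_below_reference_support_flagged(self, reference_table):
        exam = make_exam(sex="male", age=30, values=[-990.0] * 10)
        res = classify_exam(exam, reference_table, "maximum")
        assert res.category == "below-reference-support"

    def test_unbanded_age_rejected(self, reference_table):
        exam = make_exam(age=19)
        with pytest.raises(UnbandedAgeError):
            classify_exam(exam, reference_table, "maximum")

    def test_p95_statistic_exposed(self, reference_table):
        exam = make_exam(sex="female", age=45, values=list(np.linspace(-500, -300, 200)))
        res = classify_exam(exam, reference_table, "maximum", statistic="p95")
        assert res.statistic == "p95"
        expected = histogram_statistics(exam.histograms["maximum"]).p95
        assert res.statistic_hu == expected


def test_group_average_histograms_skips_unbanded(rng):
    exams = [
        make_exam(pid="A", age=30, values=list(rng.normal(-400, 40, 1000))),
        make_exam(pid="B", age=19, values=list(rng.normal(-100, 40, 1000))),
    ]
    averages = group_average_histograms(exams, "maximum")
    assert list(averages) == [DemographicGroup("female", "21-40")]
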