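"""Cohort statistics: box plots, per-point/region summaries, accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucoct.aggregate import (SubjectSeriesResult, make_boxplot_data,
                              study_accounting, summarize_point,
                              summarize_region)
from mucoct.geometry import ScanGeometry
from mucoct.io_formats import StudyMetadata, fmt_pct
from mucoct.regions import REFERENCE_ACCESS_PATTERN


def _result(subject, mp, thickness, sex="unspecified", age="unspecified",
            ratio=None, rows=None):
    return SubjectSeriesResult(subject_id=subject, measurement_point=mp,
                               sex=sex, age_group=age,
                               thickness_series_mean=thickness,
                               vessel_ratio=ratio, criteria_rows=rows or [],
                               image_count=5)


class TestBoxplot:
    def test_five_value_sample(self):
        """{1..5} under interpolation between closest ranks: Q1=1.5, Q3=4.5."""
        s = make_boxplot_data([1, 2, 3, 4, 5])
        assert (s.minimum, s.q1, s.median, s.q3, s.maximum, s.mean) == \
            (1, 1.5, 3, 4.5, 5, 3)

    def test_constant_vector(self):
        s = make_boxplot_data([7.0] * 4)
        assert s.minimum == s.q1 == s.median == s.q3 == s.maximum == 7.0
        assert s.sd == 0.0

    def test_singleton(self):
        s = make_boxplot_data([42.0])
        assert s.minimum == s.q1 == s.median == s.q3 == s.maximum == 42.0
        assert s.n == 1 and s.sd == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            make_boxplot_data([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    def test_order_invariants(self, values):
        s = make_boxplot_data(values)
        assert s.minimum <= s.q1 <= s.median <= s.q3 <= s.maximum


class TestSummarizePoint:
    def test_three_subject_arithmetic(self):
        entry = summarize_point([_result("S1", "MP9", 100.0),
                                 _result("S2", "MP9", 120.0),
                                 _result("S3", "MP9", 140.0)])
        assert entry.overall.mean == 120.0
        assert entry.overall.sd == pytest.approx(20.0)

    def test_single_subject_sd_zero(self):
        entry = summarize_point([_result("S1", "MP9", 100.0)])
        assert entry.overall.n == 1 and entry.overall.sd == 0.0

    def test_mixed_points_rejected(self):
        with pytest.raises(ValueError):
            summarize_point([_result("S1", "MP9", 1.0),
                             _result("S2", "MP10", 1.0)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_point([])

    def test_sd_recovery_at_cohort_size(self):
        """Subject means drawn with SD 15 recover a sample SD inside the
        n=47 chi-square interval [10, 20]."""
        rng = np.random.default_rng(12345)
        results = [_result(f"S{i}", "MP9", rng.normal(120, 15))
                   for i in range(47)]
        sd = summarize_point(results).overall.sd
        assert 10.0 <= sd <= 20.0


class TestSummarizeRegion:
    def test_pools_across_points(self):
        results = [_result("S1", "MP9", 100.0), _result("S2", "MP9", 120.0),
                   _result("S1", "MP10", 100.0), _result("S2", "MP10", 120.0)]
        region = summarize_region(results)
        assert region.region_id == "sublingual"
        assert region.overall.mean == 110.0
        assert set(region.per_mp) == {"MP9", "MP10"}
        assert region.image_count == 20

    def test_mixed_regions_rejected(self):
        with pytest.raises(ValueError):
            summarize_region([_result("S1", "MP9", 1.0),
                              _result("S1", "MP12", 1.0)])

    def test_sex_stratification_preserves_ordering(self):
        rng = np.random.default_rng(7)
        results = []
        for i in range(20):
            results.append(_result(f"M{i}", "MP12", rng.normal(218, 19), sex="male"))
            results.append(_result(f"F{i}", "MP12", rng.normal(175, 11), sex="female"))
        region = summarize_region(results)
        assert region.by_sex["male"].mean > region.by_sex["female"].mean

    def test_percentage_formatting_226_9(self):
        rows_a = [{"surface_integrity": "intact"}] * 226
        rows_b = [{"surface_integrity": "with_alterations"}] * 9
        region = summarize_region([_result("S1", "MP9", 120.0, rows=rows_a),
                                   _result("S2", "MP9", 120.0, rows=rows_b)])
        dist = region.criterion_pct["surface_integrity"]
        assert dist["intact"] == (226, 96.2)
        assert dist["with_alterations"] == (9, 3.8)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        cats = ["intact", "unsharp", "not_assessable"]
        rows = [{"bm_assessment": rng.choice(cats)} for _ in range(235)]
        region = summarize_region([_result("S1", "MP9", 120.0, rows=rows)])
        total = sum(p for _, p in region.criterion_pct["bm_assessment"].values())
        assert total == pytest.approx(100.0, abs=0.1)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        results = [_result(f"S{i}", "MP9", rng.normal(120, 15)) for i in range(10)]
        a = summarize_region(results)
        b = summarize_region(list(reversed(results)))
        assert a.overall.mean == pytest.approx(b.overall.mean, rel=1e-12)
        assert a.overall.sd == pytest.approx(b.overall.sd, rel=1e-12)
        assert (a.overall.q1, a.overall.median, a.overall.q3) == \
            (b.overall.q1, b.overall.median, b.overall.q3)


def _reference_metadata():
    """One metadata record per analyzed series, mirroring the reference
    cohort: 47 subjects, the published accessibility pattern, 25 male /
    22 female, age groups 14 / 30 / 3."""
    sexes = ["male"] * 25 + ["female"] * 22
    ages = ["<25"] * 14 + ["25-45"] * 30 + [">45"] * 3
    geometry = ScanGeometry()
    records = []
    for mp, n in REFERENCE_ACCESS_PATTERN.items():
        for i in range(n):
            records.append(StudyMetadata(
                subject_id=f"S{i + 1:03d}", measurement_point=mp,
                sex=sexes[i], age_group=ages[i], geometry=geometry))
    return records


class TestStudyAccounting:
    def test_reference_cohort_totals(self):
        acc = study_accounting(_reference_metadata())
        assert acc.total_images == 3560
        assert acc.per_area_images == {
            "labial": 705, "alveolar": 470, "buccal": 705, "sublingual": 705,
            "hard_palate": 235, "soft_palate_oropharynx": 570, "tonsil": 170}
        assert acc.accessibility["MP15"] == (29, 61.7)
        assert acc.accessibility["MP14"] == (40, 85.1)

    def test_duplicate_record_rejected(self):
        records = _reference_metadata()
        with pytest.raises(ValueError, match="duplicate"):
            study_accounting(records + [records[0]])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            study_accounting([])


def test_cohort_thickness_recovery_truth_mode():
    """A synthetic cohort analyzed in truth mode recovers the regional mean
    within one standard error (sublingual region, reduced cohort)."""
    from mucoct.cohort import iter_cohort
    from mucoct.pipeline import analyze_series

    geometry = ScanGeometry(n_rows=256, n_columns=240)
    results = []
    for series, truths, metadata in iter_cohort(
            n_subjects=16, measurement_points=["MP9"], seed=4,
            geometry=geometry):
        analysis = analyze_series(series, "truth", truths=truths)
        results.append(analysis.to_subject_result(metadata))
    region = summarize_region(results)
    preset_mean, preset_sd = 120.0, 15.0
    se = preset_sd / np.sqrt(len(results))
    # 1 SE plus the axial quantization step of the phantom
    assert abs(region.overall.mean - preset_mean) <= se + 5.0 / 1.37
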