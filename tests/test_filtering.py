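"""Noise/intensity filters, baseline correction and feature-level filters."""

import numpy as np
import pytest

from lcmspipe.filtering import (
    RangeFilterParams,
    baseline_correct,
    exclusion_filter,
    intensity_threshold,
    range_filter,
    scan_width_filter,
)
from lcmspipe.model import Feature, IonMode, Sample, Scan, feature_area

from conftest import gaussian_trace, make_feature


@pytest.fixture
def mixed_sample():
    scans = (
        Scan(index=0, retention_time=0.0, mz=np.array([100.0, 200.0]),
             intensity=np.array([50.0, 150.0]), centroided=True),
        Scan(index=1, retention_time=1.0, mz=np.array([100.0]),
             intensity=np.array([150.0]), centroided=True),
    )
    return Sample(id="m", scans=scans)


class TestIntensityThreshold:
    def test_zero_threshold_is_identity(self, mixed_sample):
        out = intensity_threshold(mixed_sample, 0.0)
        assert [len(s) for s in out.scans] == [2, 1]

    def test_above_global_max_empties_scans(self, mixed_sample):
        out = intensity_threshold(mixed_sample, 1e9)
        assert len(out.scans) == 2
        assert all(len(s) == 0 for s in out.scans)

    def test_mixed_pairs(self, mixed_sample):
        out = intensity_threshold(mixed_sample, 100.0)
        assert out.scans[0].intensity.tolist() == [150.0]
        assert out.scans[0].mz.tolist() == [200.0]

    def test_idempotent(self, mixed_sample):
        once = intensity_threshold(mixed_sample, 100.0)
        twice = intensity_threshold(once, 100.0)
        for a, b in zip(once.scans, twice.scans):
            assert np.array_equal(a.intensity, b.intensity)


class TestBaselineCorrect:
    def test_zero_trace_unchanged(self):
        f = Feature(id=0, mz=100.0, times=np.arange(10.0),
                    intensities=np.zeros(10), rt=0.0)
        out = baseline_correct(f)
        assert np.array_equal(out.intensities, np.zeros(10))

    def test_constant_offset_removed_within_5_percent(self):
        times, clean = gaussian_trace(50.0, 5.0, 1e5, 0.0, 100.0)
        f_clean = Feature(id=0, mz=100.0, times=times, intensities=clean, rt=50.0)
        offset = clean + 5e3
        f = Feature(id=0, mz=100.0, times=times, intensities=offset, rt=50.0)
        out = baseline_correct(f)
        ratio = feature_area(out) / feature_area(f_clean)
        assert 0.95 <= ratio <= 1.05
        assert np.array_equal(out.times, f.times) and out.rt == f.rt

    def test_linear_drift_keeps_apex_time(self):
        times, clean = gaussian_trace(40.0, 4.0, 8e4, 0.0, 100.0)
        drift = clean + 30.0 * times
        f = Feature(id=0, mz=100.0, times=times, intensities=drift, rt=40.0)
        out = baseline_correct(f)
        assert times[np.argmax(out.intensities)] == 40.0
        assert np.all(out.intensities >= 0)

    def test_short_feature_passes_through(self):
        f = Feature(id=0, mz=100.0, times=[0.0, 1.0, 2.0],
                    intensities=[1.0, 5.0, 1.0], rt=1.0)
        assert baseline_correct(f) is f


class TestRangeFilter:
    def test_covering_window_is_identity(self, mixed_sample):
        params = RangeFilterParams(1.0, 1e4, 0.0, 1e4)
        out = range_filter(mixed_sample, params)
        assert [len(s) for s in out.scans] == [2, 1]

    def test_empty_intersection(self, mixed_sample):
        params = RangeFilterParams(1.0, 10.0, 500.0, 600.0)
        assert len(range_filter(mixed_sample, params).scans) == 0

    def test_inclusive_upper_bound(self, mixed_sample):
        params = RangeFilterParams(100.0, 200.0, 0.0, 1.0)
        out = range_filter(mixed_sample, params)
        assert out.scans[0].mz.tolist() == [100.0, 200.0]  # mz == mz_max kept

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            RangeFilterParams(10.0, 1.0, 0.0, 1.0)


class TestScanWidthFilter:
    @pytest.fixture
    def widths(self):
        def feature_of_width(n, fid):
            return Feature(id=fid, mz=100.0 + fid,
                           times=np.arange(n, dtype=float),
                           intensities=np.full(n, 10.0), rt=0.0)
        return [feature_of_width(n, i) for i, n in enumerate([3, 4, 1, 10])]

    def test_narrow_main_peak_removed_at_4(self, widths):
        survivors = scan_width_filter(widths, 4)
        assert [len(f.times) for f in survivors] == [4, 10]

    def test_recovered_at_less_stringent_3(self, widths):
        survivors = scan_width_filter(widths, 3)
        assert [len(f.times) for f in survivors] == [3, 4, 10]

    def test_min_one_is_identity(self, widths):
        assert scan_width_filter(widths, 1) == widths

    def test_monotone_and_idempotent(self, widths):
        at4 = scan_width_filter(widths, 4)
        at5 = scan_width_filter(widths, 5)
        assert set(f.id for f in at5) <= set(f.id for f in at4)
        assert scan_width_filter(at4, 4) == at4


class TestExclusionFilter:
    def test_empty_list_is_identity(self):
        feats = [make_feature(0, 149.02332, 50.0)]
        assert exclusion_filter(feats, [], 10.0) == feats

    def test_exact_mass_removed(self):
        feats = [make_feature(0, 149.02332, 50.0), make_feature(1, 200.0, 60.0)]
        out = exclusion_filter(feats, [149.02332], 10.0)
        assert [f.id for f in out] == [1]

    def test_50_ppm_away_retained(self):
        mz = 149.02332 * (1 + 50e-6)
        feats = [make_feature(0, mz, 50.0)]
        assert exclusion_filter(feats, [149.02332], 10.0) == feats
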