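"""Retention-time alignment and the cross-sample feature matrix."""

import numpy as np
import pytest

from lcmspipe.alignment import (
    FeatureMatrix,
    MatrixGroup,
    TimeMap,
    apply_time_map,
    build_matrix,
    estimate_rt_shift,
)
from lcmspipe.io import write_feature_matrix
from lcmspipe.model import feature_area

from conftest import make_feature


def random_features(rng, n=30, rt_shift=0.0, rt_jitter=0.0, masses=None):
    masses = masses if masses is not None else rng.uniform(100, 600, n)
    rts = rng.uniform(100, 800, n) if not hasattr(masses, "_rts") else None
    feats = []
    for i, mz in enumerate(masses):
        rt = 100.0 + i * 20.0 + rt_shift + (rng.normal(0, rt_jitter) if rt_jitter else 0.0)
        feats.append(make_feature(i, float(mz), rt,
                                  apex=float(rng.uniform(1e4, 1e5))))
    return feats


class TestEstimateRtShift:
    def test_identity_when_target_equals_reference(self):
        rng = np.random.default_rng(0)
        feats = random_features(rng)
        tmap = estimate_rt_shift(feats, feats)
        t = np.linspace(100, 700, 50)
        assert np.max(np.abs(tmap(t) - t)) < 1e-6

    def test_uniform_shift_recovered(self):
        rng = np.random.default_rng(1)
        masses = rng.uniform(100, 600, 30)
        reference = random_features(rng, masses=masses)
        target = [make_feature(f.id, f.mz, f.rt + 10.0, apex=f.apex_intensity)
                  for f in reference]
        tmap = estimate_rt_shift(reference, target, rt_window=30.0)
        grid = np.linspace(150, 650, 100)
        shifts = grid - tmap(grid)
        assert abs(np.median(shifts) - 10.0) <= 0.5

    def test_no_mass_overlap_falls_back_to_identity(self, caplog):
        rng = np.random.default_rng(2)
        reference = random_features(rng, n=10, masses=rng.uniform(100, 300, 10))
        target = random_features(rng, n=10, masses=rng.uniform(400, 600, 10))
        with caplog.at_level("WARNING"):
            tmap = estimate_rt_shift(reference, target)
        assert tmap.is_identity
        assert any("identity" in r.message for r in caplog.records)

    def test_map_is_monotone(self):
        rng = np.random.default_rng(3)
        masses = rng.uniform(100, 600, 40)
        reference = random_features(rng, masses=masses)
        target = [make_feature(f.id, f.mz, f.rt * 1.02 + 5.0, apex=f.apex_intensity)
                  for f in reference]
        tmap = estimate_rt_shift(reference, target, rt_window=40.0)
        t = np.linspace(50, 900, 200)
        assert np.all(np.diff(tmap(t)) >= 0)

    def test_apply_time_map_shifts_times_and_rt(self):
        f = make_feature(0, 200.0, 100.0)
        mapped = apply_time_map([f], TimeMap([0.0, 1000.0], [10.0, 1010.0]))[0]
        assert mapped.rt == pytest.approx(110.0)
        assert np.allclose(mapped.times, f.times + 10.0)


class TestBuildMatrix:
    def test_shared_compound_forms_one_complete_group(self):
        per_sample = {
            sid: [make_feature(0, 300.0, 150.0)] for sid in ("a", "b", "c")
        }
        matrix = build_matrix(per_sample)
        assert len(matrix.groups) == 1
        assert np.all(~np.isnan(matrix.values))
        expected = feature_area(per_sample["a"][0])
        assert matrix.values[0].tolist() == [expected] * 3

    def test_compound_in_one_sample_leaves_missing_cells(self):
        per_sample = {
            "a": [make_feature(0, 300.0, 150.0)],
            "b": [],
        }
        matrix = build_matrix(per_sample)
        assert matrix.values.shape == (1, 2)
        assert not np.isnan(matrix.values[0, 0])
        assert np.isnan(matrix.values[0, 1])

    def test_single_sample_one_group_per_feature(self):
        rng = np.random.default_rng(4)
        feats = random_features(rng, n=12)
        matrix = build_matrix({"only": feats})
        assert len(matrix.groups) == 12

    def test_same_sample_features_never_share_a_group(self):
        # two co-eluting same-mass features from one sample must found
        # two groups even though they are within tolerance
        f1 = make_feature(0, 300.0, 150.0, apex=1e5)
        f2 = make_feature(1, 300.0, 150.5, apex=9e4)
        matrix = build_matrix({"a": [f1, f2]})
        assert len(matrix.groups) == 2

    def test_groups_ordered_by_rt_then_mz(self):
        feats = [make_feature(0, 400.0, 500.0), make_feature(1, 200.0, 100.0),
                 make_feature(2, 500.0, 100.0)]
        matrix = build_matrix({"a": feats}, rt_tol=1.0)
        assert [g.mz for g in matrix.groups] == [200.0, 500.0, 400.0]


class TestWriteFeatureMatrix:
    def test_two_by_two_csv(self, tmp_path):
        matrix = FeatureMatrix(
            groups=(MatrixGroup(0, 200.0, 100.0, "glucose"),
                    MatrixGroup(1, 300.0, 200.0)),
            sample_ids=("s1", "s2"),
            values=np.array([[1.5, 2.5], [3.5, np.nan]]),
        )
        path = tmp_path / "matrix.csv"
        write_feature_matrix(matrix, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 3
        assert lines[0] == "group_id,mz,rt,label,s1,s2"
        assert lines[1].split(",") == ["0", "200.0", "100.0", "glucose", "1.5", "2.5"]
        assert lines[2].endswith(",")  # missing cell is empty

    def test_empty_matrix_writes_header_only(self, tmp_path):
        matrix = FeatureMatrix(groups=(), sample_ids=("s1",),
                               values=np.empty((0, 1)))
        path = tmp_path / "empty.csv"
        write_feature_matrix(matrix, path)
        assert path.read_text().strip() == "group_id,mz,rt,label,s1"
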