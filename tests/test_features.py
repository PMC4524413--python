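"""Trace building from centroided scans and chromatographic deconvolution."""

import numpy as np
import pytest

from lcmspipe.features import (
    DeconvolutionParams,
    ProfileDataError,
    TraceParams,
    deconvolve,
    deconvolve_all,
    extract_features,
)
from lcmspipe.io import read_mzml
from lcmspipe.model import Feature, IonMode, Sample, Scan
from lcmspipe.synthetic import CompoundSpec, NoiseSpec, generate_sample

from conftest import gaussian_trace


def stick_sample(traces, times, mode=IonMode.POSITIVE):
    """Build a centroided sample from {mz: intensity-vector} traces."""
    scans = []
    for i, t in enumerate(times):
        mz, inten = [], []
        for m, profile in traces.items():
            if profile[i] > 0:
                mz.append(m)
                inten.append(profile[i])
        order = np.argsort(mz)
        scans.append(Scan(index=i, retention_time=t,
                          mz=np.asarray(mz)[order] if mz else np.empty(0),
                          intensity=np.asarray(inten)[order] if mz else np.empty(0),
                          ion_mode=mode, centroided=True))
    return Sample(id="s", scans=tuple(scans))


class TestExtractFeatures:
    def test_single_compound_noise_free(self, tmp_path):
        c = CompoundSpec("x", 300.0, rt=50.0, peak_sigma=3.0, apex_intensity=1e5,
                         adducts=("M+H",))
        path, manifest = generate_sample([c], NoiseSpec(seed=0), IonMode.POSITIVE,
                                         tmp_path / "one.mzML", scan_interval=1.0,
                                         duration=100.0)
        feats = extract_features(read_mzml(path), TraceParams(tol_ppm=10.0))
        assert len(feats) == 1
        truth_mz = manifest["mz"].iloc[0]
        assert abs(feats[0].mz - truth_mz) / truth_mz * 1e6 <= 10.0
        assert feats[0].rt == 50.0

    def test_ten_scan_elution_width(self):
        times = np.arange(10.0)
        traces = {250.0: np.full(10, 1e4)}
        feats = extract_features(stick_sample(traces, times))
        assert len(feats) == 1
        assert len(feats[0].times) == 10

    def test_empty_sample(self):
        assert extract_features(Sample(id="e", scans=())) == []

    def test_close_masses_resolved_by_tolerance(self):
        times = np.arange(8.0)
        mz_a = 400.0
        mz_b = 400.0 * (1 + 100e-6)  # 100 ppm away
        traces = {mz_a: np.full(8, 1e4), mz_b: np.full(8, 2e4)}
        feats = extract_features(stick_sample(traces, times), TraceParams(tol_ppm=5.0))
        assert len(feats) == 2
        assert feats[0].mz == pytest.approx(mz_a)
        assert feats[1].mz == pytest.approx(mz_b)
        # even at a huge tolerance, one trace takes at most one centroid per
        # scan, so co-occurring ions stay separate
        wide = extract_features(stick_sample(traces, times), TraceParams(tol_ppm=300.0))
        assert len(wide) == 2

    def test_profile_scan_rejected(self):
        scan = Scan(index=0, retention_time=0.0, mz=np.array([1.0, 2.0]),
                    intensity=np.array([1.0, 1.0]), centroided=False)
        with pytest.raises(ProfileDataError):
            extract_features(Sample(id="p", scans=(scan,)))

    def test_gap_tolerance_bridges_missing_scan(self):
        times = np.arange(9.0)
        profile = np.array([0, 1e4, 1e4, 0, 1e4, 1e4, 0, 0, 0])
        feats = extract_features(stick_sample({300.0: profile}, times),
                                 TraceParams(max_gap_scans=1))
        assert len(feats) == 1
        feats2 = extract_features(stick_sample({300.0: profile}, times),
                                  TraceParams(max_gap_scans=0))
        assert len(feats2) == 2

    def test_deterministic(self, tmp_path):
        c = CompoundSpec("x", 180.0, rt=40.0, peak_sigma=3.0, apex_intensity=5e4,
                         adducts=("M+H", "M+Na"), isotope_ratios=(0.14,))
        path, _ = generate_sample([c], NoiseSpec(seed=2, chemical_noise_density=2.0,
                                                 noise_intensity_scale=300.0),
                                  IonMode.POSITIVE, tmp_path / "d.mzML",
                                  scan_interval=1.0, duration=80.0)
        sample = read_mzml(path)
        a = extract_features(sample)
        b = extract_features(sample)
        assert len(a) == len(b)
        for fa, fb in zip(a, b):
            assert fa.mz == fb.mz
            assert np.array_equal(fa.intensities, fb.intensities)


def two_peak_trace(sep, sigma=5.0, apex1=1e5, apex2=8e4):
    t = np.arange(0.0, 60.0 + sep, 1.0)
    y = (apex1 * np.exp(-0.5 * ((t - 25.0) / sigma) ** 2)
         + apex2 * np.exp(-0.5 * ((t - 25.0 - sep) / sigma) ** 2))
    return Feature(id=0, mz=200.0, times=t, intensities=y,
                   rt=t[int(np.argmax(y))])


class TestDeconvolve:
    def test_single_gaussian_unchanged(self):
        t, y = gaussian_trace(30.0, 5.0, 1e5, 0.0, 60.0)
        f = Feature(id=0, mz=200.0, times=t, intensities=y, rt=30.0)
        parts = deconvolve(f)
        assert len(parts) == 1
        assert np.array_equal(parts[0].intensities, y)

    def test_resolved_pair_splits_between_apexes(self):
        f = two_peak_trace(sep=30.0)  # valley ~10% of the lower apex
        parts = deconvolve(f, DeconvolutionParams(valley_fraction=0.5))
        assert len(parts) == 2
        assert parts[0].rt == pytest.approx(25.0, abs=1.5)
        assert parts[1].rt == pytest.approx(55.0, abs=1.5)
        assert parts[0].times[-1] < parts[1].times[0]

    def test_merged_pair_kept_whole(self):
        f = two_peak_trace(sep=6.0)  # valley ~90% of the lower apex
        assert len(deconvolve(f, DeconvolutionParams(valley_fraction=0.5))) == 1

    def test_raw_intensity_conserved_across_splits(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            sep = float(rng.uniform(5.0, 45.0))
            f = two_peak_trace(sep, sigma=float(rng.uniform(3.0, 7.0)),
                               apex1=float(rng.uniform(1e4, 1e5)),
                               apex2=float(rng.uniform(1e4, 1e5)))
            parts = deconvolve(f)
            assert sum(p.intensities.sum() for p in parts) == pytest.approx(
                f.intensities.sum(), rel=1e-12)
            # children partition the time axis
            all_times = np.concatenate([p.times for p in parts])
            assert np.array_equal(all_times, f.times)

    def test_deconvolve_all_renumbers_consecutively(self):
        feats = [two_peak_trace(40.0), two_peak_trace(6.0)]
        out = deconvolve_all(feats)
        assert [f.id for f in out] == list(range(len(out)))
        assert len(out) == 3
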