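"""Scan- and feature-level cleanup filters.

Intensity thresholding and m/z / rt range cropping act on whole samples;
baseline correction, the scan-width filter and the contaminant exclusion
filter act on extracted features.  All filters are pure and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .model import Feature, Sample, Scan, feature_width_scans

__all__ = [
    "RangeFilterParams",
    "intensity_threshold",
    "baseline_correct",
    "range_filter",
    "scan_width_filter",
    "exclusion_filter",
]


@dataclass(frozen=True)
class RangeFilterParams:
    """Inclusive m/z and rt windows for cropping a sample."""

    mz_min: float
    mz_max: float
    rt_min: float
    rt_max: float

    def __post_init__(self) -> None:
        if not (self.mz_min < self.mz_max and self.rt_min < self.rt_max):
            raise ValueError("range bounds must satisfy min < max")


def intensity_threshold(sample: Sample, min_intensity: float) -> Sample:
    """Remove every pair below ``min_intensity``; scans are kept even if emptied."""
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    scans = []
    for s in sample.scans:
        keep = s.intensity >= min_intensity
        scans.append(replace(s, mz=s.mz[keep], intensity=s.intensity[keep]))
    return Sample(id=sample.id, scans=tuple(scans), metadata=sample.metadata)


def _als_baseline(y: np.ndarray, asymmetry: float, smoothness: float,
                  max_iter: int = 20, tol: float = 1e-6) -> np.ndarray:
    """Asymmetric-least-squares baseline of a trace.

    Penalized smoother with a second-difference penalty (weight
    ``smoothness``); points above the running baseline get weight
    ``asymmetry``, points below get ``1 - asymmetry``, iterated until the
    weights stop changing.
    """
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = smoothness * (d.T @ d)
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        solver_matrix = sparse.diags(w) + penalty
        z = spsolve(sparse.csc_matrix(solver_matrix), w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    return z


def baseline_correct(feature: Feature, asymmetry: float = 0.01,
                     smoothness: float = 1e4) -> Feature:
    """Subtract an asymmetric-least-squares baseline from a feature trace.

    Features narrower than 5 scans pass through unchanged.  Negative
    residuals are clamped to zero; times and rt are untouched.
    """
    if not 0.0 < asymmetry < 1.0:
        raise ValueError("asymmetry must be in (0, 1)")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if feature.times.size < 5:
        return feature
    baseline = _als_baseline(feature.intensities, asymmetry, smoothness)
    corrected = np.clip(feature.intensities - baseline, 0.0, None)
    return replace(feature, intensities=corrected)


def range_filter(sample: Sample, params: RangeFilterParams) -> Sample:
    """Crop a sample to inclusive m/z and rt windows.

    Scans outside [rt_min, rt_max] are dropped; pairs outside
    [mz_min, mz_max] are dropped (bounds inclusive on both ends).
    """
    scans = []
    for s in sample.scans:
        if not params.rt_min <= s.retention_time <= params.rt_max:
            continue
        keep = (s.mz >= params.mz_min) & (s.mz <= params.mz_max)
        scans.append(replace(s, mz=s.mz[keep], intensity=s.intensity[keep]))
    return Sample(id=sample.id, scans=tuple(scans), metadata=sample.metadata)


def scan_width_filter(features: Sequence[Feature], min_scans: int) -> list[Feature]:
    """Drop features spanning fewer than ``min_scans`` scans; order preserved."""
    if min_scans < 1:
        raise ValueError("min_scans must be >= 1")
    return [f for f in features if feature_width_scans(f) >= min_scans]


def exclusion_filter(features: Sequence[Feature], masses: Sequence[float],
                     tol_ppm: float) -> list[Feature]:
    """Drop features whose m/z lies within ``tol_ppm`` of any exclusion mass."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    masses = np.asarray(list(masses), dtype=float)
    if masses.size == 0:
        return list(features)
    out = []
    for f in features:
        ppm = np.abs(masses - f.mz) / f.mz * 1e6
        if not np.any(ppm <= tol_ppm):
            out.append(f)
    return out
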