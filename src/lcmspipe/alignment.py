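"""Cross-sample retention-time alignment and the aligned feature matrix.

Chromatographic retention times drift between runs.  Alignment here is
landmark-based: mutual nearest-neighbour feature matches between a target
run and a reference run (within a ppm mass tolerance and an rt search
window) provide landmark pairs, and a monotone piecewise-linear time map
is fitted through per-bin medians of those landmarks.  Corrected features
from all runs are then grouped greedily (most intense first) into matrix
groups by m/z and rt proximity, one feature per sample per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .model import AnnotationKind, Feature, feature_area

logger = logging.getLogger(__name__)

__all__ = [
    "MatrixGroup",
    "FeatureMatrix",
    "TimeMap",
    "estimate_rt_shift",
    "apply_time_map",
    "build_matrix",
]

MAX_LANDMARKS = 50
MIN_LANDMARKS = 5
N_BINS = 10


@dataclass(frozen=True)
class MatrixGroup:
    id: int
    mz: float
    rt: float
    label: str = ""


@dataclass(frozen=True)
class FeatureMatrix:
    """Aligned feature groups x samples intensity table (NaN = missing)."""

    groups: tuple[MatrixGroup, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.groups), len(self.sample_ids)):
            raise ValueError("values shape must be (n_groups, n_samples)")
        present = values[~np.isnan(values)]
        if np.any(present < 0):
            raise ValueError("present intensities must be non-negative")


class TimeMap:
    """Monotone piecewise-linear map from target rt to reference rt.

    Between knots the map interpolates linearly; beyond the outermost
    knots it extrapolates with the edge shift (constant offset), which
    keeps it monotone non-decreasing everywhere.
    """

    def __init__(self, knots_x: Sequence[float], knots_y: Sequence[float]):
        x = np.asarray(knots_x, dtype=float)
        y = np.maximum.accumulate(np.asarray(knots_y, dtype=float))
        if x.size != y.size or x.size < 1:
            raise ValueError("need equal-length, non-empty knot vectors")
        if np.any(np.diff(x) <= 0):
            raise ValueError("knot x values must be strictly increasing")
        self.knots_x = x
        self.knots_y = y

    @classmethod
    def identity(cls) -> "TimeMap":
        return cls([0.0, 1.0], [0.0, 1.0])

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.knots_x, self.knots_y))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        x, y = self.knots_x, self.knots_y
        out = np.interp(t, x, y)
        out = np.where(t < x[0], t + (y[0] - x[0]), out)
        out = np.where(t > x[-1], t + (y[-1] - x[-1]), out)
        return float(out) if out.ndim == 0 else out


def _mutual_nearest_pairs(
    reference: Sequence[Feature],
    target: Sequence[Feature],
    tol_ppm: float,
    rt_window: float,
) -> list[tuple[Feature, Feature]]:
    """Unique mutual nearest matches (by |delta rt| within a ppm gate)."""
    ref_mz = np.array([f.mz for f in reference])
    tgt_mz = np.array([f.mz for f in target])
    ref_rt = np.array([f.rt for f in reference])
    tgt_rt = np.array([f.rt for f in target])

    def nearest(mz, rt, other_mz, other_rt):
        ppm = np.abs(other_mz - mz) / mz * 1e6
        ok = (ppm <= tol_ppm) & (np.abs(other_rt - rt) <= rt_window)
        if not np.any(ok):
            return -1
        idx = np.flatnonzero(ok)
        return int(idx[np.argmin(np.abs(other_rt[idx] - rt))])

    t_to_r = [nearest(tgt_mz[i], tgt_rt[i], ref_mz, ref_rt) for i in range(len(target))]
    r_to_t = [nearest(ref_mz[j], ref_rt[j], tgt_mz, tgt_rt) for j in range(len(reference))]
    pairs = []
    for ti, rj in enumerate(t_to_r):
        if rj >= 0 and r_to_t[rj] == ti:
            pairs.append((reference[rj], target[ti]))
    return pairs


def estimate_rt_shift(
    reference: Sequence[Feature],
    target: Sequence[Feature],
    tol_ppm: float = 5.0,
    rt_window: float = 30.0,
) -> TimeMap:
    """Fit a monotone piecewise-linear map from target rt onto reference rt.

    Landmarks are mutual nearest matches ranked by target apex intensity
    (top 50).  When the landmark deltas carry no drift trend (robust
    Theil-Sen slope near zero) the map is a constant offset, the median of
    all landmark deltas; otherwise it passes through landmark medians in
    up to 10 equal-count rt bins.  With fewer than 5 landmarks the
    identity map is returned with a warning.
    """
    if not reference or not target:
        raise ValueError("reference and target feature lists must be non-empty")
    pairs = _mutual_nearest_pairs(reference, target, tol_ppm, rt_window)
    pairs.sort(key=lambda p: p[1].apex_intensity, reverse=True)
    pairs = pairs[:MAX_LANDMARKS]
    if len(pairs) < MIN_LANDMARKS:
        logger.warning(
            "only %d landmark pairs (need %d); falling back to identity time map",
            len(pairs), MIN_LANDMARKS,
        )
        return TimeMap.identity()
    tgt = np.array([p[1].rt for p in pairs])
    ref = np.array([p[0].rt for p in pairs])
    order = np.argsort(tgt)
    tgt, ref = tgt[order], ref[order]
    deltas = ref - tgt
    # model selection: with no appreciable drift trend in the landmark
    # deltas (robust Theil-Sen slope ~ 0), a constant-offset map estimated
    # from ALL landmarks beats noisy per-bin knots
    if len(pairs) >= MIN_LANDMARKS and np.ptp(tgt) > 0:
        slope, _, _, _ = stats.theilslopes(deltas, tgt)
        if abs(slope) < 0.005:
            shift = float(np.median(deltas))
            t0, t1 = float(tgt[0]), float(tgt[-1])
            return TimeMap([t0, t1], [t0 + shift, t1 + shift])
    n_bins = min(N_BINS, len(pairs))
    knots_x, knots_y = [], []
    for chunk_x, chunk_y in zip(np.array_split(tgt, n_bins), np.array_split(ref, n_bins)):
        if chunk_x.size == 0:
            continue
        x = float(np.median(chunk_x))
        if knots_x and x <= knots_x[-1]:
            continue
        knots_x.append(x)
        knots_y.append(float(np.median(chunk_y)))
    if len(knots_x) < 2:
        shift = knots_y[0] - knots_x[0] if knots_x else 0.0
        return TimeMap([0.0, 1.0], [shift, 1.0 + shift])
    return TimeMap(knots_x, knots_y)


def apply_time_map(features: Sequence[Feature], tmap: TimeMap) -> list[Feature]:
    """Return features with times and rt mapped into the reference time base."""
    out = []
    for f in features:
        times = tmap(f.times)
        out.append(replace(f, times=times, rt=float(tmap(f.rt))))
    return out


def _identity_label(f: Feature) -> str:
    for a in f.annotations:
        if a.kind is AnnotationKind.IDENTITY:
            return a.label
    return ""


def build_matrix(
    per_sample_features: Mapping[str, Sequence[Feature]],
    tol_ppm: float = 5.0,
    rt_tol: float = 5.0,
    value: str = "area",
) -> FeatureMatrix:
    """Group rt-corrected features across samples into a feature matrix.

    Features are processed in descending apex intensity; each joins the
    nearest existing group within ``tol_ppm`` of the group's running mean
    m/z and ``rt_tol`` of its running mean rt, provided the group has no
    feature from that sample yet, else it founds a new group.  Cell values
    are trapezoidal peak areas (``value="height"`` switches to apex
    height); absent cells are NaN.  Groups are ordered by consensus rt
    then m/z.
    """
    if not per_sample_features:
        raise ValueError("need at least one sample")
    if value not in ("area", "height"):
        raise ValueError("value must be 'area' or 'height'")
    sample_ids = tuple(per_sample_features.keys())
    queue = [
        (sid, f) for sid in sample_ids for f in per_sample_features[sid]
    ]
    queue.sort(key=lambda p: (-p[1].apex_intensity, p[0], p[1].id))

    groups: list[dict] = []
    for sid, f in queue:
        best, best_ppm = None, np.inf
        for g in groups:
            if sid in g["members"]:
                continue
            ppm = abs(f.mz - g["mz"]) / g["mz"] * 1e6
            if ppm <= tol_ppm and abs(f.rt - g["rt"]) <= rt_tol and ppm < best_ppm:
                best, best_ppm = g, ppm
        if best is None:
            best = {"mz": f.mz, "rt": f.rt, "n": 0, "members": {}, "label": ""}
            groups.append(best)
        n = best["n"]
        best["mz"] = (best["mz"] * n + f.mz) / (n + 1) if n else f.mz
        best["rt"] = (best["rt"] * n + f.rt) / (n + 1) if n else f.rt
        best["n"] = n + 1
        best["members"][sid] = f
        if not best["label"]:
            best["label"] = _identity_label(f)

    groups.sort(key=lambda g: (g["rt"], g["mz"]))
    matrix_groups = tuple(
        MatrixGroup(id=i, mz=g["mz"], rt=g["rt"], label=g["label"])
        for i, g in enumerate(groups)
    )
    values = np.full((len(groups), len(sample_ids)), np.nan)
    for gi, g in enumerate(groups):
        for si, sid in enumerate(sample_ids):
            f = g["members"].get(sid)
            if f is not None:
                values[gi, si] = feature_area(f) if value == "area" else f.apex_intensity
    return FeatureMatrix(groups=matrix_groups, sample_ids=sample_ids, values=values)
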