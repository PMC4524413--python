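"""Ion-trace (feature) extraction from centroided scans, and deconvolution
of traces into individual chromatographic peaks.

Trace building is greedy: scans are visited in time order and every
centroid joins the open trace whose running intensity-weighted mean m/z
is nearest within a ppm tolerance (global-nearest assignment per scan, so
the result does not depend on the ordering of pairs within a scan).
Traces that stall for more than ``max_gap_scans`` consecutive MS1 scans
are closed.

Deconvolution smooths a trace with a Savitzky-Golay filter, finds local
maxima above a robust SNR gate, and splits the trace at any valley deep
enough relative to its lower neighbouring apex.  Children keep the RAW
(unsmoothed) intensities, so total intensity is conserved across splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .model import Feature, IonMode, Sample, characteristic_rt

logger = logging.getLogger(__name__)

__all__ = ["TraceParams", "DeconvolutionParams", "ProfileDataError",
           "extract_features", "deconvolve", "deconvolve_all"]

MAD_SCALE = 1.4826


class ProfileDataError(TypeError):
    """Raised when trace extraction meets a profile-mode scan."""


@dataclass(frozen=True)
class TraceParams:
    """Trace continuation tolerance (ppm), allowed gap (scans) and the
    minimum apex intensity for a trace to be kept."""

    tol_ppm: float = 10.0
    max_gap_scans: int = 1
    min_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if self.max_gap_scans < 0:
            raise ValueError("max_gap_scans must be >= 0")


@dataclass(frozen=True)
class DeconvolutionParams:
    """Savitzky-Golay window (odd, scans), the valley-to-lower-apex ratio
    below which a trace splits, and the apex SNR gate."""

    sg_window: int = 9
    valley_fraction: float = 0.5
    min_snr: float = 3.0

    def __post_init__(self) -> None:
        if self.sg_window < 5 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be an odd integer >= 5")
        if not 0.0 < self.valley_fraction <= 1.0:
            raise ValueError("valley_fraction must be in (0, 1]")


class _OpenTrace:
    __slots__ = ("mz", "weight", "times", "intensities", "last_ms1_pos")

    def __init__(self, mz: float, intensity: float, time: float, ms1_pos: int):
        self.mz = mz
        self.weight = max(intensity, 1e-30)
        self.times = [time]
        self.intensities = [intensity]
        self.last_ms1_pos = ms1_pos

    def add(self, mz: float, intensity: float, time: float, ms1_pos: int) -> None:
        w = max(intensity, 1e-30)
        self.mz = (self.mz * self.weight + mz * w) / (self.weight + w)
        self.weight += w
        self.times.append(time)
        self.intensities.append(intensity)
        self.last_ms1_pos = ms1_pos


def extract_features(sample: Sample, params: TraceParams = TraceParams()) -> list[Feature]:
    """Build ion traces from the centroided MS1 scans of a sample.

    Every centroid is assigned to at most one trace; traces below
    ``min_intensity`` at apex are discarded.  Returned features carry
    mz = intensity-weighted mean of member centroids and rt = apex time.
    """
    finished: list[Feature] = []
    open_traces: list[_OpenTrace] = []
    next_id = 0

    def close(trace: _OpenTrace, mode: IonMode) -> None:
        nonlocal next_id
        intensities = np.asarray(trace.intensities)
        if intensities.max() < params.min_intensity:
            return
        times = np.asarray(trace.times)
        finished.append(
            Feature(
                id=next_id,
                mz=trace.mz,
                times=times,
                intensities=intensities,
                rt=characteristic_rt(times, intensities),
                ion_mode=mode,
            )
        )
        next_id += 1

    mode = IonMode.UNKNOWN
    ms1_pos = -1
    for scan in sample.scans:
        if scan.ms_level != 1:
            continue
        if scan.centroided is False:
            raise ProfileDataError(
                f"scan {scan.index} is profile mode; centroid the sample first"
            )
        ms1_pos += 1
        mode = scan.ion_mode
        # close traces whose count of consecutive missed scans exceeds the gap
        still_open = []
        for tr in open_traces:
            if ms1_pos - tr.last_ms1_pos - 1 > params.max_gap_scans:
                close(tr, mode)
            else:
                still_open.append(tr)
        open_traces = still_open

        if not len(scan) :
            continue
        if open_traces:
            trace_mz = np.array([tr.mz for tr in open_traces])
            # candidate (distance, centroid, trace) triples within tolerance
            cand = []
            for ci in range(len(scan)):
                ppm = np.abs(trace_mz - scan.mz[ci]) / scan.mz[ci] * 1e6
                for ti in np.flatnonzero(ppm <= params.tol_ppm):
                    cand.append((ppm[ti], ci, int(ti)))
            cand.sort()
            used_c: set[int] = set()
            used_t: set[int] = set()
            for _, ci, ti in cand:
                if ci in used_c or ti in used_t:
                    continue
                used_c.add(ci)
                used_t.add(ti)
                open_traces[ti].add(float(scan.mz[ci]), float(scan.intensity[ci]),
                                    scan.retention_time, ms1_pos)
        else:
            used_c = set()
        for ci in range(len(scan)):
            if ci not in used_c:
                open_traces.append(
                    _OpenTrace(float(scan.mz[ci]), float(scan.intensity[ci]),
                               scan.retention_time, ms1_pos)
                )

    for tr in open_traces:
        close(tr, mode)
    finished.sort(key=lambda f: (f.mz, f.rt))
    return [Feature(id=i, mz=f.mz, times=f.times, intensities=f.intensities,
                    rt=f.rt, ion_mode=f.ion_mode) for i, f in enumerate(finished)]


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if y.size < window:
        return y.copy()
    return savgol_filter(y, window, polyorder=2)


def deconvolve(feature: Feature, params: DeconvolutionParams = DeconvolutionParams(),
               id_start: int | None = None) -> list[Feature]:
    """Split one trace into chromatographic peaks at deep valleys.

    Apexes are local maxima of the smoothed trace with SNR >= ``min_snr``
    (noise = 1.4826 x MAD of the smoothing residual); between adjacent
    apexes the trace splits where the smoothed minimum falls to
    ``valley_fraction`` of the lower apex or below.  The split point
    belongs to the earlier child.  Children keep raw intensities; a trace
    with a single apex is returned unchanged.
    """
    y = feature.intensities
    if y.size < 3:
        return [feature]
    smoothed = _smooth(y, params.sg_window)
    noise = MAD_SCALE * float(np.median(np.abs(smoothed - y)))

    interior = np.flatnonzero(
        (smoothed[1:-1] >= smoothed[:-2]) & (smoothed[1:-1] > smoothed[2:])
    ) + 1
    apexes = [i for i in interior
              if smoothed[i] > 0 and (noise == 0 or smoothed[i] / noise >= params.min_snr)]
    if len(apexes) <= 1:
        return [feature]

    split_points = []
    for a, b in zip(apexes, apexes[1:]):
        valley_idx = a + int(np.argmin(smoothed[a:b + 1]))
        lower_apex = min(smoothed[a], smoothed[b])
        if smoothed[valley_idx] <= params.valley_fraction * lower_apex:
            split_points.append(valley_idx)
    if not split_points:
        return [feature]

    children = []
    start = 0
    next_id = feature.id if id_start is None else id_start
    bounds = split_points + [y.size - 1]
    for end in bounds:
        times = feature.times[start:end + 1]
        intensities = y[start:end + 1]
        children.append(
            Feature(
                id=next_id,
                mz=feature.mz,
                times=times,
                intensities=intensities,
                rt=characteristic_rt(times, intensities),
                ion_mode=feature.ion_mode,
                annotations=feature.annotations,
            )
        )
        next_id += 1
        start = end + 1
    return children


def deconvolve_all(features: Sequence[Feature],
                   params: DeconvolutionParams = DeconvolutionParams()) -> list[Feature]:
    """Deconvolve every trace, renumbering child features consecutively."""
    out: list[Feature] = []
    for f in features:
        for child in deconvolve(f, params):
            if child.id != len(out):
                child = Feature(id=len(out), mz=child.mz, times=child.times,
                                intensities=child.intensities, rt=child.rt,
                                ion_mode=child.ion_mode, annotations=child.annotations)
            out.append(child)
    return out
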