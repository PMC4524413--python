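"""Shared fixtures: small synthetic traces, scans and samples."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from lcmspipe.model import Feature, IonMode, Sample, Scan, characteristic_rt

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def gaussian_trace(apex_time: float, sigma: float, apex: float,
                   t0: float, t1: float, dt: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(t0, t1, dt)
    return t, apex * np.exp(-0.5 * ((t - apex_time) / sigma) ** 2)


def make_feature(fid: int, mz: float, apex_time: float, sigma: float = 4.0,
                 apex: float = 1e5, t0: float | None = None, t1: float | None = None,
                 mode: IonMode = IonMode.POSITIVE, dt: float = 1.0) -> Feature:
    t0 = apex_time - 4 * sigma if t0 is None else t0
    t1 = apex_time + 4 * sigma if t1 is None else t1
    times, intensities = gaussian_trace(apex_time, sigma, apex, t0, t1, dt)
    return Feature(id=fid, mz=mz, times=times, intensities=intensities,
                   rt=characteristic_rt(times, intensities), ion_mode=mode)


@pytest.fixture
def centroid_sample() -> Sample:
    """Three-scan centroided sample holding one ion at m/z 200.1."""
    scans = []
    for i, (rt, inten) in enumerate([(10.0, 50.0), (11.0, 100.0), (12.0, 60.0)]):
        scans.append(Scan(index=i, retention_time=rt,
                          mz=np.array([150.0, 200.1]),
                          intensity=np.array([5.0, inten]),
                          ion_mode=IonMode.POSITIVE, centroided=True))
    return Sample(id="s1", scans=tuple(scans))
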