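"""Core LC-MS domain types and elementary geometric operations.

The in-memory hierarchy mirrors the entities passed between processing
steps of a stepwise LC-MS pipeline:

* :class:`Scan` -- one mass spectrum: sorted m/z--intensity pairs acquired
  at a retention time.
* :class:`Feature` -- one ion trace: the intensity of a single ion species
  followed across consecutive scans, with a characteristic retention time.
* :class:`FeatureSet` -- co-eluting features (adducts, isotopes, fragments)
  believed to belong to one compound, at an averaged retention time.
* :class:`Sample` -- the ordered scans of one LC-MS run.

All operations are pure: they never mutate their inputs, so any step's
output can be snapshotted to disk and execution resumed from it.

Units: m/z in Thomson, retention time in seconds, intensity in arbitrary
detector counts.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "IonMode",
    "AnnotationKind",
    "MzIntensityPair",
    "Annotation",
    "Scan",
    "Feature",
    "FeatureSet",
    "Sample",
    "characteristic_rt",
    "feature_area",
    "feature_width_scans",
    "xic",
]


class IonMode(enum.Enum):
    """Detected ion polarity; decides which adduct rules apply."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class AnnotationKind(enum.Enum):
    ISOTOPE = "isotope"
    ADDUCT = "adduct"
    FRAGMENT = "fragment"
    IDENTITY = "identity"


class MzIntensityPair(NamedTuple):
    """One (m/z, intensity) stick of a centroided spectrum."""

    mz: float
    intensity: float


@dataclass(frozen=True)
class Annotation:
    """A relational label on a feature (isotope/adduct/fragment/identity).

    ``partner_id`` names the feature this annotation relates to (the
    monoisotopic anchor for an isotope, the co-adduct for an adduct); it is
    required for all kinds except IDENTITY. ``score`` is a dimensionless
    confidence in [0, 1].
    """

    kind: AnnotationKind
    label: str
    partner_id: int | None = None
    score: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"annotation score must be in [0, 1], got {self.score}")
        if self.kind is not AnnotationKind.IDENTITY and self.partner_id is None:
            raise ValueError(f"{self.kind.value} annotation requires partner_id")


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class Scan:
    """One spectrum: m/z and intensity arrays at a retention time.

    ``mz`` is strictly ascending; ``centroided`` is True for stick spectra,
    False for profile mode, None when the source file did not say.
    ``precursor_mz`` is present exactly when ``ms_level > 1``.
    """

    index: int
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    ion_mode: IonMode = IonMode.UNKNOWN
    precursor_mz: float | None = None
    centroided: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", _as_float_array(self.mz, "mz"))
        object.__setattr__(self, "intensity", _as_float_array(self.intensity, "intensity"))
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.mz.size and (np.any(self.mz <= 0) or np.any(np.diff(self.mz) <= 0)):
            raise ValueError("mz values must be positive and strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.index < 0 or self.retention_time < 0:
            raise ValueError("index and retention_time must be non-negative")
        if self.ms_level < 1:
            raise ValueError("ms_level must be >= 1")
        if (self.precursor_mz is not None) != (self.ms_level > 1):
            raise ValueError("precursor_mz present exactly when ms_level > 1")

    @property
    def pairs(self) -> Iterator[MzIntensityPair]:
        for m, i in zip(self.mz, self.intensity):
            yield MzIntensityPair(float(m), float(i))

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class Feature:
    """One ion trace: intensity of one m/z followed across scans.

    ``rt`` is the characteristic retention time (apex) and always lies
    inside the trace's time span. ``annotations`` accumulates isotope,
    adduct, fragment and identity labels downstream.
    """

    id: int
    mz: float
    times: np.ndarray
    intensities: np.ndarray
    rt: float
    ion_mode: IonMode = IonMode.UNKNOWN
    annotations: tuple[Annotation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _as_float_array(self.times, "times"))
        object.__setattr__(
            self, "intensities", _as_float_array(self.intensities, "intensities")
        )
        if self.times.size != self.intensities.size or self.times.size < 1:
            raise ValueError("times and intensities must have equal length >= 1")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.mz > 0:
            raise ValueError("feature mz must be positive")
        if not (self.times[0] <= self.rt <= self.times[-1]):
            raise ValueError("rt must lie within the trace time span")

    @property
    def apex_intensity(self) -> float:
        return float(self.intensities.max())

    def with_annotations(self, extra: Sequence[Annotation]) -> "Feature":
        if not extra:
            return self
        return replace(self, annotations=self.annotations + tuple(extra))

    def has_kind(self, kind: AnnotationKind) -> bool:
        return any(a.kind is kind for a in self.annotations)


@dataclass(frozen=True)
class FeatureSet:
    """Co-eluting features believed to belong to one compound.

    ``rt`` equals the arithmetic mean of member characteristic retention
    times; ``neutral_mass`` is the consensus neutral mass once adduct
    annotation has established one.
    """

    id: int
    features: tuple[Feature, ...]
    rt: float
    neutral_mass: float | None = None

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("FeatureSet requires at least one feature")
        modes = {f.ion_mode for f in self.features}
        if len(modes) > 1:
            raise ValueError("FeatureSet members must share one ion mode")
        mean_rt = sum(f.rt for f in self.features) / len(self.features)
        if not math.isclose(self.rt, mean_rt, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("FeatureSet rt must equal the mean member rt")

    @property
    def ion_mode(self) -> IonMode:
        return self.features[0].ion_mode

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class Sample:
    """One LC-MS run: ordered scans plus run-level metadata."""

    id: str
    scans: tuple[Scan, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        indices = [s.index for s in self.scans]
        if indices != sorted(indices) or len(set(indices)) != len(indices):
            raise ValueError("scan indices must be unique and ascending")
        ms1_rts = [s.retention_time for s in self.scans if s.ms_level == 1]
        if any(b < a for a, b in zip(ms1_rts, ms1_rts[1:])):
            raise ValueError("MS1 retention times must be non-decreasing")

    @property
    def ion_modes(self) -> frozenset[IonMode]:
        return frozenset(s.ion_mode for s in self.scans)

    def ms1_scans(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 1]

    def __len__(self) -> int:
        return len(self.scans)


# ---------------------------------------------------------------------------
# elementary operations


def characteristic_rt(times, intensities) -> float:
    """Apex retention time of a trace: the time of maximum intensity.

    Ties break toward the earliest time (``argmax`` returns the first
    maximum of the scan-ordered trace).
    """
    t = np.asarray(times, dtype=float)
    i = np.asarray(intensities, dtype=float)
    if t.size == 0 or t.size != i.size:
        raise ValueError("times and intensities must be non-empty and equal length")
    return float(t[int(np.argmax(i))])


def feature_area(feature: Feature) -> float:
    """Trapezoidal integral of the trace (counts * seconds); 0 for a single point."""
    if feature.times.size < 2:
        return 0.0
    return float(np.trapezoid(feature.intensities, feature.times))


def feature_width_scans(feature: Feature) -> int:
    """Number of scans the trace spans."""
    return int(feature.times.size)


def xic(sample: Sample, mz: float, tol_ppm: float) -> tuple[np.ndarray, np.ndarray]:
    """Extracted ion chromatogram: per-MS1-scan summed intensity in a ppm window.

    Scans with no pair within ``tol_ppm`` of ``mz`` contribute zero.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    half = mz * tol_ppm * 1e-6
    times = []
    totals = []
    for scan in sample.ms1_scans():
        lo = np.searchsorted(scan.mz, mz - half, side="left")
        hi = np.searchsorted(scan.mz, mz + half, side="right")
        times.append(scan.retention_time)
        totals.append(float(scan.intensity[lo:hi].sum()))
    return np.asarray(times, dtype=float), np.asarray(totals, dtype=float)
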