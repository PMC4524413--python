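"""Reading mzML and CSV side-inputs; snapshot serialization; result tables.

Every processing step of the pipeline consumes and produces one of three
cell kinds -- a :class:`~lcmspipe.model.Sample`, a list of
:class:`~lcmspipe.model.Feature`, or a list of
:class:`~lcmspipe.model.FeatureSet` -- and any of them can be snapshotted
to disk after any step and read back bit-identically.  Snapshot files are
self-describing (a 4-byte magic prefix, then JSON recording the cell kind
and schema version), so port typing can be checked from the file alone.

The mzML reader handles indexed and non-indexed mzML 1.1.0 with 32-/64-bit,
zlib-compressed or uncompressed binary arrays.  Retention times are
converted to seconds on read.
"""

from __future__ import annotations

import base64
import json
import logging
import math
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .alignment import FeatureMatrix, MatrixGroup
from .model import (
    Annotation,
    AnnotationKind,
    Feature,
    FeatureSet,
    IonMode,
    Sample,
    Scan,
)

logger = logging.getLogger(__name__)

SNAPSHOT_MAGIC = b"MCS1"
SNAPSHOT_VERSION = 1
SNAPSHOT_SUFFIX = ".mcc"

__all__ = [
    "AdductRule",
    "ReferenceEntry",
    "MzmlParseError",
    "SchemaError",
    "SnapshotError",
    "read_mzml",
    "write_snapshot",
    "read_snapshot",
    "snapshot_kind_of",
    "read_adduct_table",
    "read_reference_library",
    "read_exclusion_masses",
    "write_feature_matrix",
]


class MzmlParseError(ValueError):
    """Raised when an mzML file cannot be parsed; message carries the position."""


class SchemaError(ValueError):
    """Raised when a CSV side-input violates its schema."""


class SnapshotError(TypeError):
    """Raised when a snapshot file holds a different cell kind than expected."""


# ---------------------------------------------------------------------------
# side-input record types


@dataclass(frozen=True)
class AdductRule:
    """An ionisation rule nM+X: ion m/z = (multiplier*M + mass_shift)/|charge|.

    ``mass_shift`` is the total mass change of the ion in Da (signed),
    e.g. +1.007276 for M+H, -1.007276 for M-H.  Neutral losses are
    expressed the same way with negative shifts.
    """

    name: str
    mass_shift: float
    charge: int
    multiplier: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")
        if self.multiplier < 1:
            raise ValueError("adduct multiplier must be >= 1")

    def mz_for_neutral(self, neutral_mass: float) -> float:
        return (self.multiplier * neutral_mass + self.mass_shift) / abs(self.charge)

    def neutral_for_mz(self, mz: float) -> float:
        return (mz * abs(self.charge) - self.mass_shift) / self.multiplier

    @property
    def ion_mode(self) -> IonMode:
        return IonMode.POSITIVE if self.charge > 0 else IonMode.NEGATIVE

    def applies_to(self, mode: IonMode) -> bool:
        return mode is IonMode.UNKNOWN or self.ion_mode is mode


@dataclass(frozen=True)
class ReferenceEntry:
    """One row of a reference library: a compound with known neutral mass
    and, optionally, an expected retention time (seconds)."""

    name: str
    neutral_mass: float
    expected_rt: float | None = None
    ion_modes: frozenset[IonMode] = frozenset()

    def __post_init__(self) -> None:
        if not self.neutral_mass > 0:
            raise ValueError("neutral_mass must be positive")


# ---------------------------------------------------------------------------
# mzML reading


_NS = "{http://psi.hupo.org/ms/mzml}"

# controlled-vocabulary accessions used on read
_ACC_MS_LEVEL = "MS:1000511"
_ACC_POSITIVE = "MS:1000130"
_ACC_NEGATIVE = "MS:1000129"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MINUTE = "UO:0000031"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_accessions(element) -> dict[str, dict]:
    """Direct-child cvParam accessions of an element -> attribute dicts."""
    out = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = dict(child.attrib)
    return out


def _decode_binary_array(array_element) -> tuple[np.ndarray, bool]:
    """Decode one <binaryDataArray>; returns (values, is_mz_array)."""
    params = _cv_accessions(array_element)
    is_mz = _ACC_MZ_ARRAY in params
    binary = None
    for child in array_element:
        if _local(child.tag) == "binary":
            binary = child.text or ""
    raw = base64.b64decode(binary) if binary else b""
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    fmt = "f" if _ACC_32BIT in params else "d"
    width = 4 if fmt == "f" else 8
    values = np.asarray(struct.unpack("<%d%s" % (len(raw) // width, fmt), raw))
    return values, is_mz


def _parse_spectrum(element, index: int, path: str) -> Scan:
    params = _cv_accessions(element)
    ms_level = int(params.get(_ACC_MS_LEVEL, {}).get("value", 1))
    if _ACC_POSITIVE in params:
        mode = IonMode.POSITIVE
    elif _ACC_NEGATIVE in params:
        mode = IonMode.NEGATIVE
    else:
        logger.warning("spectrum %s in %s lacks a polarity term; ion mode UNKNOWN",
                       element.get("id", index), path)
        mode = IonMode.UNKNOWN
    if _ACC_CENTROID in params:
        centroided: bool | None = True
    elif _ACC_PROFILE in params:
        centroided = False
    else:
        centroided = None

    rt = 0.0
    precursor = None
    mz = np.empty(0)
    intensity = np.empty(0)
    for scan_el in element.iter(f"{_NS}scan"):
        scan_params = _cv_accessions(scan_el)
        if _ACC_SCAN_START in scan_params:
            attrs = scan_params[_ACC_SCAN_START]
            rt = float(attrs["value"])
            unit = attrs.get("unitAccession", "")
            if unit == _ACC_MINUTE or "minute" in attrs.get("unitName", ""):
                rt *= 60.0
        break
    if ms_level > 1:
        for ion_el in element.iter(f"{_NS}selectedIon"):
            ion_params = _cv_accessions(ion_el)
            if _ACC_SELECTED_MZ in ion_params:
                precursor = float(ion_params[_ACC_SELECTED_MZ]["value"])
            break
    for array_el in element.iter(f"{_NS}binaryDataArray"):
        values, is_mz = _decode_binary_array(array_el)
        if is_mz:
            mz = values
        else:
            intensity = values
    if mz.size and np.any(np.diff(mz) < 0):
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
    return Scan(
        index=index,
        retention_time=rt,
        mz=mz,
        intensity=intensity,
        ms_level=ms_level,
        ion_mode=mode,
        precursor_mz=precursor,
        centroided=centroided,
    )


def read_mzml(path: str | Path, sample_id: str | None = None) -> Sample:
    """Read an mzML 1.1.0 file into a :class:`Sample`.

    Scans keep file order (0-based indices); retention times are converted
    to seconds; ion mode is taken from the per-spectrum polarity term
    (UNKNOWN with a logged warning when absent); m/z arrays are sorted
    ascending if the file is unsorted.  Malformed XML raises
    :class:`MzmlParseError` naming the offending position.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name
        for suffix in (".mzML", ".mzml"):
            if sample_id.endswith(suffix):
                sample_id = sample_id[: -len(suffix)]
    scans: list[Scan] = []
    try:
        context = etree.iterparse(str(path), events=("end",),
                                  tag=f"{_NS}spectrum")
        for _, element in context:
            scans.append(_parse_spectrum(element, len(scans), str(path)))
            element.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise MzmlParseError(f"cannot parse {path}: {exc}") from exc
    except OSError as exc:
        raise MzmlParseError(f"cannot read {path}: {exc}") from exc
    return Sample(id=sample_id, scans=tuple(scans), metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# snapshots

_KIND_SAMPLE = "sample"
_KIND_FEATURES = "features"
_KIND_FEATURE_SETS = "feature_sets"


def _annotation_to_json(a: Annotation) -> dict:
    return {"kind": a.kind.value, "label": a.label,
            "partner_id": a.partner_id, "score": a.score}


def _annotation_from_json(d: dict) -> Annotation:
    return Annotation(kind=AnnotationKind(d["kind"]), label=d["label"],
                      partner_id=d["partner_id"], score=d["score"])


def _scan_to_json(s: Scan) -> dict:
    return {
        "index": s.index,
        "retention_time": s.retention_time,
        "mz": s.mz.tolist(),
        "intensity": s.intensity.tolist(),
        "ms_level": s.ms_level,
        "ion_mode": s.ion_mode.value,
        "precursor_mz": s.precursor_mz,
        "centroided": s.centroided,
    }


def _scan_from_json(d: dict) -> Scan:
    return Scan(
        index=d["index"],
        retention_time=d["retention_time"],
        mz=np.asarray(d["mz"], dtype=float),
        intensity=np.asarray(d["intensity"], dtype=float),
        ms_level=d["ms_level"],
        ion_mode=IonMode(d["ion_mode"]),
        precursor_mz=d["precursor_mz"],
        centroided=d["centroided"],
    )


def _feature_to_json(f: Feature) -> dict:
    return {
        "id": f.id,
        "mz": f.mz,
        "times": f.times.tolist(),
        "intensities": f.intensities.tolist(),
        "rt": f.rt,
        "ion_mode": f.ion_mode.value,
        "annotations": [_annotation_to_json(a) for a in f.annotations],
    }


def _feature_from_json(d: dict) -> Feature:
    return Feature(
        id=d["id"],
        mz=d["mz"],
        times=np.asarray(d["times"], dtype=float),
        intensities=np.asarray(d["intensities"], dtype=float),
        rt=d["rt"],
        ion_mode=IonMode(d["ion_mode"]),
        annotations=tuple(_annotation_from_json(a) for a in d["annotations"]),
    )


def _payload_for(obj) -> tuple[str, object]:
    if isinstance(obj, Sample):
        return _KIND_SAMPLE, {
            "id": obj.id,
            "scans": [_scan_to_json(s) for s in obj.scans],
            "metadata": dict(obj.metadata),
        }
    if isinstance(obj, (list, tuple)):
        if all(isinstance(x, Feature) for x in obj):
            return _KIND_FEATURES, [_feature_to_json(f) for f in obj]
        if all(isinstance(x, FeatureSet) for x in obj):
            return _KIND_FEATURE_SETS, [
                {
                    "id": fs.id,
                    "rt": fs.rt,
                    "neutral_mass": fs.neutral_mass,
                    "features": [_feature_to_json(f) for f in fs.features],
                }
                for fs in obj
            ]
    raise TypeError(f"cannot snapshot object of type {type(obj).__name__}")


def write_snapshot(obj, path: str | Path) -> None:
    """Serialize a Sample, feature list or feature-set list to ``path``.

    The file is the 4-byte magic ``MCS1`` followed by JSON; floats are
    written with shortest round-trip representation, so
    ``read_snapshot(write_snapshot(x)) == x`` bit-for-bit.
    """
    kind, data = _payload_for(obj)
    doc = {"kind": kind, "version": SNAPSHOT_VERSION, "data": data}
    payload = json.dumps(doc, separators=(",", ":"), allow_nan=False)
    Path(path).write_bytes(SNAPSHOT_MAGIC + payload.encode("utf-8"))


def _load_snapshot_doc(path: str | Path) -> dict:
    raw = Path(path).read_bytes()
    if raw[:4] != SNAPSHOT_MAGIC:
        raise SnapshotError(f"{path} is not a snapshot file (bad magic)")
    return json.loads(raw[4:].decode("utf-8"))


def snapshot_kind_of(path: str | Path) -> str:
    """Cell kind recorded in a snapshot file without loading the payload."""
    return _load_snapshot_doc(path)["kind"]


def read_snapshot(path: str | Path, expect: str | None = None):
    """Load a snapshot; ``expect`` (one of ``sample``, ``features``,
    ``feature_sets``) raises :class:`SnapshotError` on kind mismatch."""
    doc = _load_snapshot_doc(path)
    kind = doc["kind"]
    if expect is not None and kind != expect:
        raise SnapshotError(f"{path}: expected cell kind {expect!r}, found {kind!r}")
    data = doc["data"]
    if kind == _KIND_SAMPLE:
        return Sample(
            id=data["id"],
            scans=tuple(_scan_from_json(s) for s in data["scans"]),
            metadata=data["metadata"],
        )
    if kind == _KIND_FEATURES:
        return [_feature_from_json(f) for f in data]
    if kind == _KIND_FEATURE_SETS:
        return [
            FeatureSet(
                id=d["id"],
                features=tuple(_feature_from_json(f) for f in d["features"]),
                rt=d["rt"],
                neutral_mass=d["neutral_mass"],
            )
            for d in data
        ]
    raise SnapshotError(f"{path}: unknown cell kind {kind!r}")


# ---------------------------------------------------------------------------
# CSV side inputs


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_adduct_table(path: str | Path) -> list[AdductRule]:
    """Read adduct rules from a CSV with columns name,mass_shift,charge,multiplier."""
    df = pd.read_csv(path)
    _require_columns(df, ["name", "mass_shift", "charge", "multiplier"], path)
    rules = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rules.append(
                AdductRule(
                    name=str(row.name),
                    mass_shift=float(row.mass_shift),
                    charge=int(row.charge),
                    multiplier=int(row.multiplier),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path} row {row_no}: {exc}") from exc
    return rules


_MODE_NAMES = {"positive": IonMode.POSITIVE, "negative": IonMode.NEGATIVE}


def read_reference_library(path: str | Path) -> list[ReferenceEntry]:
    """Read a reference library CSV: name,neutral_mass,expected_rt,ion_modes.

    ``expected_rt`` may be blank (unknown); ``ion_modes`` is a
    semicolon-separated subset of {positive, negative}.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["name", "neutral_mass", "expected_rt", "ion_modes"], path)
    entries = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            mass = float(row.neutral_mass)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path} row {row_no}: bad neutral_mass") from exc
        if math.isnan(mass):
            raise SchemaError(f"{path} row {row_no}: bad neutral_mass")
        rt_raw = row.expected_rt
        rt = None
        if rt_raw is not None and not (isinstance(rt_raw, float) and math.isnan(rt_raw)):
            if str(rt_raw).strip():
                rt = float(rt_raw)
        modes = frozenset(
            _MODE_NAMES[token.strip().lower()]
            for token in str(row.ion_modes).split(";")
            if token.strip() and token.strip().lower() in _MODE_NAMES
        )
        try:
            entries.append(ReferenceEntry(str(row.name), mass, rt, modes))
        except ValueError as exc:
            raise SchemaError(f"{path} row {row_no}: {exc}") from exc
    return entries


def read_exclusion_masses(path: str | Path) -> list[float]:
    """Read a single-column CSV (header ``mz``) of contaminant m/z values."""
    df = pd.read_csv(path)
    _require_columns(df, ["mz"], path)
    masses = []
    for row_no, value in enumerate(df["mz"], start=2):
        mz = float(value)
        if not (mz > 0 and math.isfinite(mz)):
            raise SchemaError(f"{path} row {row_no}: mz must be positive, got {value}")
        masses.append(mz)
    return masses


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write the aligned feature matrix as CSV: one row per group, columns
    group id, consensus mz/rt, annotation label, then per-sample intensities.
    Missing cells are empty."""
    header = ["group_id", "mz", "rt", "label", *matrix.sample_ids]
    lines = [",".join(header)]
    for gi, group in enumerate(matrix.groups):
        cells = [str(group.id), repr(group.mz), repr(group.rt), group.label]
        for si in range(len(matrix.sample_ids)):
            v = matrix.values[gi, si]
            cells.append("" if np.isnan(v) else repr(float(v)))
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
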