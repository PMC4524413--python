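"""Typed stage-graph executor with snapshotting and batch ion-mode routing.

A workflow is a small DAG of named stages.  Every stage consumes and
produces one of three cell kinds (sample, features, feature_sets), and
:func:`validate` checks the whole graph statically -- port-kind
compatibility on every edge, acyclicity, unfed in-ports and parameter
schemas -- so that a workflow passing validation can never hit a kind
mismatch at run time.

:func:`run` processes each input file independently (a failure on one
sample never aborts the others), optionally serializing every stage
output as a snapshot, and routes ion-mode-specific parameter variants
(``per_mode``) to the variant matching each sample's polarity.
:func:`rerun_from` resumes execution at any stage from stored snapshots,
which is how a narrow part of a workflow is re-run with, say, a less
stringent scan-width setting without re-processing everything upstream.

All shipped stages are deterministic; equal inputs and parameters give
byte-identical snapshots.
"""

from __future__ import annotations

import enum
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import yaml

from . import filtering, io
from .annotation import AnnotationParams, annotate_adducts, annotate_isotopes, match_reference
from .centroiding import CentroidParams, centroid_sample
from .features import DeconvolutionParams, TraceParams, deconvolve_all, extract_features
from .grouping import GroupingParams, group_features
from .model import IonMode, Sample

logger = logging.getLogger(__name__)

__all__ = [
    "CellKind",
    "StageSpec",
    "WorkflowSpec",
    "Problem",
    "StageRecord",
    "RunReport",
    "SnapshotMissingError",
    "STAGE_REGISTRY",
    "validate",
    "run",
    "rerun_from",
    "load_workflow",
    "identification_workflow",
]


class CellKind(enum.Enum):
    NONE = "none"
    SAMPLE = "sample"
    FEATURES = "features"
    FEATURE_SETS = "feature_sets"


class SnapshotMissingError(FileNotFoundError):
    """Raised when a rerun needs a snapshot that was never written."""


@dataclass(frozen=True)
class _ParamSchema:
    """Declared parameter: python type(s) and default (None = required)."""

    types: tuple[type, ...]
    default: Any = None
    required: bool = False


@dataclass(frozen=True)
class StageDef:
    """A registered operation: port kinds, parameter schema and runner."""

    op: str
    in_kind: CellKind
    out_kind: CellKind
    schema: Mapping[str, _ParamSchema]
    runner: Callable


@dataclass(frozen=True)
class StageSpec:
    """One stage instance in a workflow: unique ``name``, registry ``op``
    and a parameter map (which may hold a ``per_mode`` variant table)."""

    name: str
    op: str
    params: Mapping[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class WorkflowSpec:
    """Ordered stages, (producer, consumer) edges, optional snapshot dir.

    With no edges given, stages form a linear chain in listed order.
    ``ion_mode_override`` supplies the polarity when files lack one.
    """

    stages: tuple[StageSpec, ...]
    edges: tuple[tuple[str, str], ...] = ()
    snapshot_dir: Path | None = None
    ion_mode_override: IonMode | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.edges and len(self.stages) > 1:
            chain = tuple(
                (a.name, b.name) for a, b in zip(self.stages, self.stages[1:])
            )
            object.__setattr__(self, "edges", chain)


@dataclass(frozen=True)
class Problem:
    """One validation finding; ``kind`` is a stable machine-readable tag."""

    kind: str
    message: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.message}"


@dataclass
class StageRecord:
    stage: str
    status: str  # ok | failed | skipped
    count: int = 0
    seconds: float = 0.0
    warnings: list[str] = field(default_factory=list)
    error: str = ""


@dataclass
class RunReport:
    """Per-sample, per-stage execution log plus collected identity matches."""

    samples: dict[str, list[StageRecord]] = field(default_factory=dict)
    matches: dict[str, list] = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return sum(any(r.status == "failed" for r in recs)
                   for recs in self.samples.values())

    @property
    def n_ok(self) -> int:
        return len(self.samples) - self.n_failed


# ---------------------------------------------------------------------------
# stage runners


def _count(obj) -> int:
    try:
        return len(obj)
    except TypeError:
        return 0


def _run_read(_, params, ctx):
    return io.read_mzml(ctx["input_path"])


def _run_centroid(sample, params, ctx):
    return centroid_sample(sample, CentroidParams(
        scales=tuple(params["scales"]), min_snr=params["min_snr"],
        window_ppm=params["window_ppm"]))


def _run_threshold(sample, params, ctx):
    return filtering.intensity_threshold(sample, params["min_intensity"])


def _run_range(sample, params, ctx):
    return filtering.range_filter(sample, filtering.RangeFilterParams(
        mz_min=params["mz_min"], mz_max=params["mz_max"],
        rt_min=params["rt_min"], rt_max=params["rt_max"]))


def _run_extract(sample, params, ctx):
    return extract_features(sample, TraceParams(
        tol_ppm=params["tol_ppm"], max_gap_scans=params["max_gap_scans"],
        min_intensity=params["min_intensity"]))


def _run_width_filter(features, params, ctx):
    return filtering.scan_width_filter(features, params["min_scans"])


def _run_exclusion(features, params, ctx):
    masses = (io.read_exclusion_masses(params["masses_csv"])
              if params["masses_csv"] else [])
    return filtering.exclusion_filter(features, masses, params["tol_ppm"])


def _run_baseline(features, params, ctx):
    return [filtering.baseline_correct(f, params["asymmetry"], params["smoothness"])
            for f in features]


def _run_deconvolve(features, params, ctx):
    return deconvolve_all(features, DeconvolutionParams(
        sg_window=params["sg_window"], valley_fraction=params["valley_fraction"],
        min_snr=params["min_snr"]))


def _run_group(features, params, ctx):
    return group_features(features, GroupingParams(
        rt_tol=params["rt_tol"], min_similarity=params["min_similarity"]))


def _run_isotopes(fs_list, params, ctx):
    p = AnnotationParams(tol_ppm=params["tol_ppm"],
                         max_isotopes=params["max_isotopes"],
                         isotope_max_ratio=params["isotope_max_ratio"])
    return [annotate_isotopes(fs, p) for fs in fs_list]


def _run_adducts(fs_list, params, ctx):
    rules = io.read_adduct_table(params["adduct_csv"])
    p = AnnotationParams(tol_ppm=params["tol_ppm"])
    return [annotate_adducts(fs, rules, ctx["ion_mode"], p) for fs in fs_list]


def _run_match(fs_list, params, ctx):
    library = io.read_reference_library(params["library_csv"])
    rules = io.read_adduct_table(params["adduct_csv"])
    matches = match_reference(fs_list, library, rules, ctx["ion_mode"],
                              tol_ppm=params["tol_ppm"], rt_tol=params["rt_tol"])
    ctx["matches"] = matches
    out = {m.feature_set.id: m.feature_set for m in matches}
    return [out.get(fs.id, fs) for fs in fs_list]


def _schema(**kwargs) -> dict[str, _ParamSchema]:
    return kwargs


def _p(types, default=None, required=False) -> _ParamSchema:
    if not isinstance(types, tuple):
        types = (types,)
    return _ParamSchema(types=types, default=default, required=required)


STAGE_REGISTRY: dict[str, StageDef] = {
    "read": StageDef("read", CellKind.NONE, CellKind.SAMPLE, _schema(), _run_read),
    "centroid": StageDef("centroid", CellKind.SAMPLE, CellKind.SAMPLE, _schema(
        scales=_p(list, [2.0, 4.0, 8.0, 16.0]),
        min_snr=_p((int, float), 3.0),
        window_ppm=_p((int, float), 10.0)), _run_centroid),
    "threshold": StageDef("threshold", CellKind.SAMPLE, CellKind.SAMPLE, _schema(
        min_intensity=_p((int, float), 0.0)), _run_threshold),
    "range": StageDef("range", CellKind.SAMPLE, CellKind.SAMPLE, _schema(
        mz_min=_p((int, float), required=True),
        mz_max=_p((int, float), required=True),
        rt_min=_p((int, float), required=True),
        rt_max=_p((int, float), required=True)), _run_range),
    "extract": StageDef("extract", CellKind.SAMPLE, CellKind.FEATURES, _schema(
        tol_ppm=_p((int, float), 10.0),
        max_gap_scans=_p(int, 1),
        min_intensity=_p((int, float), 0.0)), _run_extract),
    "width_filter": StageDef("width_filter", CellKind.FEATURES, CellKind.FEATURES,
                             _schema(min_scans=_p(int, 3)), _run_width_filter),
    "exclusion": StageDef("exclusion", CellKind.FEATURES, CellKind.FEATURES, _schema(
        masses_csv=_p(str, ""), tol_ppm=_p((int, float), 10.0)), _run_exclusion),
    "baseline": StageDef("baseline", CellKind.FEATURES, CellKind.FEATURES, _schema(
        asymmetry=_p((int, float), 0.01),
        smoothness=_p((int, float), 1e4)), _run_baseline),
    "deconvolve": StageDef("deconvolve", CellKind.FEATURES, CellKind.FEATURES, _schema(
        sg_window=_p(int, 9),
        valley_fraction=_p((int, float), 0.5),
        min_snr=_p((int, float), 3.0)), _run_deconvolve),
    "group": StageDef("group", CellKind.FEATURES, CellKind.FEATURE_SETS, _schema(
        rt_tol=_p((int, float), 5.0),
        min_similarity=_p((int, float), 0.9)), _run_group),
    "isotopes": StageDef("isotopes", CellKind.FEATURE_SETS, CellKind.FEATURE_SETS,
                         _schema(tol_ppm=_p((int, float), 10.0),
                                 max_isotopes=_p(int, 3),
                                 isotope_max_ratio=_p((int, float), 1.1)),
                         _run_isotopes),
    "adducts": StageDef("adducts", CellKind.FEATURE_SETS, CellKind.FEATURE_SETS,
                        _schema(adduct_csv=_p(str, required=True),
                                tol_ppm=_p((int, float), 10.0)), _run_adducts),
    "match": StageDef("match", CellKind.FEATURE_SETS, CellKind.FEATURE_SETS,
                      _schema(library_csv=_p(str, required=True),
                              adduct_csv=_p(str, required=True),
                              tol_ppm=_p((int, float), 5.0),
                              rt_tol=_p((int, float), 10.0)), _run_match),
}

_MODE_KEYS = {"positive": IonMode.POSITIVE, "negative": IonMode.NEGATIVE}


# ---------------------------------------------------------------------------
# validation


def _check_params(stage: StageSpec, schema: Mapping[str, _ParamSchema]) -> list[Problem]:
    problems = []
    variants = [dict(stage.params)]
    per_mode = variants[0].pop("per_mode", None)
    if per_mode is not None:
        if not isinstance(per_mode, Mapping) or \
                not set(per_mode) <= set(_MODE_KEYS):
            problems.append(Problem(
                "params", f"stage {stage.name}: per_mode must map "
                          "positive/negative to parameter tables"))
            per_mode = None
    if per_mode:
        base = variants[0]
        variants = [dict(base, **per_mode.get(k, {})) for k in _MODE_KEYS]
    for variant in variants:
        for key, value in variant.items():
            if key not in schema:
                problems.append(Problem(
                    "params", f"stage {stage.name}: unknown parameter {key!r}"))
            elif not isinstance(value, schema[key].types) or isinstance(value, bool):
                problems.append(Problem(
                    "params", f"stage {stage.name}: parameter {key!r} has type "
                              f"{type(value).__name__}"))
        for key, spec in schema.items():
            if spec.required and key not in variant:
                problems.append(Problem(
                    "params", f"stage {stage.name}: missing required parameter {key!r}"))
    return problems


def validate(workflow: WorkflowSpec) -> list[Problem]:
    """Statically check a workflow; an empty list means it is runnable.

    Reports duplicate or unknown stages, port-kind mismatches on every
    edge, cycles, unfed or multiply-fed in-ports, and parameter-schema
    violations.  Problems are data, not exceptions.
    """
    problems: list[Problem] = []
    names = [s.name for s in workflow.stages]
    by_name: dict[str, StageSpec] = {}
    for s in workflow.stages:
        if s.name in by_name:
            problems.append(Problem("duplicate", f"duplicate stage name {s.name!r}"))
        by_name[s.name] = s
        if s.op not in STAGE_REGISTRY:
            problems.append(Problem("unknown_op", f"stage {s.name}: unknown operation {s.op!r}"))
        else:
            problems.extend(_check_params(s, STAGE_REGISTRY[s.op].schema))

    for producer, consumer in workflow.edges:
        for end in (producer, consumer):
            if end not in by_name:
                problems.append(Problem("edge", f"edge references unknown stage {end!r}"))
    edges = [(p, c) for p, c in workflow.edges if p in by_name and c in by_name]

    fed: dict[str, list[str]] = {n: [] for n in names}
    for producer, consumer in edges:
        fed[consumer].append(producer)
        pd = STAGE_REGISTRY.get(by_name[producer].op)
        cd = STAGE_REGISTRY.get(by_name[consumer].op)
        if pd and cd and pd.out_kind is not cd.in_kind:
            problems.append(Problem(
                "kind_mismatch",
                f"edge {producer} -> {consumer}: produces {pd.out_kind.value}, "
                f"consumer expects {cd.in_kind.value}"))
    for name in names:
        d = STAGE_REGISTRY.get(by_name[name].op)
        if d is None:
            continue
        if d.in_kind is CellKind.NONE:
            if fed[name]:
                problems.append(Problem(
                    "unfed", f"source stage {name} must not have an incoming edge"))
        elif len(fed[name]) == 0:
            problems.append(Problem("unfed", f"stage {name}: in-port not fed"))
        elif len(fed[name]) > 1:
            problems.append(Problem(
                "unfed", f"stage {name}: in-port fed by {len(fed[name])} producers"))

    # cycle detection by Kahn's algorithm
    indegree = {n: len(fed[n]) for n in names}
    queue = [n for n in names if indegree[n] == 0]
    seen = 0
    consumers: dict[str, list[str]] = {n: [] for n in names}
    for p, c in edges:
        consumers[p].append(c)
    while queue:
        n = queue.pop()
        seen += 1
        for c in consumers[n]:
            indegree[c] -= 1
            if indegree[c] == 0:
                queue.append(c)
    if seen < len(names):
        cyclic = sorted(n for n in names if indegree[n] > 0)
        problems.append(Problem("cycle", f"cycle involving stage(s): {', '.join(cyclic)}"))
    return problems


# ---------------------------------------------------------------------------
# execution


def _topo_order(workflow: WorkflowSpec) -> list[StageSpec]:
    by_name = {s.name: s for s in workflow.stages}
    fed: dict[str, list[str]] = {n: [] for n in by_name}
    consumers: dict[str, list[str]] = {n: [] for n in by_name}
    for p, c in workflow.edges:
        fed[c].append(p)
        consumers[p].append(c)
    indegree = {n: len(fed[n]) for n in by_name}
    # stable order: follow listed stage order among ready stages
    order = []
    ready = [s.name for s in workflow.stages if indegree[s.name] == 0]
    while ready:
        n = ready.pop(0)
        order.append(by_name[n])
        for c in consumers[n]:
            indegree[c] -= 1
            if indegree[c] == 0:
                ready.append(c)
    return order


def _producer_of(workflow: WorkflowSpec, stage_name: str) -> str | None:
    for p, c in workflow.edges:
        if c == stage_name:
            return p
    return None


def _sample_mode(obj, workflow: WorkflowSpec) -> IonMode:
    modes = set()
    if isinstance(obj, Sample):
        modes = {m for m in obj.ion_modes if m is not IonMode.UNKNOWN}
    elif isinstance(obj, (list, tuple)) and obj:
        first = obj[0]
        mode = getattr(first, "ion_mode", IonMode.UNKNOWN)
        if mode is not IonMode.UNKNOWN:
            modes = {mode}
    if len(modes) == 1:
        return next(iter(modes))
    if workflow.ion_mode_override is not None:
        return workflow.ion_mode_override
    return IonMode.UNKNOWN


def _effective_params(stage: StageSpec, schema: Mapping[str, _ParamSchema],
                      mode: IonMode) -> dict[str, Any]:
    params = dict(stage.params)
    per_mode = params.pop("per_mode", None)
    if per_mode:
        if mode is IonMode.UNKNOWN:
            raise ValueError(
                f"stage {stage.name} has per-mode parameters but the sample's "
                "ion mode is unknown; set an ion_mode_override")
        params.update(per_mode.get(mode.value, {}))
    for key, spec in schema.items():
        params.setdefault(key, spec.default)
    return params


def _snapshot_path(snapshot_dir: Path, sample_id: str, stage_name: str) -> Path:
    return snapshot_dir / f"{sample_id}__{stage_name}{io.SNAPSHOT_SUFFIX}"


def _sample_id_for(path: str | Path) -> str:
    name = Path(path).name
    for suffix in (".mzML", ".mzml"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def _execute_stages(workflow: WorkflowSpec, stages: Sequence[StageSpec],
                    input_path: str | Path, preloaded: dict[str, Any],
                    report: RunReport) -> None:
    sample_id = _sample_id_for(input_path)
    records: list[StageRecord] = []
    report.samples[sample_id] = records
    outputs: dict[str, Any] = dict(preloaded)
    failed = False
    for stage in stages:
        definition = STAGE_REGISTRY[stage.op]
        record = StageRecord(stage=stage.name, status="skipped")
        records.append(record)
        if failed:
            continue
        producer = _producer_of(workflow, stage.name)
        if definition.in_kind is CellKind.NONE:
            stage_input = None
        else:
            stage_input = outputs[producer]
        mode = _sample_mode(stage_input, workflow)
        ctx = {"input_path": input_path, "ion_mode": mode,
               "sample_id": sample_id, "seed": workflow.seed}
        started = time.perf_counter()
        try:
            params = _effective_params(stage, definition.schema, mode)
            result = definition.runner(stage_input, params, ctx)
        except Exception as exc:
            record.status = "failed"
            record.error = f"{type(exc).__name__}: {exc}"
            record.seconds = time.perf_counter() - started
            logger.error("sample %s stage %s failed: %s", sample_id, stage.name, exc)
            failed = True
            continue
        record.seconds = time.perf_counter() - started
        record.status = "ok"
        record.count = _count(result)
        outputs[stage.name] = result
        if "matches" in ctx:
            report.matches[sample_id] = ctx["matches"]
        if workflow.snapshot_dir is not None:
            workflow.snapshot_dir.mkdir(parents=True, exist_ok=True)
            io.write_snapshot(
                result, _snapshot_path(workflow.snapshot_dir, sample_id, stage.name))
        logger.info("sample %s stage %s: %d item(s) in %.3f s",
                    sample_id, stage.name, record.count, record.seconds)


def run(workflow: WorkflowSpec, inputs: Sequence[str | Path]) -> RunReport:
    """Run every input file through the workflow in batch.

    Files are processed independently; a failure on one is recorded in the
    report and does not abort the others.  With ``snapshot_dir`` set, every
    stage output is serialized as ``<sample>__<stage>.mcc``.
    """
    problems = validate(workflow)
    if problems:
        raise ValueError("workflow invalid: " + "; ".join(map(str, problems)))
    order = _topo_order(workflow)
    report = RunReport()
    for input_path in inputs:
        _execute_stages(workflow, order, input_path, {}, report)
    return report


def rerun_from(workflow: WorkflowSpec, stage_name: str,
               inputs: Sequence[str | Path]) -> RunReport:
    """Resume the workflow at ``stage_name`` from stored snapshots.

    Only ``stage_name`` and its downstream stages are executed; the inputs
    of re-executed stages whose producers are not re-executed are loaded
    from the snapshot directory.  A missing snapshot raises
    :class:`SnapshotMissingError` naming the sample and stage.
    """
    problems = validate(workflow)
    if problems:
        raise ValueError("workflow invalid: " + "; ".join(map(str, problems)))
    if workflow.snapshot_dir is None:
        raise ValueError("rerun_from requires a snapshot_dir")
    names = {s.name for s in workflow.stages}
    if stage_name not in names:
        raise ValueError(f"unknown stage {stage_name!r}")
    # downstream closure of the resume stage
    consumers: dict[str, list[str]] = {n: [] for n in names}
    for p, c in workflow.edges:
        consumers[p].append(c)
    to_run = {stage_name}
    frontier = [stage_name]
    while frontier:
        for c in consumers[frontier.pop()]:
            if c not in to_run:
                to_run.add(c)
                frontier.append(c)
    order = [s for s in _topo_order(workflow) if s.name in to_run]

    report = RunReport()
    for input_path in inputs:
        sample_id = _sample_id_for(input_path)
        preloaded: dict[str, Any] = {}
        for stage in order:
            producer = _producer_of(workflow, stage.name)
            if producer is None or producer in to_run:
                continue
            path = _snapshot_path(workflow.snapshot_dir, sample_id, producer)
            if not path.exists():
                raise SnapshotMissingError(
                    f"sample {sample_id}: no snapshot for stage {producer!r} "
                    f"at {path}")
            preloaded[producer] = io.read_snapshot(path)
        _execute_stages(workflow, order, input_path, preloaded, report)
    return report


def identification_workflow(
    adduct_csv: str | Path,
    library_csv: str | Path,
    snapshot_dir: str | Path | None = None,
    min_scans: int = 4,
    scan_threshold: float = 2000.0,
    trace_min_intensity: float = 5000.0,
    tol_ppm: float = 10.0,
    match_tol_ppm: float = 5.0,
    match_rt_tol: float = 10.0,
) -> WorkflowSpec:
    """The canonical reference-standard identification chain:

    read -> centroid -> threshold -> extract -> width_filter -> deconvolve
    -> group -> isotopes -> adducts -> match.
    """
    stages = (
        StageSpec("read", "read"),
        StageSpec("centroid", "centroid"),
        StageSpec("threshold", "threshold", {"min_intensity": scan_threshold}),
        StageSpec("extract", "extract", {"tol_ppm": tol_ppm,
                                         "min_intensity": trace_min_intensity}),
        StageSpec("width_filter", "width_filter", {"min_scans": min_scans}),
        StageSpec("deconvolve", "deconvolve"),
        StageSpec("group", "group"),
        StageSpec("isotopes", "isotopes"),
        StageSpec("adducts", "adducts", {"adduct_csv": str(adduct_csv)}),
        StageSpec("match", "match", {"library_csv": str(library_csv),
                                     "adduct_csv": str(adduct_csv),
                                     "tol_ppm": match_tol_ppm,
                                     "rt_tol": match_rt_tol}),
    )
    return WorkflowSpec(
        stages=stages,
        snapshot_dir=Path(snapshot_dir) if snapshot_dir else None,
    )


# ---------------------------------------------------------------------------
# declarative configuration


def load_workflow(path: str | Path) -> WorkflowSpec:
    """Load a workflow from its YAML description.

    Schema::

        stages:
          - name: read            # unique stage name
            op: read              # registry operation (defaults to name)
            params: {...}         # may include per_mode: {positive: {...},
                                  #                        negative: {...}}
        edges:                    # optional; default is the linear chain
          - [read, centroid]
        snapshot_dir: snapshots   # optional
        ion_mode_override: positive   # optional
        seed: 0                   # optional
    """
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, Mapping) or "stages" not in doc:
        raise ValueError(f"{path}: workflow config must define 'stages'")
    stages = []
    for entry in doc["stages"]:
        if isinstance(entry, str):
            entry = {"name": entry}
        name = entry["name"]
        stages.append(StageSpec(name=name, op=entry.get("op", name),
                                params=entry.get("params", {}) or {}))
    edges = tuple((p, c) for p, c in doc.get("edges", []) or [])
    snapshot_dir = doc.get("snapshot_dir")
    override = doc.get("ion_mode_override")
    return WorkflowSpec(
        stages=tuple(stages),
        edges=edges,
        snapshot_dir=Path(snapshot_dir) if snapshot_dir else None,
        ion_mode_override=_MODE_KEYS[override] if override else None,
        seed=int(doc.get("seed", 0)),
    )
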