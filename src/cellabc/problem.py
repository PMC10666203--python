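"""Parameter-estimation problem bundles: a tsv/yaml dialect in the PEtab lineage.

A *problem bundle* is a yaml index file naming five relative paths:

.. code-block:: yaml

    model_file: model.xml
    parameter_file: parameters.tsv
    condition_file: conditions.tsv
    measurement_file: measurements.tsv
    statistic_file: statistics.tsv

The model document is XML; parameters and condition overrides address
locations inside it through a restricted XPath-like grammar (child steps,
``[@name='...']`` predicates and a final ``/@attr`` or ``/text()`` selector).
Tables are UTF-8, tab-separated, ``.`` decimal, header row mandatory; unknown
columns are preserved on round-trip but otherwise ignored.

Condition tables are wide: every column other than ``condition_id`` is itself
a target-path expression and each cell is the override value for that path
(empty cell = no override for that condition). Summary-statistic arguments
are a JSON object in the ``args`` column.

Parsing is *collecting*: structural problems (missing files, missing
columns, dangling cross-references, bad paths) become entries of a report
attached to the returned :class:`ProblemSpec` instead of a cascade of
exceptions; ``parse_problem(..., strict=True)`` raises them all at once.
:func:`validate_problem` merges that report with the semantic invariants.
"""

from __future__ import annotations

import copy
import hashlib
import io
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from lxml import etree

__all__ = [
    "ParameterSpec",
    "ConditionSpec",
    "MeasurementRecord",
    "SummaryStatisticSpec",
    "ProblemSpec",
    "ValidationIssue",
    "ProblemFormatError",
    "PathError",
    "resolve_path",
    "read_path",
    "write_path",
    "parse_problem",
    "validate_problem",
    "write_problem",
    "sample_space",
    "map_parameters",
    "load_gridded_array",
]

PRIOR_KINDS = ("uniform", "log10-uniform", "normal")
SCALES = ("lin", "log10")

INDEX_KEYS = (
    "model_file",
    "parameter_file",
    "condition_file",
    "measurement_file",
    "statistic_file",
)

REQUIRED_COLUMNS = {
    "parameter_table": [
        "parameter_id",
        "prior_kind",
        "prior_arg1",
        "prior_arg2",
        "scale",
        "estimate",
        "nominal_value",
        "target_path",
    ],
    "condition_table": ["condition_id"],
    "measurement_table": ["observable_id", "condition_id", "time", "value"],
    "statistic_table": ["statistic_id", "function_id", "args", "observable_ids"],
}


# ---------------------------------------------------------------------------
# error reporting


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str

    def __str__(self) -> str:  # one line per entry, CLI-friendly
        return f"{self.severity.upper()} {self.code}: {self.message}"


class ProblemFormatError(Exception):
    """Aggregated structural errors from a strict parse."""

    def __init__(self, issues: list[ValidationIssue]):
        self.issues = issues
        super().__init__("\n".join(str(i) for i in issues))


class PathError(Exception):
    """A target-path expression could not be parsed or resolved."""


# ---------------------------------------------------------------------------
# restricted path grammar

_STEP_RE = re.compile(r"^(?P<tag>[A-Za-z_][\w.-]*)(?:\[@name='(?P<name>[^']*)'\])?$")


def _parse_path(path: str):
    """Split a path expression into (steps, selector).

    steps: list of (tag, name-or-None); selector: ("attr", attrname) or
    ("text", None).
    """
    if not isinstance(path, str) or not path.strip():
        raise PathError("empty path expression")
    parts = path.strip().lstrip("/").split("/")
    if len(parts) < 2:
        raise PathError(f"path {path!r} lacks a /@attr or /text() selector")
    last = parts[-1]
    if last == "text()":
        selector = ("text", None)
    elif last.startswith("@") and len(last) > 1:
        selector = ("attr", last[1:])
    else:
        raise PathError(f"path {path!r} must end in /@attr or /text()")
    steps = []
    for raw in parts[:-1]:
        m = _STEP_RE.match(raw)
        if not m:
            raise PathError(f"bad path step {raw!r} in {path!r}")
        steps.append((m.group("tag"), m.group("name")))
    if not steps:
        raise PathError(f"path {path!r} has no element steps")
    return steps, selector


def resolve_path(root: etree._Element, path: str) -> tuple[etree._Element, str, Optional[str]]:
    """Resolve a path against a document root.

    Returns (element, kind, attr) with kind in {"attr", "text"}. The first
    step may name the root element itself or a child of it.
    """
    steps, (kind, attr) = _parse_path(path)
    tag0, name0 = steps[0]
    if root.tag == tag0 and (name0 is None or root.get("name") == name0):
        node = root
    else:
        node = _child(root, tag0, name0)
        if node is None:
            raise PathError(f"step {tag0!r} not found under <{root.tag}> in {path!r}")
    for tag, name in steps[1:]:
        nxt = _child(node, tag, name)
        if nxt is None:
            raise PathError(f"step {tag!r} not found under <{node.tag}> in {path!r}")
        node = nxt
    if kind == "attr" and node.get(attr) is None:
        raise PathError(f"attribute @{attr} absent on <{node.tag}> in {path!r}")
    return node, kind, attr


def _child(node, tag, name):
    for ch in node:
        if ch.tag == tag and (name is None or ch.get("name") == name):
            return ch
    return None


def read_path(root, path: str) -> str:
    node, kind, attr = resolve_path(root, path)
    return node.get(attr) if kind == "attr" else (node.text or "")


def write_path(root, path: str, value) -> None:
    node, kind, attr = resolve_path(root, path)
    text = _format_value(value)
    if kind == "attr":
        node.set(attr, text)
    else:
        node.text = text


def _format_value(value) -> str:
    if isinstance(value, str):
        return value
    x = float(value)
    if x == int(x) and abs(x) < 1e15:
        return repr(x) if "e" in repr(x) else ("%g" % x if x != int(x) else str(x))
    return repr(x)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ParameterSpec:
    parameter_id: str
    prior_kind: Optional[str]
    prior_arg1: Optional[float]
    prior_arg2: Optional[float]
    scale: str
    estimate: bool
    nominal_value: Optional[float]
    target_path: str


@dataclass
class ConditionSpec:
    condition_id: str
    overrides: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class MeasurementRecord:
    observable_id: str
    condition_id: str
    time: float
    value: Optional[float] = None
    data_ref: Optional[str] = None
    replicate_id: Optional[str] = None


@dataclass
class SummaryStatisticSpec:
    statistic_id: str
    function_id: str
    args: dict
    observable_ids: list[str]


@dataclass
class ProblemSpec:
    model_document: etree._Element
    parameter_table: list[ParameterSpec]
    condition_table: list[ConditionSpec]
    measurement_table: list[MeasurementRecord]
    statistic_table: list[SummaryStatisticSpec]
    directory: Optional[Path] = None
    parse_report: list[ValidationIssue] = field(default_factory=list)
    raw_tables: dict = field(default_factory=dict)  # DataFrames, for round-trip

    @property
    def estimated(self) -> list[ParameterSpec]:
        return [p for p in self.parameter_table if p.estimate]

    def fingerprint(self) -> str:
        """Stable hash of the problem content (model + tables)."""
        h = hashlib.sha256()
        h.update(etree.tostring(self.model_document))
        for name in ("parameter_table", "condition_table", "measurement_table", "statistic_table"):
            df = self.raw_tables.get(name)
            if df is not None:
                h.update(df.to_csv(sep="\t", index=False).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# parsing


def _read_tsv(path: Path, table: str, issues: list[ValidationIssue]):
    if not path.is_file():
        issues.append(
            ValidationIssue("error", "IO_MISSING_FILE", f"{table}: file not found: {path}")
        )
        return None
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS[table]:
        if col not in df.columns:
            issues.append(
                ValidationIssue("error", "SCHEMA_MISSING_COLUMN", f"{table}: {col}")
            )
    return df


def _to_float(cell, default=None):
    if cell is None:
        return default
    s = str(cell).strip()
    if s == "":
        return default
    try:
        return float(s)
    except ValueError:
        return math.nan


def _to_bool(cell) -> bool:
    return str(cell).strip().lower() in ("1", "true", "yes")


def parse_problem(index_path, strict: bool = False) -> ProblemSpec:
    """Read a problem bundle from its yaml index file.

    Structural problems are collected into ``ProblemSpec.parse_report``;
    with ``strict=True`` they are raised together as
    :class:`ProblemFormatError`. A missing or unreadable index file always
    raises, since nothing can be built from it.
    """
    index_path = Path(index_path)
    if not index_path.is_file():
        raise FileNotFoundError(f"problem index file not found: {index_path}")
    index = yaml.safe_load(index_path.read_text())
    if not isinstance(index, dict):
        raise ProblemFormatError(
            [ValidationIssue("error", "INDEX_MALFORMED", f"{index_path} is not a yaml mapping")]
        )
    base = index_path.parent
    issues: list[ValidationIssue] = []
    for key in INDEX_KEYS:
        if key not in index:
            issues.append(ValidationIssue("error", "INDEX_MISSING_KEY", key))
    if issues:
        raise ProblemFormatError(issues)

    model_path = base / index["model_file"]
    if model_path.is_file():
        model = etree.parse(str(model_path)).getroot()
    else:
        issues.append(
            ValidationIssue("error", "IO_MISSING_FILE", f"model_file: {model_path}")
        )
        model = etree.Element("Model")

    raw: dict[str, pd.DataFrame] = {}
    dfs = {}
    for table, key in (
        ("parameter_table", "parameter_file"),
        ("condition_table", "condition_file"),
        ("measurement_table", "measurement_file"),
        ("statistic_table", "statistic_file"),
    ):
        df = _read_tsv(base / index[key], table, issues)
        dfs[table] = df
        if df is not None:
            raw[table] = df

    parameters = _build_parameters(dfs["parameter_table"])
    conditions = _build_conditions(dfs["condition_table"])
    measurements = _build_measurements(dfs["measurement_table"])
    statistics = _build_statistics(dfs["statistic_table"], issues)

    # cross-link problems are parse-level findings too
    cond_ids = {c.condition_id for c in conditions}
    for m in measurements:
        if m.condition_id not in cond_ids:
            issues.append(
                ValidationIssue(
                    "error",
                    "LINK_UNKNOWN_CONDITION",
                    f"measurement_table: observable {m.observable_id!r} references "
                    f"condition_id {m.condition_id!r} absent from condition_table",
                )
            )

    spec = ProblemSpec(
        model_document=model,
        parameter_table=parameters,
        condition_table=conditions,
        measurement_table=measurements,
        statistic_table=statistics,
        directory=base,
        parse_report=issues,
        raw_tables=raw,
    )
    if strict and issues:
        raise ProblemFormatError(issues)
    return spec


def _build_parameters(df) -> list[ParameterSpec]:
    if df is None:
        return []
    out = []
    for _, row in df.iterrows():
        out.append(
            ParameterSpec(
                parameter_id=str(row.get("parameter_id", "")).strip(),
                prior_kind=(str(row["prior_kind"]).strip() or None)
                if "prior_kind" in df.columns
                else None,
                prior_arg1=_to_float(row.get("prior_arg1")),
                prior_arg2=_to_float(row.get("prior_arg2")),
                scale=str(row.get("scale", "lin")).strip() or "lin",
                estimate=_to_bool(row.get("estimate", "false")),
                nominal_value=_to_float(row.get("nominal_value")),
                target_path=str(row.get("target_path", "")).strip(),
            )
        )
    return out


def _build_conditions(df) -> list[ConditionSpec]:
    if df is None:
        return []
    out = []
    override_cols = [c for c in df.columns if c != "condition_id"]
    for _, row in df.iterrows():
        overrides = []
        for col in override_cols:
            cell = str(row[col]).strip()
            if cell:
                overrides.append((col, float(cell)))
        out.append(ConditionSpec(str(row.get("condition_id", "")).strip(), overrides))
    return out


def _build_measurements(df) -> list[MeasurementRecord]:
    if df is None:
        return []
    out = []
    for _, row in df.iterrows():
        value = _to_float(row.get("value"))
        ref = str(row.get("data_ref", "")).strip() or None if "data_ref" in df.columns else None
        rep = (
            str(row.get("replicate_id", "")).strip() or None
            if "replicate_id" in df.columns
            else None
        )
        out.append(
            MeasurementRecord(
                observable_id=str(row.get("observable_id", "")).strip(),
                condition_id=str(row.get("condition_id", "")).strip(),
                time=_to_float(row.get("time"), default=math.nan),
                value=value,
                data_ref=ref,
                replicate_id=rep,
            )
        )
    return out


def _build_statistics(df, issues) -> list[SummaryStatisticSpec]:
    if df is None:
        return []
    out = []
    for _, row in df.iterrows():
        raw_args = str(row.get("args", "")).strip()
        try:
            args = json.loads(raw_args) if raw_args else {}
            if not isinstance(args, dict):
                raise ValueError
        except (json.JSONDecodeError, ValueError):
            issues.append(
                ValidationIssue(
                    "error",
                    "STAT_BAD_ARGS",
                    f"statistic_table: {row.get('statistic_id')}: args is not a JSON object",
                )
            )
            args = {}
        obs = [o for o in str(row.get("observable_ids", "")).split(";") if o.strip()]
        out.append(
            SummaryStatisticSpec(
                statistic_id=str(row.get("statistic_id", "")).strip(),
                function_id=str(row.get("function_id", "")).strip(),
                args=args,
                observable_ids=[o.strip() for o in obs],
            )
        )
    return out


# ---------------------------------------------------------------------------
# validation


def validate_problem(p: ProblemSpec) -> list[ValidationIssue]:
    """Check every invariant; returns a deterministic, table-ordered report.

    Problems are report entries, never exceptions. An empty report means the
    bundle is valid.
    """
    from .summaries import STATISTIC_REGISTRY, statistic_arg_errors

    report: list[ValidationIssue] = list(p.parse_report)
    # a column reported missing at parse time makes every per-row check of
    # that column meaningless; suppress the cascade
    missing_cols = {
        i.message for i in p.parse_report if i.code == "SCHEMA_MISSING_COLUMN"
    }
    prior_cols_ok = not any(
        f"parameter_table: {c}" in missing_cols
        for c in ("prior_kind", "prior_arg1", "prior_arg2")
    )

    # parameter table
    seen = set()
    n_estimated = 0
    for i, par in enumerate(p.parameter_table):
        where = f"parameter_table row {i} ({par.parameter_id!r})"
        if par.parameter_id in seen:
            report.append(
                ValidationIssue("error", "PARAM_DUPLICATE_ID", f"{where}: duplicate id")
            )
        seen.add(par.parameter_id)
        if par.estimate:
            n_estimated += 1
        if par.estimate and prior_cols_ok:
            if par.prior_kind is None:
                report.append(
                    ValidationIssue("error", "PRIOR_MISSING", f"{where}: estimated but no prior")
                )
            elif par.prior_kind not in PRIOR_KINDS:
                report.append(
                    ValidationIssue(
                        "error", "PRIOR_KIND_UNKNOWN", f"{where}: {par.prior_kind!r}"
                    )
                )
            else:
                a1, a2 = par.prior_arg1, par.prior_arg2
                if a1 is None or a2 is None or math.isnan(a1) or math.isnan(a2):
                    report.append(
                        ValidationIssue("error", "PRIOR_MISSING", f"{where}: prior args absent")
                    )
                elif par.prior_kind in ("uniform", "log10-uniform"):
                    if not a1 < a2:
                        report.append(
                            ValidationIssue(
                                "error",
                                "PRIOR_BOUNDS",
                                f"{where}: lower bound {a1} not below upper bound {a2}",
                            )
                        )
                    if par.prior_kind == "log10-uniform" and a1 <= 0:
                        report.append(
                            ValidationIssue(
                                "error",
                                "PRIOR_POSITIVITY",
                                f"{where}: log10-uniform lower bound {a1} must be > 0",
                            )
                        )
                elif par.prior_kind == "normal" and a2 is not None and a2 <= 0:
                    report.append(
                        ValidationIssue("error", "PRIOR_SD_POSITIVITY", f"{where}: sd {a2} <= 0")
                    )
        if par.scale not in SCALES:
            report.append(ValidationIssue("error", "SCALE_UNKNOWN", f"{where}: {par.scale!r}"))
        try:
            resolve_path(p.model_document, par.target_path)
        except PathError as e:
            report.append(ValidationIssue("error", "PATH_UNRESOLVABLE", f"{where}: {e}"))
    if n_estimated == 0:
        report.append(
            ValidationIssue("error", "NO_ESTIMATED_PARAMETER", "parameter_table: no estimate=true row")
        )

    # condition table
    seen = set()
    for i, cond in enumerate(p.condition_table):
        where = f"condition_table row {i} ({cond.condition_id!r})"
        if cond.condition_id in seen:
            report.append(
                ValidationIssue("error", "CONDITION_DUPLICATE_ID", f"{where}: duplicate id")
            )
        seen.add(cond.condition_id)
        for path, _ in cond.overrides:
            try:
                resolve_path(p.model_document, path)
            except PathError as e:
                report.append(ValidationIssue("error", "PATH_UNRESOLVABLE", f"{where}: {e}"))

    # measurement table
    for i, m in enumerate(p.measurement_table):
        where = f"measurement_table row {i} ({m.observable_id!r})"
        has_value = m.value is not None and not math.isnan(m.value)
        if has_value == (m.data_ref is not None):
            report.append(
                ValidationIssue(
                    "error",
                    "MEAS_VALUE_XOR_REF",
                    f"{where}: exactly one of value/data_ref must be set",
                )
            )
        if m.time is None or math.isnan(m.time) or m.time < 0:
            report.append(ValidationIssue("error", "MEAS_TIME_INVALID", f"{where}: time {m.time}"))
        if m.data_ref is not None and p.directory is not None:
            if not (p.directory / m.data_ref).is_file():
                report.append(
                    ValidationIssue("error", "DATA_REF_MISSING", f"{where}: {m.data_ref}")
                )
    if not p.measurement_table:
        report.append(ValidationIssue("error", "NO_MEASUREMENT", "measurement_table: empty"))

    # statistic table
    for i, s in enumerate(p.statistic_table):
        where = f"statistic_table row {i} ({s.statistic_id!r})"
        if s.function_id not in STATISTIC_REGISTRY:
            report.append(
                ValidationIssue("error", "STAT_UNKNOWN_FUNCTION", f"{where}: {s.function_id!r}")
            )
        else:
            for msg in statistic_arg_errors(s.function_id, s.args):
                report.append(ValidationIssue("error", "STAT_BAD_ARGS", f"{where}: {msg}"))
    return report


# ---------------------------------------------------------------------------
# writing


def write_problem(p: ProblemSpec, index_path) -> None:
    """Serialize a bundle back to disk (yaml index + tsv tables + model xml)."""
    index_path = Path(index_path)
    base = index_path.parent
    base.mkdir(parents=True, exist_ok=True)
    names = {
        "model_file": "model.xml",
        "parameter_file": "parameters.tsv",
        "condition_file": "conditions.tsv",
        "measurement_file": "measurements.tsv",
        "statistic_file": "statistics.tsv",
    }
    index_path.write_text(yaml.safe_dump(dict(names), sort_keys=False))
    (base / names["model_file"]).write_bytes(
        etree.tostring(p.model_document, pretty_print=True, xml_declaration=False)
    )
    for table, key in (
        ("parameter_table", "parameter_file"),
        ("condition_table", "condition_file"),
        ("measurement_table", "measurement_file"),
        ("statistic_table", "statistic_file"),
    ):
        df = p.raw_tables.get(table)
        if df is None:
            df = _table_to_frame(p, table)
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        (base / names[key]).write_text(buf.getvalue())


def _table_to_frame(p: ProblemSpec, table: str) -> pd.DataFrame:
    if table == "parameter_table":
        return pd.DataFrame(
            [
                {
                    "parameter_id": s.parameter_id,
                    "prior_kind": s.prior_kind or "",
                    "prior_arg1": "" if s.prior_arg1 is None else s.prior_arg1,
                    "prior_arg2": "" if s.prior_arg2 is None else s.prior_arg2,
                    "scale": s.scale,
                    "estimate": str(s.estimate).lower(),
                    "nominal_value": "" if s.nominal_value is None else s.nominal_value,
                    "target_path": s.target_path,
                }
                for s in p.parameter_table
            ]
        )
    if table == "condition_table":
        paths = sorted({path for c in p.condition_table for path, _ in c.overrides})
        rows = []
        for c in p.condition_table:
            row = {"condition_id": c.condition_id}
            d = dict(c.overrides)
            for path in paths:
                row[path] = d.get(path, "")
            rows.append(row)
        return pd.DataFrame(rows, columns=["condition_id", *paths])
    if table == "measurement_table":
        return pd.DataFrame(
            [
                {
                    "observable_id": m.observable_id,
                    "condition_id": m.condition_id,
                    "time": m.time,
                    "value": "" if m.value is None else m.value,
                    "data_ref": m.data_ref or "",
                    "replicate_id": m.replicate_id or "",
                }
                for m in p.measurement_table
            ]
        )
    return pd.DataFrame(
        [
            {
                "statistic_id": s.statistic_id,
                "function_id": s.function_id,
                "args": json.dumps(s.args),
                "observable_ids": ";".join(s.observable_ids),
            }
            for s in p.statistic_table
        ]
    )


# ---------------------------------------------------------------------------
# sampling space and parameter mapping


def sample_space(p: ProblemSpec) -> list[tuple[str, float, float, str]]:
    """Bounds of every estimated parameter on its sampling scale.

    log10-scaled parameters are reported with log10-transformed bounds;
    normal priors report mean +/- 6 sd as nominal box bounds.
    """
    out = []
    for par in p.estimated:
        a1, a2 = par.prior_arg1, par.prior_arg2
        if par.prior_kind == "log10-uniform":
            out.append((par.parameter_id, math.log10(a1), math.log10(a2), "log10"))
        elif par.prior_kind == "uniform":
            out.append((par.parameter_id, a1, a2, par.scale))
        else:  # normal: unbounded support, report a wide nominal box
            out.append((par.parameter_id, a1 - 6 * a2, a1 + 6 * a2, par.scale))
    return out


def map_parameters(p: ProblemSpec, theta, condition_id: str):
    """Instantiate the model document for one parameter vector and condition.

    Returns a deep copy with (i) the condition's overrides applied, then
    (ii) nominal values of fixed parameters and (iii) the estimated
    parameters written at their target paths. Values sampled on a log10
    scale are back-transformed (10**theta) before writing. The input
    document is never modified.
    """
    theta = np.asarray(theta, dtype=float)
    estimated = p.estimated
    if theta.shape != (len(estimated),):
        raise ValueError(f"theta has length {theta.size}, expected {len(estimated)}")
    cond = next((c for c in p.condition_table if c.condition_id == condition_id), None)
    if cond is None:
        raise KeyError(f"unknown condition_id {condition_id!r}")
    doc = copy.deepcopy(p.model_document)
    for path, value in cond.overrides:
        write_path(doc, path, value)
    for par in p.parameter_table:
        if not par.estimate and par.nominal_value is not None and not math.isnan(par.nominal_value):
            write_path(doc, par.target_path, par.nominal_value)
    for par, val in zip(estimated, theta):
        model_value = 10.0**val if _sampling_scale(par) == "log10" else float(val)
        write_path(doc, par.target_path, model_value)
    return doc


def _sampling_scale(par: ParameterSpec) -> str:
    if par.prior_kind == "log10-uniform" or par.scale == "log10":
        return "log10"
    return "lin"


def load_gridded_array(path) -> np.ndarray:
    """Read one 2-D array from an NPY or CSV matrix file."""
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        arr = np.loadtxt(path, delimiter=",")
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D array, got shape {arr.shape}")
    return arr
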