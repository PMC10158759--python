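"""Reshape arbitrary instrument-export tables into canonical RDES.

Real-time PCR instruments export wide tables (one column per cycle) or
long tables (one row per well x cycle) with vendor-specific headers.  A
declarative :class:`ShapeSpec` — a small JSON document, so common
instrument layouts can ship as presets without per-instrument code — maps
the source columns onto the RDES fields; :func:`reshape` applies it and
returns a validated :class:`~rdes.io.PlateTable`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import PlateTable, WellRecord, _normalize_well_id, validate

__all__ = ["ShapeSpec", "ShapeSpecError", "ReshapeError", "reshape"]

#: RDES fields a spec must cover (via column_map or constants); shown to the
#: user under their canonical RDES header names.
MANDATORY_FIELDS = {
    "well": "Well",
    "sample": "Sample",
    "sample_type": "Sample type",
    "target": "Target",
    "target_type": "Target type",
    "dye": "Dye",
}
OPTIONAL_FIELDS = ("cq",)


class ShapeSpecError(Exception):
    """The spec itself is unusable (unmapped mandatory field, bad layout)."""


class ReshapeError(Exception):
    """The data do not fit the spec (duplicate readings, missing columns)."""


@dataclass
class ShapeSpec:
    """Declarative mapping from a source table onto RDES.

    layout
        ``"wide"`` (one row per well, trace in many columns) or ``"long"``
        (one row per reading).
    column_map
        source column name -> RDES field (``well``, ``sample``,
        ``sample_type``, ``target``, ``target_type``, ``dye``, ``cq``).
    cycle_columns
        wide layout: an explicit list of source columns in axis order, a
        ``{"pattern": <regex>}`` matched against headers (document order),
        or ``"auto"`` for all purely numeric headers.
        long layout: ``{"index": <cycle/temperature column>,
        "value": <fluorescence column>}``.
    constants
        fixed values for RDES fields absent from the source
        (e.g. ``{"dye": "SYBR"}``).
    """

    layout: str
    column_map: dict = field(default_factory=dict)
    cycle_columns: object = "auto"
    constants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layout not in ("wide", "long"):
            raise ShapeSpecError(f"layout must be 'wide' or 'long', got {self.layout!r}")
        covered = set(self.column_map.values()) | set(self.constants)
        missing = [disp for f, disp in MANDATORY_FIELDS.items() if f not in covered]
        if missing:
            raise ShapeSpecError(
                "spec does not cover mandatory RDES field(s): " + ", ".join(missing))
        unknown = covered - set(MANDATORY_FIELDS) - set(OPTIONAL_FIELDS)
        if unknown:
            raise ShapeSpecError(f"unknown RDES field(s) in spec: {sorted(unknown)}")

    @classmethod
    def from_json(cls, source) -> "ShapeSpec":
        if hasattr(source, "read"):
            d = json.load(source)
        elif isinstance(source, (str, Path)) and Path(str(source)).exists():
            d = json.loads(Path(source).read_text(encoding="utf-8"))
        else:
            d = json.loads(source)
        return cls(layout=d["layout"], column_map=d.get("column_map", {}),
                   cycle_columns=d.get("cycle_columns", "auto"),
                   constants=d.get("constants", {}))


def _load_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source, sep=None, engine="python", dtype=str,
                       skipinitialspace=True)


def _resolve_trace_columns(df: pd.DataFrame, spec: ShapeSpec) -> list[str]:
    mapped = set(spec.column_map)
    candidates = [c for c in df.columns if c not in mapped]
    cc = spec.cycle_columns
    if isinstance(cc, (list, tuple)):
        missing = [c for c in cc if c not in df.columns]
        if missing:
            raise ReshapeError(f"cycle columns not in source table: {missing}")
        cols = list(cc)
    elif isinstance(cc, dict) and "pattern" in cc:
        rx = re.compile(cc["pattern"])
        cols = [c for c in candidates if rx.fullmatch(str(c).strip())]
    else:  # "auto": numeric headers, document order
        cols = [c for c in candidates
                if re.fullmatch(r"-?\d+(\.\d+)?", str(c).strip())]
    if len(cols) < 2:
        raise ReshapeError(
            f"cycle_columns resolved to {len(cols)} trace column(s); need >= 2")
    return cols


def _field_values(df: pd.DataFrame, spec: ShapeSpec, fld: str) -> pd.Series:
    for src, f in spec.column_map.items():
        if f == fld:
            if src not in df.columns:
                raise ReshapeError(f"mapped column {src!r} not in source table")
            return df[src].astype(str)
    return pd.Series([str(spec.constants[fld])] * len(df), index=df.index)


def _axis_from_labels(labels) -> np.ndarray:
    """Numeric axis from column labels; non-numeric labels (e.g. "Cycle 3")
    contribute their embedded number, or their 1-based position as a last
    resort."""
    values = []
    for i, v in enumerate(labels):
        s = str(v).strip()
        try:
            values.append(float(s))
            continue
        except ValueError:
            pass
        m = re.search(r"-?\d+(\.\d+)?", s)
        values.append(float(m.group()) if m else float(i + 1))
    axis = np.array(values)
    if np.any(np.diff(axis) <= 0):
        raise ReshapeError("cycle/temperature labels are not strictly increasing")
    return axis


def _variant_for_axis(axis: np.ndarray) -> str:
    is_amp = (axis[0] == 1.0 and np.all(np.diff(axis) == 1.0)
              and np.all(axis == np.round(axis)))
    return "amplification" if is_amp else "melt"


def reshape(source, spec: ShapeSpec) -> PlateTable:
    """Apply a :class:`ShapeSpec` to a source table and return a valid plate.

    ``source`` may be a pandas DataFrame or anything ``pandas.read_csv``
    accepts (delimiter auto-detected).  The result is guaranteed to pass
    :func:`rdes.io.validate` with no errors; otherwise :class:`ReshapeError`
    is raised listing the findings.
    """
    df = _load_table(source)

    if spec.layout == "wide":
        trace_cols = _resolve_trace_columns(df, spec)
        axis = _axis_from_labels(trace_cols)
        ann = {f: _field_values(df, spec, f) for f in MANDATORY_FIELDS}
        cq = None
        if any(f == "cq" for f in spec.column_map.values()) or "cq" in spec.constants:
            cq = _field_values(df, spec, "cq")
        records = []
        for i in range(len(df)):
            trace = np.array([_to_float(df.iloc[i][c], c, i) for c in trace_cols])
            reported = _parse_optional_float(cq.iloc[i]) if cq is not None else None
            records.append(WellRecord(
                _normalize_well_id(ann["well"].iloc[i]), ann["sample"].iloc[i],
                ann["sample_type"].iloc[i], ann["target"].iloc[i],
                ann["target_type"].iloc[i], ann["dye"].iloc[i], reported, trace))
    else:  # long
        cc = spec.cycle_columns
        if not (isinstance(cc, dict) and "index" in cc and "value" in cc):
            raise ShapeSpecError(
                "long layout needs cycle_columns = {'index': ..., 'value': ...}")
        for col in (cc["index"], cc["value"]):
            if col not in df.columns:
                raise ReshapeError(f"column {col!r} not in source table")
        work = pd.DataFrame({
            "well": _field_values(df, spec, "well").map(_normalize_well_id),
            "sample": _field_values(df, spec, "sample"),
            "sample_type": _field_values(df, spec, "sample_type"),
            "target": _field_values(df, spec, "target"),
            "target_type": _field_values(df, spec, "target_type"),
            "dye": _field_values(df, spec, "dye"),
            "idx": df[cc["index"]].astype(float),
            "val": df[cc["value"]].astype(float),
        })
        if any(f == "cq" for f in spec.column_map.values()) or "cq" in spec.constants:
            work["cq"] = _field_values(df, spec, "cq")
        dup = work.duplicated(subset=["well", "dye", "idx"])
        if dup.any():
            rows = work.loc[dup, ["well", "idx"]].head(3).values.tolist()
            raise ReshapeError(
                f"duplicate (well, cycle) readings in long input, e.g. {rows}")
        axis = np.array(sorted(work["idx"].unique()))
        if len(axis) < 2:
            raise ReshapeError("long input resolves to fewer than 2 trace points")
        records = []
        keys = ["well", "sample", "sample_type", "target", "target_type", "dye"]
        for key, grp in work.groupby(keys, sort=False):
            pivot = grp.set_index("idx")["val"].reindex(axis)
            reported = None
            if "cq" in grp.columns:
                reported = _parse_optional_float(grp["cq"].iloc[0])
            records.append(WellRecord(*key, reported, pivot.to_numpy()))

    plate = PlateTable(records, _variant_for_axis(axis), axis,
                       meta={"reshaped": True, "layout": spec.layout})
    report = validate(plate)
    if not report.ok:
        msgs = "; ".join(f"{f.code}: {f.message}" for f in report.errors)
        raise ReshapeError(f"reshaped table fails RDES validation: {msgs}")
    return plate


def _to_float(cell, col, row_i) -> float:
    s = str(cell).strip()
    if s == "" or s.lower() == "nan":
        return float("nan")
    try:
        return float(s)
    except ValueError:
        raise ReshapeError(
            f"non-numeric trace cell at row {row_i}, column {col!r}: {cell!r}"
        ) from None


def _parse_optional_float(cell) -> float | None:
    s = str(cell).strip()
    if s == "" or s in ("NA", "NaN", "nan", "Undetermined", "None"):
        return None
    return float(s)
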