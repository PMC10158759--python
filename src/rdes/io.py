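"""Reading, writing and validating RDES tables.

RDES (Real-time PCR Data Essential Spreadsheet) is a flat, one-row-per-well
disclosure format for raw RT-qPCR data: six annotation columns
(``Well, Sample, Sample type, Target, Target type, Dye``), the instrument's
reported summary value (``Cq`` for amplification runs, optionally ``Tm`` for
melt runs) and then one column per cycle (or per temperature, for melt
curves) holding the raw fluorescence reading.

The module exposes :func:`read_rdes`, :func:`write_rdes` and
:func:`validate`, built around the :class:`PlateTable` / :class:`WellRecord`
containers.  The writer emits a canonical byte-deterministic form (comma
delimiter, dot decimals, row-major well order); the reader is tolerant of
the common spreadsheet-export variations (semicolon/tab delimiters, decimal
commas, zero-padded well labels) and of the column-elision marker ``…``
used when a table excerpt omits interior cycles.
"""

from __future__ import annotations

import csv
import io as _io
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SAMPLE_TYPES",
    "TARGET_TYPES",
    "WellRecord",
    "PlateTable",
    "Finding",
    "ValidationReport",
    "RdesError",
    "RdesFormatError",
    "RdesValidationError",
    "read_rdes",
    "write_rdes",
    "validate",
]

#: RDML controlled vocabulary for sample roles: unknown, standard,
#: no-template control, no-amplification control, no-target-present,
#: minus-RT control, positive control, optimisation.
SAMPLE_TYPES = frozenset({"unkn", "std", "ntc", "nac", "ntp", "nrt", "pos", "opt"})

#: Target roles: target of interest vs. reference (normalisation) gene.
TARGET_TYPES = frozenset({"toi", "ref"})

ANNOTATION_COLUMNS = ("Well", "Sample", "Sample type", "Target", "Target type", "Dye")

MISSING_CQ_TOKENS = frozenset({"NA", "NaN", "Undetermined"})

ELLIPSIS_TOKENS = frozenset({"…", "..."})

_WELL_RE = re.compile(r"^([A-P])0*([1-9]\d?)$")


class RdesError(Exception):
    """Base class for RDES errors."""


class RdesFormatError(RdesError):
    """Malformed RDES input (bad header, ragged row, non-numeric cell...)."""


class RdesValidationError(RdesError):
    """A strict writer refused a plate that fails validation."""

    def __init__(self, findings: list["Finding"]):
        self.findings = findings
        msgs = "; ".join(f"{f.code}: {f.message}" for f in findings)
        super().__init__(f"plate fails validation ({len(findings)} error(s)): {msgs}")


def _normalize_well_id(label: str) -> str:
    m = _WELL_RE.match(label.strip())
    if not m:
        raise RdesFormatError(f"invalid well label {label!r}")
    return f"{m.group(1)}{int(m.group(2))}"


def _well_sort_key(well_id: str) -> tuple[int, int]:
    m = _WELL_RE.match(well_id)
    if not m:
        return (999, 999)
    return (ord(m.group(1)) - ord("A"), int(m.group(2)))


@dataclass
class WellRecord:
    """One well's annotations, reported summary value and raw trace.

    ``trace`` is aligned with the plate axis (cycle numbers or temperatures);
    missing readings (e.g. elided columns in a published excerpt) are NaN.
    ``reported_cq`` holds the instrument's Cq (amplification) or Tm (melt);
    ``None`` means the cell was empty.
    """

    well_id: str
    sample: str
    sample_type: str
    target: str
    target_type: str
    dye: str
    reported_cq: float | None
    trace: np.ndarray

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WellRecord):
            return NotImplemented
        same_cq = (
            (self.reported_cq is None and other.reported_cq is None)
            or (
                self.reported_cq is not None
                and other.reported_cq is not None
                and self.reported_cq == other.reported_cq
            )
        )
        return (
            self.well_id == other.well_id
            and self.sample == other.sample
            and self.sample_type == other.sample_type
            and self.target == other.target
            and self.target_type == other.target_type
            and self.dye == other.dye
            and same_cq
            and self.trace.shape == other.trace.shape
            and bool(np.array_equal(self.trace, other.trace, equal_nan=True))
        )


@dataclass
class PlateTable:
    """A full RDES plate: well records sharing one cycle/temperature axis."""

    records: list[WellRecord]
    variant: str  # "amplification" | "melt"
    axis: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)

    @property
    def n_cycles(self) -> int:
        return len(self.axis)

    def record(self, well_id: str, dye: str | None = None) -> WellRecord:
        """Return the record for ``well_id`` (and ``dye``, if multiplexed)."""
        for rec in self.records:
            if rec.well_id == well_id and (dye is None or rec.dye == dye):
                return rec
        raise KeyError((well_id, dye))

    def sorted_records(self) -> list[WellRecord]:
        return sorted(self.records, key=lambda r: (_well_sort_key(r.well_id), r.dye))

    def equals(self, other: "PlateTable") -> bool:
        """Field-for-field equality of variant, axis and records.

        Record order is canonicalised (row-major by well, then dye) before
        comparison; ``meta`` (provenance) is deliberately ignored.
        """
        if not isinstance(other, PlateTable):
            return False
        return (
            self.variant == other.variant
            and self.axis.shape == other.axis.shape
            and bool(np.array_equal(self.axis, other.axis))
            and self.sorted_records() == other.sorted_records()
        )

    __eq__ = equals  # type: ignore[assignment]

    def to_frame(self):
        """Return the plate as a pandas DataFrame in RDES column order."""
        import pandas as pd

        summary = "Cq" if self.variant == "amplification" else "Tm"
        cols = list(ANNOTATION_COLUMNS) + [summary] + [
            _axis_label(v, self.variant) for v in self.axis
        ]
        rows = []
        for rec in self.sorted_records():
            rows.append(
                [rec.well_id, rec.sample, rec.sample_type, rec.target,
                 rec.target_type, rec.dye,
                 rec.reported_cq if rec.reported_cq is not None else np.nan]
                + list(rec.trace)
            )
        return pd.DataFrame(rows, columns=cols)


@dataclass
class Finding:
    """One validation finding: a stable code, an optional well, a message."""

    code: str
    well_id: str | None
    message: str

    def to_dict(self) -> dict:
        return {"code": self.code, "well_id": self.well_id, "message": self.message}


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: errors, warnings, suggestions, counts."""

    errors: list[Finding] = field(default_factory=list)
    warnings: list[Finding] = field(default_factory=list)
    suggestions: list[Finding] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "errors": [f.to_dict() for f in self.errors],
            "warnings": [f.to_dict() for f in self.warnings],
            "suggestions": [f.to_dict() for f in self.suggestions],
            "counts": dict(self.counts),
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


# ---------------------------------------------------------------------------
# reading


def _axis_label(value: float, variant: str) -> str:
    if variant == "amplification":
        return str(int(round(value)))
    return f"{value:.1f}"


def _sniff_delimiter(header_line: str) -> str:
    counts = {d: header_line.count(d) for d in (",", ";", "\t")}
    best = max(counts, key=lambda d: counts[d])
    if counts[best] == 0:
        raise RdesFormatError("could not detect a delimiter in the header row")
    return best


def _parse_number(cell: str, delimiter: str) -> float:
    cell = cell.strip()
    # decimal commas only make sense when the comma is not the field delimiter
    if delimiter in (";", "\t") and re.fullmatch(r"-?\d+,\d+", cell):
        cell = cell.replace(",", ".")
    return float(cell)


def _parse_axis_header(
    cells: Sequence[str], delimiter: str
) -> tuple[np.ndarray, str, list[int]]:
    """Parse trailing numeric headers into an axis.

    Returns (axis, variant, keep_positions) where keep_positions maps each
    axis entry to the source column position, or -1 for axis values created
    by expanding an ellipsis marker (missing in the file).
    """
    tokens: list[float | None] = []  # None = ellipsis marker
    for c in cells:
        if c.strip() in ELLIPSIS_TOKENS:
            tokens.append(None)
            continue
        try:
            tokens.append(_parse_number(c, delimiter))
        except ValueError:
            raise RdesFormatError(f"non-numeric cycle/temperature header {c!r}") from None

    concrete = [t for t in tokens if t is not None]
    if not concrete:
        raise RdesFormatError("no cycle/temperature columns found in header")
    all_int = all(float(t).is_integer() for t in concrete)

    axis: list[float] = []
    keep: list[int] = []
    for pos, tok in enumerate(tokens):
        if tok is not None:
            axis.append(tok)
            keep.append(pos)
            continue
        # ellipsis: only expandable between integer headers
        if not all_int or pos == 0 or pos == len(tokens) - 1:
            raise RdesFormatError("ellipsis column in a position that cannot be expanded")
        lo, hi = tokens[pos - 1], tokens[pos + 1]
        if lo is None or hi is None or hi <= lo + 1:
            raise RdesFormatError("ellipsis column does not span an integer gap")
        for v in range(int(lo) + 1, int(hi)):
            axis.append(float(v))
            keep.append(-1)

    arr = np.asarray(axis, dtype=float)
    if np.any(np.diff(arr) <= 0):
        raise RdesFormatError("cycle/temperature headers are not strictly increasing")
    is_amp_axis = all_int and arr[0] == 1.0 and np.all(np.diff(arr) == 1.0)
    variant = "amplification" if is_amp_axis else "melt"
    return arr, variant, keep


def read_rdes(source, variant_hint: str = "auto") -> PlateTable:
    """Parse an RDES table from a path, string or text stream.

    Parameters
    ----------
    source
        Path to a delimited text file, the file content as a string, or an
        open text stream.  The first row must be the RDES header.
    variant_hint
        ``"amplification"``, ``"melt"`` or ``"auto"``.  Auto-detection
        classifies an axis of consecutive integers starting at 1 as an
        amplification run, anything else (non-integer or non-consecutive
        temperatures) as a melt run.

    Returns
    -------
    PlateTable
        Parsed plate.  ``meta`` records the detected delimiter, the source
        column count, and any parse warnings (e.g. ``"NA"`` accepted as a
        missing Cq).

    Raises
    ------
    RdesFormatError
        On a missing mandatory column, ragged row, non-numeric trace cell
        or an empty plate.
    """
    if variant_hint not in ("amplification", "melt", "auto"):
        raise ValueError(f"unknown variant_hint {variant_hint!r}")

    text = _read_text(source)
    first_line = text.splitlines()[0] if text else ""
    delimiter = _sniff_delimiter(first_line)
    rows = list(csv.reader(_io.StringIO(text), delimiter=delimiter))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        raise RdesFormatError("empty input: no header row")
    header = [c.strip() for c in rows[0]]

    for i, want in enumerate(ANNOTATION_COLUMNS):
        if i >= len(header) or header[i] != want:
            raise RdesFormatError(
                f"missing mandatory header column {want!r} at position {i + 1}"
            )

    pos = len(ANNOTATION_COLUMNS)
    summary_name: str | None = None
    if pos < len(header) and header[pos] in ("Cq", "Tm"):
        summary_name = header[pos]
        pos += 1
    if pos >= len(header):
        raise RdesFormatError("no cycle/temperature columns found in header")

    axis, detected_variant, keep = _parse_axis_header(header[pos:], delimiter)
    variant = detected_variant if variant_hint == "auto" else variant_hint
    if variant == "amplification" and summary_name is None:
        raise RdesFormatError("missing mandatory header column 'Cq' at position 7")

    warnings: list[str] = []
    records: list[WellRecord] = []
    n_columns = len(header)
    for row_idx, row in enumerate(rows[1:], start=2):
        if len(row) != n_columns:
            raise RdesFormatError(
                f"ragged row {row_idx}: expected {n_columns} cells, got {len(row)}"
            )
        cells = [c.strip() for c in row]
        well_id = _normalize_well_id(cells[0])
        sample, sample_type, target, target_type, dye = cells[1:6]

        reported: float | None = None
        if summary_name is not None:
            raw_cq = cells[6]
            if raw_cq == "":
                reported = None
            elif raw_cq in MISSING_CQ_TOKENS:
                reported = None
                warnings.append(
                    f"row {row_idx} ({well_id}): literal {raw_cq!r} treated as missing {summary_name}"
                )
            else:
                try:
                    reported = _parse_number(raw_cq, delimiter)
                except ValueError:
                    raise RdesFormatError(
                        f"non-numeric {summary_name} cell at row {row_idx}: {raw_cq!r}"
                    ) from None

        trace = np.full(len(axis), np.nan)
        data_cells = cells[pos:]
        for axis_i, src_pos in enumerate(keep):
            if src_pos == -1:
                continue  # elided column: stays NaN
            cell = data_cells[src_pos] if src_pos < len(data_cells) else ""
            if cell in ELLIPSIS_TOKENS or cell == "":
                continue
            try:
                trace[axis_i] = _parse_number(cell, delimiter)
            except ValueError:
                raise RdesFormatError(
                    f"non-numeric trace cell at row {row_idx}, column {header[pos + src_pos]!r}: {cell!r}"
                ) from None

        records.append(
            WellRecord(well_id, sample, sample_type, target, target_type, dye,
                       reported, trace)
        )

    if not records:
        raise RdesFormatError("empty plate: header present but no data rows")

    meta = {
        "delimiter": delimiter,
        "n_source_columns": n_columns,
        "n_source_rows": len(rows) - 1,
        "summary_column": summary_name,
        "elided_columns": int(sum(1 for k in keep if k == -1)),
        "warnings": warnings,
    }
    if isinstance(source, (str, Path)) and _looks_like_path(source):
        meta["source"] = str(source)
    return PlateTable(records=records, variant=variant, axis=axis, meta=meta)


def _looks_like_path(source) -> bool:
    if isinstance(source, Path):
        return True
    return isinstance(source, str) and "\n" not in source and "," not in source


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, Path) or _looks_like_path(source):
        return Path(source).read_text(encoding="utf-8")
    return str(source)


# ---------------------------------------------------------------------------
# writing


def _format_number(x: float) -> str:
    if math.isnan(x):
        return ""
    if float(x).is_integer() and abs(x) < 1e16:
        return str(int(x))
    return repr(float(x))


def write_rdes(plate: PlateTable, path=None) -> str:
    """Serialize a plate to canonical RDES CSV.

    The canonical form is byte-deterministic: comma delimiter, dot decimals,
    unpadded well labels, rows sorted row-major by well then dye, ``Cq``
    (or ``Tm``) summary column, missing values as empty cells.

    Raises :class:`RdesValidationError` if the plate has validation errors.
    Returns the CSV text; if ``path`` is given the text is also written there.
    """
    report = validate(plate)
    if not report.ok:
        raise RdesValidationError(report.errors)

    summary = "Cq" if plate.variant == "amplification" else "Tm"
    header = list(ANNOTATION_COLUMNS) + [summary] + [
        _axis_label(v, plate.variant) for v in plate.axis
    ]
    lines = [",".join(header)]
    for rec in plate.sorted_records():
        cq = "" if rec.reported_cq is None else _format_number(rec.reported_cq)
        cells = [rec.well_id, rec.sample, rec.sample_type, rec.target,
                 rec.target_type, rec.dye, cq]
        cells += [_format_number(v) for v in rec.trace]
        lines.append(",".join(cells))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# validation


def validate(plate: PlateTable) -> ValidationReport:
    """Apply every RDES structural rule to a plate and report findings.

    Errors (any one makes strict writers refuse the plate): empty plate,
    duplicate (well, dye) rows, malformed well labels, unknown sample/target
    type tokens (validated case-sensitively, never coerced), trace/axis
    length mismatch, non-monotone axis, reported Cq outside the cycle range.

    Suggestions include ``GEO_DEPOSIT`` when the experiment is large enough
    (>= 20 distinct samples and >= 20 distinct targets) that public
    deposition, e.g. with the Gene Expression Omnibus, is recommended.
    """
    errors: list[Finding] = []
    warnings: list[Finding] = []
    suggestions: list[Finding] = []

    if not plate.records:
        errors.append(Finding("EMPTY_PLATE", None, "plate contains no well records"))

    axis = plate.axis
    if len(axis) == 0:
        errors.append(Finding("EMPTY_AXIS", None, "plate has no cycle/temperature axis"))
    elif np.any(np.diff(axis) <= 0):
        errors.append(Finding("NON_MONOTONE_AXIS", None,
                              "axis values are not strictly increasing"))
    if plate.variant == "amplification" and len(axis) and (
        axis[0] != 1.0 or not np.all(np.diff(axis) == 1.0)
    ):
        errors.append(Finding(
            "BAD_CYCLE_AXIS", None,
            "amplification axis must be consecutive integers starting at 1"))

    seen: set[tuple[str, str]] = set()
    for rec in plate.records:
        wid = rec.well_id
        if not _WELL_RE.match(wid):
            errors.append(Finding("BAD_WELL_ID", wid, f"malformed well label {wid!r}"))
        key = (wid, rec.dye)
        if key in seen:
            errors.append(Finding("DUPLICATE_WELL", wid,
                                  f"duplicate (well, dye) pair {key!r}"))
        seen.add(key)
        if rec.sample_type not in SAMPLE_TYPES:
            errors.append(Finding(
                "BAD_SAMPLE_TYPE", wid,
                f"unknown sample type {rec.sample_type!r} (allowed: "
                f"{', '.join(sorted(SAMPLE_TYPES))})"))
        if rec.target_type not in TARGET_TYPES:
            errors.append(Finding(
                "BAD_TARGET_TYPE", wid,
                f"unknown target type {rec.target_type!r} (allowed: "
                f"{', '.join(sorted(TARGET_TYPES))})"))
        if len(rec.trace) != len(axis):
            errors.append(Finding(
                "AXIS_MISMATCH", wid,
                f"trace has {len(rec.trace)} readings but the axis has {len(axis)}"))
        if rec.reported_cq is not None and len(axis):
            if plate.variant == "amplification":
                if not (1.0 <= rec.reported_cq <= axis[-1]):
                    errors.append(Finding(
                        "CQ_OUT_OF_RANGE", wid,
                        f"reported Cq {rec.reported_cq} outside [1, {axis[-1]:g}]"))
            else:
                if not (axis[0] <= rec.reported_cq <= axis[-1]):
                    warnings.append(Finding(
                        "TM_OUT_OF_RANGE", wid,
                        f"reported Tm {rec.reported_cq} outside the temperature axis"))

    samples = {r.sample for r in plate.records}
    targets = {r.target for r in plate.records}
    if len(samples) >= 20 and len(targets) >= 20:
        suggestions.append(Finding(
            "GEO_DEPOSIT", None,
            f"{len(samples)} samples x {len(targets)} targets: consider depositing "
            "the raw data with a public database such as the Gene Expression Omnibus"))

    for msg in plate.meta.get("warnings", []):
        warnings.append(Finding("PARSE_WARNING", None, msg))

    report = ValidationReport(
        errors=errors,
        warnings=warnings,
        suggestions=suggestions,
        counts={
            "n_wells": len(plate.records),
            "n_samples": len(samples),
            "n_targets": len(targets),
            "n_cycles": len(axis),
        },
    )
    return report
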