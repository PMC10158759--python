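"""RDES <-> RDML interchange (a minimal, schema-faithful RDML subset).

RDML is the XML interchange standard for real-time PCR runs.  This bridge
covers the subset an RDES table can represent: the sample and target
dictionaries, and per-reaction data blocks holding the reported Cq/Tm,
amplification data points (``adp``: cycle + fluorescence) and melt data
points (``mdp``: temperature + fluorescence).  Element names follow the
RDML 1.2 vocabulary; experimenters, thermal profiles and digital-PCR
partitions are out of scope.

RDML files on disk are conventionally ZIP containers holding
``rdml_data.xml``; :func:`from_rdml` sniffs the magic bytes and accepts
bare XML as well.  :func:`to_rdml` always emits bare XML.
"""

from __future__ import annotations

import io as _io
import zipfile
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .io import PlateTable, RdesValidationError, WellRecord, validate

__all__ = ["RdmlError", "to_rdml", "from_rdml", "RDML_NAMESPACE", "RDML_VERSION"]

RDML_NAMESPACE = "http://www.rdml.org"
RDML_VERSION = "1.2"


class RdmlError(Exception):
    pass


def _well_to_react_id(well_id: str, n_cols: int) -> int:
    row = ord(well_id[0]) - ord("A")
    col = int(well_id[1:])
    return row * n_cols + col


def _react_id_to_well(react_id: int, n_cols: int) -> str:
    row, col = divmod(react_id - 1, n_cols)
    return f"{chr(ord('A') + row)}{col + 1}"


def _plate_extent(plates: list[PlateTable]) -> tuple[int, int]:
    rows = cols = 1
    for p in plates:
        for rec in p.records:
            rows = max(rows, ord(rec.well_id[0]) - ord("A") + 1)
            cols = max(cols, int(rec.well_id[1:]))
    return rows, cols


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def to_rdml(amp: PlateTable | None, melt: PlateTable | None = None) -> str:
    """Serialize plate(s) to an RDML 1.2 subset XML document.

    ``amp`` and/or ``melt`` may be given; when both are, their (well, dye)
    sets must match exactly (they describe the same physical reactions) or
    an :class:`RdmlError` lists the offenders.  Sample and target
    dictionaries are deduplicated; missing (NaN) trace readings are
    skipped, since RDML has no placeholder for an unrecorded cycle.
    """
    plates = [p for p in (amp, melt) if p is not None]
    if not plates:
        raise ValueError("at least one of amp/melt must be given")
    for p in plates:
        report = validate(p)
        if not report.ok:
            raise RdesValidationError(report.errors)
    if amp is not None and melt is not None:
        amp_keys = {(r.well_id, r.dye) for r in amp.records}
        melt_keys = {(r.well_id, r.dye) for r in melt.records}
        if amp_keys != melt_keys:
            offenders = sorted(amp_keys ^ melt_keys)
            raise RdmlError(
                f"amplification and melt well sets differ: {offenders}")

    n_rows, n_cols = _plate_extent(plates)

    samples: dict[str, str] = {}
    targets: dict[str, tuple[str, str]] = {}
    for p in plates:
        for rec in p.records:
            samples.setdefault(rec.sample, rec.sample_type)
            targets.setdefault(rec.target, (rec.target_type, rec.dye))

    ET.register_namespace("", RDML_NAMESPACE)
    ns = f"{{{RDML_NAMESPACE}}}"
    root = ET.Element(f"{ns}rdml", {"version": RDML_VERSION})

    for dye in sorted({d for _t, d in targets.values()}):
        ET.SubElement(root, f"{ns}dye", {"id": dye})
    for sid, stype in samples.items():
        s = ET.SubElement(root, f"{ns}sample", {"id": sid})
        ET.SubElement(s, f"{ns}type").text = stype
    for tid, (ttype, dye) in targets.items():
        t = ET.SubElement(root, f"{ns}target", {"id": tid})
        ET.SubElement(t, f"{ns}type").text = ttype
        ET.SubElement(t, f"{ns}dyeId", {"id": dye})

    exp = ET.SubElement(root, f"{ns}experiment", {"id": "exp1"})
    run = ET.SubElement(exp, f"{ns}run", {"id": "run1"})
    fmt = ET.SubElement(run, f"{ns}pcrFormat")
    ET.SubElement(fmt, f"{ns}rows").text = str(n_rows)
    ET.SubElement(fmt, f"{ns}columns").text = str(n_cols)
    ET.SubElement(fmt, f"{ns}rowLabel").text = "ABC"
    ET.SubElement(fmt, f"{ns}columnLabel").text = "123"

    # one react per well, one data block per (well, dye) reaction
    reacts: dict[int, ET.Element] = {}
    datas: dict[tuple[str, str], ET.Element] = {}

    def get_data(rec: WellRecord) -> ET.Element:
        rid = _well_to_react_id(rec.well_id, n_cols)
        react = reacts.get(rid)
        if react is None:
            react = ET.SubElement(run, f"{ns}react", {"id": str(rid)})
            ET.SubElement(react, f"{ns}sample", {"id": rec.sample})
            reacts[rid] = react
        key = (rec.well_id, rec.dye)
        data = datas.get(key)
        if data is None:
            data = ET.SubElement(react, f"{ns}data")
            ET.SubElement(data, f"{ns}tar", {"id": rec.target})
            datas[key] = data
        return data

    if amp is not None:
        for rec in amp.sorted_records():
            data = get_data(rec)
            if rec.reported_cq is not None:
                ET.SubElement(data, f"{ns}cq").text = _fmt(rec.reported_cq)
            for c, f in zip(amp.axis, rec.trace):
                if np.isnan(f):
                    continue
                adp = ET.SubElement(data, f"{ns}adp")
                ET.SubElement(adp, f"{ns}cyc").text = _fmt(c)
                ET.SubElement(adp, f"{ns}fluor").text = _fmt(f)
    if melt is not None:
        for rec in melt.sorted_records():
            data = get_data(rec)
            if rec.reported_cq is not None:
                ET.SubElement(data, f"{ns}meltTemp").text = _fmt(rec.reported_cq)
            for t, f in zip(melt.axis, rec.trace):
                if np.isnan(f):
                    continue
                mdp = ET.SubElement(data, f"{ns}mdp")
                ET.SubElement(mdp, f"{ns}tmp").text = _fmt(t)
                ET.SubElement(mdp, f"{ns}fluor").text = _fmt(f)

    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_document(source) -> str:
    if isinstance(source, bytes):
        raw = source
    elif hasattr(source, "read"):
        raw = source.read()
        if isinstance(raw, str):
            return raw
    elif isinstance(source, (str, Path)) and "\n" not in str(source) \
            and Path(str(source)).exists():
        raw = Path(source).read_bytes()
    else:
        return str(source)
    if raw[:2] == b"PK":  # RDML's on-disk ZIP container
        with zipfile.ZipFile(_io.BytesIO(raw)) as zf:
            names = [n for n in zf.namelist() if n.lower().endswith(".xml")]
            if not names:
                raise RdmlError("ZIP container holds no XML document")
            preferred = [n for n in names if n == "rdml_data.xml"] or names
            raw = zf.read(preferred[0])
    return raw.decode("utf-8")


def from_rdml(source) -> tuple[PlateTable | None, PlateTable | None]:
    """Parse an RDML subset document into (amp plate, melt plate).

    ``source`` may be a path (bare XML or ZIP container), XML text/bytes,
    or an open stream.  Either plate is ``None`` when the document carries
    no data points of that kind.  Unsupported RDML content (thermal
    profiles, experimenter records...) is ignored; warnings are recorded in
    the plates' ``meta``.  Unresolvable sample/target references and
    non-monotone or ragged data-point lists are errors, because an RDES
    table is rectangular by construction.
    """
    text = _read_document(source)
    try:
        root = ET.fromstring(text)
    except ET.ParseError as e:
        raise RdmlError(f"not well-formed XML: {e}") from None
    if _local(root.tag) != "rdml":
        raise RdmlError(f"root element is {_local(root.tag)!r}, expected 'rdml'")
    version = root.get("version", "")

    samples: dict[str, str] = {}
    targets: dict[str, tuple[str, str]] = {}
    warnings: list[str] = []
    for child in root:
        tag = _local(child.tag)
        if tag == "sample":
            stype = "unkn"
            for sub in child:
                if _local(sub.tag) == "type" and sub.text:
                    stype = sub.text.strip()
            samples[child.get("id", "")] = stype
        elif tag == "target":
            ttype, dye = "toi", ""
            for sub in child:
                if _local(sub.tag) == "type" and sub.text:
                    ttype = sub.text.strip()
                elif _local(sub.tag) == "dyeId":
                    dye = sub.get("id", "") or (sub.text or "").strip()
            targets[child.get("id", "")] = (ttype, dye)
        elif tag not in ("dye", "experiment"):
            warnings.append(f"ignored unsupported RDML element <{tag}>")

    amp_rows: list[tuple[WellRecord, list[float], list[float]]] = []
    melt_rows: list[tuple[WellRecord, list[float], list[float]]] = []

    n_cols = 12
    for run in root.iter():
        if _local(run.tag) != "run":
            continue
        for el in run:
            if _local(el.tag) == "pcrFormat":
                for sub in el:
                    if _local(sub.tag) == "columns" and sub.text:
                        n_cols = int(sub.text)
        for react in el_iter(run, "react"):
            rid = react.get("id")
            try:
                well = _react_id_to_well(int(rid), n_cols)
            except (TypeError, ValueError):
                raise RdmlError(f"react id {rid!r} is not an integer") from None
            sample_id = None
            for sub in react:
                if _local(sub.tag) == "sample":
                    sample_id = sub.get("id") or (sub.text or "").strip()
            if sample_id is None or sample_id not in samples:
                raise RdmlError(f"react {rid}: unresolvable sample reference "
                                f"{sample_id!r}")
            for data in el_iter(react, "data"):
                tar = None
                cq = None
                melt_temp = None
                adp_c: list[float] = []
                adp_f: list[float] = []
                mdp_t: list[float] = []
                mdp_f: list[float] = []
                for sub in data:
                    tag = _local(sub.tag)
                    if tag == "tar":
                        tar = sub.get("id") or (sub.text or "").strip()
                    elif tag == "cq" and sub.text:
                        v = float(sub.text)
                        cq = v if v >= 0 else None
                    elif tag == "meltTemp" and sub.text:
                        melt_temp = float(sub.text)
                    elif tag == "adp":
                        c = f = None
                        for leaf in sub:
                            if _local(leaf.tag) == "cyc":
                                c = float(leaf.text)
                            elif _local(leaf.tag) == "fluor":
                                f = float(leaf.text)
                        if c is None or f is None:
                            raise RdmlError("adp without cyc/fluor")
                        adp_c.append(c)
                        adp_f.append(f)
                    elif tag == "mdp":
                        t = f = None
                        for leaf in sub:
                            if _local(leaf.tag) == "tmp":
                                t = float(leaf.text)
                            elif _local(leaf.tag) == "fluor":
                                f = float(leaf.text)
                        if t is None or f is None:
                            raise RdmlError("mdp without tmp/fluor")
                        mdp_t.append(t)
                        mdp_f.append(f)
                if tar is None or tar not in targets:
                    raise RdmlError(
                        f"react {rid}: unresolvable target reference {tar!r}")
                ttype, dye = targets[tar]
                stype = samples[sample_id]
                if adp_c:
                    if any(b <= a for a, b in zip(adp_c, adp_c[1:])):
                        raise RdmlError(
                            f"react {rid}: amplification data points not "
                            "strictly increasing in cycle")
                    rec = WellRecord(well, sample_id, stype, tar, ttype, dye,
                                     cq, np.array(adp_f))
                    amp_rows.append((rec, adp_c, adp_f))
                if mdp_t:
                    if any(b <= a for a, b in zip(mdp_t, mdp_t[1:])):
                        raise RdmlError(
                            f"react {rid}: melt data points not strictly "
                            "increasing in temperature")
                    rec = WellRecord(well, sample_id, stype, tar, ttype, dye,
                                     melt_temp, np.array(mdp_f))
                    melt_rows.append((rec, mdp_t, mdp_f))

    meta = {"rdml_version": version, "warnings": warnings}
    amp_plate = _build_plate(amp_rows, "amplification", meta)
    melt_plate = _build_plate(melt_rows, "melt", meta)
    return amp_plate, melt_plate


def el_iter(parent, local_name):
    return (el for el in parent if _local(el.tag) == local_name)


def _build_plate(rows, variant, meta) -> PlateTable | None:
    if not rows:
        return None
    axis0 = rows[0][1]
    for rec, axis, _vals in rows[1:]:
        if axis != axis0:
            raise RdmlError(
                "axis unification failed: reactions carry different "
                f"cycle/temperature lists (well {rec.well_id})")
    records = [rec for rec, _a, _v in rows]
    return PlateTable(records, variant, np.array(axis0, dtype=float), dict(meta))
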