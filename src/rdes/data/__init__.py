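"""Bundled example data.

``table1_excerpt.csv`` is a 12-well excerpt of a published embryonic vs.
adult heart RT-qPCR run in RDES format: only cycles 1-4 and 42-45 were
printed, with an ellipsis column standing in for the omitted interior
cycles, so the parsed traces carry NaN at cycles 5-41.

``table1_infilled_synthetic.csv`` is a SYNTHETIC companion: the printed
cells are kept verbatim and the missing interior cycles are filled in
deterministically with a logistic amplification model anchored to each
well's printed baseline, endpoint fluorescence and reported Cq (see
:func:`infill_plate`).  It exists so that end-to-end analyses have complete
traces to run on; the in-filled cells are model output, not measurements.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from ..io import PlateTable, WellRecord, read_rdes

__all__ = [
    "table1_excerpt_path",
    "load_table1",
    "infill_plate",
]

# model constants for the synthetic in-fill; chosen once as typical SYBR
# chemistry values (per-cycle amplification factor, threshold at 10% of
# plateau) and not fitted to anything beyond the printed anchor cells
_INFILL_EFFICIENCY = 1.90
_INFILL_THRESHOLD_FRACTION = 0.10


def table1_excerpt_path():
    """Path to the bundled 12-well RDES excerpt (printed cells only)."""
    return resources.files(__name__) / "table1_excerpt.csv"


def load_table1(infilled: bool = False) -> PlateTable:
    """Load the bundled example plate.

    With ``infilled=False`` (default) the verbatim excerpt is returned,
    with NaN traces at the unprinted cycles 5-41.  With ``infilled=True``
    the synthetic companion with complete traces is returned.
    """
    name = "table1_infilled_synthetic.csv" if infilled else "table1_excerpt.csv"
    with (resources.files(__name__) / name).open("r", encoding="utf-8") as fh:
        return read_rdes(fh)


def infill_plate(plate: PlateTable,
                 efficiency: float = _INFILL_EFFICIENCY,
                 threshold_fraction: float = _INFILL_THRESHOLD_FRACTION) -> PlateTable:
    """Fill missing trace cells with a deterministic logistic model.

    For each well the model is ``F(c) = b + P * x / (x + 1)`` with
    ``x = n0 * E**c``: ``b`` is the mean of the well's first printed cycles,
    ``P`` is chosen so the curve passes through the last printed reading,
    and ``n0`` is set so the threshold crossing at
    ``threshold_fraction * P`` lands on the well's reported Cq.  Printed
    cells are never altered; only NaN cells are filled (rounded to two
    decimals, like the instrument export).  The result is synthetic data
    for pipeline demonstrations, not a reconstruction of the measurements.
    """
    if plate.variant != "amplification":
        raise ValueError("in-fill is defined for amplification plates only")
    new_records = []
    axis = plate.axis
    for rec in plate.records:
        trace = rec.trace.copy()
        printed = ~np.isnan(trace)
        if printed.all() or rec.reported_cq is None:
            new_records.append(rec)
            continue
        first = trace[printed][: min(4, printed.sum())]
        b = float(np.mean(first))
        f_last = float(trace[printed][-1])
        cq = float(rec.reported_cq)
        c_last = float(axis[printed][-1])
        E = efficiency
        # solve P and n0 jointly: threshold crossing at cq, curve through
        # (c_last, f_last).  With q = threshold_fraction, the crossing gives
        # x(cq) = q/(1-q) * 1  when P*x/(x+1) = q*P  =>  x(cq) = q/(1-q).
        q = threshold_fraction
        x_cq = q / (1.0 - q)
        n0 = x_cq / E**cq
        x_last = n0 * E**c_last
        P = (f_last - b) * (x_last + 1.0) / x_last
        filled = trace.copy()
        for i, c in enumerate(axis):
            if printed[i]:
                continue
            x = n0 * E**c
            filled[i] = round(b + P * x / (x + 1.0), 2)
        new_records.append(WellRecord(rec.well_id, rec.sample, rec.sample_type,
                                      rec.target, rec.target_type, rec.dye,
                                      rec.reported_cq, filled))
    meta = dict(plate.meta)
    meta["synthetic_infill"] = {
        "efficiency": efficiency,
        "threshold_fraction": threshold_fraction,
    }
    return PlateTable(new_records, plate.variant, axis.copy(), meta)
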