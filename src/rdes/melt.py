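"""Melt-curve analysis: derivative curves and Tm peak calls.

Post-amplification melt data belong in a raw-data disclosure alongside the
amplification traces: the negative derivative −dF/dT peaks at the amplicon
melting temperature Tm, and more than one peak is the classic signature of
nonspecific products such as primer dimers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .io import PlateTable, RdesFormatError

__all__ = ["MeltCall", "derivative_curve", "call_tm", "analyze_melt_plate"]

NO_PEAK = "NO_PEAK"
MULTIPLE_PEAKS = "MULTIPLE_PEAKS"

#: default peak prominence, as a fraction of the derivative's global maximum
DEFAULT_PROMINENCE_FRACTION = 0.05


@dataclass
class MeltCall:
    """Tm peaks called for one well: (temperature degC, peak height) pairs."""

    well_id: str
    tm_peaks: list[tuple[float, float]] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    @property
    def n_peaks(self) -> int:
        return len(self.tm_peaks)

    def to_dict(self) -> dict:
        return {"well_id": self.well_id,
                "tm_peaks": [[t, h] for t, h in self.tm_peaks],
                "n_peaks": self.n_peaks,
                "flags": sorted(self.flags)}


def derivative_curve(trace, temperatures) -> np.ndarray:
    """Negative first derivative −dF/dT of the smoothed melt trace.

    The trace is smoothed with a 5-point local quadratic (which preserves
    peak positions of a noiseless sigmoid to well under 0.1 degC), then
    differentiated by central differences, one-sided at the endpoints.
    Needs at least 5 strictly increasing temperature points.
    """
    y = np.asarray(trace, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    if len(y) < 5 or len(t) != len(y):
        raise RdesFormatError("melt derivative needs >= 5 aligned temperature points")
    if np.any(np.diff(t) <= 0):
        raise RdesFormatError("temperature axis must be strictly increasing")
    smooth = savgol_filter(y, 5, 2)
    d = -np.gradient(smooth, t)
    # snap floating-point residue of flat traces to an exact zero
    tol = 1e-10 * max(1.0, float(np.max(np.abs(y)))) / float(np.median(np.diff(t)))
    d[np.abs(d) < tol] = 0.0
    return d


def call_tm(derivative, temperatures, min_prominence: float | None = None) -> MeltCall:
    """Call melting-temperature peaks on a −dF/dT series.

    Local maxima with prominence at least ``min_prominence`` (default: 5%
    of the series' global maximum) are kept and refined by parabolic
    interpolation through the three samples around each peak.  One peak is
    a clean single product; more than one raises the ``MULTIPLE_PEAKS``
    flag, none the ``NO_PEAK`` flag.
    """
    d = np.asarray(derivative, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    call = MeltCall(well_id="")
    top = float(np.max(d)) if len(d) else 0.0
    if top <= 0:
        call.flags.add(NO_PEAK)
        return call
    if min_prominence is None:
        min_prominence = DEFAULT_PROMINENCE_FRACTION * top
    peaks, _props = find_peaks(d, prominence=min_prominence)
    step = float(np.median(np.diff(t)))
    for i in peaks:
        if 0 < i < len(d) - 1:
            a, b, c = d[i - 1], d[i], d[i + 1]
            denom = a - 2 * b + c
            off = 0.0 if denom == 0 else float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
            tm = t[i] + off * step
            height = b - 0.25 * (a - c) * off
        else:
            tm, height = t[i], d[i]
        if height > 0:
            call.tm_peaks.append((float(tm), float(height)))
    call.tm_peaks.sort()
    if not call.tm_peaks:
        call.flags.add(NO_PEAK)
    elif len(call.tm_peaks) > 1:
        call.flags.add(MULTIPLE_PEAKS)
    return call


def analyze_melt_plate(plate: PlateTable,
                       min_prominence: float | None = None) -> list[MeltCall]:
    """Derivative + Tm peak call for every well of a melt plate."""
    if plate.variant != "melt":
        raise ValueError("melt analysis applies to melt-variant plates")
    calls = []
    for rec in plate.records:
        d = derivative_curve(rec.trace, plate.axis)
        call = call_tm(d, plate.axis, min_prominence=min_prominence)
        call.well_id = rec.well_id
        calls.append(call)
    return calls
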