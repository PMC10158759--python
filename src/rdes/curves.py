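"""Amplification-curve analysis: baseline, PCR efficiency, Cq, N0.

Reported Cq and efficiency values alone cannot be audited; this module
recomputes them from the raw per-cycle fluorescence that RDES discloses.
The estimators are deliberately simple and fully documented:

* baseline: robust centre of the longest initial cycle run with no
  systematic upward trend;
* efficiency: window-of-linearity search — the 4-6 cycle window of the
  exponential phase whose log-linear regression has the highest r²;
  efficiency E = 10**slope, so E = 2 is perfect doubling;
* Cq: fractional cycle where the baseline-subtracted trace crosses the
  quantification threshold Nq (log-linear interpolation), plus the
  second-derivative-maximum Cq which needs no threshold at all;
* N0 = Nq / E**Cq, the efficiency-corrected initial target quantity in
  the same arbitrary fluorescence units as Nq.

On a noiseless exponential F(c) = b + N0·E^c these estimators agree with
the closed forms exactly; their behaviour under noise is characterised by
the simulation-recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter

from .io import Finding, PlateTable, ValidationReport

__all__ = [
    "CurveFit",
    "ThresholdPolicy",
    "CurveError",
    "InsufficientDataError",
    "NoAmplificationError",
    "NoCrossingError",
    "fit_baseline",
    "fit_efficiency",
    "call_cq",
    "estimate_n0",
    "analyze_plate",
    "audit_reported_cq",
]

# flags
NO_AMPLIFICATION = "NO_AMPLIFICATION"
LOW_R2 = "LOW_R2"
EFFICIENCY_OUT_OF_RANGE = "EFFICIENCY_OUT_OF_RANGE"
CQ_MISMATCH = "CQ_MISMATCH"

#: a reading counts as amplification only above baseline + this many noise sd
NOISE_BAND_MULTIPLIER = 10.0

R2_FLAG_THRESHOLD = 0.99
EFFICIENCY_RANGE = (1.6, 2.2)


class CurveError(Exception):
    """Base class for curve-analysis errors."""


class InsufficientDataError(CurveError):
    pass


class NoAmplificationError(CurveError):
    pass


class NoCrossingError(CurveError):
    pass


@dataclass
class ThresholdPolicy:
    """How the quantification threshold Nq is set.

    mode:
      * ``fixed`` — ``value`` is Nq itself (fluorescence a.u.);
      * ``fraction_of_plateau`` — Nq = value x the plate's median plateau
        height (the default, 10%: a plate-level standard that does not
        depend on any one well);
      * ``sd_above_baseline`` — Nq = value x the well's baseline noise sd.
    """

    mode: str = "fraction_of_plateau"
    value: float = 0.10

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "fraction_of_plateau", "sd_above_baseline"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")


@dataclass
class CurveFit:
    """Everything recomputed from one well's raw trace."""

    well_id: str
    sample: str = ""
    sample_type: str = ""
    target: str = ""
    target_type: str = ""
    dye: str = ""
    baseline_f: float = float("nan")
    noise_sd: float = float("nan")
    window: tuple[int, int] | None = None
    efficiency_E: float | None = None
    r2: float | None = None
    plateau: float | None = None
    nq: float | None = None
    cq_threshold: float | None = None
    cq_sdm: float | None = None
    n0: float | None = None
    reported_cq: float | None = None
    flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        d = {
            "well_id": self.well_id,
            "sample": self.sample,
            "sample_type": self.sample_type,
            "target": self.target,
            "target_type": self.target_type,
            "dye": self.dye,
            "baseline_f": self.baseline_f,
            "noise_sd": self.noise_sd,
            "window": list(self.window) if self.window else None,
            "efficiency_E": self.efficiency_E,
            "r2": self.r2,
            "plateau": self.plateau,
            "nq": self.nq,
            "cq_threshold": self.cq_threshold,
            "cq_sdm": self.cq_sdm,
            "n0": self.n0,
            "reported_cq": self.reported_cq,
            "flags": sorted(self.flags),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CurveFit":
        d = dict(d)
        w = d.get("window")
        d["window"] = tuple(w) if w else None
        d["flags"] = set(d.get("flags", []))
        return cls(**d)


def _robust_center_spread(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med, 1.4826 * mad


def fit_baseline(trace: Sequence[float], axis: Sequence[float] | None = None
                 ) -> tuple[float, float]:
    """Estimate the pre-amplification fluorescence offset and its noise.

    The pre-amplification segment is the longest initial run of cycles with
    no systematic upward trend: the noise floor is taken from the detrended
    first five cycles, and the prefix grows for as long as its Theil-Sen
    slope, accumulated over the prefix, stays within 3 noise sd of flat
    (so the trend test is judged against measurement noise, not against the
    spread the trend itself induces).  Returns ``(baseline_f, noise_sd)``
    — the median and scaled MAD of that segment.

    Raises :class:`InsufficientDataError` for traces under 10 cycles.
    """
    y = np.asarray(trace, dtype=float)
    if axis is None:
        axis = np.arange(1, len(y) + 1, dtype=float)
    x = np.asarray(axis, dtype=float)
    ok = ~np.isnan(y)
    y, x = y[ok], x[ok]
    if len(y) < 10:
        raise InsufficientDataError(
            f"baseline estimation needs >= 10 cycles, got {len(y)}")

    # noise floor: residual spread around a robust line through cycles 1-5
    s0, i0 = stats.theilslopes(y[:5], x[:5])[:2]
    resid = y[:5] - (i0 + s0 * x[:5])
    noise0 = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    scale = max(abs(float(np.median(y[:5]))), 1.0)
    floor = 3.0 * max(noise0, 1e-12 * scale)

    best_len = 4
    for L in range(4, len(y) + 1):
        seg = y[:L]
        if np.all(seg == seg[0]):
            best_len = L
            continue
        slope = stats.theilslopes(seg, x[:L])[0]
        rise = slope * (x[L - 1] - x[0])
        if rise <= floor:
            best_len = L
        elif L > 10:
            break  # the amplification rise has begun; no longer prefix is flat
    seg = y[:best_len]
    med, sd = _robust_center_spread(seg)
    return med, sd


def _window_transform(y: np.ndarray, plateau: float | None) -> np.ndarray:
    """log10 of the exponential component of the baseline-subtracted signal.

    When a plateau estimate P is available the logistic saturation is
    divided out first (y -> y / (1 - y/P)), which keeps the regression
    unbiased even when the window reaches into the bend of the sigmoid;
    with ``plateau=None`` this is the plain log10(y) used in the
    closed-form contracts.
    """
    if plateau is not None and plateau > 0:
        frac = np.clip(y / plateau, None, 0.95)
        y = y / (1.0 - frac)
    return np.log10(y)


def fit_efficiency(trace: Sequence[float], axis: Sequence[float] | None,
                   baseline_f: float, noise_sd: float,
                   plateau: float | None = None,
                   k: float = NOISE_BAND_MULTIPLIER,
                   ) -> tuple[tuple[int, int], float, float]:
    """Estimate the PCR efficiency from the window of linearity.

    Candidate windows are runs of consecutive cycles whose
    baseline-subtracted readings all exceed the noise band
    (baseline + k·noise_sd) and — when a plateau estimate is supplied —
    stay below 80% of it.  Six-cycle windows are scored by the r² of the
    linear regression of the log-transformed signal on cycle number and the
    best one wins (ties broken by lower starting cycle); 5- and then
    4-cycle windows are considered only when no longer window fits, since
    shorter windows carry visibly noisier slopes.

    Returns ``(window, efficiency_E, r2)`` with ``window`` as (first, last)
    cycle labels and ``E = 10**slope``.

    Raises :class:`NoAmplificationError` when no reading clears the noise
    band or no window fits.
    """
    y = np.asarray(trace, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float) if axis is None else np.asarray(axis, float)
    sig = y - baseline_f
    band = max(k * noise_sd, 1e-12 * max(abs(baseline_f), 1.0))
    usable = sig > band
    if plateau is not None and plateau > 0:
        usable &= sig < 0.80 * plateau
    if usable.sum() < 4:
        raise NoAmplificationError(
            "fewer than 4 readings above the baseline noise band")

    best: tuple[float, int, int, float] | None = None  # (r2, length, -start, E)
    n = len(y)
    for length in (6, 5, 4):
        for start in range(0, n - length + 1):
            idx = slice(start, start + length)
            if not np.all(usable[idx]):
                continue
            ly = _window_transform(sig[idx], plateau)
            if not np.all(np.isfinite(ly)):
                continue
            res = stats.linregress(x[idx], ly)
            r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0
            E = float(10.0 ** res.slope)
            cand = (r2, length, -start, E)
            if best is None or cand[:3] > best[:3]:
                best = cand
        if best is not None:
            break  # prefer the longest window length that fits at all
    if best is None:
        raise NoAmplificationError("no 4-6 cycle window lies in the usable band")
    r2, length, neg_start, E = best
    start = -neg_start
    window = (int(x[start]), int(x[start + length - 1]))
    return window, E, r2


def _estimate_plateau(trace: np.ndarray, baseline_f: float) -> float:
    """Plateau height above baseline, from the smoothed trace maximum."""
    y = trace[~np.isnan(trace)]
    if len(y) >= 7:
        y = savgol_filter(y, 5, 2)
    return float(np.max(y) - baseline_f)


def resolve_threshold(policy: ThresholdPolicy, plateaus: Iterable[float] | None = None,
                      noise_sd: float | None = None) -> float:
    """Turn a :class:`ThresholdPolicy` into a concrete Nq (a.u.)."""
    if policy.mode == "fixed":
        return float(policy.value)
    if policy.mode == "fraction_of_plateau":
        ps = [p for p in (plateaus or []) if p > 0]
        if not ps:
            raise CurveError("fraction_of_plateau needs at least one plateau estimate")
        return float(policy.value) * float(np.median(ps))
    # sd_above_baseline
    if noise_sd is None:
        raise CurveError("sd_above_baseline needs the well's noise sd")
    return float(policy.value) * float(noise_sd)


def call_cq(trace: Sequence[float], axis: Sequence[float] | None,
            baseline_f: float, policy: "ThresholdPolicy | float",
            noise_sd: float | None = None) -> tuple[float, float | None]:
    """Recompute the quantification cycle from a raw trace.

    ``cq_threshold`` is the fractional cycle at which the
    baseline-subtracted fluorescence first crosses the threshold Nq,
    located by log-linear interpolation between the bracketing cycles
    (exact for exponential growth).  ``cq_sdm`` is the cycle of the maximum
    of the second derivative of the smoothed trace (threshold-free), refined
    by parabolic interpolation; ``None`` when the trace is too short to
    smooth.

    ``policy`` may be a :class:`ThresholdPolicy` or a pre-resolved Nq.
    Raises :class:`NoCrossingError` when Nq is never reached.
    """
    y = np.asarray(trace, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float) if axis is None else np.asarray(axis, float)
    sig = y - baseline_f

    if isinstance(policy, ThresholdPolicy):
        nq = resolve_threshold(policy, plateaus=[_estimate_plateau(y, baseline_f)],
                               noise_sd=noise_sd)
    else:
        nq = float(policy)
    if nq <= 0:
        raise CurveError("quantification threshold must be positive")

    above = np.flatnonzero(sig >= nq)
    if len(above) == 0:
        raise NoCrossingError(f"trace never reaches the threshold {nq:g}")
    j = above[0]
    if j == 0:
        cq_t = float(x[0])
    else:
        f0, f1 = sig[j - 1], sig[j]
        if f0 <= 0:
            # linear fallback when the lower bracket is at/below baseline
            cq_t = float(x[j - 1] + (nq - f0) / (f1 - f0) * (x[j] - x[j - 1]))
        else:
            cq_t = float(x[j - 1] + (math.log(nq) - math.log(f0))
                         / (math.log(f1) - math.log(f0)) * (x[j] - x[j - 1]))

    cq_sdm = _second_derivative_max(y, x)
    return cq_t, cq_sdm


def _second_derivative_max(y: np.ndarray, x: np.ndarray) -> float | None:
    """Cycle of the smoothed trace's second-derivative maximum."""
    if len(y) < 7 or np.any(np.isnan(y)):
        return None
    step = float(np.median(np.diff(x)))
    d2 = savgol_filter(y, 5, 2, deriv=2, delta=step)
    interior = slice(2, len(y) - 2)
    i = int(np.argmax(d2[interior])) + 2
    # parabolic refinement around the discrete maximum
    if 0 < i < len(y) - 1:
        a, b, c = d2[i - 1], d2[i], d2[i + 1]
        denom = a - 2 * b + c
        offset = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        offset = float(np.clip(offset, -0.5, 0.5))
    else:
        offset = 0.0
    return float(x[i] + offset * step)


def estimate_n0(efficiency_E: float, cq: float, nq: float) -> float:
    """Initial target quantity N0 = Nq / E**Cq (efficiency-corrected).

    ``nq`` is the threshold fluorescence the Cq was called at; the result is
    in the same arbitrary units.  Raises ``ValueError`` for E <= 1.
    """
    if efficiency_E <= 1.0:
        raise ValueError(f"efficiency must exceed 1, got {efficiency_E}")
    return float(nq) / float(efficiency_E) ** float(cq)


def analyze_plate(plate: PlateTable, policy: ThresholdPolicy | None = None,
                  cq_tolerance: float = 1.0) -> list[CurveFit]:
    """Run the full curve analysis on every well of an amplification plate.

    Two passes: first each well's baseline, noise and plateau are fitted so
    a plate-level threshold can be resolved (default policy: 10% of the
    median plateau); then per well the efficiency window, both Cq variants
    and N0 are computed.  Wells without detectable amplification carry the
    ``NO_AMPLIFICATION`` flag and no estimates; ``LOW_R2``,
    ``EFFICIENCY_OUT_OF_RANGE`` and ``CQ_MISMATCH`` (recomputed vs reported
    Cq differing by more than ``cq_tolerance`` cycles) flag suspect wells.
    """
    if plate.variant != "amplification":
        raise ValueError("curve analysis applies to amplification plates")
    policy = policy or ThresholdPolicy()

    fits: list[CurveFit] = []
    plateaus: list[float] = []
    prelim: list[tuple[float, float, float]] = []
    for rec in plate.records:
        b, sd = fit_baseline(rec.trace, plate.axis)
        p = _estimate_plateau(rec.trace, b)
        prelim.append((b, sd, p))
        if p > NOISE_BAND_MULTIPLIER * sd:
            plateaus.append(p)

    plate_nq: float | None = None
    if policy.mode in ("fixed", "fraction_of_plateau"):
        plate_nq = resolve_threshold(policy, plateaus=plateaus or None)

    for rec, (b, sd, p) in zip(plate.records, prelim):
        fit = CurveFit(well_id=rec.well_id, sample=rec.sample,
                       sample_type=rec.sample_type, target=rec.target,
                       target_type=rec.target_type, dye=rec.dye,
                       baseline_f=b, noise_sd=sd, plateau=p,
                       reported_cq=rec.reported_cq)
        nq = plate_nq if plate_nq is not None else resolve_threshold(
            policy, noise_sd=sd)
        fit.nq = nq
        try:
            window, E, r2 = fit_efficiency(rec.trace, plate.axis, b, sd, plateau=p)
            fit.window, fit.efficiency_E, fit.r2 = window, E, r2
            if r2 < R2_FLAG_THRESHOLD:
                fit.flags.add(LOW_R2)
            if not (EFFICIENCY_RANGE[0] < E <= EFFICIENCY_RANGE[1]):
                fit.flags.add(EFFICIENCY_OUT_OF_RANGE)
            cq_t, cq_sdm = call_cq(rec.trace, plate.axis, b, nq)
            fit.cq_threshold, fit.cq_sdm = cq_t, cq_sdm
            if E > 1.0:
                # undo logistic saturation at the crossing: the exponential
                # component there is nq / (1 - nq/plateau), not nq itself
                nq_eff = nq / (1.0 - nq / p) if p > nq else nq
                fit.n0 = estimate_n0(E, cq_t, nq_eff)
            if rec.reported_cq is not None and abs(cq_t - rec.reported_cq) > cq_tolerance:
                fit.flags.add(CQ_MISMATCH)
        except (NoAmplificationError, NoCrossingError):
            fit.flags.add(NO_AMPLIFICATION)
        fits.append(fit)
    return fits


def audit_reported_cq(plate: PlateTable, policy: ThresholdPolicy | None = None,
                      tolerance: float = 1.0) -> ValidationReport:
    """Cross-check every reported Cq against the raw trace.

    Produces a warning-only report: ``CQ_MISMATCH`` where the recomputed
    threshold Cq deviates from the reported one by more than ``tolerance``
    cycles, and ``NTC_AMPLIFICATION`` where a no-template control shows
    detectable amplification (a contamination signature).
    """
    fits = analyze_plate(plate, policy=policy, cq_tolerance=tolerance)
    warnings: list[Finding] = []
    for fit in fits:
        if CQ_MISMATCH in fit.flags:
            warnings.append(Finding(
                CQ_MISMATCH, fit.well_id,
                f"reported Cq {fit.reported_cq:g} vs recomputed "
                f"{fit.cq_threshold:.2f} (tolerance {tolerance:g})"))
        if fit.sample_type == "ntc" and NO_AMPLIFICATION not in fit.flags:
            warnings.append(Finding(
                "NTC_AMPLIFICATION", fit.well_id,
                "no-template control shows amplification: possible contamination"))
    counts = {
        "n_wells": len(fits),
        "n_amplifying": sum(1 for f in fits if NO_AMPLIFICATION not in f.flags),
        "n_cq_mismatch": sum(1 for f in fits if CQ_MISMATCH in f.flags),
    }
    return ValidationReport(warnings=warnings, counts=counts)


def fits_to_json(fits: list[CurveFit], indent: int | None = 2) -> str:
    return json.dumps([f.to_dict() for f in fits], indent=indent)


def fits_from_json(text: str) -> list[CurveFit]:
    return [CurveFit.from_dict(d) for d in json.loads(text)]
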