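"""Efficiency-corrected quantification and the Cq-dependent bias curve.

Relative quantification that assumes perfect doubling (E = 2) when the
assay's true efficiency differs is biased by a factor that grows
exponentially with Cq: fold error(Cq) = (E_assumed / E_true)**Cq.  This
module computes efficiency-corrected target quantities N0 = Nq / E**Cq
with per-target (assay-specific) efficiencies, normalizes them against the
geometric mean of the reference genes, expresses them as fold differences
versus a calibrator sample, and tabulates the bias curve itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curves import (CurveFit, EFFICIENCY_OUT_OF_RANGE, LOW_R2,
                     NO_AMPLIFICATION, estimate_n0)

__all__ = [
    "QuantResult",
    "QuantifyError",
    "per_target_efficiency",
    "normalized_expression",
    "cq_bias_assessment",
    "results_to_frame",
]

#: flags that disqualify a well from efficiency averaging / quantification
DISQUALIFYING_FLAGS = {NO_AMPLIFICATION, LOW_R2, EFFICIENCY_OUT_OF_RANGE}


class QuantifyError(Exception):
    pass


@dataclass
class QuantResult:
    """Efficiency-corrected expression values for one (sample, target)."""

    sample: str
    target: str
    n0: float
    normalized: float | None
    fold_vs_calibrator: float | None
    efficiency_used: float

    def to_dict(self) -> dict:
        return {
            "sample": self.sample, "target": self.target, "n0": self.n0,
            "normalized": self.normalized,
            "fold_vs_calibrator": self.fold_vs_calibrator,
            "efficiency_used": self.efficiency_used,
        }


def _usable(fit: CurveFit) -> bool:
    return (not (fit.flags & DISQUALIFYING_FLAGS)
            and fit.efficiency_E is not None and fit.cq_threshold is not None)


def per_target_efficiency(fits: Iterable[CurveFit]) -> dict[str, float]:
    """Mean per-well efficiency for each target, excluding flagged wells.

    An assay-specific efficiency is only trustworthy when replicated, so a
    target with fewer than two unflagged wells raises
    :class:`QuantifyError` rather than returning a single-well value.
    """
    by_target: dict[str, list[float]] = {}
    seen: set[str] = set()
    for fit in fits:
        seen.add(fit.target)
        if _usable(fit):
            by_target.setdefault(fit.target, []).append(fit.efficiency_E)
    missing = sorted(t for t in seen if len(by_target.get(t, [])) < 2)
    if missing:
        raise QuantifyError(
            "no usable efficiency for target(s) "
            + ", ".join(missing)
            + " (need >= 2 unflagged wells per target)")
    return {t: fmean(es) for t, es in by_target.items()}


def _geomean(values: Sequence[float]) -> float:
    return float(np.exp(np.mean(np.log(values))))


def normalized_expression(
    fits: Iterable[CurveFit],
    efficiencies: dict[str, float] | None = None,
    reference_targets: Sequence[str] | None = None,
    calibrator: str | None = None,
) -> tuple[list[QuantResult], list[dict]]:
    """Efficiency-corrected normalized expression per (sample, target).

    Per sample, each target-of-interest quantity N0 = Nq / E_target**Cq is
    divided by the geometric mean of the reference-target quantities for
    the same sample.  Replicate wells of the same (sample, target) are
    combined by geometric mean of their N0.  Fold differences are reported
    against the ``calibrator`` sample (default: the first sample in plate
    order, whose fold is 1 by construction).

    ``reference_targets`` defaults to the targets annotated ``ref`` in the
    plate.  Returns ``(results, errors)``: samples missing a reference
    measurement produce one error entry each instead of failing the run.
    """
    fits = list(fits)
    if efficiencies is None:
        efficiencies = per_target_efficiency(fits)
    if reference_targets is None:
        reference_targets = sorted({f.target for f in fits if f.target_type == "ref"})
    if not reference_targets:
        raise QuantifyError("no reference targets given or annotated in the fits")

    # geometric-mean N0 per (sample, target), efficiency-corrected per target
    n0: dict[tuple[str, str], list[float]] = {}
    sample_order: list[str] = []
    for fit in fits:
        if fit.sample not in sample_order:
            sample_order.append(fit.sample)
        if not _usable(fit) or fit.nq is None:
            continue
        E = efficiencies.get(fit.target)
        if E is None:
            continue
        n0.setdefault((fit.sample, fit.target), []).append(
            estimate_n0(E, fit.cq_threshold, fit.nq))
    n0_mean = {k: _geomean(v) for k, v in n0.items()}

    errors: list[dict] = []
    results: list[QuantResult] = []
    targets = sorted({f.target for f in fits})
    per_sample_ref: dict[str, float] = {}
    for s in sample_order:
        refs = [n0_mean.get((s, r)) for r in reference_targets]
        if any(r is None for r in refs):
            missing = [r for r, v in zip(reference_targets, refs) if v is None]
            errors.append({"sample": s, "code": "MISSING_REFERENCE",
                           "message": f"no usable reference well for {missing}"})
            continue
        per_sample_ref[s] = _geomean([float(r) for r in refs])

    for s in sample_order:
        if s not in per_sample_ref:
            continue
        for t in targets:
            q = n0_mean.get((s, t))
            if q is None:
                continue
            results.append(QuantResult(
                sample=s, target=t, n0=q,
                normalized=q / per_sample_ref[s],
                fold_vs_calibrator=None,
                efficiency_used=efficiencies[t]))

    cal = calibrator if calibrator is not None else (
        sample_order[0] if sample_order else None)
    cal_norm = {r.target: r.normalized for r in results if r.sample == cal}
    for r in results:
        base = cal_norm.get(r.target)
        if base:
            r.fold_vs_calibrator = r.normalized / base
    return results, errors


def cq_bias_assessment(e_true: float, e_assumed: float,
                       cq_range: tuple[float, float] = (15.0, 40.0),
                       step: float = 1.0) -> pd.DataFrame:
    """Tabulate the fold error from assuming the wrong efficiency.

    A quantity read off at quantification cycle Cq with an assumed
    efficiency, when the true assay efficiency differs, is off by
    ``fold_error = (e_assumed / e_true)**Cq`` — log-linear in Cq, so late
    Cq values (low-abundance targets) are hit hardest.  Returns a DataFrame
    with columns ``cq`` and ``fold_error`` over ``cq_range``.
    """
    for name, e in (("e_true", e_true), ("e_assumed", e_assumed)):
        if not (1.0 < e <= 2.2):
            raise ValueError(f"{name} must lie in (1, 2.2], got {e}")
    lo, hi = cq_range
    cq = np.arange(lo, hi + step / 2, step)
    fold = (e_assumed / e_true) ** cq
    return pd.DataFrame({"cq": cq, "fold_error": fold})


def results_to_frame(results: Iterable[QuantResult]) -> pd.DataFrame:
    """Tidy (sample, target, n0, normalized, fold) table."""
    return pd.DataFrame([r.to_dict() for r in results])
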