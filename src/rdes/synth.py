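"""Simulated qPCR plates with recorded ground truth.

The amplification model is logistic in the amplicon amount: with initial
quantity n0 and per-cycle efficiency E, the amplicon after c cycles is
x(c) = n0·E^c and the observed fluorescence

    F(c) = baseline + plateau · x(c) / (x(c) + 1),

so the early phase is exactly exponential (baseline + plateau·n0·E^c for
x << 1) and saturates at baseline + plateau, like a real SYBR trace.
Noise is multiplicative Gaussian (coefficient of variation ``cv``) plus
additive baseline Gaussian.  The emitted Cq column is the generator's own
noiseless threshold crossing at a stated fraction of the plate's median
plateau, so every downstream estimate can be checked against truth.

Melt curves are sums of logistic transitions: each amplicon contributes
A·sigmoid((Tm − T)/w), so −dF/dT peaks at Tm with height A/(4w).
"""

from __future__ import annotations

import json
import math
import string
from dataclasses import dataclass, field

import numpy as np

from .io import PlateTable, WellRecord

__all__ = ["SimTruth", "simulate_amplification", "simulate_melt"]

_ROWS = string.ascii_uppercase[:16]  # A..P, 384-well limit


@dataclass
class SimTruth:
    """Ground-truth parameters of a simulated plate, keyed by well."""

    seed: int
    variant: str
    n_cycles: int
    params: dict = field(default_factory=dict)   # global generator settings
    wells: dict = field(default_factory=dict)    # well_id -> truth record

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(
            {"seed": self.seed, "variant": self.variant,
             "n_cycles": self.n_cycles, "params": self.params,
             "wells": self.wells}, indent=indent)


def _design(samples, targets):
    if isinstance(samples, int):
        samples = [f"Sample_{i + 1}" for i in range(samples)]
    if isinstance(targets, int):
        n = targets
        targets = [(f"GENE{i + 1}", "toi") for i in range(n - 1)] + [("REF1", "ref")]
        if n == 1:
            targets = [("GENE1", "toi")]
    targets = [t if isinstance(t, tuple) else (t, "toi") for t in targets]
    if len(targets) > len(_ROWS):
        raise ValueError(f"at most {len(_ROWS)} targets (plate rows) supported")
    if len(samples) > 24:
        raise ValueError("at most 24 samples (plate columns) supported")
    return list(samples), list(targets)


def simulate_amplification(
    samples=12,
    targets=8,
    n_cycles: int = 45,
    seed: int = 1,
    n0_range: tuple[float, float] = (1e-7, 1e-4),
    n0_values=None,
    efficiency=None,
    baseline: float = 1.4,
    baseline_jitter: float = 0.05,
    plateau: float = 14.0,
    plateau_jitter: float = 0.5,
    cv: float = 0.01,
    additive_sd: float = 0.01,
    threshold_fraction: float = 0.10,
    sample_types: dict | None = None,
    dye: str = "SYBR",
) -> tuple[PlateTable, SimTruth]:
    """Simulate an amplification plate over a sample x target grid.

    Targets map to plate rows (A, B, ...) and samples to columns, one well
    per pair.  Per-well true n0 is log-uniform over ``n0_range`` unless
    ``n0_values`` (target x sample array) is given; per-target true
    efficiency is uniform on [1.80, 2.00] unless ``efficiency`` (scalar or
    per-target sequence) is given.  ``sample_types`` maps sample name to an
    RDES token (e.g. ``{"NTC": "ntc"}``); ntc/nac/ntp wells get n0 = 0.

    The reported Cq column is filled from the noiseless model's crossing of
    Nq = ``threshold_fraction`` x median true plateau, the same plate-level
    threshold convention the analysis engine defaults to; wells that never
    cross within the run get an empty Cq.  Defaults describe a routine
    96-well SYBR run: 45 cycles, 1% multiplicative noise, 0.01 a.u.
    additive noise.

    Returns ``(PlateTable, SimTruth)``; identical arguments and seed yield
    a byte-identical canonical CSV.
    """
    if n_cycles < 20:
        raise ValueError("n_cycles must be >= 20")
    if cv < 0 or additive_sd < 0 or not (0 < threshold_fraction < 1):
        raise ValueError("noise/threshold parameters out of admissible range")
    samples, targets = _design(samples, targets)
    rng = np.random.default_rng(seed)
    sample_types = sample_types or {}

    n_t, n_s = len(targets), len(samples)
    if efficiency is None:
        eff = rng.uniform(1.80, 2.00, size=n_t)
    else:
        eff = np.broadcast_to(np.asarray(efficiency, dtype=float), (n_t,)).copy()
    if np.any(eff <= 1.0) or np.any(eff > 2.2):
        raise ValueError("efficiency must lie in (1, 2.2]")

    lo, hi = n0_range
    if n0_values is None:
        n0 = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=(n_t, n_s))
    else:
        n0 = np.asarray(n0_values, dtype=float).reshape(n_t, n_s).copy()
    b_true = baseline + rng.normal(0.0, baseline_jitter, size=(n_t, n_s))
    p_true = plateau + rng.normal(0.0, plateau_jitter, size=(n_t, n_s))

    for j, s in enumerate(samples):
        if sample_types.get(s) in ("ntc", "nac", "ntp"):
            n0[:, j] = 0.0

    nq = threshold_fraction * float(np.median(p_true))
    axis = np.arange(1, n_cycles + 1, dtype=float)

    records: list[WellRecord] = []
    truth_wells: dict[str, dict] = {}
    for i, (tname, ttype) in enumerate(targets):
        for j, sname in enumerate(samples):
            well = f"{_ROWS[i]}{j + 1}"
            E, n0_ij = float(eff[i]), float(n0[i, j])
            b, P = float(b_true[i, j]), float(p_true[i, j])
            x = n0_ij * E ** axis
            clean = b + P * x / (x + 1.0)
            noisy = clean * (1.0 + rng.normal(0.0, cv, size=n_cycles)) \
                + rng.normal(0.0, additive_sd, size=n_cycles)

            cq_true: float | None = None
            if n0_ij > 0 and nq < P:
                x_q = nq / (P - nq)  # solves P·x/(x+1) = nq
                cq = math.log(x_q / n0_ij) / math.log(E)
                if 1.0 <= cq <= n_cycles:
                    cq_true = cq
            records.append(WellRecord(
                well, sname, sample_types.get(sname, "unkn"), tname, ttype,
                dye, cq_true, noisy))
            truth_wells[well] = {
                "sample": sname, "target": tname, "target_type": ttype,
                "n0_true": n0_ij, "e_true": E, "baseline_true": b,
                "plateau_true": P, "cq_true": cq_true,
                # initial quantity on the fluorescence scale: early-phase
                # signal is P*n0*E^c, so this is what Nq/E^Cq estimates
                "n0_fluor_true": P * n0_ij,
            }

    plate = PlateTable(records, "amplification", axis,
                       meta={"generator": "rdes.synth.simulate_amplification",
                             "seed": seed})
    truth = SimTruth(
        seed=seed, variant="amplification", n_cycles=n_cycles,
        params={"nq": nq, "threshold_fraction": threshold_fraction,
                "cv": cv, "additive_sd": additive_sd},
        wells=truth_wells)
    return plate, truth


def simulate_melt(
    samples=4,
    targets=2,
    temp_range: tuple[float, float, float] = (60.0, 95.0, 0.5),
    seed: int = 1,
    tm=None,
    amplitude: float = 8.0,
    width: float = 0.8,
    baseline: float = 1.0,
    additive_sd: float = 0.01,
    dye: str = "SYBR",
) -> tuple[PlateTable, SimTruth]:
    """Simulate a melt-curve plate.

    ``tm`` gives the true melting temperature(s): a scalar, one value per
    target, or per target a list of (Tm, amplitude) transitions for
    multi-product wells.  Default: per-target Tm drawn uniformly on
    [75, 88] degC.  The reported Tm column carries the strongest true
    transition.  The temperature axis runs over ``temp_range``
    (start, stop, step), rounded to 0.1 degC as instruments export it.
    """
    samples, targets = _design(samples, targets)
    rng = np.random.default_rng(seed)
    start, stop, step = temp_range
    temps = np.round(np.arange(start, stop + step / 2, step), 1)
    if len(temps) < 5:
        raise ValueError("temperature axis needs at least 5 points")

    n_t = len(targets)
    if tm is None:
        tm_list = [[(float(t), amplitude)] for t in rng.uniform(75.0, 88.0, n_t)]
    elif np.isscalar(tm):
        tm_list = [[(float(tm), amplitude)] for _ in range(n_t)]
    else:
        tm_list = []
        for entry in tm:
            if np.isscalar(entry):
                tm_list.append([(float(entry), amplitude)])
            else:
                tm_list.append([(float(t), float(a)) for t, a in entry])
    for trans in tm_list:
        for t, _a in trans:
            if not (temps[0] + 5.0 <= t <= temps[-1] - 5.0):
                raise ValueError(
                    f"true Tm {t} not covered by the temperature range +/- 5 degC")

    records: list[WellRecord] = []
    truth_wells: dict[str, dict] = {}
    for i, (tname, ttype) in enumerate(targets):
        transitions = tm_list[i]
        for j, sname in enumerate(samples):
            well = f"{_ROWS[i]}{j + 1}"
            f = np.full(len(temps), baseline)
            for t_m, a in transitions:
                z = (t_m - temps) / width
                f = f + a / (1.0 + np.exp(-z))
            f = f + rng.normal(0.0, additive_sd, size=len(temps))
            strongest = max(transitions, key=lambda p: p[1])[0] if any(
                a > 0 for _t, a in transitions) else None
            records.append(WellRecord(well, sname, "unkn", tname, ttype, dye,
                                      strongest, f))
            truth_wells[well] = {
                "sample": sname, "target": tname,
                "tm_true": [t for t, a in transitions if a > 0],
                "amplitudes": [a for _t, a in transitions],
            }

    plate = PlateTable(records, "melt", temps,
                       meta={"generator": "rdes.synth.simulate_melt", "seed": seed})
    truth = SimTruth(seed=seed, variant="melt", n_cycles=len(temps),
                     params={"width": width, "additive_sd": additive_sd},
                     wells=truth_wells)
    return plate, truth
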