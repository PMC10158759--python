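# Methods

This note documents the models, estimators and design choices behind
`rdes-tools`: what each component assumes, which parameters matter, and
what the synthetic-data tests do and do not demonstrate about real data.

## The RDES table model

An RDES plate is a rectangular table: every well row shares one axis of
cycle numbers (amplification) or temperatures (melt).  The containers
enforce this (`AXIS_MISMATCH` is a validation error), because a shared
axis is what makes the format trivially machine-checkable — the property
the format exists for.

Reader tolerances reflect how spreadsheets mangle CSV in practice:

* Delimiter is auto-detected among comma/semicolon/tab; the canonical
  writer always emits commas.  Decimal commas (`1,30`) are accepted only
  when the field delimiter is semicolon or tab, so they are unambiguous.
* Well labels accept zero padding (`A01`) on read and are emitted
  unpadded; rows are written row-major (`A1…A12, B1…`), ties broken by
  dye, so serialization is byte-deterministic.
* An empty Cq cell means "no value"; the literal tokens `NA`, `NaN` and
  `Undetermined` are accepted with a parse warning, never written.
* A column headed `…` (or `...`) between integer cycle headers denotes
  elided columns, as published excerpts use; the axis is expanded and the
  missing readings become NaN.  This is how a printed excerpt showing
  cycles 1–4 and 42–45 still yields a 45-cycle plate.
* Variant auto-detection: an axis of consecutive integers starting at 1
  is an amplification run; any other numeric axis (non-integer or not
  starting at 1, e.g. `60.0, 60.5, …`) is a melt run.  The melt summary
  column `Tm` is optional, mirroring `Cq`.

Sample and target type tokens use the RDML controlled vocabulary
(`unkn/std/ntc/nac/ntp/nrt/pos/opt`; `toi/ref`), validated
case-sensitively and never coerced: silent coercion is how annotation
errors survive review.  Multiplexed wells are separate rows sharing a
well label; uniqueness is enforced on (well, dye).

The deposition suggestion `GEO_DEPOSIT` fires at ≥ 20 distinct samples
and ≥ 20 distinct targets — the scale at which public-repository
deposition is worth the overhead — and is a suggestion, not an error.

## RDML interchange

The bridge targets the RDML 1.2 element vocabulary (`sample`, `target`,
`dye`, `react`, `data`, `adp` with `cyc`/`fluor`, `mdp` with
`tmp`/`fluor`, `cq`, `meltTemp`), the subset an RDES table can represent.
React ids are row-major integers over the plate extent recorded in
`pcrFormat`, RDML's convention; well labels are reconstructed from it on
import.  RDML allows per-reaction cycle lists; since RDES is rectangular,
ragged lists are an import error rather than being silently padded.
ZIP containers (RDML's on-disk convention) are detected by magic bytes.
Unsupported RDML content is ignored with a logged warning — an
interchange reader that errors on valid foreign content would be useless.

## Amplification-curve estimators

All estimators operate per well on the raw trace `F(c)`.

**Baseline.**  The pre-amplification segment is the longest initial run
with no systematic upward trend.  The noise floor is the residual spread
(scaled MAD) around a Theil–Sen line through cycles 1–5; the prefix grows
while its Theil–Sen slope, accumulated over the prefix, stays within 3
noise sd of flat.  Judging the trend against this fixed floor — not
against the prefix's own spread — matters: a prefix that swallows the
amplification rise inflates its own spread enough to look "flat" by its
own standard.  Baseline and noise are the median and scaled MAD of the
chosen segment; at least 10 cycles are required.

**Efficiency (window of linearity).**  Candidate windows are runs of
consecutive cycles whose baseline-subtracted signal exceeds the noise
band (baseline + 10·noise sd, configurable) and stays below 80% of the
plateau estimate.  Six-cycle windows are scored by the r² of a linear
regression of the log signal on cycle; the best wins, ties to the lower
starting cycle; 5- then 4-cycle windows are tried only when no longer
window fits.  The longest-first preference is deliberate: at realistic
noise (1% CV) the slope of a 4-cycle window is noisy enough that
best-r²-across-all-lengths visibly widens the efficiency error
distribution, while the longest window that fits keeps every well within
the stated recovery tolerance.  `E = 10^slope`; `LOW_R2` flags r² < 0.99
and `EFFICIENCY_OUT_OF_RANGE` flags E outside (1.6, 2.2].

When a plateau estimate `P` is available (always, inside
`analyze_plate`) the regression runs on the logistic-linearized signal
`y/(1 − y/P)` instead of `y`.  Under the saturating model this divides
out the bend of the sigmoid exactly and removes a systematic −0.03 to
−0.06 bias in `E` that plain log regression incurs when the usable
window is pushed into the bend by the noise floor.  With `plateau=None`
the transform reduces to plain `log10(y)`, which is exact on pure
exponentials.

**Cq.**  The threshold Cq is the fractional cycle where the
baseline-subtracted signal first crosses `N_q`, by log-linear
interpolation between the bracketing cycles (exact for exponential
growth).  The default `ThresholdPolicy` sets `N_q` at 10% of the plate's
median plateau — a plate-level standard, so every well on a plate is
quantified against the same threshold, which is precisely what ad hoc
per-well thresholds fail to provide.  Fixed-value and
sd-above-baseline policies are available.  The second-derivative-maximum
Cq needs no threshold at all: the trace is smoothed by a 5-point local
quadratic (Savitzky–Golay), differentiated twice, and the discrete
argmax refined by parabolic interpolation.

**N0.**  `estimate_n0(E, Cq, Nq) = Nq / E^Cq`, in the same arbitrary
fluorescence units as `N_q`.  `analyze_plate` applies the logistic
correction to the threshold first (`N_q/(1 − N_q/P)`), the signal the
exponential component actually has at the crossing; without it every N0
inherits a −0.15 log2 offset from saturation at a 10%-of-plateau
threshold.

**Audit.**  `audit_reported_cq` flags wells whose reported Cq deviates
from the recomputed one by more than 1 cycle (default), and no-template
controls with detectable amplification (contamination signature).

## Quantification

Per-target efficiency is the mean of unflagged per-well efficiencies and
requires at least two usable wells — a single-well "assay-specific"
efficiency is an oxymoron.  Normalized expression divides each target's
N0 by the geometric mean of the reference-gene N0s for the same sample;
the geometric mean is the right aggregate for ratio-scale quantities and
makes the result invariant to reference ordering and to any common
rescaling of `N_q`.  Replicate wells combine by geometric mean of N0.
Fold differences are reported against a calibrator sample (default:
first sample in plate order; its fold is 1 by construction).  Samples
missing a reference measurement yield per-sample error entries rather
than aborting the plate.

The bias curve `fold error(Cq) = (E_assumed/E_true)^Cq` tabulates the
cost of assuming perfect doubling: at `E_true = 1.9` analysed as 2.0, a
transcript read at Cq 30 is off 4.7-fold, and the error is log-linear in
Cq, so low-abundance targets (late Cq) are distorted most.

## Melt analysis

The derivative −dF/dT uses the same 5-point quadratic smoother (contract:
peak positions of noiseless sigmoids preserved to well under 0.1 °C),
central differences, one-sided at the ends; derivatives below a
10⁻¹⁰-relative floor are snapped to zero so flat traces yield exactly
`NO_PEAK`.  Peaks need a prominence of 5% of the well's derivative
maximum (configurable, absolute); positions are refined parabolically.
More than one peak flags `MULTIPLE_PEAKS` (primer-dimer indicator).

## The simulator

Amplification: amplicon `x(c) = n0·E^c`, fluorescence
`F = b + P·x/(x+1)` — exactly exponential early (preserving every
closed-form check in the window region) and saturating at `b + P` like a
real SYBR trace.  Noise is multiplicative Gaussian (CV) plus additive
baseline Gaussian, defaults 1% and 0.01 a.u. — routine instrument
performance.  Defaults describe a standard run: 96 wells (12 samples ×
8 targets, one of them a reference gene), 45 cycles, baseline
1.4 ± 0.05 a.u., plateau 14 ± 0.5 a.u., per-target E uniform on
[1.80, 2.00], per-well n0 log-uniform on [10⁻⁷, 10⁻⁴] (spanning Cq ≈ 11
to 24 at these settings).  The emitted Cq column is the noiseless
model's crossing of 10% of the median true plateau — the same convention
the analysis defaults to, so recomputed and generated Cq are directly
comparable.  The recorded truth includes `n0_fluor_true = P·n0`, the
initial quantity on the fluorescence scale, which is the quantity
`N_q/E^Cq` estimates.

Melt: sums of logistic transitions `A·σ((Tm−T)/w)` (default width
0.8 °C, amplitude 8 a.u.), so −dF/dT peaks at Tm with height ≈ A/4w.

Everything is driven by one `numpy` Generator seed; identical arguments
produce byte-identical canonical CSV.

What the simulator does *not* model — inhibitors, probe chemistries,
drifting baselines, inter-plate batch effects, pipetting error — bounds
what the recovery tests show: they demonstrate correctness of the
estimators under the stated noise model, not robustness to every failure
mode of bench data.  The structural guarantees (round-trip stability,
validation, interchange losslessness) are independent of the noise
model.

## Problem sizes and numerical choices

The test suite and the acceptance script use a 100-well plate (10 × 10)
for recovery, 50 small plates (6 wells × 30 cycles) for round-trip
stability, and noiseless melts for Tm — sizes at which every estimate is
stable across seeds while the whole suite runs in seconds.  Closed-form
agreement tests pass the known baseline to the estimators directly:
estimating the baseline from a noiseless exponential leaves an
O(10⁻⁶ a.u.) residual that is within the baseline contract but above the
10⁻⁶ relative agreement being checked; full-pipeline accuracy is covered
by the stochastic recovery tests instead.  Ties in the window search are
broken deterministically (longer window, then lower starting cycle), and
parabolic refinements are clamped to ±½ step so an ill-conditioned
vertex can never leave the bracketing interval.

## Known limitations

* The melt-variant header convention (`Tm` summary column, one-decimal
  temperatures) is this package's own; published examples of the format
  show only the amplification variant.
* The RDML bridge covers the data subset only; thermal profiles,
  experimenter metadata and digital-PCR content are ignored on import.
* A well whose target appears with two dyes in the same well cannot be
  represented in RDML's target→dye dictionary and is not supported.
* The curve estimators are this package's own documented definitions,
  satisfying the stated closed-form and recovery properties; they do not
  reproduce the numerics of any particular published analysis tool.
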