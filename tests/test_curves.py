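"""Baseline, efficiency-window, Cq and N0 estimators.

The closed-form contracts use noiseless exponentials F(c) = b + N0*E**c,
where every quantity has an analytic value; stochastic behaviour is
covered by the recovery tests against the simulator's ground truth.
"""

import math

import numpy as np
import pytest

from rdes.curves import (InsufficientDataError, NoAmplificationError,
                         NoCrossingError, analyze_plate,
                         audit_reported_cq, call_cq, estimate_n0,
                         fit_baseline, fit_efficiency)
from rdes.synth import simulate_amplification


def exponential(n0=1e-6, e=2.0, baseline=1.0, n=45):
    c = np.arange(1, n + 1, dtype=float)
    return baseline + n0 * e**c, c


class TestBaseline:
    def test_constant_trace(self):
        b, sd = fit_baseline(np.full(20, 1.5))
        assert b == 1.5 and sd == 0.0

    def test_short_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_baseline(np.ones(9))

    def test_noisy_known_baseline_recovered(self):
        rng = np.random.default_rng(0)
        y, c = exponential(n0=1e-7, e=1.9, baseline=1.4)
        y = y + rng.normal(0, 0.01, len(y))
        b, sd = fit_baseline(y, c)
        assert abs(b - 1.4) < 0.02
        assert 0 < sd < 0.03

    def test_table1_a1_baseline_matches_printed_early_cycles(self, table1_infilled):
        rec = table1_infilled.record("A1")
        b, _sd = fit_baseline(rec.trace, table1_infilled.axis)
        assert 1.25 <= b <= 1.32


class TestEfficiency:
    def test_exact_exponential_recovered_to_1e6(self):
        y, c = exponential()
        window, e, r2 = fit_efficiency(y, c, baseline_f=1.0, noise_sd=0.0)
        assert abs(e - 2.0) < 2e-6
        assert r2 > 1 - 1e-9
        assert window[1] - window[0] + 1 >= 4

    def test_flat_trace_flags_no_amplification(self):
        with pytest.raises(NoAmplificationError):
            fit_efficiency(np.full(30, 1.5), None, baseline_f=1.5, noise_sd=0.0)

    def test_window_lies_within_axis(self):
        y, c = exponential(e=1.8)
        window, _e, _r2 = fit_efficiency(y, c, 1.0, 0.0)
        assert 1 <= window[0] < window[1] <= 45


class TestCq:
    def test_exact_exponential_closed_form(self):
        # crossing Nq = 1e-3 from N0 = 1e-6 at E = 2: Cq = log2(1000)
        y, c = exponential()
        cq, _sdm = call_cq(y, c, baseline_f=1.0, policy=1e-3)
        assert cq == pytest.approx(math.log2(1000), abs=1e-9)

    def test_doubling_n0_shifts_cq_by_one_cycle(self):
        y1, c = exponential(n0=1e-6)
        y2, _ = exponential(n0=2e-6)
        cq1, _ = call_cq(y1, c, 1.0, 1e-3)
        cq2, _ = call_cq(y2, c, 1.0, 1e-3)
        assert cq1 - cq2 == pytest.approx(1.0, abs=1e-9)

    def test_threshold_above_plateau_raises(self):
        y, c = exponential()
        with pytest.raises(NoCrossingError):
            call_cq(y, c, 1.0, policy=1e9)

    def test_sdm_close_to_threshold_cq_on_sigmoid(self):
        plate, truth = simulate_amplification(samples=2, targets=1, seed=3,
                                              cv=0.0, additive_sd=0.0)
        fits = analyze_plate(plate)
        for f in fits:
            assert f.cq_sdm is not None
            # SDM sits near the curve's take-off, within a few cycles of Cq
            assert abs(f.cq_sdm - f.cq_threshold) < 4.0


class TestN0:
    def test_power_of_two(self):
        assert estimate_n0(2.0, 10.0, 1024.0) == pytest.approx(1.0)

    def test_cq_zero_returns_nq(self):
        assert estimate_n0(2.0, 0.0, 7.5) == 7.5

    def test_efficiency_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            estimate_n0(1.0, 10.0, 1.0)


class TestInvariants:
    def test_scale_equivariance(self):
        """k*trace with k*Nq leaves Cq and E unchanged."""
        y, c = exponential(e=1.9)
        k = 37.5
        cq1, _ = call_cq(y, c, 1.0, 1e-3)
        cq2, _ = call_cq(k * y, c, k * 1.0, k * 1e-3)
        assert cq1 == pytest.approx(cq2, rel=1e-12)
        _w1, e1, _ = fit_efficiency(y, c, 1.0, 0.0)
        _w2, e2, _ = fit_efficiency(k * y, c, k * 1.0, 0.0)
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_larger_n0_strictly_smaller_cq(self):
        c = None
        cqs = []
        for n0 in (1e-7, 1e-6, 1e-5, 1e-4):
            y, c = exponential(n0=n0)
            cqs.append(call_cq(y, c, 1.0, 1e-3)[0])
        assert all(a > b for a, b in zip(cqs, cqs[1:]))

    def test_delta_cq_law_exact(self):
        """Cq difference of two noiseless wells = log(R)/log(E) for N0 ratio R."""
        for e, r in ((2.0, 8.0), (1.85, 5.0)):
            y1, c = exponential(n0=1e-7, e=e)
            y2, _ = exponential(n0=1e-7 * r, e=e)
            d = call_cq(y1, c, 1.0, 1e-3)[0] - call_cq(y2, c, 1.0, 1e-3)[0]
            assert d == pytest.approx(math.log(r) / math.log(e), rel=1e-9)


@pytest.fixture(scope="module")
def recovered():
    plate, truth = simulate_amplification(samples=10, targets=10, seed=17)
    fits = analyze_plate(plate)
    return [(f, truth.wells[f.well_id]) for f in fits]


class TestRecovery:
    """Parameter recovery against simulator ground truth (fixed seeds)."""

    def test_efficiency_within_tolerance(self, recovered):
        errs = np.array([abs(f.efficiency_E - t["e_true"]) for f, t in recovered])
        assert np.mean(errs <= 0.05) >= 0.95

    def test_cq_within_half_cycle(self, recovered):
        errs = np.array([abs(f.cq_threshold - t["cq_true"]) for f, t in recovered])
        assert np.mean(errs <= 0.5) >= 0.95

    def test_n0_recovery_median_log2_error(self, recovered):
        errs = [abs(math.log2(f.n0 / t["n0_fluor_true"])) for f, t in recovered]
        assert np.median(errs) < 0.2


class TestAudit:
    def test_self_consistent_plate_has_no_mismatches(self, sim_plate):
        plate, _ = sim_plate
        report = audit_reported_cq(plate)
        assert not any(f.code == "CQ_MISMATCH" for f in report.warnings)

    def test_ntc_with_amplification_is_flagged(self):
        plate, _ = simulate_amplification(
            samples=["S1", "NTC"], targets=1, seed=4,
            n0_values=[[1e-6, 1e-6]])
        # mislabel the second sample as a no-template control, keeping its
        # amplifying trace: contamination signature
        for rec in plate.records:
            if rec.sample == "NTC":
                rec.sample_type = "ntc"
        report = audit_reported_cq(plate)
        assert any(f.code == "NTC_AMPLIFICATION" for f in report.warnings)

    def test_clean_ntc_not_flagged(self):
        plate, _ = simulate_amplification(
            samples=["S1", "NTC"], targets=1, seed=4,
            sample_types={"NTC": "ntc"})
        report = audit_reported_cq(plate)
        assert not any(f.code == "NTC_AMPLIFICATION" for f in report.warnings)

    def test_table1_fixture_audit_completes(self, table1_infilled):
        fits = analyze_plate(table1_infilled)
        assert len(fits) == 12
        assert all(f.cq_threshold is not None for f in fits)
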