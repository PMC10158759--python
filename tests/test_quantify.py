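"""Efficiency-corrected quantification and the Cq-dependent bias curve."""

import math

import numpy as np
import pytest

from rdes.curves import CurveFit, analyze_plate
from rdes.quantify import (QuantifyError, cq_bias_assessment,
                           normalized_expression, per_target_efficiency)
from rdes.synth import simulate_amplification


def fit(well, sample, target, ttype="toi", e=2.0, cq=20.0, nq=1.0, flags=()):
    return CurveFit(well_id=well, sample=sample, target=target,
                    target_type=ttype, efficiency_E=e, r2=0.999,
                    cq_threshold=cq, nq=nq, flags=set(flags))


class TestPerTargetEfficiency:
    def test_mean_of_two_wells(self):
        fits = [fit("A1", "s1", "T", e=1.8), fit("A2", "s2", "T", e=1.9)]
        assert per_target_efficiency(fits)["T"] == pytest.approx(1.85)

    def test_single_well_target_is_error(self):
        with pytest.raises(QuantifyError, match="T"):
            per_target_efficiency([fit("A1", "s1", "T")])

    def test_flagged_wells_excluded(self):
        fits = [fit("A1", "s1", "T", e=1.8), fit("A2", "s2", "T", e=1.9),
                fit("A3", "s3", "T", e=3.0, flags={"EFFICIENCY_OUT_OF_RANGE"})]
        assert per_target_efficiency(fits)["T"] == pytest.approx(1.85)

    def test_recovery_of_per_target_truth(self):
        plate, truth = simulate_amplification(
            samples=8, targets=[("TOI1", "toi"), ("REF1", "ref")],
            efficiency=[1.80, 1.95], seed=9)
        eff = per_target_efficiency(analyze_plate(plate))
        assert abs(eff["TOI1"] - 1.80) < 0.03
        assert abs(eff["REF1"] - 1.95) < 0.03


class TestNormalizedExpression:
    def test_symmetry_gives_unity(self):
        fits = [fit("A1", "s", "TOI", cq=22.0),
                fit("B1", "s", "REF", ttype="ref", cq=22.0)]
        res, errs = normalized_expression(
            fits, efficiencies={"TOI": 2.0, "REF": 2.0})
        assert not errs
        toi = next(r for r in res if r.target == "TOI")
        assert toi.normalized == pytest.approx(1.0)

    def test_delta_cq_law_one_cycle_doubles(self):
        fits = [fit("A1", "s", "TOI", cq=21.0),
                fit("B1", "s", "REF", ttype="ref", cq=22.0)]
        res, _ = normalized_expression(fits, efficiencies={"TOI": 2.0, "REF": 2.0})
        toi = next(r for r in res if r.target == "TOI")
        assert toi.normalized == pytest.approx(2.0)

    def test_missing_reference_produces_error_entry(self):
        fits = [fit("A1", "s1", "TOI"), fit("B1", "s1", "REF", ttype="ref"),
                fit("A2", "s2", "TOI")]  # s2 has no REF well
        res, errs = normalized_expression(
            fits, efficiencies={"TOI": 2.0, "REF": 2.0})
        assert [e["sample"] for e in errs] == ["s2"]
        assert {r.sample for r in res} == {"s1"}

    def test_calibrator_fold_is_one(self):
        fits = [fit("A1", "s1", "TOI", cq=20), fit("B1", "s1", "REF", "ref", cq=21),
                fit("A2", "s2", "TOI", cq=18), fit("B2", "s2", "REF", "ref", cq=21)]
        res, _ = normalized_expression(fits, efficiencies={"TOI": 2.0, "REF": 2.0})
        s1 = next(r for r in res if r.sample == "s1" and r.target == "TOI")
        s2 = next(r for r in res if r.sample == "s2" and r.target == "TOI")
        assert s1.fold_vs_calibrator == pytest.approx(1.0)
        assert s2.fold_vs_calibrator == pytest.approx(4.0)

    def test_normalization_invariant_to_common_nq_scaling(self):
        base = [fit("A1", "s1", "TOI", cq=20), fit("B1", "s1", "REF", "ref", cq=23),
                fit("A2", "s2", "TOI", cq=19), fit("B2", "s2", "REF", "ref", cq=23)]
        scaled = [fit(f.well_id, f.sample, f.target, f.target_type,
                      f.efficiency_E, f.cq_threshold, nq=50.0) for f in base]
        eff = {"TOI": 2.0, "REF": 2.0}
        r1, _ = normalized_expression(base, efficiencies=eff)
        r2, _ = normalized_expression(scaled, efficiencies=eff)
        for a, b in zip(r1, r2):
            assert a.normalized == pytest.approx(b.normalized)
            assert a.fold_vs_calibrator == pytest.approx(b.fold_vs_calibrator)

    def test_reference_geomean_permutation_invariant(self):
        fits = [fit("A1", "s", "TOI", cq=20),
                fit("B1", "s", "R1", "ref", cq=21),
                fit("C1", "s", "R2", "ref", cq=25)]
        eff = {"TOI": 2.0, "R1": 2.0, "R2": 2.0}
        r1, _ = normalized_expression(fits, eff, reference_targets=["R1", "R2"])
        r2, _ = normalized_expression(fits, eff, reference_targets=["R2", "R1"])
        t1 = next(r for r in r1 if r.target == "TOI")
        t2 = next(r for r in r2 if r.target == "TOI")
        assert t1.normalized == pytest.approx(t2.normalized)

    def test_two_group_fold_recovery_end_to_end(self):
        # group B carries 4x the target of group A; reference constant
        n_per = 4
        samples = [f"A{i}" for i in range(1, n_per + 1)] + \
                  [f"B{i}" for i in range(1, n_per + 1)]
        toi = [1e-6] * n_per + [4e-6] * n_per
        ref = [5e-6] * (2 * n_per)
        plate, _ = simulate_amplification(
            samples=samples, targets=[("TOI", "toi"), ("REF", "ref")],
            n0_values=[toi, ref], efficiency=[1.9, 1.9], seed=21)
        res, errs = normalized_expression(analyze_plate(plate))
        assert not errs
        norm = {r.sample: r.normalized for r in res if r.target == "TOI"}
        fold = np.mean([norm[f"B{i}"] for i in range(1, n_per + 1)]) / \
            np.mean([norm[f"A{i}"] for i in range(1, n_per + 1)])
        assert 3.5 <= fold <= 4.5


class TestBiasCurve:
    def test_equal_efficiencies_no_bias(self):
        curve = cq_bias_assessment(1.9, 1.9, (10, 40))
        assert np.allclose(curve.fold_error, 1.0)

    def test_reference_value_matches_repeated_multiplication(self):
        # oracle: multiply the per-cycle ratio out 30 times
        ratio = 2.0 / 1.9
        expected = 1.0
        for _ in range(30):
            expected *= ratio
        curve = cq_bias_assessment(1.9, 2.0, (30, 30))
        assert curve.fold_error.iloc[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.66, abs=0.01)

    def test_bias_grows_with_cq(self):
        curve = cq_bias_assessment(1.9, 2.0, (20, 35))
        b20 = curve.loc[curve.cq == 20, "fold_error"].iloc[0]
        b35 = curve.loc[curve.cq == 35, "fold_error"].iloc[0]
        assert b35 > b20

    def test_log_linearity(self):
        curve = cq_bias_assessment(1.8, 2.0, (15, 40))
        logs = np.log(curve.fold_error.to_numpy())
        slope = np.diff(logs) / np.diff(curve.cq.to_numpy())
        assert np.allclose(slope, math.log(2.0 / 1.8))

    @pytest.mark.parametrize("bad", [1.0, 2.3, 0.5])
    def test_out_of_range_efficiency_rejected(self, bad):
        with pytest.raises(ValueError):
            cq_bias_assessment(bad, 2.0)
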