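import math

import numpy as np
import pytest

from tjmetrics.barrier import (
    CalibrationCurve,
    ElectroRecord,
    FluxSeries,
    IonSolution,
    analyze_record,
    apply_calibration,
    compute_ter,
    dextran_papp,
    fit_standard_curve,
    ghk_dilution_potential,
    ghk_ratio,
    kimizuka_koketsu,
    nernst_limits_mV,
    solution_a,
    solution_b,
)
from tjmetrics.constants import PhysicalConstants

T37 = 310.15


def _record(v_mV, apical=None, basolateral=None, blank_mV=0.0):
    return ElectroRecord(
        raw_resistance_ohm=200.0,
        blank_resistance_ohm=100.0,
        raw_potential_mV=v_mV + blank_mV,
        blank_potential_mV=blank_mV,
        area_cm2=1.12,
        apical=apical or solution_a(),
        basolateral=basolateral or solution_b(),
        temperature_K=T37,
    )


class TestIonSolution:
    def test_chloride_totals_from_salts(self):
        s = IonSolution.from_salts(nacl_mM=140, kcl_mM=5, mgcl2_mM=1, cacl2_mM=1)
        assert s.cl_mM == 140 + 5 + 2 + 2
        assert s.na_mM == 140
        assert s.k_mM == 5

    def test_standard_solutions(self):
        assert solution_a().cl_mM == pytest.approx(149.0)
        assert solution_b().cl_mM == pytest.approx(79.0)
        assert solution_a().na_mM == 140.0
        assert solution_b().na_mM == 70.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            IonSolution(na_mM=-1, k_mM=0, cl_mM=0)


class TestTer:
    def test_blank_subtraction_times_area(self):
        rec = _record(0.0)
        assert compute_ter(rec) == pytest.approx((200 - 100) * 1.12)

    def test_raw_equal_blank_raises(self):
        rec = ElectroRecord(100.0, 100.0, 0.0, 0.0, 1.0, solution_a(), solution_b(), T37)
        with pytest.raises(ValueError, match="unphysical"):
            compute_ter(rec)


class TestGhkForward:
    def test_beta_one_standard_solutions_zero(self):
        assert ghk_dilution_potential(1.0, solution_a(), solution_b(), T37) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_identical_solutions_zero_any_beta(self):
        for beta in (0.2, 1.0, 42.0):
            assert ghk_dilution_potential(beta, solution_a(), solution_a(), T37) == 0.0

    def test_cation_limit_reproduces_nernst(self):
        # Nernst oracle: (RT/F) ln 2 for a 140:70 NaCl dilution
        ap = IonSolution(na_mM=140, k_mM=0, cl_mM=140)
        bl = IonSolution(na_mM=70, k_mM=0, cl_mM=70)
        expected = PhysicalConstants(T37).RT_over_F * math.log(2) * 1e3
        v = ghk_dilution_potential(1e12, ap, bl, T37)
        assert v == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(18.52, abs=0.01)

    def test_potential_scales_with_temperature_in_nernst_limit(self):
        ap = IonSolution(na_mM=140, k_mM=0, cl_mM=140)
        bl = IonSolution(na_mM=70, k_mM=0, cl_mM=70)
        v1 = ghk_dilution_potential(1e12, ap, bl, 300.0)
        v2 = ghk_dilution_potential(1e12, ap, bl, 600.0)
        assert v2 == pytest.approx(2 * v1, rel=1e-9)

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            ghk_dilution_potential(0.0, solution_a(), solution_b())


class TestGhkInverse:
    def test_zero_potential_gives_beta_one(self):
        assert ghk_ratio(_record(0.0)) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("beta", [0.1, 0.5, 1.0, 2.0, 7.0, 30.0, 100.0])
    def test_round_trip(self, beta):
        v = ghk_dilution_potential(beta, solution_a(), solution_b(), T37)
        assert ghk_ratio(_record(v)) == pytest.approx(beta, rel=1e-9)

    def test_round_trip_random_solutions(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            ap = IonSolution(*rng.uniform(20, 200, size=3))
            bl = IonSolution(*rng.uniform(20, 200, size=3))
            beta = float(rng.uniform(0.1, 100))
            v = ghk_dilution_potential(beta, ap, bl, T37)
            lo, hi = nernst_limits_mV(ap, bl, T37)
            if not (lo < v < hi):
                continue
            rec = _record(v, apical=ap, basolateral=bl)
            assert ghk_ratio(rec) == pytest.approx(beta, rel=1e-9)

    def test_potential_at_nernst_limit_raises(self):
        lo, hi = nernst_limits_mV(solution_a(), solution_b(), T37)
        with pytest.raises(ValueError, match="attainable"):
            ghk_ratio(_record(hi))
        with pytest.raises(ValueError, match="attainable"):
            ghk_ratio(_record(lo - 1.0))

    def test_blank_potential_subtracted(self):
        v = ghk_dilution_potential(4.0, solution_a(), solution_b(), T37)
        assert ghk_ratio(_record(v, blank_mV=0.8)) == pytest.approx(4.0, rel=1e-9)


class TestKimizukaKoketsu:
    def test_hand_evaluated_example(self):
        # oracle: (RT/F^2) / (TER * C) split evenly at beta = 1, with
        # R = 8.314, F = 96485, T = 310.15, C = 1.4e-4 mol/cm^3
        p_na, p_cl = kimizuka_koketsu(50.0, 1.0, reference_NaCl_mM=140.0, temperature_K=T37)
        assert p_na == pytest.approx(1.98e-5, rel=1e-2)
        assert p_na == pytest.approx(1.9784914e-5, rel=1e-6)
        assert p_cl == p_na

    @pytest.mark.parametrize("beta", [0.2, 1.0, 5.0, 50.0])
    @pytest.mark.parametrize("ter", [20.0, 113.0, 900.0])
    def test_defining_identities(self, beta, ter):
        p_na, p_cl = kimizuka_koketsu(ter, beta)
        assert p_na / p_cl == pytest.approx(beta, rel=1e-12)
        total = PhysicalConstants().RT_over_F / PhysicalConstants().F / (ter * 1.4e-4)
        assert p_na + p_cl == pytest.approx(total, rel=1e-12)

    def test_doubling_ter_halves_permeabilities(self):
        a = kimizuka_koketsu(100.0, 3.0)
        b = kimizuka_koketsu(200.0, 3.0)
        assert b[0] == pytest.approx(a[0] / 2, rel=1e-12)
        assert b[1] == pytest.approx(a[1] / 2, rel=1e-12)

    def test_analyze_record_consistency(self):
        v = ghk_dilution_potential(7.0, solution_a(), solution_b(), T37)
        res = analyze_record(_record(v))
        assert res.P_Na_cm_s / res.P_Cl_cm_s == pytest.approx(res.beta, rel=1e-12)
        assert res.beta == pytest.approx(7.0, rel=1e-9)


class TestCalibration:
    def test_simple_line(self):
        curve = fit_standard_curve([0, 1, 2], [0, 10, 20])
        assert curve.slope == pytest.approx(10.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert apply_calibration(curve, 15.0) == pytest.approx(1.5)
        assert curve.r_squared == pytest.approx(1.0)

    def test_fit_then_apply_round_trip(self):
        x = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        y = 7.3 * x + 2.1
        curve = fit_standard_curve(x, y)
        np.testing.assert_allclose(apply_calibration(curve, y), x, atol=1e-12)

    def test_degenerate_standards_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_standard_curve([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_negative_slope_raises(self):
        with pytest.raises(ValueError, match="slope"):
            fit_standard_curve([0, 1, 2], [20, 10, 0])

    def test_too_few_standards(self):
        with pytest.raises(ValueError):
            fit_standard_curve([1.0], [2.0])


class TestPapp:
    def test_hand_unit_conversion(self):
        # Q = 2t nmol/h, A = 1 cm^2, C0 = 0.2 mM -> ~2.78e-6 cm/s
        t = np.array([0.5, 1.0, 1.5, 2.0])
        series = FluxSeries(times_h=t, Q_nmol=2.0 * t, C0_mM=0.2, area_cm2=1.0)
        expected = (2e-9 / 3600.0) / (1.0 * 2e-7)
        assert dextran_papp(series) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.78e-6, rel=1e-2)

    def test_constant_amount_zero_permeability(self):
        series = FluxSeries(
            times_h=np.array([0.5, 1.0, 1.5]), Q_nmol=np.array([3.0, 3.0, 3.0]),
            C0_mM=0.2, area_cm2=1.0,
        )
        assert dextran_papp(series) == pytest.approx(0.0, abs=1e-18)

    def test_single_point_through_origin(self):
        series = FluxSeries(
            times_h=np.array([1.0]), Q_nmol=np.array([2.0]), C0_mM=0.2, area_cm2=1.0
        )
        assert dextran_papp(series) == pytest.approx((2e-9 / 3600.0) / 2e-7, rel=1e-12)

    def test_negative_slope_signed(self, caplog):
        series = FluxSeries(
            times_h=np.array([0.5, 1.0]), Q_nmol=np.array([2.0, 1.0]), C0_mM=0.2, area_cm2=1.0
        )
        with caplog.at_level("WARNING"):
            p = dextran_papp(series)
        assert p < 0

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            FluxSeries(times_h=np.array([1.0, 0.5]), Q_nmol=np.array([1.0, 2.0]),
                       C0_mM=0.2, area_cm2=1.0)
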