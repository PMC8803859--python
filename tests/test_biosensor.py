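"""Hydrogel electrode model: closed forms against numerical BVP/quadrature oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_bvp, trapezoid

from dropsense import (
    HydrogelSensor,
    PhysicalConstants,
    biosensor_number,
    btilde_from_slope,
    bulk_rate,
    enzymatic_rate_qE,
    glucose_calibration_slope,
    h2o2_calibration_slope,
    hydrogel_glucose_profile,
    hydrogel_h2o2_profile,
    qE_from_slope,
)


def make_sensor(btilde: float, H: float = 5.0, Dg: float = 2800.0) -> HydrogelSensor:
    """Sensor with a prescribed biosensor number (v_g = B^2 D_g / H^2)."""
    return HydrogelSensor(
        thickness_um=H, diff_glucose=Dg, rate_vg=btilde**2 * Dg / H**2
    )


def glucose_bvp_profile(sensor: HydrogelSensor, x_grid: np.ndarray) -> np.ndarray:
    """Independent oracle: solve D_g c'' - v_g c = 0, c'(0)=0, c(H)=1 numerically."""
    k2 = sensor.rate_vg / sensor.diff_glucose

    def odes(x, y):
        return np.vstack([y[1], k2 * y[0]])

    def bc(ya, yb):
        return np.array([ya[1], yb[0] - 1.0])

    x0 = np.linspace(0.0, sensor.thickness_um, 10_000)
    guess = np.vstack([np.ones_like(x0), np.zeros_like(x0)])
    sol = solve_bvp(odes, bc, x0, guess, tol=1e-10, max_nodes=200_000)
    assert sol.success
    return sol.sol(x_grid)[0]


class TestBiosensorNumber:
    def test_zero_rate_gives_zero(self):
        assert biosensor_number(make_sensor(0.0)) == 0.0

    def test_operating_point(self, sensor):
        # the default sensor sits at the ~0.25 operating point
        assert biosensor_number(sensor) == pytest.approx(0.25, abs=1e-12)

    def test_forced_unity(self):
        s = HydrogelSensor(thickness_um=5.0, rate_vg=0.04, diff_glucose=1.0, diff_h2o2=10.0)
        assert biosensor_number(s) == pytest.approx(1.0)

    def test_zero_diffusivity_with_active_enzyme_rejected(self):
        with pytest.raises(ValueError):
            HydrogelSensor(diff_glucose=0.0, rate_vg=1.0)


class TestGlucoseProfile:
    def test_boundary_and_uniform_cases(self):
        s = make_sensor(1.3)
        assert hydrogel_glucose_profile(s, 150.0, s.thickness_um) == pytest.approx(150.0)
        s0 = make_sensor(0.0)
        x = np.linspace(0, s0.thickness_um, 7)
        assert np.allclose(hydrogel_glucose_profile(s0, 150.0, x), 150.0)

    def test_center_value_unit_biosensor_number(self):
        s = make_sensor(1.0)
        assert hydrogel_glucose_profile(s, 150.0, 0.0) == pytest.approx(
            150.0 / math.cosh(1.0), rel=1e-12
        )

    def test_out_of_domain_rejected(self):
        s = make_sensor(1.0)
        with pytest.raises(ValueError):
            hydrogel_glucose_profile(s, 150.0, -0.1)
        with pytest.raises(ValueError):
            hydrogel_glucose_profile(s, 150.0, s.thickness_um + 0.1)

    @pytest.mark.parametrize("btilde", [0.25, 1.0, 3.0])
    def test_profile_matches_bvp_oracle(self, btilde):
        s = make_sensor(btilde)
        x = np.linspace(0.0, s.thickness_um, 101)
        closed = np.asarray(hydrogel_glucose_profile(s, 1.0, x))
        oracle = glucose_bvp_profile(s, x)
        assert np.max(np.abs(closed - oracle) / np.abs(oracle)) < 1e-6

    def test_interior_collocation_residual(self):
        # D_g c'' - v_g c = 0 at interior points by central differences
        s = make_sensor(1.7)
        x = np.linspace(0.0, s.thickness_um, 2001)
        c = np.asarray(hydrogel_glucose_profile(s, 1.0, x))
        h = x[1] - x[0]
        c2 = (c[2:] - 2 * c[1:-1] + c[:-2]) / h**2
        resid = s.diff_glucose * c2 - s.rate_vg * c[1:-1]
        scale = s.rate_vg * np.max(c)
        assert np.max(np.abs(resid)) / scale < 1e-6


class TestCalibrationSlopes:
    def test_h2o2_slope_scalings(self, constants):
        s = HydrogelSensor()
        base = h2o2_calibration_slope(s, constants)
        doubled_H = HydrogelSensor(thickness_um=2 * s.thickness_um)
        doubled_A = HydrogelSensor(area_mm2=2 * s.area_mm2)
        assert h2o2_calibration_slope(doubled_H, constants) == pytest.approx(base / 2)
        assert h2o2_calibration_slope(doubled_A, constants) == pytest.approx(2 * base)

    def test_h2o2_slope_equals_linear_profile_flux(self, constants):
        # i = F A D_h dc_h/dx|0 for the linear no-enzyme profile c_h = c* x/H
        s = HydrogelSensor()
        grad = 1.0 / s.thickness_um  # d/dx of x/H
        flux_current = constants.f_eff * s.area_mm2 * s.diff_h2o2 * grad
        assert h2o2_calibration_slope(s, constants) == pytest.approx(flux_current, rel=1e-12)

    def test_glucose_slope_zero_without_enzyme(self, constants):
        assert glucose_calibration_slope(make_sensor(0.0), constants) == 0.0

    def test_glucose_slope_saturates(self, constants):
        s = make_sensor(60.0)
        saturation = constants.f_eff * s.area_mm2 * s.diff_glucose / s.thickness_um
        assert glucose_calibration_slope(s, constants) == pytest.approx(saturation, rel=1e-12)

    def test_glucose_slope_monotone_in_btilde(self, constants):
        slopes = [glucose_calibration_slope(make_sensor(b), constants)
                  for b in np.linspace(0.01, 10, 40)]
        assert np.all(np.diff(slopes) > 0)

    def test_glucose_slope_against_coupled_bvp(self, constants):
        # flux of the H2O2 BVP fed by the glucose BVP must reproduce the slope
        s = make_sensor(0.25)
        k2g = s.rate_vg / s.diff_glucose

        def odes(x, y):
            # y = (cg, cg', ch, ch')
            return np.vstack([
                y[1], k2g * y[0],
                y[3], -(s.rate_vg / s.diff_h2o2) * y[0],
            ])

        def bc(ya, yb):
            return np.array([ya[1], yb[0] - 1.0, ya[2], yb[2]])

        x0 = np.linspace(0.0, s.thickness_um, 10_000)
        guess = np.vstack([np.ones_like(x0), np.zeros_like(x0),
                           np.zeros_like(x0), np.zeros_like(x0)])
        sol = solve_bvp(odes, bc, x0, guess, tol=1e-10, max_nodes=200_000)
        assert sol.success
        dch_dx0 = sol.sol(0.0)[3]
        numeric_slope = constants.f_eff * s.area_mm2 * s.diff_h2o2 * dch_dx0
        closed = glucose_calibration_slope(s, constants)
        assert abs(numeric_slope - closed) / closed < 1e-6

    def test_h2o2_profile_positive_and_zero_at_walls(self):
        s = make_sensor(0.8)
        x = np.linspace(0.0, s.thickness_um, 101)
        ch = np.asarray(hydrogel_h2o2_profile(s, 150.0, x))
        assert ch[0] == pytest.approx(0.0, abs=1e-12)
        assert ch[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(ch[1:-1] > 0)


class TestEnzymaticRate:
    def test_zero_rate(self):
        assert enzymatic_rate_qE(make_sensor(0.0)) == 0.0

    def test_small_btilde_limit_is_vg(self):
        s = make_sensor(1e-5)
        assert enzymatic_rate_qE(s) == pytest.approx(s.rate_vg, rel=1e-9)

    @pytest.mark.parametrize("btilde", [0.1, 0.25, 1.0, 4.0])
    def test_equals_volume_average_quadrature(self, btilde):
        # q_E = (1/H) int_0^H v_g c_g(x)/c* dx
        s = make_sensor(btilde)
        x = np.linspace(0.0, s.thickness_um, 40_001)
        c = np.asarray(hydrogel_glucose_profile(s, 1.0, x))
        quad = trapezoid(s.rate_vg * c, x) / s.thickness_um
        assert abs(quad - enzymatic_rate_qE(s)) / enzymatic_rate_qE(s) < 1e-8

    def test_bounded_by_vg(self, rng):
        for _ in range(20):
            s = make_sensor(float(rng.uniform(0.01, 8.0)))
            q = enzymatic_rate_qE(s)
            assert 0.0 <= q <= s.rate_vg


class TestSlopeRateIdentities:
    def test_qE_from_slope_matches_direct(self, rng, constants):
        # Eq-level identity: tanh(B)/(1-sech B) = coth(B/2)
        for _ in range(50):
            s = make_sensor(float(rng.uniform(0.02, 8.0)))
            slope = glucose_calibration_slope(s, constants)
            q = qE_from_slope(slope, biosensor_number(s), s.area_mm2, s.thickness_um, constants)
            direct = enzymatic_rate_qE(s)
            assert abs(q - direct) / direct < 1e-10

    def test_small_btilde_limit(self, constants):
        s = make_sensor(1e-10)
        slope = 1e-4
        expected = 2.0 * slope / (constants.f_eff * s.area_mm2 * s.thickness_um)
        got = qE_from_slope(slope, 0.0, s.area_mm2, s.thickness_um, constants)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_coth_special_value(self):
        # B = 2 -> coth(1), checked against independent sinh/cosh evaluation
        s = make_sensor(2.0)
        slope = glucose_calibration_slope(s)
        q = qE_from_slope(slope, 2.0, s.area_mm2, s.thickness_um)
        coth1 = math.cosh(1.0) / math.sinh(1.0)
        expected = slope * 2.0 * coth1 / (
            PhysicalConstants().f_eff * s.area_mm2 * s.thickness_um
        )
        assert q == pytest.approx(expected, rel=1e-12)
        assert coth1 == pytest.approx(1.3130352854993312, rel=1e-12)


class TestBtildeInversion:
    def test_roundtrip_at_operating_point(self, sensor, constants):
        slope = glucose_calibration_slope(sensor, constants)
        assert btilde_from_slope(
            slope, sensor.area_mm2, sensor.thickness_um, sensor.diff_glucose, constants
        ) == pytest.approx(0.25, abs=1e-8)

    def test_roundtrip_random(self, rng, constants):
        for _ in range(100):
            b = float(rng.uniform(0.01, 10.0))
            s = make_sensor(b)
            slope = glucose_calibration_slope(s, constants)
            rec = btilde_from_slope(slope, s.area_mm2, s.thickness_um, s.diff_glucose, constants)
            assert abs(rec - b) / b < 1e-8

    def test_small_slope_gives_small_btilde(self, sensor, constants):
        saturation = constants.f_eff * sensor.area_mm2 * sensor.diff_glucose / sensor.thickness_um
        assert btilde_from_slope(
            saturation * 1e-10, sensor.area_mm2, sensor.thickness_um,
            sensor.diff_glucose, constants,
        ) < 1e-4

    def test_saturated_or_invalid_slope_rejected(self, sensor, constants):
        saturation = constants.f_eff * sensor.area_mm2 * sensor.diff_glucose / sensor.thickness_um
        with pytest.raises(ValueError):
            btilde_from_slope(saturation, sensor.area_mm2, sensor.thickness_um,
                              sensor.diff_glucose, constants)
        with pytest.raises(ValueError):
            btilde_from_slope(0.0, sensor.area_mm2, sensor.thickness_um,
                              sensor.diff_glucose, constants)


def test_bulk_rate_scaling(sensor):
    # hydrogel-average rate rescaled by hydrogel/drop volume ratio
    q_gel = 10.0
    expected = q_gel * sensor.area_mm2 * sensor.thickness_um * 1e-3 / 6.5
    assert bulk_rate(q_gel, sensor, 6.5) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        bulk_rate(q_gel, sensor, 0.0)
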