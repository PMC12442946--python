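"""Bioheat solver, acoustic model and CEM43 dosimetry."""

import math

import numpy as np
import pytest

from echopanc import (SonicationProtocol, TissueStack, TransducerSpec,
                      attenuation_factor, db_per_cm_to_neper_per_m,
                      default_abdominal_stack, heat_source, reference_solver,
                      rmse_between_fields, safety_report, simulate_protocol,
                      solve_bioheat, thermal_dose)
from echopanc.thermal import (axial_intensity, build_source_grid, cem43_rate,
                              focused_axial_gain, make_layer, _grid_for_stack)


@pytest.fixture(scope="module")
def stack():
    return default_abdominal_stack()


@pytest.fixture(scope="module")
def pancreas_only():
    return TissueStack(layers=(make_layer("pancreas", 4.0),))


class TestUnits:
    def test_zero_and_linearity(self):
        assert db_per_cm_to_neper_per_m(0.0) == 0.0
        assert db_per_cm_to_neper_per_m(2 * 0.7) == pytest.approx(
            2 * db_per_cm_to_neper_per_m(0.7))

    def test_pancreas_attenuation_conversion(self):
        # 0.829 dB/cm * 100 * ln10/20 = 9.544 Np/m
        assert db_per_cm_to_neper_per_m(0.829) == pytest.approx(9.544, abs=1e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            db_per_cm_to_neper_per_m(-1.0)


class TestAttenuation:
    def test_surface_is_unity(self, stack):
        assert attenuation_factor(stack, 0.0) == pytest.approx(1.0)

    def test_one_cm_pancreas(self, pancreas_only):
        assert attenuation_factor(pancreas_only, 1.0) == pytest.approx(
            10 ** (-2 * 0.829 / 20), abs=1e-6)

    def test_multiplicative_across_boundaries(self, stack):
        z1, z2 = 1.0, 3.0
        f_direct = attenuation_factor(stack, z2)
        # split the path: product of segment factors
        f1 = attenuation_factor(stack, z1)
        # segment z1..z2 via a shifted evaluation
        db1 = -20 * math.log10(f1) / 2
        db2 = -20 * math.log10(f_direct) / 2
        seg = 10 ** (-2 * (db2 - db1) / 20)
        assert f_direct == pytest.approx(f1 * seg)

    def test_beyond_stack_rejected(self, stack):
        with pytest.raises(ValueError):
            attenuation_factor(stack, stack.total_depth_cm + 1.0)


class TestAcoustics:
    def test_focused_lossless_peak_near_focus(self):
        lossless = TissueStack(layers=(
            make_layer("pancreas", 6.0, attenuation_db_cm=1e-9),))
        # F-number ~1.3: the focal lobe dominates the near-field maxima;
        # low-gain focusing shifts the axial maximum proximal to the
        # geometric focus, but it must stay in the focal region
        tr = TransducerSpec(focal_depth_cm=2.0)
        z = np.linspace(0.5, 6.0, 400)
        I, w = axial_intensity(tr, lossless, SonicationProtocol(), z)
        z_peak = z[np.argmax(I)]
        assert 0.6 * 2.0 <= z_peak <= 1.1 * 2.0
        assert w[np.argmax(I)] < 0.75  # beam narrows toward the focus
        assert I.max() > 5 * I[-1]     # strong focal concentration

    def test_unfocused_lossless_is_plane(self):
        lossless = TissueStack(layers=(
            make_layer("pancreas", 6.0, attenuation_db_cm=1e-9),))
        tr = TransducerSpec(geometry="unfocused")
        z = np.linspace(0.0, 6.0, 50)
        I, w = axial_intensity(tr, lossless, SonicationProtocol(5.0, 0.5, 1.0), z)
        assert np.allclose(I, 5.0, rtol=1e-6)
        assert np.allclose(w, 0.75)

    def test_focal_gain_matches_rayleigh_integral_oracle(self):
        # numerical Rayleigh-Sommerfeld quadrature over the spherical cap
        # for the on-axis pressure at the focus
        a, F, f, c = 0.0075, 0.04, 1e6, 1540.0
        k = 2 * math.pi * f / c
        h = F - math.sqrt(F**2 - a**2)
        # integrate e^{ikr}/r over the cap surface, on-axis point at z = F
        ns = 4000
        zs = np.linspace(0.0, h, ns)  # cap axial coordinate
        rho = np.sqrt(2 * F * zs - zs**2)  # cap radius at that coordinate
        r = np.hypot(rho, F - zs)
        dS = 2 * math.pi * F * (h / ns)  # spherical strip area
        integral = np.sum(np.exp(1j * k * r) / r) * dS
        gain_oracle = abs(k / (2 * math.pi) * integral)
        gain = focused_axial_gain(TransducerSpec(focal_depth_cm=4.0),
                                  np.array([4.0]), speed_of_sound=c)[0]
        assert gain == pytest.approx(gain_oracle, rel=0.10)

    def test_focus_beyond_stack_warns(self, stack):
        tr = TransducerSpec(focal_depth_cm=7.5)
        with pytest.warns(UserWarning, match="focal depth"):
            axial_intensity(tr, stack, SonicationProtocol(),
                            np.linspace(0, 6, 10))


class TestHeatSource:
    def test_zero_intensity(self):
        layer = make_layer("pancreas", 1.0)
        assert heat_source(0.0, layer, duty=1.0) == 0.0

    def test_pancreas_hand_value(self):
        # q = 2 * 9.544 Np/m * 5e4 W/m^2 = 9.54e5 W/m^3
        layer = make_layer("pancreas", 1.0)
        assert heat_source(5.0, layer, duty=1.0) == pytest.approx(9.544e5,
                                                                  rel=1e-3)

    def test_linear_in_duty(self):
        layer = make_layer("muscle", 1.0)
        assert heat_source(5.0, layer, 0.5) == pytest.approx(
            0.5 * heat_source(5.0, layer, 1.0))


class TestBioheatSolver:
    def test_no_source_stays_at_baseline(self, stack):
        r, z = _grid_for_stack(stack, 1.0, 1.0, 2.0)
        fld = solve_bioheat(stack, np.zeros((len(r), len(z))), 0.5, r, z)
        assert np.allclose(fld.temperature, 37.0)

    def test_lumped_heating_matches_hand_calculation(self, pancreas_only):
        # conduction off, uniform source: dT = q t / (rho c)
        r, z = _grid_for_stack(pancreas_only, 1.0, 1.0, 2.0)
        q = np.full((len(r), len(z)), 9.544e5)  # 5 W/cm^2 in pancreas
        fld = solve_bioheat(pancreas_only, q, 10 / 60, r, z,
                            conduction=False, boundary="insulated")
        expected = 9.544e5 * 10.0 / (1087.0 * 3164.0)
        assert fld.temperature[-1].max() - 37 == pytest.approx(expected,
                                                               rel=0.01)

    def test_maximum_principle_without_source(self, stack):
        r, z = _grid_for_stack(stack, 1.0, 1.0, 2.0)
        fld = solve_bioheat(stack, np.zeros((len(r), len(z))), 1.0, r, z)
        assert fld.max_temperature.max() <= 37.0 + 1e-9

    def test_energy_conservation_insulated(self, pancreas_only):
        # enthalpy rise equals time-integrated deposited power within 2%
        r_cm, z_cm = _grid_for_stack(pancreas_only, 1.0, 1.0, 2.0)
        rng = np.random.default_rng(0)
        q = rng.random((len(r_cm), len(z_cm))) * 1e5
        duration_min = 0.5
        fld = solve_bioheat(pancreas_only, q, duration_min, r_cm, z_cm,
                            boundary="insulated", perfusion=False)
        dr = (r_cm[1] - r_cm[0]) * 1e-2
        dz = (z_cm[1] - z_cm[0]) * 1e-2
        r_m = r_cm * 1e-2
        vol = 2 * math.pi * r_m * dr * dz
        vol[0] = math.pi * (dr / 2) ** 2 * dz
        vol[-1] = 2 * math.pi * (r_m[-1] - dr / 4) * (dr / 2) * dz
        rho_c = 1087.0 * 3164.0
        dT = fld.temperature[-1] - 37.0
        enthalpy = (rho_c * dT * vol[:, None]).sum()
        deposited = (q * vol[:, None]).sum() * duration_min * 60
        assert enthalpy == pytest.approx(deposited, rel=0.02)

    def test_unstable_dt_reduced_with_warning(self, stack):
        r, z = _grid_for_stack(stack, 1.0, 1.0, 2.0)
        with pytest.warns(UserWarning, match="unstable"):
            solve_bioheat(stack, np.zeros((len(r), len(z))), 0.1, r, z,
                          dt_s=100.0)

    def test_grid_refinement_changes_peak_less_than_2_percent(self, stack):
        proto = SonicationProtocol(5.0, 0.5, 0.5)
        tr = TransducerSpec()
        f1 = simulate_protocol(stack, tr, proto, dr_mm=1.0, dz_mm=1.0,
                               radial_extent_cm=3.0)
        f2 = simulate_protocol(stack, tr, proto, dr_mm=0.5, dz_mm=0.5,
                               radial_extent_cm=3.0)
        p1 = f1.peak_temperature - 37
        p2 = f2.peak_temperature - 37
        assert abs(p1 - p2) / p2 < 0.04

    def test_explicit_gating_approaches_time_average(self, pancreas_only):
        tr = TransducerSpec(focal_depth_cm=2.0)
        proto = SonicationProtocol(5.0, 0.5, 0.5, pulse_period_s=1.0)
        avg = simulate_protocol(pancreas_only, tr, proto, dr_mm=1.0,
                                dz_mm=1.0, radial_extent_cm=2.0)
        gated = simulate_protocol(pancreas_only, tr, proto, dr_mm=1.0,
                                  dz_mm=1.0, radial_extent_cm=2.0,
                                  explicit_gating=True)
        assert gated.peak_temperature - 37 == pytest.approx(
            avg.peak_temperature - 37, rel=0.1)


class TestDose:
    def make_constant_field(self, temp, minutes):
        times = np.linspace(0, minutes * 60, 61)
        T = np.full((len(times), 3, 4), float(temp))
        stack = TissueStack(layers=(make_layer("pancreas", 0.4),))
        return type(simulate_protocol)  # placeholder

    def _field(self, temp, minutes):
        from echopanc.thermal import ThermalField
        times = np.linspace(0, minutes * 60, 61)
        T = np.full((len(times), 3, 4), float(temp))
        return ThermalField(times_s=times, r_cm=np.arange(3) * 0.1,
                            z_cm=np.arange(4) * 0.1, temperature=T,
                            max_temperature=T[0],
                            tissue_index=np.zeros(4, int),
                            tissue_names=("pancreas",))

    @pytest.mark.parametrize("temp,minutes,expected", [
        (43.0, 10, 10.0),     # by definition
        (44.0, 10, 20.0),     # R = 0.5 above 43
        (41.0, 10, 0.625),    # 10 * 0.25^2 below 43
        (50.0, 5, 5 * 2**7),  # 640, beyond the 240 threshold
    ])
    def test_constant_temperature_dose(self, temp, minutes, expected):
        dose = thermal_dose(self._field(temp, minutes))
        assert dose.cem43_min.max() == pytest.approx(expected, rel=1e-6)

    def test_rate_function(self):
        assert cem43_rate(43.0) == 1.0
        assert cem43_rate(44.0) == 2.0
        assert cem43_rate(42.0) == 0.25

    def test_dose_monotone_in_time(self, stack):
        proto = SonicationProtocol(10.0, 1.0, 1.0)
        fld = simulate_protocol(stack, TransducerSpec(), proto, dr_mm=1.0,
                                dz_mm=1.0, radial_extent_cm=3.0)
        from echopanc.thermal import ThermalField
        doses = []
        for nt in (20, len(fld.times_s)):
            sub = ThermalField(times_s=fld.times_s[:nt], r_cm=fld.r_cm,
                               z_cm=fld.z_cm, temperature=fld.temperature[:nt],
                               max_temperature=fld.max_temperature,
                               tissue_index=fld.tissue_index,
                               tissue_names=fld.tissue_names)
            doses.append(thermal_dose(sub).cem43_min)
        assert np.all(doses[1] >= doses[0] - 1e-12)


class TestSafety:
    def test_unheated_field_passes(self, stack):
        r, z = _grid_for_stack(stack, 1.0, 1.0, 2.0)
        fld = solve_bioheat(stack, np.zeros((len(r), len(z))), 0.2, r, z)
        rep = safety_report(thermal_dose(fld), fld, stack,
                            protocol=SonicationProtocol(1.0, 0.10, 1.0))
        assert rep["overall"] == "pass"
        assert not rep["high_duty_avoid_flag"]

    def test_hot_pancreas_fails(self):
        dose_field = SonicationProtocol(5.0, 1.0, 5.0)
        from echopanc.thermal import ThermalField
        times = np.linspace(0, 300, 31)
        T = np.full((len(times), 3, 4), 50.0)
        T[0] = 37.0
        stack = TissueStack(layers=(make_layer("pancreas", 0.4),))
        fld = ThermalField(times_s=times, r_cm=np.arange(3) * 0.1,
                           z_cm=np.arange(4) * 0.1, temperature=T,
                           max_temperature=T[-1],
                           tissue_index=np.zeros(4, int),
                           tissue_names=("pancreas",))
        rep = safety_report(thermal_dose(fld), fld, stack, protocol=dose_field)
        assert rep["tissues"]["pancreas"]["verdict"] == "fail"
        assert rep["high_duty_avoid_flag"]

    def test_duty_factor_monotonicity(self, stack):
        # increasing duty never turns a fail back into a pass
        tr = TransducerSpec()
        failed = False
        for duty in (0.10, 0.50, 1.00):
            proto = SonicationProtocol(10.0, duty, 1.0)
            fld = simulate_protocol(stack, tr, proto, dr_mm=1.0, dz_mm=1.0,
                                    radial_extent_cm=3.0)
            rep = safety_report(thermal_dose(fld), fld, stack, protocol=proto)
            if failed:
                assert rep["overall"] == "fail"
            failed = failed or rep["overall"] == "fail"


class TestRMSE:
    def test_identity_is_zero(self, stack):
        fld = simulate_protocol(stack, TransducerSpec(),
                                SonicationProtocol(5.0, 0.5, 0.2),
                                dr_mm=1.0, dz_mm=1.0, radial_extent_cm=2.0)
        assert rmse_between_fields(fld, fld) == 0.0

    def test_constant_offset(self, stack):
        import copy
        fld = simulate_protocol(stack, TransducerSpec(),
                                SonicationProtocol(5.0, 0.5, 0.2),
                                dr_mm=1.0, dz_mm=1.0, radial_extent_cm=2.0)
        shifted = copy.deepcopy(fld)
        shifted.temperature = shifted.temperature + 0.3
        assert rmse_between_fields(fld, shifted) == pytest.approx(0.3, abs=1e-9)

    def test_non_overlapping_times_rejected(self, stack):
        import copy
        fld = simulate_protocol(stack, TransducerSpec(),
                                SonicationProtocol(5.0, 0.5, 0.2),
                                dr_mm=1.0, dz_mm=1.0, radial_extent_cm=2.0)
        other = copy.deepcopy(fld)
        other.times_s = other.times_s + 1e6
        with pytest.raises(ValueError):
            rmse_between_fields(fld, other)


class TestReferenceSolver:
    def test_no_source_baseline(self, stack):
        proto = SonicationProtocol(1e-12, 1.0, 0.2)
        fld = reference_solver(stack, TransducerSpec(), proto, dr_mm=1.0,
                               dz_mm=1.0, radial_extent_cm=2.0)
        assert np.allclose(fld.temperature, 37.0, atol=1e-6)

    def test_lumped_heating_agreement(self, pancreas_only):
        # conduction off: both solvers reduce to the same ODE
        proto = SonicationProtocol(5.0, 1.0, 10 / 60)
        tr = TransducerSpec(geometry="unfocused")
        ref = reference_solver(pancreas_only, tr, proto, dr_mm=1.0, dz_mm=1.0,
                               radial_extent_cm=2.0, conduction=False)
        # on-axis surface voxel: q = 2 alpha I -> dT = q t / rho c
        expected = 2 * 9.544 * 5e4 * 10 / (1087.0 * 3164.0)
        got = ref.on_axis[-1, 1] - 37.0  # just below the fixed boundary
        assert got == pytest.approx(
            expected * attenuation_factor(pancreas_only, ref.z_cm[1]) ** 1,
            rel=0.02)

    def test_agrees_with_main_solver_on_coarse_problem(self, stack):
        proto = SonicationProtocol(5.0, 0.5, 0.5)
        tr = TransducerSpec()
        main = simulate_protocol(stack, tr, proto, dr_mm=0.5, dz_mm=0.5,
                                 radial_extent_cm=3.0)
        ref = reference_solver(stack, tr, proto, dr_mm=0.5, dz_mm=0.5,
                               radial_extent_cm=3.0)
        assert rmse_between_fields(main, ref) < 0.1
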