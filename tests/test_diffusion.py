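"""Transport model: diffusivity estimation, erf series, oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pherosim.diffusion import (
    CalibrationError,
    Geometry,
    HydrogelParams,
    InvalidParameterError,
    SecretionSource,
    TransportParams,
    calibrate_secretion_rate,
    concentration_profile,
    default_transport_params,
    estimate_stokes_einstein_d0,
    fd_reference_solver,
    hydrogel_corrected_d,
    induction_extent,
    secretion_concentration,
    step_source_concentration,
)

SIX_HOURS = 6 * 3600.0


class TestStokesEinstein:
    def test_reference_value(self):
        # Hand evaluation: r = (3 M vbar / (4 pi N_A))^(1/3) = 0.789 nm,
        # D = kT / (6 pi eta r) = 3.53e-4 mm^2/s at 303 K in water.
        d0 = estimate_stokes_einstein_d0(1700.0, 303.0, 7.97e-4, 0.73)
        assert d0 == pytest.approx(3.53e-4, rel=0.01)

    def test_viscosity_halves_diffusivity(self):
        base = estimate_stokes_einstein_d0(1700.0, 303.0, 7.97e-4, 0.73)
        doubled = estimate_stokes_einstein_d0(1700.0, 303.0, 2 * 7.97e-4, 0.73)
        assert doubled == pytest.approx(base / 2, rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(m1=st.floats(100.0, 1e5), factor=st.floats(1.01, 10.0))
    def test_decreasing_in_molecular_weight(self, m1, factor):
        d_small = estimate_stokes_einstein_d0(m1, 303.0, 7.97e-4, 0.73)
        d_large = estimate_stokes_einstein_d0(m1 * factor, 303.0, 7.97e-4, 0.73)
        assert d_large < d_small

    @pytest.mark.parametrize("bad", [(-1, 303, 1e-3, 0.7), (1700, 0, 1e-3, 0.7),
                                     (1700, 303, -1e-3, 0.7), (1700, 303, 1e-3, 0)])
    def test_rejects_nonpositive_arguments(self, bad):
        with pytest.raises(InvalidParameterError):
            estimate_stokes_einstein_d0(*bad)


class TestHydrogelCorrection:
    def test_vanishing_polymer_fraction_recovers_free_diffusivity(self):
        gel = HydrogelParams(polymer_volume_fraction=1e-12)
        assert hydrogel_corrected_d(1.0, gel) == pytest.approx(1.0, rel=1e-6)

    def test_default_agarose_factor(self):
        # Direct evaluation of the obstruction formula at the defaults:
        # exp(-pi ((0.7885+1.9)/(0.0064^-0.5 + 3.8))^2) = 0.9181.
        factor = hydrogel_corrected_d(1.0, HydrogelParams())
        assert 0.0 < factor < 1.0
        assert factor == pytest.approx(0.9181, abs=2e-4)

    def test_monotone_in_obstruction(self):
        lo = hydrogel_corrected_d(1.0, HydrogelParams(polymer_volume_fraction=0.005))
        hi = hydrogel_corrected_d(1.0, HydrogelParams(polymer_volume_fraction=0.02))
        assert hi < lo
        small = hydrogel_corrected_d(1.0, HydrogelParams(solute_radius=0.5))
        big = hydrogel_corrected_d(1.0, HydrogelParams(solute_radius=2.0))
        assert big < small

    @pytest.mark.parametrize("phi", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_invalid_volume_fraction(self, phi):
        with pytest.raises(InvalidParameterError):
            HydrogelParams(polymer_volume_fraction=phi)


class TestStepSource:
    def test_initial_step_is_exact(self, geom, transport):
        assert step_source_concentration(2.5, 0.0, geom, transport) == 10.0
        assert step_source_concentration(5.0, 0.0, geom, transport) == 5.0
        assert step_source_concentration(7.0, 0.0, geom, transport) == 0.0

    def test_short_time_limit_inside_source(self, geom, transport):
        assert step_source_concentration(2.5, 1e-3, geom, transport) == pytest.approx(
            10.0, rel=1e-9
        )

    def test_long_time_equilibrium(self, geom, transport):
        # Closed domain conserves mass: C -> C0 h / l = 5 uM everywhere.
        for x in [0.0, 3.0, 7.0, 10.0]:
            assert step_source_concentration(x, 5e5, geom, transport) == pytest.approx(
                5.0, rel=1e-6
            )

    def test_boundary_value_is_half_c0_at_early_times(self, geom, transport):
        # While the walls are unfelt the boundary sits at C0/2.
        for t in [60.0, 600.0, 3600.0]:
            c = step_source_concentration(geom.source_extent_h, t, geom, transport)
            assert c == pytest.approx(5.0, rel=0.01)

    def test_mass_conservation(self, geom, transport):
        xs = np.linspace(0.0, geom.domain_length_l, 2001)
        for t in [0.0, 600.0, 3600.0, SIX_HOURS, 48 * 3600.0]:
            c = step_source_concentration(xs, t, geom, transport)
            mass = np.trapezoid(c, xs)
            assert mass == pytest.approx(50.0, rel=1e-3)

    def test_profile_nonincreasing_in_x(self, geom, transport):
        xs = np.linspace(0.0, 10.0, 501)
        for t in [60.0, 3600.0, SIX_HOURS]:
            c = step_source_concentration(xs, t, geom, transport)
            assert np.all(np.diff(c) <= 1e-12)

    def test_series_truncation_converged(self, geom):
        xs = np.linspace(0.0, 10.0, 101)
        for t in [600.0, SIX_HOURS, 48 * 3600.0]:
            p12 = default_transport_params(n_image_terms=12)
            p24 = default_transport_params(n_image_terms=24)
            a = step_source_concentration(xs, t, geom, p12)
            b = step_source_concentration(xs, t, geom, p24)
            assert np.abs(a - b).max() <= 1e-9 * 10.0

    def test_domain_errors(self, geom, transport):
        with pytest.raises(InvalidParameterError):
            step_source_concentration(-0.1, 1.0, geom, transport)
        with pytest.raises(InvalidParameterError):
            step_source_concentration(10.5, 1.0, geom, transport)
        with pytest.raises(InvalidParameterError):
            step_source_concentration(1.0, -1.0, geom, transport)


class TestConcentrationProfile:
    def test_matches_pointwise_evaluation(self, geom, transport):
        field = concentration_profile([2.0, 7.5], [600.0, 3600.0], geom, transport)
        for i, t in enumerate(field.times):
            for j, x in enumerate(field.positions):
                assert field.values[i, j] == pytest.approx(
                    step_source_concentration(x, t, geom, transport), rel=1e-12
                )

    def test_time_slices_conserve_mass(self, geom, transport):
        xs = np.linspace(0.0, 10.0, 1001)
        field = concentration_profile(xs, [600.0, SIX_HOURS], geom, transport)
        for row in field.values:
            assert np.trapezoid(row, xs) == pytest.approx(50.0, rel=1e-3)

    def test_values_nonnegative(self, geom, transport):
        field = concentration_profile(
            np.linspace(0, 10, 201), [1.0, 60.0, SIX_HOURS], geom, transport
        )
        assert np.all(field.values >= 0.0)


class TestFiniteDifferenceOracle:
    def test_zero_everything_stays_zero(self, geom, transport):
        fld = fd_reference_solver(
            geom, transport.d_effective, lambda x: np.zeros_like(x), None, 600.0
        )
        assert np.all(fld.values == 0.0)

    def test_uniform_profile_is_equilibrium(self, geom, transport):
        fld = fd_reference_solver(
            geom, transport.d_effective, lambda x: np.full_like(x, 3.0), None, 3600.0,
            time_step=5.0,
        )
        assert np.abs(fld.values - 3.0).max() < 1e-10

    def test_explicit_scheme_rejects_unstable_step(self, geom, transport):
        with pytest.raises(InvalidParameterError):
            fd_reference_solver(
                geom, transport.d_effective, lambda x: np.zeros_like(x), None, 600.0,
                grid_spacing=0.05, time_step=100.0, method="explicit",
            )

    def test_grid_must_resolve_geometry(self, transport):
        geom = Geometry(source_extent_h=5.0, domain_length_l=10.0)
        with pytest.raises(InvalidParameterError):
            fd_reference_solver(
                geom, transport.d_effective, lambda x: np.zeros_like(x), None, 60.0,
                grid_spacing=0.07,
            )

    def test_series_agrees_with_crank_nicolson(self, geom, transport):
        # The central oracle-equivalence check: sup-norm within 1e-3 C0.
        h, c0 = geom.source_extent_h, transport.c0_initial
        step_ic = lambda x: np.where(x < h, c0, np.where(x == h, 0.5 * c0, 0.0))
        times = [600.0, 3600.0, SIX_HOURS]
        fld = fd_reference_solver(
            geom, transport.d_effective, step_ic, None, max(times),
            grid_spacing=0.05, time_step=1.0, save_times=times,
        )
        for i, t in enumerate(fld.times):
            series = step_source_concentration(fld.positions, t, geom, transport)
            assert np.abs(series - fld.values[i]).max() < 1e-3 * c0

    def test_source_mass_injection_conserved(self, geom, transport):
        q = 1e-4
        src = lambda x: np.where(x < 5.0, q, np.where(x == 5.0, q / 2, 0.0))
        fld = fd_reference_solver(
            geom, transport.d_effective, lambda x: np.zeros_like(x), src, 3600.0,
            time_step=2.0,
        )
        mass = np.trapezoid(fld.values[-1], fld.positions)
        injected = q * 5.0 * 3600.0
        assert mass == pytest.approx(injected, rel=1e-4)


class TestSecretionSource:
    def test_no_cells_no_signal(self, geom, transport):
        src = SecretionSource(od600=0.0, per_od_rate=1e-3)
        assert secretion_concentration(7.0, SIX_HOURS, geom, src, transport) == 0.0

    def test_exact_linearity_in_od(self, geom, transport):
        lo = SecretionSource(od600=0.1, per_od_rate=1e-3)
        hi = SecretionSource(od600=2.0, per_od_rate=1e-3)
        for x, t in [(3.0, 600.0), (5.0, 3600.0), (8.5, SIX_HOURS)]:
            a = secretion_concentration(x, t, geom, lo, transport)
            b = secretion_concentration(x, t, geom, hi, transport)
            assert b == pytest.approx(20.0 * a, rel=1e-12)

    def test_strictly_increasing_in_time(self, geom, transport):
        src = SecretionSource(od600=1.0, per_od_rate=1e-3)
        vals = [secretion_concentration(7.0, t, geom, src, transport)
                for t in [600.0, 3600.0, 2 * 3600.0, SIX_HOURS]]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_calibration_round_trip(self, geom, transport):
        q = calibrate_secretion_rate(geom, transport, 10.0, 0.75, SIX_HOURS)
        assert q > 0 and math.isfinite(q)
        src = SecretionSource(od600=0.75, per_od_rate=q)
        boundary = secretion_concentration(5.0, SIX_HOURS, geom, src, transport)
        target = step_source_concentration(5.0, SIX_HOURS, geom, transport)
        assert boundary == pytest.approx(target, rel=1e-6)

    def test_calibrated_boundary_matches_step_source(self, geom, transport):
        q = calibrate_secretion_rate(geom, transport)
        src = SecretionSource(od600=0.75, per_od_rate=q)
        a = secretion_concentration(5.0, SIX_HOURS, geom, src, transport)
        b = step_source_concentration(5.0, SIX_HOURS, geom, transport)
        assert abs(a - b) <= 0.1 * b

    def test_doubling_reference_doubles_rate(self, geom, transport):
        q1 = calibrate_secretion_rate(geom, transport, reference_c0=10.0)
        q2 = calibrate_secretion_rate(geom, transport, reference_c0=20.0)
        assert q2 == pytest.approx(2.0 * q1, rel=1e-12)

    def test_agrees_with_fd_solution(self, geom, transport):
        q = 1e-3
        src = SecretionSource(od600=1.0, per_od_rate=q)
        svec = lambda x: np.where(x < 5.0, q, np.where(x == 5.0, q / 2, 0.0))
        fld = fd_reference_solver(
            geom, transport.d_effective, lambda x: np.zeros_like(x), svec, SIX_HOURS,
            time_step=2.0,
        )
        for x in [2.0, 5.0, 7.0, 9.0]:
            duhamel = secretion_concentration(x, SIX_HOURS, geom, src, transport)
            grid = np.interp(x, fld.positions, fld.values[-1])
            assert duhamel == pytest.approx(grid, rel=2e-3)


class TestInductionExtent:
    def test_unreachable_threshold(self, geom, transport):
        assert induction_extent(SIX_HOURS, 50.0, geom, transport) == 0.0

    def test_tiny_threshold_fills_compartment(self, geom, transport):
        assert induction_extent(SIX_HOURS, 1e-12, geom, transport) == 5.0

    def test_wild_type_threshold_reached_beyond_4mm(self, geom, transport):
        # 10 nM = 0.01 uM threshold from a 10 uM source after six hours.
        extent = induction_extent(SIX_HOURS, 0.01, geom, transport)
        assert extent >= 4.0

    def test_intermediate_threshold_located_by_bisection(self, geom, transport):
        thr = 2.0  # uM: crossed inside the reporter compartment at 6 h
        d = induction_extent(SIX_HOURS, thr, geom, transport)
        assert 0.0 < d < 5.0
        c_at = step_source_concentration(5.0 + d, SIX_HOURS, geom, transport)
        assert c_at == pytest.approx(thr, rel=1e-3)

    def test_parameter_validation(self, geom, transport):
        with pytest.raises(InvalidParameterError):
            induction_extent(SIX_HOURS, -1.0, geom, transport)
        with pytest.raises(InvalidParameterError):
            induction_extent(0.0, 0.01, geom, transport)


class TestTypeValidation:
    def test_geometry_rejects_inverted_domain(self):
        with pytest.raises(InvalidParameterError):
            Geometry(source_extent_h=10.0, domain_length_l=5.0)

    def test_transport_requires_effective_below_free(self):
        with pytest.raises(InvalidParameterError):
            TransportParams(d0_free=1e-4, d_effective=2e-4)

    def test_calibration_error_on_zero_reference(self, geom, transport):
        with pytest.raises((CalibrationError, InvalidParameterError)):
            calibrate_secretion_rate(geom, transport, reference_c0=0.0)
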