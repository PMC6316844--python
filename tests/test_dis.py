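"""Derivative isotherm computation and DIS decomposition."""

import math

import numpy as np
import pytest

from claysorb.dis import (
    DEFAULT_U_MAX,
    GasIsotherm,
    LocalDomain,
    derivative_isotherm,
    domain_area,
    fit_dis,
    local_derivative,
    theta_local,
)
from claysorb.synthetic import gas_isotherm_scenario, gen_gas_isotherm


def gas_from_u(u, v):
    return GasIsotherm(tuple(np.exp(u)), tuple(v))


class TestDerivativeIsotherm:
    def test_linear_input_gives_constant_slope(self):
        u = np.linspace(-14.0, -3.0, 60)
        deriv = derivative_isotherm(gas_from_u(u, 5.0 + 0.75 * u))
        assert np.allclose(deriv.y_arr, 0.75, atol=1e-10)

    def test_logistic_peak_position_and_height(self):
        """Pure Langmuir uptake: derivative peaks at u0 with height V_m/4."""
        u0, v_m = -8.0, 2.0
        u = np.linspace(-16.0, -3.0, 400)
        v = v_m * np.exp(u - u0) / (1.0 + np.exp(u - u0))
        deriv = derivative_isotherm(gas_from_u(u, v))
        i = np.argmax(deriv.y_arr)
        assert deriv.u_arr[i] == pytest.approx(u0, abs=2 * (u[1] - u[0]))
        assert deriv.y_arr[i] == pytest.approx(v_m / 4.0, rel=1e-3)

    def test_noisy_derivative_tracks_analytic_curve(self):
        """Instrument-level noise: derivative within 3% RMS of the truth."""
        dom = LocalDomain(1.0, -8.0, 1.5)
        scn = gas_isotherm_scenario(0, domains=((1.0, -8.0, 1.5),), noise=0.001)
        deriv = derivative_isotherm(gen_gas_isotherm(scn), smoothing_window=7)
        analytic = local_derivative(dom, deriv.u_arr)
        rms = math.sqrt(np.mean((deriv.y_arr - analytic) ** 2))
        assert rms / analytic.max() < 0.03

    def test_window_larger_than_series_rejected(self):
        u = np.linspace(-10, -4, 12)
        with pytest.raises(ValueError, match="window"):
            derivative_isotherm(gas_from_u(u, np.ones_like(u)), smoothing_window=15)


class TestLocalDerivative:
    def test_logistic_case_peak(self):
        dom = LocalDomain(2.0, -7.0, 0.0)
        u = np.linspace(-14, -1, 800)
        y = local_derivative(dom, u)
        assert y.max() == pytest.approx(2.0 / 4.0, rel=1e-4)
        assert u[np.argmax(y)] == pytest.approx(-7.0, abs=0.02)

    def test_omega_two_at_half_coverage(self):
        # at theta = 1/2: dv/du = v_m / (4 - omega) = v_m / 2
        dom = LocalDomain(1.0, -6.0, 2.0)
        assert local_derivative(dom, np.array([-6.0]))[0] == pytest.approx(0.5, rel=1e-6)

    def test_integral_conserves_monolayer_capacity(self):
        dom = LocalDomain(1.7, -8.0, 2.5)
        u = np.linspace(-30.0, -1e-6, 20000)
        integral = np.trapezoid(local_derivative(dom, u), u)
        theta_span = float(
            theta_local(u[-1], dom.u_half, dom.omega)[0]
            - theta_local(u[0], dom.u_half, dom.omega)[0]
        )
        assert integral == pytest.approx(dom.v_m * theta_span, rel=1e-3)
        assert integral == pytest.approx(dom.v_m, rel=1e-3)

    def test_bisection_matches_forward_table_inversion(self):
        """theta(u) from bisection vs the forward map u(theta) inverted by
        dense table lookup (independent brute-force oracle)."""
        u_half, omega = -7.0, 3.0
        theta_tab = np.linspace(1e-9, 1 - 1e-9, 2_000_001)
        u_tab = u_half + np.log(theta_tab / (1 - theta_tab)) - omega * (theta_tab - 0.5)
        u = np.linspace(-12.0, -2.0, 101)
        theta_lookup = np.interp(u, u_tab, theta_tab)
        theta_bis = theta_local(u, u_half, omega)
        assert np.max(np.abs(theta_bis - theta_lookup)) < 1e-8

    def test_peak_height_nondecreasing_in_omega(self):
        u = np.linspace(-14, -1, 2000)
        heights = [
            local_derivative(LocalDomain(1.0, -7.0, w), u).max()
            for w in (0.0, 1.0, 2.0, 3.0, 3.9)
        ]
        assert all(b >= a for a, b in zip(heights, heights[1:]))
        assert all(h >= 0 for h in heights)

    def test_omega_at_four_rejected(self):
        with pytest.raises(ValueError):
            LocalDomain(1.0, -7.0, 4.0)
        with pytest.raises(ValueError, match="multivalued"):
            theta_local(np.array([-5.0]), -7.0, 4.5)


class TestFitDIS:
    def test_single_domain_noise_free_recovery(self):
        scn = gas_isotherm_scenario(0, domains=((1.0, -8.0, 1.5),), noise=0.0)
        dec = fit_dis(derivative_isotherm(gen_gas_isotherm(scn)), 1)
        d = dec.domains[0]
        assert abs(d.v_m - 1.0) < 5e-3
        assert abs(d.u_half + 8.0) / 8.0 < 5e-3
        assert abs(d.omega - 1.5) / 1.5 < 5e-3

    def test_residual_nonincreasing_in_n_domains(self):
        deriv = derivative_isotherm(gen_gas_isotherm(gas_isotherm_scenario(1)))
        rms1 = fit_dis(deriv, 1).residual_rms
        rms2 = fit_dis(deriv, 2).residual_rms
        assert rms2 <= rms1 * (1 + 1e-9)

    def test_over_parameterization_rejected(self):
        u = np.linspace(-10, -4, 14)
        v = 1.0 / (1.0 + np.exp(-(u + 7)))
        deriv = derivative_isotherm(gas_from_u(u, v), smoothing_window=3)
        with pytest.raises(ValueError, match="over-parameterized"):
            fit_dis(deriv, 5, u_max=None)

    def test_edge_labels_respect_split_override(self):
        dec = fit_dis(
            derivative_isotherm(gen_gas_isotherm(gas_isotherm_scenario(0, noise=0.0))),
            2,
            split_u=-8.5,
        )
        labels = [d.label for d in dec.domains]
        assert labels == ["edge", "basal"]
        assert dec.edge_fraction == pytest.approx(0.3, abs=0.01)


class TestDomainArea:
    def test_zero_capacity_zero_area(self):
        assert domain_area(LocalDomain(0.0, -5.0, 0.0)) == 0.0

    def test_one_mole_unit_arithmetic(self):
        # 22414 cm^3 STP = 1 mol -> N_A * 0.138 nm^2 = 8.31e4 m^2/g
        area = domain_area(LocalDomain(22414.0, -5.0, 0.0))
        assert area == pytest.approx(8.31e4, rel=1e-3)

    def test_domain_areas_sum_to_total_on_single_domain_data(self):
        scn = gas_isotherm_scenario(2, domains=((0.8, -8.0, 1.0),), noise=0.0)
        dec = fit_dis(
            derivative_isotherm(gen_gas_isotherm(scn)), 1, cross_section_nm2=0.138
        )
        total = domain_area(LocalDomain(dec.total_v_m, -8.0, 1.0))
        assert sum(dec.areas) == pytest.approx(total, rel=0.01)
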