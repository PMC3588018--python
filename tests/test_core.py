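"""Pointwise physics: Langevin function, permittivity law, ion and headgroup
densities.  Frozen expected values come from independent arbitrary-precision
evaluation of the closed forms; property tests check the structural
invariants (oddness, bounds, normalization, limits)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlpb.constants import CONSTANTS
from mlpb.core import (
    gamma_factor,
    headgroup_charge_density,
    headgroup_probability,
    ion_charge_density,
    ion_number_densities,
    langevin,
    langevin_over_u,
    onsager_permittivity,
    polarization,
    relative_permittivity,
)
from mlpb.parameters import ModelParameters, dppc_gel


class TestLangevin:
    @pytest.mark.parametrize(
        ("u", "expected"),
        [
            (0.0, 0.0),
            (1.0, 0.3130352854993313),     # coth(1) - 1, 30-digit evaluation
            (10.0, 0.9000000041223073),    # coth(10) - 1/10
            (-1.0, -0.3130352854993313),
        ],
    )
    def test_reference_values(self, u, expected):
        assert langevin(u) == pytest.approx(expected, abs=1e-14)

    def test_matches_closed_form_away_from_zero(self):
        u = np.concatenate([np.geomspace(1e-3, 50, 200), -np.geomspace(1e-3, 50, 200)])
        closed = 1.0 / np.tanh(u) - 1.0 / u
        assert np.max(np.abs(langevin(u) - closed)) < 1e-12

    def test_continuous_at_series_switch(self):
        # branch mismatch across the series/closed-form threshold must sit at
        # roundoff level, far below the series truncation error
        for u0 in (1e-2, -1e-2):
            lo, hi = u0 * (1 - 1e-12), u0 * (1 + 1e-12)
            assert abs(langevin(lo) - langevin(hi)) < 1e-12

    @given(st.floats(min_value=-50, max_value=50, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_odd_and_bounded(self, u):
        val = langevin(u)
        assert -1.0 < val < 1.0
        assert langevin(-u) == pytest.approx(-val, abs=1e-15)

    def test_strictly_increasing(self):
        u = np.linspace(-30, 30, 2001)
        assert np.all(np.diff(langevin(u)) > 0)

    def test_ratio_limit_at_zero(self):
        assert langevin_over_u(0.0) == pytest.approx(1.0 / 3.0, abs=1e-16)
        u = np.geomspace(1e-6, 50, 100)
        ratio = langevin_over_u(u)
        # closed-form roundoff near the series threshold is O(eps/u^2) ~ 1e-8
        assert np.all(ratio <= 1.0 / 3.0 * (1 + 1e-8))
        smooth = u > 1e-3
        assert np.all(np.diff(ratio[smooth]) < 0)


class TestGammaFactor:
    @pytest.mark.parametrize(
        ("n_refr", "expected"),
        [(1.33, 1.884450), (1.0, 1.5), (np.sqrt(7.0), 4.5)],
    )
    def test_values(self, n_refr, expected):
        assert gamma_factor(n_refr) == pytest.approx(expected, abs=1e-9)


class TestPolarization:
    def test_zero_field(self, room_params):
        assert polarization(0.0, room_params) == 0.0

    def test_saturation_plateau(self, room_params):
        p = room_params
        plateau = p.n0w * (2 + p.n_squared) / 3 * p.p0
        # L(u) = 1 - 1/u + O(exp): at E = 1e15 V/m, u ~ 5e6
        assert polarization(1e15, p) == pytest.approx(plateau, rel=1e-6)

    def test_reference_value(self, room_params):
        # 30-digit independent evaluation at E = 1e8 V/m, 298 K
        assert polarization(1e8, room_params) == pytest.approx(
            0.066933988133128143, rel=1e-12
        )

    def test_monotone_in_field(self, room_params):
        E = np.geomspace(1e3, 1e11, 300)
        assert np.all(np.diff(polarization(E, room_params)) > 0)


class TestPermittivity:
    def test_bulk_value_at_room_temperature(self, room_params):
        # the model's headline bulk value: 78.5 at 298 K
        assert onsager_permittivity(room_params) == pytest.approx(78.5, abs=0.05)

    def test_strong_field_limit_is_electronic(self, room_params):
        assert relative_permittivity(1e14, room_params) == pytest.approx(
            room_params.n_squared, rel=1e-3
        )

    def test_reference_value_310K(self, gel_params):
        # 30-digit independent evaluation at E = 1e7 V/m, 310 K
        assert relative_permittivity(1e7, gel_params) == pytest.approx(
            75.508085595233681, rel=1e-12
        )

    def test_zero_field_equals_onsager_exactly(self, gel_params):
        assert relative_permittivity(0.0, gel_params) == onsager_permittivity(gel_params)

    def test_strictly_decreasing_bounded_below(self, gel_params):
        E = np.geomspace(1e2, 1e12, 500)
        eps = relative_permittivity(E, gel_params)
        assert np.all(np.diff(eps) < 0)
        assert np.all(eps > gel_params.n_squared)

    def test_continuous_at_series_switch(self, gel_params):
        # field at which u crosses the series threshold
        u_switch = 1e-2
        E0 = u_switch / (gamma_factor(gel_params.n_refr) * gel_params.p0 * gel_params.beta)
        lo = relative_permittivity(E0 * (1 - 1e-9), gel_params)
        hi = relative_permittivity(E0 * (1 + 1e-9), gel_params)
        assert abs(lo - hi) / lo < 1e-9

    def test_onsager_vanishing_dipole(self):
        p = dppc_gel().replace(p0=1e-45)  # effectively dipole-free water
        assert onsager_permittivity(p) == pytest.approx(1.33**2, abs=1e-6)

    def test_bulk_permittivity_decreases_with_temperature(self, gel_params, liquid_params):
        assert onsager_permittivity(gel_params) == pytest.approx(75.5, abs=0.1)
        assert onsager_permittivity(liquid_params) == pytest.approx(72.6, abs=0.1)


class TestIonDensities:
    def test_zero_potential(self, gel_params):
        np_, nm_ = ion_number_densities(0.0, gel_params)
        assert np_ == pytest.approx(gel_params.n0)
        assert nm_ == pytest.approx(gel_params.n0)

    def test_unit_thermal_potential(self, gel_params):
        phi = -1.0 / (CONSTANTS.e0 * gel_params.beta)  # -kT/e0
        np_, nm_ = ion_number_densities(phi, gel_params)
        assert np_ == pytest.approx(gel_params.n0 * np.e, rel=1e-12)
        assert nm_ == pytest.approx(gel_params.n0 / np.e, rel=1e-12)

    def test_minus_60mV_exponent(self, gel_params):
        # e0 * 0.060 / (kB * 310) evaluated independently = 2.24603576546
        np_, _ = ion_number_densities(-0.060, gel_params)
        assert np_ == pytest.approx(gel_params.n0 * np.exp(2.24603576546), rel=1e-9)

    @given(st.floats(min_value=-0.5, max_value=0.5))
    @settings(max_examples=100, derandomize=True)
    def test_mass_action_product(self, phi):
        p = dppc_gel()
        np_, nm_ = ion_number_densities(phi, p)
        assert np_ * nm_ == pytest.approx(p.n0**2, rel=1e-12)

    def test_overflow_guard(self, gel_params):
        with pytest.raises(OverflowError):
            ion_number_densities(1e3, gel_params)

    def test_charge_density_sign_and_linearization(self, gel_params):
        p = gel_params
        assert ion_charge_density(0.0, p) == 0.0
        assert ion_charge_density(-0.05, p) > 0  # counter-ion excess
        # Debye-Hueckel limit: rho ~ -2 e0^2 n0 beta phi + O(phi^3)
        phi = 1e-5
        lin = -2 * CONSTANTS.e0**2 * p.n0 * p.beta * phi
        u = CONSTANTS.e0 * phi * p.beta
        assert ion_charge_density(phi, p) == pytest.approx(lin * (1 + u * u / 6), rel=1e-9)
        assert ion_charge_density(phi, p) == pytest.approx(
            -ion_charge_density(-phi, p), rel=1e-12
        )


class TestHeadgroupProbability:
    def test_flat_potential_gives_uniform_density(self, gel_params):
        x = np.linspace(0, gel_params.D, 201)
        for alpha in (None, 0.5, 7.0):
            prob, lam = headgroup_probability(x, np.zeros_like(x), gel_params, alpha=alpha)
            assert np.allclose(prob, 1.0)
            # Lambda compensates the constant lattice factor alpha/(alpha+1)
            lam_exact = 1.0 if alpha is None else (alpha + 1.0) / alpha
            assert lam == pytest.approx(lam_exact, rel=1e-12)

    def test_linear_potential_closed_form(self, gel_params):
        # phi = c x: Lambda = D k / (1 - exp(-k D)) with k = e0 c beta
        p = gel_params
        c = 2e8  # V/m slope, thermal-scale variation over D
        x = np.linspace(0, p.D, 4001)
        prob, lam = headgroup_probability(x, c * x, p)
        k = CONSTANTS.e0 * c * p.beta
        lam_exact = p.D * k / (1.0 - np.exp(-k * p.D))
        assert lam == pytest.approx(lam_exact, rel=1e-7)
        assert prob[0] == pytest.approx(lam_exact, rel=1e-7)

    @pytest.mark.parametrize("alpha", [None, 1e-3, 0.1, 1.0, 10.0, 1e3])
    def test_normalization(self, gel_params, alpha):
        p = gel_params
        x = np.linspace(0, p.D, 2001)
        phi = -0.05 * np.exp(-x / p.D)  # arbitrary bounded profile
        prob, _ = headgroup_probability(x, phi, p, alpha=alpha)
        assert np.all(prob >= 0)
        assert np.trapezoid(prob, x) / p.D == pytest.approx(1.0, abs=1e-8)

    def test_lattice_limits(self, gel_params):
        p = gel_params
        x = np.linspace(0, p.D, 2001)
        phi = -0.06 * (1 - x / p.D)
        boltz, _ = headgroup_probability(x, phi, p, alpha=None)
        tiny, _ = headgroup_probability(x, phi, p, alpha=1e-8)
        huge, _ = headgroup_probability(x, phi, p, alpha=1e8)
        assert np.max(np.abs(tiny / boltz - 1)) < 1e-6
        assert np.max(np.abs(huge - 1)) < 1e-6

    def test_invalid_inputs(self, gel_params):
        x = np.linspace(0, gel_params.D, 11)
        with pytest.raises(ValueError):
            headgroup_probability(x, np.full_like(x, np.nan), gel_params)
        with pytest.raises(ValueError):
            headgroup_probability(x, np.zeros(5), gel_params)
        with pytest.raises(ValueError):
            headgroup_probability(x, np.zeros_like(x), gel_params, alpha=-1.0)


class TestHeadgroupChargeDensity:
    def test_uniform_density_value_and_support(self, gel_params):
        p = gel_params
        inside = CONSTANTS.e0 / (p.D * p.a0)
        assert headgroup_charge_density(1.0, 0.5 * p.D, p) == pytest.approx(inside)
        assert headgroup_charge_density(1.0, 1.5 * p.D, p) == 0.0

    def test_integral_is_minus_sigma(self, gel_params):
        p = gel_params
        x = np.linspace(0, p.D, 3001)
        phi = -0.05 * np.exp(-3 * x / p.D)
        prob, _ = headgroup_probability(x, phi, p)
        rho = headgroup_charge_density(prob, x, p)
        assert np.trapezoid(rho, x) == pytest.approx(-p.sigma, rel=1e-8)


class TestModelParameters:
    def test_derived_quantities(self, gel_params):
        assert gel_params.sigma < 0
        assert gel_params.sigma == pytest.approx(-CONSTANTS.e0 / 0.48e-18)
        assert gel_params.beta == pytest.approx(1 / (CONSTANTS.kB * 310.0))

    @pytest.mark.parametrize(
        "bad",
        [
            {"T": -1.0},
            {"a0": 0.0},
            {"D": 20e-9},  # D >= L
            {"p0": -1e-30},
            {"n0w": 0.0},
            {"n_refr": 0.9},
            {"alpha": -2.0},
        ],
    )
    def test_invalid_parameters_rejected(self, gel_params, bad):
        with pytest.raises(ValueError):
            gel_params.replace(**bad)
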