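"""Potentials, Boltzmann densities and barrier-crossing kinetics."""

import numpy as np
import pytest
from scipy.linalg import expm

from smfretsim.landscapes import (
    BistableLandscape,
    HarmonicLandscape,
    RateResult,
    TabulatedLandscape,
    ThermoState,
    barrier_height,
    boltzmann_density,
    bs_transition_rate,
    evaluate_gradient,
    evaluate_potential,
    partition_function,
    symmetric_rate_matrix,
    transition_matrix,
    two_state_harmonic_density,
)


class TestPotentials:
    @pytest.mark.parametrize(
        "land,r,expected",
        [
            (HarmonicLandscape(0.025, 40.0), 40.0, 0.0),
            (HarmonicLandscape(0.025, 40.0), 50.0, 1.25),     # k/2 * 10^2
            (BistableLandscape(1e-4, 50.0, 15.0), 50.0, 1.265625),
            (BistableLandscape(1e-4, 50.0, 15.0), 35.0, 0.0),
            (BistableLandscape(1e-4, 50.0, 15.0), 65.0, 0.0),
        ],
    )
    def test_potential_values(self, land, r, expected):
        assert evaluate_potential(land, r) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "land,r,expected",
        [
            (BistableLandscape(1e-4, 50.0, 15.0), 35.0, 0.0),
            (BistableLandscape(1e-4, 50.0, 15.0), 65.0, 0.0),
            (BistableLandscape(1e-4, 50.0, 15.0), 50.0, 0.0),  # symmetric barrier top
            (HarmonicLandscape(0.025, 40.0), 50.0, 0.25),      # k (r - rc)
        ],
    )
    def test_gradient_values(self, land, r, expected):
        assert evaluate_gradient(land, r) == pytest.approx(expected, abs=1e-12)

    def test_gradient_matches_finite_difference(self, bistable):
        r = np.linspace(20.0, 80.0, 37)
        h = 1e-6
        fd = (bistable.potential(r + h) - bistable.potential(r - h)) / (2 * h)
        np.testing.assert_allclose(bistable.gradient(r), fd, atol=1e-6)

    def test_non_finite_rejected(self, harmonic40):
        with pytest.raises(ValueError):
            evaluate_potential(harmonic40, np.nan)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HarmonicLandscape(k_harmonic=-1.0, center=0.0)
        with pytest.raises(ValueError):
            BistableLandscape(k_bistable=1e-4, center=50.0, well_offset=0.0)


class TestBarrierHeight:
    def test_example_landscape(self, bistable):
        assert barrier_height(bistable) == pytest.approx(1.265625, abs=1e-12)

    def test_linearity_in_force_constant(self):
        b1 = BistableLandscape(1e-4, 50.0, 15.0)
        b2 = BistableLandscape(2e-4, 50.0, 15.0)
        assert barrier_height(b2) == pytest.approx(2 * barrier_height(b1))

    def test_requires_bistable(self, harmonic40):
        with pytest.raises(TypeError):
            barrier_height(harmonic40)


class TestTabulated:
    def test_interpolation_and_range_error(self, bistable, thermo_ex2):
        grid = np.linspace(10.0, 90.0, 401)
        tab = TabulatedLandscape(grid, bistable.potential(grid))
        r = np.linspace(12.0, 88.0, 57)
        np.testing.assert_allclose(tab.potential(r), bistable.potential(r), atol=5e-3)
        with pytest.raises(ValueError):
            tab.potential(5.0)

    def test_finite_difference_gradient(self, bistable):
        grid = np.linspace(10.0, 90.0, 2001)
        tab = TabulatedLandscape(grid, bistable.potential(grid))
        r = np.array([30.0, 45.0, 60.0])
        np.testing.assert_allclose(tab.gradient(r), bistable.gradient(r), atol=1e-3)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            TabulatedLandscape([0.0, 1.0, 1.0], [0.0, 0.0, 0.0])


class TestBoltzmannDensity:
    def test_symmetry_of_bistable(self, bistable, thermo_ex2):
        assert boltzmann_density(bistable, thermo_ex2, 35.0) == pytest.approx(
            boltzmann_density(bistable, thermo_ex2, 65.0), rel=1e-10)

    @pytest.mark.parametrize("land_name", ["harmonic40", "bistable"])
    def test_normalization(self, land_name, thermo_ex2, request):
        land = request.getfixturevalue(land_name)
        grid = np.linspace(0.0, 150.0, 40001)
        dens = boltzmann_density(land, thermo_ex2, grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)
        assert dens.min() >= 0

    def test_two_harmonic_closed_form(self, harmonic40, harmonic65, thermo_ex1):
        # hand evaluation: 0.5 sqrt(beta k / 2 pi) (1 + exp(-beta V2(40)))
        val = two_state_harmonic_density(harmonic40, harmonic65, thermo_ex1, 40.0)
        beta, k = 1.339, 0.025
        expected = 0.5 * np.sqrt(beta * k / (2 * np.pi)) * (
            1.0 + np.exp(-beta * 0.5 * k * 25.0**2))
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(0.0365, abs=2e-4)

    def test_pair_normalization(self, harmonic40, harmonic65, thermo_ex1):
        grid = np.linspace(0.0, 150.0, 40001)
        dens = boltzmann_density((harmonic40, harmonic65), thermo_ex1, grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)


class TestTransitionRates:
    def test_symmetric_landscape_gives_equal_rates(self, bistable, thermo_ex2):
        k_fwd = bs_transition_rate(bistable, thermo_ex2, 0.002, 50.0, 35.0, 65.0)
        k_rev = bs_transition_rate(bistable, thermo_ex2, 0.002, 50.0, 65.0, 35.0)
        assert k_fwd == pytest.approx(k_rev, rel=1e-8)

    def test_linear_in_diffusion_coefficient(self, bistable, thermo_ex2):
        k1 = bs_transition_rate(bistable, thermo_ex2, 0.002, 50.0, 35.0, 65.0)
        k2 = bs_transition_rate(bistable, thermo_ex2, 0.004, 50.0, 35.0, 65.0)
        assert k2 == pytest.approx(2 * k1, rel=1e-8)

    def test_high_barrier_matches_kramers(self):
        # steeper double well: beta*dV = 1.679 * 0.25 * 4e-4 * 15^4 ~ 8.5
        land = BistableLandscape(4e-4, 50.0, 15.0)
        thermo = ThermoState(beta=1.679)
        rate = bs_transition_rate(land, thermo, 0.002, 50.0, 35.0, 65.0)
        beta, D = thermo.beta, 0.002
        k_well = float(land.curvature(35.0))
        k_barr = abs(float(land.curvature(50.0)))
        dV = barrier_height(land)
        kramers = beta * D / (2 * np.pi) * np.sqrt(k_well * k_barr) * np.exp(-beta * dV)
        kramers *= 1e6  # 1/ns -> 1/ms
        assert rate == pytest.approx(kramers, rel=0.10)

    def test_matches_dense_trapezoid_oracle(self, bistable, thermo_ex2):
        # brute-force evaluation of the double integral on a 10^6-point grid
        beta, D = thermo_ex2.beta, 0.002
        x = np.linspace(-50.0, 50.0 + 1e-9, 1_000_001)
        w = np.exp(-beta * bistable.potential(x))
        pop = np.trapezoid(w, x)
        y = np.linspace(35.0, 65.0, 1_000_001)
        flux = np.trapezoid(np.exp(beta * bistable.potential(y)) / D, y)
        oracle = 1e6 / (pop * flux)
        rate = bs_transition_rate(bistable, thermo_ex2, D, 50.0, 35.0, 65.0)
        assert rate == pytest.approx(oracle, rel=1e-3)

    def test_interval_well_specification(self, bistable, thermo_ex2):
        k_point = bs_transition_rate(bistable, thermo_ex2, 0.002, 50.0, 35.0, 65.0)
        k_range = bs_transition_rate(bistable, thermo_ex2, 0.002, 50.0,
                                     (25.0, 45.0), (55.0, 75.0))
        assert k_range == pytest.approx(k_point, rel=1e-6)


class TestTransitionMatrix:
    def test_zero_lag_is_identity(self):
        rr = transition_matrix(symmetric_rate_matrix(0.5), tau=0.0)
        np.testing.assert_allclose(rr.T, np.eye(2), atol=1e-12)

    def test_symmetric_closed_form(self):
        q = 0.032128
        rr = transition_matrix(symmetric_rate_matrix(q), tau=1.0)
        off = (1.0 - np.exp(-2 * q)) / 2.0
        assert rr.T[0, 1] == pytest.approx(off, rel=1e-10)
        assert rr.T[0, 1] == pytest.approx(0.031117, abs=1e-6)

    @pytest.mark.parametrize("tau", [0.0, 0.3, 1.0, 7.5])
    def test_rows_sum_to_one_and_nonnegative(self, tau):
        Q = np.array([[-0.4, 0.4], [0.1, -0.1]])
        rr = transition_matrix(Q, tau=tau)
        np.testing.assert_allclose(rr.T.sum(axis=1), 1.0, atol=1e-10)
        assert rr.T.min() >= 0

    def test_semigroup_property(self):
        Q = np.array([[-0.4, 0.4], [0.1, -0.1]])
        t1 = transition_matrix(Q, tau=0.7).T
        t2 = transition_matrix(Q, tau=1.6).T
        t12 = transition_matrix(Q, tau=2.3).T
        np.testing.assert_allclose(t1 @ t2, t12, atol=1e-9)

    def test_malformed_q_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(np.array([[-0.5, 0.4], [0.1, -0.1]]), tau=1.0)
        with pytest.raises(ValueError):
            transition_matrix(symmetric_rate_matrix(0.5), tau=-1.0)

    def test_rate_result_validation(self):
        with pytest.raises(ValueError):
            RateResult(Q=np.array([[-1.0, 1.0], [1.0, -1.0]]), tau=1.0,
                       T=np.array([[0.9, 0.2], [0.1, 0.9]]))
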