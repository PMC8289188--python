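"""Closed-form model functions against trivial values and ODE oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from pomamyloid.models import (
    BindingParams,
    IsodesmicParams,
    QuenchParams,
    RateConcParams,
    action_volume_to_radius,
    binding_fraction,
    binding_fraction_depletion,
    isodesmic_extent,
    isodesmic_extent_reversible,
    radius_to_action_volume,
    rate_vs_conc,
    sphere_of_action_ratio,
    titration_signal,
)


def ode_extent(t_grid, a, b):
    """Independent oracle: integrate dp/dt = a(1-p)^2 - b p numerically."""
    sol = solve_ivp(
        lambda _, p: a * (1 - p) ** 2 - b * p,
        (0.0, float(t_grid[-1])),
        [0.0],
        t_eval=t_grid,
        rtol=1e-10,
        atol=1e-12,
        method="LSODA",
    )
    return sol.y[0]


class TestIsodesmicExtent:
    @pytest.mark.parametrize(
        "t, k, expected",
        [(0.0, 0.7, 0.0), (0.0, 0.0, 0.0), (1.0, 1.0, 0.5), (9.0, 1.0, 0.9)],
    )
    def test_known_values(self, t, k, expected):
        assert isodesmic_extent(t, k) == pytest.approx(expected, abs=1e-12)

    def test_matches_ode_oracle_irreversible(self):
        t = np.linspace(0, 150, 301)
        p = isodesmic_extent(t, 0.2)
        assert np.max(np.abs(p - ode_extent(t, 0.2, 0.0))) < 1e-6

    def test_monotone_and_bounded(self):
        t = np.linspace(0, 500, 1000)
        p = isodesmic_extent(t, 0.3)
        assert np.all(np.diff(p) > 0)
        assert np.all(p < 1.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            isodesmic_extent(-1.0, 0.1)
        with pytest.raises(ValueError):
            isodesmic_extent(1.0, -0.1)


class TestIsodesmicReversible:
    def test_matches_ode_oracle_example(self):
        # k_f*c0 = 0.3 /h, k_b = 0.05 /h
        t = np.linspace(0, 150, 301)
        params = IsodesmicParams(k_f=0.3 / 75.0, k_b=0.05, c0=75.0)
        p = isodesmic_extent_reversible(t, params)
        assert np.max(np.abs(p - ode_extent(t, 0.3, 0.05))) < 1e-5

    def test_matches_ode_oracle_random_draws(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0, 150, 151)
        for _ in range(20):
            a = rng.uniform(0.01, 1.0)
            b = rng.uniform(0.0, 0.5)
            params = IsodesmicParams(k_f=a, k_b=b, c0=1.0)
            p = isodesmic_extent_reversible(t, params)
            assert np.max(np.abs(p - ode_extent(t, a, b))) < 1e-5

    def test_zero_backward_rate_equals_irreversible(self):
        t = np.linspace(0, 150, 200)
        params = IsodesmicParams(k_f=0.004, k_b=0.0, c0=75.0)
        np.testing.assert_array_equal(
            isodesmic_extent_reversible(t, params), isodesmic_extent(t, 0.3)
        )

    def test_small_backward_rate_converges_to_irreversible(self):
        t = np.linspace(0, 150, 200)
        params = IsodesmicParams(k_f=0.3, k_b=1e-8, c0=1.0)
        diff = isodesmic_extent_reversible(t, params) - isodesmic_extent(t, 0.3)
        assert np.max(np.abs(diff)) < 1e-4

    def test_equilibrium_extent_below_one(self):
        params = IsodesmicParams(k_f=0.3, k_b=0.05, c0=1.0)
        p = isodesmic_extent_reversible(np.array([1e6]), params)
        assert 0.0 < p[0] < 1.0

    def test_starts_at_zero(self):
        params = IsodesmicParams(k_f=0.3, k_b=0.05, c0=1.0)
        assert isodesmic_extent_reversible(0.0, params) == 0.0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            IsodesmicParams(k_f=-0.1, k_b=0.0, c0=1.0)
        with pytest.raises(ValueError):
            IsodesmicParams(k_f=0.1, k_b=0.0, c0=0.0)


class TestRateVsConc:
    def test_limits(self):
        p = RateConcParams(alpha=0.2, beta=0.05, gamma=0.01)
        assert rate_vs_conc(0.0, p) == pytest.approx(0.21)
        assert rate_vs_conc(1e9, p) == pytest.approx(0.01)

    def test_beta_zero_is_constant(self):
        p = RateConcParams(alpha=0.2, beta=0.0, gamma=0.01)
        c = np.linspace(0, 750, 20)
        np.testing.assert_allclose(rate_vs_conc(c, p), 0.21)

    def test_decreasing_for_inhibitor(self):
        p = RateConcParams(alpha=0.2, beta=0.005, gamma=0.01)
        k = rate_vs_conc(np.linspace(0, 750, 50), p)
        assert np.all(np.diff(k) < 0)

    def test_scale_parameterization(self):
        p_rate = RateConcParams(alpha=0.2, beta=0.005, gamma=0.01)
        p_scale = RateConcParams(alpha=0.2, beta=200.0, gamma=0.01)
        c = np.linspace(0, 750, 10)
        np.testing.assert_allclose(
            rate_vs_conc(c, p_rate, "rate"), rate_vs_conc(c, p_scale, "scale")
        )

    def test_negative_conc_rejected(self):
        with pytest.raises(ValueError):
            rate_vs_conc(-1.0, RateConcParams(0.2, 0.05, 0.01))


class TestBinding:
    @pytest.mark.parametrize("c, Kd, expected", [(0.0, 2.5, 0.0), (2.5, 2.5, 0.5), (22.5, 2.5, 0.9)])
    def test_known_fractions(self, c, Kd, expected):
        assert binding_fraction(c, Kd) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(Kd=st.floats(0.01, 100.0), scale=st.floats(0.1, 100.0))
    def test_fraction_monotone_and_bounded(self, Kd, scale):
        c = np.linspace(0, scale * Kd, 50)
        theta = binding_fraction(c, Kd)
        assert np.all((theta >= 0) & (theta < 1))
        assert np.all(np.diff(theta) > 0)
        assert binding_fraction(Kd, Kd) == 0.5

    def test_invalid_kd(self):
        with pytest.raises(ValueError):
            binding_fraction(1.0, 0.0)

    def test_titration_signal_endpoints(self):
        p = BindingParams(Kd=2.5, S0=100.0, Sinf=40.0)
        assert titration_signal(0.0, p) == pytest.approx(100.0)
        assert titration_signal(1e9, p) == pytest.approx(40.0, rel=1e-6)
        assert titration_signal(2.5, p) == pytest.approx(70.0)

    def test_depletion_reduces_to_langmuir_at_high_protein_excess_ligand(self):
        # with negligible protein the total ligand is the free ligand
        c = np.linspace(0.0, 25.0, 20)
        theta_dep = binding_fraction_depletion(c, Kd=2.5, protein_conc=1e-9)
        np.testing.assert_allclose(theta_dep, binding_fraction(c, 2.5), rtol=1e-6)

    def test_depletion_theta_below_langmuir(self):
        # binding removes free ligand, so the bound fraction lags behind
        c = np.linspace(0.5, 25.0, 20)
        theta_dep = binding_fraction_depletion(c, Kd=2.5, protein_conc=4.0)
        assert np.all(theta_dep < binding_fraction(c, 2.5))


class TestSphereOfAction:
    def test_no_quencher(self):
        assert sphere_of_action_ratio(0.0, QuenchParams(Ksv=5.0, V=1.0)) == 1.0

    def test_linear_limit_exact(self):
        Q = np.linspace(0, 0.5, 11)
        ratio = sphere_of_action_ratio(Q, QuenchParams(Ksv=5.0, V=0.0))
        np.testing.assert_array_equal(ratio, 1.0 + 5.0 * Q)

    def test_closed_form_oracle(self):
        # independent evaluation with V computed from r = 7.7 A by direct
        # arithmetic: V = 6.02214076e23 * (4/3)*pi*(0.77e-9 m)^3 * 1e3 L/m^3
        V = 6.02214076e23 * (4.0 / 3.0) * np.pi * (0.77e-9) ** 3 * 1e3
        expected = (1.0 + 5.24 * 0.1) * np.exp(V * 0.1)
        params = QuenchParams(Ksv=5.24, V=float(radius_to_action_volume(7.7)))
        assert sphere_of_action_ratio(0.1, params) == pytest.approx(expected, rel=1e-10)

    def test_convex_when_static_term_present(self):
        Q = np.linspace(0, 0.5, 20)
        ratio = sphere_of_action_ratio(Q, QuenchParams(Ksv=5.24, V=1.15))
        assert np.all(np.diff(ratio, 2) > 0)


class TestVolumeRadiusConversion:
    def test_radius_7p7_oracle(self):
        # direct arithmetic with Avogadro's number (litre-based convention)
        expected = 6.02214076e23 * (4.0 / 3.0) * np.pi * (0.77) ** 3 * 1e-24
        assert radius_to_action_volume(7.7) == pytest.approx(expected, rel=1e-12)
        assert radius_to_action_volume(7.7) == pytest.approx(1.1516, rel=1e-4)

    def test_zero_radius(self):
        assert radius_to_action_volume(0.0) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(r=st.floats(1e-3, 100.0))
    def test_round_trip_identity(self, r):
        assert action_volume_to_radius(radius_to_action_volume(r)) == pytest.approx(
            r, rel=1e-10
        )

    def test_monotone_bijection(self):
        r = np.linspace(0.0, 50.0, 200)
        V = radius_to_action_volume(r)
        assert np.all(np.diff(V) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            radius_to_action_volume(-1.0)
        with pytest.raises(ValueError):
            action_volume_to_radius(-1.0)
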