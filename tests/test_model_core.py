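"""Unit tests for the reaction kinetics and analytic helpers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliovasc import (
    DomainError,
    ModelParameters,
    ParameterError,
    SimulationState,
    Variant,
    angiogenic_activation,
    homogeneous_oxygen_steady_state,
    reaction_terms,
    smooth_heaviside,
    switch_fractions,
)


def state_of(rho, v, sigma):
    to = lambda a: np.atleast_1d(np.asarray(a, dtype=float))
    return SimulationState(t=0.0, rho=to(rho), v=to(v), sigma=to(sigma))


class TestSwitchFractions:
    @pytest.mark.parametrize(
        "sigma, lambda1, lambda2, alpha_expected",
        [
            (1.0, 2.0, 1.0, 0.5),            # f21 = f12 = 1 by symmetry
            (0.0, 2.0, 1.0, 1.0),            # anoxia: fully migratory
            (0.0, 5.0, 3.0, 1.0),
            (0.25, 2.0, 2.0, 1.75 / 2.25),   # hand evaluation of the closed form
        ],
    )
    def test_closed_form(self, sigma, lambda1, lambda2, alpha_expected):
        p = ModelParameters(lambda1=lambda1, lambda2=lambda2)
        fr = switch_fractions(sigma, p)
        assert fr.alpha == pytest.approx(alpha_expected, rel=1e-12)
        assert fr.beta == pytest.approx(1.0 - alpha_expected, rel=1e-12)

    @given(
        sigma=st.floats(0.0, 2.0),
        lambda2=st.floats(0.01, 10.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_partition_of_unity_and_bounds(self, sigma, lambda2):
        p = ModelParameters(lambda1=2.0, lambda2=lambda2)
        fr = switch_fractions(sigma, p)
        assert fr.alpha + fr.beta == 1.0  # exact by construction
        assert 0.0 <= fr.alpha <= 1.0
        assert 0.0 <= fr.beta <= 1.0

    def test_alpha_strictly_decreasing_in_oxygen(self, default_params):
        sigma = np.linspace(0.0, default_params.lambda1 * 0.999, 200)
        alpha = switch_fractions(sigma, default_params).alpha
        assert np.all(np.diff(alpha) < 0)
        beta = switch_fractions(sigma, default_params).beta
        assert np.all(np.diff(beta) > 0)

    def test_out_of_range_oxygen_rejected(self, default_params):
        with pytest.raises(DomainError):
            switch_fractions(-0.5, default_params)
        with pytest.raises(DomainError):
            switch_fractions(default_params.lambda1 + 0.5, default_params)

    @given(
        lambda1=st.floats(1.1, 10.0),
        lambda2=st.floats(0.05, 10.0),
        sigma0=st.floats(0.1, 1.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_normalisation_recovers_intrinsic_rates(self, lambda1, lambda2, sigma0):
        """D_rho*alpha(sigma0) == D and b_rho*beta(sigma0) == b exactly."""
        p = ModelParameters(lambda1=lambda1, lambda2=lambda2, sigma0=sigma0)
        alpha0, beta0 = switch_fractions(sigma0, p)
        assert (p.D / alpha0) * alpha0 == pytest.approx(p.D, rel=1e-14)
        assert (p.b / beta0) * beta0 == pytest.approx(p.b, rel=1e-14)


class TestSmoothHeaviside:
    def test_midpoint_and_saturation(self):
        assert smooth_heaviside(0.0, 0.3) == pytest.approx(0.5)
        assert smooth_heaviside(-10 * 0.3, 0.3) >= 0.9999
        assert smooth_heaviside(+10 * 0.3, 0.3) <= 0.0001

    def test_monotone_decreasing(self):
        xi = np.linspace(-1, 1, 101)
        h = smooth_heaviside(xi, 0.05)
        assert np.all(np.diff(h) < 0)

    def test_converges_to_step(self):
        for xi, target in ((-0.2, 1.0), (0.2, 0.0)):
            vals = [smooth_heaviside(xi, th) for th in (0.1, 0.01, 0.001)]
            errors = [abs(v - target) for v in vals]
            assert errors == sorted(errors, reverse=True)
            assert errors[-1] < 1e-10

    def test_rejects_nonpositive_steepness(self):
        with pytest.raises(ParameterError):
            smooth_heaviside(0.1, 0.0)


class TestReactionTerms:
    def test_healthy_tissue_fixed_point(self, default_params):
        """No tumour, normal vasculature, physiological oxygen: nothing moves."""
        p = default_params
        s = state_of(0.0, p.v0, p.sigma0)
        r = reaction_terms(s, p, Variant.III)
        assert np.all(r.rho == 0)
        assert np.all(r.v == 0)
        assert np.all(r.sigma == 0)

    def test_logistic_rate_at_physiological_oxygen(self):
        """beta(sigma0) cancels by normalisation: rate = b*rho*(1-rho/N)."""
        p = ModelParameters(sigma0=1.0, lambda1=2.0, lambda2=1.0)
        s = state_of(p.N / 2, p.v0, p.sigma0)
        for variant in (Variant.I, Variant.II):
            r = reaction_terms(s, p, variant)
            assert r.rho[0] == pytest.approx(p.b * p.N / 4, rel=1e-12)

    def test_occlusion_magnitude_at_capacity(self):
        """g2*v*rho^n = 5e-13 * 0.5 * 100^6 = 0.25/day at full density."""
        p = ModelParameters(g2=5.0e-13, n=6, g1=0.0)
        s = state_of(100.0, 0.5, p.sigma0)
        r = reaction_terms(s, p, Variant.III)
        # rho = N: logistic term vanishes, v-rate is pure occlusion
        assert r.v[0] == pytest.approx(-0.25, rel=1e-12)

    def test_occlusion_steepness_ratio(self, default_params):
        """With n=6 occlusion at rho=N is 2^6 = 64x that at rho=N/2."""
        p = default_params.with_updates(g1=0.0)
        at = lambda rho: -reaction_terms(state_of(rho, 0.5, 0.1), p, Variant.III).v[0]
        assert at(p.N) / at(p.N / 2) == pytest.approx(64.0, rel=1e-12)

    def test_hierarchy_limits_match(self, default_params):
        """III with g1=g2=0 reduces to II; II with h2=0 reduces to I (rho)."""
        rng = np.random.default_rng(7)
        p3 = default_params.with_updates(g1=0.0, g2=0.0)
        rho = rng.uniform(0, p3.N, 32)
        v = rng.uniform(0, 1, 32)
        sigma = rng.uniform(0, p3.sigma0, 32)
        s = SimulationState(0.0, rho, v, sigma)
        r3 = reaction_terms(s, p3, Variant.III)
        r2 = reaction_terms(s, p3, Variant.II)
        assert np.allclose(r3.rho, r2.rho, rtol=1e-14)
        assert np.allclose(r3.sigma, r2.sigma, rtol=1e-14)
        assert np.all(r3.v == 0)

        p2 = default_params.with_updates(h2=0.0)
        s0 = SimulationState(0.0, rho, v, np.full(32, p2.sigma0))
        r2b = reaction_terms(s0, p2, Variant.II)
        r1 = reaction_terms(s0, p2, Variant.I)
        assert np.allclose(r2b.rho, r1.rho, rtol=1e-14)
        # at sigma = sigma0 and h2 = 0 the oxygen equation is inert
        assert np.allclose(r2b.sigma, 0.0, atol=1e-14)

    def test_variant_i_oxygen_inert(self, default_params):
        s = state_of(50.0, 0.3, 0.5)
        r = reaction_terms(s, default_params, "I")
        assert np.all(r.sigma == 0)
        assert np.all(r.v == 0)

    def test_unknown_variant_and_negative_inputs_rejected(self, default_params):
        s = state_of(1.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            reaction_terms(s, default_params, "IV")
        with pytest.raises(DomainError):
            reaction_terms(state_of(-1.0, 0.5, 0.5), default_params, "III")


class TestAngiogenicActivation:
    @given(
        rho=st.floats(0.0, 100.0),
        sigma=st.floats(0.0, 1.0),
        v=st.floats(0.0, 1.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_bounded_unit_interval(self, rho, sigma, v, default_params):
        m = angiogenic_activation(rho, sigma, v, default_params)
        assert 0.0 <= m <= 1.0

    def test_limits(self, default_params):
        p = default_params
        # saturates to 1 as vessels vanish with hypoxic cells present
        assert angiogenic_activation(50.0, 0.0, 1e-12, p) == pytest.approx(1.0, abs=1e-9)
        # no cells -> no pro-angiogenic factor -> no activation
        assert angiogenic_activation(0.0, 0.0, 0.5, p) == 0.0
        # degenerate point 0/0 defined as 0
        assert angiogenic_activation(0.0, 0.0, 0.0, p) == 0.0
        # well-oxygenated tissue produces (almost) nothing
        assert angiogenic_activation(50.0, p.sigma0, 0.5, p) < 1e-10


class TestOxygenSteadyState:
    def test_closed_form_examples(self, default_params):
        p = default_params
        assert homogeneous_oxygen_steady_state(0.0, 0.5, p) == pytest.approx(p.sigma0)
        assert homogeneous_oxygen_steady_state(100.0, 0.0, p) == 0.0
        got = homogeneous_oxygen_steady_state(100.0, 0.5, p)
        assert got == pytest.approx(0.1685 / 0.7415, rel=1e-9)

    def test_matches_long_time_ode_integration(self, default_params):
        """Independent oracle: integrate the uniform oxygen ODE to t=1e3."""
        from scipy.integrate import solve_ivp

        p = default_params
        rho, v = 40.0, 0.7

        def ode(t, y):
            return [p.h1 * v * (p.sigma0 - y[0]) - p.h2 * rho * y[0]]

        sol = solve_ivp(ode, (0, 1e3), [p.sigma0], rtol=1e-10, atol=1e-13)
        assert sol.y[0, -1] == pytest.approx(
            homogeneous_oxygen_steady_state(rho, v, p), rel=1e-8
        )

    def test_degenerate_input_rejected(self):
        p = ModelParameters(h2=0.0)
        with pytest.raises(DomainError):
            homogeneous_oxygen_steady_state(10.0, 0.0, p)


class TestModelParameters:
    def test_invariant_violations_all_reported(self):
        with pytest.raises(ParameterError) as err:
            ModelParameters(lambda1=0.5, sigma0=1.0, v0=1.5)
        msg = str(err.value)
        assert "lambda1" in msg and "v0" in msg

    def test_hierarchy_rates_may_be_zero(self):
        p = ModelParameters(g1=0.0, g2=0.0, h2=0.0)
        assert p.g1 == p.g2 == p.h2 == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            ModelParameters(D=-1.0)
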