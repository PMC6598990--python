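"""Chebyshev collocation, the reduced ODE system, and its Jacobian spectrum."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sddestab as sd
from sddestab import pseudospectral as ps
from sddestab.equilibria import trivial_equilibrium
from sddestab.sd_dde_core import HistoryPair, integrate, rhs_F


class TestNodesAndMatrix:
    def test_smallest_discretisations(self):
        np.testing.assert_allclose(ps.cheb_nodes(1, 2.0), [0.0, -2.0], atol=1e-15)
        np.testing.assert_allclose(ps.cheb_nodes(2, 2.0), [0.0, -1.0, -2.0],
                                   atol=1e-15)

    def test_endpoints_for_any_M(self):
        for M in (1, 4, 9, 16):
            nodes = ps.cheb_nodes(M, 3.7)
            assert nodes[0] == 0.0
            assert nodes[-1] == pytest.approx(-3.7, abs=1e-14)
            assert np.all(np.diff(nodes) < 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ps.cheb_nodes(0, 1.0)
        with pytest.raises(ValueError):
            ps.cheb_nodes(3, -1.0)

    def test_differentiation_matrix_basics(self):
        disc = ps.ChebyshevDiscretisation.build(8, 2.0)
        D = ps.diff_matrix(disc)
        assert np.max(np.abs(D.sum(axis=1))) < 1e-12          # constants
        np.testing.assert_allclose(D @ disc.nodes, np.ones(9), atol=1e-12)

    def test_two_point_matrix_entries(self):
        h = 1.7
        disc = ps.ChebyshevDiscretisation.build(1, h)
        np.testing.assert_allclose(disc.D, [[1 / h, -1 / h], [1 / h, -1 / h]],
                                   atol=1e-14)

    @given(st.integers(2, 10))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_exact_on_monomials_up_to_degree_M(self, M):
        disc = ps.ChebyshevDiscretisation.build(M, 1.3)
        for k in range(M + 1):
            vals = disc.nodes ** k
            deriv = k * disc.nodes ** (k - 1) if k else np.zeros(M + 1)
            np.testing.assert_allclose(disc.D @ vals, deriv, atol=1e-9)


class TestInterpolation:
    def test_reproduces_polynomials_and_nodal_values(self, rng):
        disc = ps.ChebyshevDiscretisation.build(7, 2.0)
        coeffs = rng.standard_normal(8)
        poly = np.polynomial.Polynomial(coeffs)
        vals = poly(disc.nodes)
        for th in rng.uniform(-2.0, 0.0, 50):
            assert ps.interp_eval(vals, disc, float(th)) == pytest.approx(
                poly(th), rel=1e-11, abs=1e-11)
        for k, node in enumerate(disc.nodes):
            assert ps.interp_eval(vals, disc, float(node)) == vals[k]

    def test_spectral_accuracy_on_exponential(self):
        disc = ps.ChebyshevDiscretisation.build(15, 1.0)
        vals = np.exp(disc.nodes)
        th = np.linspace(-1.0, 0.0, 101)
        err = np.max(np.abs(ps.interp_eval(vals, disc, th) - np.exp(th)))
        assert err < 1e-10

    def test_domain_error(self):
        disc = ps.ChebyshevDiscretisation.build(4, 1.0)
        with pytest.raises(ValueError):
            ps.interp_eval(np.ones(5), disc, 0.5)


class TestReducedSystem:
    def test_equilibrium_state_gives_zero_vector(self, fixed_delay_cfg,
                                                 fixed_delay_eq):
        disc = ps.ChebyshevDiscretisation.build(10, 3.0)
        state = ps.discrete_equilibrium(fixed_delay_eq, disc)
        out = ps.assemble_rhs(state, fixed_delay_cfg)
        assert np.max(np.abs(out)) < 1e-10

    def test_constant_non_equilibrium_state(self, fixed_delay_cfg):
        disc = ps.ChebyshevDiscretisation.build(10, 3.0)
        state = ps.DiscreteState(w=np.full(11, 1.2), v=np.full(11, 0.8), disc=disc)
        out = ps.assemble_rhs(state, fixed_delay_cfg)
        F = rhs_F(HistoryPair.constant(1.2, 0.8, 3.0), fixed_delay_cfg)
        assert out[0] == pytest.approx(F[0], rel=1e-12)
        assert out[11] == pytest.approx(F[1], rel=1e-12)
        assert np.max(np.abs(out[1:11])) < 1e-12
        assert np.max(np.abs(out[12:])) < 1e-12

    def test_perturbing_one_node_breaks_equilibrium(self, fixed_delay_cfg,
                                                    fixed_delay_eq):
        disc = ps.ChebyshevDiscretisation.build(10, 3.0)
        state = ps.discrete_equilibrium(fixed_delay_eq, disc)
        state.v[4] += 0.05
        out = ps.assemble_rhs(state, fixed_delay_cfg)
        assert np.max(np.abs(out)) > 1e-4

    def test_interior_rows_are_exact_interpolant_derivatives(self, fixed_delay_cfg,
                                                             rng):
        disc = ps.ChebyshevDiscretisation.build(9, 3.0)
        w = rng.uniform(0.5, 1.5, 10)
        v = rng.uniform(0.5, 1.5, 10)
        state = ps.DiscreteState(w=w, v=v, disc=disc)
        out = ps.assemble_rhs(state, fixed_delay_cfg)
        np.testing.assert_allclose(out[1:10], (disc.D @ w)[1:], atol=1e-12)
        np.testing.assert_allclose(out[11:], (disc.D @ v)[1:], atol=1e-12)


class TestSpectrum:
    def test_trivial_equilibrium_roots(self, fixed_delay_cfg):
        eigs = ps.jacobian_eigenvalues(fixed_delay_cfg,
                                       trivial_equilibrium(fixed_delay_cfg), M=15)
        q0 = fixed_delay_cfg.stem.q(0.0)
        assert np.min(np.abs(eigs - q0)) < 1e-8
        assert np.min(np.abs(eigs + fixed_delay_cfg.stem.mu)) < 1e-8

    def test_conjugate_pair_on_analytic_boundary(self):
        from sddestab import analytic_boundary as ab
        eta = tau = 1.5
        lo, hi = ab.parametrisation_interval(eta)
        omega = lo + 0.8 * (hi - lo)
        m, r = ab.boundary_point(omega, eta)
        mu, p = ab.to_mu_p((m, r), tau, 1.0, 0.9)
        cfg = sd.scenario("(s)_d,(pv)_0", mu=mu, p=p, tau=tau)
        eigs = ps.jacobian_eigenvalues(cfg, M=15)
        lead = eigs[0]
        assert abs(lead.real) < 1e-6
        assert abs(abs(lead.imag) - omega / tau) < 1e-6

    def test_sign_agrees_with_analytic_verdict_on_grid(self):
        # stability verdict of the rightmost eigenvalue against the closed
        # form over a (mu, p) grid of the fixed-delay scenario
        from sddestab.analytic_boundary import crossing_p_analytic
        tau = 1.5
        cfg = sd.scenario("(s)_d,(pv)_0", tau=tau)
        for mu in np.linspace(2.0, 9.0, 5):
            p_cross = crossing_p_analytic(mu, tau, 1.0, 0.9)
            for p in np.linspace(1.5, 25.0, 5):
                cfgi = cfg.with_(mu=float(mu), p=float(p))
                if cfgi.stem.q(0.0) <= 0:
                    continue
                lead = ps.jacobian_eigenvalues(cfgi, M=15)[0]
                analytically_stable = (p_cross is None) or (p < p_cross)
                if abs(p - (p_cross or np.inf)) / p < 1e-3:
                    continue  # too close to the boundary to call
                assert (lead.real < 0) == analytically_stable

    def test_physical_filter_flags_leading_pair(self, fixed_delay_cfg):
        flags = ps.filter_physical(fixed_delay_cfg, M=15, n_check=4)
        assert flags[0]["physical"] and flags[1]["physical"]


class TestReducedDynamics:
    def test_ode_path_tracks_delay_integrator(self, fixed_delay_cfg,
                                              fixed_delay_eq):
        eq = fixed_delay_eq
        h = 2 * eq.tau_eq
        w0, v0 = 1.05 * eq.w, 0.95 * eq.v
        path = integrate(HistoryPair.constant(w0, v0, h), fixed_delay_cfg, 10.0)
        disc = ps.ChebyshevDiscretisation.build(15, h)
        st0 = ps.DiscreteState(w=np.full(16, w0), v=np.full(16, v0), disc=disc)
        sol = ps.integrate_ode(st0, fixed_delay_cfg, 10.0)
        ts = np.linspace(1.0, 10.0, 10)
        werr = max(abs(float(path.w(t)) - float(sol.sol(t)[0])) for t in ts)
        verr = max(abs(float(path.v(t)) - float(sol.sol(t)[16])) for t in ts)
        assert werr < 1e-4 and verr < 1e-4
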